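# Methods

## Scope and estimand

`seqmonitor` analyzes two-arm parallel-group trials with a binary endpoint
and equal-probability (Bernoulli) randomization. The estimand throughout
is the odds ratio of the event between intervention and control; looks are
indexed by *responders* — participants with observed follow-up — so
non-responders never occupy a look slot. The `responded` flag on each
record lets users index by randomized participants instead when follow-up
is immediate.

## Frequentist machinery

At a look of n responders the 2×2 table is formed from the first n
responding records in accrual order. Inference is Wald-type on the log
odds ratio: SE = √(Σ 1/cell), log-symmetric CI, two-sided P from the
normal approximation. The OR, CI and P are therefore mutually consistent —
the geometric mean of the CI bounds is the point estimate, and the CI
excludes 1 exactly when p < α at the matching level. This consistency is
what the package's checks against published-style (OR, CI, P) triples
exercise; it is also why the Wald test was chosen over likelihood-ratio or
exact alternatives, which would decouple the three numbers.

Zero cells (inevitable in the first few looks) take the Haldane–Anscombe
correction: +0.5 on **all four** cells, applied only when some cell is
zero, with the estimate flagged `corrected`. Trajectories therefore have
no holes and start at `start_n = 2` by default, with a look at every
responder (`step = 1`). Significance uses the strict inequality p < α
(default .05); a P value exactly equal to α is non-significant. A crossing
is recorded wherever the significance state differs from the previous
look, with a first look that is already significant counting as a crossing
into significance.

## Bayesian monitor

The prior on β = log OR is normal with mean 0 and SD 0.2 (the *skeptical*
prior: OR 1 is the prior median, and ORs outside roughly [0.68, 1.48] sit
beyond ±2 prior SD). The scale is log-OR; "mean 0" is exactly "no effect".

**Conjugate engine (primary).** The Haldane-corrected Wald summary
(log OR, SE) feeds the normal–normal precision-weighted update. It is
deterministic and O(1) per look, so monitoring at every responder is
cheap. Shrinkage is the point: the posterior mean is always between the
prior mean and the sample log OR, and early looks with huge SEs barely
move the posterior — this is what protects against early false success
calls without any multiplicity correction.

**Grid engine (exact oracle).** The exact two-binomial likelihood with a
uniform prior on the control event probability p_c and the skeptical prior
on β, evaluated on a (β, p_c) grid (defaults 1201 × 401, extending ±8 SD
past both the prior and the Wald likelihood) and marginalized to β.
Decision probabilities use a centred-mass CDF with linear interpolation so
thresholds falling on or between grid points split mass correctly. A grid
that leaks more than 1e-6 posterior mass onto its β boundary raises an
error advising a finer/wider grid. MCMC is deliberately avoided — nothing
in this model requires it.

**Accuracy of the conjugate approximation.** On tables with all cells ≥ 5,
moderate event rates (p_c 0.3–0.5) and ORs in the prior-plausible range
(0.75–2), the two engines agree to within 0.017 in P(OR > 1) and 0.008 in
median OR over the package's fixed 60-table suite. At low event rates
(p_c ≈ 0.2 and below) the exact marginal posterior is visibly skewed by
the uniform nuisance prior — even a perfectly balanced null table such as
(12, 48, 12, 48) has exact P(OR > 1) ≈ 0.478 rather than 0.5 — and the
normal approximation can deviate by ~0.03 in P(OR > 1). Users monitoring
rare events should prefer `method="grid"`.

**Decision rules.** Success when P(OR > 1) > 0.95; futility when
P(1/1.25 < OR < 1.25) > 0.95. Both inequalities are strict, both
thresholds and bounds are parameters, and success is checked before
futility if both fire at one look (an arbitrary, documented tie-break).
Looks cease at the first stop. With no data the posterior is the prior:
P(success) = 0.5 exactly and P(futility) = 2Φ(ln 1.25 / 0.2) − 1 ≈ 0.7354,
so neither rule can fire before data accrue.

**Calibration.** Under a vague prior (SD 10) the conjugate 95% credible
interval behaves like the Wald interval and covers the true log OR at the
nominal rate (the package's calibration check uses 500 simulated trials of
535 participants at OR 1.8). Under the *skeptical* prior the same interval
deliberately under-covers for true effects far from the null — at OR 1.8
the truth lies ~3 prior SD out, shrinkage pulls the posterior mean roughly
halfway to zero at n ≈ 535, and frequentist coverage drops below 50%. That
is the designed behaviour of a skeptical prior, not an implementation
artifact: it trades coverage at implausible effect sizes for protection
against early overclaiming.

## Bootstrap extension

`extend` appends n_extra records drawn i.i.d. with replacement from the
responding records, copying (arm, outcome) pairs; accrual indices continue
after the original maximum. Default is unstratified resampling (arm sizes
drift binomially); `stratify_by_arm=True` draws outcomes within arm under
alternating allocation. Non-responders are excluded from the pool. The
extension is a thought experiment — "pretend the next 400 participants
resemble those we already have" — not a bootstrap CI procedure.

## Synthetic trials

`generate` draws arm ~ Bernoulli(allocation), outcome ~ Bernoulli(p_arm),
responded ~ Bernoulli(1 − attrition_prob), all independent, in a fixed
draw order from one `numpy.random.default_rng(seed)` stream, so a config
reproduces its trial bit-exactly. The intervention probability is derived
from (p_control, true OR) on the odds scale, exactly. Regime drift maps
accrual segments to control probabilities while holding the OR fixed on
the odds scale, keeping the estimand stable across regimes. Attrition is
missing-completely-at-random; informative attrition, covariates, blocked
randomization and non-binary endpoints are out of scope.

Two presets mimic the *designs* of the package's motivating examples — a
535-participant school-based smoking-cessation messaging trial with
substantial follow-up attrition (preset: p_control 0.25, OR 1.8, attrition
0.2) and a 560-participant nested alcohol text-message experiment with an
immediately observed outcome (p_control 0.30, OR 1.1, no attrition). The
event probabilities and ORs are synthetic package defaults chosen as
plausible for such interventions; they are **not** estimates of any real
trial's data.

What the generator does *not* emulate: correlated outcomes, secular trends
other than piecewise drift, informative missingness, or measurement error.
Passing tests on these synthetic trials show the machinery is correct
under the stated model, not that any real trial satisfies that model.

## Operating characteristics

`run_oc` simulates `reps` trials with per-rep seeds `base_seed + rep` and
analyzes each by (i) naive peeking — ever p < α over the schedule, (ii) a
single final look, and (iii) the Bayesian monitor, all on identical data
(a paired design, chosen for variance reduction and clean ≤ comparisons).
Default desk-scale problem sizes: 1000 replicates of a 500-participant
null trial with looks at every responder from n = 20, which runs in a few
seconds thanks to a cumulative-sum vectorized trajectory path. Typical
results at these sizes: naive ever-crossing rate ≈ 0.35, single-look rate
≈ 0.05, Bayesian false-success rate ≈ 0.03.

## Numerical and design notes

- Trajectory points are computed by the same scalar code path as a
  one-shot analysis, so recomputation at any look is bit-identical; the
  vectorized path is reserved for Monte-Carlo internals.
- All probabilities come from `scipy.stats`; no hand-rolled distributions.
- Per-responder look schedules always include the final look even when the
  step does not land on it.
- The CLI writes a JSON manifest per run (resolved config, seeds, paths,
  version, timestamp); `rerun_manifest` reproduces CSV outputs
  byte-identically.
- Seeds are plain integers into `numpy.random.default_rng`; derived seeds
  stay below 2^31.

## Known limitations

- Wald inference is approximate; for very small looks the corrected
  estimate is defined but noisy, and exact (Fisher-style) inference is
  deliberately out of scope.
- The conjugate engine conditions on the observed SE rather than treating
  the control rate as a nuisance parameter; the grid engine is the remedy
  where that matters (rare events, tiny tables).
- Printed (OR, CI, P) triples from the literature are rounded to 2–3
  significant figures; inverting them reproduces the printed P only to
  about ±0.01, the propagation of that rounding.
- No alpha-spending or group-sequential frequentist boundaries are
  provided; the package's frequentist side exists to display the peeking
  problem, not to correct it.
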