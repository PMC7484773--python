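import pytest

from seqmonitor import (
    ContingencyTable,
    SyntheticTrialConfig,
    TrialRecord,
    generate,
    implied_intervention_probability,
)


@pytest.fixture
def four_responders():
    """i:event, c:non-event, i:non-event, c:event — hand-countable table."""
    return [
        TrialRecord(1, "intervention", 1),
        TrialRecord(2, "control", 0),
        TrialRecord(3, "intervention", 0),
        TrialRecord(4, "control", 1),
    ]


def build_table_suite() -> list[ContingencyTable]:
    """Deterministic suite of 2x2 tables with every cell >= 5.

    Expected cells of two-arm designs over a grid of per-arm sizes,
    moderate control event probabilities, and odds ratios in the range the
    skeptical prior treats as plausible; used for conjugate-vs-grid
    comparisons and flat-prior checks.  At low event rates (p_control ~0.2
    and below) the exact marginal posterior is visibly skewed by the
    uniform nuisance prior and the normal approximation drifts past the
    comparison bands, so the suite targets the moderate-rate regime the
    monitor is designed for.
    """
    suite = []
    for n_arm in (30, 60, 120, 250):
        for pc in (0.3, 0.4, 0.5):
            for or_ in (0.75, 1.0, 1.25, 1.5, 2.0):
                pi = implied_intervention_probability(pc, or_)
                ei = round(n_arm * pi)
                ec = round(n_arm * pc)
                t = ContingencyTable(ei, n_arm - ei, ec, n_arm - ec)
                if all(c >= 5 for c in t.cells()):
                    suite.append(t)
    return suite


@pytest.fixture(scope="session")
def table_suite():
    suite = build_table_suite()
    assert len(suite) >= 50
    return suite


@pytest.fixture(scope="session")
def flatline_source_trial():
    """Fixed-seed synthetic trial whose sample OR at N=535 is ~1.6."""
    return generate(SyntheticTrialConfig(n=535, p_control=0.25, true_or=1.6, seed=6))
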