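import numpy as np
import pytest

from ddimix.data_model import ContingencyTable, ReportRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def hand_reports():
    """Ten reports with mixed drug/ADE sets, classified by hand in tests."""
    raw = [
        ("r01", {"warfarin", "aspirin"}, {"bleeding"}),
        ("r02", {"warfarin"}, {"bleeding"}),
        ("r03", {"aspirin"}, set()),
        ("r04", {"warfarin", "aspirin", "statin"}, {"myopathy"}),
        ("r05", set(), {"bleeding"}),
        ("r06", {"statin"}, {"myopathy", "bleeding"}),
        ("r07", {"warfarin", "aspirin"}, set()),
        ("r08", {"aspirin", "statin"}, {"bleeding"}),
        ("r09", set(), set()),
        ("r10", {"warfarin"}, set()),
    ]
    return [ReportRecord(i, frozenset(d), frozenset(a)) for i, d, a in raw]


@pytest.fixture
def balanced_table():
    """One report in each of the eight cells: every rate is 1/2."""
    return ContingencyTable(a=1, b=1, c=1, d=1, e=1, f=1, g=1, h=1)


def random_reports(rng, n=200, drugs=("d1", "d2", "d3", "d4", "d5"), ades=("e1", "e2")):
    out = []
    for i in range(n):
        ds = frozenset(d for d in drugs if rng.random() < 0.35)
        es = frozenset(a for a in ades if rng.random() < 0.3)
        out.append(ReportRecord(f"r{i}", ds, es))
    return out
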