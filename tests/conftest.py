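import numpy as np
import pytest

from peaks2func import (
    AdductRule,
    CompoundDB,
    CompoundRecord,
    FixtureSpec,
    PathwayEntry,
    PathwayLibrary,
    PeakTable,
    RankedPeakList,
)

GLUCOSE_MASS = 180.06339
M_PLUS_H = AdductRule("M+H", 1, 1.007276, 1, "positive")
M_PLUS_NA = AdductRule("M+Na", 1, 22.989218, 1, "positive")
M_PLUS_2H = AdductRule("M+2H", 1, 2.014552, 2, "positive")


@pytest.fixture
def mh_rule():
    return M_PLUS_H


@pytest.fixture
def small_db():
    """Three compounds, one currency-flagged, with a synonym for glucose."""
    return CompoundDB(
        records=[
            CompoundRecord("glc", GLUCOSE_MASS, "Glucose", ("alpha-D-Glucose", "Dextrose")),
            CompoundRecord("ala", 89.04768, "Alanine"),
            CompoundRecord("h2o", 18.010565, "Water"),
        ],
        currency_ids={"h2o"},
    )


@pytest.fixture
def tiny_library():
    return PathwayLibrary(
        pathways=[
            PathwayEntry("P1", "sugars", frozenset({"glc"}), frozenset()),
            PathwayEntry("P2", "aminos", frozenset({"ala"}), frozenset({"g1", "g2"})),
        ]
    )


def make_peak_table(intensities, groups=None, mz=None, rt=None, sample_ids=None):
    intensities = np.asarray(intensities, dtype=float)
    n_feat, n_samp = intensities.shape
    return PeakTable(
        feature_ids=[f"f{i}" for i in range(n_feat)],
        mz=np.asarray(mz, dtype=float) if mz is not None else np.linspace(100, 200, n_feat),
        rt=None if rt is None else np.asarray(rt, dtype=float),
        intensities=intensities,
        sample_ids=sample_ids or [f"s{j}" for j in range(n_samp)],
        group_labels=list(groups) if groups is not None else ["g"] * n_samp,
    )


def make_peaks(mz, p=None, t=None, rt=None, mode="positive"):
    mz = np.asarray(mz, dtype=float)
    return RankedPeakList(
        mz=mz,
        rt=None if rt is None else np.asarray(rt, dtype=float),
        p_value=np.asarray(p, dtype=float) if p is not None else np.full(mz.size, 0.5),
        statistic=np.asarray(t, dtype=float) if t is not None else np.zeros(mz.size),
        mode=mode,
    )


@pytest.fixture
def default_spec():
    return FixtureSpec(seed=7)
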