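"""Pre-analysis utilities: technical-replicate merging, background-feature
exclusion, and the two-group feature ranking that produces the input for
pathway activity prediction.

Replicate merging follows a missing-proportion / coefficient-of-variation
rule: within a biological subject, a feature whose replicates are more
than 1/3 missing is checked for stability, and if the CV of the surviving
replicates exceeds 1.0 it is considered highly variant and set to zero;
otherwise the mean of the non-missing replicates is kept.

Background exclusion operates on the m/z centroid stream of a whole
chromatographic run: centroid m/z values are binned at a ppm width, and a
bin whose longest run of consecutive scans covers at least half of the
chromatogram is excluded as background/contaminant.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import stats

from .errors import DataError
from .io_formats import PeakTable, RankedPeakList, _as_text


# ---------------------------------------------------------------------------
# Technical replicates
# ---------------------------------------------------------------------------

@dataclass
class ReplicateMap:
    """Mapping sample_id -> biological subject id."""

    mapping: dict[str, str]

    @classmethod
    def from_tsv(cls, stream) -> "ReplicateMap":
        mapping: dict[str, str] = {}
        for row in csv.reader(_as_text(stream), delimiter="\t"):
            if not any(c.strip() for c in row):
                continue
            if len(row) < 2:
                raise DataError("replicate map rows need (sample_id, subject_id)")
            mapping[row[0].strip()] = row[1].strip()
        return cls(mapping)

    def subjects(self) -> list[str]:
        seen: list[str] = []
        for subject in self.mapping.values():
            if subject not in seen:
                seen.append(subject)
        return seen


def _merge_one(values: np.ndarray, missing_threshold: float, cv_threshold: float) -> float:
    """Apply the missing-proportion / CV rule to one feature of one subject."""
    r = values.size
    present = values[~np.isnan(values)]
    if present.size == 0:
        return math.nan
    f_missing = (r - present.size) / r
    mean = float(present.mean())
    if f_missing > missing_threshold:
        if present.size < 2 or mean == 0:
            cv = 0.0  # SD undefined at n=1; a single surviving value is kept
        else:
            cv = float(present.std(ddof=1)) / mean
        if cv > cv_threshold:
            return 0.0  # highly variant
    return mean


def merge_technical_replicates(
    table: PeakTable,
    reps: ReplicateMap | Mapping[str, str],
    missing_threshold: float = 1 / 3,
    cv_threshold: float = 1.0,
) -> PeakTable:
    """Collapse technical replicates into one column per biological subject.

    Per feature and subject with ``r`` replicates, let ``f`` be the
    missing proportion.  If ``f <= missing_threshold`` the mean of the
    non-missing values is used.  If ``f > missing_threshold`` the CV
    (sample SD / mean of the non-missing values) is evaluated, and the
    feature is zeroed as *highly variant* when ``CV > cv_threshold``;
    otherwise the mean is kept.  Both comparisons are strict ("over").
    Subjects with a single replicate pass through unchanged; a subject
    whose replicates are all missing stays missing.
    """
    if not 0 < missing_threshold <= 1:
        raise DataError("missing_threshold must lie in (0, 1]")
    if cv_threshold <= 0:
        raise DataError("cv_threshold must be positive")
    mapping = reps.mapping if isinstance(reps, ReplicateMap) else dict(reps)
    unknown = set(mapping) - set(table.sample_ids)
    if unknown:
        raise DataError(f"replicate map names unknown sample ids: {sorted(unknown)}")
    missing = set(table.sample_ids) - set(mapping)
    if missing:
        raise DataError(f"samples absent from replicate map: {sorted(missing)}")

    subjects = []
    for sid in table.sample_ids:
        if mapping[sid] not in subjects:
            subjects.append(mapping[sid])
    col_of = {sid: j for j, sid in enumerate(table.sample_ids)}
    group_of_subject: dict[str, str] = {}
    for sid, subject in mapping.items():
        group_of_subject.setdefault(subject, table.group_labels[col_of[sid]])

    merged = np.empty((table.n_features, len(subjects)))
    for j, subject in enumerate(subjects):
        cols = [col_of[sid] for sid in table.sample_ids if mapping[sid] == subject]
        block = table.intensities[:, cols]
        if len(cols) == 1:
            merged[:, j] = block[:, 0]
            continue
        for i in range(table.n_features):
            merged[i, j] = _merge_one(block[i], missing_threshold, cv_threshold)

    return PeakTable(
        feature_ids=list(table.feature_ids),
        mz=table.mz.copy(),
        rt=None if table.rt is None else table.rt.copy(),
        intensities=merged,
        sample_ids=subjects,
        group_labels=[group_of_subject[s] for s in subjects],
        mode=table.mode,
        neutral_mass=table.neutral_mass,
    )


# ---------------------------------------------------------------------------
# Background feature exclusion
# ---------------------------------------------------------------------------

@dataclass
class CentroidStream:
    """All m/z centroids of a run: rows of (scan_index, mz), sorted by scan."""

    scan_index: np.ndarray
    mz: np.ndarray
    n_scans: int

    def __post_init__(self) -> None:
        self.scan_index = np.asarray(self.scan_index, dtype=int)
        self.mz = np.asarray(self.mz, dtype=float)
        if self.scan_index.size != self.mz.size:
            raise DataError("scan_index and mz must have equal length")
        if self.scan_index.size and self.scan_index.max() >= self.n_scans:
            raise DataError("scan_index out of range for n_scans")
        if self.scan_index.size and self.scan_index.min() < 0:
            raise DataError("scan_index must be non-negative")
        order = np.argsort(self.scan_index, kind="stable")
        self.scan_index = self.scan_index[order]
        self.mz = self.mz[order]


def _longest_consecutive_run(scans: np.ndarray) -> int:
    """Length of the longest run of consecutive integers in ``scans``."""
    u = np.unique(scans)
    if u.size == 0:
        return 0
    breaks = np.flatnonzero(np.diff(u) != 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [u.size - 1]))
    return int((ends - starts + 1).max())


def filter_background_features(
    stream: CentroidStream,
    mz_bin_ppm: float = 10.0,
    run_fraction: float = 0.5,
) -> tuple[set[float], set[float]]:
    """Split centroid m/z bins into (kept, excluded) background sets.

    Centroids are single-linkage binned: after sorting, a new bin starts
    wherever the relative gap to the previous m/z exceeds ``mz_bin_ppm``.
    A bin is excluded iff its longest run of consecutive scan indices is
    at least ``ceil(run_fraction * n_scans)`` — features persisting across
    half the chromatogram by default.  Bins are reported by their mean m/z.
    """
    if stream.mz.size == 0:
        return set(), set()
    if stream.n_scans < 2:
        raise DataError("background filtering needs at least 2 scans")
    threshold = math.ceil(run_fraction * stream.n_scans)

    order = np.argsort(stream.mz, kind="stable")
    mz_sorted = stream.mz[order]
    scan_sorted = stream.scan_index[order]
    rel_gap = np.diff(mz_sorted) / mz_sorted[:-1] * 1e6
    bin_starts = np.concatenate(([0], np.flatnonzero(rel_gap > mz_bin_ppm) + 1))
    bin_ends = np.concatenate((bin_starts[1:], [mz_sorted.size]))

    kept: set[float] = set()
    excluded: set[float] = set()
    for a, b in zip(bin_starts, bin_ends):
        center = float(mz_sorted[a:b].mean())
        if _longest_consecutive_run(scan_sorted[a:b]) >= threshold:
            excluded.add(center)
        else:
            kept.add(center)
    return kept, excluded


def read_centroid_stream(stream, n_scans: int | None = None) -> CentroidStream:
    """Read a centroid TSV with columns scan_index, mz (header optional)."""
    scans, mzs = [], []
    for row in csv.reader(_as_text(stream), delimiter="\t"):
        if not any(c.strip() for c in row):
            continue
        try:
            scans.append(int(row[0]))
        except ValueError:
            continue  # header
        mzs.append(float(row[1]))
    n = n_scans if n_scans is not None else (max(scans) + 1 if scans else 0)
    return CentroidStream(np.array(scans, dtype=int), np.array(mzs), n_scans=n)


# ---------------------------------------------------------------------------
# Feature ranking
# ---------------------------------------------------------------------------

def rank_features(table: PeakTable, log_transform: bool = True) -> RankedPeakList:
    """Welch two-sample t-test per feature, producing a ranked peak list.

    Intensities are log-transformed (``ln(x + 1)``) before testing by
    default, reflecting the right-skew of MS intensity data.  Features
    with fewer than 2 non-missing values in either group are dropped.
    Exactly two group labels are required; the statistic is oriented as
    group1 - group2, with group order taken from first appearance.
    """
    groups = []
    for g in table.group_labels:
        if g not in groups:
            groups.append(g)
    if len(groups) != 2:
        raise DataError(
            f"rank_features needs exactly 2 groups, found {len(groups)} "
            f"({groups}); select a two-group contrast first"
        )
    g1 = np.array([g == groups[0] for g in table.group_labels])
    g2 = ~g1

    X = table.intensities
    if log_transform:
        X = np.log1p(X)
    a, b = X[:, g1], X[:, g2]
    n_a = np.sum(~np.isnan(a), axis=1)
    n_b = np.sum(~np.isnan(b), axis=1)
    keep = (n_a >= 2) & (n_b >= 2)
    n_dropped = int((~keep).sum())
    if n_dropped:
        warnings.warn(
            f"dropped {n_dropped} features with fewer than 2 non-missing "
            "values per group",
            stacklevel=2,
        )

    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(
            a[keep], b[keep], axis=1, equal_var=False, nan_policy="omit"
        )
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    # zero variance in both groups: equal means => no evidence; unequal => extreme
    degenerate = np.isnan(t)
    if degenerate.any():
        mean_a = np.nanmean(a[keep], axis=1)
        mean_b = np.nanmean(b[keep], axis=1)
        same = degenerate & np.isclose(mean_a, mean_b)
        t[same], p[same] = 0.0, 1.0
        diff = degenerate & ~same
        t[diff] = np.where(mean_a[diff] > mean_b[diff], np.inf, -np.inf)
        p[diff] = 0.0

    return RankedPeakList(
        mz=table.mz[keep],
        rt=None if table.rt is None else table.rt[keep],
        p_value=np.clip(p, 0.0, 1.0),
        statistic=t,
        mode=table.mode,
        neutral_mass=table.neutral_mass,
    ).sorted()
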