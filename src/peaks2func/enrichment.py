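"""Pathway activity prediction from putatively annotated MS peaks.

The algorithm (mummichog-style) takes a ranked peak list, putatively
annotates *all* peaks against a compound database under an adduct model,
and asks, per pathway, whether the compounds implied by the significant
peaks over-represent the pathway relative to what random peak subsets of
the same size imply.  Because annotation is many-to-many and noisy, the
raw over-representation p-value (a conservative EASE-adjusted
hypergeometric) is not taken at face value: it is calibrated against a
permutation null in which significant-peak sets are redrawn uniformly
from the full peak list, and a Gamma distribution fitted to the
-ln(p) null scores supplies the final calibrated p-value ("gamma_p").

Two counting units are supported: v1 counts candidate compounds, v2
counts empirical compounds (RT-co-eluting adduct groups), which requires
retention time.

Counting universe: the compounds (or empirical compounds) annotatable
from the full input peak list — conditioning on what the instrument
could actually see — not the whole database.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import (
    AdductRule,
    PeakAnnotation,
    annotate_peaks,
    build_empirical_compounds,
    cluster_rts_single_linkage,
    default_rt_tolerance,
)
from .errors import DataError
from .io_formats import CompoundDB, PathwayLibrary, RankedPeakList


# ---------------------------------------------------------------------------
# EASE-adjusted hypergeometric
# ---------------------------------------------------------------------------

def ease_pvalue(k: int, n_sig: int, K: int, N: int) -> float:
    """EASE-adjusted right-tail hypergeometric overlap probability.

    With ``n_sig`` draws from a universe of ``N`` containing ``K``
    pathway members, returns P(X >= k - 1) — the conservative variant
    that discounts one overlapping member.  ``k = 0`` returns 1.
    """
    if not (0 <= k <= min(n_sig, K)):
        raise DataError(f"inconsistent counts: k={k}, n_sig={n_sig}, K={K}")
    if K > N or n_sig > N:
        raise DataError(f"inconsistent counts: K={K}, n_sig={n_sig}, N={N}")
    return float(_ease_vec(np.array([k]), n_sig, np.array([K]), N)[0])


def _ease_vec(k: np.ndarray, n_sig: int, K: np.ndarray, N: int) -> np.ndarray:
    """Vectorized ease_pvalue over per-pathway overlap/size arrays."""
    p = stats.hypergeom.sf(k - 2, N, K, n_sig)
    return np.where(k == 0, 1.0, np.clip(p, 0.0, 1.0))


# ---------------------------------------------------------------------------
# Gamma-calibrated permutation null
# ---------------------------------------------------------------------------

@dataclass
class GammaNull:
    """Fitted null for -ln(p) scores, with a point mass at p = 1.

    The continuous part is Gamma(shape, scale) with location fixed at 0,
    fitted by maximum likelihood to the positive scores; ``p_one_frac``
    is the fraction of null p-values equal to 1 (score 0).  When the
    null is degenerate the sorted scores are kept and the upper tail is
    evaluated empirically instead.
    """

    shape: float
    scale: float
    location: float = 0.0
    p_one_frac: float = 0.0
    empirical: np.ndarray | None = None

    def __iter__(self):
        return iter((self.shape, self.scale, self.location))

    def sf(self, s: float | np.ndarray) -> np.ndarray:
        s = np.asarray(s, dtype=float)
        if self.empirical is not None:
            idx = np.searchsorted(self.empirical, s, side="left")
            tail = (self.empirical.size - idx) / self.empirical.size
            return np.where(s <= 0, 1.0, tail)
        cont = (1.0 - self.p_one_frac) * stats.gamma.sf(
            s, self.shape, loc=self.location, scale=self.scale
        )
        return np.where(s <= 0, 1.0, cont)

    def pvalue(self, p_obs: float | np.ndarray) -> np.ndarray:
        p_obs = np.asarray(p_obs, dtype=float)
        with np.errstate(divide="ignore"):
            s = -np.log(np.clip(p_obs, np.finfo(float).tiny, None))
        return self.sf(s)


def fit_gamma_null(null_scores) -> GammaNull:
    """Fit the permutation null: Gamma MLE on s = -ln(p), location 0.

    Requires at least 100 pooled null p-values in (0, 1].  Null values
    exactly 1 contribute a point mass at score 0 rather than entering
    the MLE.  A degenerate null (fewer than two distinct positive
    scores, or a failed fit) falls back to the empirical upper tail with
    a warning.
    """
    p = np.asarray(list(null_scores), dtype=float)
    if p.size < 100:
        raise DataError(f"need >= 100 pooled null values, got {p.size}")
    if np.any((p <= 0) | (p > 1)):
        raise DataError("null p-values must lie in (0, 1]")
    s = -np.log(p)
    s_pos = s[s > 0]
    p_one_frac = 1.0 - s_pos.size / s.size

    def _fallback(reason: str) -> GammaNull:
        warnings.warn(
            f"degenerate permutation null ({reason}); using empirical tail",
            stacklevel=3,
        )
        return GammaNull(
            shape=float("nan"), scale=float("nan"),
            p_one_frac=p_one_frac, empirical=np.sort(s),
        )

    if np.unique(s_pos).size < 2:
        return _fallback("fewer than 2 distinct scores")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            shape, loc, scale = stats.gamma.fit(s_pos, floc=0.0)
    except Exception:
        return _fallback("gamma MLE failed")
    if not (np.isfinite(shape) and np.isfinite(scale) and shape > 0 and scale > 0):
        return _fallback("gamma MLE returned non-finite parameters")
    return GammaNull(shape=float(shape), scale=float(scale), location=float(loc),
                     p_one_frac=p_one_frac)


# ---------------------------------------------------------------------------
# Configuration and result containers
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentConfig:
    """Knobs of the pathway-activity algorithm.

    ``sig_cutoff`` defines the significant peak set from the ranked
    list; ``version`` selects compound-level (v1) or empirical-compound
    (v2) counting; ``reuse_ec_structure`` reuses the observed empirical
    compounds during permutations instead of re-forming them per
    permutation (faster, slightly less faithful).
    """

    sig_cutoff: float = 0.05
    n_permutations: int = 100
    seed: int = 0
    version: str = "v1"
    min_pathway_hits: int = 1
    ppm_tol: float = 5.0
    rt_tol: float | None = None
    reuse_ec_structure: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.sig_cutoff < 1:
            raise DataError("sig_cutoff must lie in (0, 1)")
        if self.n_permutations < 20:
            raise DataError("n_permutations must be >= 20")
        if self.version not in ("v1", "v2"):
            raise DataError("version must be 'v1' or 'v2'")


@dataclass
class PathwayEnrichmentResult:
    """Per-pathway overlap counts with EASE and Gamma-calibrated p-values.

    Rows are sorted by gamma_p, ties broken by ease_p then pathway_id.
    ``pathway_size`` counts the pathway members annotatable from the
    full peak list (the counting universe), which is also ``hits_total``
    under that universe definition.
    """

    pathway_ids: list[str]
    pathway_names: list[str]
    pathway_size: np.ndarray
    hits_total: np.ndarray
    hits_sig: np.ndarray
    ease_p: np.ndarray
    gamma_p: np.ndarray
    universe_size: int = 0
    n_sig_units: int = 0
    gamma_null: GammaNull | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pathway_id": self.pathway_ids,
                "pathway_name": self.pathway_names,
                "pathway_size": self.pathway_size.astype(int),
                "hits_total": self.hits_total.astype(int),
                "hits_sig": self.hits_sig.astype(int),
                "ease_p": self.ease_p,
                "gamma_p": self.gamma_p,
            }
        )

    def gamma_p_by_id(self) -> dict[str, float]:
        return dict(zip(self.pathway_ids, self.gamma_p.tolist()))

    def __len__(self) -> int:
        return len(self.pathway_ids)


# ---------------------------------------------------------------------------
# Counting structures
# ---------------------------------------------------------------------------

class _CompoundCounter:
    """v1 counting: unit = candidate compound annotatable from the peaks."""

    def __init__(self, n_peaks: int, ann: PeakAnnotation, lib: PathwayLibrary):
        self.universe = sorted(ann.annotated_compounds)
        idx = {c: j for j, c in enumerate(self.universe)}
        self.N = len(self.universe)
        self.A = np.zeros((n_peaks, self.N), dtype=bool)
        for m in ann.matches:
            self.A[m.feature_index, idx[m.compound_id]] = True
        self.P = np.zeros((len(lib.pathways), self.N), dtype=bool)
        for r, pw in enumerate(lib.pathways):
            for c in pw.compound_ids:
                if c in idx:
                    self.P[r, idx[c]] = True
        self.K = self.P.sum(axis=1)
        self._Pi = self.P.astype(np.int64)

    def counts(self, mask: np.ndarray) -> tuple[int, np.ndarray]:
        hit = self.A[mask].any(axis=0)
        return int(hit.sum()), (self._Pi @ hit.astype(np.int64))

    def counts_batch(self, draws: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """draws: (n_perm, n_draw) peak indices -> (n_sig per perm, k per perm x pathway)."""
        hits = self.A[draws].any(axis=1)          # (n_perm, N)
        n_sig = hits.sum(axis=1)
        k = hits.astype(np.int64) @ self._Pi.T     # (n_perm, n_pathways)
        return n_sig, k


class _EmpiricalCompoundCounter:
    """v2 counting: unit = (compound, RT cluster) empirical compound.

    The universe and per-pathway capacities come from the empirical
    compounds formed on the full peak list.  For a peak subset the
    empirical compounds are re-formed among the subset's matches by
    default; clamping keeps subset counts within the full-structure
    capacity (dropping a bridging peak can split one observed group in
    two, which cannot represent more underlying molecules than the full
    data supports).
    """

    def __init__(
        self,
        peaks: RankedPeakList,
        ann: PeakAnnotation,
        lib: PathwayLibrary,
        rt_tol: float | None,
        reuse_structure: bool,
    ):
        if peaks.rt is None:
            raise DataError("v2 counting requires retention time")
        self.rt_tol = rt_tol if rt_tol is not None else default_rt_tolerance(peaks.rt)
        self.reuse = reuse_structure
        self.ecs = build_empirical_compounds(ann, peaks, self.rt_tol)
        self.N = len(self.ecs)
        n_peaks = len(peaks)

        # per-compound peak/RT arrays for re-forming on subsets
        by_compound: dict[str, list[int]] = {}
        for m in ann.matches:
            by_compound.setdefault(m.compound_id, []).append(m.feature_index)
        self.comp_ids = sorted(by_compound)
        self.comp_peaks: list[np.ndarray] = []
        self.comp_rts: list[np.ndarray] = []
        for c in self.comp_ids:
            pk = np.array(sorted(set(by_compound[c])), dtype=int)
            rt = peaks.rt[pk]
            order = np.argsort(rt, kind="stable")
            self.comp_peaks.append(pk[order])
            self.comp_rts.append(rt[order])

        # full-structure EC capacity per compound and EC incidence
        self.K_comp = {c: 0 for c in self.comp_ids}
        self.E = np.zeros((n_peaks, self.N), dtype=bool)
        ec_compound = []
        for j, ec in enumerate(self.ecs):
            cid = sorted(ec.compound_ids)[0]
            self.K_comp[cid] += 1
            ec_compound.append(cid)
            for m in ec.matches:
                self.E[m.feature_index, j] = True

        self.P = np.zeros((len(lib.pathways), self.N), dtype=bool)
        for r, pw in enumerate(lib.pathways):
            for j, cid in enumerate(ec_compound):
                if cid in pw.compound_ids:
                    self.P[r, j] = True
        self.K = self.P.sum(axis=1)
        self._Pi = self.P.astype(np.int64)
        self.pathway_has = [
            np.array([cid in pw.compound_ids for cid in self.comp_ids])
            for pw in lib.pathways
        ]
        self.K_comp_arr = np.array([self.K_comp[c] for c in self.comp_ids])

    def counts(self, mask: np.ndarray) -> tuple[int, np.ndarray]:
        if self.reuse:
            hit = self.E[mask].any(axis=0)
            return int(hit.sum()), (self._Pi @ hit.astype(np.int64))
        n_clusters = np.zeros(len(self.comp_ids), dtype=int)
        for ci, (pk, rt) in enumerate(zip(self.comp_peaks, self.comp_rts)):
            sel = mask[pk]
            if not sel.any():
                continue
            r = rt[sel]
            n = 1 + int(np.count_nonzero(np.diff(r) > self.rt_tol))
            n_clusters[ci] = min(n, self.K_comp_arr[ci])
        n_sig = min(int(n_clusters.sum()), self.N)
        k = np.array(
            [min(int(n_clusters[h].sum()), Kp) for h, Kp in zip(self.pathway_has, self.K)]
        )
        return n_sig, k

    def counts_batch(self, draws: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        n_perm = draws.shape[0]
        n_sig = np.zeros(n_perm, dtype=int)
        k = np.zeros((n_perm, self.P.shape[0]), dtype=int)
        n_peaks = self.E.shape[0]
        for t in range(n_perm):
            mask = np.zeros(n_peaks, dtype=bool)
            mask[draws[t]] = True
            n_sig[t], k[t] = self.counts(mask)
        return n_sig, k


# ---------------------------------------------------------------------------
# The enrichment driver
# ---------------------------------------------------------------------------

def _run_enrichment(counter, lib, cfg, sig_mask, n_peaks, rng) -> PathwayEnrichmentResult:
    N = counter.N
    if N == 0:
        raise DataError("no annotation possible: zero annotatable peaks")
    n_sig_obs, k_obs = counter.counts(sig_mask)
    if n_sig_obs == 0:
        raise DataError("significant peak set annotates no compounds")
    K = counter.K
    ease_obs = _ease_vec(k_obs, n_sig_obs, K, N)

    n_draw = int(sig_mask.sum())
    draws = np.empty((cfg.n_permutations, n_draw), dtype=int)
    for t in range(cfg.n_permutations):
        draws[t] = rng.choice(n_peaks, size=n_draw, replace=False)
    n_sig_perm, k_perm = counter.counts_batch(draws)
    null = np.empty((cfg.n_permutations, len(K)))
    for t in range(cfg.n_permutations):
        if n_sig_perm[t] == 0:
            null[t] = 1.0
        else:
            null[t] = _ease_vec(k_perm[t], int(n_sig_perm[t]), K, N)
    gnull = fit_gamma_null(null.ravel())
    gamma_p = gnull.pvalue(ease_obs)

    keep = counter.K >= max(cfg.min_pathway_hits, 1)
    ids = [pw.pathway_id for pw in lib.pathways]
    names = [pw.pathway_name for pw in lib.pathways]
    idx = [i for i in range(len(ids)) if keep[i]]
    order = sorted(idx, key=lambda i: (gamma_p[i], ease_obs[i], ids[i]))
    return PathwayEnrichmentResult(
        pathway_ids=[ids[i] for i in order],
        pathway_names=[names[i] for i in order],
        pathway_size=K[order],
        hits_total=K[order],
        hits_sig=np.asarray(k_obs)[order],
        ease_p=ease_obs[order],
        gamma_p=gamma_p[order],
        universe_size=N,
        n_sig_units=n_sig_obs,
        gamma_null=gnull,
    )


def make_counter(
    peaks: RankedPeakList,
    ann: PeakAnnotation,
    lib: PathwayLibrary,
    cfg: EnrichmentConfig,
):
    if cfg.version == "v2":
        return _EmpiricalCompoundCounter(
            peaks, ann, lib, cfg.rt_tol, cfg.reuse_ec_structure
        )
    return _CompoundCounter(len(peaks), ann, lib)


def mummichog_enrich(
    peaks: RankedPeakList,
    db: CompoundDB,
    lib: PathwayLibrary,
    rules: list[AdductRule],
    cfg: EnrichmentConfig,
    explicit_sig: set[int] | None = None,
) -> PathwayEnrichmentResult:
    """Pathway activity prediction from a ranked peak list.

    The significant set is either the peaks with ``p <= cfg.sig_cutoff``
    or, to support enrichment of arbitrary peak groups of interest, an
    explicit set of peak indices.  All peaks are putatively annotated;
    per-pathway EASE p-values are computed at the compound (v1) or
    empirical-compound (v2) level and calibrated against a seeded
    permutation null (uniform redraws of the significant-set size from
    the full peak list) via a fitted Gamma distribution.
    """
    if cfg.version == "v2" and peaks.rt is None:
        raise DataError("v2 requires retention time; use version='v1'")
    n_peaks = len(peaks)
    if explicit_sig is not None:
        sig_mask = np.zeros(n_peaks, dtype=bool)
        sig_mask[sorted(explicit_sig)] = True
    else:
        sig_mask = peaks.p_value <= cfg.sig_cutoff
    if not sig_mask.any():
        raise DataError("no significant peaks at the chosen cutoff")

    ann = annotate_peaks(peaks, db, rules, ppm_tol=cfg.ppm_tol)
    if not ann.matches:
        raise DataError("no annotation possible: zero annotatable peaks")
    counter = make_counter(peaks, ann, lib, cfg)
    rng = np.random.default_rng(cfg.seed)
    return _run_enrichment(counter, lib, cfg, sig_mask, n_peaks, rng)
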