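"""Cross-omics and cross-dataset integration.

Joint gene+metabolite pathway analysis runs over-representation
separately per omics (plain hypergeometric — inputs here are identified
hits, not putative annotations) and combines the two p-values per
pathway, either unweighted (Fisher's method) or with Stouffer's
weighted Z, where the weights are the proportions of genes vs
metabolites in the combined universe (overall weighting) or within the
individual pathway (pathway-level weighting).  This counteracts the
tendency of transcriptomics, with its many significant features, to
dominate a naive concatenated query.

Functional meta-analysis integrates several untargeted datasets either
at the pathway level (combine per-dataset calibrated pathway p-values)
or by pooling peaks from complementary acquisitions of the same samples
into a single enrichment with improved metabolome coverage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import AdductRule, annotate_peaks
from .enrichment import (
    EnrichmentConfig,
    PathwayEnrichmentResult,
    _CompoundCounter,
    _run_enrichment,
)
from .annotation import Match, PeakAnnotation
from .errors import DataError
from .io_formats import CompoundDB, PathwayLibrary, RankedPeakList

_TINY = np.finfo(float).tiny
_EPS = np.finfo(float).eps


# ---------------------------------------------------------------------------
# P-value combination primitives
# ---------------------------------------------------------------------------

def _clamp_open(ps: np.ndarray, clamp_high: bool) -> np.ndarray:
    out = ps.copy()
    if np.any(out <= 0):
        warnings.warn("p-value <= 0 clamped to smallest positive value", stacklevel=3)
        out[out <= 0] = _TINY
    if clamp_high and np.any(out >= 1):
        warnings.warn("p-value >= 1 clamped into the open interval", stacklevel=3)
        out[out >= 1] = 1 - _EPS
    return out


def combine_fisher(ps) -> tuple[float, float]:
    """Fisher's method: X2 = -2 sum(ln p), chi-square with 2k df.

    Returns (statistic, combined p).  A single p is returned unchanged
    (the df-2 identity).  Zero inputs are clamped to the smallest
    positive representable value with a warning.
    """
    ps = np.asarray(list(ps), dtype=float)
    if ps.size == 0:
        raise DataError("combine_fisher needs at least one p-value")
    if np.any(ps > 1):
        raise DataError("p-values must be <= 1")
    ps = _clamp_open(ps, clamp_high=False)
    x2 = float(-2.0 * np.sum(np.log(ps)))
    return x2, float(stats.chi2.sf(x2, df=2 * ps.size))


def combine_stouffer(ps, weights=None) -> tuple[float, float]:
    """Weighted Stouffer combination: Z_c = sum(w Z) / sqrt(sum w^2).

    ``Z_i`` is the upper-tail normal quantile of ``p_i``; the combined
    p is the upper tail of ``Z_c``.  Weights must be non-negative and
    not all zero (default: equal).  Scale-invariant in the weights.
    """
    ps = np.asarray(list(ps), dtype=float)
    if ps.size == 0:
        raise DataError("combine_stouffer needs at least one p-value")
    if np.any(ps > 1):
        raise DataError("p-values must be <= 1")
    w = np.ones_like(ps) if weights is None else np.asarray(list(weights), dtype=float)
    if w.shape != ps.shape:
        raise DataError("weights must match p-values in length")
    if np.any(w < 0) or not np.any(w > 0):
        raise DataError("weights must be non-negative and not all zero")
    ps = _clamp_open(ps, clamp_high=True)
    z = stats.norm.isf(ps)
    z_c = float(np.sum(w * z) / np.sqrt(np.sum(w**2)))
    return z_c, float(stats.norm.sf(z_c))


# ---------------------------------------------------------------------------
# Joint gene + metabolite pathway analysis
# ---------------------------------------------------------------------------

@dataclass
class OmicsQuery:
    """Identified hits from two omics layers plus their universe sizes."""

    gene_hits: set[str]
    metabolite_hits: set[str]
    n_genes_universe: int
    n_metabolites_universe: int

    def __post_init__(self) -> None:
        if len(self.gene_hits) > self.n_genes_universe:
            raise DataError("more gene hits than genes in the universe")
        if len(self.metabolite_hits) > self.n_metabolites_universe:
            raise DataError("more metabolite hits than metabolites in the universe")


@dataclass
class CombinedPathwayResult:
    pathway_ids: list[str]
    pathway_names: list[str]
    p_gene: np.ndarray
    p_met: np.ndarray
    w_gene: np.ndarray
    w_met: np.ndarray
    p_combined: np.ndarray
    method: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pathway_id": self.pathway_ids,
                "pathway_name": self.pathway_names,
                "p_gene": self.p_gene,
                "p_met": self.p_met,
                "w_gene": self.w_gene,
                "w_met": self.w_met,
                "p_combined": self.p_combined,
                "method": self.method,
            }
        )

    def __len__(self) -> int:
        return len(self.pathway_ids)


def _ora_pvalue(k: int, n_hits: int, K: int, N: int) -> float:
    """Plain right-tail hypergeometric P(X >= k); 1 when K or k is 0."""
    if K == 0 or n_hits == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n_hits))


VALID_LIBRARY_MODES = ("metabolic", "all", "metabolite_only", "gene_only")


def joint_pathway_analysis(
    query: OmicsQuery,
    lib: PathwayLibrary,
    method: str = "stouffer_pathway",
    library_mode: str = "all",
) -> CombinedPathwayResult:
    """Integrated pathway analysis of gene and metabolite hit lists.

    Per pathway, genes and metabolites are tested separately by
    over-representation against their own universes, then combined:

    * ``fisher`` — unweighted Fisher's method;
    * ``stouffer_overall`` — Stouffer with weights G/(G+C), C/(G+C)
      from the combined universe;
    * ``stouffer_pathway`` — Stouffer with weights from the pathway's
      own gene/metabolite member counts.

    A pathway with members from only one omics uses that omics' p-value
    directly.  ``library_mode`` ``metabolite_only``/``gene_only`` run a
    single-omics analysis with no combination step; ``metabolic``
    restricts to pathways whose category is metabolic.
    """
    if method not in ("fisher", "stouffer_overall", "stouffer_pathway"):
        raise DataError(f"unknown combination method {method!r}")
    if library_mode not in VALID_LIBRARY_MODES:
        raise DataError(f"unknown library mode {library_mode!r}")
    if not query.gene_hits and not query.metabolite_hits:
        raise DataError("empty query: no gene and no metabolite hits")

    pathways = lib.pathways
    if library_mode == "metabolic":
        pathways = [p for p in pathways if p.category == "metabolic"]
    G, C = query.n_genes_universe, query.n_metabolites_universe

    ids, names = [], []
    pg_list, pm_list, wg_list, wm_list, pc_list = [], [], [], [], []
    for pw in pathways:
        gene_members = pw.gene_ids if library_mode != "metabolite_only" else frozenset()
        met_members = pw.compound_ids if library_mode != "gene_only" else frozenset()
        if not gene_members and not met_members:
            continue
        k_g = len(gene_members & query.gene_hits)
        k_m = len(met_members & query.metabolite_hits)
        p_g = _ora_pvalue(k_g, len(query.gene_hits), len(gene_members), G)
        p_m = _ora_pvalue(k_m, len(query.metabolite_hits), len(met_members), C)

        if library_mode == "gene_only" or not met_members:
            w_g, w_m, p_c = 1.0, 0.0, p_g
        elif library_mode == "metabolite_only" or not gene_members:
            w_g, w_m, p_c = 0.0, 1.0, p_m
        elif method == "fisher":
            w_g = w_m = 0.5
            _, p_c = combine_fisher([p_g, p_m])
        else:
            if method == "stouffer_overall":
                w_g, w_m = G / (G + C), C / (G + C)
            else:
                g_p, c_p = len(gene_members), len(met_members)
                w_g, w_m = g_p / (g_p + c_p), c_p / (g_p + c_p)
            _, p_c = combine_stouffer([p_g, p_m], [w_g, w_m])

        ids.append(pw.pathway_id)
        names.append(pw.pathway_name)
        pg_list.append(p_g)
        pm_list.append(p_m)
        wg_list.append(w_g)
        wm_list.append(w_m)
        pc_list.append(p_c)

    order = sorted(range(len(ids)), key=lambda i: (pc_list[i], ids[i]))
    return CombinedPathwayResult(
        pathway_ids=[ids[i] for i in order],
        pathway_names=[names[i] for i in order],
        p_gene=np.array(pg_list)[order],
        p_met=np.array(pm_list)[order],
        w_gene=np.array(wg_list)[order],
        w_met=np.array(wm_list)[order],
        p_combined=np.array(pc_list)[order],
        method=method,
    )


# ---------------------------------------------------------------------------
# Functional meta-analysis
# ---------------------------------------------------------------------------

@dataclass
class MetaAnalysisResult:
    """Pathway-level integration across datasets.

    ``dataset_p`` is a (pathway x dataset) matrix of calibrated
    p-values (1.0, flagged in ``missing``, where a dataset lacked the
    pathway); ``venn`` flags per-dataset significance at ``alpha``.
    """

    pathway_ids: list[str]
    pathway_names: list[str]
    dataset_p: np.ndarray
    p_integrated: np.ndarray
    venn: np.ndarray
    missing: np.ndarray
    method: str
    alpha: float

    def to_frame(self) -> pd.DataFrame:
        data: dict[str, object] = {
            "pathway_id": self.pathway_ids,
            "pathway_name": self.pathway_names,
        }
        for j in range(self.dataset_p.shape[1]):
            data[f"p_dataset{j + 1}"] = self.dataset_p[:, j]
        data["p_integrated"] = self.p_integrated
        for j in range(self.venn.shape[1]):
            data[f"sig_dataset{j + 1}"] = self.venn[:, j]
        return pd.DataFrame(data)

    def __len__(self) -> int:
        return len(self.pathway_ids)


def meta_analysis_pathway_level(
    results: list[PathwayEnrichmentResult],
    method: str = "fisher",
    alpha: float = 0.05,
    weights=None,
) -> MetaAnalysisResult:
    """Combine per-dataset pathway p-values into integrated p-values.

    Pathways are reconciled by id across the datasets; a pathway absent
    from a dataset contributes p = 1 (absence of evidence penalizes)
    and is flagged.  ``method`` is ``fisher`` or ``stouffer`` (equal
    dataset weights unless a weight vector is given).
    """
    if len(results) < 2:
        raise DataError("meta-analysis needs at least 2 datasets")
    if method not in ("fisher", "stouffer"):
        raise DataError(f"unknown combination method {method!r}")
    w = None
    if weights is not None:
        w = np.asarray(list(weights), dtype=float)
        if w.size != len(results):
            raise DataError("need one weight per dataset")

    maps = [r.gamma_p_by_id() for r in results]
    names: dict[str, str] = {}
    for r in results:
        for pid, name in zip(r.pathway_ids, r.pathway_names):
            names.setdefault(pid, name)
    all_ids = sorted(names)

    D = len(results)
    P = np.ones((len(all_ids), D))
    missing = np.zeros((len(all_ids), D), dtype=bool)
    for i, pid in enumerate(all_ids):
        for j, m in enumerate(maps):
            if pid in m:
                P[i, j] = m[pid]
            else:
                missing[i, j] = True

    integrated = np.empty(len(all_ids))
    for i in range(len(all_ids)):
        if method == "fisher":
            _, integrated[i] = combine_fisher(P[i])
        else:
            _, integrated[i] = combine_stouffer(P[i], w)
    venn = (P <= alpha) & ~missing

    order = sorted(range(len(all_ids)), key=lambda i: (integrated[i], all_ids[i]))
    return MetaAnalysisResult(
        pathway_ids=[all_ids[i] for i in order],
        pathway_names=[names[all_ids[i]] for i in order],
        dataset_p=P[order],
        p_integrated=integrated[order],
        venn=venn[order],
        missing=missing[order],
        method=method,
        alpha=alpha,
    )


def meta_analysis_peak_pooling(
    peaklists: list[RankedPeakList],
    db: CompoundDB,
    lib: PathwayLibrary,
    rules_per_list: list[list[AdductRule]],
    cfg: EnrichmentConfig,
) -> PathwayEnrichmentResult:
    """Pool complementary peak lists of the same samples into one enrichment.

    Each list is annotated under its own adduct rules (its own ion
    mode); annotated compounds and significant annotations are unioned,
    and a single enrichment runs on the pooled annotation with
    permutations drawing from the pooled peak space.  Counting is at
    the compound level: retention times are not comparable across the
    complementary chromatographic conditions the lists come from.
    """
    if len(peaklists) < 2:
        raise DataError("peak pooling needs at least 2 peak lists")
    if len(rules_per_list) != len(peaklists):
        raise DataError("need one adduct rule set per peak list")

    seen: set[tuple[float, float | None, str]] = set()
    for pl in peaklists:
        for i in range(len(pl)):
            key = (float(pl.mz[i]), None if pl.rt is None else float(pl.rt[i]), pl.mode)
            if key in seen:
                raise DataError(f"conflicting duplicate (mz, rt, mode) triple {key} across lists")
            seen.add(key)

    pooled_matches: list[Match] = []
    pooled_p: list[np.ndarray] = []
    offset = 0
    for pl, rules in zip(peaklists, rules_per_list):
        ann = annotate_peaks(pl, db, rules, ppm_tol=cfg.ppm_tol)
        for m in ann.matches:
            pooled_matches.append(
                Match(m.feature_index + offset, m.compound_id, m.adduct_name, m.ppm_error)
            )
        pooled_p.append(pl.p_value)
        offset += len(pl)
    if not pooled_matches:
        raise DataError("no annotation possible: zero annotatable peaks")

    p_all = np.concatenate(pooled_p)
    sig_mask = p_all <= cfg.sig_cutoff
    if not sig_mask.any():
        raise DataError("no significant peaks at the chosen cutoff")
    ann_pooled = PeakAnnotation(matches=pooled_matches)
    counter = _CompoundCounter(offset, ann_pooled, lib)
    rng = np.random.default_rng(cfg.seed)
    return _run_enrichment(counter, lib, cfg, sig_mask, offset, rng)
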