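"""Putative annotation of m/z features and empirical-compound formation.

Without MS2 spectra, an LC-MS1 feature can only be *putatively* matched
to compounds: a feature at observed m/z matches compound M under adduct
rule A when the predicted ion m/z ``(n*M + shift)/|z|`` lies within a ppm
tolerance.  Matches are many-to-many by design.  Currency metabolites
(water, CO2, ATP, ...) are excluded by default because they occur in
most pathways and would dominate enrichment spuriously.

When retention time is available, matches to the same candidate compound
that co-elute (single-linkage within an RT tolerance) are merged into
*empirical compounds* — groups of peaks consistent with the adduct forms
of one underlying molecule.  Counting at the empirical-compound level is
what distinguishes the v2 pathway-activity algorithm from v1.

The module also provides the lipid-aware compound-name normalizer used
for mapping user-supplied names onto the compound database.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .errors import DataError
from .io_formats import CompoundDB, RankedPeakList, _as_text

PROTON_MASS = 1.007276  # Da


# ---------------------------------------------------------------------------
# Adduct rules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AdductRule:
    """One ionized form: predicted m/z = (nmer * M + mass_shift) / |charge|."""

    name: str
    nmer: int
    mass_shift: float
    charge: int
    mode: str

    def __post_init__(self) -> None:
        if self.nmer < 1:
            raise DataError(f"adduct {self.name!r}: nmer must be >= 1")
        if self.charge == 0:
            raise DataError(f"adduct {self.name!r}: charge must be nonzero")
        if self.mode not in ("positive", "negative"):
            raise DataError(f"adduct {self.name!r}: mode must be positive or negative")


def load_adduct_rules(stream=None, mode: str | None = None) -> list[AdductRule]:
    """Load adduct rules from a TSV (name, nmer, mass_shift, charge, mode).

    With no stream, the default rule table shipped with the package is
    used.  ``mode`` filters to one ionization mode.
    """
    if stream is None:
        text = resources.files("peaks2func").joinpath("data/adducts.tsv").read_text("utf-8")
    else:
        text = _as_text(stream).read()
    rules: list[AdductRule] = []
    rows = list(csv.reader(text.splitlines(), delimiter="\t"))
    for row in rows[1:]:
        if len(row) < 5 or not any(c.strip() for c in row):
            continue
        rules.append(
            AdductRule(
                name=row[0].strip(),
                nmer=int(row[1]),
                mass_shift=float(row[2]),
                charge=int(row[3]),
                mode=row[4].strip(),
            )
        )
    if mode is not None:
        rules = [r for r in rules if r.mode == mode]
    return rules


def predicted_mz(mass: float, rule: AdductRule) -> float:
    """Predicted ion m/z of a neutral monoisotopic mass under one rule."""
    if mass <= 0:
        raise DataError("neutral mass must be positive")
    return (rule.nmer * mass + rule.mass_shift) / abs(rule.charge)


# ---------------------------------------------------------------------------
# Peak annotation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Match:
    feature_index: int
    compound_id: str
    adduct_name: str
    ppm_error: float


@dataclass
class PeakAnnotation:
    matches: list[Match]
    annotated_features: set[int] = field(default_factory=set)
    annotated_compounds: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.annotated_features:
            self.annotated_features = {m.feature_index for m in self.matches}
        if not self.annotated_compounds:
            self.annotated_compounds = {m.compound_id for m in self.matches}


_NEUTRAL_RULE = AdductRule("M", 1, 0.0, 1, "positive")


def annotate_peaks(
    peaks: RankedPeakList,
    db: CompoundDB,
    rules: list[AdductRule],
    ppm_tol: float = 5.0,
    drop_currency: bool = True,
) -> PeakAnnotation:
    """Match every peak against every (compound, adduct) prediction.

    A match is kept when |observed - predicted| / predicted * 1e6 is at
    most ``ppm_tol``.  Many-to-many matches are preserved.  Currency
    metabolites are dropped from consideration unless requested
    otherwise.  Tables flagged ``neutral_mass`` are matched directly on
    neutral mass (identity rule), since their m/z column carries no
    adduct shift.
    """
    if peaks.neutral_mass:
        usable = [_NEUTRAL_RULE]
    else:
        wanted_modes = (
            {"positive", "negative"} if peaks.mode == "mixed" else {peaks.mode}
        )
        usable = [r for r in rules if r.mode in wanted_modes]
        if not usable:
            raise DataError(f"no adduct rules available for mode {peaks.mode!r}")

    keep_idx = [
        i for i, rec in enumerate(db.records)
        if not (drop_currency and rec.compound_id in db.currency_ids)
    ]
    matches: list[Match] = []
    if not keep_idx:
        return PeakAnnotation(matches=[])
    masses = db.masses[keep_idx]
    ids = [db.records[i].compound_id for i in keep_idx]
    obs = np.asarray(peaks.mz, dtype=float)

    for rule in usable:
        pred = (rule.nmer * masses + rule.mass_shift) / abs(rule.charge)
        valid = pred > 0
        order = np.argsort(pred[valid], kind="stable")
        pred_sorted = pred[valid][order]
        idx_sorted = np.array(keep_idx, dtype=int)[valid][order]
        id_sorted = [ids[j] for j in np.flatnonzero(valid)[order]]
        half = ppm_tol * 1e-6
        lo = np.searchsorted(pred_sorted, obs / (1 + half), side="left")
        hi = np.searchsorted(pred_sorted, obs / (1 - half), side="right")
        for i, (a, b) in enumerate(zip(lo, hi)):
            for j in range(a, b):
                ppm = (obs[i] - pred_sorted[j]) / pred_sorted[j] * 1e6
                if abs(ppm) <= ppm_tol:
                    matches.append(Match(i, id_sorted[j], rule.name, float(ppm)))
        del idx_sorted

    matches.sort(key=lambda m: (m.feature_index, m.compound_id, m.adduct_name))
    return PeakAnnotation(matches=matches)


# ---------------------------------------------------------------------------
# Empirical compounds
# ---------------------------------------------------------------------------

@dataclass
class EmpiricalCompound:
    """Co-eluting peaks consistent with adduct forms of one compound."""

    ec_id: str
    matches: list[Match]
    rt_center: float
    compound_ids: frozenset[str]


def default_rt_tolerance(rt: np.ndarray) -> float:
    """1% of the observed RT range (falls back to 1 s on a degenerate range)."""
    span = float(np.max(rt) - np.min(rt))
    return 0.01 * span if span > 0 else 1.0


def cluster_rts_single_linkage(rts: np.ndarray, rt_tol: float) -> list[np.ndarray]:
    """Split sorted RTs wherever the gap to the previous value exceeds rt_tol.

    On a 1-D axis this sort-and-split is exactly single-linkage
    clustering at threshold ``rt_tol``.  Returns index arrays into the
    input, one per cluster.
    """
    order = np.argsort(rts, kind="stable")
    gaps = np.diff(rts[order])
    breaks = np.flatnonzero(gaps > rt_tol)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks + 1, [len(order)]))
    return [order[a:b] for a, b in zip(starts, ends)]


def build_empirical_compounds(
    ann: PeakAnnotation,
    peaks: RankedPeakList,
    rt_tol: float | None = None,
) -> list[EmpiricalCompound]:
    """Group matches into empirical compounds by candidate + RT proximity.

    Matches sharing a candidate compound are single-linkage clustered on
    the RT of their peaks at tolerance ``rt_tol`` (default: 1% of the
    observed RT range).  Each cluster becomes one EmpiricalCompound; the
    same compound seen at well-separated RTs yields several.  The output
    partitions the match set.
    """
    if peaks.rt is None:
        raise DataError(
            "empirical compounds need retention time; for m/z-only data "
            "use the v1 (compound-level) path"
        )
    if rt_tol is None:
        rt_tol = default_rt_tolerance(peaks.rt)
    if rt_tol <= 0:
        raise DataError("rt_tol must be positive")

    by_compound: dict[str, list[Match]] = {}
    for m in ann.matches:
        by_compound.setdefault(m.compound_id, []).append(m)

    ecs: list[EmpiricalCompound] = []
    for cid in sorted(by_compound):
        ms = by_compound[cid]
        rts = np.array([peaks.rt[m.feature_index] for m in ms], dtype=float)
        for idx in cluster_rts_single_linkage(rts, rt_tol):
            members = [ms[i] for i in idx]
            ecs.append(
                EmpiricalCompound(
                    ec_id="",
                    matches=members,
                    rt_center=float(rts[idx].mean()),
                    compound_ids=frozenset({cid}),
                )
            )
    ecs.sort(key=lambda e: (sorted(e.compound_ids)[0], e.rt_center))
    for k, ec in enumerate(ecs, start=1):
        ec.ec_id = f"EC{k:05d}"
    return ecs


# ---------------------------------------------------------------------------
# Compound-name normalization and matching
# ---------------------------------------------------------------------------

_CHAIN_RE = r"(?:[doptme]+-)?\d+:\d+(?:\(\d*[ez]?\))?(?:[/_](?:[doptme]+-)?\d+:\d+(?:\(\d*[ez]?\))?)*"
_BARE_LIPID_RE = re.compile(r"^(?P<cls>[a-z][a-z0-9\- ]*?)[\s\-]+(?P<chain>" + _CHAIN_RE + r")$")


def normalize_compound_name(name: str) -> str:
    """Canonicalize a compound/lipid name for robust matching.

    Lowercases, collapses whitespace, normalizes bracket style to
    ``(...)``, removes the space between a lipid class token and its
    chain descriptor, and wraps a bare chain descriptor in parentheses,
    so that ``"PC (16:0/18:1)"``, ``"PC(16:0/18:1)"`` and
    ``"pc 16:0/18:1"`` all map to ``"pc(16:0/18:1)"``.  Chain separators
    ``/`` and ``_`` are preserved as given.  Idempotent.
    """
    s = " ".join(name.lower().split())
    s = s.translate(str.maketrans("[]{}", "()()"))
    s = re.sub(r"\s*\(\s*", "(", s)
    s = re.sub(r"\s*\)\s*", ")", s).strip()
    m = _BARE_LIPID_RE.match(s)
    if m and "(" not in s:
        s = f"{m.group('cls').strip()}({m.group('chain')})"
    return s


def match_names(
    names: list[str], db: CompoundDB
) -> list[tuple[str, str | None, str]]:
    """Map free-text compound names onto database IDs.

    Priority: exact primary name > exact synonym > normalized-form match
    (against normalized primary names and synonyms); first hit in
    database order wins.  Returns (input, compound_id or None,
    match_type) with match_type in {exact, synonym, normalized, none}.
    """
    primary = {rec.primary_name: rec.compound_id for rec in reversed(db.records)}
    synonym: dict[str, str] = {}
    normalized: dict[str, str] = {}
    for rec in reversed(db.records):
        for syn in rec.synonyms:
            synonym[syn] = rec.compound_id
        normalized[normalize_compound_name(rec.primary_name)] = rec.compound_id
        for syn in rec.synonyms:
            normalized[normalize_compound_name(syn)] = rec.compound_id

    out: list[tuple[str, str | None, str]] = []
    for name in names:
        if name in primary:
            out.append((name, primary[name], "exact"))
        elif name in synonym:
            out.append((name, synonym[name], "synonym"))
        elif (norm := normalize_compound_name(name)) in normalized:
            out.append((name, normalized[norm], "normalized"))
        else:
            out.append((name, None, "none"))
    return out
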