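"""Readers and writers for every external representation the tool touches.

All downstream modules consume only the domain types defined here:

* :class:`PeakTable` — feature x sample intensity matrix keyed by m/z
  (and optionally retention time), with one group label per sample.
* :class:`RankedPeakList` — per-feature (m/z, rt, p, t) rows, the input
  to putative annotation and pathway activity prediction.
* :class:`PathwayLibrary` — GMT-style pathway/metabolite-set library
  whose members may be compounds, genes, or both.
* :class:`CompoundDB` — compound records with monoisotopic masses,
  synonyms and a currency-metabolite flag.

Conventions
-----------
* Missing values are ``NaN`` in the intensity matrix.  An empty cell,
  ``NA`` or ``NaN`` (case-insensitive) on input all map to missing;
  a measured ``0`` stays zero.  The distinction matters for the
  technical-replicate merging rule.
* All text I/O is UTF-8 and independent of OS line endings.
* Peak-table feature keys use the ``mz__rt`` dialect (double
  underscore); a purely numeric key is interpreted as m/z only.
"""

from __future__ import annotations

import csv
import io
import math
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DataError

MISSING_SENTINELS = {"", "na", "nan", "null"}

_POSITIVE, _NEGATIVE, _MIXED = "positive", "negative", "mixed"
VALID_MODES = (_POSITIVE, _NEGATIVE, _MIXED)


def _as_text(stream) -> io.StringIO:
    """Accept a path, a string of content-bearing text, or a file object.

    Paths win over raw content: a short string naming an existing file is
    read from disk; anything containing a newline or tab is treated as
    literal document text.
    """
    if isinstance(stream, Path):
        return io.StringIO(stream.read_text(encoding="utf-8"))
    if isinstance(stream, str):
        if "\n" not in stream and "\t" not in stream and Path(stream).exists():
            return io.StringIO(Path(stream).read_text(encoding="utf-8"))
        return io.StringIO(stream)
    return io.StringIO(stream.read())


def _parse_float(token: str, context: str) -> float:
    try:
        return float(token)
    except ValueError:
        raise DataError(f"non-numeric value {token!r} in {context}") from None


def _is_missing(token: str) -> bool:
    return token.strip().lower() in MISSING_SENTINELS


def _data_rows(stream, sep: str) -> list[list[str]]:
    """Tokenize, dropping blank lines and '#' comment/header lines."""
    rows = csv.reader(_as_text(stream), delimiter=sep)
    return [
        r for r in rows
        if any(c.strip() for c in r) and not r[0].lstrip().startswith("#")
    ]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class PeakTable:
    """Feature x sample intensity matrix with m/z (and optional RT) keys.

    ``intensities`` holds NaN for missing cells; measured zeros are kept
    as 0.0.  ``neutral_mass`` marks tables whose m/z column is already a
    neutral monoisotopic mass (e.g. from mzTab-M theoretical masses), in
    which case annotation must not apply adduct mass shifts.
    """

    feature_ids: list[str]
    mz: np.ndarray
    rt: np.ndarray | None
    intensities: np.ndarray
    sample_ids: list[str]
    group_labels: list[str]
    mode: str = _POSITIVE
    neutral_mass: bool = False

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.rt is not None:
            self.rt = np.asarray(self.rt, dtype=float)
        n_feat, n_samp = len(self.feature_ids), len(self.sample_ids)
        if self.intensities.shape != (n_feat, n_samp):
            raise DataError(
                f"intensity matrix shape {self.intensities.shape} does not "
                f"match {n_feat} features x {n_samp} samples"
            )
        if len(self.group_labels) != n_samp:
            raise DataError("one group label per sample is required")
        if self.mz.shape != (n_feat,):
            raise DataError("one m/z value per feature is required")
        if np.any(self.mz <= 0):
            raise DataError("m/z values must be strictly positive")
        if self.rt is not None and np.any(self.rt < 0):
            raise DataError("retention times must be non-negative")
        if self.mode not in VALID_MODES:
            raise DataError(f"unknown ionization mode {self.mode!r}")

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


@dataclass
class RankedPeakList:
    """Rows of (m/z, rt, p-value, signed statistic), canonically sorted.

    The canonical order is ascending p-value, ties broken by descending
    |statistic|, then ascending m/z — deterministic for any input.
    """

    mz: np.ndarray
    rt: np.ndarray | None
    p_value: np.ndarray
    statistic: np.ndarray
    mode: str = _POSITIVE
    neutral_mass: bool = False

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.p_value = np.asarray(self.p_value, dtype=float)
        self.statistic = np.asarray(self.statistic, dtype=float)
        if self.rt is not None:
            self.rt = np.asarray(self.rt, dtype=float)
        if np.any((self.p_value < 0) | (self.p_value > 1)):
            bad = self.p_value[(self.p_value < 0) | (self.p_value > 1)][0]
            raise DataError(f"p-value {bad} outside [0, 1]")
        if self.mode not in VALID_MODES:
            raise DataError(f"unknown ionization mode {self.mode!r}")

    def __len__(self) -> int:
        return len(self.mz)

    def sorted(self) -> "RankedPeakList":
        """Return a copy in the canonical deterministic order."""
        order = np.lexsort((self.mz, -np.abs(self.statistic), self.p_value))
        return RankedPeakList(
            mz=self.mz[order],
            rt=None if self.rt is None else self.rt[order],
            p_value=self.p_value[order],
            statistic=self.statistic[order],
            mode=self.mode,
            neutral_mass=self.neutral_mass,
        )


@dataclass(frozen=True)
class PathwayEntry:
    pathway_id: str
    pathway_name: str
    compound_ids: frozenset[str]
    gene_ids: frozenset[str]
    category: str = "metabolic"


@dataclass
class PathwayLibrary:
    pathways: list[PathwayEntry]
    universe_compounds: set[str] = field(default_factory=set)
    universe_genes: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.universe_compounds and not self.universe_genes:
            for p in self.pathways:
                self.universe_compounds |= p.compound_ids
                self.universe_genes |= p.gene_ids
        for p in self.pathways:
            if not p.compound_ids and not p.gene_ids:
                raise DataError(f"pathway {p.pathway_id} has no members")
            if not p.compound_ids <= self.universe_compounds:
                raise DataError(f"pathway {p.pathway_id} has compounds outside the universe")
            if not p.gene_ids <= self.universe_genes:
                raise DataError(f"pathway {p.pathway_id} has genes outside the universe")


@dataclass(frozen=True)
class CompoundRecord:
    compound_id: str
    monoisotopic_mass: float
    primary_name: str
    synonyms: tuple[str, ...] = ()


@dataclass
class CompoundDB:
    records: list[CompoundRecord]
    currency_ids: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.compound_id in seen:
                raise DataError(f"duplicate compound id {rec.compound_id!r}")
            seen.add(rec.compound_id)
            if rec.monoisotopic_mass <= 0:
                raise DataError(
                    f"compound {rec.compound_id!r} has non-positive mass "
                    f"{rec.monoisotopic_mass}"
                )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.compound_id for r in self.records]

    @property
    def masses(self) -> np.ndarray:
        return np.array([r.monoisotopic_mass for r in self.records], dtype=float)

    def by_id(self, compound_id: str) -> CompoundRecord:
        for rec in self.records:
            if rec.compound_id == compound_id:
                return rec
        raise KeyError(compound_id)


# ---------------------------------------------------------------------------
# Peak tables
# ---------------------------------------------------------------------------

_FEATURE_KEY_RE = re.compile(r"^(?P<mz>[0-9.eE+-]+)(?:__(?P<rt>[0-9.eE+-]+))?$")


def parse_feature_key(key: str) -> tuple[float, float | None]:
    """Split an ``mz__rt`` (or bare ``mz``) feature key."""
    m = _FEATURE_KEY_RE.match(key.strip())
    if m is None:
        raise DataError(f"cannot parse feature key {key!r} as 'mz' or 'mz__rt'")
    mz = _parse_float(m.group("mz"), f"feature key {key!r}")
    rt = m.group("rt")
    return mz, (None if rt is None else _parse_float(rt, f"feature key {key!r}"))


def read_peak_table(stream, dialect: str = "tsv", mode: str = _POSITIVE) -> PeakTable:
    """Read a two-header peak intensity table.

    The first header row carries sample IDs, the second carries group
    labels, and the first column is the feature key encoded ``mz__rt``
    or ``mz``.
    """
    sep = "\t" if dialect == "tsv" else ","
    rows = _data_rows(stream, sep)
    if len(rows) < 2:
        raise DataError("peak table needs a sample-ID row and a group-label row")
    sample_ids = [c.strip() for c in rows[0][1:]]
    group_labels = [c.strip() for c in rows[1][1:]]
    if len(group_labels) != len(sample_ids):
        raise DataError("group-label row length does not match sample-ID row")

    feature_ids: list[str] = []
    mzs: list[float] = []
    rts: list[float | None] = []
    data: list[list[float]] = []
    seen: set[str] = set()
    for irow, row in enumerate(rows[2:], start=3):
        key = row[0].strip()
        if key in seen:
            raise DataError(f"duplicate feature key {key!r}")
        seen.add(key)
        mz, rt = parse_feature_key(key)
        cells = row[1:]
        if len(cells) != len(sample_ids):
            raise DataError(f"row {irow} has {len(cells)} cells, expected {len(sample_ids)}")
        vals = [
            math.nan if _is_missing(c)
            else _parse_float(c, f"row {irow} ({key}), column {sample_ids[j]}")
            for j, c in enumerate(cells)
        ]
        feature_ids.append(key)
        mzs.append(mz)
        rts.append(rt)
        data.append(vals)

    has_rt = [r is not None for r in rts]
    if any(has_rt) and not all(has_rt):
        raise DataError("retention time present for some features but not all")
    rt_arr = np.array(rts, dtype=float) if all(has_rt) and rts else None
    return PeakTable(
        feature_ids=feature_ids,
        mz=np.array(mzs, dtype=float),
        rt=rt_arr,
        intensities=np.array(data, dtype=float).reshape(len(feature_ids), len(sample_ids)),
        sample_ids=sample_ids,
        group_labels=group_labels,
        mode=mode,
    )


def write_peak_table(table: PeakTable, stream, dialect: str = "tsv") -> None:
    """Write a peak table in the two-header dialect at full precision."""
    sep = "\t" if dialect == "tsv" else ","
    out = stream if hasattr(stream, "write") else open(stream, "w", encoding="utf-8", newline="")
    close = out is not stream
    try:
        out.write("feature" + sep + sep.join(table.sample_ids) + "\n")
        out.write("group" + sep + sep.join(table.group_labels) + "\n")
        for i, fid in enumerate(table.feature_ids):
            cells = [
                "NA" if math.isnan(v) else repr(float(v))
                for v in table.intensities[i]
            ]
            out.write(fid + sep + sep.join(cells) + "\n")
    finally:
        if close:
            out.close()


# ---------------------------------------------------------------------------
# Ranked peak lists
# ---------------------------------------------------------------------------

_COLUMN_ALIASES = {
    "mz": {"m.z", "mz", "m/z", "m_z", "mass"},
    "rt": {"r.t", "rt", "retention_time", "retention.time"},
    "p": {"p.value", "p_value", "pvalue", "p"},
    "t": {"t.score", "t_score", "tscore", "t", "statistic", "stat"},
}


def _locate_columns(header: Sequence[str], wanted: Iterable[str]) -> dict[str, int]:
    lowered = [h.strip().lower() for h in header]
    found: dict[str, int] = {}
    for name in wanted:
        for j, h in enumerate(lowered):
            if h in _COLUMN_ALIASES[name]:
                found[name] = j
                break
    return found


def read_ranked_peaks(
    stream, has_rt: bool = False, mode: str = _POSITIVE, dialect: str = "tsv"
) -> RankedPeakList:
    """Read a ranked peak list (m/z, optional RT, p-value, t statistic).

    Columns are matched case-insensitively in any order; the result is
    returned in the canonical sort order (ascending p, descending |t|,
    ascending m/z).
    """
    sep = "\t" if dialect == "tsv" else ","
    rows = _data_rows(stream, sep)
    if not rows:
        raise DataError("empty ranked peak list")
    wanted = ["mz", "p", "t"] + (["rt"] if has_rt else [])
    cols = _locate_columns(rows[0], wanted)
    for name in wanted:
        if name not in cols:
            pretty = {"mz": "m.z", "rt": "r.t", "p": "p.value", "t": "t.score"}[name]
            raise DataError(f"missing mandatory column {pretty!r}")

    mzs, rts, ps, ts = [], [], [], []
    for irow, row in enumerate(rows[1:], start=2):
        mzs.append(_parse_float(row[cols["mz"]], f"row {irow}, m.z"))
        ps.append(_parse_float(row[cols["p"]], f"row {irow}, p.value"))
        ts.append(_parse_float(row[cols["t"]], f"row {irow}, t.score"))
        if has_rt:
            rts.append(_parse_float(row[cols["rt"]], f"row {irow}, r.t"))
        if not 0 <= ps[-1] <= 1:
            raise DataError(f"p-value {ps[-1]} outside [0, 1] at row {irow}")

    keys = list(zip(mzs, rts)) if has_rt else list(zip(mzs))
    if len(set(keys)) != len(keys):
        dup = next(k for k in keys if keys.count(k) > 1)
        raise DataError(f"duplicate (mz, rt) row {dup}")
    return RankedPeakList(
        mz=np.array(mzs),
        rt=np.array(rts) if has_rt else None,
        p_value=np.array(ps),
        statistic=np.array(ts),
        mode=mode,
    ).sorted()


# ---------------------------------------------------------------------------
# mzTab-M 2.0 (MTD + SML sections)
# ---------------------------------------------------------------------------

_ASSAY_COL_RE = re.compile(r"^abundance_assay\[(\d+)\]$")


def read_mztab_m(stream) -> PeakTable:
    """Read the small-molecule summary (SML) of an mzTab-M 2.0 document.

    One PeakTable row is produced per SML row.  ``exp_mass_to_charge``
    is preferred as the m/z key; when absent, ``theoretical_neutral_mass``
    is used and the table is flagged ``neutral_mass`` so that annotation
    skips adduct mass shifts.  Assay-to-study-variable mappings from the
    MTD section become the group labels.  SMF/SME sections are ignored.
    """
    mtd: dict[str, str] = {}
    smh: list[str] | None = None
    sml_rows: list[list[str]] = []
    for raw in _as_text(stream):
        line = raw.rstrip("\r\n")
        if not line.strip():
            continue
        fields = line.split("\t")
        tag = fields[0].strip()
        if tag == "MTD" and len(fields) >= 3:
            mtd[fields[1].strip()] = fields[2].strip()
        elif tag == "SMH":
            smh = [f.strip() for f in fields]
        elif tag == "SML":
            sml_rows.append(fields)

    version = mtd.get("mzTab-version", "")
    if version and version != "2.0.0-M":
        warnings.warn(
            f"mzTab version {version!r} is not '2.0.0-M'; attempting to parse anyway",
            stacklevel=2,
        )
    if smh is None or not sml_rows:
        raise DataError("no SML (small molecule summary) section found")

    col = {name: j for j, name in enumerate(smh)}
    assay_cols = sorted(
        ((int(m.group(1)), j) for name, j in col.items() if (m := _ASSAY_COL_RE.match(name))),
    )
    if not assay_cols:
        raise DataError("SML section has no abundance_assay columns")

    sample_ids = [
        mtd.get(f"assay[{num}]", f"assay[{num}]") for num, _ in assay_cols
    ]
    assay_to_group: dict[int, str] = {}
    for key, value in mtd.items():
        m = re.match(r"^study_variable\[(\d+)\]-assay_refs$", key)
        if m:
            sv_name = mtd.get(f"study_variable[{m.group(1)}]", f"study_variable[{m.group(1)}]")
            for ref in value.split("|"):
                ma = re.match(r"^assay\[(\d+)\]$", ref.strip())
                if ma:
                    assay_to_group[int(ma.group(1))] = sv_name
    group_labels = [assay_to_group.get(num, "unassigned") for num, _ in assay_cols]

    def cell(row: list[str], name: str) -> str:
        j = col.get(name)
        return row[j].strip() if j is not None and j < len(row) else ""

    feature_ids, mzs, data = [], [], []
    neutral_flags = []
    for row in sml_rows:
        sml_id = cell(row, "SML_ID") or f"SML{len(feature_ids) + 1}"
        exp_mz = cell(row, "exp_mass_to_charge")
        theo = cell(row, "theoretical_neutral_mass")
        if exp_mz and not _is_missing(exp_mz):
            mzs.append(_parse_float(exp_mz, f"SML {sml_id}, exp_mass_to_charge"))
            neutral_flags.append(False)
        elif theo and not _is_missing(theo):
            mzs.append(_parse_float(theo, f"SML {sml_id}, theoretical_neutral_mass"))
            neutral_flags.append(True)
        else:
            raise DataError(f"SML row {sml_id} has neither experimental m/z nor neutral mass")
        feature_ids.append(sml_id)
        vals = []
        for _, j in assay_cols:
            tok = row[j].strip() if j < len(row) else ""
            vals.append(math.nan if _is_missing(tok) else _parse_float(tok, f"SML {sml_id}"))
        data.append(vals)

    polarity = mtd.get("assay[1]-ms_run_ref", "")
    del polarity  # scan polarity is not reliably present; callers set mode
    return PeakTable(
        feature_ids=feature_ids,
        mz=np.array(mzs),
        rt=None,
        intensities=np.array(data, dtype=float),
        sample_ids=sample_ids,
        group_labels=group_labels,
        neutral_mass=all(neutral_flags),
    )


# ---------------------------------------------------------------------------
# Pathway libraries (GMT dialect) and compound databases
# ---------------------------------------------------------------------------

def read_pathway_library(stream) -> PathwayLibrary:
    """Read a GMT-dialect library: id TAB name TAB member TAB member ...

    Members prefixed ``cpd:`` are compounds, ``gene:`` genes; an
    unprefixed member defaults to compound.  Member sets are sets: a
    repeated member counts once.
    """
    pathways: list[PathwayEntry] = []
    for lineno, raw in enumerate(_as_text(stream), start=1):
        line = raw.rstrip("\r\n")
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise DataError(f"GMT line {lineno} has {len(fields)} fields, expected >= 3")
        pid, name, *members = [f.strip() for f in fields]
        cpds, genes = set(), set()
        for m in members:
            if not m:
                continue
            if m.startswith("gene:"):
                genes.add(m[5:])
            elif m.startswith("cpd:"):
                cpds.add(m[4:])
            else:
                cpds.add(m)
        pathways.append(PathwayEntry(pid, name, frozenset(cpds), frozenset(genes)))
    return PathwayLibrary(pathways=pathways)


def write_pathway_library(lib: PathwayLibrary, stream) -> None:
    out = stream if hasattr(stream, "write") else open(stream, "w", encoding="utf-8", newline="")
    close = out is not stream
    try:
        for p in lib.pathways:
            members = ["cpd:" + c for c in sorted(p.compound_ids)]
            members += ["gene:" + g for g in sorted(p.gene_ids)]
            out.write("\t".join([p.pathway_id, p.pathway_name] + members) + "\n")
    finally:
        if close:
            out.close()


def read_compound_db(stream, dialect: str = "tsv") -> CompoundDB:
    """Read a compound database TSV: id, monoisotopic_mass, name, synonyms, is_currency."""
    sep = "\t" if dialect == "tsv" else ","
    rows = _data_rows(stream, sep)
    if not rows:
        raise DataError("empty compound database")
    header = [h.strip().lower() for h in rows[0]]
    required = ["id", "monoisotopic_mass", "name"]
    for name in required:
        if name not in header:
            raise DataError(f"missing compound-db column {name!r}")
    col = {name: header.index(name) for name in header}

    records: list[CompoundRecord] = []
    currency: set[str] = set()
    for row in rows[1:]:
        cid = row[col["id"]].strip()
        mass = _parse_float(row[col["monoisotopic_mass"]], f"compound {cid!r} mass")
        if mass <= 0:
            raise DataError(f"compound {cid!r} has non-positive mass {mass}")
        syn_tok = row[col["synonyms"]].strip() if "synonyms" in col and col["synonyms"] < len(row) else ""
        synonyms = tuple(s.strip() for s in syn_tok.split(";") if s.strip())
        records.append(CompoundRecord(cid, mass, row[col["name"]].strip(), synonyms))
        if "is_currency" in col and col["is_currency"] < len(row):
            if row[col["is_currency"]].strip() == "1":
                currency.add(cid)
    return CompoundDB(records=records, currency_ids=currency)


def write_compound_db(db: CompoundDB, stream) -> None:
    out = stream if hasattr(stream, "write") else open(stream, "w", encoding="utf-8", newline="")
    close = out is not stream
    try:
        out.write("id\tmonoisotopic_mass\tname\tsynonyms\tis_currency\n")
        for rec in db.records:
            out.write(
                "\t".join(
                    [
                        rec.compound_id,
                        repr(rec.monoisotopic_mass),
                        rec.primary_name,
                        ";".join(rec.synonyms),
                        "1" if rec.compound_id in db.currency_ids else "0",
                    ]
                )
                + "\n"
            )
    finally:
        if close:
            out.close()


# ---------------------------------------------------------------------------
# Results tables
# ---------------------------------------------------------------------------

def _format_cell(v) -> str:
    if isinstance(v, (float, np.floating)):
        if math.isnan(v):
            return "NA"
        return f"{v:.6g}"
    if isinstance(v, (bool, np.bool_)):
        return "true" if v else "false"
    return str(v)


def write_results_table(result, stream, header_lines: Sequence[str] = ()) -> None:
    """Write any tabular result deterministically as TSV.

    Accepts a pandas DataFrame or any result object exposing
    ``to_frame()``.  Column order is the type's documented fixed order;
    floats are printed at 6 significant digits, so writing the same
    result twice yields byte-identical files.
    """
    frame = result if isinstance(result, pd.DataFrame) else result.to_frame()
    out = stream if hasattr(stream, "write") else open(stream, "w", encoding="utf-8", newline="")
    close = out is not stream
    try:
        for line in header_lines:
            out.write("# " + line + "\n")
        out.write("\t".join(map(str, frame.columns)) + "\n")
        for _, row in frame.iterrows():
            out.write("\t".join(_format_cell(v) for v in row) + "\n")
    finally:
        if close:
            out.close()
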