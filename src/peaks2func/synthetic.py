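"""Deterministic synthetic-data generators with known ground truth.

Every generator is a pure function of its seed and emulates the
structure of untargeted LC-MS1 data at the level the downstream methods
consume: compound databases with well-separated monoisotopic masses,
pathway libraries with controlled overlap, peak tables whose features
are adduct ions of database compounds (with ppm-scale mass error,
co-eluting adducts, log-normal intensities, and planted group effects
on the members of chosen "active" pathways), decoy peaks matching no
compound, and multivariate-normal feature matrices with a known sparse
precision matrix for network benchmarks.

These fixtures capture annotation ambiguity, mass error, RT co-elution
and planted differential signal; they do not model isotope envelopes,
chromatographic peak shape, or matrix effects of real instruments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .annotation import AdductRule, load_adduct_rules, predicted_mz
from .errors import DataError
from .io_formats import (
    CompoundDB,
    CompoundRecord,
    PathwayEntry,
    PathwayLibrary,
    PeakTable,
    RankedPeakList,
)


@dataclass
class FixtureSpec:
    """Study conditions for the synthetic fixtures.

    Defaults describe a modest two-group untargeted experiment: 100
    compounds organized in 20 pathways of 8-12 members, 6 samples per
    group, one active pathway whose members carry a log-fold-change of
    2 in group 2, log-normal intensities with noise_sd on the log
    scale, 20% decoy peaks, and a 30-900 s retention window.
    """

    seed: int = 0
    n_compounds: int = 100
    n_pathways: int = 20
    pathway_size_range: tuple[int, int] = (8, 12)
    n_samples_per_group: int = 6
    n_active_pathways: int = 1
    effect_size: float = 2.0
    noise_sd: float = 0.5
    n_currency: int = 3
    decoy_peak_fraction: float = 0.2
    rt_range: tuple[float, float] = (30.0, 900.0)
    mass_error_ppm_sd: float = 2.0
    coelution_window_s: float = 2.0
    adduct_rules: list[AdductRule] = field(default_factory=list)
    mode: str = "positive"

    def __post_init__(self) -> None:
        if min(self.n_compounds, self.n_pathways, self.n_samples_per_group) <= 0:
            raise DataError("all fixture counts must be positive")
        if self.effect_size < 0:
            raise DataError("effect_size must be non-negative")
        if not self.adduct_rules:
            self.adduct_rules = load_adduct_rules(mode=self.mode)


MASS_RANGE = (80.0, 800.0)
MIN_SPACING_PPM = 50.0


def generate_compound_db(spec: FixtureSpec) -> CompoundDB:
    """Compounds with masses uniform in [80, 800] Da at > 50 ppm spacing."""
    rng = np.random.default_rng(spec.seed)
    lo, hi = MASS_RANGE
    masses: list[float] = []
    attempts = 0
    while len(masses) < spec.n_compounds:
        attempts += 1
        if attempts > 200 * spec.n_compounds:
            raise DataError(
                f"cannot place {spec.n_compounds} masses at > {MIN_SPACING_PPM} ppm spacing"
            )
        m = float(rng.uniform(lo, hi))
        if all(abs(m - x) / x * 1e6 > MIN_SPACING_PPM for x in masses):
            masses.append(m)
    records = [
        CompoundRecord(f"C{i + 1:04d}", m, f"compound-{i + 1}")
        for i, m in enumerate(masses)
    ]
    currency = set()
    if spec.n_currency:
        picks = rng.choice(spec.n_compounds, size=min(spec.n_currency, spec.n_compounds),
                           replace=False)
        currency = {records[i].compound_id for i in picks}
    return CompoundDB(records=records, currency_ids=currency)


def generate_pathway_library(
    db: CompoundDB,
    spec: FixtureSpec,
    overlap: bool = True,
    genes_per_pathway: int = 0,
) -> PathwayLibrary:
    """Pathways sampled from the database, with or without overlap.

    With ``overlap=False`` the pathways partition disjoint slices of the
    compound list; otherwise members are drawn without replacement
    within each pathway but freely across pathways.  Optional gene
    members support joint-analysis fixtures.
    """
    rng = np.random.default_rng(spec.seed + 1)
    ids = db.ids
    lo, hi = spec.pathway_size_range
    if hi > len(ids):
        raise DataError("pathway size exceeds database size")
    pathways: list[PathwayEntry] = []
    cursor = 0
    gene_counter = 0
    for i in range(spec.n_pathways):
        size = int(rng.integers(lo, hi + 1))
        if overlap:
            members = [ids[j] for j in rng.choice(len(ids), size=size, replace=False)]
        else:
            if cursor + size > len(ids):
                raise DataError("not enough compounds for non-overlapping pathways")
            members = ids[cursor:cursor + size]
            cursor += size
        genes = frozenset(
            f"G{gene_counter + j + 1:05d}" for j in range(genes_per_pathway)
        )
        gene_counter += genes_per_pathway
        pathways.append(
            PathwayEntry(f"P{i + 1:03d}", f"pathway-{i + 1}", frozenset(members), genes)
        )
    return PathwayLibrary(pathways=pathways)


def _decoy_mzs(rng, n: int, predicted: np.ndarray, guard_ppm: float = 10.0) -> np.ndarray:
    """m/z values at least guard_ppm away from every predicted adduct m/z."""
    pred = np.sort(predicted)
    out: list[float] = []
    while len(out) < n:
        m = float(rng.uniform(MASS_RANGE[0], MASS_RANGE[1] + 60.0))
        j = np.searchsorted(pred, m)
        near = []
        if j > 0:
            near.append(pred[j - 1])
        if j < pred.size:
            near.append(pred[j])
        if all(abs(m - x) / x * 1e6 > guard_ppm for x in near):
            out.append(m)
    return np.array(out)


def generate_peak_table(
    db: CompoundDB,
    lib: PathwayLibrary,
    spec: FixtureSpec,
) -> tuple[PeakTable, dict]:
    """Two-group peak table of adduct ions with planted pathway effects.

    Every non-currency compound is observed as 1-3 adduct peaks at its
    predicted m/z plus Normal(0, 2 ppm) mass error; adducts of one
    compound co-elute within the co-elution window.  Intensities are
    log-normal; features of compounds in the active pathways have their
    group-2 intensities multiplied by exp(effect_size).  Decoy peaks
    lie >= 10 ppm from every predicted adduct m/z.  Returns the table
    and a ground-truth dict (active pathways, planted feature ids,
    feature-to-compound map).
    """
    if spec.n_active_pathways > len(lib.pathways):
        raise DataError("more active pathways requested than pathways available")
    rng = np.random.default_rng(spec.seed + 2)
    rules = spec.adduct_rules
    active_idx = rng.choice(len(lib.pathways), size=spec.n_active_pathways, replace=False)
    active_ids = [lib.pathways[i].pathway_id for i in sorted(active_idx)]
    active_compounds: set[str] = set()
    for i in active_idx:
        active_compounds |= set(lib.pathways[i].compound_ids)

    observable = [r for r in db.records if r.compound_id not in db.currency_ids]
    all_predicted = np.array(
        [predicted_mz(rec.monoisotopic_mass, rule) for rec in observable for rule in rules]
    )

    mzs: list[float] = []
    rts: list[float] = []
    planted: list[int] = []
    feature_compound: list[str | None] = []
    for rec in observable:
        n_add = int(rng.integers(1, min(3, len(rules)) + 1))
        rule_idx = rng.choice(len(rules), size=n_add, replace=False)
        rt0 = float(rng.uniform(*spec.rt_range))
        for ri in sorted(rule_idx):
            mz0 = predicted_mz(rec.monoisotopic_mass, rules[ri])
            mz = mz0 * (1 + rng.normal(0.0, spec.mass_error_ppm_sd) * 1e-6)
            rt = rt0 + float(rng.uniform(-spec.coelution_window_s / 2,
                                         spec.coelution_window_s / 2))
            rt = min(max(rt, 0.0), spec.rt_range[1] + spec.coelution_window_s)
            if rec.compound_id in active_compounds:
                planted.append(len(mzs))
            feature_compound.append(rec.compound_id)
            mzs.append(mz)
            rts.append(rt)

    n_decoys = int(round(spec.decoy_peak_fraction * len(mzs)))
    for m in _decoy_mzs(rng, n_decoys, all_predicted):
        feature_compound.append(None)
        mzs.append(float(m))
        rts.append(float(rng.uniform(*spec.rt_range)))

    n_feat = len(mzs)
    n_per = spec.n_samples_per_group
    base = rng.normal(np.log(1e5), 1.0, size=n_feat)
    noise = rng.normal(0.0, spec.noise_sd, size=(n_feat, 2 * n_per))
    logI = base[:, None] + noise
    planted_mask = np.zeros(n_feat, dtype=bool)
    planted_mask[planted] = True
    logI[planted_mask, n_per:] += spec.effect_size
    intensities = np.exp(logI)

    feature_ids = [f"{mz:.5f}__{rt:.2f}" for mz, rt in zip(mzs, rts)]
    table = PeakTable(
        feature_ids=feature_ids,
        mz=np.array(mzs),
        rt=np.array(rts),
        intensities=intensities,
        sample_ids=[f"S{j + 1}" for j in range(2 * n_per)],
        group_labels=["group1"] * n_per + ["group2"] * n_per,
        mode=spec.mode,
    )
    truth = {
        "active_pathways": active_ids,
        "planted_features": [feature_ids[i] for i in planted],
        "feature_compound": dict(zip(feature_ids, feature_compound)),
    }
    return table, truth


def generate_complementary_peak_lists(
    db: CompoundDB,
    lib: PathwayLibrary,
    spec: FixtureSpec,
) -> tuple[RankedPeakList, RankedPeakList, dict]:
    """Positive/negative-mode peak lists where coverage is complementary.

    Each compound ionizes in exactly one mode (assigned alternately in
    database order), so roughly half of every pathway's members are
    visible per mode and only pooling the two lists sees the whole
    pathway.  Active-pathway peaks get p-values uniform below 0.01;
    background peaks get uniform p-values.  Decoys are added per mode.
    """
    rng = np.random.default_rng(spec.seed + 3)
    pos_rules = load_adduct_rules(mode="positive")
    neg_rules = load_adduct_rules(mode="negative")
    active_idx = rng.choice(len(lib.pathways), size=spec.n_active_pathways, replace=False)
    active_ids = [lib.pathways[i].pathway_id for i in sorted(active_idx)]
    active_compounds: set[str] = set()
    for i in active_idx:
        active_compounds |= set(lib.pathways[i].compound_ids)

    observable = [r for r in db.records if r.compound_id not in db.currency_ids]
    lists = {}
    for mode, rules, parity in (("positive", pos_rules, 0), ("negative", neg_rules, 1)):
        own = [r for j, r in enumerate(observable) if j % 2 == parity]
        predicted = np.array(
            [predicted_mz(rec.monoisotopic_mass, rule) for rec in observable for rule in rules]
        )
        mzs, ps, ts, rts = [], [], [], []
        for rec in own:
            rule = rules[int(rng.integers(0, len(rules)))]
            mz0 = predicted_mz(rec.monoisotopic_mass, rule)
            mzs.append(mz0 * (1 + rng.normal(0.0, spec.mass_error_ppm_sd) * 1e-6))
            rts.append(float(rng.uniform(*spec.rt_range)))
            if rec.compound_id in active_compounds:
                ps.append(float(rng.uniform(0.0, 0.01)))
                ts.append(float(rng.normal(5.0, 1.0)))
            else:
                ps.append(float(rng.uniform(0.0, 1.0)))
                ts.append(float(rng.normal(0.0, 1.0)))
        n_decoys = int(round(spec.decoy_peak_fraction * len(own)))
        for m in _decoy_mzs(rng, n_decoys, predicted):
            mzs.append(float(m))
            rts.append(float(rng.uniform(*spec.rt_range)))
            ps.append(float(rng.uniform(0.0, 1.0)))
            ts.append(float(rng.normal(0.0, 1.0)))
        lists[mode] = RankedPeakList(
            mz=np.array(mzs), rt=np.array(rts), p_value=np.array(ps),
            statistic=np.array(ts), mode=mode,
        ).sorted()
    truth = {"active_pathways": active_ids}
    return lists["positive"], lists["negative"], truth


def generate_network_data(
    precision: np.ndarray, n: int, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Multivariate-normal draws from a known precision matrix.

    Returns (samples x features matrix, true partial correlation matrix
    rho_ij = -Theta_ij / sqrt(Theta_ii Theta_jj)).
    """
    theta = np.asarray(precision, dtype=float)
    if theta.ndim != 2 or theta.shape[0] != theta.shape[1]:
        raise DataError("precision matrix must be square")
    if not np.allclose(theta, theta.T):
        raise DataError("precision matrix must be symmetric")
    eigvals = np.linalg.eigvalsh(theta)
    if eigvals.min() <= 0:
        raise DataError("precision matrix must be positive definite")
    cov = np.linalg.inv(theta)
    rng = np.random.default_rng(seed)
    X = rng.multivariate_normal(np.zeros(theta.shape[0]), cov, size=n,
                                method="cholesky")
    d = np.sqrt(np.diag(theta))
    rho = -theta / np.outer(d, d)
    np.fill_diagonal(rho, 1.0)
    return X, rho


def chain_precision(p: int, off_diag: float = 0.4) -> np.ndarray:
    """Tridiagonal (chain) precision matrix with unit diagonal."""
    theta = np.eye(p)
    for i in range(p - 1):
        theta[i, i + 1] = theta[i + 1, i] = off_diag
    return theta


def null_spec(seed: int = 0, **overrides) -> FixtureSpec:
    """FixtureSpec with no planted effect (exchangeable groups)."""
    return replace(FixtureSpec(seed=seed), effect_size=0.0, **overrides)
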