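# Methods

This note documents the statistical machinery, the defaults, and the
choices made where the design was genuinely open. Nothing here states a
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Putative annotation

A peak with observed m/z *x* matches compound *M* (monoisotopic mass,
Da) under adduct rule *(name, n, Δ, z)* iff

    |x − (n·M + Δ)/|z|| / ((n·M + Δ)/|z|) · 10⁶ ≤ ppm_tol.

* **Adduct table.** Shipped as an editable TSV
  (`peaks2func/data/adducts.tsv`): positive mode M+H, M+Na, M+K, M+NH4,
  M+2H, M+H−H2O, 2M+H; negative mode M−H, M+Cl, M−H−H2O, M−2H, 2M−H,
  M+FA−H. Mass shifts include the proton mass 1.007276 Da; the electron
  mass is ignored (< 0.5 ppm for typical metabolites, far inside the
  matching tolerance).
* **ppm_tol = 5.0** by default — typical for modern HRMS instruments;
  exposed everywhere as a flag.
* **Currency metabolites** (flagged in the compound DB) are dropped by
  default: they occur in most pathways and would dominate any
  enrichment spuriously.
* Tables whose m/z column is already a neutral mass (mzTab-M documents
  reporting only `theoretical_neutral_mass`) are flagged and matched by
  the identity rule — applying adduct shifts to an already-neutral mass
  would be wrong.
* The matcher is a sorted-array window search; the test suite holds it
  to exact set equality with a brute-force enumeration of every
  (peak, compound, rule) triple.

## Empirical compounds (v2 counting unit)

Matches to the same candidate compound whose peaks lie within an RT
tolerance merge into one empirical compound, via single-linkage
clustering — on a 1-D RT axis this is exactly sort-and-split at the
tolerance. One compound observed at well-separated RTs yields several
empirical compounds; the output partitions the match set.

* **rt_tol** defaults to 1% of the observed RT range, adapting to
  gradient length; any absolute value can be passed instead.
* Isotope (¹³C) grouping is not modeled; grouping is adduct-only.
* Whether empirical-compound formation should additionally require
  complementary adduct pairs is an open modeling question; this
  implementation requires only a shared candidate plus RT proximity.

## Pathway activity prediction

Given a ranked peak list, the significant set `L_sig` is the peaks with
p ≤ `sig_cutoff` (default 0.05), or any explicit peak-index set
(supporting enrichment of arbitrary peak groups, e.g. a heatmap
cluster). All peaks are annotated; counting is per candidate compound
(v1) or per empirical compound (v2; requires RT).

The counting universe `N` is what is annotatable **from the full input
peak list**, not the whole database — conditioning on what the
instrument could see. Per pathway with `K` annotatable members and `k`
members hit by significant annotations out of `n_sig` significant
units, the raw score is the EASE-adjusted hypergeometric

    ease_p = P(X ≥ k − 1),  X ~ Hypergeom(N, K, n_sig),  ease_p(k=0) = 1,

a deliberately conservative variant that discounts one overlapping
member.

**Permutation calibration.** For each of `n_permutations` (default 100,
minimum 20), `|L_sig|` peaks are redrawn uniformly without replacement
from the full list and the per-pathway `ease_p` recomputed — so the
many-to-many annotation multiplicity propagates into the null. In v2
the empirical compounds are re-formed per permutation by default
(dropping a bridging peak can split a cluster; counts are clamped at
the full-data capacity so the hypergeometric stays well-defined);
`reuse_ec_structure=True` (`--fast-perm`) reuses the observed grouping.

The pooled null p-values are transformed to scores `s = −ln p` and a
Gamma(shape, scale) with location 0 is fitted by maximum likelihood to
the positive scores; null values exactly 1 form a point mass at 0
rather than entering the MLE (zeros break the likelihood, and modeling
the mass explicitly keeps the tail calibrated). The reported

    gamma_p = (1 − P[p_null = 1]) · Γ̄(−ln ease_p_obs)

is monotone in `ease_p`. A degenerate null (fewer than two distinct
positive scores, or a failed fit) falls back to the empirical upper
tail with a warning. On the bundled null fixtures (no planted effect,
200 repetitions × 100 permutations) the fraction of pathways with
`gamma_p < 0.05` lands near 0.04–0.05 — the calibration the
permutation scheme is meant to buy.

Pathways are reported sorted by `gamma_p`, ties by `ease_p` then id;
`pathway_size` counts annotatable members and, because the universe is
annotation-conditioned, coincides with `hits_total`.

## Joint gene + metabolite pathway analysis

Inputs here are identified hits, not putative annotations, so the ORA
is the plain hypergeometric `P(X ≥ k)` per omics against its own
universe (G genes, C metabolites). Combination per pathway:

* `fisher` — `X² = −2 Σ ln pᵢ`, upper tail of χ² with 2k df;
* `stouffer_overall` — weights `w_g = G/(G+C)`, `w_m = C/(G+C)`;
* `stouffer_pathway` — weights from the pathway's own gene/metabolite
  member counts;
* weighted Stouffer uses the textbook normalization
  `Z_c = Σ wᵢ Φ⁻¹(1−pᵢ) / √(Σ wᵢ²)`.

A pathway with members from only one omics reports that omics' p
directly. Combination is one-sided throughout (small p = stronger
pathway activity); effect directionality is not modeled. Note that
Fisher's method only *accumulates* evidence for informative inputs:
combining near-null p-values (e.g. two copies of 0.7) yields a larger
combined p — an inherent property of the method, not a defect.

## Functional meta-analysis

* **Pathway level** — per-dataset calibrated pathway p-values are
  reconciled by pathway id and combined by Fisher or equal-weight
  Stouffer (a per-dataset weight vector can be supplied). A pathway
  absent from a dataset contributes p = 1 and is flagged: absence of
  evidence penalizes, and the p-value matrix stays rectangular.
  Per-dataset significance flags at `alpha` provide the Venn structure.
* **Peak pooling** — each list is annotated under its own adduct rules
  (its own ion mode); annotated compounds and significant annotations
  are unioned and a single enrichment runs with permutations drawing
  from the pooled peak space. Counting is at the compound level even
  when v2 is requested: the pooled lists come from different
  chromatographic conditions, so RTs are not comparable across lists
  and cross-list RT clustering would be meaningless. Identical
  (mz, rt, mode) triples across lists are rejected as conflicting.

## DSPC networks

Features are column-standardized (optionally after `log1p`); features
with > 20% missing values are dropped with a warning and remaining
missing entries are half-minimum imputed — common metabolomics
practice, and overridable upstream. On the empirical correlation
matrix Σ̂ the graphical lasso estimates a sparse precision Θ̂ at penalty
λ, then the de-sparsified estimator

    T̂ = Θ̂ + Θ̂ᵀ − Θ̂ᵀ Σ̂ Θ̂

de-biases it; `ρ̂ᵢⱼ = −T̂ᵢⱼ/√(T̂ᵢᵢT̂ⱼⱼ)` (clamped to [−1, 1]) with
two-sided normal p-values from `Var(T̂ᵢⱼ) = (T̂ᵢᵢT̂ⱼⱼ + T̂ᵢⱼ²)/n` and
Benjamini–Hochberg q-values across all pairs. The edge list keeps
pairs with q ≤ `fdr_alpha`; the full pair table is always emitted.

* **λ selection**: grid {0.01, 0.02, 0.05, 0.1, 0.2, 0.3, 0.5}
  minimizing the extended BIC (γ = 0.5); `lam=0` (valid only for
  p < n) reduces exactly to the dense inverse-correlation estimate and
  is verified against it to 10⁻⁶.
* **Extreme p ≫ n**: the coordinate-descent solver can hit non-SPD
  iterates. The solver is retried with the correlation matrix shrunk
  toward the identity ((1−ε)Σ̂ + εI, ε ∈ {0.05, 0.1, 0.2, 0.4}), with a
  warning; the shrunk matrix is then used consistently in de-biasing.
  Estimates in this regime are conservative, and the CLI additionally
  caps network input at the 100 most variable features by default
  (`--max-features 0` disables) — partial correlations from a dozen
  samples over hundreds of features are not statistically meaningful
  anyway.

## Pre-analysis utilities

* **Replicate merging.** Per feature and biological subject with r
  technical replicates and missing fraction f: f ≤ 1/3 → mean of
  non-missing; f > 1/3 → evaluate CV = sample SD (ddof = 1) / mean of
  the non-missing values, and zero the feature as *highly variant* when
  CV > 1.0, else keep the mean. Both comparisons are strict ("over");
  a single surviving value has CV defined as 0 and is kept (SD is
  undefined at n = 1, and discarding a lone real measurement would
  destroy signal); CV is computed on raw intensities. The optional
  kernel-density smoothing sometimes offered alongside this rule has no
  defined target quantity or bandwidth and is not implemented.
* **Background exclusion.** Centroids are single-linkage binned on m/z
  at 10 ppm (flag); a bin is excluded iff its longest run of
  *consecutive* scan indices ≥ ceil(run_fraction · n_scans), default
  run_fraction 0.5 — "consecutively across half of the chromatogram"
  reads as a run, not total occupancy.
* **Feature ranking.** Welch two-sample t-tests per feature on
  ln(x + 1)-transformed intensities (intensity data are right-skewed;
  `--no-log` disables), statistic oriented group1 − group2 with group
  order by first appearance. Features with < 2 non-missing values in
  either group are dropped with a count. Zero-variance features get
  t = 0, p = 1 when means agree (no evidence) and p = 0 when they
  differ exactly.

## Synthetic fixtures: what they do and do not emulate

The generators are pure functions of their seed. Default study
conditions: 100 compounds (masses uniform in [80, 800] Da at > 50 ppm
spacing, 3 currency), 20 pathways of 8–12 members, 6 samples per group,
one active pathway, log-fold-change 2 on active members, log-normal
intensities with SD 0.5 on the log scale, Normal(0, 2 ppm) mass error,
2 s co-elution windows, 20% decoy peaks placed ≥ 10 ppm from every
predicted adduct m/z (making non-annotation provable), RT uniform in
[30, 900] s. The complementary-mode generator assigns each compound to
exactly one ion mode so only pooling sees whole pathways. Network
fixtures draw from a known precision matrix and return the implied true
partial correlations.

These fixtures capture annotation ambiguity, mass error, co-elution and
planted differential signal. They do **not** model isotope envelopes,
chromatographic peak shape, intensity-dependent mass error, missingness
mechanisms, or batch structure — so passing tests demonstrate
correctness of the algorithms under the stated generative model, not
instrument-level realism.

## Numerical conventions

* Missing ≠ zero everywhere: empty cells, `NA`, `NaN`, `null` map to
  NaN; a measured 0 stays 0 (the replicate rule depends on this).
* p-values of 0 (or 1, where a quantile is needed) are clamped into the
  open interval with a warning before combination.
* Results TSVs print floats at 6 significant digits and are
  byte-deterministic; peak tables round-trip at full precision.
* All sorting has total, documented tie-breaks (p, then |t|, then m/z
  for peaks; gamma_p, ease_p, id for pathways; q, p, node ids for
  edges), so equal seeds give byte-identical outputs end to end.

## Problem sizes used in the checks

Acceptance-style checks run at: 100 random databases (≤ 50 compounds,
200 peaks) for the annotation oracle; exhaustive N ≤ 30 for EASE; 200
null repetitions × 100 permutations for calibration; 50 seeds each for
planted recovery and pooling gains; 20 chain-precision seeds (p = 20,
n = 2000) plus 50 null seeds for DSPC. These sizes give Monte-Carlo
error comfortably inside the asserted bands while keeping the whole
suite fast.
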