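# Methods

This document specifies the models, formulas, parameter defaults and known
limitations of the karyoasym package. Everything stated here is either a
definition or a property verified by the test suite; no empirical claim is
made that the package does not itself compute.

## 1. Karyotype model (`karyoasym.model`)

A `Chromosome` is a pair of arm lengths `(short_arm, long_arm)` with
`short_arm ≤ long_arm` (the `from_arms` factory swaps arms if given in the
other order). Derived quantities:

- arm ratio `r = long/short` (`inf` for telocentric, `short = 0`);
- centromeric index `CI = 100·short/(short+long)`.

Morphology classes by arm ratio (half-open intervals):

| Class | Arm ratio |
|---|---|
| M (metacentric)   | [1, 1.5) |
| S (submetacentric)| [1.5, 3) |
| A (acrocentric)   | [3, ∞)   |
| T (telocentric)   | ∞ (short arm 0) |

`merge_telocentric=True` (the default everywhere) reports T chromosomes as
A, matching the convention of the karyomorphometric literature the
packaged dataset comes from; pass `merge_telocentric=False` to keep T
separate.

A `HomologPair` holds 1–2 homologs; per-pair arm lengths are the means
over homologs (`b_i = mean_short`, `B_i = mean_long`). A `Karyotype` is a
tuple of pairs, sorted by decreasing mean total length on construction.
`hcl` (haploid complement length) is the sum of per-pair mean totals. The
karyotype formula (e.g. `40M+2S`) counts *chromosomes* (2 per full pair)
by class in M, S, A, T order.

## 2. Asymmetry indices (`karyoasym.indices`)

With per-pair arms `(b_i, B_i)`, `i = 1..n`:

- `tf_fraction` TF = Σb / Σ(b+B); `ask_fraction` Ask = ΣB / Σ(b+B)
  (both returned as fractions in [0,1]; multiply by 100 for %).
- `syi` = 100·Σb / ΣB.
- `a1` = 1 − (1/n)·Σ(b_i/B_i).
- `a_watanabe` A = (1/n)·Σ(B_i−b_i)/(B_i+b_i).
- `a2` = sd/mean of the per-pair total lengths. **Default `ddof=1`**
  (sample standard deviation), which reproduces the published values of
  the packaged dataset; pass `ddof=0` for the population form. Requires
  ≥ 2 pairs (`ValueError` otherwise; `index_set` reports NaN).
- `cv_ci` = 100·CV of the centromeric indices, same `ddof` convention;
  undefined (ValueError) for an all-telocentric complement (mean CI = 0).

All indices are invariant under global rescaling of arm lengths and are
computed on per-pair means, so homolog-level measurement noise that
preserves the arm ratio does not move the intrachromosomal indices.

Categorical summaries:

- **Stebbins category** (3×4 grid): the digit comes from the size ratio
  longest/shortest chromosome (<2 → 1, 2–4 → 2, >4 → 3); the letter comes
  from the proportion of chromosomes with arm ratio ≥ 2
  (0 → A, (0, 0.5] → B, (0.5, 1) → C, 1 → D). `literal_header=True` flips
  the letter axis (D for fully symmetric), an alternative reading of the
  table header in part of the literature; the default is the conventional
  orientation (A = most symmetric).
- **Degree of asymmetry** by the fraction of acrocentric + telocentric
  chromosomes: SA ≤ 30% < MA ≤ 50% < StA.

## 3. Ideal karyotypes (`karyoasym.ideals`)

Six reference complements labelled A–F with uniform arm ratios
1.0, 1.4, 2.0, 4.0, 9.0 and ∞ (telocentric). Defaults: `n_pairs=10`,
`total_length=100.0` (the haploid complement length). All chromosomes in
an ideal have equal length, so the ideals differ only in intrachromosomal
asymmetry — this keeps them pure anchors for the intrachromosomal indices
(TF, Ask, Syi, A1, A); they are deliberately *not* meaningful anchors for
A2, which is zero for all of them.

## 4. Clustering pipeline (`karyoasym.cluster`)

`run_cluster_analysis(values, ...)` takes one scalar index value per taxon
*including* the six ideals and:

1. **Categorization**: five equal-width bins over the pooled range of the
   real taxa and the ideals (`n_bins=5` default; `use_raw_values=True`
   skips binning). Bins are half-open with the last bin closed.
2. **Distance**: absolute difference of ordinal bin codes.
3. **UPGMA**: size-weighted average linkage producing an ultrametric tree
   and the cophenetic matrix. Distance ties (common with ordinal codes)
   are broken uniformly at random; `n_replicates=10` replicates are run
   with per-replicate seeds derived from the master `seed` (default 1)
   via `numpy.random.default_rng([seed, replicate+1])`, with shuffled
   leaf input order per replicate.
4. **Consensus**: strict-majority (> 50%) consensus over *rooted* clades,
   implemented directly (library consensus methods treat trees as
   unrooted, which degenerates for small rooted trees). Internal node
   labels carry percentage support.
5. **Rooting**: the consensus is (re)oriented on the outgroup `ideal_A`,
   the fully symmetric ideal.
6. **Nearest ideal**: each taxon is assigned the ideal with the smallest
   mean cophenetic distance across replicates; exact ties resolve to the
   more symmetric ideal (earlier in A–F order).

Properties verified in tests: UPGMA matches an independent brute-force
oracle and scipy's average linkage/cophenet on tie-free inputs; consensus
of identical trees returns that tree with 100% support; the ideals
themselves cluster as contiguous blocks of the A–F ladder; a fully
metacentric complement is assigned ideal A.

## 5. Group comparison (`karyoasym.compare`)

- `one_way_anova`: classical fixed-effects one-way ANOVA from explicit
  sums of squares (cross-checked against `scipy.stats.f_oneway` in the
  tests). `min_group_size` drops groups smaller than the threshold before
  the analysis; the analysis of the packaged dataset uses
  `min_group_size=2`, which removes the single-member subfamily
  Vanillioideae — a singleton contributes no within-group variance and
  its inclusion is not a meaningful contrast. Degenerate inputs: all
  values identical → F = 0, p = 1; zero within-group variance with
  between-group spread → F = ∞, p = 0.
- `tukey_hsd`: Tukey–Kramer pairwise comparisons (statsmodels
  `pairwise_tukeyhsd`, `alpha=0.05` default) plus a compact letter display
  built by insertion–absorption over the mean-ordered groups.
- `summarize_by_group`: per-group n, mean, min, max and mode (mode at 2
  decimals by default, ties to the smallest value).

## 6. Synthetic karyotypes (`karyoasym.simulate`)

`SimSpec` defaults: `n_pairs=10`, `morphology_mix={M: .6, S: .3, A: .1}`,
`size_cv=0.2`, `mean_length=3.0` µm, `homolog_jitter=0.0`, `seed=0`.
Generation per pair:

- total length ~ lognormal parameterized so that the *arithmetic* mean is
  `mean_length` and the coefficient of variation is `size_cv`
  (`σ² = ln(1+cv²)`, `µ = ln(mean) − σ²/2`);
- morphology class drawn from `morphology_mix`; arm ratio uniform within
  the class interval (M [1,1.5), S [1.5,3), A [3,10) — the A class is
  truncated at r = 10 to keep finite arms; T is exactly telocentric);
- `homolog_jitter` scales the two homologs of a pair by independent
  factors while preserving the arm ratio.

Per-replicate seeds in `recover_parameters_experiment` derive from
`numpy.random.SeedSequence([seed, spec_index, replicate])`.

**Scope**: the generator models marginal size variation and morphology
mixes only. It does not model correlated size–morphology structure,
bimodal complements, B chromosomes, or measurement error other than
ratio-preserving jitter, so it validates index arithmetic and pipeline
behaviour, not biological realism.

## 7. Packaged dataset (`karyoasym.table2`)

A 62-row karyomorphometric table of Brazilian Orchidaceae (61 unique taxa,
4 subfamilies), verified on load against a SHA-256 checksum. Source quirks
preserved verbatim and surfaced by `validation_report()`:

- one taxon appears twice (*Cyclopogon elatus*, two accessions);
- one taxon's karyotype formula total disagrees with its stated 2n
  (*Pelexia laxa*; whitelisted, kept as printed);
- the source text states 64 species while the table has 62 rows.

For clustering, duplicate taxon labels are disambiguated with a numeric
suffix (e.g. `Cyclopogon elatus (2)`).

## 8. Numerical and reproducibility choices

- All randomness flows from explicit integer seeds through
  `numpy.random.default_rng` / `SeedSequence`; repeated runs with the same
  seed are bit-identical.
- UPGMA tie detection uses an absolute tolerance of 1e-12 on distances.
- Pipeline outputs (`karyoasym.pipeline.run_full_analysis`) are plain CSV
  and Newick files stamped with the package version and a configuration
  hash.

## 9. Known limitations

- The Ask% and A1 subfamily ANOVA F statistics recomputed from the
  packaged table (4.4141 and 5.6402) differ slightly from the values
  published with the original dataset (4.4915 and 5.77). The published
  statistics were evidently computed from unrounded per-species values,
  while the table prints indices to 2 decimals; the other three statistics
  (A2, Syi, A) reproduce exactly from the printed values. The discrepancy
  is documented, not corrected for.
- The categorization step (equal-width binning) makes consensus topologies
  sensitive to the pooled value range; adding or removing taxa can shift
  bin edges.
- Majority consensus over 10 replicates can return poorly resolved trees
  when ordinal-code ties are pervasive; support values should be read
  before interpreting clades.
- Stebbins letter assignment at exactly 50% arm-ratio≥2 chromosomes falls
  in class B by the half-open convention used here; other software may
  differ at the boundary.
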