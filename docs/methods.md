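# Methods

This note documents the models, thresholds and design choices behind
`mutgen`, and what the synthetic-data generator does and does not emulate.

## Study design being modeled

A family quintet is a sire, a dam and three offspring, whole-genome
sequenced from somatic tissue at ~31× mean autosomal coverage. The sire and
dam come from different inbred backgrounds, so strain-informative markers
segregate through the pedigree and allow read-backed phasing. Candidate
mutations are Mendelian violations; candidates surviving the discovery
filters are deeply re-sequenced (targeted validation, ≥ 300×) and the
validation VAFs drive origin classification. In parallel, offspring-vs-
parents aCGH arrays (~1 M probes, ~3 kb spacing) are screened for de novo
copy-number variants, validated by per-tissue copy-number estimates, and
their junctions sequenced.

## Variant allele fraction model

VAF is alternate reads over total depth at the site (`alt_depth / depth`;
the alternative convention alt/(ref+alt) differs only at triallelic or
noisy sites and is not used). Expected VAFs by origin:

* de novo (fixed in the gamete): 0.5;
* early embryonic: under the three-cell founder model, three cells of the
  64-cell embryo found the animal, i.e. six haploid genomes, so a mosaic
  in 1, 2 or 3 founder cells sits at 1/6, 2/6 or 3/6. A 3-cell mosaic is
  *indistinguishable from de novo by VAF alone*; classification of such
  events as de novo is expected behavior, not an error, and the embryonic-
  accuracy checks therefore score 1- and 2-cell injections;
* parental somatic mosaic: sub-heterozygous VAF in the parent's tissue with
  the offspring a full heterozygote;
* parental germline mosaic: parents negative in somatic tissue, two or
  more siblings heterozygous.

## Thresholds

Discovery cascade (each criterion evaluated independently; a candidate
passes only if all pass): parental VAF < 0.05 in *each* parent (strict),
offspring VAF > 0.25 (strict), MQ0 fraction ≤ 0.1 in every animal
(inclusive), depth ≥ 7 in every animal (inclusive; zero depth fails here
rather than dividing), two-sided Fisher strand-bias P > 0.05 (strict),
position outside the repeat mask. The site's per-animal records are
assumed computed over reads overlapping ±10 bp of the locus — a documented
precondition on input generation, since the package consumes site tables,
not alignments.

Validation decision tree: parent VAF ≥ 0.35 → inherited; parent VAF in
[0.05, 0.35) → parental somatic mosaic; ≥ 2 sibling carriers with parents
below 0.05 → parental germline mosaic; single carrier at VAF ≥ 0.39 →
de novo; VAF in [0.10, 0.39) → embryonic; below 0.10 → false positive.
Only the 0.39 cut is fixed by the validation rule the analysis follows;
0.35, 0.05, 0.10 and the phasing minimum of 3 linked reads are package
defaults, exposed in `ClassifyConfig` and logged with every run. The
embryonic cell count is the nearest lineage fraction with ties going to
the lower count (0.25 → 1 cell).

aCGH: a call needs ≥ 5 *consecutive* probes each individually beyond
|log2| > 0.4 — "altered probe" is read per-probe, not as a run mean, and a
single sub-threshold probe breaks a run (no gap bridging; configurable in
`CnvConfig`). Recurrence across animals is reciprocal overlap ≥ 0.5. A
de novo call requires a copy change ≥ 0.5 in at least two germ-layer
tissues with both parents at two copies; de novo deletions additionally
need mean log2 < −0.75 (shallower losses are post-fertilization somatic
events). Sex chromosomes are excluded throughout.

## Statistics

* Per-offspring SNV/indel counts: Poisson GEE, log link, exchangeable
  working correlation, sandwich (cluster-robust) variance, two-sided Wald
  test. The cluster unit is the sire/family (litters are nested within
  sires here); configurable. With singleton clusters the estimates reduce
  to an independence Poisson GLM, which the tests verify.
* CNV frequencies: one-tailed Fisher exact tests. The tail direction
  follows the stated alternative per endpoint — duplications: exposed
  higher; deletions: exposed lower. The data-dependence of choosing a
  direction per endpoint is inherited from the analysis being modeled and
  flagged here.
* CIs: exact Poisson (chi-square inversion) for count rates; modified-Wald
  (Agresti–Coull, z = 1.96) for binomial CNV frequencies.
* Multiplicity: Holm–Šidák step-down, adjusted p = 1 − (1 − p)^(m − i + 1)
  at ascending rank i, ties kept in input order. By default the adjusted
  values are **not** monotonized across ranks — the raw step-down formula,
  which can be non-monotone when a small p carries a large exponent;
  `monotonize=True` gives the conventional non-decreasing variant.
* Spectrum contrast: 2×C exact conditional test (probability-ordering
  criterion, invariant to swapping groups). Enumeration is used when the
  number of margin-compatible tables is ≤ 2×10⁵; beyond that a seeded
  Monte-Carlo estimate with ≥ 10⁵ multivariate-hypergeometric draws is
  returned, labeled as such. The enumeration bound is a desk-scale choice;
  both paths estimate the same quantity and agree on overlapping inputs.
* Signature refitting: non-negative least squares of the normalized
  96-context spectrum on column-normalized signatures, weights < 0.06
  zeroed and renormalized (the convention of standard refitting tools),
  residual reported as cosine distance.

## Synthetic-data generator

The generator's defaults are the study conditions: mean depth 31×
(Poisson — the standard shotgun approximation; the real platform's depth
distribution is not published, so this is a placeholder, not a claim),
per-base error 10⁻³ folded into the binomial allele draw, strand counts
split 50/50 binomially unless a bias is configured, alt reads linked to
the nearest informative marker with probability 0.8 (phasing was possible
only "where possible" in practice), validation re-draws at 300×. aCGH
probes sit every 3 kb with Gaussian log2 noise (default sd 0.15);
duplications add log2(3/2), heterozygous deletions log2(1/2), and a mosaic
in cell fraction f is attenuated to log2((2 ± f)/2) — a half-mosaic
duplication (≈ 0.32) sits below the 0.4 threshold, which is exactly why
mosaic CNVs evade array detection. Junctions carry an exact shared overlap
of 0–6 bp between donor and acceptor flanks, or inserted bases (the two
are mutually exclusive at one junction).

What it does **not** emulate: read-level artifacts (FASTQ, mapper
behavior, indel realignment), real mouse reference sequence or repeat
structure, GC-dependent coverage bias, array spatial artifacts, or
selection against damaged embryos. Passing round-trip tests therefore
demonstrates the correctness of the *analysis logic* under the stated
statistical model, not the end-to-end accuracy of any wet-lab pipeline.

Pipeline problem sizes: the end-to-end driver simulates 2 families per
exposure group with a few thousand background sites per family and aCGH
cohorts of 171/83/98 arrays at 2000 probes each; the verification scripts
use 600 de novo and 300 embryonic injections, 1000 random probe series,
700 junctions and 1000 GEE replicates. These sizes keep every run
desk-scale while leaving Monte-Carlo error well inside the tested
tolerance bands.

## Numerical and design choices

* Coordinates are 1-based inclusive everywhere inside the package; BED
  (0-based half-open) is converted at the IO boundary only. Interval sets
  normalize to sorted, merged form; truly overlapping input warns.
* Candidate discovery calls an allele present in a genotype at VAF ≥ 0.2
  and requires ≥ 3 supporting reads in the offspring — permissive on
  purpose, since the cascade does the real filtering. Multi-allelic sites
  are evaluated per alt allele.
* The strand-bias Fisher test is the exact two-sided probability-ordering
  test; an all-zero table returns P = 1 by convention. Note the filter
  removes ~2–4 % of true heterozygotes at 31× purely through the
  discreteness of the test — visible in the round-trip recovery rate
  (~96 %), and inherent to this filter design.
* CNV parental origin is a maximum-likelihood decision among
  {paternal, maternal, no-signal} binomial hypotheses (2/3 / 1/3 / 1/2 for
  duplications; allele dropout for deletions), requiring ≥ 5 informative
  sites. The evidence margin (`bayes_factor`) defaults to 1 (pure ML),
  which achieves ≥ 95 % accuracy at 100 informative reads; raise it for a
  more conservative caller that returns "unknown" in marginal cases.
* Mutation clusters are maximal same-animal runs with gaps ≤ the window;
  the annotated probability is a union-bound figure of merit
  (n · P(Binomial(n−1, w/G) ≥ k−1)), not an exact test.
* The genome size used in the sperm-assay extrapolation is an explicit
  parameter: the published per-genome expectations imply a diploid genome
  near 6.2 Gb, which is inconsistent with the 4.7 Gb figure used
  elsewhere; the package takes the expectation (or the genome size) as
  input rather than hard-coding either.
* Per-offspring SNV CIs are exact Poisson. The interval construction
  behind the originally published per-offspring CIs could not be
  identified (it matches neither exact-Poisson nor normal approximations),
  so those bounds are not reproduced — a known limitation.
* Similarly, the published modified-Wald upper bounds for zero-count
  control rows (e.g. 0.0188 for 0/171) do not follow from the standard
  Agresti–Coull formula, which this package uses; the standard value
  (0.0264) is reported instead.
* Plotting is deliberately out of scope; reports are TSV/JSON.

## Known limitations

Beyond the generator's idealizations: the filter cascade's ±10 bp locus
re-examination is a contract on input generation, not re-verified;
lowess normalization uses all uniform probes rather than a rank-invariant
subset (an array-vendor internal); the exact spectrum test falls back to
Monte-Carlo above the enumeration bound; and GEE small-sample behavior
with very few clusters (2 per group, as in the sequenced cohort) makes
those p-values indicative rather than calibrated — the type-I error
guarantee is tested at 20 clusters per group.
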