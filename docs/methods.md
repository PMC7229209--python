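# Methods

This note documents the models, parameter choices and numerical details
behind each stage of `umwgs`, and what the synthetic-cohort tests do and do
not demonstrate about real data.

## Signature refitting

A sample's substitution catalogue **c** (counts over the 96 pyrimidine-centred
trinucleotide classes; optionally the 78 doublet classes) is decomposed over
a reference signature matrix **S** (columns are probability vectors) by
non-negative least squares,

    ê = argmin_{e ≥ 0} ‖c − S e‖₂ ,

solved exactly with an active-set method (`scipy.optimize.nnls`).  Fitting
is on raw counts rather than frequencies so exposures read directly as
mutation counts attributable to each signature; fractions are exposures
divided by their sum.  All columns of the supplied matrix are candidates —
no sparsity penalty or pre-selection.  The solution satisfies the KKT
conditions (zero gradient on active components, non-negative gradient on
zero components), which the tests verify along with a dense simplex-grid
oracle.

Strand handling: purine-centred contexts are reverse-complemented onto the
canonical classes, doublets are collapsed with their reverse complements
(palindromic references keep the lexicographically smaller alternative),
and indels are excluded from both catalogues.

**Burden and phenotype flags.**  TMB = substitution count / callable Mb,
with a default callable size of 2,800 Mb (configurable; roughly the
callable autosomal genome at WGS depth).  Flags:

* `uvr`: combined SBS7a+SBS7b fraction ≥ 0.1 **and** TMB above the cohort
  median.  The fraction threshold is deliberately permissive — UV exposure
  contributes a distinctive spectrum well before it dominates — and the
  "high TMB" condition anchors the flag to the cohort rather than an
  absolute rate.
* `deamination_hypermutator`: SBS1 fraction ≥ 0.5 **and** TMB > 3/Mb.  This
  phenotype is defined by SBS1 *dominance* with frank hypermutation.

Both thresholds are configurable arguments.

## Hotspot rescue calling

For each panel position the tumour's (variant, reference) read counts are
compared against the element-wise pooled counts of all normal samples with
a **two-sided** Fisher's exact test; p-values are Bonferroni-multiplied by
the family size, which defaults to (panel positions × tumour samples), and
called at corrected p < 0.001.  Two-sided testing is the conservative
choice where the sidedness of the original procedure is ambiguous.  The
matched normal is kept in the pool by default (`exclude_matched_normal`
removes it); with ~100 normals its marginal contribution is negligible, and
keeping it makes the background strictly harder to beat.  The caller
reports evidence — it does not genotype; integration with upstream calls is
annotation-only.

## WGD versus heterogeneity

Let (aᵢ, nᵢ) be variant/total read counts at somatic sites inside
allelically balanced segments (major CN = minor CN).  Two two-component
binomial mixtures are fit by maximum likelihood:

* tetraploid: atoms (θ, θ/2), free parameters θ and weight w — mutations
  before the duplication sit on two of four copies, mutations after on one;
* heterogeneous diploid: atoms (θ, φ) with φ free below θ — a clonal peak
  and a subclone peak that can sit anywhere.

θ is free rather than pinned at its purity-implied value so purity error is
absorbed by the fit.  The tetraploid model is the φ = θ/2 slice of the
heterogeneous one, so 2·(ℓ_het − ℓ_tet) is referred to a χ²₁ tail; at
p < 0.001 heterogeneity is accepted and the segment profile is halved
(copy numbers rounded to nearest, ties to even; ploidy halved).

Numerics: EM with closed-form M-steps — the heterogeneous θ, φ updates are
responsibility-weighted binomial means (relabelled so θ ≥ φ), and the
tetraploid update is the root in (0,1) of an exact quadratic stationarity
condition.  Ten quantile-spaced starting atoms guard against local optima,
and the heterogeneous fit is additionally seeded with the tetraploid
optimum so the nesting inequality ℓ_het ≥ ℓ_tet holds numerically.  The
comparison requires at least 20 balanced-region sites; below that the
upstream copy-number call stands.  The pipeline caps the fit at 2,000
randomly chosen balanced sites per sample — ample for a one-parameter
contrast — so hypermutated samples do not dominate runtime.

A caveat the tests make explicit: at purity 1.0 a diploid tumour with a
50% subclone produces atoms (0.5, 0.25), identical to a pure tetraploid.
The test is only informative when purity, depth or subclone fraction break
that symmetry; the simulated calibration uses subclone fraction 0.3.

## Arm calls and categories

For each chromosome arm (GRCh37 cytoband-derived table), segments are
intersected with the arm and the fractions of arm length with total copy
number above/below the sample baseline (round(ploidy)) are accumulated; an
arm is called gain (loss) when the aberrant fraction reaches 0.5, and left
undefined when segment coverage of the arm is below 0.5.  Monosomy 3
requires loss of both 3p and 3q — chromosome 3 is lost as a unit in this
disease.  Categories: (D3, no 8q gain) → 1, (D3, 8q gain) → 2, (M3, no 8q
gain) → 3, (M3, 8q gain) → 4.

Fraction of genome altered is length-weighted with baseline (1,1) for
diploids (including WGD-adjusted profiles) and (2,2) for unadjusted
tetraploids; high gain is total CN ≥ 6.  The isochromosome-8q check lists
samples with 8p loss but no 8q gain (expected to be empty).

## Drivers and double hits

Loss-of-function = {nonsense, frameshift, splice, SV breakpoint}.  Gαq
hotspot hits are collected per sample; more than one hit is an exclusivity
exception unless it is the known PLCB4 p.D630 + GNAQ/GNA11 p.R183 pattern.
For tumour suppressors, LOH means minor CN 0 over the locus (copy-neutral
when total CN ≥ 2); mutation + LOH or two trans-phased mutations are double
hits, with unphased pairs flagged `phase="unknown"` rather than discarded.
Biallelic calls whose supporting mutation has VAF < 0.15 carry a
subclonality caveat (annotated, never suppressed).  Allele representation
of two mutations is compared by a two-sided Fisher's exact test on their
read counts; p < 0.001 is read as unequal representation.

TP53 variants combine three published scores: PHANTM ≥ 0.5 (benign
polymorphisms score ~0, recurrent hotspots ~1), FATHMM > 0.5 (published
deleteriousness cut-off), RFS ≥ 0 (closer to the protein-truncating mean
0.42 than the synonymous mean −2.50).  Truncating consequences are
pathogenic outright; otherwise ≥ 2 deleterious verdicts → pathogenic, 0 →
benign-leaning, else uncertain.  The majority rule is this package's
choice where the combination of scores is inherently narrative; the
per-score verdicts are always reported alongside.

## Survival

Kaplan–Meier product-limit curves with the median defined as the first
time S(t) ≤ 0.5 (infinite when never reached); censorings tied with events
keep the censored subject at risk at that time.  Group comparisons use the
Mantel–Cox log-rank test (df = 1) with no multiplicity adjustment.  Both
are computed through lifelines behind a typed interface; tests pin them to
hand-computed worked examples.

## Synthetic cohorts

Defaults describe a 103-sample whole-genome cohort: categories drawn with
probabilities 24/11/13/55 ÷ 103, primary sites choroid/iris/ciliary body at
88/8/4%, purity uniform on (0.35, 0.95), read depth Poisson(60) with floor
10 (avoiding zero-depth degenerates), callable genome 2,800 Mb.  Burden:
baseline 0.5 mutations/Mb (log-normal spread σ = 0.35), iris 4/Mb with a
0.45/0.25/0.30 SBS7a/7b/5 mixture plus CC>TT-dominated doublets, MBD4-like
hypermutators (rate 2/103) at 5/Mb with an 0.8/0.2 SBS1/SBS5 mixture
(floored above 3/Mb).  Per-sample signature fractions are Dirichlet-jittered
around the site mixture (concentration 300) and contexts are sampled
directly from the mixture column — no reference genome is consulted, so
context strings are self-contained.  Copy-number profiles are arm-level:
chr3 (1,0) for M3, 8q (2,1) for gains, 6p gain in category 2, 8p loss only
alongside 8q gain, and RPL5/TP53 disruption injected at 48% with 8q gain vs
22% without (via 1p loss, 17p loss or a TP53 mutation).  Rare samples are
genuinely tetraploid (2/103) or diploid-with-subclone emitted with doubled
segments and ploidy 4 (3/103), mimicking two-population copy-number fitting
overestimating a heterogeneous tumour.  Relapse times are exponential with
per-category hazards (0.03, 0.10, 0.09, 0.28)/year — medians ≈ 23, 6.9,
7.7 and 2.5 years — under administrative censoring at 10 years.

What the simulator does **not** emulate: read-level artefacts (mapping
error, strand bias), subclonal architecture beyond one subclone, focal
CNAs and breakpoint structure, indel realism beyond class labels, and
covariate-dependent censoring.  Passing tests therefore demonstrate the
correctness and calibration of the algorithms under the stated generative
assumptions, not performance on real sequencing data.

## Problem sizes and determinism

Every stochastic routine takes an explicit seed and is bit-reproducible
given one; the pipeline writes fixed-precision TSVs so reruns are
byte-identical.  The validation script uses the sizes its checks are
stated at: 200 samples × 1,000 mutations for signature recovery, 20
instances against a 0.001-resolution simplex grid, 100 + 100 samples ×
500 sites at depth 80 for WGD calibration, 10,000 null draws for the
hotspot family-wise error, 200 seeds × 100 subjects for log-rank power,
and one 103-sample end-to-end cohort.
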