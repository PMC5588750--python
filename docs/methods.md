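# Methods

This note documents the models, defaults and numerical choices behind
`gutmtx`, and what its synthetic-data tests do and do not establish.

## Study design and data model

The experimental layout is a balanced 2 × 2 factorial with replication:
genotype ∈ {WT, Plin2} crossed with diet ∈ {HF, LF}, four replicates per
cell, sixteen samples in total.  Only the four pairwise comparisons with
one factor held fixed are analyzed — Geno-HF (Plin2-HF vs. WT-HF),
Geno-LF (Plin2-LF vs. WT-LF), Diet-Plin2 (Plin2-HF vs. Plin2-LF) and
Diet-WT (WT-HF vs. WT-LF).  Throughout, *group 1* is the first-named
group of a comparison, and positive fold changes mean upregulation in
group 2.

Transcripts carry a taxon bin drawn from a configured list of exactly 17
labels (plus `unassigned`), zero or more 4-field EC numbers, a length in
bp, and optionally a finer organism label.  The 17 default labels are
configuration, not constants: any 17-label list is accepted.  A
transcript with several EC numbers contributes to each of them.

## Quantification

* **Low-expression filter.**  A transcript is removed when its mapped
  reads summed over all samples are < 5 (strict).  The threshold is read
  as a dataset-total rule; a per-sample variant is available behind
  `per_sample=True`.  Per-sample totals are recomputed from the retained
  transcripts before normalization, so the pipeline is self-contained:
  filter → recompute totals → RPKM.
* **RPKM** = count / ((length/10³) · (total mapped reads/10⁶)); zero
  counts are exactly zero.
* **Taxon abundance** is the per-taxon sum of member-transcript RPKM.
* **Presence tiers.**  A transcript is present in a genotype/diet group
  when its mean RPKM over the group's replicates is > 0 (lowest tier) or
  ≥ 10 / ≥ 100.  Group means (rather than per-sample values) are used
  because presence is a group-level notion here; presence sets are
  nested across tiers by construction.
* **Rarefaction** subsamples reads without replacement (multivariate
  hypergeometric draws from the count vector) at a grid of depths and
  reports mean distinct transcripts or enzymes over replicates.

## Diversity

Per sample, on species-level abundance vectors (organism label when
present, else the taxon bin): richness S; Shannon H = −Σ pᵢ ln pᵢ
(natural log); Gini-Simpson 1 − Σ pᵢ²; Fisher's α solving
S = α·ln(1 + N/α) by Brent root-finding (|ΔS| < 1e-9; undefined with a
warning for S ≤ 1 or S → N); Chao1 = S + F1²/(2F2), bias-corrected
S + F1(F1−1)/(2(F2+1)) when F2 = 0, with a bootstrap sd over 100
multinomial resamples of the N observed individuals (fixed seed); and
the beta ratio |units in the sample| / |units across all samples|.
Chao1 always runs on integer counts; the other indices use RPKM when an
expression matrix is supplied.  Group comparisons use the Welch
(unequal-variance) two-sample *t* test; two zero-variance groups with
equal means return p = 1 by convention.

## Differential expression

Testing runs on raw counts, fold changes on RPKM — two separate tracks.

* **Size factors**: median over all-positive transcripts of
  countᵢⱼ / geometric-meanᵢ, not rescaled afterwards.  When no
  transcript is positive everywhere, an explicit `pseudo_reference`
  fallback uses positive-sample geometric means.
* **Dispersion** (var = μ + φμ²): per transcript, the raw
  method-of-moments estimate (w − z)/μ² from the pooled within-group
  variance w of normalized counts, with shot noise z = μ·mean(1/sⱼ)
  removed and negative values clipped to 0; a trend φ(μ) = a0 + a1/μ is
  fitted by gamma-style IRLS (weights 1/fitted²) over transcripts with
  positive raw dispersion; the working value is max(raw, trend).  This
  deliberately never shrinks below the raw estimate, trading power for
  conservatism with n = 4 replicates.
* **Exact test**: two-sided, conditioning on the two groups' summed
  count k_S.  Group totals are modeled as independent NB with means
  μ̂·s_A, μ̂·s_B (s = summed size factors, μ̂ = k_S/(s_A+s_B)) and
  group-sum dispersions φ·Σsⱼ²/(Σsⱼ)² — the dispersion a sum of NB
  replicates carries.  p is the total probability of allocations no more
  likely than the observed one (with a 1+1e-8 tie guard), normalized by
  the probability of the conditioning event; k_S = 0 gives p = 1.  In
  the φ → 0 limit the conditional law is binomial, which the tests use
  as an oracle.  Numerical agreement with any particular published
  implementation of this recipe is a non-goal; correctness rests on the
  Poisson-limit identity, null calibration and planted-truth recovery.
* **eFC** is the signed piecewise statistic (ratio of larger to smaller
  value, signed by direction, when both group means are positive; raw
  difference when either is zero), evaluated on group-mean RPKM.  It is
  antisymmetric, zero at equality, and |eFC| ≥ 1 whenever both inputs
  are positive.
* **Significance**: BH-adjusted q < 0.05 within each comparison and
  log₂|eFC| > 2.  The magnitude gate applies to |eFC| so downregulation
  is called symmetrically; note that for the zero branch the gate
  compares the raw difference's magnitude.
* **Enzyme aggregation**: per EC, r1/r2 are summed member group means,
  enzyme eFC = eFC(r1, r2), and aeFC = eFC/n where n counts member
  transcripts expressed (nonzero mean RPKM) in either group — the
  "either group" reading resolves the ambiguity of a per-sample n for a
  two-group comparison.  An enzyme is significant when ≥ 1 member
  transcript is.  Taxon-restricted aeFC repeats the same arithmetic on
  taxon-filtered member sets and is missing (NaN) where a taxon
  expresses no member.

## Enrichment and multivariate analysis

Enrichment is an upper-tail hypergeometric test (enrichment only, not
depletion): universe = all transcripts observed in ≥ 1 sample for taxon
sets, all expressed ECs for pathway sets; sets with fewer than two
universe members are dropped before BH adjustment.

PERMANOVA computes Anderson's pseudo-F from the Gower-centered squared
distance matrix.  One factor: F = (SS_f/df_f)/(SS_res/df_res) with
projection-based sums of squares; two crossed factors use the additive
model's residual, which is exact for the balanced design.  p-values come
from unrestricted permutation of raw observations,
p = (#{F* ≥ F} + 1)/(n_perm + 1), so p ≥ 1/(n_perm+1); BH runs across
the family of tests executed together.  When the residual sum of
squares vanishes to round-off (≤ 1e-10 of the total trace), F is ∞ for a
positive factor SS and the case of all-equal samples reports p = 1.
Bray-Curtis is the default metric for abundance matrices and Euclidean
for PC-score tests; an all-zero sample pair has Bray-Curtis 0 with a
warning.  Defaults: 9999 permutations for desk-scale runs; 100,000 is a
config value away.  PCA log10(x+1)-transforms, centers features, and
uses the SVD; signs are fixed by making each component's
largest-magnitude loading positive, so results are bit-reproducible.

## Pathway graphs and coordinated runs

KGML enzyme entries become EC nodes; two enzymes are adjacent (directed)
when one reaction's product compound is another's substrate.  Any
adjacency mediated by a reversible reaction is emitted in both
directions — a deliberately permissive convention, since reversibility
makes the substrate/product distinction positional.  A simplified
edge-list dialect (one `EC<TAB>EC` line per edge, bare lines for
isolated enzymes) covers pathways without usable KGML.

A *coordinated run* is a maximal directed path whose enzymes all carry
same-sign nonzero aeFC (missing or zero values break runs), with
maximality meaning no same-sign extension exists at either end; minimum
length 3 by default.  This is a declared formalization of the
qualitative "consecutive enzymes shifting together" observation — the
definition is ours, anchored by fixture tests.  Runs are enumerated
source-to-sink within each sign subgraph in deterministic lexicographic
order; cyclic same-sign components are reported as their longest simple
path with a warning.  In the pipeline, runs are detected on the aeFC of
*significant* enzymes only, which keeps sign noise from null enzymes
out of the paths.

## Synthetic data

The generator draws counts for sample (g, d, r) of transcript t from
NB(mean = s_gdr · μ_t · 2^(g·G_t + d·D_t + g·d·I_t), dispersion φ), with
effects additive on the log2 scale over the 2 × 2 factorial so each
comparison's true fold change is analytic.  Defaults describe the
emulated design: 4 replicates per group; 5000 transcripts;
Firmicutes-dominated composition over the 17 bins (Lachnospiraceae 30%);
log-normal lengths (median 900 bp, σ = 0.6); log-normal baseline means
(median 40 counts, σ = 1.3) — a wide but desk-scale expression range;
log-normal depth factors (σ = 0.15); φ = 0.2, a typical overdispersion
for biological replicates; 5% of transcripts differential per factor
with |log2FC| ~ U(2, 5) and random sign; 30% of transcripts carrying an
EC; and a planted 5-enzyme chain (first chain of a disjoint-chain toy
pathway fixture) whose dedicated transcripts share a +3 log2 genotype
effect at baseline mean 500.  Setting the differential fraction to zero
yields a fully null dataset, planted chain included.  Randomness is one
seed split into per-component sub-streams (SeedSequence.spawn), so
identical config + seed is byte-identical output.

What the generator does *not* emulate: sequencing reads, assembly and
annotation error, taxon-correlated expression structure, compositional
coupling between transcripts, or library-size effects beyond a scalar
depth factor.  Passing tests therefore establish the statistical
machinery under its own model assumptions — calibration, recovery and
determinism — not performance on real sequencing artifacts.

## Problem sizes and scale

The bundled analysis runs at 5000 transcripts × 16 samples with 9999
permutations — sizes chosen so the whole workflow replays in minutes on
a laptop while keeping every group comparison replicated.  Statistical
tests in the suite use 1000–2000 transcripts, 199–9999 permutations and
frozen seeds.  The headline dataset-level counts of the motivating
experiment (hundreds of thousands of distinct transcripts from ~419M
reads) are functions of its sequencing depth and are not reproduced
here; the package treats all such totals as data-dependent outputs.

## Known limitations

* The exact NB test is conservative for very low totals (discreteness)
  and the max(raw, trend) dispersion rule is deliberately cautious.
* p-values of the conditional exact test are not invariant to
  amplifying a single sample's counts (the amplified noise is real
  data); size factors absorb the scale exactly, calls remain concordant.
* Two-way PERMANOVA uses unrestricted permutation; restricted
  (within-stratum) permutation is out of scope.
* Fisher's α is undefined for single-species samples and diverges as
  S → N on count data; both cases warn and return NaN.
* Pathway-set enrichment treats each weakly connected component of a
  supplied pathway file as one set; with curated per-pathway KGML files,
  one file = one set.
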