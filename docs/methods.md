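# Methods

This note documents the models and procedures implemented in `promshape`,
the defaults and why they were chosen, what the synthetic benchmark does
and does not emulate, and the package's known limitations.

## Problem setting

Given single-nucleotide variants (SNVs) lying within 5 kb upstream of a
transcription start site (TSS), the task is binary classification:
*functional* (regulatory, disease-associated) versus *neutral* (common
polymorphism). Coordinates follow VCF (1-based positions) for variants and
BED (0-based half-open intervals) for annotation tracks; conversion is
centralized in `variants.pos_to_bed`/`bed_to_pos`. Promoter membership
respects gene strand ("+": `[tss−span, tss−1]`; "−": `[tss+1, tss+span]`,
span 5000 by default), while all sequence windows are taken from the
forward reference strand — the feature definitions are anchored on the
variant, not the gene. Dataset construction supports an inclusive minor
allele frequency filter (MAF ≥ 0.01 keeps a variant at exactly 1%) and
removal of records shared between cohorts on (chrom, pos, ref, alt).
Variants whose 15-mer window contains an N, overruns a contig, or
mismatches the declared reference allele are excluded from feature
extraction with a logged reason; no imputation is attempted.

## Pentamer shape model

A complete table maps each of the 1024 5-mers to six values: MGW (Å) and
ProT (degrees) of the central base pair, and roll/HelT (degrees) of the
two central base-pair steps (`roll_left` for the step entering the centre,
`roll_right` for the step leaving it). For a sequence of length L
(1-based):

* MGW/ProT at position *i* (3 ≤ i ≤ L−2) are direct lookups of the
  pentamer centred at *i*.
* The step between bases *j* and *j+1* (2 ≤ j ≤ L−2) averages the
  available contributions: `roll_right` of the pentamer centred at *j* and
  `roll_left` of the pentamer centred at *j+1*. Edge steps with a single
  defined contribution use that value unmodified (no extrapolation).
* Base-pair-level roll/HelT at position *i* is the mean of the defined
  adjacent steps *i−1* and *i*.

A table flagged *symmetric* satisfies the reverse-complement identities
mgw(s) = mgw(rc(s)), prot(s) = prot(rc(s)),
roll_left(s) = roll_right(rc(s)), helt_left(s) = helt_right(rc(s)); for
such tables the profile of the reverse complement is exactly the reversed
profile, which the test suite asserts.

**The 88-column shape group.** The variant window is the 15-mer (flank 7)
— the minimal window for which all four parameters are defined at the 11
variant-centred offsets −5..+5. For each parameter in the fixed order
(MGW, ProT, Roll, HelT) the group holds the 11 *mutated-sequence* values
followed by the 11 differences (mutated − reference). Two consequences are
useful as checks: MGW/ProT differences vanish exactly outside offsets
±2 and base-pair roll/HelT differences outside ±3, because pentamers
further away do not contain the substituted base. The choice of
mutated-sequence values (rather than reference values) for the first half
is a design decision; both variants carry the same information jointly
with the differences.

## The other feature groups

* **sequence (52)** = 36 one-hot bits for the reference 9-mer + 4 one-hot
  bits for the alternative allele + 12 mutation-type indicators (the
  ordered unequal base pairs, lexicographic). The alt-allele one-hot is
  the minimal completion that reconciles the 9-mer + mutation-type design
  with a 52-column group; the encoding is injective in (9-mer, alt).
* **gc (8)**: GC fraction of the centred 7- and 9-nt windows for reference
  and mutated sequence, the difference (mut − ref), and — as the
  completion to 8 columns — its absolute value, per window length.
* **dinucleotide (16)**: observed minus expected frequency of each ordered
  pair among the 8 overlapping dinucleotides of the reference 9-mer, with
  expectation from the 9-mer's own mononucleotide frequencies (difference
  rather than ratio avoids division by zero); the 16 features sum to 0.
* **histone (38)** / **tfbs (12)** / **dnase (1)**: binary position
  overlaps with interval tracks (2 marks × 16 cell lines, 10 TFs, DNase),
  plus per-mark, either-mark and per-TF cell-line/TF means and any-track
  indicators. Overlap is positional (cluster-style tracks), not
  signal-height based.
* **conservation (10)**: per-position GERP-like and PhastCons-like track
  scores at the site and their 9-nt window means, plus a surrogate
  composition Z-score: for i.i.d. background base probabilities *q*,
  Z(s) = (Σᵢ log q_{sᵢ} − w·μ₁)/√(w·σ₁²) with μ₁ = Σ_b q_b log q_b and
  σ₁² = Σ_b q_b log²q_b − μ₁², evaluated for reference and mutated windows
  of length 7 and 9 together with their differences. A uniform background
  makes σ₁² = 0 and is rejected as degenerate. This standardized
  log-likelihood is a self-contained conservation-style score; the
  interface accepts any alternative scorer producing the same 10 columns.
* **tf_disruption (1)** / **tf_maxscore (1)**: PWM scanning with log-odds
  Σⱼ log(pⱼ(base)/bg(base)) maximized over offsets and both strands.
  `tf_maxscore` is the best hit over all PWMs and both alleles. The
  disruption statistic is Δ = best_ref − best_mut for the PWM with the
  strongest reference hit; its p-value is an empirical tail probability
  over `n_null` (default 100) uniform random center substitutions with
  add-one smoothing, p = (1 + #{Δ_null ≥ Δ_obs})/(n_null + 1), seeded per
  variant from the extraction seed.

Group sizes are enforced by `FeatureSchema` (total 227; the core
{sequence, gc, shape} set is 148) and any subset of groups can be
assembled in canonical order.

## Monte Carlo feature selection

Defaults: `s` = 1000 projections, `m_frac` = 0.25 of the features per
projection, `t` = 5 stratified splits per projection with training
fraction 2/3, unpruned Gini trees with minimum leaf 2, exponents
`u` = `v` = 1. Per tree τ with held-out weighted accuracy wAcc (mean
per-class recall):

    RI_g += wAcc^u · Σ_{nodes n splitting on g} IG(n) · (n_n/n_τ)^v

where IG(n) is the Gini impurity decrease at n, n_n the training samples
reaching n and n_τ the tree's training-set size. Interdependency strength
accumulates IG(n)·(n_n/n_τ) onto the ordered pair (ancestor feature,
descendant feature) for every distinct ancestor split feature on the path
to n (self-pairs excluded); the undirected export sums both directions.
Ties in RI are broken by canonical column order. The implementation warns
when any feature was never drawn (with s·m well above d·ln d this has
vanishing probability). `s` counts projections, not projections × splits.
Tree growing uses scikit-learn's `DecisionTreeClassifier`; trees operate
internally in float32, so RI values (not rankings) can wiggle at the last
few bits under monotone feature transforms.

## Classifier and evaluation

The classifier is XGBoost gradient tree boosting with the binary logistic
objective: 300 trees, maximum depth 8, learning rate 0.1, no row or column
subsampling, single-threaded for bit-level determinism given a seed.

The 8:2 stratified split computes the total test size as round(0.2·n)
(half away from zero), gives each class ⌊0.2·n_class⌋ seats and assigns
remaining seats by largest fractional remainder with ties favouring the
positive class — this rounding scheme is fixed because it is the unique
natural rule reproducing exact published cohort splits (e.g. 1,772/3,806
→ 355/761 test, 1,417/3,045 train). Leave-one-chromosome-out
cross-validation builds one fold per chromosome, skips folds whose test
part lacks a class (with a warning) and aggregates retained folds by
unweighted mean and sample standard deviation (ddof 1; 0 for a single
fold). Hard-label metrics use threshold 0.5.

ROC-AUC is the Mann–Whitney statistic (average ranks give ties half
credit). Average precision is the step-wise sum Σ_k (R_k − R_{k−1})·P_k
over descending unique thresholds — the convention under which "area under
the PR curve" and "average precision" coincide; no interpolation is
applied. Welch's t uses unbiased variances with the functional class as
the first argument; the two-sample KS p-value uses the asymptotic
Kolmogorov distribution (via scipy). Permutation ablation jointly permutes
the rows of all columns in a group set with one shared seeded permutation,
preserving within-set dependence, then re-scores the fixed model.

## Synthetic benchmark: what it emulates, and its ceiling

Defaults: 22 contigs of 12 kb at GC 0.5, one TSS per contig (alternating
strand) with a full 5 kb upstream window, 400 functional / 800 neutral
variants, binary tracks covering 30% of each promoter window, scored
tracks as 100-bp tiles, random Dirichlet PWMs of width 8, and a slightly
AT-rich Z-score background (0.29, 0.21, 0.21, 0.29) — chosen non-uniform
because the uniform background is the degenerate case. The fixed default
seed is 20181129.

The planted class signal acts through allele choice: with probability
`p_gc_gain` = 0.8 a functional variant is forced to be an A/T → G/C
substitution; otherwise, and for all neutral variants, (ref, alt) is drawn
uniformly over the 12 ordered unequal pairs (sites are resampled until the
genome matches the drawn reference base; positions are unique). The
synthetic pentamer table trends monotonically with pentamer GC count
(GC-rich ⇒ narrower minor groove, larger ProT/roll/HelT), so a GC-gaining
substitution also shifts the local shape profile — reproducing the
correlated GC/shape structure seen in real promoter variants without
hand-coding feature values.

**Information ceiling.** Because the genome context is i.i.d. and
identical across classes, and shape is a deterministic function of
sequence, the class-conditional distributions differ *only* through the
(ref, alt) mutation class. With the defaults, P(GC-gain | functional)
= 0.8 + 0.2/3 ≈ 0.867 versus P(GC-gain | neutral) = 1/3, which bounds the
achievable ROC-AUC by (1 + 0.867 − 0.333)/2 ≈ 0.767 and the average
precision by roughly 0.55–0.60 at prevalence 1/3 — no classifier can do
better on this generator, and the observed hold-out values (AUC ≈ 0.76,
AP ≈ 0.53–0.56) sit at that ceiling. Two further consequences: the same
single allele-class bit is redundantly encoded in the sequence, GC and
shape groups, so (a) continuous shape `*_diff` features — exact proxies of
the bit with additional split-friendly variation — tend to out-rank the
few discrete GC columns in MCFS, and (b) permuting a single group in the
ablation barely degrades AP (the model can be rebuilt on either remaining
group), making the single-vs-joint ablation ordering noise-dominated.
Real promoter data is not like this: its groups carry complementary,
high-dimensional information, which is precisely what this generator does
not emulate. Passing results on the benchmark therefore demonstrate
pipeline correctness and signal recovery up to the generator's ceiling,
not real-data performance levels.

Other deliberate simplifications: no linkage structure, no realistic
allele-frequency spectrum, no motif grammar in promoters, no matching of
real TSS-distance distributions, and no derivation of shape values from
molecular simulation (tables are inputs; the bundled generator is labeled
synthetic).

## Numerical choices and degenerate inputs

* Pentamer tables must be complete (1024 entries); duplicates resolve to
  the last row with a warning.
* Sequences with N are rejected from shape computation; windows overrunning
  a contig raise a boundary error rather than padding.
* Precision is defined as 0 when nothing is predicted positive (logged).
* AUC/AP require both classes / at least one positive; single-class inputs
  raise an explicit undefined-metric error rather than returning NaN.
* All randomness flows through `numpy.random.Generator` seeded explicitly;
  per-variant TF-null seeds derive from the extraction seed and the
  variant's position in the input, so results are independent of chunking.

## Problem sizes used in the bundled experiments

Unit tests run on small bundles (tens to hundreds of variants, 4–8
contigs); the end-to-end benchmark and `scripts/acceptance.py` use the
default study conditions (400/800 variants, 22 contigs, full MCFS with
1000 projections), which complete in about a minute on one CPU.

## Known limitations

* The 88-column shape layout is one consistent reconstruction of a
  "shape values + differences over an SNV-centred grid" design; other
  grids of the same cardinality exist.
* The surrogate Z-score is a background log-likelihood standardization,
  not a cross-species alignment score; with real alignment-based scores
  the conservation group would be more informative.
* The TF-disruption p-value uses an empirical center-substitution null,
  not a binding-energy model; its resolution is 1/(n_null + 1).
* No calibration of classifier scores, no bootstrap/DeLong confidence
  intervals (extension points are noted in the evaluation module).
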