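# Methods

This note documents the statistical procedures, the synthetic data model,
and the numerical/design choices made where more than one reasonable
implementation exists.

## Study design assumed by the pipeline

The expected layout is a gene × array matrix of RMA-normalized (log2)
expression values with a sample sheet assigning each array a condition
(cold, drought, heat, salt, or control), a timepoint in hours (1, 2, 5,
10, 24), and a replicate letter. Controls are matched triplicates at
every timepoint; missing arrays are permitted (the emulated design drops
heat / 5 h / replicate C). Because the sampling sheet is explicit, any
subset of stresses, timepoints or replicate counts works, subject to a
minimum of two arrays per group in the differential-expression tests.

## Differential expression

The test is the two-class unpaired permutation procedure built on the
regularized statistic

    d_i = (mean_B(i) − mean_A(i)) / (s_i + s0),

where `s_i = sqrt((1/nA + 1/nB) · pooled variance)` and the
exchangeability factor `s0` is chosen among the percentiles
{0, 5, …, 95} of the `s_i` distribution to minimize the coefficient of
variation of the MAD of `d` across quintiles of `s_i`. Group labels are
permuted (all C(nA+nB, nA) assignments enumerated when that space is no
larger than the requested permutation count — for 3 vs 3 the 20 balanced
assignments are enumerated and resampled with replacement to 100) and the
expected order statistics `d̄_(i)` are the per-rank means of the sorted
permuted `d`.

Calling uses the classic asymmetric cut thresholds: scanning outward from
the centre of the sorted `d`, the first rank whose deviation
`d_(i) − d̄_(i)` reaches Δ fixes `cutup` (and symmetrically `cutlo`);
every gene with `d ≥ cutup` is called up and `d ≤ cutlo` down, making the
call regions contiguous in `d`. The per-permutation false-positive count
is the number of permuted `d` values beyond the same cuts, and the median
FDR is the median of those counts divided by the observed call count. Δ
is the smallest value on a 0.01 grid whose median FDR is at or below the
target (default 0.01).

An earlier variant that called each gene from its own rank deviation
(`|d_(i) − d̄_(i)| ≥ Δ` per gene) was rejected: with genuine signal
present it reports a near-zero median FDR while letting through a large
tail of null genes, because the permuted deviations and the observed
deviations are not compared on a common scale. The threshold form ties
both to the same cut values and controls the realized false-call fraction
in null simulations (observed ≤ 2× the nominal target in the test suite).

Per-stress DE sets are unions of the per-timepoint calls; a gene up at
one timepoint and down at another enters both per-stress sets and is
flagged. This makes per-direction totals overlap-aware: the same gene can
legitimately count once in the up total and once in the down total.

## Co-expression network

Adjacency is `|Pearson r|^B` over all supplied arrays (stress and
control) of the DE-gene submatrix, with `B = 23`. The topological overlap
measure uses the unsigned form

    TOM_ij = (Σ_{u≠i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij),

`k_i = Σ_{u≠i} a_iu`; the clustering distance is `1 − TOM` with zero
diagonal. For an isolated pair this reduces to `1 − a_ij`, which the test
suite asserts, and the full matrix is checked against a brute-force
triple loop to 1e-12.

Modules are the connected components of the average-linkage dendrogram
below a static height of 0.91 (scipy `linkage` + `fcluster` with the
distance criterion — the classic cut-tree-by-height, not a dynamic cut),
subject to a minimum size of 25; smaller branches get the unassigned
label 0 and labels are dense in decreasing size order. Merging computes
each module eigengene as the first right singular vector of the
standardized member matrix, sign-oriented to correlate positively with
the module mean profile (principal components are sign-ambiguous; the
orientation rule makes outputs deterministic), and repeatedly merges the
closest pair with eigengene dissimilarity `1 − r < 0.1` until none
qualifies. Plain (signed) correlation is used for merging, so
anticorrelated modules are never merged even in the unsigned network;
merging is idempotent.

Module stress profiles are the per-timepoint means over member genes of
(stress mean − control mean), with standard errors over genes; a module
is responsive to a stress when any timepoint's mean difference reaches
1.0 RMA in magnitude. Edge export writes all pairs with adjacency ≥ 0.35
and flags those ≥ 0.45 for display-level filtering.

With `B = 23` and a cut height of 0.91, a block of co-expressed genes is
only detectable when its within-module correlations are roughly 0.92 or
higher (`0.92^23 ≈ 0.15` of adjacency is about where the TOM distance
crosses the cut). This is the regime the procedure is designed for —
tightly co-regulated stress modules — and the recovery tests therefore
run the generator at residual SD 0.2, where planted modules sit near
r ≈ 0.95. At residual SD 0.25 and above, recovery degrades sharply; that
cliff is a property of the fixed power/cut-height combination, not of the
clustering code.

## Network plasticity

For a condition pair (A, B), the eligible genes are those DE in both
conditions, split into TF and non-TF (TG) groups by a user-supplied TF
list. `r_A` and `r_B` are the TF × TG Pearson correlation matrices over
each condition's stress arrays (all timepoints × replicates; genes
constant within a condition are dropped with a warning). The plasticity
score is `|Δr| = |r_A − r_B|`, unsigned in both observed and null
tallies, since the procedure thresholds symmetric correlation change.

The null shuffles each eligible gene's profile independently
(Fisher–Yates) across the pooled stress arrays of *all* conditions
(controls excluded), draws two disjoint column subsets of N = 15, and
recomputes all pair correlations; exceedance counts are accumulated on a
Δr grid of step 0.01 over [0, 2]. The default permutation count is 7,200;
tests and the desk-scale pipeline run 40–500 permutations, which changes
only the Monte-Carlo error of the mean false-positive count, not the
semantics. The cutoff is the smallest grid value where mean null
exceedances / max(observed exceedances, 1) is at or below the target FDR
(default 0.05); when no observed pair reaches the qualifying cutoff the
comparison is reported as "no signal". Disjointness of the two null
subsets mirrors the comparison of two non-overlapping condition panels.
When a condition has fewer than 2N arrays available (heat, with one
dropped array), the observed correlations use the arrays that exist while
the null keeps N = 15 drawn from the pooled stress arrays.

A useful calibration point, recomputed by `scripts/acceptance.py`: for
146 TF × 1,910 TG independent null profiles of 59 exchangeable values,
the per-permutation mean count of pairs with |Δr| ≥ 0.97 is ≈ 2,190 of
278,860 — i.e. the null places ≈ 0.8% of pair mass beyond that cutoff.
This follows from the exact null density of the Pearson correlation at
n = 15 (`f(r) ∝ (1 − r²)^5.5`) and is insensitive to the marginal
distribution of the profiles.

Non-plastic genes are those that entered at least one comparison and
never had any pairing exceed the comparison's cutoff in any comparison;
genes that entered no comparison are not reported (absence of evidence is
not stability).

## Promoter elements

Counting is exhaustive over all 4^k motifs for k ∈ {5..8}: overlapping
occurrences on the given strand only, with windows containing N skipped
(so motifs never match across assembly gaps). Enrichment is a one-sided
hypergeometric test on promoter presence — the number of set promoters
containing the motif, against the background presence count — rather than
on raw hit counts, which makes the test robust to repeat-rich promoters;
a hit-count binomial alternative is available behind the `statistic`
parameter. BH correction spans all motifs of all lengths tested in one
table, and significance is FDR < 0.01. Nested motifs (a 5-mer inside a
significant 8-mer) are reported as separate rows, not collapsed: sub-motif
significance is informative about the core. Per-module summaries count
total significant motifs and those significant in exactly one module.

Promoter extraction from FASTA + GFF3 is strand-aware: for + genes the
`L` bases ending immediately before the gene start, for − genes the `L`
bases after the gene end, reverse-complemented; sequences truncated at
contig edges are flagged. GFF3 coordinates are treated as 1-based
inclusive and converted to 0-based half-open internally.

## Set overlap, terms, undefined genes

The overlap test draws class-sized subsets of the universe uniformly
without replacement (default 10,000 permutations — enough to stabilize
the null SD to about 1%) and summarizes with
`Z = (observed − mean) / SD` and a two-tailed normal p-value; the
closed-form hypergeometric mean `nK/N` and SD are available as the
`hypergeometric` method and agree with the permutation moments within
Monte-Carlo error. A degenerate null (SD = 0, e.g. class = universe)
reports Z as undefined rather than infinite.

Term enrichment is a flat hypergeometric tail per term with BH
correction; a term is significant only when FDR < 0.05 *and* strictly
more than 5 set genes map to it, so tiny-term artifacts never reach
significance. Terms are used as given — no ontology-graph propagation.

The undefined-gene filter declares a gene defined when it has an
alignment at ≥ 70% identity covering ≥ 70% of its own length to a target
with an informative annotation (both bounds inclusive), or an informative
domain-scan flag; alignments to targets annotated only as
"expressed/unknown" do not count. Alignment tables are consumed
pre-computed; no aligner is run.

## Synthetic data generator

Gene values follow `x_gj = baseline_g + m_g · (profile(module_g, cond_j,
t_j) + u_{module_g, j}) + ε_gj` with `baseline_g ~ N(8, 2)` (RMA-like
scale and spread), loadings `m_g ~ U(0.8, 1.2)`, latent per-array module
co-fluctuation `u ~ N(0, 0.2)` (biological replicate variation is
correlated within a module, which no mean profile captures), and residual
noise `ε ~ N(0, noise_sd)` (default 0.3). Each module responds to one
primary stress — cycled so all stresses are covered — at amplitude
`de_effect_rma` (default 1.5) with a rapid-onset time ramp from 0.7× to
1× of the effect across the five sampling times; most non-drought modules
additionally respond to drought at half amplitude, echoing
drought-dominated modular responses. The default design is 4 stresses ×
5 timepoints × 3 replicates plus matched controls with the heat 5 h
replicate C array dropped.

Plastic TF–target pairs are generated from a shared standard-normal
latent per pair: the TF adds `c·z` in both conditions of the pair while
the target adds `+c·z` in the first and `−c·z` in the second (default
c = 1.0), giving generating-model correlations `±c²/(c² + noise_sd²)`
(≈ ±0.92 at the defaults, |Δr| ≈ 1.83). Both genes also get a flat
expression shift of `de_effect_rma` in both conditions so they enter the
DE-in-both universe without adding shared time structure that would
dilute the planted correlation flip.

Promoters are i.i.d. uniform ACGT of 500 nt with configured motifs
planted at recorded offsets in a configured fraction of a target module's
genes. Annotations provide the TF list (drawn 80% from non-module genes,
mirroring the depletion of TFs from modules), a "non-modular" gene class,
and a term map with one term covering module 1 exactly.

What the generator does **not** emulate: probe-level effects and
normalization artifacts, realistic GC/codon composition or repeat
structure in promoters, ontology graph structure, correlated noise across
modules, and heavy-tailed expression noise. Passing tests therefore
demonstrate correctness of the statistical machinery under the assumed
model, not robustness to every pathology of real microarray data.

## Problem sizes and runtime choices

The test suite runs generators at 200–400 genes, 2–4 modules, and 40–200
plasticity permutations; the acceptance script uses 10,000 permutations
for overlap nulls and 500 for the Δr null. These sizes keep the full
suite under a minute while leaving every Monte-Carlo assertion at least
three standard errors away from its bound. All randomness flows through
`numpy.random.default_rng` seeds carried in the config objects; identical
configuration and seed reproduce every output byte-for-byte.
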