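# stressnet

Analysis pipeline for abiotic-stress transcriptome time courses in plants,
built around the study design used for *Brachypodium distachyon*: four
stresses (cold, drought, heat, high salinity) profiled at 1, 2, 5, 10 and
24 h after onset in biological triplicate against matched controls, on the
RMA (log2) expression scale.

It is aimed at researchers who want to go from a normalized gene × array
matrix to (1) differential-expression calls, (2) co-expression modules
with stress-response profiles, (3) condition-dependent rewiring of
TF–target correlations, and (4) candidate *cis*-regulatory elements — with
every stage testable against a synthetic data generator that knows its own
ground truth.

## Methods at a glance

**Differential expression (SAM-style).** For each stress × timepoint, a
two-class unpaired permutation test on the regularized statistic
`d_i = (x̄_stress − x̄_control) / (s_i + s0)`, where `s_i` is the pooled-SD
standard error and `s0` a fudge factor chosen to decouple `d` from
per-gene variance. Observed sorted `d` values are compared with their
permutation-expected order statistics; the calling threshold Δ is the
smallest grid value whose median permutation false-discovery rate is below
the target (default 0.01). Per-stress gene sets are unions over
timepoints.

**Co-expression network.** Unsigned soft-threshold adjacency
`a_ij = |cor(x_i, x_j)|^B` (default `B = 23`) over the DE genes, converted
to the topological overlap measure

```
TOM_ij = (Σ_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij)
```

Modules are branches of the average-linkage dendrogram of `1 − TOM` cut
statically at 0.91 with a minimum size of 25, then merged when their
eigengenes (first principal components) correlate above 0.9. A module is
called responsive to a stress when its mean stress-minus-control profile
reaches |1.0| RMA at any timepoint.

**Network plasticity.** For a pair of conditions, genes DE in both are
split into TF and target (TG) groups; each TF–TG pair gets one Pearson
correlation per condition. A permutation null (each gene's profile
Fisher–Yates-shuffled across the pooled stress arrays, two disjoint
subsets of N = 15 arrays drawn, all pair correlations recomputed) sets the
smallest |Δr| cutoff at which mean null exceedances / observed exceedances
≤ 0.05, SAM-style.

**Promoter elements.** Every 5–8 nt sequence is counted in 500-nt
upstream regions (overlapping hits, given strand, windows with N skipped)
and tested for module enrichment against the genome-wide promoter
background with a one-sided hypergeometric test on promoter presence,
Benjamini–Hochberg corrected across all motifs (significant at FDR < 0.01).

**Set overlap and annotation.** Permutation and closed-form hypergeometric
Z-tests for depletion/enrichment of gene classes among module members;
flat term over-representation (FDR < 0.05 and > 5 mapped genes); and a
homology filter that labels genes "undefined" unless they align at ≥ 70%
identity over ≥ 70% of their length to an informatively annotated target
or carry an informative domain hit.

## Worked example

Run the whole pipeline on a synthetic dataset (260 genes, three planted
modules, 8 planted plastic TF–target pairs, one planted promoter motif):

```python
import stressnet as sn

res = sn.run_pipeline({
    "seed": 7, "outdir": "demo_out",
    "simulate": {"n_genes": 260, "module_sizes": [45, 40, 35],
                 "noise_sd_rma": 0.2, "de_effect_rma": 2.0,
                 "n_plastic_pairs": 8, "n_tfs": 20},
    "params": {"plasticity": {"n_permutations": 200}},
})
de = res["de"]
print({s: len(de.de_genes(s)) for s in sorted(de.up)})
print(res["network"]["assignment"].module_sizes.to_string())
print(res["plasticity"]["summary"].to_string(index=False))
```

prints

```
{'cold': 50, 'drought': 95, 'heat': 45, 'salt': 28}
module
1    45
2    40
3    35
stress_a stress_b  gene_pairings  plastic_pairs  plastic_pct  mean_false_positives      fdr  delta_r_cutoff
    cold  drought              0              0          0.0                  0.00 0.000000            2.00
    cold     heat              0              0          0.0                  0.00 0.000000            2.00
    cold     salt              0              0          0.0                  0.00 0.000000            2.00
 drought     heat             40              0          0.0                  0.04 0.040000            1.12
 drought     salt            152             14          9.2                  0.64 0.045714            1.03
    heat     salt              0              0          0.0                  0.00 0.000000            2.00
```

All three planted modules are recovered exactly (45/40/35 genes), DE
calls concentrate in each module's planted stress, and the drought–salt
comparison — the pair in which plastic relationships were planted — is the
one with substantial rewiring: 14 of 152 TF–TG pairings cross the
Δr = 1.03 cutoff at an achieved FDR of 0.046, while pairs of conditions
without planted plasticity show essentially none. The same run writes
per-stress gene lists, SAM diagnostics, module membership/profile tables,
an edge list, per-module element tables and the overlap report into
`demo_out/`.

The same stages are available from the shell:

```bash
stressnet simulate --seed 7 --n-genes 500 --outdir fixture/
stressnet diffexpr --expression fixture/expression.tsv --design fixture/design.tsv --outdir de/
stressnet run-all --config pipeline.yaml
```

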