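"""Published summary tables from the Brachypodium distachyon abiotic-stress
microarray study that this pipeline re-implements.

These printed values serve as inputs for consistency checks and
desk-scale cross-validation of the statistics (they are *data*, not
results computed by this package): the per-module membership and
enrichment summary, the per-stress differential-expression totals, and
the pairwise condition plasticity summary.
"""

from __future__ import annotations

import pandas as pd

# Module membership and enrichment summary: module number, member count N,
# undefined genes, unique/total enriched functional terms, unique/total
# enriched promoter DNA elements (5-8 nt, FDR < 0.01).
MODULE_SUMMARY = pd.DataFrame(
    [
        (1, 1114, 96, 20, 81, 60, 235),
        (2, 966, 70, 59, 75, 299, 441),
        (3, 961, 74, 27, 53, 56, 208),
        (4, 725, 39, 55, 101, 323, 504),
        (5, 640, 52, 0, 0, 90, 225),
        (6, 367, 18, 11, 13, 107, 151),
        (7, 350, 18, 54, 110, 97, 145),
        (8, 226, 22, 0, 0, 5, 24),
        (9, 198, 15, 1, 7, 12, 45),
        (10, 156, 6, 0, 15, 190, 354),
        (11, 134, 5, 3, 4, 0, 8),
        (12, 110, 2, 0, 0, 32, 69),
        (13, 101, 7, 0, 0, 8, 50),
        (14, 64, 4, 0, 0, 9, 37),
        (15, 52, 0, 0, 0, 4, 12),
        (16, 42, 1, 1, 2, 3, 17),
        (17, 42, 0, 0, 0, 8, 13),
        (18, 38, 2, 4, 25, 1, 15),
        (19, 37, 3, 0, 0, 1, 26),
        (20, 26, 4, 0, 0, 0, 0),
        (21, 25, 2, 0, 0, 6, 12),
        (22, 25, 1, 0, 0, 1, 1),
    ],
    columns=[
        "module", "n", "undefined_genes",
        "unique_go_terms", "total_go_terms",
        "unique_dna_elements", "total_dna_elements",
    ],
)

# Per-stress differential expression totals (union over timepoints).
DE_COUNTS = pd.DataFrame(
    {
        "stress": ["cold", "heat", "salt", "drought"],
        "up": [447, 458, 1565, 2290],
        "down": [40, 1621, 1137, 5790],
    }
)

# Genes differentially expressed under a stress and under no other stress
# (the "unique" Venn region), with the per-stress DE totals they refer to.
VENN_UNIQUE = pd.DataFrame(
    {
        "stress": ["cold", "heat", "salt"],
        "unique": [161, 930, 507],
        "total": [487, 2079, 2702],
    }
)

# Pairwise condition plasticity summary: total TF-TG pairings, pairs
# exceeding the delta-r cutoff, mean null exceedances per permutation,
# achieved FDR and the cutoff itself.
PLASTICITY_SUMMARY = pd.DataFrame(
    [
        ("drought", "salt", 276950, 27916, 1368.1, 0.049, 0.97),
        ("drought", "cold", 16665, 2921, 144.9, 0.049, 0.96),
        ("drought", "heat", 70434, 4890, 239.9, 0.049, 0.98),
        ("salt", "heat", 26562, 241, 11.9, 0.049, 1.35),
        ("salt", "cold", 8132, 2027, 94.8, 0.047, 0.94),
        ("heat", "cold", 522, 128, 6.0, 0.047, 0.88),
    ],
    columns=[
        "stress_a", "stress_b", "gene_pairings", "plastic_pairs",
        "mean_false_positives", "fdr", "delta_r_cutoff",
    ],
)

# Gene-universe constants used by the overlap analyses:
# differentially expressed genes, module members, and the two gene classes
# whose module overlap was tested (calcium-binding loci; DE TF loci).
DE_UNIVERSE_N = 9496
MODULE_MEMBERS_N = 6399
CALCIUM_CLASS_N = 359
CALCIUM_OBSERVED_IN_MODULES = 88
TF_CLASS_N = 600
TF_OBSERVED_IN_MODULES = 369
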