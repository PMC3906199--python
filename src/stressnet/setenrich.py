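"""Gene-set overlap tests, generic term enrichment, and the
undefined-gene classification filter.

The overlap test asks whether a gene class (e.g. calcium-binding loci or
differentially expressed TFs) is over- or under-represented among module
members: either by drawing class-sized random subsets of the universe
(permutation) or by the closed-form hypergeometric mean and SD.  The
Z-score and a two-tailed normal p-value follow the permutation summary.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import erf, sqrt

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


@dataclass
class OverlapTest:
    universe_n: int
    members_n: int
    class_n: int
    observed: int
    expected: float
    sd: float
    z: float | None
    p_two_tailed: float | None
    method: str


def _normal_two_tailed(z: float) -> float:
    return 2.0 * (1.0 - 0.5 * (1.0 + erf(abs(z) / sqrt(2.0))))


def overlap_test(
    universe: set[str] | list[str],
    members: set[str],
    gene_class: set[str],
    method: str = "permutation",
    n_permutations: int = 10000,
    seed: int = 0,
) -> OverlapTest:
    """Overlap of ``gene_class`` with ``members`` against random class draws.

    Permutation: class-sized subsets of the universe are drawn uniformly
    without replacement; the overlap mean/SD over draws give the null.
    Hypergeometric: closed-form mean n*K/N and the matching SD.  A
    degenerate null (SD = 0) yields Z = None.
    """
    universe = list(dict.fromkeys(universe))
    n_universe = len(universe)
    if not members <= set(universe):
        raise ValueError("member set must be a subset of the universe")
    if not gene_class <= set(universe):
        raise ValueError("gene class must be a subset of the universe")
    observed = len(members & gene_class)
    K = len(members)
    n = len(gene_class)
    if method == "hypergeometric":
        expected = n * K / n_universe
        var = (
            n * (K / n_universe) * (1 - K / n_universe)
            * (n_universe - n) / (n_universe - 1)
            if n_universe > 1
            else 0.0
        )
        sd = sqrt(var)
    elif method == "permutation":
        rng = np.random.default_rng(seed)
        is_member = np.zeros(n_universe, dtype=bool)
        member_set = members
        for i, g in enumerate(universe):
            is_member[i] = g in member_set
        draws = np.empty(n_permutations, dtype=np.int64)
        for p in range(n_permutations):
            idx = rng.choice(n_universe, size=n, replace=False)
            draws[p] = int(is_member[idx].sum())
        expected = float(draws.mean())
        sd = float(draws.std(ddof=0))
    else:
        raise ValueError("method must be 'permutation' or 'hypergeometric'")
    if sd > 0:
        z = (observed - expected) / sd
        p = _normal_two_tailed(z)
    else:
        z, p = None, None
    return OverlapTest(
        universe_n=n_universe,
        members_n=K,
        class_n=n,
        observed=observed,
        expected=expected,
        sd=sd,
        z=z,
        p_two_tailed=p,
        method=method,
    )


def term_enrichment(
    gene_set: set[str],
    background: set[str],
    term_map: dict[str, list[str] | set[str]],
    fdr_threshold: float = 0.05,
    min_mapped: int = 5,
) -> pd.DataFrame:
    """Hypergeometric term over-representation with a BH correction.

    A term is significant when its corrected p-value is below
    ``fdr_threshold`` AND strictly more than ``min_mapped`` set genes map
    to it (the two-clause rule used for functional-term calls).
    """
    if not gene_set:
        return pd.DataFrame(
            columns=["term", "set_hits", "bg_hits", "p", "fdr", "significant"]
        )
    if not gene_set <= background:
        raise ValueError("gene set must be a subset of the background")
    N = len(background)
    n = len(gene_set)
    rows = []
    for term, genes in sorted(term_map.items()):
        tg = set(genes) & background
        K = len(tg)
        if K == 0:
            continue
        x = len(gene_set & tg)
        p = float(hypergeom.sf(x - 1, N, K, n))
        rows.append({"term": term, "set_hits": x, "bg_hits": K, "p": p})
    if not rows:
        return pd.DataFrame(
            columns=["term", "set_hits", "bg_hits", "p", "fdr", "significant"]
        )
    table = pd.DataFrame(rows)
    _, fdr, _, _ = multipletests(table["p"].to_numpy(), method="fdr_bh")
    table["fdr"] = fdr
    table["significant"] = (table["fdr"] < fdr_threshold) & (
        table["set_hits"] > min_mapped
    )
    return table.sort_values(["fdr", "p", "term"], ignore_index=True)


def classify_undefined(
    genes: list[str] | set[str],
    alignments: pd.DataFrame,
    informative_domain_genes: set[str] | None = None,
    min_identity_pct: float = 70.0,
    min_coverage: float = 0.70,
) -> set[str]:
    """Genes with no informative annotation route.

    ``alignments`` needs columns gene / identity_pct / coverage /
    target_informative; coverage is the aligned fraction of the query's
    total length (0..1).  A gene is *defined* when it has an alignment with
    identity and coverage at or above the thresholds to an informatively
    annotated target, or carries an informative domain-scan flag; all other
    genes are undefined.
    """
    informative_domain_genes = informative_domain_genes or set()
    required = {"gene", "identity_pct", "coverage", "target_informative"}
    if not required <= set(alignments.columns):
        raise ValueError(f"alignment table must have columns {sorted(required)}")
    if (alignments["coverage"] > 1).any():
        raise ValueError("coverage must be a fraction in [0, 1]")
    good = alignments[
        (alignments["identity_pct"] >= min_identity_pct)
        & (alignments["coverage"] >= min_coverage)
        & alignments["target_informative"].astype(bool)
    ]
    defined = set(good["gene"]) | set(informative_domain_genes)
    return set(genes) - defined
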