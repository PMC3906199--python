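"""Differential correlation ("network plasticity") of TF-target pairs.

For a pair of stress conditions, every gene differentially expressed in
both conditions is split into a transcription-factor (TF) group and a
target (TG) group.  Each TF-TG pair gets one Pearson correlation per
condition; the pair is plastic when |r_A - r_B| exceeds a cutoff chosen
so that the permutation-estimated false discovery rate is at or below a
target (SAM-like threshold selection).

The null is built by Fisher-Yates shuffling each gene's profile across
the pooled stress arrays, drawing two disjoint column subsets of equal
size N, and recomputing all pair correlations per permutation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sam import DECallSet

logger = logging.getLogger(__name__)


@dataclass
class PlasticityParams:
    n_permutations: int = 7200
    subset_size: int = 15
    target_fdr: float = 0.05
    grid_step: float = 0.01
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.subset_size < 3:
            raise ValueError("subset_size must be >= 3")
        if not 0 < self.target_fdr < 1:
            raise ValueError("target_fdr must be in (0, 1)")
        if self.grid_step <= 0:
            raise ValueError("grid_step must be > 0")

    @property
    def grid(self) -> np.ndarray:
        return np.round(np.arange(0.0, 2.0 + self.grid_step, self.grid_step), 10)


@dataclass
class PlasticityComparison:
    condition_a: str
    condition_b: str
    tf_genes: list[str]
    tg_genes: list[str]
    r_a: pd.DataFrame  # TF x TG
    r_b: pd.DataFrame
    delta_r_cutoff: float
    n_pairings: int
    n_plastic: int
    mean_false_positives: float
    fdr: float
    no_signal: bool = False
    plastic_mask: pd.DataFrame | None = None
    dropped_genes: list[str] = field(default_factory=list)

    @property
    def delta_r(self) -> pd.DataFrame:
        return (self.r_a - self.r_b).abs()

    def pair_table(self) -> pd.DataFrame:
        """Tidy per-pair table: tf, tg, r_a, r_b, delta_r, plastic."""
        d = self.delta_r
        recs = []
        for tf in d.index:
            for tg in d.columns:
                recs.append(
                    (tf, tg, self.r_a.at[tf, tg], self.r_b.at[tf, tg], d.at[tf, tg])
                )
        df = pd.DataFrame(recs, columns=["tf", "tg", "r_a", "r_b", "delta_r"])
        df["plastic"] = (not self.no_signal) & (df["delta_r"] >= self.delta_r_cutoff)
        return df


def _corr_cross(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Pearson correlations between rows of X and rows of Y (shared columns)."""
    Xz = X - X.mean(axis=1, keepdims=True)
    Yz = Y - Y.mean(axis=1, keepdims=True)
    xn = np.sqrt((Xz**2).sum(axis=1, keepdims=True))
    yn = np.sqrt((Yz**2).sum(axis=1, keepdims=True))
    return (Xz / xn) @ (Yz / yn).T


def pair_correlations(
    matrix: pd.DataFrame,
    design: pd.DataFrame,
    de: DECallSet,
    tf_list: list[str] | set[str],
    conditions: tuple[str, str],
) -> tuple[list[str], list[str], pd.DataFrame, pd.DataFrame]:
    """TF/TG groups and their per-condition correlation matrices.

    The gene universe is genes differentially expressed in both conditions;
    correlations are taken over each condition's stress arrays (all
    timepoints and replicates).  Genes constant within a condition are
    dropped with a logged warning.
    """
    cond_a, cond_b = conditions
    de_both = de.de_genes(cond_a) & de.de_genes(cond_b)
    tf_set = set(tf_list)
    tfs = sorted(de_both & tf_set)
    tgs = sorted(de_both - tf_set)
    cols_a = design.loc[
        (design["condition"] == cond_a) & ~design["is_control"], "sample_id"
    ].tolist()
    cols_b = design.loc[
        (design["condition"] == cond_b) & ~design["is_control"], "sample_id"
    ].tolist()
    dropped = []
    for g in tfs + tgs:
        va = matrix.loc[g, cols_a].to_numpy(dtype=float)
        vb = matrix.loc[g, cols_b].to_numpy(dtype=float)
        if va.std() == 0 or vb.std() == 0:
            dropped.append(g)
    if dropped:
        logger.warning(
            "dropping %d zero-variance genes from %s-%s comparison",
            len(dropped), cond_a, cond_b,
        )
        tfs = [g for g in tfs if g not in set(dropped)]
        tgs = [g for g in tgs if g not in set(dropped)]
    if not tfs or not tgs:
        empty = pd.DataFrame(index=tfs, columns=tgs, dtype=float)
        return tfs, tgs, empty, empty
    Xa = matrix.loc[tfs, cols_a].to_numpy(dtype=float)
    Ya = matrix.loc[tgs, cols_a].to_numpy(dtype=float)
    Xb = matrix.loc[tfs, cols_b].to_numpy(dtype=float)
    Yb = matrix.loc[tgs, cols_b].to_numpy(dtype=float)
    r_a = pd.DataFrame(_corr_cross(Xa, Ya), index=tfs, columns=tgs)
    r_b = pd.DataFrame(_corr_cross(Xb, Yb), index=tfs, columns=tgs)
    return tfs, tgs, r_a, r_b


def permutation_null(
    profiles: np.ndarray,
    n_tf: int,
    params: PlasticityParams,
) -> np.ndarray:
    """Null exceedance counts: permutations x grid cutoffs.

    ``profiles`` holds the TF rows first, then the TG rows, over the pooled
    stress arrays.  Per permutation each row is independently shuffled, two
    disjoint subsets of ``subset_size`` columns are drawn, and the count of
    pairs with |delta r| at or above each grid cutoff is recorded.
    """
    n_genes, n_arrays = profiles.shape
    N = params.subset_size
    if 2 * N > n_arrays:
        raise ValueError(f"need >= {2 * N} arrays for two disjoint subsets of {N}")
    rng = np.random.default_rng(params.rng_seed)
    grid = params.grid
    counts = np.zeros((params.n_permutations, grid.size), dtype=np.int64)
    for p in range(params.n_permutations):
        shuffled = rng.permuted(profiles, axis=1)
        cols = rng.permutation(n_arrays)
        sub_a, sub_b = cols[:N], cols[N : 2 * N]
        ra = _corr_cross(shuffled[:n_tf, sub_a], shuffled[n_tf:, sub_a])
        rb = _corr_cross(shuffled[:n_tf, sub_b], shuffled[n_tf:, sub_b])
        dr = np.abs(ra - rb).ravel()
        # exceedance count at cutoff c = number of delta-r values >= c
        hist, _ = np.histogram(dr, bins=np.append(grid, np.inf))
        counts[p] = hist[::-1].cumsum()[::-1]
    return counts


def select_cutoff(
    observed_delta_r: np.ndarray,
    null_counts: np.ndarray,
    params: PlasticityParams,
) -> tuple[float, int, float, float, bool]:
    """Smallest grid cutoff whose permutation FDR is at or below target.

    FDR(c) = mean null exceedances at c / max(observed exceedances at c, 1).
    Returns (cutoff, n_plastic, mean false positives, fdr, no_signal).
    """
    grid = params.grid
    obs = observed_delta_r[np.isfinite(observed_delta_r)]
    hist, _ = np.histogram(obs, bins=np.append(grid, np.inf))
    obs_counts = hist[::-1].cumsum()[::-1]
    mean_fp = null_counts.mean(axis=0)
    fdr = mean_fp / np.maximum(obs_counts, 1)
    ok = fdr <= params.target_fdr
    if not ok.any():
        return float(grid[-1]), 0, float(mean_fp[-1]), float(fdr[-1]), True
    i = int(np.argmax(ok))
    no_signal = obs_counts[i] == 0
    return (
        float(grid[i]),
        int(obs_counts[i]),
        float(mean_fp[i]),
        float(fdr[i]),
        bool(no_signal),
    )


def compare_conditions(
    matrix: pd.DataFrame,
    design: pd.DataFrame,
    de: DECallSet,
    tf_list: list[str] | set[str],
    conditions: tuple[str, str],
    params: PlasticityParams | None = None,
) -> PlasticityComparison:
    """Full plasticity analysis of one condition pair."""
    params = params or PlasticityParams()
    tfs, tgs, r_a, r_b = pair_correlations(matrix, design, de, tf_list, conditions)
    if not tfs or not tgs:
        return PlasticityComparison(
            conditions[0], conditions[1], tfs, tgs, r_a, r_b,
            delta_r_cutoff=2.0, n_pairings=0, n_plastic=0,
            mean_false_positives=0.0, fdr=0.0, no_signal=True,
        )
    pool_cols = design.loc[~design["is_control"], "sample_id"].tolist()
    profiles = matrix.loc[tfs + tgs, pool_cols].to_numpy(dtype=float)
    null_counts = permutation_null(profiles, len(tfs), params)
    delta = (r_a - r_b).abs()
    cutoff, n_plastic, mean_fp, fdr, no_signal = select_cutoff(
        delta.to_numpy().ravel(), null_counts, params
    )
    mask = delta >= cutoff if not no_signal else delta > 2.0
    return PlasticityComparison(
        conditions[0], conditions[1], tfs, tgs, r_a, r_b,
        delta_r_cutoff=cutoff,
        n_pairings=int(delta.size),
        n_plastic=n_plastic,
        mean_false_positives=mean_fp,
        fdr=fdr,
        no_signal=no_signal,
        plastic_mask=mask,
    )


def summary_table(comparisons: list[PlasticityComparison]) -> pd.DataFrame:
    """One row per condition pair: pairings, plastic pairs, mean false
    positives per permutation, achieved FDR and the delta-r cutoff."""
    rows = []
    for c in comparisons:
        pct = 100.0 * c.n_plastic / c.n_pairings if c.n_pairings else 0.0
        rows.append(
            {
                "stress_a": c.condition_a,
                "stress_b": c.condition_b,
                "gene_pairings": c.n_pairings,
                "plastic_pairs": c.n_plastic,
                "plastic_pct": round(pct, 1),
                "mean_false_positives": c.mean_false_positives,
                "fdr": c.fdr,
                "delta_r_cutoff": c.delta_r_cutoff,
            }
        )
    return pd.DataFrame(rows)


def nonplastic_genes(comparisons: list[PlasticityComparison]) -> set[str]:
    """Genes that entered at least one comparison and never exceeded the
    plasticity cutoff in any pairing of any comparison."""
    eligible: set[str] = set()
    plastic: set[str] = set()
    for c in comparisons:
        eligible |= set(c.tf_genes) | set(c.tg_genes)
        if c.plastic_mask is None or c.no_signal:
            continue
        mask = c.plastic_mask
        for tf in mask.index[mask.any(axis=1)]:
            plastic.add(tf)
        for tg in mask.columns[mask.any(axis=0)]:
            plastic.add(tg)
    return eligible - plastic


def correlation_histogram(
    comparison: PlasticityComparison, bin_width: float = 0.05
) -> pd.DataFrame:
    """2-D histogram of pair correlations (r_a bin, r_b bin, count) for
    heatmap-scatterplot style displays."""
    edges = np.arange(-1.0, 1.0 + bin_width, bin_width)
    h, _, _ = np.histogram2d(
        comparison.r_a.to_numpy().ravel(),
        comparison.r_b.to_numpy().ravel(),
        bins=[edges, edges],
    )
    rows = []
    for i in range(len(edges) - 1):
        for j in range(len(edges) - 1):
            if h[i, j]:
                rows.append((edges[i], edges[j], int(h[i, j])))
    return pd.DataFrame(rows, columns=["r_a_bin", "r_b_bin", "count"])
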