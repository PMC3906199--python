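"""Weighted co-expression network: soft-threshold adjacency, topological
overlap, static-cut module detection, eigengene merging, and module-level
stress-response profiles.

Unsigned adjacency raises the absolute Pearson correlation to a soft power
(default B = 23); the topological overlap measure (TOM) rescales adjacency
by shared network neighbourhoods,

    TOM_ij = (sum_{u != i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij),

with connectivity k_i = sum_{u != i} a_iu.  Modules are branches of the
average-linkage dendrogram of 1 - TOM cut at a fixed height, merged when
their eigengenes (first principal components) correlate above 1 minus the
merge cut height.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform


@dataclass
class NetworkParams:
    soft_power: float = 23.0
    cut_height: float = 0.91
    min_module_size: int = 25
    merge_cut_height: float = 0.1  # 1 - eigengene correlation
    export_threshold: float = 0.35
    display_filter: float = 0.45

    def __post_init__(self) -> None:
        if self.soft_power < 1:
            raise ValueError("soft_power must be >= 1")
        if not 0 < self.cut_height <= 1:
            raise ValueError("cut_height must be in (0, 1]")
        if self.min_module_size < 1:
            raise ValueError("min_module_size must be >= 1")
        if self.export_threshold > self.display_filter:
            raise ValueError("export_threshold must not exceed display_filter")


@dataclass
class ModuleAssignment:
    labels: pd.Series  # gene -> module number, 0 = unassigned
    eigengenes: pd.DataFrame | None = None  # arrays x modules

    @property
    def module_sizes(self) -> pd.Series:
        assigned = self.labels[self.labels > 0]
        return assigned.value_counts().sort_index()

    def members(self, module: int) -> list[str]:
        return list(self.labels.index[self.labels == module])


def adjacency(matrix: pd.DataFrame, params: NetworkParams | None = None) -> pd.DataFrame:
    """Unsigned soft-threshold adjacency |cor|^B over all supplied arrays."""
    params = params or NetworkParams()
    X = matrix.to_numpy(dtype=float)
    sd = X.std(axis=1)
    if np.any(sd == 0):
        bad = matrix.index[sd == 0][0]
        raise ValueError(f"zero-variance gene {bad!r}; filter before network construction")
    corr = np.corrcoef(X)
    a = np.abs(corr) ** params.soft_power
    np.fill_diagonal(a, 1.0)
    return pd.DataFrame(a, index=matrix.index, columns=matrix.index)


def tom_dissimilarity(adj: pd.DataFrame) -> pd.DataFrame:
    """1 - TOM with zero diagonal (the clustering distance)."""
    a = adj.to_numpy(dtype=float)
    k = a.sum(axis=0) - 1.0  # connectivity, diagonal excluded
    # sum over u of a_iu a_uj minus the u=i and u=j terms (diagonal of a is 1)
    num = a @ a - 2.0 * a + a
    den = np.minimum.outer(k, k) + 1.0 - a
    np.fill_diagonal(den, 1.0)  # diagonal is overwritten below
    tom = num / den
    np.fill_diagonal(tom, 1.0)
    dis = 1.0 - tom
    np.fill_diagonal(dis, 0.0)
    dis = np.clip((dis + dis.T) / 2.0, 0.0, 1.0)
    return pd.DataFrame(dis, index=adj.index, columns=adj.columns)


def _relabel_by_size(labels: np.ndarray) -> np.ndarray:
    """Dense module numbers 1..K ordered by decreasing size (ties: first gene)."""
    out = np.zeros_like(labels)
    mods = [m for m in np.unique(labels) if m != 0]
    order = sorted(
        mods,
        key=lambda m: (-int((labels == m).sum()), int(np.argmax(labels == m))),
    )
    for new, old in enumerate(order, start=1):
        out[labels == old] = new
    return out


def detect_modules(
    dissim: pd.DataFrame, params: NetworkParams | None = None
) -> ModuleAssignment:
    """Static cut of the average-linkage dendrogram at ``cut_height``.

    Branches (connected components below the cut) with at least
    ``min_module_size`` genes become modules, numbered by decreasing size;
    all other genes get label 0.
    """
    params = params or NetworkParams()
    genes = dissim.index
    n = len(genes)
    if n < 2:
        return ModuleAssignment(pd.Series(np.zeros(n, dtype=int), index=genes))
    Z = linkage(squareform(dissim.to_numpy(dtype=float), checks=False), method="average")
    raw = fcluster(Z, t=params.cut_height, criterion="distance")
    labels = raw.astype(int)
    for m in np.unique(labels):
        if (labels == m).sum() < params.min_module_size:
            labels[labels == m] = 0
    labels = _relabel_by_size(labels)
    return ModuleAssignment(pd.Series(labels, index=genes, name="module"))


def module_eigengene(matrix: pd.DataFrame, members: list[str]) -> pd.Series:
    """First principal component of the standardised member expression,
    sign-oriented to correlate positively with the module mean profile."""
    X = matrix.loc[members].to_numpy(dtype=float)
    Xz = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, keepdims=True)
    _, _, vt = np.linalg.svd(Xz, full_matrices=False)
    eig = vt[0]
    mean_profile = Xz.mean(axis=0)
    if np.dot(eig, mean_profile) < 0:
        eig = -eig
    eig = eig / np.linalg.norm(eig)
    return pd.Series(eig, index=matrix.columns)


def merge_modules(
    assignment: ModuleAssignment,
    matrix: pd.DataFrame,
    params: NetworkParams | None = None,
) -> ModuleAssignment:
    """Iteratively merge module pairs whose eigengene dissimilarity
    (1 - correlation) is below ``merge_cut_height``; relabel densely by size."""
    params = params or NetworkParams()
    labels = assignment.labels.copy()
    while True:
        mods = sorted(m for m in labels.unique() if m != 0)
        if len(mods) < 2:
            break
        eigs = {m: module_eigengene(matrix, list(labels.index[labels == m])) for m in mods}
        best: tuple[float, int, int] | None = None
        for i, m1 in enumerate(mods):
            for m2 in mods[i + 1 :]:
                dis = 1.0 - float(np.corrcoef(eigs[m1], eigs[m2])[0, 1])
                if dis < params.merge_cut_height and (best is None or dis < best[0]):
                    best = (dis, m1, m2)
        if best is None:
            break
        _, m1, m2 = best
        labels[labels == m2] = m1
    arr = _relabel_by_size(labels.to_numpy())
    labels = pd.Series(arr, index=labels.index, name="module")
    mods = sorted(m for m in np.unique(arr) if m != 0)
    eig_df = (
        pd.DataFrame({m: module_eigengene(matrix, list(labels.index[labels == m])) for m in mods})
        if mods
        else None
    )
    return ModuleAssignment(labels, eig_df)


def module_profiles(
    assignment: ModuleAssignment,
    matrix: pd.DataFrame,
    design: pd.DataFrame,
    de_threshold_rma: float = 1.0,
) -> pd.DataFrame:
    """Mean stress-minus-control expression difference per module/stress/hour.

    Returns a tidy frame (module, stress, timepoint_h, mean_delta_rma, se,
    n_genes, responsive); a module is called responsive to a stress when the
    absolute mean difference reaches ``de_threshold_rma`` at any timepoint.
    """
    rows = []
    controls = design[design["is_control"]]
    stresses = sorted(design.loc[~design["is_control"], "condition"].unique())
    for m in sorted(assignment.labels.unique()):
        if m == 0:
            continue
        members = assignment.members(m)
        if not members:
            warnings.warn(f"module {m} has no members; skipped")
            continue
        sub = matrix.loc[members]
        for stress in stresses:
            deltas_by_t = {}
            for t in sorted(design.loc[design["condition"] == stress, "timepoint_h"].unique()):
                s_ids = design.loc[
                    (design["condition"] == stress) & (design["timepoint_h"] == t),
                    "sample_id",
                ]
                c_ids = controls.loc[controls["timepoint_h"] == t, "sample_id"]
                if not len(s_ids) or not len(c_ids):
                    continue
                per_gene = sub[list(s_ids)].mean(axis=1) - sub[list(c_ids)].mean(axis=1)
                deltas_by_t[t] = per_gene
            responsive = any(
                abs(d.mean()) >= de_threshold_rma for d in deltas_by_t.values()
            )
            for t, per_gene in deltas_by_t.items():
                rows.append(
                    {
                        "module": m,
                        "stress": stress,
                        "timepoint_h": t,
                        "mean_delta_rma": per_gene.mean(),
                        "se": per_gene.std(ddof=1) / np.sqrt(len(per_gene))
                        if len(per_gene) > 1
                        else 0.0,
                        "n_genes": len(per_gene),
                        "responsive": responsive,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["module", "stress", "timepoint_h", "mean_delta_rma", "se", "n_genes", "responsive"],
    )


def export_edge_list(
    adj: pd.DataFrame,
    assignment: ModuleAssignment | None = None,
    params: NetworkParams | None = None,
) -> pd.DataFrame:
    """Weighted edges with adjacency >= export threshold; edges at or above
    the display filter carry a display flag (mirrors post-export filtering
    in a viewer)."""
    params = params or NetworkParams()
    a = adj.to_numpy(dtype=float)
    genes = list(adj.index)
    iu, ju = np.triu_indices(len(genes), k=1)
    keep = a[iu, ju] >= params.export_threshold
    rows = {
        "gene_a": [genes[i] for i in iu[keep]],
        "gene_b": [genes[j] for j in ju[keep]],
        "adjacency": a[iu, ju][keep],
    }
    df = pd.DataFrame(rows)
    df["display"] = df["adjacency"] >= params.display_filter
    if assignment is not None:
        df["module_a"] = assignment.labels.reindex(df["gene_a"]).to_numpy()
        df["module_b"] = assignment.labels.reindex(df["gene_b"]).to_numpy()
    return df
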