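"""Two-class unpaired permutation differential expression (SAM-style).

The d-statistic is a regularised t-like score,

    d_i = (mean_B - mean_A) / (s_i + s0),

with ``s_i`` the pooled-SD standard error of the group difference and
``s0`` an exchangeability ("fudge") factor chosen to decouple d from the
per-gene variance.  Significance is assessed against the expected order
statistics of d under label permutations: gene i (in d-sorted order) is
called when |d_(i) - dbar_(i)| >= delta, and delta is chosen as the
smallest grid value whose median permutation false-discovery rate falls
below the target.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd


@dataclass
class SAMParams:
    n_permutations: int = 100
    s0: float | None = None  # estimated from the data when None
    delta: float | None = None  # selected from target_median_fdr when None
    target_median_fdr: float = 0.01
    delta_grid_step: float = 0.01
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not 0 < self.target_median_fdr < 1:
            raise ValueError("target_median_fdr must be in (0, 1)")
        if self.delta is not None and self.delta < 0:
            raise ValueError("delta must be >= 0")


@dataclass
class SAMResult:
    """Per-gene d scores plus the calling threshold actually used."""

    d: pd.Series
    s: pd.Series
    s0: float
    expected_d: np.ndarray  # permutation-mean order statistics, ascending
    delta: float
    median_fdr: float
    called: pd.Series  # -1 / 0 / +1 per gene
    n_up: int = 0
    n_down: int = 0

    def __post_init__(self) -> None:
        self.n_up = int((self.called == 1).sum())
        self.n_down = int((self.called == -1).sum())


def _d_stat(A: np.ndarray, B: np.ndarray, s0: float) -> tuple[np.ndarray, np.ndarray]:
    nA, nB = A.shape[1], B.shape[1]
    diff = B.mean(axis=1) - A.mean(axis=1)
    ssA = ((A - A.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    ssB = ((B - B.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    pooled = (ssA + ssB) / (nA + nB - 2)
    s = np.sqrt((1.0 / nA + 1.0 / nB) * pooled)
    den = s + s0
    d = np.divide(diff, den, out=np.zeros_like(diff), where=den > 0)
    return d, s


def estimate_s0(diff: np.ndarray, s: np.ndarray) -> float:
    """Fudge-factor estimate: the percentile of s (0, 5, ..., 95) minimising
    the coefficient of variation of the MAD of d across quintiles of s."""
    candidates = np.percentile(s, np.arange(0, 100, 5))
    qs = np.quantile(s, [0.2, 0.4, 0.6, 0.8])
    bins = np.searchsorted(qs, s)
    best, best_cv = 0.0, np.inf
    for s0 in candidates:
        den = s + s0
        d = np.divide(diff, den, out=np.zeros_like(diff), where=den > 0)
        mads = []
        for b in range(5):
            db = d[bins == b]
            if db.size == 0:
                continue
            med = np.median(db)
            mads.append(np.median(np.abs(db - med)) / 0.6745)
        mads = np.asarray(mads)
        mean = mads.mean()
        if mean == 0:
            continue
        cv = mads.std() / mean
        if cv < best_cv:
            best_cv, best = cv, float(s0)
    return best


def _permutation_labels(
    nA: int, nB: int, n_perm: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Group-A index sets for each permutation.

    When the exchangeable space is small (e.g. 3 vs 3 gives C(6,3)=20
    assignments) every assignment is enumerated and then resampled with
    replacement up to ``n_perm`` so the requested permutation count is
    honoured without leaving the exhaustive space.
    """
    from math import comb

    total = nA + nB
    n_exact = comb(total, nA)
    if n_exact <= n_perm:
        all_sets = [np.array(c) for c in combinations(range(total), nA)]
        if n_exact == n_perm:
            return all_sets
        picks = rng.integers(0, n_exact, size=n_perm)
        return [all_sets[i] for i in picks]
    out = []
    for _ in range(n_perm):
        out.append(rng.permutation(total)[:nA])
    return out


def sam_test(
    matrix: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    params: SAMParams | None = None,
) -> SAMResult:
    """SAM two-class unpaired test of group B against group A.

    ``group_a`` is the reference (e.g. control arrays); positive d means
    higher expression in ``group_b``.
    """
    params = params or SAMParams()
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 arrays")
    if set(group_a) & set(group_b):
        raise ValueError("groups must be disjoint")
    A = matrix[list(group_a)].to_numpy(dtype=float)
    B = matrix[list(group_b)].to_numpy(dtype=float)
    n_genes = A.shape[0]
    genes = matrix.index

    if n_genes == 0:
        empty = pd.Series(dtype=float, index=genes)
        return SAMResult(empty, empty, 0.0, np.array([]), 0.0, 0.0,
                         pd.Series(dtype=int, index=genes))

    diff = B.mean(axis=1) - A.mean(axis=1)
    _, s = _d_stat(A, B, 0.0)
    s0 = params.s0 if params.s0 is not None else estimate_s0(diff, s)
    d, s = _d_stat(A, B, s0)

    rng = np.random.default_rng(params.rng_seed)
    pooled = np.concatenate([A, B], axis=1)
    nA = A.shape[1]
    all_idx = np.arange(pooled.shape[1])
    perm_sorted = np.empty((params.n_permutations, n_genes))
    for p, ia in enumerate(_permutation_labels(nA, B.shape[1], params.n_permutations, rng)):
        ib = np.setdiff1d(all_idx, ia)
        dp, _ = _d_stat(pooled[:, ia], pooled[:, ib], s0)
        perm_sorted[p] = np.sort(dp)
    expected_d = perm_sorted.mean(axis=0)

    sorted_d = np.sort(d)
    dev = sorted_d - expected_d
    mid = n_genes // 2

    def cuts_at(delta: float) -> tuple[float, float]:
        """Asymmetric call thresholds (cutlo, cutup) in d units.

        Scanning outward from the centre of the sorted d values, the first
        position whose deviation from the permutation-expected order
        statistic reaches delta sets the threshold; every gene beyond it is
        called (the call regions are contiguous in d)."""
        up = np.flatnonzero(dev[mid:] >= delta)
        cutup = sorted_d[mid + up[0]] if up.size else np.inf
        lo = np.flatnonzero(dev[:mid] <= -delta)
        cutlo = sorted_d[lo[-1]] if lo.size else -np.inf
        return cutlo, cutup

    def calls_at(delta: float) -> np.ndarray:
        cutlo, cutup = cuts_at(delta)
        return np.where(d >= cutup, 1, np.where(d <= cutlo, -1, 0))

    def median_fdr_at(delta: float, n_obs: int) -> float:
        """Median over permutations of (#permuted d beyond the cuts) / n_obs."""
        if n_obs == 0:
            return 0.0
        cutlo, cutup = cuts_at(delta)
        perm_calls = (perm_sorted >= cutup).sum(axis=1) + (perm_sorted <= cutlo).sum(axis=1)
        return float(np.median(perm_calls)) / n_obs

    if params.delta is not None:
        delta = params.delta
    else:
        max_dev = np.abs(dev).max() if n_genes else 0.0
        grid = np.arange(0.0, max_dev + 2 * params.delta_grid_step, params.delta_grid_step)
        delta = grid[-1]
        for c in grid:
            n_obs = int(np.count_nonzero(calls_at(c)))
            if median_fdr_at(c, n_obs) <= params.target_median_fdr:
                delta = float(c)
                break
    called = calls_at(delta)
    med_fdr = median_fdr_at(delta, int(np.count_nonzero(called)))
    return SAMResult(
        d=pd.Series(d, index=genes),
        s=pd.Series(s, index=genes),
        s0=s0,
        expected_d=expected_d,
        delta=delta,
        median_fdr=med_fdr,
        called=pd.Series(called, index=genes),
    )


@dataclass
class DECallSet:
    """Differential-expression calls per stress with per-timepoint provenance."""

    up: dict[str, set[str]]
    down: dict[str, set[str]]
    per_timepoint: pd.DataFrame  # stress, timepoint_h, gene, sign
    diagnostics: pd.DataFrame  # stress, timepoint_h, delta, median_fdr, n_up, n_down
    both_directions: dict[str, set[str]] = field(default_factory=dict)

    def de_genes(self, stress: str) -> set[str]:
        return self.up.get(stress, set()) | self.down.get(stress, set())

    def all_de_genes(self) -> set[str]:
        out: set[str] = set()
        for s in self.up:
            out |= self.de_genes(s)
        return out


def call_all(
    matrix: pd.DataFrame,
    design: pd.DataFrame,
    params: SAMParams | None = None,
) -> DECallSet:
    """One SAM test per (stress, timepoint) against matched controls.

    Per-stress up/down sets are unions over timepoints; a gene called up at
    one time and down at another enters both sets and is flagged in
    ``both_directions``.
    """
    params = params or SAMParams()
    stresses = sorted(design.loc[~design["is_control"], "condition"].unique())
    up: dict[str, set[str]] = {s: set() for s in stresses}
    down: dict[str, set[str]] = {s: set() for s in stresses}
    tp_rows, diag_rows = [], []
    controls = design[design["is_control"]]
    if len(matrix.index) and not len(controls):
        raise ValueError("design has no control arrays")
    for stress in stresses:
        sub = design[(design["condition"] == stress) & ~design["is_control"]]
        for t in sorted(sub["timepoint_h"].unique()):
            ctrl_ids = controls.loc[controls["timepoint_h"] == t, "sample_id"].tolist()
            stress_ids = sub.loc[sub["timepoint_h"] == t, "sample_id"].tolist()
            if len(ctrl_ids) < 2 or len(stress_ids) < 2:
                raise ValueError(
                    f"{stress} {t}h: need >=2 control and stress arrays"
                )
            if matrix.shape[0] == 0:
                continue
            res = sam_test(matrix, ctrl_ids, stress_ids, params)
            for g in res.called.index[res.called == 1]:
                up[stress].add(g)
                tp_rows.append((stress, t, g, 1))
            for g in res.called.index[res.called == -1]:
                down[stress].add(g)
                tp_rows.append((stress, t, g, -1))
            diag_rows.append(
                (stress, t, res.s0, res.delta, res.median_fdr, res.n_up, res.n_down)
            )
    both = {s: up[s] & down[s] for s in stresses}
    return DECallSet(
        up=up,
        down=down,
        per_timepoint=pd.DataFrame(
            tp_rows, columns=["stress", "timepoint_h", "gene", "sign"]
        ),
        diagnostics=pd.DataFrame(
            diag_rows,
            columns=["stress", "timepoint_h", "s0", "delta", "median_fdr", "n_up", "n_down"],
        ),
        both_directions=both,
    )


def venn_partition(
    sets: dict[str, set[str]]
) -> dict[frozenset[str], int]:
    """Counts of the 15 non-empty regions of the 4-set Venn diagram.

    Keys are frozensets of the set names whose exclusive intersection the
    region represents; counts sum to the size of the union.
    """
    names = sorted(sets)
    if len(names) != 4:
        raise ValueError("venn_partition expects exactly four sets")
    regions: dict[frozenset[str], int] = {}
    for r in range(1, 16):
        members = frozenset(n for i, n in enumerate(names) if r >> i & 1)
        regions[members] = 0
    universe = set().union(*sets.values())
    for g in universe:
        sig = frozenset(n for n in names if g in sets[n])
        regions[sig] += 1
    return regions
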