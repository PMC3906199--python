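"""Exhaustive short-motif (5-8 nt) promoter enrichment.

Every k-mer over {A,C,G,T} for k in the configured range is counted in a
set of promoters (overlapping occurrences, given strand only, windows
containing N skipped) and tested for over-representation against a
genome-wide promoter background with a one-sided hypergeometric test on
promoter presence, Benjamini-Hochberg corrected across all tested motifs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

_BASE_CODE = np.full(256, -1, dtype=np.int8)
for _i, _c in enumerate(b"ACGT"):
    _BASE_CODE[_c] = _i


@dataclass
class ElementParams:
    k_min: int = 5
    k_max: int = 8
    fdr_threshold: float = 0.01
    statistic: str = "presence"  # 'presence' (hypergeometric) | 'hits-binomial'

    def __post_init__(self) -> None:
        if not 5 <= self.k_min <= self.k_max <= 8:
            raise ValueError("k range must satisfy 5 <= k_min <= k_max <= 8")
        if not 0 < self.fdr_threshold < 1:
            raise ValueError("fdr_threshold must be in (0, 1)")
        if self.statistic not in ("presence", "hits-binomial"):
            raise ValueError("statistic must be 'presence' or 'hits-binomial'")

    @property
    def ks(self) -> range:
        return range(self.k_min, self.k_max + 1)


@dataclass
class KmerCounts:
    """Per-k arrays of total hits and promoter presence, plus set size."""

    hits: dict[int, np.ndarray]  # k -> int64[4^k]
    promoters: dict[int, np.ndarray]  # k -> int64[4^k]
    n_promoters: int
    total_positions: dict[int, int]  # k -> N-free window count


def encode(seq: str) -> np.ndarray:
    """0-3 codes for ACGT; -1 for N or any other character."""
    return _BASE_CODE[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]


def decode_kmer(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append("ACGT"[code % 4])
        code //= 4
    return "".join(reversed(out))


def kmer_code(motif: str) -> int:
    code = 0
    for c in motif.upper():
        i = "ACGT".find(c)
        if i < 0:
            raise ValueError(f"non-ACGT character in motif {motif!r}")
        code = code * 4 + i
    return code


def _window_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Integer codes of all valid (N-free) k-windows of one sequence."""
    n = codes.size
    if n < k:
        return np.empty(0, dtype=np.int64)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    win = np.lib.stride_tricks.sliding_window_view(codes, k)
    valid = (win >= 0).all(axis=1)
    if not valid.any():
        return np.empty(0, dtype=np.int64)
    return (win[valid].astype(np.int64) * powers).sum(axis=1)


def count_kmers(
    promoters: dict[str, str], params: ElementParams | None = None
) -> KmerCounts:
    """Overlapping k-mer occurrence and promoter-presence counts."""
    params = params or ElementParams()
    hits = {k: np.zeros(4**k, dtype=np.int64) for k in params.ks}
    pres = {k: np.zeros(4**k, dtype=np.int64) for k in params.ks}
    total = {k: 0 for k in params.ks}
    for seq in promoters.values():
        codes = encode(seq)
        for k in params.ks:
            wc = _window_codes(codes, k)
            total[k] += wc.size
            if wc.size:
                hits[k] += np.bincount(wc, minlength=4**k)
                uniq = np.unique(wc)
                pres[k][uniq] += 1
    return KmerCounts(hits, pres, len(promoters), total)


def enrich_motifs(
    set_counts: KmerCounts,
    background_counts: KmerCounts,
    params: ElementParams | None = None,
) -> pd.DataFrame:
    """Enrichment table over every motif present in the background.

    One-sided p-value per motif: with the 'presence' statistic, the
    hypergeometric tail probability of drawing at least the observed number
    of motif-containing promoters when sampling the set's promoters from the
    background pool.  BH correction spans all tested motifs of all lengths.
    """
    params = params or ElementParams()
    if set_counts.n_promoters > background_counts.n_promoters:
        raise ValueError("promoter set is larger than the background")
    frames = []
    for k in params.ks:
        bg_pres = background_counts.promoters[k]
        tested = np.flatnonzero(bg_pres > 0)
        if tested.size == 0:
            continue
        x = set_counts.promoters[k][tested]
        K = bg_pres[tested]
        if np.any(x > np.minimum(K, set_counts.n_promoters)):
            raise ValueError("set promoter counts exceed background; set must be a subset")
        if params.statistic == "presence":
            p = hypergeom.sf(
                x - 1, background_counts.n_promoters, K, set_counts.n_promoters
            )
        else:
            from scipy.stats import binom

            rate = background_counts.hits[k][tested] / max(
                background_counts.total_positions[k], 1
            )
            n_pos = set_counts.total_positions[k]
            p = binom.sf(set_counts.hits[k][tested] - 1, n_pos, rate)
        frames.append(
            pd.DataFrame(
                {
                    "motif": [decode_kmer(int(c), k) for c in tested],
                    "k": k,
                    "hits": set_counts.hits[k][tested],
                    "promoters": x,
                    "bg_hits": background_counts.hits[k][tested],
                    "bg_promoters": K,
                    "p": p,
                }
            )
        )
    if not frames:
        return pd.DataFrame(
            columns=["motif", "k", "hits", "promoters", "bg_hits", "bg_promoters", "p", "fdr", "significant"]
        )
    table = pd.concat(frames, ignore_index=True)
    _, fdr, _, _ = multipletests(table["p"].to_numpy(), method="fdr_bh")
    table["fdr"] = fdr
    table["significant"] = table["fdr"] < params.fdr_threshold
    return table.sort_values(["fdr", "p", "motif"], ignore_index=True)


def enrich_module_promoters(
    module_promoters: dict[int, dict[str, str]],
    background_promoters: dict[str, str],
    params: ElementParams | None = None,
) -> dict[int, pd.DataFrame]:
    """Per-module enrichment tables against a shared genome background."""
    params = params or ElementParams()
    bg = count_kmers(background_promoters, params)
    return {
        m: enrich_motifs(count_kmers(proms, params), bg, params)
        for m, proms in module_promoters.items()
    }


def unique_total_summary(tables: dict[int, pd.DataFrame]) -> pd.DataFrame:
    """Per-module counts of total significant motifs and motifs significant
    in that module only."""
    sig = {m: set(t.loc[t["significant"], "motif"]) for m, t in tables.items()}
    rows = []
    for m in sorted(sig):
        others = set().union(*(sig[o] for o in sig if o != m)) if len(sig) > 1 else set()
        rows.append(
            {
                "module": m,
                "unique_elements": len(sig[m] - others),
                "total_elements": len(sig[m]),
            }
        )
    return pd.DataFrame(rows, columns=["module", "unique_elements", "total_elements"])


def query_core(
    core: str,
    module_promoters: dict[str, str],
    background_promoters: dict[str, str],
    params: ElementParams | None = None,
) -> tuple[int, int, float]:
    """(hits, promoters, FDR) for one core motif in a module's promoters.

    The FDR comes from the full-table correction, so a single query is
    penalised identically to the exhaustive scan.
    """
    params = params or ElementParams()
    if not params.k_min <= len(core) <= params.k_max:
        raise ValueError(f"core length {len(core)} outside [{params.k_min}, {params.k_max}]")
    if not module_promoters:
        return 0, 0, 1.0
    table = enrich_motifs(
        count_kmers(module_promoters, params),
        count_kmers(background_promoters, params),
        params,
    )
    row = table[table["motif"] == core.upper()]
    if row.empty:
        return 0, 0, 1.0
    r = row.iloc[0]
    return int(r["hits"]), int(r["promoters"]), float(r["fdr"])
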