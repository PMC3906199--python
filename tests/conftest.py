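"""Shared synthetic fixtures.

Everything is generated in-process with fixed seeds; no data files.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import stressnet as sn


@pytest.fixture(scope="session")
def tight_fixture():
    """Four well-separated modules at high signal-to-noise (r ~ 0.95).

    Used for module recovery and everything downstream of detection.
    """
    cfg = sn.SyntheticConfig(
        n_genes=260,
        module_sizes=[60, 50, 40, 30],
        de_effect_rma=2.0,
        noise_sd_rma=0.2,
        n_plastic_pairs=0,
        rng_seed=2,
    )
    matrix, design, truth = sn.generate_dataset(cfg)
    return cfg, matrix, design, truth


@pytest.fixture(scope="session")
def plastic_fixture():
    """Fixture with planted drought-salt plastic TF-target pairs."""
    cfg = sn.SyntheticConfig(
        n_genes=400,
        module_sizes=[50, 40, 30],
        de_effect_rma=2.0,
        noise_sd_rma=0.3,
        n_plastic_pairs=15,
        n_tfs=30,
        rng_seed=5,
    )
    matrix, design, truth = sn.generate_dataset(cfg)
    de = sn.call_all(matrix, design, sn.SAMParams(rng_seed=1))
    return cfg, matrix, design, truth, de


@pytest.fixture(scope="session")
def promoter_fixture():
    """Two modules; an 8-nt motif planted in module 1 at rate 0.6."""
    cfg = sn.SyntheticConfig(
        n_genes=300,
        module_sizes=[50, 40],
        planted_motifs=[("CAACGGTC", 1, 0.6)],
        n_plastic_pairs=0,
        rng_seed=9,
    )
    matrix, design, truth = sn.generate_dataset(cfg)
    promoters = sn.generate_promoters(cfg, truth)
    return cfg, truth, promoters


def null_matrix(n_genes: int, n_a: int, n_b: int, seed: int) -> tuple[pd.DataFrame, list, list]:
    rng = np.random.default_rng(seed)
    X = rng.normal(0, 1, (n_genes, n_a + n_b))
    cols = [f"a{i}" for i in range(n_a)] + [f"b{i}" for i in range(n_b)]
    m = pd.DataFrame(X, index=[f"g{i}" for i in range(n_genes)], columns=cols)
    return m, cols[:n_a], cols[n_a:]
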