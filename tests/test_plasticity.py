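"""Differential-correlation machinery: correlations, null, cutoff, recovery."""

import numpy as np
import pandas as pd
import pytest

import stressnet as sn
from stressnet.plasticity import summary_table


def test_tf_identical_to_tg_has_unit_correlation(plastic_fixture):
    cfg, matrix, design, truth, de = plastic_fixture
    # make a private copy with a TG duplicating a TF profile
    tfs, tgs, r_a, _ = sn.pair_correlations(
        matrix, design, de, truth.tf_genes, ("drought", "salt")
    )
    m2 = matrix.copy()
    m2.loc[tgs[0]] = m2.loc[tfs[0]]
    _, _, r_a2, r_b2 = sn.pair_correlations(
        m2, design, de, truth.tf_genes, ("drought", "salt")
    )
    assert r_a2.at[tfs[0], tgs[0]] == pytest.approx(1.0)
    assert r_b2.at[tfs[0], tgs[0]] == pytest.approx(1.0)


def test_constant_gene_dropped_with_warning(plastic_fixture, caplog):
    cfg, matrix, design, truth, de = plastic_fixture
    tfs, tgs, *_ = sn.pair_correlations(
        matrix, design, de, truth.tf_genes, ("drought", "salt")
    )
    m2 = matrix.copy()
    salt_cols = design.loc[design.condition == "salt", "sample_id"]
    m2.loc[tgs[0], salt_cols] = 3.0
    with caplog.at_level("WARNING", logger="stressnet.plasticity"):
        tfs2, tgs2, *_ = sn.pair_correlations(
            m2, design, de, truth.tf_genes, ("drought", "salt")
        )
    assert tgs[0] not in tgs2
    assert "zero-variance" in caplog.text


def test_planted_correlations_recovered(plastic_fixture):
    cfg, matrix, design, truth, de = plastic_fixture
    tfs, tgs, r_a, r_b = sn.pair_correlations(
        matrix, design, de, truth.tf_genes, ("drought", "salt")
    )
    # each condition has 15 arrays, so a single r estimate can sit ~0.2 from
    # the generating value; the sign flip and the ensemble mean are stable
    dev_a, dev_b = [], []
    for row in truth.plastic_pairs.itertuples():
        if row.tf in r_a.index and row.tg in r_a.columns:
            ra, rb = r_a.at[row.tf, row.tg], r_b.at[row.tf, row.tg]
            assert ra > 0.5 and rb < -0.5
            assert ra == pytest.approx(row.r_a_true, abs=0.3)
            assert rb == pytest.approx(row.r_b_true, abs=0.3)
            dev_a.append(ra - row.r_a_true)
            dev_b.append(rb - row.r_b_true)
    assert len(dev_a) >= 10
    assert abs(np.mean(dev_a)) < 0.1 and abs(np.mean(dev_b)) < 0.1


@pytest.fixture(scope="module")
def null_counts():
    rng = np.random.default_rng(0)
    profiles = rng.normal(0, 1, (30, 40))
    params = sn.PlasticityParams(n_permutations=50, subset_size=10, rng_seed=1)
    return sn.permutation_null(profiles, 10, params), params


class TestPermutationNull:

    def test_extreme_cutoffs_bound_counts(self, null_counts):
        counts, params = null_counts
        n_pairings = 10 * 20
        assert (counts[:, 0] == n_pairings).all()  # cutoff 0: everything exceeds
        assert (counts[:, -1] == 0).all()  # cutoff 2: nothing exceeds

    def test_counts_non_increasing_in_cutoff(self, null_counts):
        counts, _ = null_counts
        assert (np.diff(counts, axis=1) <= 0).all()

    def test_reproducible_under_seed(self):
        rng = np.random.default_rng(2)
        profiles = rng.normal(0, 1, (12, 40))
        params = sn.PlasticityParams(n_permutations=20, subset_size=10, rng_seed=5)
        c1 = sn.permutation_null(profiles, 4, params)
        c2 = sn.permutation_null(profiles, 4, params)
        assert (c1 == c2).all()

    def test_too_few_arrays_rejected(self):
        profiles = np.zeros((5, 20))
        params = sn.PlasticityParams(n_permutations=5, subset_size=15)
        with pytest.raises(ValueError):
            sn.permutation_null(profiles, 2, params)


class TestSelectCutoff:
    def test_published_style_counts_give_published_fdr(self):
        """At the drought-salt cutoff the ratio 1368.1 / 27,916 is 0.049."""
        params = sn.PlasticityParams(grid_step=0.01)
        grid = params.grid
        # observed: 27,916 pairs at |delta r| >= 0.97 (placed just above)
        observed = np.concatenate([
            np.full(248_000, 0.5), np.full(27_916 - 1000, 0.975), np.full(1000, 1.2),
        ])
        # null: mean 1368.1 exceedances at 0.97 and nothing below 0.97 qualifying
        mean_fp = np.interp(grid, [0, 0.96, 0.97, 2.0], [250_000, 30_000, 1368.1, 0])
        null_counts = np.round(mean_fp)[None, :]
        cutoff, n_plastic, fp, fdr, no_signal = sn.select_cutoff(observed, null_counts, params)
        assert cutoff == pytest.approx(0.97)
        assert n_plastic == 27_916
        assert fdr == pytest.approx(fp / 27_916)
        assert round(fdr, 3) <= 0.05

    def test_zero_null_exceedance_gives_zero_fdr(self):
        params = sn.PlasticityParams(grid_step=0.01)
        grid = params.grid
        observed = np.full(100, 0.6)
        null_counts = np.where(grid < 0.5, 100, 0)[None, :]
        cutoff, n_plastic, fp, fdr, no_signal = sn.select_cutoff(observed, null_counts, params)
        assert cutoff <= 0.5
        assert fdr == 0.0
        assert not no_signal

    def test_no_observed_exceedances_is_no_signal(self):
        params = sn.PlasticityParams()
        observed = np.zeros(0)
        null_counts = np.ones((10, params.grid.size))
        *_, no_signal = sn.select_cutoff(observed, null_counts, params)
        assert no_signal

    def test_selected_cutoff_is_minimal(self, plastic_fixture):
        cfg, matrix, design, truth, de = plastic_fixture
        params = sn.PlasticityParams(n_permutations=100, rng_seed=3)
        comp = sn.compare_conditions(matrix, design, de, truth.tf_genes,
                                     ("drought", "salt"), params)
        grid = params.grid
        i = int(np.where(np.isclose(grid, comp.delta_r_cutoff))[0][0])
        assert comp.fdr <= params.target_fdr
        if i > 0:
            # recompute FDR at the next-smaller cutoff: must violate the target
            pool = design.loc[~design.is_control, "sample_id"]
            profiles = matrix.loc[comp.tf_genes + comp.tg_genes, pool].to_numpy()
            null_counts = sn.permutation_null(profiles, len(comp.tf_genes), params)
            obs = comp.delta_r.to_numpy().ravel()
            below = grid[i - 1]
            obs_n = (obs >= below).sum()
            fp = null_counts.mean(axis=0)[i - 1]
            assert fp / max(obs_n, 1) > params.target_fdr


@pytest.fixture(scope="module")
def comparison(plastic_fixture):
    cfg, matrix, design, truth, de = plastic_fixture
    params = sn.PlasticityParams(n_permutations=200, rng_seed=3)
    return truth, sn.compare_conditions(
        matrix, design, de, truth.tf_genes, ("drought", "salt"), params
    )


class TestPlantedPairRecovery:

    def test_sensitivity_at_least_ninety_percent(self, comparison):
        truth, comp = comparison
        mask = comp.plastic_mask
        planted = [
            (r.tf, r.tg) for r in truth.plastic_pairs.itertuples()
            if r.tf in mask.index and r.tg in mask.columns
        ]
        assert len(planted) >= 10
        hits = sum(mask.at[tf, tg] for tf, tg in planted)
        assert hits / len(planted) >= 0.9

    def test_false_positive_fraction_bounded(self, comparison):
        truth, comp = comparison
        mask = comp.plastic_mask
        planted = {(r.tf, r.tg) for r in truth.plastic_pairs.itertuples()}
        fp = sum(
            mask.at[tf, tg]
            for tf in mask.index for tg in mask.columns
            if (tf, tg) not in planted
        )
        assert fp <= max(2 * comp.mean_false_positives, 2.0)

    def test_achieved_fdr_within_target(self, comparison):
        _, comp = comparison
        assert comp.fdr <= 0.05


class TestNonPlasticGenes:
    def test_stable_gene_reported_and_uncompared_gene_excluded(self, plastic_fixture):
        cfg, matrix, design, truth, de = plastic_fixture
        params = sn.PlasticityParams(n_permutations=100, rng_seed=3)
        comp = sn.compare_conditions(matrix, design, de, truth.tf_genes,
                                     ("drought", "salt"), params)
        stable = sn.nonplastic_genes([comp])
        # planted plastic targets must not be in the stable set
        assert not ({r.tg for r in truth.plastic_pairs.itertuples()} & stable)
        assert stable <= set(comp.tf_genes) | set(comp.tg_genes)
        # a gene outside every comparison is not reported
        assert "not_a_gene" not in stable

    def test_all_pairs_plastic_gives_empty_set(self):
        r = pd.DataFrame([[0.9]], index=["tf1"], columns=["tg1"])
        comp = sn.PlasticityComparison(
            "a", "b", ["tf1"], ["tg1"], r, -r, delta_r_cutoff=0.5,
            n_pairings=1, n_plastic=1, mean_false_positives=0.0, fdr=0.0,
            plastic_mask=pd.DataFrame([[True]], index=["tf1"], columns=["tg1"]),
        )
        assert sn.nonplastic_genes([comp]) == set()


def test_summary_table_shape(plastic_fixture):
    cfg, matrix, design, truth, de = plastic_fixture
    params = sn.PlasticityParams(n_permutations=60, rng_seed=3)
    comps = [
        sn.compare_conditions(matrix, design, de, truth.tf_genes, pair, params)
        for pair in (("drought", "salt"), ("cold", "heat"))
    ]
    table = summary_table(comps)
    assert list(table.columns) == [
        "stress_a", "stress_b", "gene_pairings", "plastic_pairs", "plastic_pct",
        "mean_false_positives", "fdr", "delta_r_cutoff",
    ]
    assert (table.plastic_pairs <= table.gene_pairings).all()
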