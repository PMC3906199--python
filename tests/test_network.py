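"""Adjacency/TOM arithmetic, module detection and merging, profiles, export."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import stressnet as sn


def _frame(X):
    return pd.DataFrame(
        X, index=[f"g{i}" for i in range(X.shape[0])],
        columns=[f"a{i}" for i in range(X.shape[1])],
    )


class TestAdjacency:
    def test_perfect_correlation_is_one_for_any_power(self):
        x = np.linspace(0, 1, 8)
        m = _frame(np.vstack([x, 2 * x + 3]))
        for b in (1, 6, 23):
            a = sn.adjacency(m, sn.NetworkParams(soft_power=b))
            assert a.iloc[0, 1] == pytest.approx(1.0)

    def test_soft_power_arithmetic(self):
        # correlation 0.9 at B=23 gives 0.9^23
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 2000)
        y = 0.9 * x + np.sqrt(1 - 0.81) * rng.normal(0, 1, 2000)
        m = _frame(np.vstack([x, y]))
        r = np.corrcoef(x, y)[0, 1]
        a = sn.adjacency(m, sn.NetworkParams(soft_power=23))
        assert a.iloc[0, 1] == pytest.approx(abs(r) ** 23, rel=1e-12)
        assert 0.05 < a.iloc[0, 1] < 0.15  # ~0.0886 at r = 0.9

    def test_zero_variance_gene_named(self):
        m = _frame(np.random.default_rng(1).normal(0, 1, (3, 6)))
        m.iloc[2] = 4.0
        with pytest.raises(ValueError, match="g2"):
            sn.adjacency(m)


class TestTOM:
    def test_matches_brute_force_triple_loop(self):
        rng = np.random.default_rng(3)
        m = _frame(rng.normal(0, 1, (10, 15)))
        adj = sn.adjacency(m, sn.NetworkParams(soft_power=6))
        a = adj.to_numpy()
        n = a.shape[0]
        oracle = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                num = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j)) + a[i, j]
                ki = sum(a[i, u] for u in range(n) if u != i)
                kj = sum(a[j, u] for u in range(n) if u != j)
                oracle[i, j] = 1.0 - num / (min(ki, kj) + 1.0 - a[i, j])
        dis = sn.tom_dissimilarity(adj).to_numpy()
        assert np.abs(dis - oracle).max() < 1e-12
        assert dis.min() >= 0 and dis.max() <= 1

    def test_isolated_pair_reduces_to_one_minus_adjacency(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, 10)
        y = 0.8 * x + 0.6 * rng.normal(0, 1, 10)
        m = _frame(np.vstack([x, y]))
        adj = sn.adjacency(m, sn.NetworkParams(soft_power=2))
        dis = sn.tom_dissimilarity(adj)
        assert dis.iloc[0, 1] == pytest.approx(1 - adj.iloc[0, 1], abs=1e-12)


def _block_dissim(sizes, within=0.1, between=0.99):
    n = sum(sizes)
    d = np.full((n, n), between)
    pos = 0
    for s in sizes:
        d[pos : pos + s, pos : pos + s] = within
        pos += s
    np.fill_diagonal(d, 0.0)
    genes = [f"g{i}" for i in range(n)]
    return pd.DataFrame(d, index=genes, columns=genes)


class TestDetectModules:
    def test_two_planted_blocks_found_exactly(self):
        asg = sn.detect_modules(_block_dissim([30, 30]))
        assert dict(asg.module_sizes) == {1: 30, 2: 30}

    def test_everything_above_cut_unassigned(self):
        asg = sn.detect_modules(_block_dissim([30, 30], within=0.95, between=0.99))
        assert (asg.labels == 0).all()

    def test_small_cohesive_block_below_min_size_unassigned(self):
        asg = sn.detect_modules(_block_dissim([10], within=0.05))
        assert (asg.labels == 0).all()

    def test_labels_ordered_by_decreasing_size(self):
        asg = sn.detect_modules(_block_dissim([30, 50, 40]))
        sizes = asg.module_sizes
        assert list(sizes.loc[[1, 2, 3]]) == [50, 40, 30]


class TestMergeModules:
    def _split_module_fixture(self, anticorrelated=False):
        """Two detected modules driven by one latent profile (or its negative)."""
        rng = np.random.default_rng(5)
        z = rng.normal(0, 1, 40)
        X1 = z + rng.normal(0, 0.1, (30, 40))
        X2 = (-z if anticorrelated else z) + rng.normal(0, 0.1, (30, 40))
        m = _frame(np.vstack([X1, X2]))
        labels = pd.Series([1] * 30 + [2] * 30, index=m.index, name="module")
        return sn.ModuleAssignment(labels), m

    def test_same_latent_profile_merged(self):
        asg, m = self._split_module_fixture()
        merged = sn.merge_modules(asg, m)
        assert merged.module_sizes.to_dict() == {1: 60}

    def test_anticorrelated_eigengenes_not_merged(self):
        asg, m = self._split_module_fixture(anticorrelated=True)
        merged = sn.merge_modules(asg, m)
        assert len(merged.module_sizes) == 2

    def test_single_module_unchanged_and_idempotent(self):
        rng = np.random.default_rng(6)
        m = _frame(rng.normal(0, 1, (30, 20)))
        labels = pd.Series([1] * 30, index=m.index, name="module")
        once = sn.merge_modules(sn.ModuleAssignment(labels), m)
        twice = sn.merge_modules(once, m)
        assert once.labels.equals(labels)
        assert twice.labels.equals(once.labels)

    def test_merging_is_idempotent_on_fixture(self, tight_fixture):
        _, matrix, design, truth = tight_fixture
        asg = sn.detect_modules(sn.tom_dissimilarity(sn.adjacency(matrix)))
        once = sn.merge_modules(asg, matrix)
        twice = sn.merge_modules(once, matrix)
        assert once.labels.equals(twice.labels)


def test_module_recovery_on_planted_fixture(tight_fixture):
    """Planted modules recovered at ARI >= 0.8 under default parameters."""
    _, matrix, design, truth = tight_fixture
    asg = sn.merge_modules(
        sn.detect_modules(sn.tom_dissimilarity(sn.adjacency(matrix))), matrix
    )
    ari = adjusted_rand_score(truth.module_labels.values, asg.labels.values)
    assert ari >= 0.8


class TestModuleProfiles:
    def _design(self):
        rows = []
        for cond in ("cold", "control"):
            for t in (1, 24):
                for rep in "AB":
                    rows.append(
                        dict(sample_id=f"{cond}_{t}h_{rep}", condition=cond,
                             timepoint_h=t, replicate=rep, is_control=cond == "control")
                    )
        return pd.DataFrame(rows)

    def test_exact_unit_shift_flags_responsive_with_zero_se(self):
        design = self._design()
        m = pd.DataFrame(
            8.0, index=[f"g{i}" for i in range(4)], columns=design.sample_id
        )
        cold24 = design.sample_id[(design.condition == "cold") & (design.timepoint_h == 24)]
        m[cold24] = 9.0  # every gene exactly +1 at 24 h
        labels = pd.Series([1] * 4, index=m.index, name="module")
        prof = sn.module_profiles(sn.ModuleAssignment(labels), m, design)
        row = prof[(prof.stress == "cold") & (prof.timepoint_h == 24)].iloc[0]
        assert row.mean_delta_rma == pytest.approx(1.0)
        assert row.se == pytest.approx(0.0)
        assert row.responsive

    def test_flat_module_not_responsive(self):
        design = self._design()
        m = pd.DataFrame(8.0, index=["g0", "g1"], columns=design.sample_id)
        labels = pd.Series([1, 1], index=m.index, name="module")
        prof = sn.module_profiles(sn.ModuleAssignment(labels), m, design)
        assert not prof.responsive.any()

    def test_fixture_module_responds_to_its_planted_stresses(self, tight_fixture):
        _, matrix, design, truth = tight_fixture
        prof = sn.module_profiles(
            sn.ModuleAssignment(truth.module_labels), matrix, design
        )
        # every planted stress with full effect (>= 1 RMA after the ramp)
        # must be flagged, and stresses with no planted effect must not be
        for m in truth.module_profiles.index:
            true_prof = truth.module_profiles.loc[m]
            for stress in ("cold", "drought", "heat", "salt"):
                flagged = prof[(prof.module == m) & (prof.stress == stress)].responsive.iloc[0]
                true_max = true_prof[stress].abs().max()
                if true_max >= 1.3:
                    assert flagged, (m, stress)
                elif true_max == 0.0:
                    assert not flagged, (m, stress)


class TestExportEdgeList:
    def _adj(self, values):
        genes = [f"g{i}" for i in range(4)]
        a = np.eye(4)
        (a[0, 1], a[0, 2], a[0, 3]) = values
        (a[1, 0], a[2, 0], a[3, 0]) = values
        return pd.DataFrame(a, index=genes, columns=genes)

    def test_all_below_threshold_gives_empty_list(self):
        edges = sn.export_edge_list(self._adj((0.1, 0.2, 0.3)))
        assert edges.empty

    def test_threshold_and_display_filtering(self):
        edges = sn.export_edge_list(self._adj((0.5, 0.4, 0.2)))
        assert len(edges) == 2
        assert edges.display.sum() == 1

    def test_zero_threshold_exports_all_pairs(self):
        rng = np.random.default_rng(7)
        m = _frame(rng.normal(0, 1, (6, 10)))
        adj = sn.adjacency(m, sn.NetworkParams(soft_power=1))
        params = sn.NetworkParams(export_threshold=0.0, display_filter=0.45)
        edges = sn.export_edge_list(adj, params=params)
        assert len(edges) == 6 * 5 // 2
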