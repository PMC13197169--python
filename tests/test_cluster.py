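"""Cluster permutation machinery: t statistics, cluster formation,
max-mass nulls, contrasts."""

import numpy as np
import pytest
from scipy import stats

from planact import cluster
from planact.cluster import (
    DiffWaveSet,
    cluster_test,
    factorial_contrasts,
    form_clusters,
    linear_trend,
    paired_cluster_test,
    perm_null_one_sample,
    planned_final_vs_nonfinal,
    pointwise_t_one_sample,
)


class TestPointwiseT:
    def test_matches_loop_oracle(self, rng):
        x = rng.standard_normal((10, 50))
        t, df = pointwise_t_one_sample(x)
        assert df == 9
        for j in range(50):
            col = x[:, j]
            expected = col.mean() / (col.std(ddof=1) / np.sqrt(10))
            assert t[j] == pytest.approx(expected, abs=1e-12)

    def test_symmetric_values_give_zero_t(self):
        x = np.vstack([np.ones((3, 20)), -np.ones((3, 20))])
        t, _ = pointwise_t_one_sample(x)
        assert np.allclose(t, 0)

    def test_zero_variance_flagged_as_signed_infinity(self):
        x = np.full((5, 4), 2.0)
        x[:, 1] = -3.0
        x[:, 2] = 0.0
        t, _ = pointwise_t_one_sample(x)
        assert t[0] == np.inf and t[1] == -np.inf and t[2] == 0

    def test_needs_two_participants(self):
        with pytest.raises(ValueError):
            pointwise_t_one_sample(np.ones((1, 5)))


class TestClusterFormation:
    def test_two_clusters_with_expected_masses(self):
        t = np.array([0, 0, 3, 3, 3, 0, -3], dtype=float)
        clusters = form_clusters(t, df=22, cluster_alpha=0.05)  # crit ~2.07
        assert len(clusters) == 2
        pos, neg = clusters
        assert (pos.start_idx, pos.end_idx, pos.mass, pos.sign) == (2, 4, 9.0, 1)
        assert (neg.start_idx, neg.end_idx, neg.mass, neg.sign) == (6, 6, -3.0, -1)

    def test_all_zero_series_gives_no_clusters(self):
        assert form_clusters(np.zeros(50), df=10) == []

    def test_agreement_with_runlength_oracle(self, rng):
        crit = stats.t.ppf(0.975, 15)
        for _ in range(1000):
            t = rng.standard_normal(30) * 2
            clusters = form_clusters(t, df=15)
            # oracle: scan runs by hand
            expected = []
            for sign in (1, -1):
                run = []
                for i, v in enumerate(t):
                    if sign * v > crit:
                        run.append(i)
                    elif run:
                        expected.append((run[0], run[-1], sum(t[run]), sign))
                        run = []
                if run:
                    expected.append((run[0], run[-1], sum(t[run]), sign))
            got = [(c.start_idx, c.end_idx, c.mass, c.sign) for c in clusters]
            assert sorted(got) == sorted(
                [(a, b, pytest.approx(m, abs=1e-9), s) for a, b, m, s in expected]
            )

    def test_one_tailed_ignores_other_sign(self):
        t = np.array([3.0, -3.0])
        up = form_clusters(t, df=22, tail="greater")
        assert [c.sign for c in up] == [1]
        down = form_clusters(t, df=22, tail="less")
        assert [c.sign for c in down] == [-1]

    def test_nan_breaks_contiguity(self):
        t = np.array([3, 3, np.nan, 3, 3], dtype=float)
        clusters = form_clusters(t, df=22)
        assert [(c.start_idx, c.end_idx) for c in clusters] == [(0, 1), (3, 4)]


class TestMneOracle:
    def test_observed_clusters_match_mne(self, rng):
        mne_stats = pytest.importorskip("mne.stats")
        x = rng.standard_normal((12, 80)) + 0.35
        t_obs, df = pointwise_t_one_sample(x)
        crit = stats.t.ppf(0.975, df)
        ours = form_clusters(t_obs, df)
        t_mne, clusters_mne, _, _ = mne_stats.permutation_cluster_1samp_test(
            x, threshold=crit, tail=0, n_permutations=50, seed=0, out_type="mask",
            verbose=False,
        )
        assert np.allclose(t_obs, t_mne, atol=1e-10)
        masses_mne = sorted(float(t_mne[m].sum()) for m in clusters_mne)
        masses_ours = sorted(c.mass for c in ours)
        assert np.allclose(masses_ours, masses_mne, atol=1e-10)


class TestPermutationNull:
    def test_deterministic_per_seed(self, rng):
        x = rng.standard_normal((8, 40))
        a = perm_null_one_sample(x, 200, seed=5)
        b = perm_null_one_sample(x, 200, seed=5)
        assert np.array_equal(a, b)
        c = perm_null_one_sample(x, 200, seed=6)
        assert not np.array_equal(a, c)

    def test_global_sign_flip_leaves_null_unchanged(self, rng):
        # the flip set is negation-closed, so the null multiset is
        # invariant under flipping all participants
        x = rng.standard_normal((8, 40)) + 0.5
        a = perm_null_one_sample(x, 200, seed=3)
        b = perm_null_one_sample(-x, 200, seed=3)
        assert np.allclose(sorted(a), sorted(b))

    def test_paired_equals_one_sample_on_difference(self, rng):
        a = rng.standard_normal((9, 30))
        b = rng.standard_normal((9, 30))
        null_paired = cluster.perm_null_paired(a, b, 300, seed=11)
        null_onesample = perm_null_one_sample(a - b, 300, seed=11)
        assert np.array_equal(null_paired, null_onesample)

    def test_unpaired_shapes_rejected(self, rng):
        with pytest.raises(ValueError):
            cluster.perm_null_paired(
                rng.standard_normal((5, 10)), rng.standard_normal((6, 10))
            )


class TestClusterTest:
    def test_p_floor_convention(self, rng):
        x = rng.standard_normal((23, 100)) - 50.0
        res = cluster_test(x, n_permutations=5000, seed=1)
        assert all(c.p == pytest.approx(1 / 5001) for c in res.clusters)
        assert f"{res.clusters[0].p:.4f}" == "0.0002"

    def test_identical_conditions_give_no_small_p(self, rng):
        a = rng.standard_normal((8, 30))
        res = paired_cluster_test(a, a.copy() + 0.0, n_permutations=100, seed=0)
        assert res.clusters == []

    def test_p_monotone_in_mass_within_result(self, rng):
        x = rng.standard_normal((15, 200)) * 3 + 0.8
        res = cluster_test(x, n_permutations=500, seed=2)
        ordered = sorted(res.clusters, key=lambda c: abs(c.mass))
        ps = [c.p for c in ordered]
        assert all(p1 >= p2 for p1, p2 in zip(ps, ps[1:]))

    def test_result_roundtrips_to_dict(self, rng):
        res = cluster_test(rng.standard_normal((6, 20)), 100, seed=0)
        d = res.to_dict()
        assert d["n_permutations"] == 100
        assert isinstance(d["clusters"], list)

    def test_degenerate_constant_effect_hits_floor(self):
        # zero variance everywhere: infinite t, one full-window cluster
        x = np.full((10, 50), 0.5)
        res = cluster_test(x, n_permutations=500, tail="greater",
                           test_alpha=0.025, seed=4)
        assert len(res.clusters) == 1
        c = res.clusters[0]
        assert (c.start_idx, c.end_idx) == (0, 49)
        assert c.p <= 0.025 and c.significant


class TestContrasts:
    def _dw(self, values, cells):
        return DiffWaveSet(
            values=values, cells=cells, times_s=np.arange(values.shape[2]) / 200.0
        )

    def test_identical_cells_give_zero_contrasts(self, rng):
        base = rng.standard_normal((6, 1, 30))
        dw = self._dw(
            np.tile(base, (1, 4, 1)), cluster.position_length_cells()
        )
        out = factorial_contrasts(dw, n_permutations=100, seed=0)
        for res in out.values():
            assert np.allclose(res.t_obs[np.isfinite(res.t_obs)], 0)

    def test_first_move_only_effect_isolates_position_contrast(self):
        delta = 2.0
        n, t = 6, 20
        vals = np.zeros((n, 4, t))
        cells = cluster.position_length_cells()
        for j, (pc, _ln) in enumerate(cells):
            if pc == "first":
                vals[:, j, :] = delta
        f2, o2, f4, o4 = (vals[:, cells.index(c), :] for c in cells)
        position = (f2 + f4) / 2 - (o2 + o4) / 2
        assert np.allclose(position, delta)
        interaction = (f4 - o4) - (f2 - o2)
        assert np.allclose(interaction, 0)

    def test_factorial_matches_brute_force_cellwise(self, rng):
        vals = rng.standard_normal((7, 4, 15))
        dw = self._dw(vals, cluster.position_length_cells())
        out = factorial_contrasts(dw, n_permutations=50, seed=1)
        cells = cluster.position_length_cells()
        f2 = vals[:, cells.index(("first", 2))]
        o2 = vals[:, cells.index(("other", 2))]
        f4 = vals[:, cells.index(("first", 4))]
        o4 = vals[:, cells.index(("other", 4))]
        expected = (f4 - o4) - (f2 - o2)
        t_expected, _ = pointwise_t_one_sample(expected)
        assert np.allclose(out["interaction"].t_obs, t_expected, atol=1e-12)

    def test_missing_cell_excludes_participant(self, rng):
        vals = rng.standard_normal((5, 4, 10))
        vals[2, 1, :] = np.nan
        dw = self._dw(vals, cluster.position_length_cells())
        out = factorial_contrasts(dw, n_permutations=50, seed=0)
        assert out["position"].t_obs.shape == (10,)
        assert np.all(np.isfinite(out["position"].t_obs))
        assert out["position"].df == 3  # one participant dropped

    def test_trend_weights_arithmetic(self):
        # positions [3d, 2d, d, 0] -> contrast 5d per sample
        d = 1.7
        pos = np.stack(
            [np.full((4, 12), v) for v in (3 * d, 2 * d, d, 0.0)], axis=1
        )
        contrast, _ = linear_trend(pos, n_permutations=50, seed=0)
        assert np.allclose(contrast, 5 * d)

    def test_trend_zero_for_equal_positions(self, rng):
        base = rng.standard_normal((5, 1, 12))
        contrast, _ = linear_trend(
            np.tile(base, (1, 4, 1)), n_permutations=50, seed=0
        )
        assert np.allclose(contrast, 0)

    def test_trend_rejects_bad_weights(self, rng):
        pos = rng.standard_normal((4, 4, 10))
        with pytest.raises(ValueError):
            linear_trend(pos, weights=(1, 0, 0, 0), n_permutations=10)
        with pytest.raises(ValueError):
            linear_trend(pos[:, :3], n_permutations=10)

    def test_planned_contrast_matches_set_average_oracle(self, rng):
        cells = list(cluster.NONFINAL_CELLS + cluster.FINAL_CELLS)
        vals = rng.standard_normal((6, len(cells), 18))
        dw = self._dw(vals, cells)
        contrast, _ = planned_final_vs_nonfinal(dw, n_permutations=50, seed=0)
        nonfinal = np.mean(
            [vals[:, cells.index(c)] for c in cluster.NONFINAL_CELLS], axis=0
        )
        final = np.mean(
            [vals[:, cells.index(c)] for c in cluster.FINAL_CELLS], axis=0
        )
        assert np.allclose(contrast, nonfinal - final, atol=1e-12)

    def test_planned_contrast_isolates_nonfinal_effect(self):
        cells = list(cluster.NONFINAL_CELLS + cluster.FINAL_CELLS)
        vals = np.zeros((5, len(cells), 10))
        for c in cluster.NONFINAL_CELLS:
            vals[:, cells.index(c)] = 1.3
        dw = self._dw(vals, cells)
        contrast, _ = planned_final_vs_nonfinal(dw, n_permutations=50, seed=0)
        assert np.allclose(contrast, 1.3)


class TestNanDiscipline:
    def test_clusters_never_touch_masked_samples(self, rng):
        x = rng.standard_normal((10, 100)) + 1.0
        x[:, :10] = np.nan
        x[:, -10:] = np.nan
        res = cluster_test(x, n_permutations=200, seed=0)
        for c in res.clusters:
            assert c.start_idx >= 10
            assert c.end_idx <= 89
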