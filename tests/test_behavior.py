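"""Behavioral RT structuring and RT-robustness procedures."""

import numpy as np
import pandas as pd
import pytest

from planact import behavior
from planact.behavior import (
    amplitude_window_mean,
    build_rt_table,
    paired_t,
    rt_amplitude_correlation,
    rt_match_analysis,
    rt_match_subsample,
)
from planact.simulate import RP_ROI


class TestAmplitudeWindowMean:
    def test_constant_epoch_gives_constant(self, small_epochs):
        es = small_epochs.select(np.arange(3))
        es.data[:] = 4.5
        assert np.allclose(amplitude_window_mean(es), 4.5)

    def test_linear_ramp_gives_midpoint(self, small_epochs):
        es = small_epochs.select(np.arange(1))
        tsel = (es.times_s >= -1.0) & (es.times_s <= 0.0)
        ramp = np.zeros_like(es.times_s)
        ramp[tsel] = np.linspace(0, -2, tsel.sum())
        es.data[:] = ramp[None, None, :]
        assert amplitude_window_mean(es)[0] == pytest.approx(-1.0)

    def test_matches_loop_oracle(self, small_epochs, rng):
        es = small_epochs.select(np.arange(5))
        es.data[:] = rng.standard_normal(es.data.shape)
        amps = amplitude_window_mean(es)
        idx = es.montage.index(RP_ROI)
        tsel = (es.times_s >= -1.0) & (es.times_s <= 0.0)
        for k in range(5):
            acc = 0.0
            for t in np.flatnonzero(tsel):
                acc += np.mean([es.data[k, i, t] for i in idx])
            assert amps[k] == pytest.approx(acc / tsel.sum(), abs=1e-12)

    def test_empty_window_raises(self, small_epochs):
        with pytest.raises(ValueError):
            amplitude_window_mean(small_epochs, window_s=(5.0, 6.0))


class TestPairedT:
    def test_matches_scipy(self, rng):
        from scipy import stats

        a = rng.standard_normal(15)
        b = rng.standard_normal(15) + 0.4
        t, p, df = paired_t(a, b)
        ref = stats.ttest_rel(a, b)
        assert t == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, abs=1e-12)
        assert df == 14


class TestMatching:
    def _table(self, rng, n_participants=5, n=120, self_shift=0.0, amp_effect=0.0):
        rows = []
        for pid in range(n_participants):
            for cond, shift in (("self", self_shift), ("stim", 0.0)):
                rts = np.exp(rng.standard_normal(n) * 0.3 + shift)
                amp = (amp_effect if cond == "self" else 0.0) + rng.standard_normal(n)
                rows.append(
                    pd.DataFrame(
                        {
                            "participant_id": pid,
                            "condition": cond,
                            "rt_s": rts,
                            "amplitude_uv": amp,
                        }
                    )
                )
        return pd.concat(rows, ignore_index=True)

    def test_identical_distributions_recover_full_sample_mean(self, rng):
        table = self._table(rng, n_participants=1, n=4000)
        grp = table[table["condition"] == "self"]
        stim = table[table["condition"] == "stim"]
        amps, rts, targets = rt_match_subsample(
            grp["rt_s"].to_numpy(),
            stim["rt_s"].to_numpy(),
            grp["amplitude_uv"].to_numpy(),
            n_iterations=300,
            rng=0,
        )
        assert amps.mean() == pytest.approx(grp["amplitude_uv"].mean(), abs=0.05)
        assert rts.mean() == pytest.approx(grp["rt_s"].mean(), rel=0.02)

    def test_subsample_bin_counts_match_targets_exactly(self, rng):
        self_rt = np.exp(rng.standard_normal(200) * 0.4)
        stim_rt = np.exp(rng.standard_normal(150) * 0.3)
        _, _, targets = rt_match_subsample(
            self_rt, stim_rt, np.zeros(200), n_iterations=10, rng=1
        )
        stim_edges = np.quantile(stim_rt, np.linspace(0, 1, 6))
        stim_counts, _ = np.histogram(stim_rt, stim_edges)
        scale = targets.sum() / stim_counts.sum()
        assert np.all(targets <= stim_counts)
        # proportional (floor) rescaling of the stimulus bin profile
        assert np.all(targets >= np.floor(stim_counts * scale) - 1)

    def test_deterministic_per_seed(self, rng):
        self_rt = np.exp(rng.standard_normal(100) * 0.4)
        stim_rt = np.exp(rng.standard_normal(90) * 0.3)
        amp = rng.standard_normal(100)
        a = rt_match_subsample(self_rt, stim_rt, amp, n_iterations=50, rng=7)
        b = rt_match_subsample(self_rt, stim_rt, amp, n_iterations=50, rng=7)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_analysis_reduces_rt_gap_and_detects_amplitude_effect(self, rng):
        table = self._table(rng, self_shift=0.4, amp_effect=-1.0)
        res = rt_match_analysis(table, n_iterations=200, seed=0)
        # unmatched standardized gap is the injected 0.4 log-shift over
        # the pooled log SD (~1.1); matching must shrink it severalfold
        unmatched = np.mean(
            [
                (np.log(g[g["condition"] == "self"]["rt_s"]).mean()
                 - np.log(g[g["condition"] == "stim"]["rt_s"]).mean())
                / np.log(g["rt_s"]).std(ddof=0)
                for _, g in table.groupby("participant_id")
            ]
        )
        assert res.standardized_rt_difference < unmatched / 4
        assert res.t_stat < 0 and res.p_value < 0.05

    def test_empty_condition_rejected(self):
        with pytest.raises(ValueError):
            rt_match_subsample(np.array([]), np.ones(10), np.array([]))


class TestCorrelations:
    def test_exact_linear_dependence_gives_r_one(self):
        pids = np.repeat(np.arange(6), 10)
        rt = np.tile(np.linspace(1, 2, 10), 6) + pids * 0.1
        table = pd.DataFrame(
            {
                "participant_id": pids,
                "condition": "self",
                "rt_s": rt,
                "amplitude_uv": 3.0 * rt,
            }
        )
        out = rt_amplitude_correlation(table)
        assert out["r"].iloc[0] == pytest.approx(1.0)

    def test_r_invariant_to_affine_rescaling(self, rng):
        pids = np.repeat(np.arange(8), 20)
        table = pd.DataFrame(
            {
                "participant_id": pids,
                "condition": "stim",
                "rt_s": np.exp(rng.standard_normal(160) * 0.2),
                "amplitude_uv": rng.standard_normal(160),
            }
        )
        r1 = rt_amplitude_correlation(table)["r"].iloc[0]
        table2 = table.assign(
            rt_s=table["rt_s"] * 4 + 1, amplitude_uv=table["amplitude_uv"] * -2 + 5
        )
        r2 = rt_amplitude_correlation(table2)["r"].iloc[0]
        assert abs(r1) == pytest.approx(abs(r2), abs=1e-12)

    def test_independent_amplitude_rejection_rate_near_alpha(self):
        hits = 0
        n_sims = 200
        rng = np.random.default_rng(5)
        for _ in range(n_sims):
            pids = np.repeat(np.arange(10), 5)
            table = pd.DataFrame(
                {
                    "participant_id": pids,
                    "condition": "self",
                    "rt_s": np.exp(rng.standard_normal(50) * 0.2),
                    "amplitude_uv": rng.standard_normal(50),
                }
            )
            hits += rt_amplitude_correlation(table)["p"].iloc[0] < 0.05
        assert 0.01 < hits / n_sims < 0.1

    def test_too_few_participants_rejected(self):
        table = pd.DataFrame(
            {
                "participant_id": [1, 2],
                "condition": "self",
                "rt_s": [1.0, 1.2],
                "amplitude_uv": [0.1, 0.2],
            }
        )
        with pytest.raises(ValueError):
            rt_amplitude_correlation(table)


class TestRtTable:
    def test_table_columns_and_standardization(self, small_dataset):
        sets, _ = small_dataset
        table = build_rt_table(sets)
        assert {"amplitude_uv", "log_rt", "rt_z"} <= set(table.columns)
        for _, grp in table.groupby("participant_id"):
            assert grp["rt_z"].mean() == pytest.approx(0.0, abs=1e-9)
            assert grp["rt_z"].std(ddof=0) == pytest.approx(1.0, abs=1e-9)
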