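"""Simulation studies: calibration and recovery of the full pipeline.

Each study regenerates its inputs from scratch with the synthetic
generator, runs the corresponding analysis, and returns summary numbers
(false-positive rates, detection rates, recovery correlations).  The
problem sizes are chosen so the whole battery runs on one CPU in
minutes; they are stated in each docstring.
"""

from __future__ import annotations

import time
from dataclasses import replace

import numpy as np

from . import behavior, cluster, decoding, tfr, tol
from .simulate import (
    BETA_ROI,
    RP_ROI,
    Montage,
    SimulationConfig,
    beta_envelope,
    default_rt_params,
    noise_component,
    simulate_dataset,
    simulate_rts,
    time_grid,
)

# study conditions shared by the calibration/recovery batteries
N_PARTICIPANTS = 23
N_TIMEPOINTS = 301
PINK_SD = 6.0
WHITE_SD = 3.0


def _null_noise(
    rng: np.random.Generator, n_participants: int = N_PARTICIPANTS,
    n_timepoints: int = N_TIMEPOINTS, n_series: int = 1
) -> np.ndarray:
    """1/f + white noise series: (n_series, participants, time)."""
    t = np.arange(n_timepoints) / 200.0
    out = noise_component(
        t, 1.0, WHITE_SD, PINK_SD, rng=rng, size=n_series * n_participants
    )
    return out.reshape(n_series, n_participants, n_timepoints)


# ---------------------------------------------------------------------------
# task / state space


def study_problem_bank(seed: int = 0) -> dict:
    """Generate the 12 x 6 bank and verify its structural guarantees."""
    t0 = time.time()
    bank = tol.generate_problem_bank(12, 6, {2: 6, 4: 6}, seed=seed)
    lengths = [p.optimal_length for p in bank]
    return {
        "n_problems": len(bank),
        "n_unique_optimal": sum(p.n_optimal_paths == 1 for p in bank),
        "n_length_2": lengths.count(2),
        "n_length_4": lengths.count(4),
        "n_families": len({p.family_id for p in bank}),
        "runtime_s": time.time() - t0,
    }


def study_state_space(seed: int = 0, n_pairs: int = 100) -> dict:
    """Enumeration count, move-graph connectivity, distance symmetry."""
    t0 = time.time()
    states = tol.enumerate_states()
    dist0 = tol.bfs_distances(states[0])
    rng = np.random.default_rng(seed)
    symmetric = 0
    for _ in range(n_pairs):
        a, b = rng.choice(len(states), 2, replace=False)
        d_ab, _ = tol.shortest_paths(states[a], states[b])
        d_ba, _ = tol.shortest_paths(states[b], states[a])
        symmetric += d_ab == d_ba
    branching = max(len(tol.legal_moves(s)) for s in states)
    return {
        "n_states": len(states),
        "n_reachable": len(dist0),
        "n_symmetric_pairs": symmetric,
        "n_pairs": n_pairs,
        "max_branching": branching,
        "diameter": max(
            max(tol.bfs_distances(s).values()) for s in states
        ),
        "runtime_s": time.time() - t0,
    }


# ---------------------------------------------------------------------------
# FWER calibration


def _any_significant(result: cluster.ClusterTestResult) -> bool:
    return len(result.significant_clusters) > 0


def study_fwer(
    n_reps: int = 500,
    n_permutations: int = 1000,
    seed: int = 0,
) -> dict:
    """Family-wise false-positive rate of every test family under pure
    1/f + white noise (no effect), 23 participants x 301 timepoints.

    Returns the fraction of repetitions with at least one significant
    cluster, per family.
    """
    rng = np.random.default_rng(seed)
    hits = {
        "one_sample": 0,
        "paired": 0,
        "factorial_position": 0,
        "factorial_length": 0,
        "factorial_interaction": 0,
        "linear_trend": 0,
        "planned_contrast": 0,
        "decoding_vs_chance": 0,
    }
    t_grid = np.arange(N_TIMEPOINTS) / 200.0 - 1.0
    for _ in range(n_reps):
        # one-sample
        x = _null_noise(rng)[0]
        res = cluster.cluster_test(x, n_permutations, seed=rng)
        hits["one_sample"] += _any_significant(res)
        # paired
        a, b = _null_noise(rng, n_series=2)
        res = cluster.paired_cluster_test(a, b, n_permutations, seed=rng)
        hits["paired"] += _any_significant(res)
        # factorial on four null difference-wave cells
        cells = cluster.position_length_cells()
        dw = cluster.DiffWaveSet(
            values=np.moveaxis(_null_noise(rng, n_series=4), 0, 1),
            cells=cells,
            times_s=t_grid,
        )
        fact = cluster.factorial_contrasts(
            dw, n_permutations=n_permutations, seed=int(rng.integers(2**31 - 1))
        )
        for name in ("position", "length", "interaction"):
            hits[f"factorial_{name}"] += _any_significant(fact[name])
        # linear trend across four null positions
        pos = np.moveaxis(_null_noise(rng, n_series=4), 0, 1)
        _, res = cluster.linear_trend(
            pos, n_permutations=n_permutations, seed=rng
        )
        hits["linear_trend"] += _any_significant(res)
        # planned final vs nonfinal on six null cells
        dw6 = cluster.DiffWaveSet(
            values=np.moveaxis(_null_noise(rng, n_series=6), 0, 1),
            cells=list(cluster.NONFINAL_CELLS + cluster.FINAL_CELLS),
            times_s=t_grid,
        )
        _, res = cluster.planned_final_vs_nonfinal(
            dw6, n_permutations=n_permutations, seed=rng
        )
        hits["planned_contrast"] += _any_significant(res)
        # decoding-vs-chance: the one-sided (alpha = 0.025) procedure
        # applied to both directions, so its family-wise level is 0.05
        acc = 0.5 + 0.01 * _null_noise(rng)[0] / PINK_SD
        s = int(rng.integers(2**31 - 1))
        res_hi = decoding.decode_against_chance(
            acc, n_permutations=n_permutations, seed=s
        )
        res_lo = cluster.cluster_test(
            acc - 0.5, n_permutations=n_permutations, test_alpha=0.025,
            tail="less", seed=s,
        )
        hits["decoding_vs_chance"] += _any_significant(res_hi) or _any_significant(
            res_lo
        )
    return {k: v / n_reps for k, v in hits.items()} | {"n_reps": n_reps}


# ---------------------------------------------------------------------------
# effect recovery (readiness potential)


def _recovery_config(rp_amps: dict, seed: int, trials: int = 20) -> SimulationConfig:
    return SimulationConfig(
        n_participants=N_PARTICIPANTS,
        trials_per_cell=trials,
        rp_amplitude_by_cell=rp_amps,
        beta_suppression_by_cell={},
        beta_base_amp_uv=0.0,
        seed=seed,
    )


_ROI_MONTAGE = Montage().subset(RP_ROI)


def study_factorial_recovery(
    n_sims: int = 100, n_permutations: int = 1000, seed: int = 0
) -> dict:
    """Detection rates of the 2 x 2 factorial with a self-only,
    first-move-only preparatory boost injected (23 participants,
    20 trials per cell, ROI channels).

    The position main effect should be detected in nearly every dataset;
    the length effect and interaction should stay at the false-positive
    level.
    """
    base = 1.5
    rp_amps = {}
    for length in (2, 4):
        rp_amps[("self", length, "first")] = 6.0
        rp_amps[("self", length, "other")] = base
        rp_amps[("stim", length, "first")] = base
        rp_amps[("stim", length, "other")] = base
    rng = np.random.default_rng(seed)
    hits = {"position": 0, "length": 0, "interaction": 0}
    for _ in range(n_sims):
        cfg = _recovery_config(rp_amps, int(rng.integers(2**31 - 1)))
        sets, _ = simulate_dataset(cfg, montage=_ROI_MONTAGE)
        dw = cluster.build_diff_waves(
            sets, RP_ROI, cluster.position_length_cells(),
            cluster.factorial_cell_of_trial,
        )
        fact = cluster.factorial_contrasts(
            dw, n_permutations=n_permutations, seed=int(rng.integers(2**31 - 1))
        )
        for name in hits:
            hits[name] += _any_significant(fact[name])
    return {k: v / n_sims for k, v in hits.items()} | {"n_sims": n_sims}


def study_trend_recovery(
    n_sims: int = 100, n_permutations: int = 1000, seed: int = 0
) -> dict:
    """Linear-trend detection across the four positions of four-move
    sequences: a monotone self-condition amplitude gradient vs a flat
    profile (23 participants, 20 trials per cell)."""
    gradient = {("self", 4, p): a for p, a in zip((1, 2, 3, 4), (5.0, 4.0, 3.0, 2.0))}
    flat = {("self", 4, p): 3.5 for p in (1, 2, 3, 4)}
    for amps in (gradient, flat):
        amps.update({("stim", 4, p): 1.5 for p in (1, 2, 3, 4)})
    rng = np.random.default_rng(seed)
    rates = {}
    for label, amps in (("gradient", gradient), ("flat", flat)):
        hits = 0
        for _ in range(n_sims):
            cfg = replace(
                _recovery_config(amps, int(rng.integers(2**31 - 1))),
                sequence_lengths=(4,),
            )
            sets, _ = simulate_dataset(cfg, montage=_ROI_MONTAGE)
            dw = cluster.build_diff_waves(
                sets, RP_ROI, [(4, p) for p in (1, 2, 3, 4)],
                lambda tr: (tr.sequence_length, tr.move_position),
            )
            pos = np.stack([dw.cell((4, p)) for p in (1, 2, 3, 4)], axis=1)
            _, res = cluster.linear_trend(
                pos, n_permutations=n_permutations, seed=rng
            )
            hits += _any_significant(res)
        rates[label] = hits / n_sims
    return rates | {"n_sims": n_sims}


# ---------------------------------------------------------------------------
# beta-band recovery


def study_beta_recovery(seed: int = 0, n_trials: int = 100) -> dict:
    """Band-power recovery of an injected 20 Hz envelope suppression.

    Simulates one condition cell on the long epoch window, extracts
    13-30 Hz ROI power, and correlates the trial-average series with the
    injected envelope squared over valid (unmasked) samples.
    """
    cfg = SimulationConfig(
        n_participants=1,
        trials_per_cell=n_trials,
        rp_amplitude_by_cell={},
        beta_suppression_by_cell={("self", 2, "first"): 0.6},
        epoch_window_s=(-2.0, 1.0),
        sequence_lengths=(2,),
        pink_sd_uv=3.0,
        white_sd_uv=1.5,
        seed=seed,
    )
    montage = Montage().subset(BETA_ROI)
    sets, _ = simulate_dataset(cfg, montage=montage)
    es = sets[0]
    mask = np.array(
        [t.condition == "self" and t.move_position == 1 for t in es.trials]
    )
    es = es.select(mask)
    power = tfr.tfr_hanning_convolution(es)
    band = tfr.band_roi_average(power)
    series = band.power.mean(axis=0)
    env = beta_envelope(es.times_s, cfg.beta_base_amp_uv, 0.6, cfg.beta_ramp_window_s)
    valid = power.valid_mask
    r = np.corrcoef(series[valid], env[valid] ** 2)[0, 1]
    n_masked_start = int((~valid[: len(valid) // 2]).sum())
    n_masked_end = int((~valid[len(valid) // 2 :]).sum())
    return {
        "envelope_correlation": float(r),
        "edge_mask_samples_start": n_masked_start,
        "edge_mask_samples_end": n_masked_end,
    }


# ---------------------------------------------------------------------------
# decoding calibration and recovery


def _decode_group(
    rng: np.random.Generator,
    n_participants: int,
    n_per_class: int,
    n_channels: int,
    times_s: np.ndarray,
    pattern_amp: float = 0.0,
    pattern_window: tuple = (-0.5, 0.0),
    n_repeats: int = 2,
) -> np.ndarray:
    """Per-participant decoding accuracy series on synthetic patterns.

    Class 1 trials receive a participant-specific spatial pattern of
    amplitude ``pattern_amp`` inside ``pattern_window``; both classes
    are otherwise identical 1/f + white noise, so amp = 0 is an exact
    null (equivalent to permuted labels).
    """
    n_t = len(times_s)
    acc = np.empty((n_participants, n_t))
    in_win = (times_s >= pattern_window[0]) & (times_s <= pattern_window[1])
    for p in range(n_participants):
        noise = noise_component(
            times_s, 1.0, WHITE_SD, PINK_SD, rng=rng,
            size=2 * n_per_class * n_channels,
        ).reshape(2 * n_per_class, n_channels, n_t)
        labels = np.repeat([0, 1], n_per_class)
        if pattern_amp:
            pattern = rng.standard_normal(n_channels)
            pattern /= np.linalg.norm(pattern)
            noise[n_per_class:] += (
                pattern_amp * pattern[None, :, None] * in_win[None, None, :]
            )
        cfg = decoding.DecodingConfig(
            n_repeats=n_repeats, seed=int(rng.integers(2**31 - 1))
        )
        res = decoding.crossval_decode(noise, labels, cfg, times_s=times_s)
        acc[p] = res.accuracy
    return acc


def study_decoding_null(
    n_nulls: int = 200,
    n_participants: int = 12,
    n_per_class: int = 25,
    n_channels: int = 13,
    n_permutations: int = 1000,
    seed: int = 0,
) -> dict:
    """Decoding false-positive calibration: label-exchangeable null data
    (identical class distributions) through the full cross-validated
    decoder and the one-sided group cluster test."""
    rng = np.random.default_rng(seed)
    times = time_grid((-0.5, 0.0), 200.0)
    mean_acc = np.empty(n_nulls)
    hits = 0
    for i in range(n_nulls):
        acc = _decode_group(rng, n_participants, n_per_class, n_channels, times)
        mean_acc[i] = acc.mean()
        res = decoding.decode_against_chance(
            acc, n_permutations=n_permutations, seed=int(rng.integers(2**31 - 1))
        )
        hits += _any_significant(res)
    return {
        "mean_accuracy": float(mean_acc.mean()),
        "se_accuracy": float(mean_acc.std(ddof=1) / np.sqrt(n_nulls)),
        "significant_rate": hits / n_nulls,
        "n_nulls": n_nulls,
    }


def study_decoding_recovery(
    n_sims: int = 100,
    n_participants: int = 12,
    n_per_class: int = 25,
    n_channels: int = 13,
    pattern_amp: float = 4.0,
    n_permutations: int = 1000,
    seed: int = 0,
) -> dict:
    """Recovery of a class-dependent spatial pattern confined to
    [-0.5, 0] s: rate of significant above-chance clusters overlapping
    the injected window."""
    rng = np.random.default_rng(seed)
    times = time_grid((-1.0, 0.0), 200.0)
    hits = 0
    for _ in range(n_sims):
        acc = _decode_group(
            rng, n_participants, n_per_class, n_channels, times,
            pattern_amp=pattern_amp,
        )
        res = decoding.decode_against_chance(
            acc, n_permutations=n_permutations,
            seed=int(rng.integers(2**31 - 1)), times_s=times,
        )
        overlap = any(
            c.significant and c.end_s >= -0.5 and c.start_s <= 0.0
            for c in res.clusters
        )
        hits += overlap
    return {"recovery_rate": hits / n_sims, "n_sims": n_sims}


# ---------------------------------------------------------------------------
# residualization


def study_residualization(seed: int = 0, n_participants: int = 6) -> dict:
    """Max |corr(RT, amplitude)| after RT residualization over all
    channels x timepoints, per synthetic participant."""
    cfg = SimulationConfig(
        n_participants=n_participants, trials_per_cell=15, seed=seed
    )
    sets, _ = simulate_dataset(cfg, montage=_ROI_MONTAGE)
    max_post = []
    for es in sets:
        _, report = decoding.residualize_rt(es)
        max_post.append(report.max_abs_post)
    return {
        "max_abs_post_corr": float(max(max_post)),
        "n_participants": n_participants,
    }


# ---------------------------------------------------------------------------
# RT matching


def study_rt_matching(
    n_sims: int = 100,
    n_participants: int = N_PARTICIPANTS,
    n_per_cell: int = 40,
    effect_uv: float = -1.0,
    n_bins: int = 5,
    n_iterations: int = 1000,
    seed: int = 0,
) -> dict:
    """Matched-subsampling robustness: residual standardized RT mismatch
    and the power of the matched paired amplitude comparison.

    Trial amplitudes carry an RT-linked component plus a genuine
    condition effect (``effect_uv`` on self trials); matching must
    equate RTs while preserving the condition effect.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    params = default_rt_params()
    cells = list(params)
    rt_slope = 1.0   # µV per log-RT z unit: the RT confound
    noise_sd = 2.0
    std_diffs = np.empty(n_sims)
    rejections = 0
    for s in range(n_sims):
        rows = []
        for pid in range(n_participants):
            for cell in cells:
                cond, length, pc = cell
                rts = simulate_rts(cell, params, n_per_cell, rng)
                rows.append(
                    pd.DataFrame(
                        {
                            "participant_id": pid,
                            "condition": cond,
                            "rt_s": rts,
                        }
                    )
                )
        table = pd.concat(rows, ignore_index=True)
        log_rt = np.log(table["rt_s"])
        rt_z = log_rt.groupby(table["participant_id"]).transform(
            lambda x: (x - x.mean()) / x.std(ddof=0)
        )
        table["amplitude_uv"] = (
            np.where(table["condition"] == "self", effect_uv, 0.0)
            + rt_slope * rt_z
            + noise_sd * rng.standard_normal(len(table))
        )
        match = behavior.rt_match_analysis(
            table, n_bins=n_bins, n_iterations=n_iterations,
            seed=int(rng.integers(2**31 - 1)),
        )
        std_diffs[s] = match.standardized_rt_difference
        rejections += match.p_value < 0.05 and np.sign(match.t_stat) == np.sign(
            effect_uv
        )
    return {
        "mean_standardized_rt_difference": float(std_diffs.mean()),
        "max_standardized_rt_difference": float(std_diffs.max()),
        "power": rejections / n_sims,
        "n_sims": n_sims,
    }


# ---------------------------------------------------------------------------
# Monte-Carlo p floor


def study_p_floor(seed: int = 0, n_permutations: int = 5000) -> dict:
    """With an overwhelming injected effect every cluster p must equal
    the convention floor 1/(n_permutations + 1)."""
    rng = np.random.default_rng(seed)
    noise = _null_noise(rng)[0]
    effect = 20 * (PINK_SD + WHITE_SD)
    res = cluster.cluster_test(
        noise - effect, n_permutations=n_permutations, seed=rng
    )
    ps = [c.p for c in res.clusters if c.significant]
    return {
        "n_significant": len(ps),
        "max_p": max(ps) if ps else float("nan"),
        "min_p": min(ps) if ps else float("nan"),
        "floor": 1 / (n_permutations + 1),
        "printed_floor": float(f"{1 / (n_permutations + 1):.4f}"),
        "all_at_floor": bool(ps) and max(ps) == 1 / (n_permutations + 1),
    }


# ---------------------------------------------------------------------------
# behavioral cell means


def study_rt_cell_means(seed: int = 0, n: int = 10000) -> dict:
    """Sample means of the default RT generator per design cell."""
    rng = np.random.default_rng(seed)
    out = {}
    for cell in default_rt_params():
        cond, length, pc = cell
        draws = simulate_rts(cell, n=n, rng=rng)
        out[f"rt_{cond}_{length}move_{pc}"] = float(draws.mean())
    return out
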