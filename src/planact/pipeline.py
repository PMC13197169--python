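"""Orchestration: configuration, serialization, and the end-to-end driver.

``run_pipeline`` executes the full replica on synthetic data:
simulation, artifact rejection, the ERP cluster analyses (factorial,
four-condition pairwise, six-position pairwise, linear trend, planned
final-vs-nonfinal), the beta-band analyses on the longer epoch window,
per-condition decoding with and without RT residualization, and the
behavioral RT robustness checks.  Every stage writes its artifacts to
the run directory; the report renders exclusively from those artifacts.
All randomness derives from the master seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior, cluster, decoding, tfr
from .preprocess import PreprocessConfig, reject_artifacts
from .simulate import (
    BETA_ROI,
    RP_ROI,
    EpochSet,
    Montage,
    SimulationConfig,
    TrialRecord,
    simulate_dataset,
)

logger = logging.getLogger(__name__)

BETA_ANALYSIS_WINDOW_S = (-0.998, 0.499)

SIX_POSITION_CELLS = [(2, 1), (2, 2), (4, 1), (4, 2), (4, 3), (4, 4)]


def _position_cell_of_trial(trial: TrialRecord):
    return (trial.sequence_length, trial.move_position)


@dataclass(frozen=True)
class RunConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    decoding: decoding.DecodingConfig = field(default_factory=decoding.DecodingConfig)
    n_perm_factorial: int = 5000
    n_perm_pairwise: int = 1000
    n_perm_trend: int = 5000
    n_perm_planned: int = 5000
    n_perm_decoding: int = 5000
    cluster_alpha: float = 0.05
    test_alpha: float = 0.05
    decoding_test_alpha: float = 0.025
    rt_match_bins: int = 5
    rt_match_iterations: int = 1000
    run_beta: bool = True
    run_decoding: bool = True
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("rp_amplitude_by_cell", "beta_suppression_by_cell",
                    "rt_lognormal_params"):
            d["simulation"][key] = {
                "|".join(map(str, k)): [float(x) for x in np.atleast_1d(v)]
                if isinstance(v, tuple) else float(v)
                for k, v in d["simulation"][key].items()
            }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sim = dict(d.pop("simulation"))
        for key in ("rp_amplitude_by_cell", "beta_suppression_by_cell",
                    "rt_lognormal_params"):
            raw = sim[key]
            parsed = {}
            for k, v in raw.items():
                cond, length, pos = k.split("|")
                cell = (cond, int(length), pos)
                parsed[cell] = tuple(v) if isinstance(v, list) else v
            sim[key] = parsed
        for tup in ("epoch_window_s", "beta_window_s", "iti_jitter_s",
                    "sequence_lengths"):
            sim[tup] = tuple(sim[tup])
        pre = dict(d.pop("preprocess"))
        for tup in ("rejection_channels", "mastoid_channels", "epoch_window_s"):
            pre[tup] = tuple(pre[tup])
        dec = dict(d.pop("decoding"))
        dec["channel_exclusions"] = tuple(dec["channel_exclusions"])
        dec["window_s"] = tuple(dec["window_s"])
        return cls(
            simulation=SimulationConfig(**sim),
            preprocess=PreprocessConfig(**pre),
            decoding=decoding.DecodingConfig(**dec),
            **d,
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# epoch container I/O


def write_epochs(epochs: EpochSet, prefix) -> None:
    """Array container: <prefix>.npy plus a JSON sidecar with montage,
    sampling metadata and the trial table."""
    prefix = Path(prefix)
    np.save(prefix.with_suffix(".npy"), epochs.data)
    sidecar = {
        "times_s": epochs.times_s.tolist(),
        "channels": list(epochs.montage.channels),
        "sampling_rate_hz": epochs.sampling_rate_hz,
        "trials": [vars(t) for t in epochs.trials],
    }
    with open(prefix.with_suffix(".json"), "w") as fh:
        json.dump(sidecar, fh)


def read_epochs(prefix) -> EpochSet:
    prefix = Path(prefix)
    sidecar_path = prefix.with_suffix(".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar_path}")
    with open(sidecar_path) as fh:
        sidecar = json.load(fh)
    data = np.load(prefix.with_suffix(".npy"))
    channels = tuple(sidecar["channels"])
    montage = Montage(channels=channels) if set(RP_ROI + BETA_ROI) <= set(
        channels
    ) else Montage(channels=channels, require_rois=False)
    return EpochSet(
        data=data,
        times_s=np.array(sidecar["times_s"]),
        montage=montage,
        trials=[TrialRecord(**t) for t in sidecar["trials"]],
        sampling_rate_hz=sidecar["sampling_rate_hz"],
    )


# ---------------------------------------------------------------------------
# analysis suites


def erp_analysis_suite(
    epoch_sets,
    roi,
    times_s,
    config: RunConfig,
    seed: int,
    transform=None,
    time_window=None,
) -> dict:
    """The shared analysis suite run on ROI series (ERP or band power).

    Returns named ClusterTestResults: factorial effects, per-cell
    pairwise self-vs-stim tests, six-position pairwise tests, the linear
    trend over four-move positions, and the planned final-vs-nonfinal
    contrast.
    """
    def _transform(es):
        series = es.roi_average(roi) if transform is None else transform(es)
        if time_window is not None:
            tsel = (times_s >= time_window[0]) & (times_s <= time_window[1])
            return series[:, tsel]
        return series

    ts = times_s
    if time_window is not None:
        tsel = (times_s >= time_window[0]) & (times_s <= time_window[1])
        ts = times_s[tsel]

    rng = np.random.default_rng(seed)

    def sub():
        return int(rng.integers(0, 2**31 - 1))

    results: dict = {}
    # factorial on (position class x length) difference waves
    dw_factorial = cluster.build_diff_waves(
        epoch_sets,
        roi,
        cluster.position_length_cells(),
        cluster.factorial_cell_of_trial,
        transform=_transform,
    )
    dw_factorial.times_s = ts
    for name, res in cluster.factorial_contrasts(
        dw_factorial,
        n_permutations=config.n_perm_factorial,
        cluster_alpha=config.cluster_alpha,
        test_alpha=config.test_alpha,
        seed=sub(),
    ).items():
        results[f"factorial_{name}"] = res

    # pairwise self vs stim per factorial cell (paired label-swap tests)
    per_participant = [( _transform(es), es.trials) for es in epoch_sets]
    for cell in cluster.position_length_cells():
        pos_class, length = cell
        a_rows, b_rows = [], []
        for series, trials in per_participant:
            sel = {
                cond: [
                    i
                    for i, tr in enumerate(trials)
                    if tr.condition == cond
                    and cluster.factorial_cell_of_trial(tr) == cell
                ]
                for cond in ("self", "stim")
            }
            if sel["self"] and sel["stim"]:
                a_rows.append(series[sel["self"]].mean(axis=0))
                b_rows.append(series[sel["stim"]].mean(axis=0))
        results[f"pairwise_{pos_class}_{length}move"] = cluster.paired_cluster_test(
            np.array(a_rows),
            np.array(b_rows),
            n_permutations=config.n_perm_pairwise,
            cluster_alpha=config.cluster_alpha,
            test_alpha=config.test_alpha,
            seed=sub(),
            times_s=ts,
        )

    # six-position difference waves
    dw_positions = cluster.build_diff_waves(
        epoch_sets,
        roi,
        SIX_POSITION_CELLS,
        _position_cell_of_trial,
        transform=_transform,
    )
    dw_positions.times_s = ts
    for cell in SIX_POSITION_CELLS:
        length, pos = cell
        vals = dw_positions.cell(cell)
        vals = vals[~np.isnan(vals).all(axis=1)]
        results[f"position_{length}move_m{pos}"] = cluster.cluster_test(
            vals,
            n_permutations=config.n_perm_pairwise,
            cluster_alpha=config.cluster_alpha,
            test_alpha=config.test_alpha,
            seed=sub(),
            times_s=ts,
        )

    # linear trend across the four positions of four-move sequences
    four_cells = [(4, p) for p in (1, 2, 3, 4)]
    pos_series = np.stack(
        [dw_positions.cell(c) for c in four_cells], axis=1
    )  # participants x 4 x time
    _, results["linear_trend"] = cluster.linear_trend(
        pos_series,
        n_permutations=config.n_perm_trend,
        cluster_alpha=config.cluster_alpha,
        test_alpha=config.test_alpha,
        seed=sub(),
        times_s=ts,
    )

    # planned final vs nonfinal
    _, results["planned_final_vs_nonfinal"] = cluster.planned_final_vs_nonfinal(
        dw_positions,
        n_permutations=config.n_perm_planned,
        cluster_alpha=config.cluster_alpha,
        test_alpha=config.test_alpha,
        seed=sub(),
    )
    results["planned_final_vs_nonfinal"].times_s = ts
    return results


def decoding_suite(
    epoch_sets, config: RunConfig, seed: int, residualize: bool = False
) -> dict:
    """Per-cell decoding across participants plus group cluster tests."""
    rng = np.random.default_rng(seed)
    cells = cluster.position_length_cells()
    acc_by_cell: dict = {c: [] for c in cells}
    times = None
    for es in epoch_sets:
        if residualize:
            es, report = decoding.residualize_rt(es)
            if report.max_abs_post > 1e-8:
                raise RuntimeError("residualization failed to null RT correlation")
        for cell in cells:
            mask = np.array(
                [cluster.factorial_cell_of_trial(tr) == cell for tr in es.trials]
            )
            sub_epochs = es.select(mask)
            cfg = dataclasses.replace(
                config.decoding, seed=int(rng.integers(0, 2**31 - 1))
            )
            res = decoding.crossval_decode(sub_epochs, config=cfg, cell=cell)
            acc_by_cell[cell].append(res.accuracy)
            times = res.times_s

    out: dict = {"accuracy": {}, "tests": {}}
    for cell in cells:
        acc = np.array(acc_by_cell[cell])
        name = f"{cell[0]}_{cell[1]}move"
        out["accuracy"][name] = acc
        out["tests"][f"vs_chance_{name}"] = decoding.decode_against_chance(
            acc,
            chance=config.decoding.chance_level,
            n_permutations=config.n_perm_decoding,
            cluster_alpha=config.cluster_alpha,
            test_alpha=config.decoding_test_alpha,
            seed=int(rng.integers(0, 2**31 - 1)),
            times_s=times,
        )
    # factorial on the accuracy time series
    dw = cluster.DiffWaveSet(
        values=np.stack([np.array(acc_by_cell[c]) for c in cells], axis=1),
        cells=cells,
        times_s=times,
    )
    for name, res in cluster.factorial_contrasts(
        dw,
        n_permutations=config.n_perm_factorial,
        cluster_alpha=config.cluster_alpha,
        test_alpha=config.test_alpha,
        seed=int(rng.integers(0, 2**31 - 1)),
    ).items():
        out["tests"][f"factorial_{name}"] = res
    out["times_s"] = times
    return out


# ---------------------------------------------------------------------------
# driver


def _save_results(results: dict, path: Path) -> None:
    serializable = {
        name: (res[1] if isinstance(res, tuple) else res).to_dict()
        for name, res in results.items()
    }
    with open(path, "w") as fh:
        json.dump(serializable, fh, indent=1)


def run_pipeline(config: RunConfig, out_dir) -> Path:
    """Execute the full replica; returns the run directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.save(out / "config.yaml")
    master = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in master.spawn(8)]

    stage = "simulate"
    try:
        sim_cfg = dataclasses.replace(config.simulation, seed=seeds[0])
        epoch_sets, behavior_table = simulate_dataset(sim_cfg)
        behavior_table.to_csv(out / "behavior.csv", index=False)

        stage = "reject"
        kept_sets, reject_log = [], []
        for es in epoch_sets:
            kept, rejected = reject_artifacts(
                es,
                config.preprocess.rejection_threshold_uv,
                config.preprocess.rejection_channels,
            )
            kept_sets.append(kept)
            reject_log.append(
                {
                    "participant_id": es.trials[0].participant_id,
                    "n_in": len(es.trials),
                    "n_rejected": int(rejected.sum()),
                }
            )
        pd.DataFrame(reject_log).to_csv(out / "rejection_log.csv", index=False)

        stage = "erp"
        times = kept_sets[0].times_s
        erp_results = erp_analysis_suite(
            kept_sets, RP_ROI, times, config, seeds[1]
        )
        _save_results(erp_results, out / "erp_results.json")
        cluster.results_table(erp_results).to_csv(out / "erp_clusters.csv", index=False)
        grand = {
            "times_s": times.tolist(),
            "self": np.mean(
                [
                    es.roi_average(RP_ROI)[
                        [i for i, t in enumerate(es.trials) if t.condition == "self"]
                    ].mean(axis=0)
                    for es in kept_sets
                ],
                axis=0,
            ).tolist(),
            "stim": np.mean(
                [
                    es.roi_average(RP_ROI)[
                        [i for i, t in enumerate(es.trials) if t.condition == "stim"]
                    ].mean(axis=0)
                    for es in kept_sets
                ],
                axis=0,
            ).tolist(),
        }
        with open(out / "erp_grand_average.json", "w") as fh:
            json.dump(grand, fh)

        summary: dict = {"stages": {}}
        if config.run_beta:
            stage = "beta"
            beta_cfg = dataclasses.replace(
                config.simulation,
                seed=seeds[2],
                epoch_window_s=config.simulation.beta_window_s,
            )
            beta_sets, _ = simulate_dataset(beta_cfg)
            beta_times = beta_sets[0].times_s
            band_series = []
            for es in beta_sets:
                sub_es = es.pick(BETA_ROI)
                power = tfr.tfr_hanning_convolution(sub_es)
                band = tfr.band_roi_average(power, roi=BETA_ROI)
                band_series.append(band.power)
            tsel = (beta_times >= BETA_ANALYSIS_WINDOW_S[0]) & (
                beta_times <= BETA_ANALYSIS_WINDOW_S[1]
            )
            band_cache = {id(es): s for es, s in zip(beta_sets, band_series)}
            beta_results = erp_analysis_suite(
                beta_sets,
                BETA_ROI,
                beta_times,
                config,
                seeds[3],
                transform=lambda es: band_cache[id(es)],
                time_window=BETA_ANALYSIS_WINDOW_S,
            )
            _save_results(beta_results, out / "beta_results.json")
            cluster.results_table(beta_results).to_csv(
                out / "beta_clusters.csv", index=False
            )
            summary["stages"]["beta"] = {
                "analysis_window_s": list(BETA_ANALYSIS_WINDOW_S),
                "n_valid_samples": int(tsel.sum()),
            }

        if config.run_decoding:
            stage = "decoding"
            dec_raw = decoding_suite(kept_sets, config, seeds[4], residualize=False)
            dec_res = decoding_suite(kept_sets, config, seeds[5], residualize=True)
            for tag, dec in (("raw", dec_raw), ("rt_residualized", dec_res)):
                _save_results(dec["tests"], out / f"decoding_{tag}_results.json")
                np.savez(
                    out / f"decoding_{tag}_accuracy.npz",
                    times_s=dec["times_s"],
                    **{k: v for k, v in dec["accuracy"].items()},
                )

        stage = "behavior"
        rt_table = behavior.build_rt_table(kept_sets)
        rt_table.to_csv(out / "rt_table.csv", index=False)
        match = behavior.rt_match_analysis(
            rt_table,
            n_bins=config.rt_match_bins,
            n_iterations=config.rt_match_iterations,
            seed=seeds[6],
        )
        corr = behavior.rt_amplitude_correlation(rt_table)
        corr.to_csv(out / "rt_amplitude_correlation.csv", index=False)
        cell_means = (
            behavior_table.assign(
                position_class=np.where(
                    behavior_table["move_position"] == 1, "first", "other"
                )
            )
            .groupby(["condition", "sequence_length", "position_class"])["rt_s"]
            .agg(["mean", "std", "count"])
            .reset_index()
        )
        cell_means.to_csv(out / "rt_cell_means.csv", index=False)

        summary["stages"]["behavior"] = {
            "rt_match_t": match.t_stat,
            "rt_match_p": match.p_value,
            "rt_match_std_rt_diff": match.standardized_rt_difference,
            "mixed_model_formula": behavior.RT_MIXED_MODEL_FORMULA,
        }
        summary["seed"] = config.seed
        summary["baseline"] = "none"
        summary["n_significant_erp"] = int(
            sum(len(r.significant_clusters) for r in erp_results.values())
        )
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=1)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc
    return out


# ---------------------------------------------------------------------------
# report


def render_report(run_dir) -> Path:
    """PNG figures rendered from the run's serialized artifacts."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    run = Path(run_dir)
    fig_dir = run / "figures"
    fig_dir.mkdir(exist_ok=True)
    missing = []

    # RT distributions
    if (run / "behavior.csv").exists():
        table = pd.read_csv(run / "behavior.csv")
        fig, ax = plt.subplots(figsize=(7, 4))
        groups, labels = [], []
        for cond in ("self", "stim"):
            for length in (2, 4):
                for pc, sel in (
                    ("first", table["move_position"] == 1),
                    ("other", table["move_position"] > 1),
                ):
                    sub = table[
                        (table["condition"] == cond)
                        & (table["sequence_length"] == length)
                        & sel
                    ]["rt_s"]
                    groups.append(sub.to_numpy())
                    labels.append(f"{cond}\n{length}mv {pc}")
        ax.violinplot(groups, showmeans=True)
        ax.set_xticks(range(1, len(labels) + 1), labels, fontsize=7)
        ax.set_ylabel("RT (s)")
        fig.savefig(fig_dir / "rt_distributions.png", dpi=110)
        plt.close(fig)
    else:
        missing.append("behavior.csv")

    # grand-average waveforms with significance bars
    if (run / "erp_grand_average.json").exists():
        with open(run / "erp_grand_average.json") as fh:
            grand = json.load(fh)
        with open(run / "erp_results.json") as fh:
            erp = json.load(fh)
        fig, ax = plt.subplots(figsize=(7, 4))
        t = np.array(grand["times_s"])
        ax.plot(t, grand["self"], label="self-generated")
        ax.plot(t, grand["stim"], label="stimulus-driven")
        y0 = min(min(grand["self"]), min(grand["stim"]))
        for c in erp.get("factorial_position", {}).get("clusters", []):
            if c["significant"] and c["start_s"] is not None:
                ax.hlines(y0 * 1.05, c["start_s"], c["end_s"], lw=4, color="k")
        ax.axvline(0, color="gray", ls=":")
        ax.set_xlabel("time (s)")
        ax.set_ylabel("amplitude (µV)")
        ax.invert_yaxis()
        ax.legend()
        fig.savefig(fig_dir / "rp_waveforms.png", dpi=110)
        plt.close(fig)
    else:
        missing.append("erp_grand_average.json")

    # decoding accuracy with chance line
    acc_file = run / "decoding_raw_accuracy.npz"
    if acc_file.exists():
        with np.load(acc_file) as npz:
            times = npz["times_s"]
            fig, ax = plt.subplots(figsize=(7, 4))
            for key in npz.files:
                if key == "times_s":
                    continue
                ax.plot(times, npz[key].mean(axis=0), label=key)
        ax.axhline(0.5, color="gray", ls=":", label="chance")
        ax.set_xlabel("time (s)")
        ax.set_ylabel("accuracy")
        ax.legend(fontsize=7)
        fig.savefig(fig_dir / "decoding_accuracy.png", dpi=110)
        plt.close(fig)

    if missing:
        logger.warning("render_report: missing artifacts %s", missing)
        with open(fig_dir / "missing.json", "w") as fh:
            json.dump(missing, fh)
    return fig_dir
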