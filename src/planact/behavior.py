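"""Behavioral RT structuring and the RT-robustness procedures.

Two checks guard against reaction-time confounds of the preparatory
amplitude effects: (1) distribution-matched subsampling — self-generated
trials are resampled within participant to match the stimulus-driven RT
distribution via quantile bins, and the condition contrast on mean
premovement amplitude is re-evaluated on the matched sets; (2) simple
association checks between participant-mean RT and mean amplitude.

The trial-level mixed model of RT (formula:
``RT ~ position * condition * length + (1 + position + condition | ID)``,
on log RT) is recorded here for reference but fitting is delegated to a
standard mixed-model package; this module's own statistics are the
closed-form paired t test and Pearson correlations that feed the
robustness checks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import EpochSet, RP_ROI

logger = logging.getLogger(__name__)

RT_MIXED_MODEL_FORMULA = (
    "log_rt ~ position * condition * length + (1 + position + condition | participant)"
)


def amplitude_window_mean(
    epochs: EpochSet,
    window_s: tuple = (-1.0, 0.0),
    roi: Sequence[str] = RP_ROI,
) -> np.ndarray:
    """Per-trial mean amplitude: ROI channels averaged, then the window."""
    tsel = (epochs.times_s >= window_s[0]) & (epochs.times_s <= window_s[1])
    if not tsel.any():
        raise ValueError("amplitude window contains no samples")
    return epochs.roi_average(roi)[:, tsel].mean(axis=1)


def build_rt_table(
    epoch_sets: Sequence[EpochSet],
    window_s: tuple = (-1.0, 0.0),
    roi: Sequence[str] = RP_ROI,
) -> pd.DataFrame:
    """Tidy table: one row per trial with premovement amplitude and
    log RT standardized within participant."""
    frames = []
    for es in epoch_sets:
        t = es.table()
        t["amplitude_uv"] = amplitude_window_mean(es, window_s, roi)
        t["log_rt"] = np.log(t["rt_s"])
        sd = t["log_rt"].std(ddof=0)
        t["rt_z"] = (t["log_rt"] - t["log_rt"].mean()) / (sd if sd > 0 else 1.0)
        frames.append(t)
    return pd.concat(frames, ignore_index=True)


@dataclass
class MatchResult:
    """RT-matched subsampling outcome for one group of participants."""

    participant_ids: list
    matched_self_amp: np.ndarray      # participants (mean over iterations)
    stim_amp: np.ndarray
    matched_self_rt: np.ndarray
    stim_rt: np.ndarray
    log_rt_sd: np.ndarray             # per participant, all trials pooled
    bin_targets: list                 # per participant: per-bin subsample sizes
    n_iterations: int
    n_bins: int
    t_stat: float = np.nan
    p_value: float = np.nan
    df: int = 0

    @property
    def standardized_rt_difference(self) -> float:
        """Mean RT mismatch after matching, in within-participant log-RT
        SD units (|mean over participants|)."""
        dz = (np.log(self.matched_self_rt) - np.log(self.stim_rt)) / self.log_rt_sd
        return float(abs(dz.mean()))


def paired_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float, int]:
    """Closed-form paired t test; returns (t, two-sided p, df)."""
    d = np.asarray(a, float) - np.asarray(b, float)
    n = len(d)
    if n < 2:
        raise ValueError("need at least 2 pairs")
    sd = d.std(ddof=1)
    if sd == 0:
        t = np.inf * np.sign(d.mean()) if d.mean() != 0 else 0.0
        return float(t), 0.0 if d.mean() != 0 else 1.0, n - 1
    t = d.mean() / (sd / np.sqrt(n))
    p = 2 * stats.t.sf(abs(t), n - 1)
    return float(t), float(p), n - 1


def _bin_targets(
    self_bins: np.ndarray, stim_counts: np.ndarray
) -> np.ndarray:
    """Per-bin subsample sizes: stimulus counts, proportionally rescaled
    when the self side is deficient in any bin."""
    self_counts = np.array(
        [int((self_bins == b).sum()) for b in range(len(stim_counts))]
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = np.where(stim_counts > 0, self_counts / stim_counts, np.inf)
    scale = min(1.0, ratios.min())
    if scale > 0:
        if scale < 1.0:
            logger.warning(
                "rt_match_subsample: self side deficient, rescaling bin targets "
                "by %.3f",
                scale,
            )
        targets = np.floor(stim_counts * scale).astype(int)
    else:
        # an empty self-side bin: exact proportional rescaling is
        # impossible, clip per bin instead (logged)
        logger.warning(
            "rt_match_subsample: empty self-side bin, clipping bin targets"
        )
        targets = np.minimum(self_counts, stim_counts).astype(int)
    return targets


def rt_match_subsample(
    self_rts: np.ndarray,
    stim_rts: np.ndarray,
    self_amp: np.ndarray,
    n_bins: int = 5,
    n_iterations: int = 1000,
    rng: np.random.Generator | int | None = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One participant's matched subsampling.

    Quantile bin edges come from the stimulus-driven RT distribution;
    per iteration, self trials are drawn without replacement within each
    bin to hit the (possibly rescaled) stimulus bin counts.  Returns
    (per-iteration mean self amplitude, per-iteration mean self RT,
    bin target vector).
    """
    self_rts = np.asarray(self_rts, float)
    stim_rts = np.asarray(stim_rts, float)
    self_amp = np.asarray(self_amp, float)
    if len(self_rts) == 0 or len(stim_rts) == 0:
        raise ValueError("both conditions must have trials")
    rng = np.random.default_rng(rng)
    # n_bins quantile bins have n_bins + 1 edges including the stimulus
    # min and max: self trials outside the stimulus RT range fall in no
    # bin and can never be sampled.
    edges = np.quantile(stim_rts, np.linspace(0, 1, n_bins + 1))
    stim_bins = np.clip(np.searchsorted(edges[1:-1], stim_rts, side="right"), 0, n_bins - 1)
    self_bins = np.searchsorted(edges[1:-1], self_rts, side="right")
    out_of_range = (self_rts < edges[0]) | (self_rts > edges[-1])
    self_bins = np.where(out_of_range, -1, self_bins)
    stim_counts = np.array([int((stim_bins == b).sum()) for b in range(n_bins)])
    targets = _bin_targets(self_bins, stim_counts)

    amp_sums = np.zeros(n_iterations)
    rt_sums = np.zeros(n_iterations)
    total = targets.sum()
    if total == 0:
        raise ValueError("matching produced an empty subsample")
    for b in range(n_bins):
        k = targets[b]
        if k == 0:
            continue
        idx = np.flatnonzero(self_bins == b)
        keys = rng.random((n_iterations, len(idx)))
        order = np.argpartition(keys, k - 1, axis=1)[:, :k]
        chosen = idx[order]                      # iterations x k
        amp_sums += self_amp[chosen].sum(axis=1)
        rt_sums += self_rts[chosen].sum(axis=1)
    return amp_sums / total, rt_sums / total, targets


def rt_match_analysis(
    table: pd.DataFrame,
    n_bins: int = 5,
    n_iterations: int = 1000,
    seed: int = 0,
    amplitude_col: str = "amplitude_uv",
) -> MatchResult:
    """Across-participant RT-matched comparison of mean amplitude.

    Per participant, self trials are matched to the stimulus RT
    distribution; iteration-averaged matched means are compared with the
    stimulus means by a paired t test across participants.
    """
    seeds = np.random.SeedSequence(seed).spawn(table["participant_id"].nunique())
    pids, m_amp, s_amp, m_rt, s_rt, sd_log, targets = [], [], [], [], [], [], []
    for ss, (pid, grp) in zip(seeds, table.groupby("participant_id")):
        self_g = grp[grp["condition"] == "self"]
        stim_g = grp[grp["condition"] == "stim"]
        amps, rts, tg = rt_match_subsample(
            self_g["rt_s"].to_numpy(),
            stim_g["rt_s"].to_numpy(),
            self_g[amplitude_col].to_numpy(),
            n_bins=n_bins,
            n_iterations=n_iterations,
            rng=np.random.default_rng(ss),
        )
        pids.append(pid)
        m_amp.append(amps.mean())
        m_rt.append(rts.mean())
        s_amp.append(stim_g[amplitude_col].mean())
        s_rt.append(stim_g["rt_s"].mean())
        sd_log.append(np.log(grp["rt_s"]).std(ddof=0))
        targets.append(tg.tolist())
    m_amp, s_amp = np.array(m_amp), np.array(s_amp)
    t, p, df = paired_t(m_amp, s_amp)
    return MatchResult(
        participant_ids=pids,
        matched_self_amp=m_amp,
        stim_amp=s_amp,
        matched_self_rt=np.array(m_rt),
        stim_rt=np.array(s_rt),
        log_rt_sd=np.array(sd_log),
        bin_targets=targets,
        n_iterations=n_iterations,
        n_bins=n_bins,
        t_stat=t,
        p_value=p,
        df=df,
    )


def rt_amplitude_correlation(
    table: pd.DataFrame, amplitude_col: str = "amplitude_uv"
) -> pd.DataFrame:
    """Pearson correlation between participant-mean RT and amplitude,
    separately per condition, with two-sided p from the t transform."""
    rows = []
    for condition, grp in table.groupby("condition"):
        means = grp.groupby("participant_id")[["rt_s", amplitude_col]].mean()
        if len(means) < 3:
            raise ValueError("need at least 3 participants per condition")
        if means["rt_s"].std() == 0 or means[amplitude_col].std() == 0:
            raise ValueError("zero variance in participant means")
        r, p = stats.pearsonr(means["rt_s"], means[amplitude_col])
        rows.append(
            {"condition": condition, "r": float(r), "p": float(p), "n": len(means)}
        )
    return pd.DataFrame(rows)
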