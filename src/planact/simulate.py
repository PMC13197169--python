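"""Synthetic EEG generator for sequential-action experiments.

Emulates per-participant epoch sets time-locked to key presses in a
Tower of London task with two action conditions (self-generated vs
stimulus-driven), two sequence lengths (2 vs 4 moves) and per-move
positions.  The generative model is deliberately minimal and additive:

* a slow negative preparatory ramp (readiness potential) with a
  frontocentral spatial profile peaking at FCz,
* a beta-band (default 20 Hz) oscillation with a left-central spatial
  profile (C3/C1) whose envelope is suppressed approaching movement,
* 1/f ("pink") plus white background noise, independent per channel.

Reaction times are log-normal with cell-specific parameters whose
defaults reproduce the reference cell means (e.g. self-generated
four-move first move ~ 5.36 s).  All draws are pure functions of
(config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

RP_ROI: tuple[str, ...] = ("Fz", "FCz", "Cz", "FC1", "FC2")
BETA_ROI: tuple[str, ...] = ("Cz", "C1", "C3")
OCCIPITAL: tuple[str, ...] = ("O1", "O2", "POz")
MASTOIDS: tuple[str, ...] = ("M1", "M2")

DEFAULT_CHANNELS: tuple[str, ...] = (
    "Fz", "FCz", "Cz", "FC1", "FC2", "C1", "C3", "C4",
    "CP1", "CP2", "Pz", "POz", "O1", "O2", "M1", "M2", "EOG",
)

# Fixed Gaussian-like spatial profiles.  Mastoids and EOG carry noise only.
_RP_WEIGHTS = {
    "Fz": 0.8, "FCz": 1.0, "Cz": 0.9, "FC1": 0.85, "FC2": 0.85,
    "C1": 0.6, "C3": 0.4, "C4": 0.4, "CP1": 0.35, "CP2": 0.35,
    "Pz": 0.25, "POz": 0.1, "O1": 0.05, "O2": 0.05, "M1": 0.0, "M2": 0.0,
    "EOG": 0.0,
}
_BETA_WEIGHTS = {
    "Fz": 0.1, "FCz": 0.3, "Cz": 0.8, "FC1": 0.4, "FC2": 0.2,
    "C1": 0.9, "C3": 1.0, "C4": 0.3, "CP1": 0.5, "CP2": 0.2,
    "Pz": 0.2, "POz": 0.05, "O1": 0.0, "O2": 0.0, "M1": 0.0, "M2": 0.0,
    "EOG": 0.0,
}


@dataclass(frozen=True)
class Montage:
    """Ordered channel names plus per-component spatial weight maps."""

    channels: tuple[str, ...] = DEFAULT_CHANNELS
    rp_weights: dict = field(default_factory=lambda: dict(_RP_WEIGHTS))
    beta_weights: dict = field(default_factory=lambda: dict(_BETA_WEIGHTS))
    require_rois: bool = True   # False permits channel-subset views

    def __post_init__(self) -> None:
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel names must be unique")
        if self.require_rois:
            for roi in (RP_ROI, BETA_ROI):
                missing = set(roi) - set(self.channels)
                if missing:
                    raise ValueError(f"montage is missing ROI channels {missing}")

    def subset(self, names: Sequence[str]) -> "Montage":
        return Montage(
            channels=tuple(names),
            rp_weights=dict(self.rp_weights),
            beta_weights=dict(self.beta_weights),
            require_rois=False,
        )

    def index(self, names: Sequence[str]) -> np.ndarray:
        try:
            return np.array([self.channels.index(n) for n in names])
        except ValueError as exc:
            raise KeyError(f"channel not in montage: {exc}") from exc

    def weight_vector(self, which: str) -> np.ndarray:
        table = self.rp_weights if which == "rp" else self.beta_weights
        return np.array([table.get(ch, 0.0) for ch in self.channels])


@dataclass(frozen=True)
class TrialRecord:
    participant_id: int
    condition: str          # "self" | "stim"
    sequence_length: int    # 2 | 4
    move_position: int      # 1..sequence_length
    rt_s: float
    epoch_index: int

    def __post_init__(self) -> None:
        if self.condition not in ("self", "stim"):
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.move_position > self.sequence_length:
            raise ValueError("move_position exceeds sequence_length")
        if self.rt_s <= 0:
            raise ValueError("rt_s must be positive")


@dataclass
class EpochSet:
    """Trials x channels x time array (µV) with aligned trial metadata."""

    data: np.ndarray
    times_s: np.ndarray
    montage: Montage
    trials: list
    sampling_rate_hz: float

    def __post_init__(self) -> None:
        n_tr, n_ch, n_t = self.data.shape
        if n_tr != len(self.trials):
            raise ValueError("trial metadata does not match data")
        if n_ch != len(self.montage.channels):
            raise ValueError("montage does not match data")
        if n_t != len(self.times_s):
            raise ValueError("time grid does not match data")

    def table(self) -> pd.DataFrame:
        return pd.DataFrame([vars(t) for t in self.trials])

    def select(self, mask: np.ndarray) -> "EpochSet":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return EpochSet(
            data=self.data[idx],
            times_s=self.times_s,
            montage=self.montage,
            trials=[self.trials[i] for i in idx],
            sampling_rate_hz=self.sampling_rate_hz,
        )

    def roi_average(self, roi: Sequence[str]) -> np.ndarray:
        """Mean over ROI channels -> trials x time."""
        return self.data[:, self.montage.index(roi), :].mean(axis=1)

    def pick(self, channels: Sequence[str]) -> "EpochSet":
        """Channel-subset view (copy) of the epochs."""
        idx = self.montage.index(channels)
        return EpochSet(
            data=self.data[:, idx, :],
            times_s=self.times_s,
            montage=self.montage.subset(channels),
            trials=list(self.trials),
            sampling_rate_hz=self.sampling_rate_hz,
        )


# Cell keys are (condition, sequence_length, position_class) with
# position_class "first" or "other".
_RT_CELL_MEANS_SD = {
    ("self", 2, "first"): (3.63, 0.77),
    ("self", 2, "other"): (1.02, 0.36),
    ("self", 4, "first"): (5.36, 1.29),
    ("self", 4, "other"): (1.24, 0.42),
    ("stim", 2, "first"): (1.57, 0.37),
    ("stim", 2, "other"): (1.18, 0.21),
    ("stim", 4, "first"): (1.59, 0.35),
    ("stim", 4, "other"): (1.13, 0.19),
}


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a log-normal with the given arithmetic mean and SD."""
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2
    return mu, float(np.sqrt(sigma2))


def default_rt_params() -> dict:
    return {cell: _lognormal_params(m, s) for cell, (m, s) in _RT_CELL_MEANS_SD.items()}


def default_rp_amplitudes() -> dict:
    """Ramp peak (µV, magnitude) per cell; preparation is strongest for
    self-generated first moves."""
    amps = {}
    for length in (2, 4):
        amps[("self", length, "first")] = 6.0
        amps[("self", length, "other")] = 2.0
        amps[("stim", length, "first")] = 1.5
        amps[("stim", length, "other")] = 1.5
    return amps


def default_beta_suppression() -> dict:
    """Fractional pre-movement beta envelope suppression per cell."""
    supp = {}
    for length in (2, 4):
        supp[("self", length, "first")] = 0.6
        supp[("self", length, "other")] = 0.45
        supp[("stim", length, "first")] = 0.3
        supp[("stim", length, "other")] = 0.3
    return supp


@dataclass(frozen=True)
class SimulationConfig:
    n_participants: int = 23
    sampling_rate_hz: float = 200.0
    epoch_window_s: tuple[float, float] = (-1.0, 0.5)
    beta_window_s: tuple[float, float] = (-2.0, 1.0)
    rp_amplitude_by_cell: dict = field(default_factory=default_rp_amplitudes)
    beta_suppression_by_cell: dict = field(default_factory=default_beta_suppression)
    beta_center_freq_hz: float = 20.0
    beta_base_amp_uv: float = 3.0
    beta_ramp_window_s: float = 0.8
    rp_onset_s: float = -0.9
    noise_exponent: float = 1.0
    pink_sd_uv: float = 6.0
    white_sd_uv: float = 3.0
    rt_lognormal_params: dict = field(default_factory=default_rt_params)
    iti_jitter_s: tuple[float, float] = (2.5, 6.5)
    trials_per_cell: int = 40
    sequence_lengths: tuple[int, ...] = (2, 4)
    participant_scale_sd: float = 0.1
    # t = 0 is the first (selection) key press of a move; set to "release"
    # to time-lock to the second press instead (shifts epochs by one
    # press-to-press interval in the continuous simulator).
    time_lock: str = "selection"
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.epoch_window_s
        if not lo < 0 < hi:
            raise ValueError("epoch window must contain movement onset (0)")
        if self.time_lock not in ("selection", "release"):
            raise ValueError("time_lock must be 'selection' or 'release'")


def time_grid(window_s: tuple[float, float], rate_hz: float) -> np.ndarray:
    """Closed sample grid [lo, hi] inclusive at 1/rate steps."""
    lo, hi = window_s
    n = int(round((hi - lo) * rate_hz)) + 1
    return lo + np.arange(n) / rate_hz


def rp_component(
    times_s: np.ndarray,
    peak_uv: float,
    onset_s: float = -0.9,
    decay_s: float = 0.15,
) -> np.ndarray:
    """Readiness-potential template: zero before onset, linear negative ramp
    reaching -|peak| at movement onset, exponential recovery afterwards."""
    times_s = np.asarray(times_s, dtype=float)
    out = np.zeros_like(times_s)
    if peak_uv == 0:
        return out
    ramp = (times_s >= onset_s) & (times_s <= 0)
    out[ramp] = -abs(peak_uv) * (times_s[ramp] - onset_s) / (0 - onset_s)
    post = times_s > 0
    out[post] = -abs(peak_uv) * np.exp(-times_s[post] / decay_s)
    return out


def beta_envelope(
    times_s: np.ndarray,
    base_amp_uv: float,
    suppression_frac: float,
    ramp_window_s: float = 0.8,
    rebound_end_s: float = 0.5,
) -> np.ndarray:
    """Amplitude envelope: flat at base, linear decline to
    base*(1 - suppression) over the pre-movement ramp window, recovery to
    base by ``rebound_end_s``."""
    if not 0 <= suppression_frac <= 1:
        raise ValueError("suppression_frac must lie in [0, 1]")
    times_s = np.asarray(times_s, dtype=float)
    floor = base_amp_uv * (1 - suppression_frac)
    env = np.full_like(times_s, base_amp_uv)
    if ramp_window_s > 0:
        falling = (times_s >= -ramp_window_s) & (times_s <= 0)
        env[falling] = base_amp_uv + (floor - base_amp_uv) * (
            times_s[falling] + ramp_window_s
        ) / ramp_window_s
    if rebound_end_s > 0:
        rising = (times_s > 0) & (times_s <= rebound_end_s)
        env[rising] = floor + (base_amp_uv - floor) * times_s[rising] / rebound_end_s
    env[times_s > rebound_end_s] = base_amp_uv
    return env


def beta_component(
    times_s: np.ndarray,
    center_freq_hz: float,
    base_amp_uv: float,
    suppression_frac: float,
    ramp_window_s: float = 0.8,
    rng: np.random.Generator | None = None,
    phase: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Envelope-modulated beta sinusoid; returns (signal, envelope)."""
    env = beta_envelope(times_s, base_amp_uv, suppression_frac, ramp_window_s)
    if phase is None:
        rng = np.random.default_rng() if rng is None else rng
        phase = rng.uniform(0, 2 * np.pi)
    sig = env * np.cos(2 * np.pi * center_freq_hz * np.asarray(times_s) + phase)
    return sig, env


def noise_component(
    times_s: np.ndarray,
    one_over_f_exponent: float = 1.0,
    white_sd_uv: float = 3.0,
    pink_sd_uv: float = 6.0,
    rng: np.random.Generator | int | None = None,
    size: int | None = None,
) -> np.ndarray:
    """1/f^a shaped noise plus white noise.

    The shaped part is normalized to sample SD ``pink_sd_uv`` per
    realization; the white part has SD ``white_sd_uv``.  ``size`` draws a
    batch (size x time).  Deterministic given an integer seed or Generator.
    """
    if one_over_f_exponent < 0:
        raise ValueError("exponent must be >= 0")
    rng = np.random.default_rng(rng)
    n = len(times_s)
    shape = (1 if size is None else size, n)
    out = np.zeros(shape)
    if pink_sd_uv > 0:
        freqs = np.fft.rfftfreq(n)
        scale = np.zeros_like(freqs)
        scale[1:] = freqs[1:] ** (-one_over_f_exponent / 2)
        spec = (
            rng.standard_normal((shape[0], len(freqs)))
            + 1j * rng.standard_normal((shape[0], len(freqs)))
        ) * scale
        pink = np.fft.irfft(spec, n=n, axis=-1)
        sd = pink.std(axis=-1, keepdims=True)
        sd[sd == 0] = 1.0
        out += pink / sd * pink_sd_uv
    if white_sd_uv > 0:
        out += rng.standard_normal(shape) * white_sd_uv
    return out[0] if size is None else out


def position_class(move_position: int) -> str:
    return "first" if move_position == 1 else "other"


def cell_value(mapping: dict, condition: str, length: int, pos: int, default=0.0):
    """Cell lookup: an exact (condition, length, position) key takes
    precedence over the (condition, length, position-class) key."""
    if (condition, length, pos) in mapping:
        return mapping[(condition, length, pos)]
    return mapping.get((condition, length, position_class(pos)), default)


def simulate_rts(
    cell: tuple[str, int, str],
    params: dict | None = None,
    n: int = 1,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Log-normal RT draws for one (condition, length, position-class) cell."""
    if n < 1:
        raise ValueError("n must be >= 1")
    params = default_rt_params() if params is None else params
    if cell not in params:
        raise KeyError(f"unknown RT cell {cell!r}")
    mu, sigma = params[cell]
    rng = np.random.default_rng(rng)
    return np.exp(mu + sigma * rng.standard_normal(n))


def _positions_and_counts(length: int, n_first: int, n_other: int) -> list[tuple[int, int]]:
    """Split the 'other' trial budget across non-first positions."""
    out = [(1, n_first)]
    others = list(range(2, length + 1))
    base, extra = divmod(n_other, len(others))
    for i, pos in enumerate(others):
        out.append((pos, base + (1 if i < extra else 0)))
    return out


def simulate_participant(
    config: SimulationConfig,
    participant_id: int,
    rng: np.random.Generator,
    montage: Montage | None = None,
    window_s: tuple[float, float] | None = None,
) -> EpochSet:
    """One participant's epochs across all design cells."""
    montage = Montage() if montage is None else montage
    window = config.epoch_window_s if window_s is None else window_s
    times = time_grid(window, config.sampling_rate_hz)
    n_ch = len(montage.channels)
    rp_w = montage.weight_vector("rp")
    beta_w = montage.weight_vector("beta")
    subj_scale = 1.0 + config.participant_scale_sd * rng.standard_normal()

    data_rows, trials = [], []
    epoch_index = 0
    for condition in ("self", "stim"):
        for length in config.sequence_lengths:
            for pos, count in _positions_and_counts(
                length, config.trials_per_cell, config.trials_per_cell
            ):
                if count == 0:
                    continue
                cell = (condition, length, position_class(pos))
                rp_amp = (
                    cell_value(config.rp_amplitude_by_cell, condition, length, pos)
                    * subj_scale
                )
                supp = cell_value(config.beta_suppression_by_cell, condition, length, pos)
                rts = simulate_rts(cell, config.rt_lognormal_params, count, rng)
                rp = rp_component(times, rp_amp, config.rp_onset_s)
                env = beta_envelope(
                    times,
                    config.beta_base_amp_uv,
                    supp,
                    config.beta_ramp_window_s,
                )
                phases = rng.uniform(0, 2 * np.pi, size=count)
                beta_sig = env[None, :] * np.cos(
                    2 * np.pi * config.beta_center_freq_hz * times[None, :]
                    + phases[:, None]
                )
                noise = noise_component(
                    times,
                    config.noise_exponent,
                    config.white_sd_uv,
                    config.pink_sd_uv,
                    rng=rng,
                    size=count * n_ch,
                ).reshape(count, n_ch, len(times))
                epochs = (
                    rp_w[None, :, None] * rp[None, None, :]
                    + beta_w[None, :, None] * beta_sig[:, None, :]
                    + noise
                )
                data_rows.append(epochs)
                for i in range(count):
                    trials.append(
                        TrialRecord(
                            participant_id=participant_id,
                            condition=condition,
                            sequence_length=length,
                            move_position=pos,
                            rt_s=float(rts[i]),
                            epoch_index=epoch_index,
                        )
                    )
                    epoch_index += 1
    return EpochSet(
        data=np.concatenate(data_rows, axis=0),
        times_s=times,
        montage=montage,
        trials=trials,
        sampling_rate_hz=config.sampling_rate_hz,
    )


def simulate_dataset(
    config: SimulationConfig,
    montage: Montage | None = None,
    window_s: tuple[float, float] | None = None,
) -> tuple[list[EpochSet], pd.DataFrame]:
    """All participants' epoch sets plus the tidy behavioral table."""
    montage = Montage() if montage is None else montage
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_participants)
    epoch_sets = []
    tables = []
    for pid, ss in enumerate(seeds, start=1):
        es = simulate_participant(
            config, pid, np.random.default_rng(ss), montage, window_s
        )
        epoch_sets.append(es)
        tables.append(es.table())
    behavior = pd.concat(tables, ignore_index=True)
    return epoch_sets, behavior


def simulate_continuous(
    config: SimulationConfig,
    participant_id: int,
    n_trials_per_cell: int = 4,
    native_rate_hz: float = 1000.0,
    rng: np.random.Generator | int | None = None,
    montage: Montage | None = None,
) -> tuple[np.ndarray, pd.DataFrame, float]:
    """A continuous multichannel recording with embedded move events.

    Events are separated by the jittered inter-move interval; around each
    event the same additive components as :func:`simulate_participant` are
    injected.  Returns (channels x samples array, event table with
    ``event_sample`` column at the native rate, native rate).
    """
    montage = Montage() if montage is None else montage
    rng = np.random.default_rng(rng)
    lo, hi = config.epoch_window_s
    pre = abs(lo) + 0.5
    rows = []
    for condition in ("self", "stim"):
        for length in (2, 4):
            for pos, count in _positions_and_counts(
                length, n_trials_per_cell, n_trials_per_cell
            ):
                cell = (condition, length, position_class(pos))
                for _ in range(count):
                    rows.append((condition, length, pos, cell))
    rng.shuffle(rows)

    gaps = rng.uniform(*config.iti_jitter_s, size=len(rows))
    event_times = pre + np.cumsum(gaps)
    total_s = event_times[-1] + hi + 0.5
    n = int(total_s * native_rate_hz)
    n_ch = len(montage.channels)
    data = noise_component(
        np.arange(n) / native_rate_hz,
        config.noise_exponent,
        config.white_sd_uv,
        config.pink_sd_uv,
        rng=rng,
        size=n_ch,
    )
    rp_w = montage.weight_vector("rp")
    beta_w = montage.weight_vector("beta")
    local_t = time_grid((lo, hi), native_rate_hz)
    records = []
    for i, ((condition, length, pos, cell), t0) in enumerate(zip(rows, event_times)):
        s0 = int(round(t0 * native_rate_hz)) + int(round(lo * native_rate_hz))
        rp_amp = config.rp_amplitude_by_cell.get(cell, 0.0)
        supp = config.beta_suppression_by_cell.get(cell, 0.0)
        rp = rp_component(local_t, rp_amp, config.rp_onset_s)
        beta_sig, _ = beta_component(
            local_t,
            config.beta_center_freq_hz,
            config.beta_base_amp_uv,
            supp,
            config.beta_ramp_window_s,
            rng=rng,
        )
        seg = rp_w[:, None] * rp[None, :] + beta_w[:, None] * beta_sig[None, :]
        data[:, s0 : s0 + len(local_t)] += seg
        rt = float(simulate_rts(cell, config.rt_lognormal_params, 1, rng)[0])
        records.append(
            {
                "participant_id": participant_id,
                "condition": condition,
                "sequence_length": length,
                "move_position": pos,
                "rt_s": rt,
                "event_sample": int(round(t0 * native_rate_hz)),
            }
        )
    return data, pd.DataFrame(records), native_rate_hz
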