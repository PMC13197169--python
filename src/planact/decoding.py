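"""Per-timepoint linear-discriminant decoding of action type.

At every timepoint the spatial pattern across channels (excluding EOG
and occipital sites) is the feature vector for classifying
self-generated vs stimulus-driven trials.  Accuracy comes from
stratified five-fold cross-validation repeated five times; z-score
normalization and the discriminant are fit on training folds only.
Group-level inference reuses the cluster permutation machinery,
one-sided against chance (0.5) at alpha = 0.025.

The discriminant is the classical closed form w = S⁻¹(m₁ − m₀) with the
pooled within-class covariance S shrunk toward a scaled identity:
S_γ = (1 − γ) S + γ (tr S / p) I.  The shrinkage intensity γ is a fixed,
configurable policy (default 0.1), raised with a warning when a fold has
too few trials for a stable covariance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .cluster import ClusterTestResult, cluster_test
from .simulate import EpochSet, OCCIPITAL

logger = logging.getLogger(__name__)

DEFAULT_EXCLUSIONS = OCCIPITAL + ("EOG",)


@dataclass(frozen=True)
class DecodingConfig:
    n_folds: int = 5
    n_repeats: int = 5
    channel_exclusions: tuple = DEFAULT_EXCLUSIONS
    window_s: tuple = (-1.0, 0.0)
    chance_level: float = 0.5
    shrinkage: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("need at least 2 folds")
        if not 0 <= self.shrinkage <= 1:
            raise ValueError("shrinkage must lie in [0, 1]")


@dataclass
class DecodingResult:
    accuracy: np.ndarray                  # time
    fold_accuracy: np.ndarray             # repeats x folds x time
    times_s: np.ndarray
    n_trials_per_class: dict
    config: DecodingConfig
    cell: tuple | None = None


@dataclass
class ResidualizationReport:
    pre_corr: np.ndarray                  # channels x time
    post_corr: np.ndarray
    max_abs_post: float


# ---------------------------------------------------------------------------
# LDA


def _fit_lda_batch(
    x_train: np.ndarray, y: np.ndarray, shrinkage: float
) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form shrinkage LDA fit at every timepoint at once.

    x_train: trials x channels x time, y: binary labels (0/1).
    Returns (weights: time x channels, bias: time).
    """
    n, p, _ = x_train.shape
    x0, x1 = x_train[y == 0], x_train[y == 1]
    if len(x0) < 2 or len(x1) < 2:
        raise ValueError("need at least 2 trials per class")
    if n < p + 2 and shrinkage < 0.5:
        logger.warning(
            "LDA: %d trials for %d channels; raising shrinkage to 0.5", n, p
        )
        shrinkage = 0.5
    m0, m1 = x0.mean(axis=0), x1.mean(axis=0)          # channels x time
    c0, c1 = x0 - m0, x1 - m1
    # pooled within-class covariance, per timepoint: time x channels x channels
    cov = (
        np.einsum("iat,ibt->tab", c0, c0, optimize=True)
        + np.einsum("iat,ibt->tab", c1, c1, optimize=True)
    ) / (n - 2)
    nu = np.trace(cov, axis1=1, axis2=2) / p
    cov = (1 - shrinkage) * cov
    idx = np.arange(p)
    cov[:, idx, idx] += shrinkage * nu[:, None]
    diff = (m1 - m0).T                                  # time x channels
    w = np.linalg.solve(cov, diff[:, :, None])[:, :, 0]
    bias = -np.einsum("tc,ct->t", w, (m0 + m1) / 2)
    return w, bias


def lda_train(
    features: np.ndarray, labels: np.ndarray, shrinkage: float = 0.1
) -> tuple[np.ndarray, float]:
    """Train a single shrinkage-LDA discriminant (trials x channels).

    Returns (weights, bias); decision is sign(w @ x + b), positive for
    the second class in sorted label order.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {classes}")
    y = (labels == classes[1]).astype(int)
    w, b = _fit_lda_batch(features[:, :, None], y, shrinkage)
    return w[0], float(b[0])


def lda_predict(features: np.ndarray, weights: np.ndarray, bias: float) -> np.ndarray:
    """Class indices (0/1); exact ties resolve to the first class (logged)."""
    scores = features @ weights + bias
    ties = scores == 0
    if np.any(ties):
        logger.info("lda_predict: %d decision-boundary ties -> first class", ties.sum())
    return (scores > 0).astype(int)


# ---------------------------------------------------------------------------
# cross-validated decoding


def _stratified_folds(
    y: np.ndarray, n_folds: int, rng: np.random.Generator
) -> np.ndarray:
    """Fold assignment per trial, stratified by class."""
    assignment = np.empty(len(y), dtype=int)
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        assignment[idx] = np.arange(len(idx)) % n_folds
    return assignment


def crossval_decode(
    epochs: EpochSet | np.ndarray,
    labels: Sequence | None = None,
    config: DecodingConfig | None = None,
    times_s: np.ndarray | None = None,
    cell: tuple | None = None,
) -> DecodingResult:
    """Same-time decoding accuracy at every timepoint.

    Accepts an EpochSet (labels taken from trial conditions, channels
    restricted by the exclusion list, time restricted to the decoding
    window) or a raw trials x channels x time array with explicit labels.
    """
    config = DecodingConfig() if config is None else config
    if isinstance(epochs, EpochSet):
        keep = [
            i
            for i, ch in enumerate(epochs.montage.channels)
            if ch not in config.channel_exclusions
        ]
        tsel = (epochs.times_s >= config.window_s[0]) & (
            epochs.times_s <= config.window_s[1]
        )
        data = epochs.data[:, keep][:, :, tsel]
        times_s = epochs.times_s[tsel]
        labels = np.array([t.condition for t in epochs.trials])
    else:
        data = np.asarray(epochs, dtype=float)
        labels = np.asarray(labels)
        if times_s is None:
            times_s = np.arange(data.shape[-1], dtype=float)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {classes}")
    y = (labels == classes[1]).astype(int)
    counts = {str(c): int((labels == c).sum()) for c in classes}
    if min(counts.values()) < config.n_folds:
        raise ValueError("each class needs at least n_folds trials")

    n_t = data.shape[-1]
    rng = np.random.default_rng(config.seed)
    fold_acc = np.empty((config.n_repeats, config.n_folds, n_t))
    for rep in range(config.n_repeats):
        assignment = _stratified_folds(y, config.n_folds, rng)
        for fold in range(config.n_folds):
            test = assignment == fold
            x_tr, y_tr = data[~test], y[~test]
            x_te, y_te = data[test], y[test]
            # z-normalization fit on training folds only
            mu = x_tr.mean(axis=0)
            sd = x_tr.std(axis=0, ddof=0)
            sd[sd == 0] = 1.0
            x_tr = (x_tr - mu) / sd
            x_te = (x_te - mu) / sd
            w, b = _fit_lda_batch(x_tr, y_tr, config.shrinkage)
            scores = np.einsum("ict,tc->it", x_te, w) + b[None, :]
            pred = (scores > 0).astype(int)
            fold_acc[rep, fold] = (pred == y_te[:, None]).mean(axis=0)
    accuracy = fold_acc.mean(axis=(0, 1))
    return DecodingResult(
        accuracy=accuracy,
        fold_accuracy=fold_acc,
        times_s=np.asarray(times_s),
        n_trials_per_class=counts,
        config=config,
        cell=cell,
    )


def decode_against_chance(
    acc_by_participant: np.ndarray,
    chance: float = 0.5,
    n_permutations: int = 5000,
    cluster_alpha: float = 0.05,
    test_alpha: float = 0.025,
    seed: int = 0,
    times_s: np.ndarray | None = None,
) -> ClusterTestResult:
    """One-sided cluster permutation test of accuracy > chance."""
    acc = np.asarray(acc_by_participant, dtype=float)
    return cluster_test(
        acc - chance,
        n_permutations=n_permutations,
        cluster_alpha=cluster_alpha,
        test_alpha=test_alpha,
        tail="greater",
        seed=seed,
        times_s=times_s,
    )


# ---------------------------------------------------------------------------
# RT residualization


def residualize_rt(
    epochs: EpochSet | np.ndarray, rts: Sequence[float] | None = None
) -> tuple[EpochSet | np.ndarray, ResidualizationReport]:
    """Remove RT-related variance from single-trial amplitudes by OLS.

    RT is log-transformed and standardized within the input (one
    participant), then regressed out of every channel x timepoint,
    retaining the trial-mean intercept and removing only the slope term.
    The post-regression correlation is zero to numerical precision.
    """
    if isinstance(epochs, EpochSet):
        data = epochs.data
        rts = np.array([t.rt_s for t in epochs.trials])
    else:
        data = np.asarray(epochs, dtype=float)
        rts = np.asarray(rts, dtype=float)
    log_rt = np.log(rts)
    sd = log_rt.std(ddof=0)
    if sd <= 1e-12 * (1 + np.abs(log_rt).max()):
        logger.warning("residualize_rt: zero RT variance, returning input unchanged")
        zeros = np.zeros(data.shape[1:])
        return epochs, ResidualizationReport(zeros, zeros, 0.0)
    rt_z = (log_rt - log_rt.mean()) / sd

    def _corr(x: np.ndarray) -> np.ndarray:
        xc = x - x.mean(axis=0)
        denom = np.sqrt((xc**2).sum(axis=0)) * np.sqrt((rt_z**2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.einsum("i...,i->...", xc, rt_z) / denom
        return np.nan_to_num(r)

    pre = _corr(data)
    slope = np.einsum("i...,i->...", data, rt_z) / (rt_z**2).sum()
    residual = data - slope[None, ...] * rt_z.reshape((-1,) + (1,) * (data.ndim - 1))
    post = _corr(residual)
    report = ResidualizationReport(
        pre_corr=pre, post_corr=post, max_abs_post=float(np.abs(post).max())
    )
    if isinstance(epochs, EpochSet):
        out = EpochSet(
            data=residual,
            times_s=epochs.times_s,
            montage=epochs.montage,
            trials=list(epochs.trials),
            sampling_rate_hz=epochs.sampling_rate_hz,
        )
        return out, report
    return residual, report
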