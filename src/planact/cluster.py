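"""Cluster-based permutation inference over time series.

Implements the full inferential machinery used throughout the pipeline:
pointwise dependent-sample t statistics, formation of contiguous
supra-threshold clusters scored by summed-t mass, Monte-Carlo sign-flip
nulls of the maximum cluster mass (family-wise error control over
timepoints), and the factorial / positional / trend / planned contrasts
computed on self-minus-stimulus difference waves.

Conventions
-----------
* Monte-Carlo p = (b + 1) / (n_permutations + 1), never zero; at 5,000
  permutations the floor prints as 0.0002.
* Two-tailed tests use per-tail max-mass nulls and compare each
  cluster's p against test_alpha / 2 (the "corrected alpha" convention);
  p values themselves are not doubled, so the printed floor is the same
  for one- and two-tailed tests.
* The sign-flip set is closed under negation (antithetic halves), which
  makes the positive- and negative-tail null distributions identical as
  multisets and p monotone in |mass| within a result.
* NaN samples (e.g. the time-frequency edge mask) can never join a
  cluster, so clusters cannot span masked gaps.
* Zero-variance samples yield t = signed infinity (logged); a cluster
  containing such a sample has infinite mass and lands on the p floor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

LINEAR_TREND_WEIGHTS = (1.5, 0.5, -0.5, -1.5)

_FINITE_CAP = 1e30  # stand-in for infinite t inside vectorized mass sums


@dataclass
class Cluster:
    start_idx: int
    end_idx: int              # inclusive
    mass: float
    sign: int                 # +1 | -1
    start_s: float | None = None
    end_s: float | None = None
    p: float | None = None
    significant: bool | None = None

    @property
    def n_samples(self) -> int:
        return self.end_idx - self.start_idx + 1


@dataclass
class ClusterTestResult:
    clusters: list
    n_permutations: int
    cluster_alpha: float
    test_alpha: float
    tail: str
    df: int
    t_obs: np.ndarray
    null_max_mass: np.ndarray
    seed: int | None = None
    times_s: np.ndarray | None = None

    @property
    def significant_clusters(self) -> list:
        return [c for c in self.clusters if c.significant]

    def null_quantiles(self, qs=(0.5, 0.95, 0.975, 0.99)) -> dict:
        finite = self.null_max_mass[np.isfinite(self.null_max_mass)]
        if len(finite) == 0:
            return {q: float("nan") for q in qs}
        return {q: float(np.quantile(finite, q)) for q in qs}

    def to_dict(self) -> dict:
        return {
            "clusters": [
                {
                    "start_idx": c.start_idx,
                    "end_idx": c.end_idx,
                    "start_s": c.start_s,
                    "end_s": c.end_s,
                    "mass": c.mass,
                    "sign": c.sign,
                    "p": c.p,
                    "significant": c.significant,
                }
                for c in self.clusters
            ],
            "n_permutations": self.n_permutations,
            "cluster_alpha": self.cluster_alpha,
            "test_alpha": self.test_alpha,
            "tail": self.tail,
            "df": self.df,
            "seed": self.seed,
            "null_quantiles": self.null_quantiles(),
        }


# ---------------------------------------------------------------------------
# pointwise statistics


def pointwise_t_one_sample(values: np.ndarray) -> tuple[np.ndarray, int]:
    """Dependent-sample t against zero at each timepoint.

    ``values`` is participants x time.  Zero-variance samples produce
    signed infinity (or 0 when the mean is also zero) with a warning.
    """
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    if n < 2:
        raise ValueError("need at least 2 participants")
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    zero_var = (sd == 0) & np.isfinite(mean)
    if zero_var.any():
        logger.warning(
            "pointwise_t: %d zero-variance samples set to signed infinity",
            int(zero_var.sum()),
        )
        m = mean[zero_var]
        t[zero_var] = np.where(m > 0, np.inf, np.where(m < 0, -np.inf, 0.0))
    return t, n - 1


def critical_t(df: int, cluster_alpha: float, tail: str) -> float:
    """Cluster-forming threshold on the t scale."""
    if tail == "two":
        return float(stats.t.ppf(1 - cluster_alpha / 2, df))
    return float(stats.t.ppf(1 - cluster_alpha, df))


# ---------------------------------------------------------------------------
# cluster formation


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """(start, end-inclusive) of maximal True runs."""
    padded = np.concatenate([[False], mask, [False]])
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1) - 1
    return list(zip(starts.tolist(), ends.tolist()))


def form_clusters(
    t_series: np.ndarray,
    df: int,
    cluster_alpha: float = 0.05,
    tail: str = "two",
    times_s: np.ndarray | None = None,
) -> list[Cluster]:
    """Maximal same-sign supra-threshold runs with summed-t mass.

    Single-sample runs are valid clusters.  NaN samples never join a
    cluster.
    """
    t_series = np.asarray(t_series, dtype=float)
    crit = critical_t(df, cluster_alpha, tail)
    clusters: list[Cluster] = []
    with np.errstate(invalid="ignore"):
        tails = []
        if tail in ("two", "greater"):
            tails.append((t_series > crit, 1))
        if tail in ("two", "less"):
            tails.append((t_series < -crit, -1))
    for mask, sign in tails:
        for start, end in _runs(mask):
            seg = t_series[start : end + 1]
            clusters.append(
                Cluster(
                    start_idx=start,
                    end_idx=end,
                    mass=float(seg.sum()),
                    sign=sign,
                    start_s=None if times_s is None else float(times_s[start]),
                    end_s=None if times_s is None else float(times_s[end]),
                )
            )
    clusters.sort(key=lambda c: c.start_idx)
    return clusters


# ---------------------------------------------------------------------------
# permutation null


def _sign_matrix(n_permutations: int, n: int, rng: np.random.Generator) -> np.ndarray:
    """Random sign flips, closed under negation (antithetic halves)."""
    half = n_permutations // 2
    s = rng.integers(0, 2, size=(half, n)) * 2 - 1
    parts = [s, -s]
    if n_permutations % 2:
        parts.append(rng.integers(0, 2, size=(1, n)) * 2 - 1)
    return np.vstack(parts)


def _t_matrix(signs: np.ndarray, values: np.ndarray) -> np.ndarray:
    """t statistics for every sign assignment; permutations x time.

    Sign flips leave per-sample sums of squares unchanged, so only the
    permuted mean needs a matrix product.
    """
    n = values.shape[0]
    mean = signs @ values / n
    ss = (values**2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        var = np.maximum(ss[None, :] - n * mean**2, 0.0) / (n - 1)
        t = mean / np.sqrt(var / n)
    return t


def _max_pos_masses(t_mat: np.ndarray, crit: float) -> np.ndarray:
    """Per row: maximum positive-cluster mass (0 when no cluster)."""
    P, T = t_mat.shape
    t_mat = np.nan_to_num(t_mat, nan=0.0, posinf=_FINITE_CAP, neginf=-_FINITE_CAP)
    mask = np.zeros((P, T + 1), dtype=bool)
    mask[:, :T] = t_mat > crit
    vals = np.zeros((P, T + 1))
    vals[:, :T] = np.where(mask[:, :T], t_mat, 0.0)
    flat_mask = mask.ravel()
    padded = np.concatenate([[False], flat_mask])
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    if len(ends) < len(starts):  # run touching the very end
        ends = np.append(ends, len(flat_mask))
    cums = np.concatenate([[0.0], np.cumsum(vals.ravel())])
    masses = cums[ends] - cums[starts]
    rows = starts // (T + 1)
    out = np.zeros(P)
    np.maximum.at(out, rows, masses)
    return out


def perm_null_one_sample(
    values: np.ndarray,
    n_permutations: int = 5000,
    cluster_alpha: float = 0.05,
    tail: str = "two",
    seed: int | np.random.Generator | None = 0,
) -> np.ndarray:
    """Max-cluster-mass null under per-participant whole-series sign flips.

    Because the flip set is negation-closed, the returned vector serves
    as the null for either tail (positive masses; compare |mass|).
    """
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    signs = _sign_matrix(n_permutations, n, rng)
    crit = critical_t(values.shape[0] - 1, cluster_alpha, tail)
    t_mat = _t_matrix(signs, values)
    return _max_pos_masses(t_mat, crit)


def perm_null_paired(
    cond_a: np.ndarray,
    cond_b: np.ndarray,
    n_permutations: int = 1000,
    cluster_alpha: float = 0.05,
    tail: str = "two",
    seed: int | np.random.Generator | None = 0,
) -> np.ndarray:
    """Within-participant condition-label swaps.

    Swapping A/B inside participant i negates that participant's paired
    difference, so this is exactly the one-sample sign-flip null on
    A - B with the same flip sequence.
    """
    cond_a, cond_b = np.asarray(cond_a, float), np.asarray(cond_b, float)
    if cond_a.shape != cond_b.shape:
        raise ValueError("paired conditions must have identical shape")
    return perm_null_one_sample(
        cond_a - cond_b, n_permutations, cluster_alpha, tail, seed
    )


# ---------------------------------------------------------------------------
# the test


def cluster_test(
    values: np.ndarray,
    n_permutations: int = 5000,
    cluster_alpha: float = 0.05,
    test_alpha: float = 0.05,
    tail: str = "two",
    seed: int | np.random.Generator | None = 0,
    times_s: np.ndarray | None = None,
) -> ClusterTestResult:
    """One-sample cluster permutation test against zero.

    ``values`` is participants x time (difference scores or contrasts).
    Each observed cluster's Monte-Carlo p is (b + 1)/(n_permutations + 1)
    with b the count of null max masses >= |mass|.  Two-tailed results
    are flagged significant at test_alpha / 2 per tail; one-tailed at
    test_alpha.
    """
    values = np.asarray(values, dtype=float)
    t_obs, df = pointwise_t_one_sample(values)
    clusters = form_clusters(t_obs, df, cluster_alpha, tail, times_s)
    null = perm_null_one_sample(values, n_permutations, cluster_alpha, tail, seed)
    alpha_sig = test_alpha / 2 if tail == "two" else test_alpha
    for c in clusters:
        b = int(np.sum(null >= min(abs(c.mass), _FINITE_CAP)))
        c.p = (b + 1) / (n_permutations + 1)
        c.significant = c.p <= alpha_sig
    return ClusterTestResult(
        clusters=clusters,
        n_permutations=n_permutations,
        cluster_alpha=cluster_alpha,
        test_alpha=test_alpha,
        tail=tail,
        df=df,
        t_obs=t_obs,
        null_max_mass=null,
        seed=seed if isinstance(seed, int) else None,
        times_s=times_s,
    )


def paired_cluster_test(
    cond_a: np.ndarray,
    cond_b: np.ndarray,
    n_permutations: int = 1000,
    cluster_alpha: float = 0.05,
    test_alpha: float = 0.05,
    tail: str = "two",
    seed: int | np.random.Generator | None = 0,
    times_s: np.ndarray | None = None,
) -> ClusterTestResult:
    """Dependent-sample cluster permutation test (condition-label swaps)."""
    cond_a, cond_b = np.asarray(cond_a, float), np.asarray(cond_b, float)
    if cond_a.shape != cond_b.shape:
        raise ValueError("paired conditions must have identical shape")
    return cluster_test(
        cond_a - cond_b, n_permutations, cluster_alpha, test_alpha, tail, seed, times_s
    )


# ---------------------------------------------------------------------------
# difference-wave containers and contrasts


@dataclass
class DiffWaveSet:
    """Self-minus-stimulus difference waves per participant and design cell.

    ``values`` is participants x cells x time; a participant missing a
    cell carries NaN there and is excluded from factorial-style tests.
    """

    values: np.ndarray
    cells: list          # list of cell labels, e.g. ("first", 2) or (2, 1)
    times_s: np.ndarray
    participant_ids: list | None = None

    def __post_init__(self) -> None:
        if self.values.shape[1] != len(self.cells):
            raise ValueError("cell labels must match values axis 1")

    def cell(self, label) -> np.ndarray:
        return self.values[:, self.cells.index(label), :]

    def complete_participants(self) -> np.ndarray:
        """Mask of participants with no missing cell."""
        return ~np.isnan(self.values).all(axis=2).any(axis=1)


def build_diff_waves(
    epoch_sets: Sequence,
    roi: Sequence[str],
    cells: Sequence,
    cell_of_trial: Callable,
    transform: Callable | None = None,
) -> DiffWaveSet:
    """Assemble self-minus-stim difference waves from per-participant epochs.

    ``cell_of_trial`` maps a TrialRecord to a cell label or None;
    ``transform`` maps an EpochSet to a trials x time array (default:
    ROI channel average).  Cells with no trials for a participant in
    either condition become NaN.
    """
    cells = list(cells)
    first = epoch_sets[0]
    values = None
    pids = []
    for i, es in enumerate(epoch_sets):
        series = es.roi_average(roi) if transform is None else transform(es)
        if values is None:
            values = np.full((len(epoch_sets), len(cells), series.shape[1]), np.nan)
        pids.append(es.trials[0].participant_id if es.trials else None)
        for j, cell in enumerate(cells):
            means = {}
            for condition in ("self", "stim"):
                rows = [
                    k
                    for k, tr in enumerate(es.trials)
                    if tr.condition == condition and cell_of_trial(tr) == cell
                ]
                if rows:
                    means[condition] = series[rows].mean(axis=0)
            if "self" in means and "stim" in means:
                values[i, j] = means["self"] - means["stim"]
            else:
                logger.info(
                    "build_diff_waves: participant %s missing cell %r", pids[-1], cell
                )
    return DiffWaveSet(
        values=values, cells=cells, times_s=first.times_s, participant_ids=pids
    )


def position_length_cells():
    """The four factorial cells: (position class, sequence length)."""
    return [("first", 2), ("other", 2), ("first", 4), ("other", 4)]


def factorial_cell_of_trial(trial):
    return ("first" if trial.move_position == 1 else "other", trial.sequence_length)


def factorial_contrasts(
    diffwaves: DiffWaveSet,
    n_permutations: int = 5000,
    cluster_alpha: float = 0.05,
    test_alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """2 x 2 factorial on difference waves: position and length main
    effects and their interaction, each as a one-sample cluster test.

    Participants with any missing cell are excluded (logged).
    """
    needed = position_length_cells()
    missing = [c for c in needed if c not in diffwaves.cells]
    if missing:
        raise ValueError(f"difference waves missing cells {missing}")
    complete = diffwaves.complete_participants()
    if not complete.all():
        logger.info(
            "factorial_contrasts: excluding %d participants with missing cells",
            int((~complete).sum()),
        )
    f2 = diffwaves.cell(("first", 2))[complete]
    o2 = diffwaves.cell(("other", 2))[complete]
    f4 = diffwaves.cell(("first", 4))[complete]
    o4 = diffwaves.cell(("other", 4))[complete]
    contrasts = {
        "position": (f2 + f4) / 2 - (o2 + o4) / 2,
        "length": (f4 + o4) / 2 - (f2 + o2) / 2,
        "interaction": (f4 - o4) - (f2 - o2),
    }
    rng = np.random.default_rng(seed)
    out = {}
    for name, contrast in contrasts.items():
        out[name] = cluster_test(
            contrast,
            n_permutations=n_permutations,
            cluster_alpha=cluster_alpha,
            test_alpha=test_alpha,
            tail="two",
            seed=rng,
            times_s=diffwaves.times_s,
        )
        out[name].seed = seed
    return out


def linear_trend(
    position_series: np.ndarray,
    weights: Sequence[float] = LINEAR_TREND_WEIGHTS,
    n_permutations: int = 5000,
    cluster_alpha: float = 0.05,
    test_alpha: float = 0.05,
    seed: int = 0,
    times_s: np.ndarray | None = None,
) -> tuple[np.ndarray, ClusterTestResult]:
    """Linear trend across move positions of four-move sequences.

    ``position_series`` is participants x 4 positions x time; the default
    weights (1.5, 0.5, -0.5, -1.5) test a monotone decline.
    """
    position_series = np.asarray(position_series, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if position_series.shape[1] != len(weights):
        raise ValueError("number of positions must match the contrast weights")
    if abs(weights.sum()) > 1e-12:
        raise ValueError("trend weights must sum to zero")
    complete = ~np.isnan(position_series).all(axis=2).any(axis=1)
    if not complete.all():
        logger.info(
            "linear_trend: excluding %d participants with missing positions",
            int((~complete).sum()),
        )
    contrast = np.tensordot(position_series[complete], weights, axes=([1], [0]))
    result = cluster_test(
        contrast,
        n_permutations=n_permutations,
        cluster_alpha=cluster_alpha,
        test_alpha=test_alpha,
        tail="two",
        seed=seed,
        times_s=times_s,
    )
    return contrast, result


NONFINAL_CELLS = ((2, 1), (4, 1), (4, 2), (4, 3))
FINAL_CELLS = ((2, 2), (4, 4))


def planned_final_vs_nonfinal(
    diffwaves: DiffWaveSet,
    n_permutations: int = 5000,
    cluster_alpha: float = 0.05,
    test_alpha: float = 0.05,
    seed: int = 0,
) -> tuple[np.ndarray, ClusterTestResult]:
    """Nonfinal minus final moves, collapsed across sequence length.

    Cells are (sequence_length, move_position); nonfinal = {2-move first;
    4-move first, second, third}, final = {2-move final; 4-move final}.
    """
    for cell in NONFINAL_CELLS + FINAL_CELLS:
        if cell not in diffwaves.cells:
            raise ValueError(f"difference waves missing cell {cell}")
    complete = diffwaves.complete_participants()
    if not complete.all():
        logger.info(
            "planned_final_vs_nonfinal: excluding %d participants",
            int((~complete).sum()),
        )
    nonfinal = np.mean([diffwaves.cell(c)[complete] for c in NONFINAL_CELLS], axis=0)
    final = np.mean([diffwaves.cell(c)[complete] for c in FINAL_CELLS], axis=0)
    contrast = nonfinal - final
    result = cluster_test(
        contrast,
        n_permutations=n_permutations,
        cluster_alpha=cluster_alpha,
        test_alpha=test_alpha,
        tail="two",
        seed=seed,
        times_s=diffwaves.times_s,
    )
    return contrast, result


def results_table(results: dict) -> pd.DataFrame:
    """Flatten named ClusterTestResults into one per-cluster table."""
    rows = []
    for name, res in results.items():
        if isinstance(res, tuple):
            res = res[1]
        for c in res.clusters:
            rows.append(
                {
                    "analysis": name,
                    "start_s": c.start_s,
                    "end_s": c.end_s,
                    "mass": c.mass,
                    "sign": c.sign,
                    "p": c.p,
                    "significant": c.significant,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["analysis", "start_s", "end_s", "mass", "sign", "p", "significant"],
    )
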