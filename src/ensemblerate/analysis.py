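"""Descriptive statistics: faithful-prediction errors, rating variability,
cross-condition correlations and paired tests, and clustering of fitted
linear-transform parameters.

The *faithful* prediction is the target image's baseline rating on
single-target trials and the arithmetic mean of the four baselines on
combined trials.  Errors are signed data-minus-prediction, so ratings
below the prediction give negative errors.  Per-participant summaries
first average errors within predicted-rating bins (integer ratings for
single-target trials, 1-point-wide half-open bins for combined trials)
and then across bins, so sparsely populated prediction levels are not
swamped by common ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.cluster import KMeans

from .data import BaselineTable, Dataset, TrialRecord, ValidationError
from .fitting import MAIN_CONDITIONS

__all__ = [
    "ErrorSummary",
    "ClusterResult",
    "faithful_prediction",
    "faithful_error",
    "bin_predictions",
    "summarize_errors",
    "summaries_frame",
    "correlate_and_test",
    "cluster_params",
]


def faithful_prediction(trial: TrialRecord, baselines: BaselineTable) -> float:
    """Baseline of the target (1-of-4) or mean of the four baselines (combined)."""
    if trial.trial_type == "one_of_four":
        target = trial.images[trial.target_position - 1]
        return float(baselines.get(trial.participant_id, target))
    values = [baselines.get(trial.participant_id, img) for img in trial.shown_images]
    return float(np.mean(values))


def faithful_error(trial: TrialRecord, baselines: BaselineTable) -> float:
    """Signed error, data minus faithful prediction.

    Requires a baseline rating for every displayed image (not just the
    target), mirroring the completeness the combined prediction needs.
    """
    if trial.response is None:
        raise ValidationError("trial has no response")
    for img in trial.shown_images:
        baselines.get(trial.participant_id, img)
    return float(trial.response) - faithful_prediction(trial, baselines)


def bin_predictions(predictions: Sequence[float], trial_type: str) -> np.ndarray:
    """Integer bin labels (the bin's lower edge) for faithful predictions.

    Single-target predictions are integer baselines, binned at their own
    value (bins 1..9).  Combined predictions fall in 1-point-wide
    half-open bins [1,2), [2,3), ..., [8,9] — the top bin is closed so a
    prediction of exactly 9 lands in bin 8.
    """
    pred = np.asarray(predictions, dtype=float)
    if trial_type == "one_of_four":
        return np.round(pred).astype(int)
    if trial_type == "four_combined":
        return np.minimum(np.floor(pred), 8).astype(int)
    raise ValidationError(f"no binning rule for trial type {trial_type!r}")


@dataclass
class ErrorSummary:
    """Per participant x condition error and variability summary."""

    participant_id: str
    condition: str
    bin_mean_error: dict[int, float]
    bin_counts: dict[int, int]
    overall_mean_error: float
    rating_sd: float
    overall_mode: str = "bins"  # how overall_mean_error aggregates

    @property
    def trial_weighted_mean_error(self) -> float:
        total = sum(self.bin_counts.values())
        return sum(
            self.bin_mean_error[b] * self.bin_counts[b] for b in self.bin_mean_error
        ) / total


def summarize_errors(
    dataset: Dataset,
    conditions: Sequence[str] = MAIN_CONDITIONS,
    overall: str = "bins",
) -> list[ErrorSummary]:
    """Faithful-error and rating-SD summaries per participant x condition.

    ``overall="bins"`` (default) averages the per-bin mean errors with
    equal weight per bin; ``overall="trials"`` averages over trials.  The
    rating SD is computed within each predicted-rating bin (sample SD,
    bins with at least two trials) and then averaged across bins.
    """
    if overall not in ("bins", "trials"):
        raise ValueError(f"unknown overall mode {overall!r}")
    summaries: list[ErrorSummary] = []
    for pid in dataset.participants:
        for condition in conditions:
            trials = dataset.trials_for(pid, condition)
            if not trials:
                raise ValidationError(f"no trials for {pid!r} in condition {condition!r}")
            trial_type = trials[0].trial_type
            pred = np.array([faithful_prediction(t, dataset.baselines) for t in trials])
            resp = np.array([float(t.response) for t in trials])
            err = resp - pred
            bins = bin_predictions(pred, trial_type)

            bin_mean: dict[int, float] = {}
            bin_counts: dict[int, int] = {}
            bin_sds: list[float] = []
            for b in sorted(set(bins.tolist())):
                sel = bins == b
                bin_mean[b] = float(err[sel].mean())
                bin_counts[b] = int(sel.sum())
                if sel.sum() >= 2:
                    bin_sds.append(float(resp[sel].std(ddof=1)))
            overall_mean = (
                float(np.mean(list(bin_mean.values()))) if overall == "bins" else float(err.mean())
            )
            summaries.append(ErrorSummary(
                participant_id=pid, condition=condition,
                bin_mean_error=bin_mean, bin_counts=bin_counts,
                overall_mean_error=overall_mean,
                rating_sd=float(np.mean(bin_sds)) if bin_sds else float("nan"),
                overall_mode=overall,
            ))
    return summaries


def summaries_frame(summaries: Sequence[ErrorSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "participant_id": s.participant_id,
            "condition": s.condition,
            "mean_error": s.overall_mean_error,
            "rating_sd": s.rating_sd,
            "n_bins": len(s.bin_mean_error),
            "n_trials": sum(s.bin_counts.values()),
        }
        for s in summaries
    )


_PAIRS = (
    # (condition A, condition B); mean difference is B minus A
    ("precue_1of4", "postcue_1of4"),
    ("precue_combined", "postcue_combined"),
    ("precue_1of4", "precue_combined"),
    ("postcue_1of4", "postcue_combined"),
)


def correlate_and_test(summaries: Sequence[ErrorSummary]) -> pd.DataFrame:
    """Pearson correlations and paired t-tests across conditions.

    For each measure (mean error, rating SD) and each condition pair:
    Pearson r and p over participants, a two-sided paired t-test, and the
    mean difference (second condition minus first).
    """
    frame = summaries_frame(summaries)
    wide = {
        measure: frame.pivot(index="participant_id", columns="condition", values=measure)
        for measure in ("mean_error", "rating_sd")
    }
    n = len(wide["mean_error"])
    if n < 3:
        raise ValidationError("need at least 3 participants for correlations")
    rows = []
    for measure, table in wide.items():
        for cond_a, cond_b in _PAIRS:
            if cond_a not in table.columns or cond_b not in table.columns:
                continue
            a = table[cond_a].to_numpy(dtype=float)
            b = table[cond_b].to_numpy(dtype=float)
            if np.var(a) == 0 or np.var(b) == 0:
                raise ValidationError(
                    f"zero-variance input for {measure} ({cond_a} vs {cond_b})"
                )
            r, p_r = sps.pearsonr(a, b)
            t, p_t = sps.ttest_rel(b, a)
            rows.append({
                "measure": measure,
                "condition_a": cond_a,
                "condition_b": cond_b,
                "pearson_r": float(r),
                "pearson_p": float(p_r),
                "t": float(t),
                "t_p": float(p_t),
                "mean_difference": float(np.mean(b - a)),
                "n": n,
            })
    return pd.DataFrame(rows)


@dataclass
class ClusterResult:
    k: int
    assignments: np.ndarray
    centroids: np.ndarray
    mean_wss: dict[int, float]  # mean within-cluster sum of squares per k

    def cluster_sizes(self) -> list[int]:
        return [int((self.assignments == j).sum()) for j in range(self.k)]


def cluster_params(
    points: np.ndarray,
    k_max: int = 4,
    seed: int = 0,
    n_restarts: int = 50,
    drop_ratio: float = 0.5,
    force_k: int | None = None,
) -> ClusterResult:
    """k-means over fitted parameter points with an elbow-based choice of k.

    Runs seeded k-means for k = 1..k_max (capped at the number of
    distinct points) and tracks the mean within-cluster sum of squared
    distances.  k is grown while adding a cluster drops that statistic by
    at least ``drop_ratio`` (a 50% drop by default); ``force_k`` bypasses
    the elbow rule.  Clusters are labeled in decreasing size order so
    label 0 is always the largest cluster.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2:
        raise ValidationError("points must be a 2-D array (n_points, n_dims)")
    n_unique = len(np.unique(points, axis=0))
    k_max = min(max(k_max, force_k or 1), n_unique)
    if len(points) < k_max + 1:
        raise ValidationError(f"need more than {k_max} points to consider k up to {k_max}")
    if force_k is not None and force_k > k_max:
        raise ValidationError(f"cannot force k={force_k} with {n_unique} distinct points")

    mean_wss: dict[int, float] = {}
    fits: dict[int, KMeans] = {}
    for k in range(1, k_max + 1):
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
        km.fit(points)
        fits[k] = km
        mean_wss[k] = float(km.inertia_ / len(points))

    if force_k is not None:
        selected = force_k
    else:
        selected = 1
        for k in range(2, k_max + 1):
            previous = mean_wss[k - 1]
            if previous <= 0:
                break
            if mean_wss[k] <= drop_ratio * previous:
                selected = k
            else:
                break

    km = fits[selected]
    labels = km.labels_.copy()
    sizes = np.array([(labels == j).sum() for j in range(selected)])
    order = np.argsort(-sizes, kind="stable")
    relabel = np.empty(selected, dtype=int)
    relabel[order] = np.arange(selected)
    return ClusterResult(
        k=selected,
        assignments=relabel[labels],
        centroids=km.cluster_centers_[order],
        mean_wss=mean_wss,
    )
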