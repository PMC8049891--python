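"""Recompute the study-level headline statistics from a canonical dataset.

Each function maps a :class:`~ensemblerate.data.Dataset` holding the
trial-level ratings of the original experiment (or a synthetic stand-in)
to one of the reported quantities: mean faithful-prediction errors per
condition, attenuation-model parameter means, the faithful model's
winner count, the linear-transform cluster split, and rating-SD
statistics.  :func:`compute_targets` bundles them into a single
machine-readable dict keyed t1..t10.
"""

from __future__ import annotations

import numpy as np

from . import analysis, fitting
from .data import Dataset
from .models import SINGLE_FAMILIES

__all__ = [
    "mean_condition_errors",
    "attenuation_parameter_means",
    "faithful_winner_count",
    "linear_cluster_split",
    "rating_sd_statistics",
    "compute_targets",
]


def mean_condition_errors(dataset: Dataset) -> dict[str, float]:
    """Cross-participant mean faithful-prediction error per condition
    (per-bin means averaged across bins, then across participants)."""
    summaries = analysis.summarize_errors(dataset, overall="bins")
    frame = analysis.summaries_frame(summaries)
    return frame.groupby("condition")["mean_error"].mean().to_dict()


def attenuation_parameter_means(
    dataset: Dataset, condition: str = "postcue_1of4"
) -> tuple[float, float]:
    """Cross-participant means of the fold-averaged (P_beau, g) from the
    high-pleasure attenuation model fitted by LOOCV."""
    beaus, gains = [], []
    for pid in dataset.participants:
        trials = dataset.trials_for(pid, condition)
        cv = fitting.loocv(trials, dataset.baselines, "high_pleasure_attenuation")
        beaus.append(cv.mean_params["P_beau"])
        gains.append(cv.mean_params["g"])
    return float(np.mean(beaus)), float(np.mean(gains))


def faithful_winner_count(dataset: Dataset, condition: str = "precue_1of4") -> int:
    """Participants for whom the faithful model has least-or-tied mean
    held-out RMSE among all eight single-target families."""
    results = []
    for pid in dataset.participants:
        trials = dataset.trials_for(pid, condition)
        for family in SINGLE_FAMILIES:
            results.append(fitting.loocv(trials, dataset.baselines, family))
    table = fitting.compare_models(results).set_index("model")
    return int(table.loc["faithful", "winner_count"])


def linear_cluster_split(
    dataset: Dataset, condition: str = "precue_combined", seed: int = 0
) -> tuple[int, np.ndarray]:
    """k-means (k forced to 2) of per-participant fold-averaged (a, b) of
    the linear-transform combined model; returns (larger cluster size,
    centroids ordered by decreasing cluster size)."""
    points = []
    for pid in dataset.participants:
        trials = dataset.trials_for(pid, condition)
        cv = fitting.loocv(trials, dataset.baselines, "linear_combined")
        points.append([cv.mean_params["a"], cv.mean_params["b"]])
    result = analysis.cluster_params(np.asarray(points), k_max=2, seed=seed, force_k=2)
    return result.cluster_sizes()[0], result.centroids


def rating_sd_statistics(dataset: Dataset) -> dict[str, float]:
    """Per-condition cross-participant mean rating SDs, their maximum,
    and the paired postcue-minus-precue mean difference (each
    participant's SDs averaged over the two trial types per cue timing)."""
    summaries = analysis.summarize_errors(dataset, overall="bins")
    frame = analysis.summaries_frame(summaries)
    wide = frame.pivot(index="participant_id", columns="condition", values="rating_sd")
    cell_means = wide.mean(axis=0)
    post = wide[["postcue_1of4", "postcue_combined"]].mean(axis=1)
    pre = wide[["precue_1of4", "precue_combined"]].mean(axis=1)
    out = {f"mean_sd:{cond}": float(cell_means[cond]) for cond in cell_means.index}
    out["max_cell_sd"] = float(cell_means.max())
    out["postcue_minus_precue_sd"] = float((post - pre).mean())
    return out


def compute_targets(dataset: Dataset, seed: int = 0) -> dict[str, dict]:
    """All reported statistics, keyed t1..t10, as {value, n} records."""
    n_participants = len(dataset.participants)
    errors = mean_condition_errors(dataset)
    p_beau, gain = attenuation_parameter_means(dataset)
    winners = faithful_winner_count(dataset)
    big_cluster, _ = linear_cluster_split(dataset, seed=seed)
    sds = rating_sd_statistics(dataset)
    return {
        "t1": {"value": errors["precue_1of4"], "n": n_participants},
        "t2": {"value": errors["postcue_1of4"], "n": n_participants},
        "t3": {"value": errors["precue_combined"], "n": n_participants},
        "t4": {"value": errors["postcue_combined"], "n": n_participants},
        "t5": {"value": p_beau, "n": n_participants},
        "t6": {"value": gain, "n": n_participants},
        "t7": {"value": winners, "n": n_participants},
        "t8": {"value": big_cluster, "n": n_participants},
        "t9": {"value": sds["postcue_minus_precue_sd"], "n": n_participants},
        "t10": {"value": sds["max_cell_sd"], "n": n_participants},
    }
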