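"""End-to-end orchestration: simulate (or import) -> fit -> analyze -> report.

A run produces a *bundle* directory::

    out/
      dataset/trials.csv, baselines.csv, metadata.json
      fits.csv              one row per participant x condition x model
      comparison.csv        cross-participant RMSE means, SEMs, winner counts
      error_summaries.csv   faithful-error and rating-SD summaries
      stats_tests.csv       correlations and paired tests
      clusters.json         k-means of linear-transform (a, b) per condition
      manifest.json         the resolved configuration

All outputs are plain text and byte-stable for a fixed configuration.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import analysis, fitting
from .data import Dataset, ValidationError, import_deposited, read_dataset, write_dataset
from .synth import DesignSpec, configs_from_population, simulate_dataset

__all__ = ["RunConfig", "run_pipeline", "make_report"]

log = logging.getLogger("ensemblerate")


@dataclass
class RunConfig:
    seed: int
    out_dir: str
    design: dict = field(default_factory=dict)
    observer_population: dict | None = None
    deposited_path: str | None = None
    deposited_column_map: dict | None = None
    models: Sequence[str] | None = None
    conditions: Sequence[str] | None = None
    cv_mode: str = "per_fold"
    error_overall: str = "bins"
    cluster_k_max: int = 4

    @classmethod
    def from_mapping(cls, raw: Mapping) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**dict(raw))

    def validate(self) -> None:
        synthetic = self.deposited_path is None
        if not synthetic and self.observer_population is not None:
            raise ValidationError("configure either a synthetic population or a deposited path, not both")
        if synthetic and self.seed is None:
            raise ValidationError("synthetic runs require a seed")
        if self.cv_mode not in ("per_fold", "pooled"):
            raise ValidationError(f"unknown cv_mode {self.cv_mode!r}")
        if self.error_overall not in ("bins", "trials"):
            raise ValidationError(f"unknown error_overall {self.error_overall!r}")


def _stage(name: str):
    log.info("stage %s", name)
    return time.monotonic()


def build_dataset(config: RunConfig) -> Dataset:
    if config.deposited_path is not None:
        if not config.deposited_column_map:
            raise ValidationError("deposited runs need deposited_column_map")
        return import_deposited(config.deposited_path, config.deposited_column_map)
    design = DesignSpec(seed=config.seed, **config.design)
    configs = configs_from_population(
        config.observer_population or {}, design.n_participants, config.seed,
        image_ids=design.image_ids(),
    )
    return simulate_dataset(design, configs)


def cluster_frame_to_json(clusters: dict[str, analysis.ClusterResult],
                          participants: dict[str, list[str]]) -> dict:
    return {
        condition: {
            "k": result.k,
            "centroids": [[round(float(v), 10) for v in c] for c in result.centroids],
            "cluster_sizes": result.cluster_sizes(),
            "assignments": {
                pid: int(label)
                for pid, label in zip(participants[condition], result.assignments)
            },
            "mean_wss": {str(k): result.mean_wss[k] for k in sorted(result.mean_wss)},
        }
        for condition, result in clusters.items()
    }


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages; returns the bundle directory."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    started = _stage("dataset")
    try:
        dataset = build_dataset(config)
        write_dataset(dataset, out / "dataset")
    except Exception as exc:
        raise RuntimeError(f"stage 'dataset' failed: {exc}") from exc
    log.info("dataset: %d trials in %.1fs", len(dataset.trials), time.monotonic() - started)

    started = _stage("fit")
    try:
        fits, cv_results = fitting.fit_all(
            dataset, models=config.models, conditions=config.conditions, mode=config.cv_mode
        )
        comparison = fitting.compare_models(cv_results)
    except Exception as exc:
        raise RuntimeError(f"stage 'fit' failed: {exc}") from exc
    fits.to_csv(out / "fits.csv", index=False)
    comparison.to_csv(out / "comparison.csv", index=False)
    log.info("fit: %d cells in %.1fs", len(fits), time.monotonic() - started)

    started = _stage("analyze")
    try:
        conditions = tuple(config.conditions) if config.conditions else fitting.MAIN_CONDITIONS
        summaries = analysis.summarize_errors(dataset, conditions, overall=config.error_overall)
        analysis.summaries_frame(summaries).to_csv(out / "error_summaries.csv", index=False)
        tests = analysis.correlate_and_test(summaries) if len(dataset.participants) >= 3 else pd.DataFrame()
        tests.to_csv(out / "stats_tests.csv", index=False)

        clusters: dict[str, analysis.ClusterResult] = {}
        cluster_pids: dict[str, list[str]] = {}
        for condition in conditions:
            if not condition.endswith("combined"):
                continue
            sub = fits[(fits["condition"] == condition) & (fits["model"] == "linear_combined")]
            if len(sub) <= config.cluster_k_max:
                continue
            points = sub[["param:a", "param:b"]].to_numpy(dtype=float)
            clusters[condition] = analysis.cluster_params(
                points, k_max=config.cluster_k_max, seed=config.seed
            )
            cluster_pids[condition] = sub["participant_id"].tolist()
        (out / "clusters.json").write_text(
            json.dumps(cluster_frame_to_json(clusters, cluster_pids), indent=2)
        )
    except Exception as exc:
        raise RuntimeError(f"stage 'analyze' failed: {exc}") from exc
    log.info("analyze: done in %.1fs", time.monotonic() - started)

    manifest = {
        "config": {
            **dataclasses.asdict(config),
            "models": list(config.models) if config.models else None,
            "conditions": list(config.conditions) if config.conditions else None,
        },
        "n_trials": len(dataset.trials),
        "n_participants": len(dataset.participants),
        "provenance": dataset.provenance,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------


def make_report(bundle: str | Path, out_dir: str | Path | None = None) -> Path:
    """Render a human-readable report (markdown + figures) from a bundle.

    Missing optional artifacts (e.g. no cluster result) produce a note in
    the report instead of an error; missing core tables raise.
    """
    bundle = Path(bundle)
    out = Path(out_dir) if out_dir else bundle / "report"
    out.mkdir(parents=True, exist_ok=True)

    for required in ("fits.csv", "comparison.csv", "error_summaries.csv"):
        if not (bundle / required).exists():
            raise FileNotFoundError(f"bundle incomplete: missing {required}")

    comparison = pd.read_csv(bundle / "comparison.csv")
    summaries = pd.read_csv(bundle / "error_summaries.csv")

    lines = ["# Run report", ""]
    lines.append("## Faithful-prediction errors and rating variability")
    lines.append("")
    agg = summaries.groupby("condition")[["mean_error", "rating_sd"]].mean().round(3)
    lines.append(agg.to_markdown())
    lines.append("")

    lines.append("## Model comparison (held-out RMSE)")
    lines.append("")
    show = comparison.copy()
    show[["mean_rmse", "sem"]] = show[["mean_rmse", "sem"]].round(3)
    lines.append(show.to_markdown(index=False))
    lines.append("")
    for condition, sub in comparison.groupby("condition"):
        best = sub.loc[sub["mean_rmse"].idxmin()]
        lines.append(
            f"- best model for `{condition}`: **{best['model']}** "
            f"(mean RMSE {best['mean_rmse']:.3f}, winner count "
            f"{int(best['winner_count'])}/{int(best['n_participants'])})"
        )
    lines.append("")

    lines.append("## Clusters of linear-transform parameters")
    lines.append("")
    clusters_path = bundle / "clusters.json"
    clusters = json.loads(clusters_path.read_text()) if clusters_path.exists() else {}
    if not clusters:
        lines.append("_No cluster result available for this run._")
    for condition, result in clusters.items():
        lines.append(
            f"- `{condition}`: k = {result['k']}, sizes {result['cluster_sizes']}, "
            f"centroids (a, b) = "
            + ", ".join(f"({c[0]:.2f}, {c[1]:.2f})" for c in result["centroids"])
        )
    lines.append("")

    tests_path = bundle / "stats_tests.csv"
    if tests_path.exists():
        tests = pd.read_csv(tests_path)
        if len(tests):
            lines.append("## Correlations and paired tests")
            lines.append("")
            rounded = tests.copy()
            for col in ("pearson_r", "pearson_p", "t", "t_p", "mean_difference"):
                rounded[col] = rounded[col].round(3)
            lines.append(rounded.to_markdown(index=False))
            lines.append("")

    _plot_figures(comparison, summaries, clusters, bundle, out)
    report_path = out / "report.md"
    report_path.write_text("\n".join(lines))
    return report_path


def _plot_figures(comparison: pd.DataFrame, summaries: pd.DataFrame,
                  clusters: dict, bundle: Path, out: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    # RMSE bars per condition
    conditions = comparison["condition"].unique()
    fig, axes = plt.subplots(1, len(conditions), figsize=(4 * len(conditions), 3.2), squeeze=False)
    for ax, condition in zip(axes[0], conditions):
        sub = comparison[comparison["condition"] == condition]
        ax.bar(range(len(sub)), sub["mean_rmse"], yerr=sub["sem"], color="0.6")
        ax.set_xticks(range(len(sub)))
        ax.set_xticklabels(sub["model"], rotation=60, ha="right", fontsize=7)
        ax.set_title(condition, fontsize=9)
        ax.set_ylabel("held-out RMSE")
    fig.tight_layout()
    fig.savefig(out / "model_rmse.png", dpi=120)
    plt.close(fig)

    # mean error scatter precue vs postcue
    wide = summaries.pivot(index="participant_id", columns="condition", values="mean_error")
    pairs = [("precue_1of4", "postcue_1of4"), ("precue_combined", "postcue_combined")]
    pairs = [p for p in pairs if p[0] in wide.columns and p[1] in wide.columns]
    if pairs:
        fig, axes = plt.subplots(1, len(pairs), figsize=(4 * len(pairs), 3.6), squeeze=False)
        for ax, (ca, cb) in zip(axes[0], pairs):
            ax.scatter(wide[ca], wide[cb], s=18, color="0.3")
            lim = [wide[[ca, cb]].min().min() - 0.2, wide[[ca, cb]].max().max() + 0.2]
            ax.plot(lim, lim, "k--", lw=0.8)
            ax.axhline(0, color="0.8", lw=0.8)
            ax.axvline(0, color="0.8", lw=0.8)
            ax.set_xlabel(f"mean error, {ca}")
            ax.set_ylabel(f"mean error, {cb}")
        fig.tight_layout()
        fig.savefig(out / "error_scatter.png", dpi=120)
        plt.close(fig)

    if clusters:
        fits = pd.read_csv(bundle / "fits.csv")
        fig, axes = plt.subplots(1, len(clusters), figsize=(4 * len(clusters), 3.6), squeeze=False)
        for ax, (condition, result) in zip(axes[0], clusters.items()):
            sub = fits[(fits["condition"] == condition) & (fits["model"] == "linear_combined")]
            labels = [result["assignments"][pid] for pid in sub["participant_id"]]
            ax.scatter(sub["param:a"], sub["param:b"], c=labels, cmap="coolwarm", s=20)
            cents = np.array(result["centroids"])
            ax.scatter(cents[:, 0], cents[:, 1], marker="x", color="k", s=60)
            ax.set_xlabel("a (intercept)")
            ax.set_ylabel("b (slope)")
            ax.set_title(condition, fontsize=9)
        fig.tight_layout()
        fig.savefig(out / "clusters.png", dpi=120)
        plt.close(fig)
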