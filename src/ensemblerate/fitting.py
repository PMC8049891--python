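"""Per-participant model fitting, leave-one-out cross-validation, and
cross-participant model comparison.

Fitting minimizes the root-mean-square error (RMSE) between a model's
deterministic predictions and the observed trial-level ratings, subject
to the family's box bounds (plus a simplex constraint for the weighted
families).  To stay deterministic while being robust to the local minima
of the piecewise families, the optimizer is restarted from a fixed grid
of start points (three values per parameter spanning the bounds; simplex
parameters use the uniform point and the vertices).  Families whose
objective is quadratic in the parameters (the linear transforms and the
average-biased weight) are solved in closed form when the least-squares
solution lies inside the bounds.

LOOCV refits on every leave-one-out fold.  With one left-out trial the
per-fold test RMSE is that trial's absolute error, so the default
``mode="per_fold"`` summary is the mean absolute held-out error; the
alternative reading — pool all held-out errors before taking the root —
is available as ``mode="pooled"``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .data import BaselineTable, Dataset, TrialRecord, ValidationError
from .models import COMBINED_FAMILIES, SINGLE_FAMILIES, ModelSpec, get_model

__all__ = [
    "FitResult",
    "CVResult",
    "trial_arrays",
    "fit_model",
    "loocv",
    "compare_models",
    "fit_all",
    "MAIN_CONDITIONS",
    "families_for_condition",
]

MAIN_CONDITIONS = ("precue_1of4", "postcue_1of4", "precue_combined", "postcue_combined")

_TIE_TOL = 1e-9
_VAR_EPS = 1e-12


def families_for_condition(condition: str) -> tuple[str, ...]:
    return SINGLE_FAMILIES if condition.endswith("1of4") else COMBINED_FAMILIES


@dataclass
class FitResult:
    model: str
    params: dict[str, float]
    train_rmse: float
    degenerate: bool = False

    def params_array(self) -> np.ndarray:
        spec = get_model(self.model)
        return spec.params_array(self.params)


@dataclass
class CVResult:
    """Leave-one-out results for one participant x model x condition."""

    participant_id: str
    model: str
    condition: str
    fold_params: np.ndarray  # (n_folds, n_params)
    heldout_pred: np.ndarray
    heldout_err: np.ndarray  # response - prediction
    mean_heldout_rmse: float
    mean_params: dict[str, float]
    mode: str = "per_fold"

    @property
    def n_folds(self) -> int:
        return len(self.heldout_err)

    @property
    def per_fold_rmse(self) -> float:
        return float(np.mean(np.abs(self.heldout_err)))

    @property
    def pooled_rmse(self) -> float:
        return float(np.sqrt(np.mean(self.heldout_err**2)))


# ---------------------------------------------------------------------------
# design arrays
# ---------------------------------------------------------------------------


def trial_arrays(
    trials: Sequence[TrialRecord], baselines: BaselineTable
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(P, t, y): baselines at the four positions, 1-based target, response.

    ``t`` is 0 on four_combined trials (unused by combined families).
    """
    if not trials:
        raise ValidationError("no trials to fit")
    P = np.empty((len(trials), 4))
    t = np.zeros(len(trials), dtype=int)
    y = np.empty(len(trials))
    for i, trial in enumerate(trials):
        if trial.trial_type == "baseline":
            raise ValidationError("baseline trials cannot be fitted")
        if trial.response is None:
            raise ValidationError("cannot fit trials without responses")
        P[i] = [baselines.get(trial.participant_id, img) for img in trial.images]
        y[i] = trial.response
        if trial.trial_type == "one_of_four":
            t[i] = trial.target_position
    return P, t, y


def _rmse(pred: np.ndarray, y: np.ndarray) -> float:
    return float(np.sqrt(np.mean((pred - y) ** 2)))


# ---------------------------------------------------------------------------
# optimizer machinery
# ---------------------------------------------------------------------------


def _grid_starts(spec: ModelSpec) -> list[np.ndarray]:
    """Fixed deterministic multi-start grid spanning the bounds."""
    if spec.n_params == 0:
        return [np.empty(0)]
    simplex_idx = [spec.param_names.index(p) for p in spec.simplex_params]
    plain_idx = [i for i in range(spec.n_params) if i not in simplex_idx]

    plain_axes = [
        (spec.lower[i], 0.5 * (spec.lower[i] + spec.upper[i]), spec.upper[i])
        for i in plain_idx
    ]
    if simplex_idx:
        k = len(simplex_idx)
        simplex_starts = [np.full(k, 1.0 / (k + 1))]  # uniform over all k+1 weights
        simplex_starts += [np.eye(k)[j] * (1 - 1e-6) for j in range(k)]
        simplex_starts.append(np.zeros(k))  # all mass on the implicit weight
    else:
        simplex_starts = [np.empty(0)]

    starts: list[np.ndarray] = []
    for plain in itertools.product(*plain_axes) if plain_axes else [()]:
        for simp in simplex_starts:
            x = np.empty(spec.n_params)
            for i, v in zip(plain_idx, plain):
                x[i] = v
            for i, v in zip(simplex_idx, simp):
                x[i] = v
            starts.append(x)
    # dedupe, preserving order
    seen: set[tuple] = set()
    unique = []
    for x in starts:
        key = tuple(np.round(x, 12))
        if key not in seen:
            seen.add(key)
            unique.append(x)
    return unique


def _project(spec: ModelSpec, x: np.ndarray) -> np.ndarray:
    x = np.clip(x, spec.lower, spec.upper)
    if spec.simplex_params:
        idx = [spec.param_names.index(p) for p in spec.simplex_params]
        total = x[idx].sum()
        if total > 1.0:
            x[idx] *= 1.0 / total
    return x


def _minimize(spec: ModelSpec, P: np.ndarray, t: np.ndarray, y: np.ndarray,
              starts: Iterable[np.ndarray]) -> tuple[np.ndarray, float]:
    def objective(x: np.ndarray) -> float:
        return _rmse(spec._predict(x, P, t), y)

    bounds = list(zip(spec.lower, spec.upper))
    best_x: np.ndarray | None = None
    best_f = np.inf
    if spec.simplex_params:
        idx = [spec.param_names.index(p) for p in spec.simplex_params]
        constraints = [{"type": "ineq", "fun": lambda x: 1.0 - x[idx].sum()}]
        method = "SLSQP"
    else:
        constraints = []
        method = "L-BFGS-B"
    for x0 in starts:
        res = optimize.minimize(
            objective, _project(spec, np.array(x0, dtype=float)),
            method=method, bounds=bounds, constraints=constraints,
            options={"maxiter": 200},
        )
        x = _project(spec, res.x)
        f = objective(x)
        if f < best_f - _TIE_TOL or best_x is None:
            best_x, best_f = x, f
    assert best_x is not None
    return best_x, best_f


def _closed_form(spec: ModelSpec, P: np.ndarray, t: np.ndarray,
                 y: np.ndarray) -> tuple[np.ndarray, bool] | None:
    """Exact RMSE minimizer for the quadratic-objective families.

    Returns ``(params, degenerate)`` or ``None`` when the closed form
    does not apply (family not quadratic, or the unconstrained optimum
    leaves the bounds and a numeric solve is needed).
    """
    if spec.name in ("linear_single", "linear_combined"):
        x = P[np.arange(len(P)), t - 1] if spec.name == "linear_single" else P.mean(axis=1)
        var = float(np.var(x))
        if var < _VAR_EPS:
            # all predictors identical: best constant fit
            return np.array([float(np.clip(np.mean(y), spec.lower[0], spec.upper[0])), 0.0]), True
        b = float(np.cov(x, y, bias=True)[0, 1] / var)
        a = float(np.mean(y) - b * np.mean(x))
        params = np.array([a, b])
        if np.all(params >= spec.lower) and np.all(params <= spec.upper):
            return params, False
        return None
    if spec.name == "average_biased":
        pt = P[np.arange(len(P)), t - 1]
        z = P.mean(axis=1) - pt
        denom = float(np.sum(z * z))
        if denom < _VAR_EPS:
            return np.array([0.0]), True
        w = float(np.sum(z * (y - pt)) / denom)
        return np.array([np.clip(w, 0.0, 1.0)]), False  # 1-D quadratic: clip is exact
    return None


def _fit_arrays(spec: ModelSpec, P: np.ndarray, t: np.ndarray, y: np.ndarray,
                starts: Sequence[np.ndarray] | None = None) -> FitResult:
    if spec.n_params == 0:
        return FitResult(spec.name, {}, _rmse(spec._predict(np.empty(0), P, t), y))
    degenerate = bool(np.ptp(P) < _VAR_EPS)
    closed = _closed_form(spec, P, t, y)
    if closed is not None:
        params, flat = closed
        return FitResult(
            spec.name, spec.params_dict(params),
            _rmse(spec._predict(params, P, t), y),
            degenerate=degenerate or flat,
        )
    if starts is None:
        starts = _grid_starts(spec)
    x, f = _minimize(spec, P, t, y, starts)
    return FitResult(spec.name, spec.params_dict(x), f, degenerate=degenerate)


# ---------------------------------------------------------------------------
# public fitting API
# ---------------------------------------------------------------------------


def _check_trials(trials: Sequence[TrialRecord], spec: ModelSpec, min_extra: int) -> None:
    types = {trial.trial_type for trial in trials}
    if len(types) > 1:
        raise ValidationError(f"trials mix types {sorted(types)}; fit one condition at a time")
    trial_type = types.pop() if types else None
    wanted = "one_of_four" if spec.kind == "single" else "four_combined"
    if trial_type != wanted:
        raise ValidationError(f"model {spec.name} applies to {wanted} trials, got {trial_type}")
    if len(trials) < spec.n_params + min_extra:
        raise ValidationError(
            f"{spec.name} needs at least {spec.n_params + min_extra} trials, got {len(trials)}"
        )


def fit_model(
    trials: Sequence[TrialRecord],
    baselines: BaselineTable,
    model: str,
    starts: Sequence[np.ndarray] | None = None,
) -> FitResult:
    """Fit one family to one participant-condition's trials by RMSE.

    Degenerate inputs (all baselines identical) are flagged on the
    result; the returned parameters then give the best constant fit.
    """
    spec = get_model(model)
    _check_trials(trials, spec, min_extra=1)
    P, t, y = trial_arrays(trials, baselines)
    return _fit_arrays(spec, P, t, y, starts)


def loocv(
    trials: Sequence[TrialRecord],
    baselines: BaselineTable,
    model: str,
    mode: str = "per_fold",
    warm: bool = True,
) -> CVResult:
    """Leave-one-out cross-validation for one participant x model x condition.

    Each fold refits on all trials but one and predicts the held-out
    trial.  ``warm=True`` starts each fold's optimizer from the full-data
    multi-start optimum (folds differ from the full data by one trial, so
    this is both fast and deterministic); ``warm=False`` reruns the full
    grid per fold.  Closed-form families are solved exactly per fold
    either way.
    """
    if mode not in ("per_fold", "pooled"):
        raise ValueError(f"unknown LOOCV mode {mode!r}")
    spec = get_model(model)
    _check_trials(trials, spec, min_extra=2)
    P, t, y = trial_arrays(trials, baselines)
    n = len(y)
    participant = trials[0].participant_id
    condition = trials[0].condition

    fold_params = np.empty((n, spec.n_params))
    pred = np.empty(n)
    if spec.n_params == 0:
        # no fitting occurs: held-out predictions equal full-data predictions
        pred[:] = spec._predict(np.empty(0), P, t)
    else:
        full = _fit_arrays(spec, P, t, y)
        warm_starts = [full.params_array()] if warm else None
        mask = np.ones(n, dtype=bool)
        for i in range(n):
            mask[i] = False
            fit = _fit_arrays(spec, P[mask], t[mask], y[mask], starts=warm_starts)
            mask[i] = True
            x = fit.params_array()
            fold_params[i] = x
            pred[i] = spec._predict(x, P[i: i + 1], t[i: i + 1])[0]

    err = y - pred
    summary = float(np.mean(np.abs(err))) if mode == "per_fold" else float(np.sqrt(np.mean(err**2)))
    mean_params = spec.params_dict(fold_params.mean(axis=0)) if spec.n_params else {}
    return CVResult(
        participant_id=participant, model=model, condition=condition,
        fold_params=fold_params, heldout_pred=pred, heldout_err=err,
        mean_heldout_rmse=summary, mean_params=mean_params, mode=mode,
    )


def compare_models(cv_results: Sequence[CVResult], tie_tol: float = _TIE_TOL) -> pd.DataFrame:
    """Cross-participant comparison table per condition.

    Columns: ``condition, model, mean_rmse, sem, winner_count, n_participants``.
    ``winner_count`` counts the participants for whom the model's mean
    held-out RMSE is least or within ``tie_tol`` of the least, so ties
    credit every tied model.  Raises on an incomplete participant x model
    grid within a condition.
    """
    if not cv_results:
        raise ValidationError("no CV results to compare")
    frame = pd.DataFrame(
        {
            "participant_id": r.participant_id,
            "condition": r.condition,
            "model": r.model,
            "rmse": r.mean_heldout_rmse,
        }
        for r in cv_results
    )
    rows = []
    for condition, sub in frame.groupby("condition", sort=False):
        cell = sub.pivot_table(index="participant_id", columns="model", values="rmse")
        if cell.isna().any().any():
            missing = [
                (pid, model)
                for pid in cell.index
                for model in cell.columns
                if pd.isna(cell.loc[pid, model])
            ]
            raise ValidationError(f"{condition}: missing participant x model cells {missing}")
        mins = cell.min(axis=1)
        for model in sub["model"].unique():
            values = cell[model]
            rows.append({
                "condition": condition,
                "model": model,
                "mean_rmse": float(values.mean()),
                "sem": float(values.std(ddof=1) / np.sqrt(len(values))) if len(values) > 1 else 0.0,
                "winner_count": int((values <= mins + tie_tol).sum()),
                "n_participants": int(len(values)),
            })
    return pd.DataFrame(rows)


def fit_all(
    dataset: Dataset,
    models: Sequence[str] | None = None,
    conditions: Sequence[str] | None = None,
    mode: str = "per_fold",
    warm: bool = True,
) -> tuple[pd.DataFrame, list[CVResult]]:
    """LOOCV every applicable (participant, condition, model) cell.

    Returns a tidy results frame (one row per cell, fold-averaged
    parameters in ``param:<name>`` columns) plus the raw CV results.
    """
    conditions = tuple(conditions) if conditions else MAIN_CONDITIONS
    results: list[CVResult] = []
    rows = []
    for pid in dataset.participants:
        for condition in conditions:
            trials = dataset.trials_for(pid, condition)
            if not trials:
                continue
            wanted = tuple(models) if models else families_for_condition(condition)
            for family in wanted:
                if get_model(family).kind != (
                    "single" if condition.endswith("1of4") else "combined"
                ):
                    continue
                cv = loocv(trials, dataset.baselines, family, mode=mode, warm=warm)
                results.append(cv)
                row = {
                    "participant_id": pid,
                    "condition": condition,
                    "model": family,
                    "n_trials": cv.n_folds,
                    "mean_heldout_rmse": cv.mean_heldout_rmse,
                }
                for name, value in cv.mean_params.items():
                    row[f"param:{name}"] = value
                rows.append(row)
    return pd.DataFrame(rows), results
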