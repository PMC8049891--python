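"""Deterministic rating models for single-target and combined trials.

Every model maps the four displayed images' baseline pleasures
``P = (P_1, ..., P_4)`` (and, for single-target models, the cued position
``t``) to a real-valued predicted rating.  Predictions are deliberately
*not* clipped to the 1-9 response range: clipping belongs to the response
stage of the simulator, and an un-clipped prediction lets the RMSE cost
penalize out-of-range fits naturally.

Single-target families
    faithful                    P̂ = P_t
    averaging                   P̂ = P̄
    average_biased              P̂ = (1-w) P_t + w P̄,          0 ≤ w ≤ 1
    weighted_avg_position       P̂ = Σ_i w_i P_i,  w on the simplex (3 free)
    weighted_avg_biased         P̂ = (1-w) P_t + w Σ_i v_i P_i, v simplex
    linear_single               P̂ = a + b P_t
    weighted_avg_pleasure_rank  P̂ = Σ_k u_k P_(k)  (baselines sorted
                                descending; rank-indexed simplex weights)
    high_pleasure_attenuation   P̂ = P_t if P_t < P_beau,
                                else P_beau + g (P_t - P_beau)

Combined families
    faithful_averaging          P̂ = P̄
    linear_combined             P̂ = a + b P̄
    attenuation_combined        the attenuation rule applied to P̄

with P̄ the arithmetic mean of the four baselines.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np

__all__ = [
    "ModelSpec",
    "SINGLE_FAMILIES",
    "COMBINED_FAMILIES",
    "get_model",
    "predict_single",
    "predict_combined",
]

_BOUND_EPS = 1e-9


@dataclass(frozen=True)
class ModelSpec:
    """A model family: named box-bounded parameters plus a predictor.

    ``simplex_params`` names parameters that are free coordinates of a
    probability simplex — each lies in [0, 1] and their sum must not
    exceed 1 (the remaining simplex mass is the implicit last weight).
    """

    name: str
    kind: str  # "single" | "combined"
    param_names: tuple[str, ...]
    lower: tuple[float, ...]
    upper: tuple[float, ...]
    _predict: Callable[[np.ndarray, np.ndarray, np.ndarray], np.ndarray]
    simplex_params: tuple[str, ...] = ()

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def params_array(self, params: Mapping[str, float] | Sequence[float] | None) -> np.ndarray:
        if params is None:
            params = {}
        if isinstance(params, Mapping):
            unknown = set(params) - set(self.param_names)
            if unknown:
                raise ValueError(f"{self.name}: unknown parameter(s) {sorted(unknown)}")
            missing = [p for p in self.param_names if p not in params]
            if missing:
                raise ValueError(f"{self.name}: missing parameter(s) {missing}")
            values = np.array([float(params[p]) for p in self.param_names])
        else:
            values = np.asarray(params, dtype=float)
            if values.shape != (self.n_params,):
                raise ValueError(
                    f"{self.name}: expected {self.n_params} parameters, got {values.shape}"
                )
        return values

    def params_dict(self, values: Sequence[float]) -> dict[str, float]:
        return {name: float(v) for name, v in zip(self.param_names, values)}

    def validate_params(self, values: np.ndarray) -> None:
        lower = np.asarray(self.lower)
        upper = np.asarray(self.upper)
        if np.any(values < lower - _BOUND_EPS) or np.any(values > upper + _BOUND_EPS):
            raise ValueError(
                f"{self.name}: parameters {self.params_dict(values)} outside bounds"
            )
        if self.simplex_params:
            idx = [self.param_names.index(p) for p in self.simplex_params]
            if values[idx].sum() > 1.0 + _BOUND_EPS:
                raise ValueError(
                    f"{self.name}: simplex parameters {self.simplex_params} sum above 1"
                )

    def predict(
        self,
        params: Mapping[str, float] | Sequence[float] | None,
        P: np.ndarray,
        t: np.ndarray | int | None = None,
    ) -> np.ndarray | float:
        """Validated prediction; vectorized over trials.

        ``P`` is ``(4,)`` or ``(n, 4)``; ``t`` is a 1-based position
        (scalar or ``(n,)``), required for single-target families.
        """
        values = self.params_array(params)
        self.validate_params(values)
        P = np.asarray(P, dtype=float)
        scalar = P.ndim == 1
        P2 = np.atleast_2d(P)
        if P2.shape[1] != 4:
            raise ValueError("P must have four baseline pleasures per trial")
        if self.kind == "single":
            if t is None:
                raise ValueError(f"{self.name} requires a target position")
            tarr = np.broadcast_to(np.asarray(t, dtype=int), (P2.shape[0],))
            if np.any((tarr < 1) | (tarr > 4)):
                raise ValueError("target position must be in 1..4")
        else:
            tarr = np.zeros(P2.shape[0], dtype=int)
        out = self._predict(values, P2, tarr)
        return float(out[0]) if scalar else out


def _target(P: np.ndarray, t: np.ndarray) -> np.ndarray:
    return P[np.arange(P.shape[0]), t - 1]


def _attenuate(x: np.ndarray, p_beau: float, g: float) -> np.ndarray:
    return np.where(x < p_beau, x, p_beau + g * (x - p_beau))


def _simplex_full(free: np.ndarray) -> np.ndarray:
    return np.append(free, 1.0 - free.sum())


_SPECS: dict[str, ModelSpec] = {}


def _register(spec: ModelSpec) -> None:
    _SPECS[spec.name] = spec


_register(ModelSpec(
    name="faithful", kind="single", param_names=(), lower=(), upper=(),
    _predict=lambda v, P, t: _target(P, t),
))
_register(ModelSpec(
    name="averaging", kind="single", param_names=(), lower=(), upper=(),
    _predict=lambda v, P, t: P.mean(axis=1),
))
_register(ModelSpec(
    name="average_biased", kind="single",
    param_names=("w",), lower=(0.0,), upper=(1.0,),
    _predict=lambda v, P, t: (1 - v[0]) * _target(P, t) + v[0] * P.mean(axis=1),
))
_register(ModelSpec(
    name="weighted_avg_position", kind="single",
    param_names=("w1", "w2", "w3"), lower=(0.0,) * 3, upper=(1.0,) * 3,
    simplex_params=("w1", "w2", "w3"),
    _predict=lambda v, P, t: P @ _simplex_full(v),
))
_register(ModelSpec(
    name="weighted_avg_biased", kind="single",
    param_names=("w", "v1", "v2", "v3"),
    lower=(0.0,) * 4, upper=(1.0,) * 4,
    simplex_params=("v1", "v2", "v3"),
    _predict=lambda v, P, t: (1 - v[0]) * _target(P, t) + v[0] * (P @ _simplex_full(v[1:])),
))
_register(ModelSpec(
    name="linear_single", kind="single",
    param_names=("a", "b"), lower=(-8.0, 0.0), upper=(8.0, 2.0),
    _predict=lambda v, P, t: v[0] + v[1] * _target(P, t),
))
_register(ModelSpec(
    name="weighted_avg_pleasure_rank", kind="single",
    param_names=("u1", "u2", "u3"), lower=(0.0,) * 3, upper=(1.0,) * 3,
    simplex_params=("u1", "u2", "u3"),
    # baselines sorted descending per trial; weights indexed by pleasure rank
    _predict=lambda v, P, t: -np.sort(-P, axis=1) @ _simplex_full(v),
))
_register(ModelSpec(
    name="high_pleasure_attenuation", kind="single",
    param_names=("P_beau", "g"), lower=(1.0, 0.0), upper=(9.0, 1.0),
    _predict=lambda v, P, t: _attenuate(_target(P, t), v[0], v[1]),
))

_register(ModelSpec(
    name="faithful_averaging", kind="combined", param_names=(), lower=(), upper=(),
    _predict=lambda v, P, t: P.mean(axis=1),
))
_register(ModelSpec(
    name="linear_combined", kind="combined",
    param_names=("a", "b"), lower=(-8.0, 0.0), upper=(8.0, 2.0),
    _predict=lambda v, P, t: v[0] + v[1] * P.mean(axis=1),
))
_register(ModelSpec(
    name="attenuation_combined", kind="combined",
    param_names=("P_beau", "g"), lower=(1.0, 0.0), upper=(9.0, 1.0),
    _predict=lambda v, P, t: _attenuate(P.mean(axis=1), v[0], v[1]),
))

#: registry order mirrors the model-comparison figures
SINGLE_FAMILIES = (
    "faithful",
    "averaging",
    "average_biased",
    "weighted_avg_position",
    "weighted_avg_biased",
    "linear_single",
    "weighted_avg_pleasure_rank",
    "high_pleasure_attenuation",
)
COMBINED_FAMILIES = ("faithful_averaging", "linear_combined", "attenuation_combined")


def get_model(name: str) -> ModelSpec:
    try:
        return _SPECS[name]
    except KeyError:
        raise KeyError(
            f"unknown model family {name!r}; known: {sorted(_SPECS)}"
        ) from None


def predict_single(name: str, params, target_position, baselines) -> np.ndarray | float:
    """Predicted rating(s) of a single-target family. ``baselines`` is (4,) or (n, 4)."""
    spec = get_model(name)
    if spec.kind != "single":
        raise ValueError(f"{name} is not a single-target (1-of-4) family")
    return spec.predict(params, baselines, target_position)


def predict_combined(name: str, params, baselines) -> np.ndarray | float:
    """Predicted rating(s) of a combined family. ``baselines`` is (4,) or (n, 4)."""
    spec = get_model(name)
    if spec.kind != "combined":
        raise ValueError(f"{name} is not a combined (4-combined) family")
    return spec.predict(params, baselines)
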