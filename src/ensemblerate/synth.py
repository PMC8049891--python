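"""Synthetic trial designs and simulated observers.

The generator has two halves:

* :func:`build_design` lays out the trial structure — alternating
  precue/postcue blocks, each showing every image once as a 1-of-4 target
  and once inside a 4-combined quadruple, plus a final baseline block —
  with responses left unset.
* :func:`simulate_responses` fills in responses from an
  :class:`ObserverConfig`: a deterministic model prediction evaluated on
  the observer's latent ("true") pleasures, plus Gaussian late noise,
  rounded half-up to the nearest key and clipped to 1-9, with an optional
  constant rate of uniform random guesses.

Everything is reproducible from integer seeds via
:class:`numpy.random.SeedSequence` spawning.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .data import (
    RATING_MAX,
    RATING_MIN,
    BaselineTable,
    Dataset,
    TrialRecord,
    ValidationError,
)
from .models import get_model

__all__ = [
    "DesignSpec",
    "ObserverConfig",
    "DEFAULT_SIGMA",
    "default_true_pleasures",
    "build_design",
    "simulate_baseline",
    "simulate_responses",
    "simulate_dataset",
    "configs_from_population",
]

#: late-noise SDs (rating points) per condition; the postcued 1-of-4
#: default is 0.15 points higher than the rest, mirroring the observed
#: precue/postcue variability gap.
DEFAULT_SIGMA = {
    "baseline": 1.5,
    "precue_1of4": 1.5,
    "postcue_1of4": 1.65,
    "precue_combined": 1.5,
    "postcue_combined": 1.5,
}

_CUE_ORDER = {"precue": ("precue", "postcue"), "postcue": ("postcue", "precue")}


@dataclass(frozen=True)
class DesignSpec:
    """Structure of the trial design for a batch of participants."""

    n_participants: int = 25
    n_images: int = 36
    n_blocks: int = 8
    alternation_start: str = "random"  # "random" | "precue" | "postcue"
    seed: int = 0

    @property
    def trials_per_block(self) -> int:
        # every image once as target + once in a combined quadruple
        return self.n_images + self.n_images // 4

    def validate(self) -> None:
        if self.n_images % 4 != 0:
            raise ValidationError("n_images must be divisible by 4")
        if self.n_participants < 1 or self.n_blocks < 1:
            raise ValidationError("need at least one participant and one block")
        if self.alternation_start not in ("random", "precue", "postcue"):
            raise ValidationError(f"bad alternation_start {self.alternation_start!r}")

    def image_ids(self) -> list[str]:
        return [f"img{i:02d}" for i in range(1, self.n_images + 1)]

    def participant_ids(self) -> list[str]:
        return [f"p{i:02d}" for i in range(1, self.n_participants + 1)]


def default_true_pleasures(image_ids: Sequence[str]) -> dict[str, float]:
    """Latent pleasures spanning the full 1-9 scale uniformly."""
    values = np.linspace(RATING_MIN, RATING_MAX, len(image_ids))
    return {img: float(v) for img, v in zip(image_ids, values)}


@dataclass
class ObserverConfig:
    """Generative truth for one synthetic participant.

    ``single_model`` maps each cue timing to a ``(family, params)`` pair
    from the single-target registry; ``combined_model`` is one such pair
    from the combined registry.  ``sigma_late`` keys are the condition
    labels ``baseline``, ``precue_1of4``, ``postcue_1of4``,
    ``precue_combined``, ``postcue_combined``.
    """

    participant_id: str
    true_pleasure: dict[str, float]
    single_model: dict[str, tuple[str, dict]] = field(
        default_factory=lambda: {"precue": ("faithful", {}), "postcue": ("faithful", {})}
    )
    combined_model: tuple[str, dict] = ("faithful_averaging", {})
    sigma_late: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SIGMA))
    guess_rate: float = 0.0
    seed: int = 0
    #: if False, responses are generated from the observer's own simulated
    #: (noisy, rounded) baseline ratings instead of the latent pleasures
    use_true_pleasures: bool = True

    def validate(self) -> None:
        for img, value in self.true_pleasure.items():
            if not (RATING_MIN <= value <= RATING_MAX):
                raise ValidationError(
                    f"true pleasure for {img} is {value}, outside the rating scale"
                )
        for key, sigma in self.sigma_late.items():
            if sigma < 0:
                raise ValidationError(f"sigma_late[{key!r}] must be >= 0")
        if not (0.0 <= self.guess_rate <= 1.0):
            raise ValidationError("guess_rate must lie in [0, 1]")
        for timing in ("precue", "postcue"):
            if timing not in self.single_model:
                raise ValidationError(f"single_model missing cue timing {timing!r}")
            family, params = self.single_model[timing]
            spec = get_model(family)
            if spec.kind != "single":
                raise ValidationError(f"{family} is not a single-target family")
            spec.validate_params(spec.params_array(params))
        family, params = self.combined_model
        spec = get_model(family)
        if spec.kind != "combined":
            raise ValidationError(f"{family} is not a combined family")
        spec.validate_params(spec.params_array(params))


# ---------------------------------------------------------------------------
# Design
# ---------------------------------------------------------------------------


def _build_participant_design(
    pid: str, spec: DesignSpec, rng: np.random.Generator
) -> list[TrialRecord]:
    images = spec.image_ids()
    n = len(images)
    if spec.alternation_start == "random":
        start = "precue" if rng.random() < 0.5 else "postcue"
    else:
        start = spec.alternation_start
    order = _CUE_ORDER[start]

    trials: list[TrialRecord] = []
    for block in range(1, spec.n_blocks + 1):
        timing = order[(block - 1) % 2]
        block_trials: list[TrialRecord] = []

        # 1-of-4: each image once as target, uniform random position,
        # three distractors drawn without replacement from the rest
        for img in rng.permutation(images):
            img = str(img)
            target_pos = int(rng.integers(1, 5))
            others = [x for x in images if x != img]
            distractors = [str(x) for x in rng.choice(others, size=3, replace=False)]
            rng.shuffle(distractors)
            slots: list[str | None] = [None] * 4
            slots[target_pos - 1] = img
            free = [i for i in range(4) if slots[i] is None]
            for i, d in zip(free, distractors):
                slots[i] = d
            block_trials.append(TrialRecord(
                participant_id=pid, block_index=block, cue_timing=timing,
                trial_type="one_of_four", images=tuple(slots),
                target_position=target_pos, response=None, trial_index=-1,
            ))

        # 4-combined: a random partition of the image set into quadruples;
        # within-quadruple order is the (random) position assignment
        perm = [str(x) for x in rng.permutation(images)]
        for k in range(n // 4):
            quad = tuple(perm[4 * k: 4 * k + 4])
            block_trials.append(TrialRecord(
                participant_id=pid, block_index=block, cue_timing=timing,
                trial_type="four_combined", images=quad,
                target_position=None, response=None, trial_index=-1,
            ))

        idx = rng.permutation(len(block_trials))
        for trial_index, j in enumerate(idx):
            trials.append(replace(block_trials[j], trial_index=trial_index))

    # baseline block: run last, stored as block_index 0; each image once
    # at a random position
    for trial_index, img in enumerate(rng.permutation(images)):
        pos = int(rng.integers(1, 5))
        slots = [None] * 4
        slots[pos - 1] = str(img)
        trials.append(TrialRecord(
            participant_id=pid, block_index=0, cue_timing="none",
            trial_type="baseline", images=tuple(slots),
            target_position=None, response=None, trial_index=trial_index,
        ))
    return trials


def build_design(spec: DesignSpec) -> list[TrialRecord]:
    """All participants' trials, responses unset (``None``)."""
    spec.validate()
    children = np.random.SeedSequence(spec.seed).spawn(spec.n_participants)
    trials: list[TrialRecord] = []
    for pid, child in zip(spec.participant_ids(), children):
        trials.extend(_build_participant_design(pid, spec, np.random.default_rng(child)))
    return trials


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def _emit_response(mean: float, sigma: float, guess_rate: float,
                   rng: np.random.Generator) -> int:
    if guess_rate > 0 and rng.random() < guess_rate:
        return int(rng.integers(RATING_MIN, RATING_MAX + 1))
    noisy = mean + (rng.normal(0.0, sigma) if sigma > 0 else 0.0)
    return int(np.clip(_round_half_up(noisy), RATING_MIN, RATING_MAX))


def simulate_baseline(
    config: ObserverConfig, rng: np.random.Generator | None = None
) -> dict[str, int]:
    """Simulated baseline ratings: true pleasure + noise, rounded, clipped."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    sigma = config.sigma_late["baseline"]
    return {
        img: _emit_response(value, sigma, config.guess_rate, rng)
        for img, value in config.true_pleasure.items()
    }


def _trial_prediction(trial: TrialRecord, pleasures: Mapping[str, float],
                      config: ObserverConfig) -> float:
    if trial.trial_type == "baseline":
        return float(pleasures[trial.shown_images[0]])
    P = np.array([pleasures[img] for img in trial.images], dtype=float)
    if trial.trial_type == "one_of_four":
        family, params = config.single_model[trial.cue_timing]
        return float(get_model(family).predict(params, P, trial.target_position))
    family, params = config.combined_model
    return float(get_model(family).predict(params, P))


def simulate_responses(
    design: Sequence[TrialRecord], config: ObserverConfig
) -> tuple[list[TrialRecord], dict[str, int]]:
    """Fill in one observer's responses for their trials of ``design``.

    Returns ``(trials_with_responses, baseline_ratings)``.  Baseline-block
    responses double as the observer's baseline table entries.  With
    ``use_true_pleasures=False`` the model predictions are evaluated on
    the simulated baseline ratings instead of the latent pleasures.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    own = [t for t in design if t.participant_id == config.participant_id]
    if not own:
        raise ValidationError(f"design has no trials for {config.participant_id!r}")

    # baseline ratings first (the baseline block is acquired last, but the
    # draw order only needs to be deterministic, not chronological)
    baseline_rng = np.random.default_rng(np.random.SeedSequence((config.seed, 1)))
    baseline = simulate_baseline(config, baseline_rng)
    pleasures: Mapping[str, float]
    if config.use_true_pleasures:
        pleasures = config.true_pleasure
    else:
        pleasures = {k: float(v) for k, v in baseline.items()}

    out: list[TrialRecord] = []
    for trial in own:
        if trial.trial_type == "baseline":
            out.append(replace(trial, response=baseline[trial.shown_images[0]]))
            continue
        mean = _trial_prediction(trial, pleasures, config)
        sigma = config.sigma_late[trial.condition]
        out.append(replace(
            trial, response=_emit_response(mean, sigma, config.guess_rate, rng)
        ))
    return out, baseline


def simulate_dataset(
    spec: DesignSpec, configs: Sequence[ObserverConfig]
) -> Dataset:
    """Build the design and simulate every configured observer.

    ``configs`` must cover exactly the participants of ``spec`` (matched
    by id).  The dataset's baseline table is taken from the simulated
    baseline-block responses, so fitted models see the same (noisy,
    discretized) reference pleasures a real analysis would.
    """
    design = build_design(spec)
    by_id = {c.participant_id: c for c in configs}
    expected = spec.participant_ids()
    if sorted(by_id) != sorted(expected):
        raise ValidationError(
            f"configs cover {sorted(by_id)} but the design needs {expected}"
        )
    trials: list[TrialRecord] = []
    baselines = BaselineTable()
    for pid in expected:
        sim, baseline = simulate_responses(design, by_id[pid])
        trials.extend(sim)
        for img, rating in baseline.items():
            baselines.set(pid, img, rating)
    dataset = Dataset(
        trials=trials,
        baselines=baselines,
        provenance="synthetic",
        metadata={"design_seed": spec.seed, "note": "baseline block acquired last, stored as block 0"},
    )
    dataset.validate()
    return dataset


def configs_from_population(
    population: Mapping,
    n_participants: int,
    seed: int,
    image_ids: Sequence[str] | None = None,
) -> list[ObserverConfig]:
    """Draw per-participant configs from population-level settings.

    ``population`` mirrors the YAML observer config::

        single_model:
          precue:  {family: faithful}
          postcue: {family: high_pleasure_attenuation, params: {P_beau: 4.6, g: 0.5}}
        combined_model: {family: linear_combined, params: {a: -1.4, b: 1.2}}
        sigma_late: {postcue_1of4: 1.65}     # unspecified keys use defaults
        guess_rate: 0.05
        jitter: {P_beau: 0.5, g: 0.1}        # per-participant Gaussian SD
                                             # on any model parameter of
                                             # that name, clipped to bounds

    Participant seeds are spawned from ``seed``; the same seed yields the
    same population.
    """
    if image_ids is None:
        image_ids = DesignSpec(n_participants=n_participants).image_ids()
    true_pop = population.get("true_pleasure") or default_true_pleasures(image_ids)
    sigma = dict(DEFAULT_SIGMA)
    sigma.update(population.get("sigma_late", {}))
    guess_rate = float(population.get("guess_rate", 0.0))
    jitter = {k: float(v) for k, v in population.get("jitter", {}).items()}

    def parse_model(entry, default_family):
        if entry is None:
            return (default_family, {})
        return (entry["family"], dict(entry.get("params", {})))

    single_pop = population.get("single_model", {})
    single = {
        "precue": parse_model(single_pop.get("precue"), "faithful"),
        "postcue": parse_model(single_pop.get("postcue"), "faithful"),
    }
    combined = parse_model(population.get("combined_model"), "faithful_averaging")

    children = np.random.SeedSequence((seed, 77)).spawn(n_participants)
    configs = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)

        def jittered(family: str, params: dict) -> dict:
            spec = get_model(family)
            out = dict(params)
            for j, name in enumerate(spec.param_names):
                if name in jitter and name in out and jitter[name] > 0:
                    value = out[name] + rng.normal(0.0, jitter[name])
                    out[name] = float(np.clip(value, spec.lower[j], spec.upper[j]))
            return out

        configs.append(ObserverConfig(
            participant_id=f"p{i + 1:02d}",
            true_pleasure=dict(true_pop),
            single_model={k: (fam, jittered(fam, par)) for k, (fam, par) in single.items()},
            combined_model=(combined[0], jittered(combined[0], combined[1])),
            sigma_late=dict(sigma),
            guess_rate=guess_rate,
            seed=int(rng.integers(0, 2**31 - 1)),
            use_true_pleasures=bool(population.get("use_true_pleasures", True)),
        ))
    return configs
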