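import numpy as np
import pytest

from ensemblerate.data import BaselineTable, Dataset, TrialRecord
from ensemblerate.synth import (
    DesignSpec,
    ObserverConfig,
    default_true_pleasures,
    simulate_dataset,
)


def make_trial(
    pid="p01",
    block=1,
    timing="precue",
    ttype="one_of_four",
    images=("A", "B", "C", "D"),
    target=1,
    response=5,
    index=0,
):
    if ttype == "four_combined":
        target = None
    if ttype == "baseline":
        timing = "none"
        target = None
    return TrialRecord(
        participant_id=pid,
        block_index=block,
        cue_timing=timing,
        trial_type=ttype,
        images=tuple(images),
        target_position=target,
        response=response,
        trial_index=index,
    )


def make_baselines(pid="p01", mapping=None):
    table = BaselineTable()
    for image, rating in (mapping or {"A": 8, "B": 4, "C": 5, "D": 3}).items():
        table.set(pid, image, rating)
    return table


@pytest.fixture
def toy_baselines():
    return make_baselines()


@pytest.fixture
def toy_dataset(toy_baselines):
    trials = [
        make_trial(response=7, index=0),
        make_trial(ttype="four_combined", response=5, index=1),
        make_trial(ttype="baseline", images=("A", None, None, None), response=8, block=0, index=0),
    ]
    # the baseline block entry must match the baseline table
    return Dataset(trials=trials, baselines=toy_baselines)


def quiet_sigma():
    return {k: 0.0 for k in ("baseline", "precue_1of4", "postcue_1of4",
                             "precue_combined", "postcue_combined")}


def flat_sigma(value):
    return {k: float(value) for k in quiet_sigma()}


def integer_true_pleasures(image_ids):
    """Integer-valued latent pleasures spanning 1..9 (rounding becomes a no-op)."""
    values = np.round(np.linspace(1, 9, len(image_ids)))
    return {img: float(v) for img, v in zip(image_ids, values)}


def noiseless_config(pid="p01", seed=0, **overrides):
    spec = DesignSpec(n_participants=1)
    defaults = dict(
        participant_id=pid,
        true_pleasure=default_true_pleasures(spec.image_ids()),
        sigma_late=quiet_sigma(),
        guess_rate=0.0,
        seed=seed,
    )
    defaults.update(overrides)
    return ObserverConfig(**defaults)


@pytest.fixture(scope="session")
def small_faithful_dataset():
    """2 participants, 8 images, 4 blocks, noiseless faithful observers."""
    spec = DesignSpec(n_participants=2, n_images=8, n_blocks=4, seed=3)
    configs = [
        ObserverConfig(
            participant_id=pid,
            true_pleasure=integer_true_pleasures(spec.image_ids()),
            sigma_late=quiet_sigma(),
            seed=11 + i,
        )
        for i, pid in enumerate(spec.participant_ids())
    ]
    return simulate_dataset(spec, configs)
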