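"""Canonical trial-level data model and flat-file (CSV) input/output.

The experiment produces three kinds of trials:

* ``one_of_four`` — four images shown, one position is cued and its
  pleasure must be rated;
* ``four_combined`` — four images shown, the combined pleasure of all
  four is rated;
* ``baseline`` — a single image shown alone and rated.

Positions are 1-based screen quadrants: 1 = upper-left, 2 = upper-right,
3 = lower-left, 4 = lower-right.  Responses are key presses on a 1-9
scale.  A :class:`Dataset` bundles the trial records with the per
participant-and-image baseline ratings that every model uses as its
reference pleasures.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "CUE_TIMINGS",
    "TRIAL_TYPES",
    "RATING_MIN",
    "RATING_MAX",
    "N_POSITIONS",
    "ValidationError",
    "TrialRecord",
    "BaselineTable",
    "Dataset",
    "write_dataset",
    "read_dataset",
    "import_deposited",
]

CUE_TIMINGS = ("precue", "postcue", "none")
TRIAL_TYPES = ("one_of_four", "four_combined", "baseline")
RATING_MIN = 1
RATING_MAX = 9
N_POSITIONS = 4

TRIAL_COLUMNS = [
    "participant_id",
    "block_index",
    "cue_timing",
    "trial_type",
    "pos1_image",
    "pos2_image",
    "pos3_image",
    "pos4_image",
    "target_position",
    "response",
    "trial_index",
]
BASELINE_COLUMNS = ["participant_id", "image_id", "baseline_pleasure"]


class ValidationError(ValueError):
    """A record violates the data-model invariants."""


@dataclass(frozen=True)
class TrialRecord:
    """One rating trial.

    ``images`` has exactly four slots indexed by position - 1; unused
    slots (all but one on baseline trials) are ``None``.  ``response``
    may be ``None`` on freshly built designs that have not been
    simulated or collected yet.
    """

    participant_id: str
    block_index: int
    cue_timing: str
    trial_type: str
    images: tuple[str | None, str | None, str | None, str | None]
    target_position: int | None
    response: int | None
    trial_index: int

    def validate(self, require_response: bool = True) -> None:
        label = (
            f"trial (participant={self.participant_id}, block={self.block_index}, "
            f"index={self.trial_index})"
        )
        if self.cue_timing not in CUE_TIMINGS:
            raise ValidationError(f"{label}: unknown cue_timing {self.cue_timing!r}")
        if self.trial_type not in TRIAL_TYPES:
            raise ValidationError(f"{label}: unknown trial_type {self.trial_type!r}")
        if len(self.images) != N_POSITIONS:
            raise ValidationError(f"{label}: images must have {N_POSITIONS} slots")
        if self.response is None:
            if require_response:
                raise ValidationError(f"{label}: missing response")
        elif not (RATING_MIN <= self.response <= RATING_MAX):
            raise ValidationError(
                f"{label}: response {self.response} outside "
                f"[{RATING_MIN}, {RATING_MAX}]"
            )
        present = [img for img in self.images if img is not None]
        if self.trial_type == "baseline":
            if len(present) != 1:
                raise ValidationError(f"{label}: baseline trial must show exactly one image")
            if self.cue_timing != "none":
                raise ValidationError(f"{label}: baseline trial must have cue_timing 'none'")
            if self.target_position is not None:
                raise ValidationError(f"{label}: baseline trial must not carry a target_position")
        else:
            if len(present) != N_POSITIONS or len(set(present)) != N_POSITIONS:
                raise ValidationError(
                    f"{label}: {self.trial_type} trial must show 4 distinct images"
                )
            if self.cue_timing == "none":
                raise ValidationError(f"{label}: {self.trial_type} trial needs a cue timing")
            if self.trial_type == "one_of_four":
                if self.target_position not in (1, 2, 3, 4):
                    raise ValidationError(f"{label}: one_of_four trial needs target_position 1-4")
            elif self.target_position is not None:
                raise ValidationError(f"{label}: four_combined trial must not have a target")

    @property
    def shown_images(self) -> tuple[str, ...]:
        return tuple(img for img in self.images if img is not None)

    @property
    def condition(self) -> str:
        """Analysis condition label, e.g. ``precue_1of4``."""
        if self.trial_type == "baseline":
            return "baseline"
        kind = "1of4" if self.trial_type == "one_of_four" else "combined"
        return f"{self.cue_timing}_{kind}"


@dataclass
class BaselineTable:
    """Baseline pleasure rating per (participant, image)."""

    ratings: dict[tuple[str, str], int] = field(default_factory=dict)

    def set(self, participant_id: str, image_id: str, rating: int) -> None:
        self.ratings[(participant_id, image_id)] = int(rating)

    def get(self, participant_id: str, image_id: str) -> int:
        try:
            return self.ratings[(participant_id, image_id)]
        except KeyError:
            raise ValidationError(
                f"no baseline rating for participant {participant_id!r}, "
                f"image {image_id!r}"
            ) from None

    def for_participant(self, participant_id: str) -> dict[str, int]:
        return {
            image: rating
            for (pid, image), rating in self.ratings.items()
            if pid == participant_id
        }

    def validate(self) -> None:
        for (pid, image), rating in self.ratings.items():
            if not (RATING_MIN <= rating <= RATING_MAX):
                raise ValidationError(
                    f"baseline for ({pid}, {image}) is {rating}, outside "
                    f"[{RATING_MIN}, {RATING_MAX}]"
                )

    def __len__(self) -> int:
        return len(self.ratings)


@dataclass
class Dataset:
    trials: list[TrialRecord]
    baselines: BaselineTable
    provenance: str = "synthetic"  # "synthetic" | "deposited"
    metadata: dict = field(default_factory=dict)

    def validate(self, require_response: bool = True) -> None:
        if self.provenance not in ("synthetic", "deposited"):
            raise ValidationError(f"unknown provenance {self.provenance!r}")
        self.baselines.validate()
        for trial in self.trials:
            trial.validate(require_response=require_response)
            for image in trial.shown_images:
                self.baselines.get(trial.participant_id, image)

    @property
    def participants(self) -> list[str]:
        seen: dict[str, None] = {}
        for trial in self.trials:
            seen.setdefault(trial.participant_id, None)
        return list(seen)

    def trials_for(
        self, participant_id: str, condition: str | None = None
    ) -> list[TrialRecord]:
        out = [t for t in self.trials if t.participant_id == participant_id]
        if condition is not None:
            out = [t for t in out if t.condition == condition]
        return out


# ---------------------------------------------------------------------------
# CSV serialization
# ---------------------------------------------------------------------------


def _trials_frame(trials: Iterable[TrialRecord]) -> pd.DataFrame:
    rows = []
    for t in trials:
        rows.append(
            {
                "participant_id": t.participant_id,
                "block_index": t.block_index,
                "cue_timing": t.cue_timing,
                "trial_type": t.trial_type,
                "pos1_image": t.images[0],
                "pos2_image": t.images[1],
                "pos3_image": t.images[2],
                "pos4_image": t.images[3],
                "target_position": t.target_position,
                "response": t.response,
                "trial_index": t.trial_index,
            }
        )
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def _trial_from_row(row: Mapping) -> TrialRecord:
    def _opt_int(value):
        if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
            return None
        return int(float(value))

    def _opt_str(value):
        if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
            return None
        return str(value)

    return TrialRecord(
        participant_id=str(row["participant_id"]),
        block_index=int(row["block_index"]),
        cue_timing=str(row["cue_timing"]),
        trial_type=str(row["trial_type"]),
        images=(
            _opt_str(row["pos1_image"]),
            _opt_str(row["pos2_image"]),
            _opt_str(row["pos3_image"]),
            _opt_str(row["pos4_image"]),
        ),
        target_position=_opt_int(row["target_position"]),
        response=_opt_int(row["response"]),
        trial_index=int(row["trial_index"]),
    )


def write_dataset(dataset: Dataset, path: str | Path) -> None:
    """Write a validated dataset as ``trials.csv`` + ``baselines.csv``.

    ``path`` is a directory (created if missing).  Raises
    :class:`ValidationError` naming the first offending record if the
    dataset violates the invariants.
    """
    dataset.validate()
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    _trials_frame(dataset.trials).to_csv(path / "trials.csv", index=False)
    base = pd.DataFrame(
        [
            {"participant_id": pid, "image_id": image, "baseline_pleasure": rating}
            for (pid, image), rating in dataset.baselines.ratings.items()
        ],
        columns=BASELINE_COLUMNS,
    )
    base.to_csv(path / "baselines.csv", index=False)
    meta = {"provenance": dataset.provenance, "metadata": dataset.metadata}
    (path / "metadata.json").write_text(json.dumps(meta, indent=2, default=str))


def read_dataset(path: str | Path) -> Dataset:
    """Inverse of :func:`write_dataset`; returns a validated :class:`Dataset`.

    Unknown columns in ``trials.csv`` are not lost: their names and values
    are stashed under ``metadata["extra_trial_columns"]``.
    """
    path = Path(path)
    trials_path = path / "trials.csv"
    base_path = path / "baselines.csv"
    if not trials_path.exists() or not base_path.exists():
        raise FileNotFoundError(f"expected trials.csv and baselines.csv under {path}")
    trials_df = pd.read_csv(trials_path)
    missing = [c for c in TRIAL_COLUMNS if c not in trials_df.columns]
    if missing:
        raise ValidationError(f"trials.csv missing columns: {missing}")
    base_df = pd.read_csv(base_path)
    missing = [c for c in BASELINE_COLUMNS if c not in base_df.columns]
    if missing:
        raise ValidationError(f"baselines.csv missing columns: {missing}")

    metadata: dict = {}
    provenance = "synthetic"
    meta_path = path / "metadata.json"
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        provenance = meta.get("provenance", "synthetic")
        metadata = dict(meta.get("metadata", {}))

    extra = [c for c in trials_df.columns if c not in TRIAL_COLUMNS]
    if extra:
        metadata["extra_trial_columns"] = {
            c: trials_df[c].tolist() for c in extra
        }

    trials = [_trial_from_row(row) for row in trials_df.to_dict("records")]
    baselines = BaselineTable()
    for row in base_df.to_dict("records"):
        baselines.set(str(row["participant_id"]), str(row["image_id"]), int(row["baseline_pleasure"]))
    dataset = Dataset(trials=trials, baselines=baselines, provenance=provenance, metadata=metadata)
    dataset.validate()
    return dataset


# ---------------------------------------------------------------------------
# Import of externally deposited data
# ---------------------------------------------------------------------------

#: canonical fields the caller's column map must provide for trials
REQUIRED_MAPPED_FIELDS = (
    "participant_id",
    "cue_timing",
    "trial_type",
    "pos1_image",
    "pos2_image",
    "pos3_image",
    "pos4_image",
    "target_position",
    "response",
)
EXPECTED_TRIALS_PER_BLOCK = 45


def import_deposited(path: str | Path, column_map: Mapping) -> Dataset:
    """Load an externally deposited raw-data directory into the canonical model.

    The deposited layout is not standardized, so the caller supplies
    ``column_map``::

        {
          "trials_file": "main.csv",          # relative to ``path``
          "baselines_file": "baseline.csv",   # optional; else derived from
                                              # trial_type == "baseline" rows
          "columns": {canonical_field: source_column, ...},
          "values": {canonical_field: {source_value: canonical_value, ...}},
        }

    ``columns`` must cover :data:`REQUIRED_MAPPED_FIELDS`; ``block_index``
    and ``trial_index`` are filled with zeros/running indices when not
    mapped.  Rows whose mapped values cannot be coerced are dropped and
    counted in ``metadata["import_report"]``.  Trial counts inconsistent
    with the 45-trials-per-block design produce a warning, not an error.
    """
    path = Path(path)
    if not path.is_dir():
        raise FileNotFoundError(f"{path} is not a directory")
    files = sorted(p.name for p in path.iterdir() if p.suffix.lower() in (".csv", ".tsv", ".txt"))
    if not files:
        raise FileNotFoundError(f"no delimited data files found in {path}")

    columns = dict(column_map.get("columns", {}))
    missing = [f for f in REQUIRED_MAPPED_FIELDS if f not in columns]
    if missing:
        raise ValidationError(f"column map is missing canonical fields: {missing}")
    value_maps = {k: dict(v) for k, v in dict(column_map.get("values", {})).items()}

    trials_file = column_map.get("trials_file") or files[0]
    df = pd.read_csv(path / trials_file)
    absent = [src for src in columns.values() if src not in df.columns]
    if absent:
        raise ValidationError(f"{trials_file} lacks mapped columns: {absent}")

    dropped = 0
    trials: list[TrialRecord] = []
    block_counter: dict[tuple[str, int], int] = {}
    for _, row in df.iterrows():
        try:
            def get(fieldname, default=None):
                if fieldname not in columns:
                    return default
                value = row[columns[fieldname]]
                if fieldname in value_maps and value in value_maps[fieldname]:
                    value = value_maps[fieldname][value]
                return value

            pid = str(get("participant_id"))
            block = int(get("block_index", 0) or 0)
            key = (pid, block)
            block_counter[key] = block_counter.get(key, 0) + 1
            images = []
            for pos in range(1, 5):
                value = get(f"pos{pos}_image")
                images.append(None if value is None or pd.isna(value) else str(value))
            target = get("target_position")
            target = None if target is None or pd.isna(target) else int(float(target))
            trial = TrialRecord(
                participant_id=pid,
                block_index=block,
                cue_timing=str(get("cue_timing")),
                trial_type=str(get("trial_type")),
                images=tuple(images),  # type: ignore[arg-type]
                target_position=target,
                response=int(float(get("response"))),
                trial_index=int(get("trial_index", block_counter[key] - 1) or 0),
            )
            trial.validate()
            trials.append(trial)
        except (ValidationError, ValueError, TypeError, KeyError):
            dropped += 1

    baselines = BaselineTable()
    baselines_file = column_map.get("baselines_file")
    if baselines_file:
        bdf = pd.read_csv(path / baselines_file)
        bcols = column_map.get("baseline_columns", {
            "participant_id": "participant_id",
            "image_id": "image_id",
            "baseline_pleasure": "baseline_pleasure",
        })
        for _, row in bdf.iterrows():
            baselines.set(
                str(row[bcols["participant_id"]]),
                str(row[bcols["image_id"]]),
                int(float(row[bcols["baseline_pleasure"]])),
            )
    else:
        for trial in trials:
            if trial.trial_type == "baseline" and trial.response is not None:
                baselines.set(trial.participant_id, trial.shown_images[0], trial.response)

    main_blocks = {k: n for k, n in block_counter.items() if k[1] != 0}
    odd = [k for k, n in main_blocks.items() if n != EXPECTED_TRIALS_PER_BLOCK]
    if odd:
        warnings.warn(
            f"{len(odd)} block(s) deviate from the expected "
            f"{EXPECTED_TRIALS_PER_BLOCK} trials per block",
            stacklevel=2,
        )

    dataset = Dataset(
        trials=trials,
        baselines=baselines,
        provenance="deposited",
        metadata={
            "import_report": {
                "source_file": trials_file,
                "rows_read": int(len(df)),
                "rows_dropped": int(dropped),
            }
        },
    )
    dataset.validate()
    return dataset
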