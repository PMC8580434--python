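"""Reading, validating and writing landmark-coordinate tables.

The on-disk interchange formats are deliberately plain:

* Landmark CSV — one row per digitised point, columns
  ``trial_id, frame_index, object_kind, tentacle_id, point_role, x, y``.
  ``object_kind`` is one of ``centre``, ``axis_ref``, ``stimulus``,
  ``tentacle``; tentacle rows additionally carry ``tentacle_id`` and
  ``point_role`` (``base`` or ``tip``).  Static trials have a single frame
  (index 0); rotating trials one frame per retained video frame.
* Experiment manifest — YAML (or JSON, which YAML subsumes) holding a list
  of trial-metadata records, optionally with per-trial landmark file paths.

Angles in files and reports are degrees; coordinates are pixels in image
convention (y down).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import DegenerateGeometryError, SchemaError
from .geometry import (
    Point,
    TentacleObservation,
    body_angle_of,
    build_body_frame,
    tentacle_vector,
    world_angle,
)

__all__ = [
    "LANDMARK_COLUMNS",
    "OBJECT_KINDS",
    "TrialMeta",
    "FrameLandmarks",
    "Trial",
    "FilterOutcome",
    "read_manifest",
    "write_manifest",
    "read_landmarks",
    "write_landmarks",
    "write_results",
    "write_summary",
    "filter_trials",
]

logger = logging.getLogger(__name__)

LANDMARK_COLUMNS = (
    "trial_id", "frame_index", "object_kind", "tentacle_id", "point_role",
    "x", "y",
)
OBJECT_KINDS = frozenset({"centre", "axis_ref", "stimulus", "tentacle"})
EXPERIMENTS = frozenset({"static_position", "static_width", "rotating"})


# ---------------------------------------------------------------------------
# Trial metadata
# ---------------------------------------------------------------------------

@dataclass
class TrialMeta:
    """Metadata describing one behavioural trial."""

    trial_id: str
    animal_id: str
    experiment: str  # static_position | static_width | rotating
    treatment_label: str
    stimulus_present: bool
    stimulus_angle_body: float | None = None  # degrees; static trials
    stimulus_width: float | None = None  # degrees of arc
    rotation_rpm: float | None = None
    rotation_direction: int | None = None  # +1 or -1
    rotation_start_angle_body: float | None = None
    frame_rate_raw: float = 1.0
    viewing_side: str = "above"
    landmark_path: str | None = None  # optional pointer used by manifests

    def __post_init__(self) -> None:
        if self.experiment not in EXPERIMENTS:
            raise SchemaError(
                f"trial {self.trial_id}: unknown experiment "
                f"{self.experiment!r}"
            )
        if self.viewing_side not in ("above", "below"):
            raise SchemaError(
                f"trial {self.trial_id}: viewing_side must be above/below"
            )
        if self.experiment in ("static_position", "static_width"):
            if self.stimulus_present and self.stimulus_angle_body is None:
                raise SchemaError(
                    f"trial {self.trial_id}: static trial with a stimulus "
                    "needs stimulus_angle_body"
                )
            if not self.stimulus_present and self.stimulus_angle_body is not None:
                raise SchemaError(
                    f"trial {self.trial_id}: control trial must not set "
                    "stimulus_angle_body"
                )
        else:  # rotating
            if not self.rotation_rpm or self.rotation_rpm <= 0:
                raise SchemaError(
                    f"trial {self.trial_id}: rotating trial needs "
                    "rotation_rpm > 0"
                )
            if self.rotation_direction not in (1, -1):
                raise SchemaError(
                    f"trial {self.trial_id}: rotation_direction must be +1/-1"
                )
            if self.rotation_start_angle_body is None:
                raise SchemaError(
                    f"trial {self.trial_id}: rotating trial needs "
                    "rotation_start_angle_body"
                )

    @property
    def is_static(self) -> bool:
        return self.experiment in ("static_position", "static_width")

    def to_dict(self) -> dict:
        return {k: v for k, v in dataclasses.asdict(self).items()
                if v is not None}


# ---------------------------------------------------------------------------
# Assembled trials
# ---------------------------------------------------------------------------

@dataclass
class FrameLandmarks:
    """All landmarks digitised in one video frame."""

    frame_index: int
    centre: Point
    axis_ref: Point
    stimulus: Point | None
    tentacles: dict[str, tuple[Point, Point]]  # id -> (base, tip)

    @property
    def n_tentacles(self) -> int:
        return len(self.tentacles)


@dataclass
class Trial:
    """One behavioural trial: metadata plus per-frame landmark sets."""

    meta: TrialMeta
    frames: list[FrameLandmarks]

    def __post_init__(self) -> None:
        idx = [f.frame_index for f in self.frames]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise SchemaError(
                f"trial {self.meta.trial_id}: frame indices must be "
                "strictly increasing"
            )
        if self.meta.is_static and len(self.frames) != 1:
            raise SchemaError(
                f"trial {self.meta.trial_id}: static trials have exactly "
                f"one frame, got {len(self.frames)}"
            )

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def frame_observations(self, frame: FrameLandmarks
                           ) -> list[TentacleObservation]:
        """Body-frame tentacle vectors for one frame; zero-length dropped."""
        bf = build_body_frame(frame.centre, frame.axis_ref,
                              self.meta.viewing_side)
        out = []
        for tid in sorted(frame.tentacles):
            base, tip = frame.tentacles[tid]
            try:
                out.append(tentacle_vector(base, tip, bf, tentacle_id=tid,
                                           frame_index=frame.frame_index))
            except DegenerateGeometryError:
                logger.warning(
                    "trial %s frame %d: tentacle %s has base == tip; dropped",
                    self.meta.trial_id, frame.frame_index, tid)
        return out

    def stimulus_angle_body(self, frame: FrameLandmarks) -> float | None:
        """Observed stimulus direction in the body frame, if digitised."""
        if frame.stimulus is None:
            return None
        bf = build_body_frame(frame.centre, frame.axis_ref,
                              self.meta.viewing_side)
        return body_angle_of(bf, world_angle(frame.centre, frame.stimulus))

    @property
    def total_tentacles(self) -> int:
        """Distinct tentacles extended at any point during the trial."""
        ids: set[str] = set()
        for f in self.frames:
            ids.update(f.tentacles)
        return len(ids)


# ---------------------------------------------------------------------------
# Manifest IO
# ---------------------------------------------------------------------------

def read_manifest(path: str | Path) -> list[TrialMeta]:
    """Read an experiment manifest (YAML or JSON) into TrialMeta records."""
    raw = yaml.safe_load(Path(path).read_text())
    if isinstance(raw, dict):
        raw = raw.get("trials", raw)
    if not isinstance(raw, list):
        raise SchemaError("manifest must be a list of trial records "
                          "or a mapping with a 'trials' key")
    metas = []
    for rec in raw:
        try:
            metas.append(TrialMeta(**rec))
        except TypeError as exc:
            raise SchemaError(f"bad manifest record {rec!r}: {exc}") from exc
    return metas


def write_manifest(metas: Sequence[TrialMeta], path: str | Path) -> None:
    payload = {"trials": [m.to_dict() for m in metas]}
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


# ---------------------------------------------------------------------------
# Landmark CSV IO
# ---------------------------------------------------------------------------

def _point(row) -> Point:
    return (float(row.x), float(row.y))


def read_landmarks(path: str | Path, meta: TrialMeta | str | Path) -> Trial:
    """Read one trial's landmark CSV and assemble a validated Trial.

    ``meta`` may be a TrialMeta or a path to a single-trial manifest.
    """
    if not isinstance(meta, TrialMeta):
        metas = read_manifest(meta)
        if len(metas) != 1:
            raise SchemaError("expected a single-trial manifest")
        meta = metas[0]
    df = pd.read_csv(path, dtype={"trial_id": str, "tentacle_id": str,
                                  "point_role": str, "object_kind": str},
                     float_precision="round_trip")
    missing = set(LANDMARK_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"landmark file missing columns {sorted(missing)}")
    unknown = set(df.object_kind.unique()) - OBJECT_KINDS
    if unknown:
        raise SchemaError(f"unknown object_kind values {sorted(unknown)}")
    if not np.isfinite(df[["x", "y"]].to_numpy()).all():
        raise SchemaError("landmark coordinates must be finite")
    frames = []
    for fidx, grp in df.groupby("frame_index", sort=True):
        frames.append(_assemble_frame(meta.trial_id, int(fidx), grp))
    if not frames:
        raise SchemaError(f"trial {meta.trial_id}: landmark file is empty")
    return Trial(meta=meta, frames=frames)


def _assemble_frame(trial_id: str, fidx: int, grp: pd.DataFrame
                    ) -> FrameLandmarks:
    def singleton(kind: str, required: bool = True) -> Point | None:
        rows = grp[grp.object_kind == kind]
        if len(rows) == 0:
            if required:
                raise SchemaError(
                    f"trial {trial_id} frame {fidx}: missing {kind} landmark"
                )
            return None
        if len(rows) > 1:
            raise SchemaError(
                f"trial {trial_id} frame {fidx}: multiple {kind} landmarks"
            )
        return _point(rows.iloc[0])

    centre = singleton("centre")
    axis_ref = singleton("axis_ref")
    stimulus = singleton("stimulus", required=False)

    tentacles: dict[str, tuple[Point, Point]] = {}
    trows = grp[grp.object_kind == "tentacle"]
    for tid, tgrp in trows.groupby("tentacle_id"):
        roles = dict(zip(tgrp.point_role, (_point(r) for r in tgrp.itertuples())))
        if set(tgrp.point_role) != {"base", "tip"} or len(tgrp) != 2:
            raise SchemaError(
                f"trial {trial_id} frame {fidx}: tentacle {tid} needs "
                "exactly one base and one tip record"
            )
        tentacles[str(tid)] = (roles["base"], roles["tip"])
    return FrameLandmarks(frame_index=fidx, centre=centre, axis_ref=axis_ref,
                          stimulus=stimulus, tentacles=tentacles)


def write_landmarks(trial: Trial, path: str | Path) -> None:
    """Write a Trial back to the landmark CSV schema (lossless round-trip)."""
    rows = []
    tid = trial.meta.trial_id

    def add(fidx, kind, x, y, tent_id="", role=""):
        rows.append({"trial_id": tid, "frame_index": fidx,
                     "object_kind": kind, "tentacle_id": tent_id,
                     "point_role": role, "x": repr(float(x)),
                     "y": repr(float(y))})

    for f in trial.frames:
        add(f.frame_index, "centre", *f.centre)
        add(f.frame_index, "axis_ref", *f.axis_ref)
        if f.stimulus is not None:
            add(f.frame_index, "stimulus", *f.stimulus)
        for tent_id in sorted(f.tentacles):
            base, tip = f.tentacles[tent_id]
            add(f.frame_index, "tentacle", *base, tent_id, "base")
            add(f.frame_index, "tentacle", *tip, tent_id, "tip")
    out = Path(path)
    out.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows, columns=LANDMARK_COLUMNS).to_csv(out, index=False)


# ---------------------------------------------------------------------------
# Result tables
# ---------------------------------------------------------------------------

def write_results(table, path: str | Path, columns=None) -> None:
    """Write per-trial or per-frame results as a tab-separated table.

    ``table`` is a DataFrame, a sequence of dicts, or a sequence of
    dataclass instances.  Floats are written at full precision so that a
    re-read reproduces the values exactly.
    """
    if isinstance(table, pd.DataFrame):
        df = table
    else:
        recs = [dataclasses.asdict(r) if dataclasses.is_dataclass(r) else dict(r)
                for r in table]
        df = pd.DataFrame(recs, columns=columns)
    out = Path(path)
    out.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(out, sep="\t", index=False)


def write_summary(summary: dict, path: str | Path) -> None:
    """Write a structured analysis summary as JSON."""
    out = Path(path)
    out.parent.mkdir(parents=True, exist_ok=True)
    out.write_text(json.dumps(summary, indent=2, default=_json_default,
                              allow_nan=True))


def _json_default(obj):
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"cannot serialise {type(obj)}")


# ---------------------------------------------------------------------------
# Trial-level exclusion filter
# ---------------------------------------------------------------------------

@dataclass
class FilterOutcome:
    kept: list[Trial]
    excluded: list[Trial]
    reasons: dict[str, str] = field(default_factory=dict)


def filter_trials(trials: Iterable[Trial],
                  min_tentacles: int = 3) -> FilterOutcome:
    """Apply the trial-level exclusion rules.

    Static trials are excluded when fewer than ``min_tentacles`` tentacles
    were extended; rotating trials only when no tentacle was extended in
    any frame.  Exclusion reasons are logged and returned.
    """
    kept: list[Trial] = []
    excluded: list[Trial] = []
    reasons: dict[str, str] = {}
    for trial in trials:
        tid = trial.meta.trial_id
        if trial.meta.is_static:
            n = trial.frames[0].n_tentacles
            if n < min_tentacles:
                reasons[tid] = (f"static trial extended {n} tentacles "
                                f"(< {min_tentacles})")
        else:
            if trial.total_tentacles == 0:
                reasons[tid] = "rotating trial extended no tentacles"
        if tid in reasons:
            logger.info("excluding trial %s: %s", tid, reasons[tid])
            excluded.append(trial)
        else:
            kept.append(trial)
    return FilterOutcome(kept=kept, excluded=excluded, reasons=reasons)
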