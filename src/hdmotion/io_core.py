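"""Data model, validation, session/feature-table CSV I/O and mULMS arithmetic.

Recordings come from three body-worn tri-axial accelerometers (one per
wrist plus one on the sternum) sampled at 100 Hz in units of g while the
participant performs a token-transfer task at one of three difficulty
levels.  Sessions are stored as plain long-format CSV
(``sample_index,sensor,x,y,z``) with ``#key=value`` header comments for the
participant id, task and sampling frequency; cohorts are described by a
YAML manifest.
"""

from __future__ import annotations

import csv
import enum
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import yaml

from .registry import FEATURE_NAMES, SENSORS

logger = logging.getLogger(__name__)

#: hardware constants of the recording setup
SAMPLING_HZ = 100.0
ACCEL_RANGE_G = 8.0
MIN_SAMPLES = 400  # >= 3 STFT windows of 2 s with 50% overlap


class ValidationError(ValueError):
    """Raised when an input violates a data-model invariant."""


class Placement(str, enum.Enum):
    NON_DOMINANT_WRIST = "non_dominant_wrist"
    DOMINANT_WRIST = "dominant_wrist"
    CHEST = "chest"


class Task(str, enum.Enum):
    BASELINE_SIMPLE = "baseline_simple"
    BASELINE_COMPLEX = "baseline_complex"
    DUAL = "dual"


class Group(str, enum.Enum):
    HD = "HD"
    CONTROL = "control"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class TriaxialSignal:
    """One sensor's 100 Hz tri-axial acceleration stream, in g."""

    placement: Placement
    fs: float
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray

    def __post_init__(self) -> None:
        self.placement = Placement(self.placement)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if self.fs != SAMPLING_HZ:
            raise ValidationError(
                f"sampling frequency must be {SAMPLING_HZ:g} Hz, got {self.fs!r}"
            )
        n = len(self.x)
        if len(self.y) != n or len(self.z) != n:
            raise ValidationError("axes x, y, z must have equal length")
        if n < MIN_SAMPLES:
            raise ValidationError(
                f"signal too short: {n} samples < {MIN_SAMPLES} minimum"
            )
        for name, arr in (("x", self.x), ("y", self.y), ("z", self.z)):
            if not np.all(np.isfinite(arr)):
                raise ValidationError(f"non-finite value in axis {name}")
            if np.any(np.abs(arr) > ACCEL_RANGE_G):
                i = int(np.argmax(np.abs(arr) > ACCEL_RANGE_G))
                raise ValidationError(
                    f"acceleration out of ±{ACCEL_RANGE_G:g} g range "
                    f"at sample {i} on axis {name}"
                )

    def __len__(self) -> int:
        return len(self.x)

    def axes(self) -> dict[str, np.ndarray]:
        return {"x": self.x, "y": self.y, "z": self.z}


@dataclass
class TaskRecording:
    """Three time-aligned tri-axial signals for one participant-task."""

    participant_id: str
    task: Task
    sensors: dict[Placement, TriaxialSignal]

    def __post_init__(self) -> None:
        self.task = Task(self.task)
        self.sensors = {Placement(k): v for k, v in self.sensors.items()}
        missing = [p.value for p in Placement if p not in self.sensors]
        if missing:
            raise ValidationError(f"missing placement: {', '.join(missing)}")
        lengths = {len(s) for s in self.sensors.values()}
        if len(lengths) != 1:
            raise ValidationError(
                f"sensors have unequal lengths: {sorted(lengths)}"
            )

    def __len__(self) -> int:
        return len(next(iter(self.sensors.values())))


MULMS_ITEM_NAMES = (
    "left_upper_limb_dystonia",
    "right_upper_limb_dystonia",
    "trunk_chorea",
    "left_upper_limb_chorea",
    "right_upper_limb_chorea",
)


def compute_mulms(items: Iterable[int]) -> int:
    """Sum the five upper-limb UHDRS sub-items into the mULMS (0..20).

    The modified upper-limb motor score adds the clinician ratings (each
    0-4) for left/right upper-limb dystonia, trunk chorea and left/right
    upper-limb chorea.
    """
    items = list(items)
    if len(items) != 5:
        raise ValidationError(f"expected 5 mULMS items, got {len(items)}")
    for name, v in zip(MULMS_ITEM_NAMES, items):
        if not isinstance(v, (int, np.integer)) or isinstance(v, bool):
            raise ValidationError(f"mULMS item {name} must be an integer, got {v!r}")
        if not 0 <= v <= 4:
            raise ValidationError(f"mULMS item {name} out of range [0, 4]: {v}")
    return int(sum(items))


@dataclass
class Participant:
    id: str
    group: Group
    mulms_items: tuple[int, ...] | None = None
    mulms: int | None = None

    def __post_init__(self) -> None:
        self.group = Group(self.group)
        if self.mulms_items is not None:
            self.mulms_items = tuple(int(v) for v in self.mulms_items)
            total = compute_mulms(self.mulms_items)
            if self.mulms is None:
                self.mulms = total
            elif self.mulms != total:
                raise ValidationError(
                    f"participant {self.id}: mulms={self.mulms} does not equal "
                    f"sum of items {total}"
                )
        if self.mulms is not None and not 0 <= self.mulms <= 20:
            raise ValidationError(
                f"participant {self.id}: mULMS out of range [0, 20]: {self.mulms}"
            )


@dataclass
class CohortDataset:
    """Participants with labels, mULMS and per-task recordings.

    Task failure in severe disease is ordered: every participant performs
    the baseline simple task; if the baseline complex recording is absent
    the dual-task recording must be absent too.
    """

    participants: list[Participant]
    recordings: dict[tuple[str, Task], TaskRecording] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [p.id for p in self.participants]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate participant ids")
        for p in self.participants:
            if (p.id, Task.BASELINE_SIMPLE) not in self.recordings:
                raise ValidationError(
                    f"participant {p.id} lacks a baseline_simple recording"
                )
            has_complex = (p.id, Task.BASELINE_COMPLEX) in self.recordings
            has_dual = (p.id, Task.DUAL) in self.recordings
            if has_dual and not has_complex:
                raise ValidationError(
                    f"participant {p.id}: dual recording present but "
                    "baseline_complex missing (failure ordering violated)"
                )

    def tasks_of(self, participant_id: str) -> list[Task]:
        return [t for t in Task if (participant_id, t) in self.recordings]

    def labels(self) -> dict[str, Group]:
        return {p.id: p.group for p in self.participants}


@dataclass
class FeatureVector:
    """The 234 named feature values of one participant-task."""

    participant_id: str
    task: Task
    values: dict[str, float]

    def __post_init__(self) -> None:
        self.task = Task(self.task)
        if tuple(self.values.keys()) != FEATURE_NAMES:
            if len(self.values) != len(FEATURE_NAMES):
                raise ValidationError(
                    f"expected {len(FEATURE_NAMES)} features, got {len(self.values)}"
                )
            if set(self.values) != set(FEATURE_NAMES):
                extra = sorted(set(self.values) - set(FEATURE_NAMES))[:5]
                missing = sorted(set(FEATURE_NAMES) - set(self.values))[:5]
                raise ValidationError(
                    f"feature names outside the registry (extra={extra}, "
                    f"missing={missing})"
                )
            # right names, wrong order: re-canonicalise
            self.values = {n: self.values[n] for n in FEATURE_NAMES}
        for n, v in self.values.items():
            if not math.isfinite(v):
                raise ValidationError(f"non-finite feature value for {n}: {v!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.values[n] for n in FEATURE_NAMES], dtype=float)


# ---------------------------------------------------------------------------
# session CSV
# ---------------------------------------------------------------------------


def write_session_csv(recording: TaskRecording, path: str | Path) -> None:
    """Write one recording as long-format CSV with metadata header comments."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        fh.write(f"#participant_id={recording.participant_id}\n")
        fh.write(f"#task={recording.task.value}\n")
        fh.write("#fs=100\n")
        writer = csv.writer(fh)
        writer.writerow(["sample_index", "sensor", "x", "y", "z"])
        for placement in SENSORS:
            sig = recording.sensors[Placement(placement)]
            for i in range(len(sig)):
                writer.writerow(
                    [i, placement,
                     repr(float(sig.x[i])), repr(float(sig.y[i])),
                     repr(float(sig.z[i]))]
                )


def read_session_csv(path: str | Path) -> TaskRecording:
    """Read a session CSV into a validated :class:`TaskRecording`.

    Sensors are trimmed to the common (shortest) length; a mismatch larger
    than one sample is an error.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    per_sensor: dict[str, list[tuple[float, float, float]]] = {}
    with path.open() as fh:
        header_seen = False
        for row_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "=" in line:
                    k, v = line[1:].split("=", 1)
                    meta[k.strip()] = v.strip()
                continue
            cells = line.split(",")
            if not header_seen:
                if cells[:5] != ["sample_index", "sensor", "x", "y", "z"]:
                    raise ValidationError(
                        f"{path}: unexpected header at row {row_no}: {line!r}"
                    )
                header_seen = True
                continue
            if len(cells) != 5:
                raise ValidationError(f"{path}: malformed row {row_no}: {line!r}")
            _, sensor, xs, ys, zs = cells
            if sensor not in SENSORS:
                raise ValidationError(
                    f"{path}: unknown sensor {sensor!r} at row {row_no}"
                )
            try:
                vals = (float(xs), float(ys), float(zs))
            except ValueError as exc:
                raise ValidationError(
                    f"{path}: non-numeric cell at row {row_no}: {exc}"
                ) from None
            for v in vals:
                if not math.isfinite(v) or abs(v) > ACCEL_RANGE_G:
                    raise ValidationError(
                        f"{path}: acceleration out of ±{ACCEL_RANGE_G:g} g "
                        f"range at row {row_no}"
                    )
            per_sensor.setdefault(sensor, []).append(vals)

    missing = [s for s in SENSORS if s not in per_sensor]
    if missing:
        raise ValidationError(f"{path}: missing placement: {', '.join(missing)}")
    fs = float(meta.get("fs", "nan"))
    if fs != SAMPLING_HZ:
        raise ValidationError(f"{path}: fs must be 100, got {meta.get('fs')!r}")

    lengths = {s: len(rows) for s, rows in per_sensor.items()}
    n_min, n_max = min(lengths.values()), max(lengths.values())
    if n_max - n_min > 1:
        raise ValidationError(
            f"{path}: sensor length mismatch > 1 sample: {lengths}"
        )
    if n_max != n_min:
        logger.warning("%s: trimming sensors to common length %d", path, n_min)
    if n_min < MIN_SAMPLES:
        raise ValidationError(
            f"{path}: too few samples ({n_min} < {MIN_SAMPLES})"
        )

    sensors = {}
    for s, rows in per_sensor.items():
        arr = np.asarray(rows[:n_min], dtype=float)
        sensors[Placement(s)] = TriaxialSignal(
            placement=Placement(s), fs=fs, x=arr[:, 0], y=arr[:, 1], z=arr[:, 2]
        )
    return TaskRecording(
        participant_id=meta.get("participant_id", path.stem),
        task=Task(meta.get("task", "baseline_simple")),
        sensors=sensors,
    )


# ---------------------------------------------------------------------------
# feature-table CSV
# ---------------------------------------------------------------------------


def write_feature_table(vectors: list[FeatureVector], path: str | Path) -> None:
    """Write feature vectors as CSV: id, task, then the 234 canonical columns.

    Values are written with ``repr`` (17 significant digits) so that a
    write/read round trip is bit-exact.
    """
    if not vectors:
        raise ValidationError("no feature vectors to write")
    tasks = {v.task for v in vectors}
    if len(tasks) != 1:
        raise ValidationError(
            f"heterogeneous tasks in one table: {sorted(t.value for t in tasks)}"
        )
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["participant_id", "task", *FEATURE_NAMES])
        for v in vectors:
            writer.writerow(
                [v.participant_id, v.task.value]
                + [repr(float(v.values[n])) for n in FEATURE_NAMES]
            )


def read_feature_table(path: str | Path) -> list[FeatureVector]:
    path = Path(path)
    with path.open() as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if header[:2] != ["participant_id", "task"]:
            raise ValidationError(f"{path}: unexpected leading columns {header[:2]}")
        names = header[2:]
        if len(names) != len(FEATURE_NAMES):
            raise ValidationError(
                f"{path}: expected {len(FEATURE_NAMES)} features, got {len(names)}"
            )
        if tuple(names) != FEATURE_NAMES:
            raise ValidationError(f"{path}: feature columns differ from the registry")
        vectors = []
        for row in reader:
            vectors.append(
                FeatureVector(
                    participant_id=row[0],
                    task=Task(row[1]),
                    values={n: float(v) for n, v in zip(names, row[2:])},
                )
            )
    return vectors


# ---------------------------------------------------------------------------
# cohort manifest
# ---------------------------------------------------------------------------


def write_cohort(cohort: CohortDataset, out_dir: str | Path) -> Path:
    """Write session CSVs plus a ``cohort.yaml`` manifest; returns manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"participants": []}
    for p in cohort.participants:
        entry: dict = {"id": p.id, "group": p.group.value, "sessions": {}}
        if p.mulms_items is not None:
            entry["mulms_items"] = list(p.mulms_items)
            entry["mulms"] = p.mulms
        elif p.mulms is not None:
            entry["mulms"] = p.mulms
        for task in cohort.tasks_of(p.id):
            fname = f"{p.id}_{task.value}.csv"
            write_session_csv(cohort.recordings[(p.id, task)], out_dir / fname)
            entry["sessions"][task.value] = fname
        manifest["participants"].append(entry)
    manifest_path = out_dir / "cohort.yaml"
    with manifest_path.open("w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return manifest_path


def read_cohort(manifest_path: str | Path) -> CohortDataset:
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    with manifest_path.open() as fh:
        manifest = yaml.safe_load(fh)
    participants: list[Participant] = []
    recordings: dict[tuple[str, Task], TaskRecording] = {}
    for entry in manifest["participants"]:
        items = entry.get("mulms_items")
        participants.append(
            Participant(
                id=str(entry["id"]),
                group=Group(entry["group"]),
                mulms_items=tuple(items) if items is not None else None,
                mulms=entry.get("mulms"),
            )
        )
        for task_name, fname in entry.get("sessions", {}).items():
            rec = read_session_csv(base / fname)
            recordings[(str(entry["id"]), Task(task_name))] = rec
    return CohortDataset(participants=participants, recordings=recordings)
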