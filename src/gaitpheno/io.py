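"""Data model and plain-text exchange format for time-normalized gait cycles.

A gait cycle is the interval between two successive initial contacts of the
same foot, time-normalized to 0-100% and sampled on a fixed grid of 201
epochs (0.5% spacing).  Each cycle carries named joint-angle channels in
degrees (sign convention: positive = flexion / dorsiflexion / anterior tilt,
negative = extension), the within-cycle gait events that bound the support
phases, stride metadata and the identity of the subject and side.

Exchange format (one cycle = two files):

* ``<cycle_id>.csv`` — long format with columns ``epoch_pct, channel, degrees``;
* ``<cycle_id>.json`` — sidecar with ``cycle_id, subject_id, side,
  events{opposite_toe_off, opposite_initial_contact, toe_off},
  stride_time_s, stride_length_m, subject_height_m``.

A cohort directory additionally holds one ``clinical.csv`` table with one row
per subject (unknowns encoded as empty fields).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

N_EPOCHS = 201
#: The fixed percentage grid 0.0, 0.5, ..., 100.0.
EPOCH_GRID = np.linspace(0.0, 100.0, N_EPOCHS)

#: Sagittal-plane channels (mandatory; these drive the DTW classification).
SAGITTAL_CHANNELS = (
    "pelvic_tilt",
    "hip_flexion",
    "knee_flexion",
    "ankle_dorsiflexion",
    "forefoot_flexion",
)

#: Non-sagittal channels needed for the full kinematic parameter set.
NON_SAGITTAL_CHANNELS = (
    "pelvic_rotation",
    "pelvic_obliquity",
    "hip_abduction",
    "hip_rotation",
    "foot_progression",
)

CHANNEL_VOCABULARY = SAGITTAL_CHANNELS + NON_SAGITTAL_CHANNELS

#: Decimal places kept when writing angles (round trip is exact at this precision).
ANGLE_DECIMALS = 6


class GaitValidationError(ValueError):
    """An object violates a gait-cycle invariant (names the cycle and rule)."""


class GaitParseError(ValueError):
    """A file in the exchange format is malformed (names the file)."""


@dataclass(frozen=True)
class AngleSeries:
    """One joint-angle channel over the 201-epoch cycle grid, in degrees."""

    channel: str
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.channel not in CHANNEL_VOCABULARY:
            raise GaitValidationError(
                f"unknown channel {self.channel!r}; expected one of {CHANNEL_VOCABULARY}"
            )
        values = np.asarray(self.values, dtype=float)
        if values.shape != (N_EPOCHS,):
            raise GaitValidationError(
                f"channel {self.channel!r}: expected {N_EPOCHS} epochs, got {values.shape}"
            )
        if not np.all(np.isfinite(values)):
            raise GaitValidationError(f"channel {self.channel!r}: non-finite angle values")
        object.__setattr__(self, "values", values)


@dataclass(frozen=True)
class GaitEvents:
    """Within-cycle event times in % of cycle (initial contact is epoch 0)."""

    opposite_toe_off: float
    opposite_initial_contact: float
    toe_off: float

    def __post_init__(self) -> None:
        if not (0.0 < self.opposite_toe_off < self.opposite_initial_contact < self.toe_off < 100.0):
            raise GaitValidationError(
                "events must satisfy 0 < opposite_toe_off < opposite_initial_contact"
                f" < toe_off < 100, got ({self.opposite_toe_off}, "
                f"{self.opposite_initial_contact}, {self.toe_off})"
            )


@dataclass(frozen=True)
class PhaseWindows:
    """Half-open phase intervals [a, b) in % of cycle derived from gait events.

    ``stance`` tiles into first double support, single support and second
    double support; ``swing`` is [toe_off, 100).  ``terminal_swing`` is the
    final third of swing (a conventional split; the boundary is configurable
    through :func:`phase_windows`).
    """

    stance: tuple[float, float]
    first_double_support: tuple[float, float]
    single_support: tuple[float, float]
    second_double_support: tuple[float, float]
    swing: tuple[float, float]
    terminal_swing: tuple[float, float]

    def as_dict(self) -> dict[str, tuple[float, float]]:
        return {
            "stance": self.stance,
            "first_double_support": self.first_double_support,
            "single_support": self.single_support,
            "second_double_support": self.second_double_support,
            "swing": self.swing,
            "terminal_swing": self.terminal_swing,
        }


def phase_windows(events: GaitEvents, terminal_swing_fraction: float = 1.0 / 3.0) -> PhaseWindows:
    """Derive the support/swing phase windows from the gait events.

    Parameters
    ----------
    events
        Validated gait events (% of cycle).
    terminal_swing_fraction
        Fraction of the swing window, measured from its end, that counts as
        terminal swing.  Default: the final third.
    """
    to = events.toe_off
    oto = events.opposite_toe_off
    oic = events.opposite_initial_contact
    swing = (to, 100.0)
    ts_start = to + (1.0 - terminal_swing_fraction) * (100.0 - to)
    return PhaseWindows(
        stance=(0.0, to),
        first_double_support=(0.0, oto),
        single_support=(oto, oic),
        second_double_support=(oic, to),
        swing=swing,
        terminal_swing=(ts_start, 100.0),
    )


@dataclass
class GaitCycle:
    """One time-normalized stride of one limb.

    The five sagittal channels are mandatory; the five non-sagittal channels
    are required only for the full 37-parameter kinematic extraction.
    """

    cycle_id: str
    subject_id: str
    side: str
    channels: dict[str, AngleSeries]
    events: GaitEvents
    stride_time: float
    stride_length: float
    subject_height: float

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise GaitValidationError(f"cycle {self.cycle_id}: side must be left|right, got {self.side!r}")
        missing = [c for c in SAGITTAL_CHANNELS if c not in self.channels]
        if missing:
            raise GaitValidationError(
                f"cycle {self.cycle_id}: missing mandatory sagittal channels {missing}"
            )
        for name, series in self.channels.items():
            if name != series.channel:
                raise GaitValidationError(
                    f"cycle {self.cycle_id}: channel key {name!r} != series channel {series.channel!r}"
                )
        if not (self.stride_time > 0):
            raise GaitValidationError(f"cycle {self.cycle_id}: stride_time must be > 0")
        if self.stride_length < 0:
            raise GaitValidationError(f"cycle {self.cycle_id}: stride_length must be >= 0")
        if not (self.subject_height > 0):
            raise GaitValidationError(f"cycle {self.cycle_id}: subject_height must be > 0")

    def angles(self, channel: str) -> np.ndarray:
        try:
            return self.channels[channel].values
        except KeyError:
            raise GaitValidationError(
                f"cycle {self.cycle_id}: channel {channel!r} not present"
            ) from None

    def stack(self, channels: Sequence[str]) -> np.ndarray:
        """Return a (201, n_channels) matrix of the requested channels."""
        return np.column_stack([self.angles(c) for c in channels])

    def has_full_channel_set(self) -> bool:
        return all(c in self.channels for c in CHANNEL_VOCABULARY)


_SEX_VALUES = ("female", "male")
_GMFCS_VALUES = ("I", "II", "III")
_FLAG_VALUES = ("yes", "no", "unknown")
_CONDITION_VALUES = ("HSP", "healthy")


@dataclass(frozen=True)
class ClinicalRecord:
    """Subject-level clinical descriptors attached to every cycle of a subject.

    ``gmfcs`` is the Gross Motor Function Classification System stage (I-III
    in this ambulatory cohort); pathology flags are tri-state yes/no/unknown.
    Healthy subjects carry gmfcs I and all flags "no".
    """

    subject_id: str
    age: float
    sex: str
    gmfcs: str
    polyneuropathy: str
    abnormal_vep: str
    thin_corpus_callosum: str
    condition: str

    def __post_init__(self) -> None:
        if not (2.0 <= self.age <= 20.0):
            raise GaitValidationError(
                f"subject {self.subject_id}: age {self.age} outside the paediatric range [2, 20]"
            )
        for name, value, allowed in (
            ("sex", self.sex, _SEX_VALUES),
            ("gmfcs", self.gmfcs, _GMFCS_VALUES),
            ("polyneuropathy", self.polyneuropathy, _FLAG_VALUES),
            ("abnormal_vep", self.abnormal_vep, _FLAG_VALUES),
            ("thin_corpus_callosum", self.thin_corpus_callosum, _FLAG_VALUES),
            ("condition", self.condition, _CONDITION_VALUES),
        ):
            if value not in allowed:
                raise GaitValidationError(
                    f"subject {self.subject_id}: {name} must be one of {allowed}, got {value!r}"
                )
        if self.condition == "healthy":
            for name, value in (
                ("polyneuropathy", self.polyneuropathy),
                ("abnormal_vep", self.abnormal_vep),
                ("thin_corpus_callosum", self.thin_corpus_callosum),
            ):
                if value != "no":
                    raise GaitValidationError(
                        f"subject {self.subject_id}: healthy subjects must have {name}='no'"
                    )


def resample_to_epochs(times: np.ndarray, angles: np.ndarray, channel: str,
                       n_epochs: int = N_EPOCHS) -> AngleSeries:
    """Resample a raw capture onto the fixed percentage grid.

    ``times`` are percentages of the cycle spanning [0, 100]; interpolation is
    monotone piecewise-cubic (PCHIP), which is smooth and does not overshoot
    at kinematic peaks.  Endpoints are preserved exactly.
    """
    times = np.asarray(times, dtype=float)
    angles = np.asarray(angles, dtype=float)
    if times.ndim != 1 or times.shape != angles.shape or times.size < 4:
        raise GaitParseError("need >= 4 (time, angle) samples of equal length")
    if np.any(np.diff(times) <= 0):
        raise GaitParseError("timestamps must be strictly increasing")
    if not (math.isclose(times[0], 0.0, abs_tol=1e-9) and math.isclose(times[-1], 100.0, abs_tol=1e-9)):
        raise GaitParseError("samples must span the full cycle (first time 0, last time 100)")
    grid = np.linspace(0.0, 100.0, n_epochs)
    values = PchipInterpolator(times, angles)(grid)
    values[0] = angles[0]
    values[-1] = angles[-1]
    return AngleSeries(channel=channel, values=values)


# ---------------------------------------------------------------------------
# Exchange-format readers and writers
# ---------------------------------------------------------------------------

def write_cycle(cycle: GaitCycle, directory: Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for name in CHANNEL_VOCABULARY:
        if name not in cycle.channels:
            continue
        vals = np.round(cycle.channels[name].values, ANGLE_DECIMALS)
        for epoch, v in zip(EPOCH_GRID, vals):
            rows.append((epoch, name, v))
    frame = pd.DataFrame(rows, columns=["epoch_pct", "channel", "degrees"])
    frame.to_csv(directory / f"{cycle.cycle_id}.csv", index=False,
                 float_format=f"%.{ANGLE_DECIMALS}f")
    sidecar = {
        "cycle_id": cycle.cycle_id,
        "subject_id": cycle.subject_id,
        "side": cycle.side,
        "events": {
            "opposite_toe_off": cycle.events.opposite_toe_off,
            "opposite_initial_contact": cycle.events.opposite_initial_contact,
            "toe_off": cycle.events.toe_off,
        },
        "stride_time_s": cycle.stride_time,
        "stride_length_m": cycle.stride_length,
        "subject_height_m": cycle.subject_height,
    }
    (directory / f"{cycle.cycle_id}.json").write_text(json.dumps(sidecar, indent=1))


def read_cycle(sidecar_path: Path) -> GaitCycle:
    sidecar_path = Path(sidecar_path)
    try:
        meta = json.loads(sidecar_path.read_text())
    except json.JSONDecodeError as exc:
        raise GaitParseError(f"{sidecar_path}: invalid JSON sidecar ({exc})") from exc
    csv_path = sidecar_path.with_suffix(".csv")
    if not csv_path.exists():
        raise GaitParseError(f"{csv_path}: missing angle file for sidecar {sidecar_path.name}")
    try:
        frame = pd.read_csv(csv_path)
    except Exception as exc:  # pandas raises several parse error types
        raise GaitParseError(f"{csv_path}: cannot parse ({exc})") from exc
    required = {"epoch_pct", "channel", "degrees"}
    if not required.issubset(frame.columns):
        raise GaitParseError(f"{csv_path}: expected columns {sorted(required)}")
    channels: dict[str, AngleSeries] = {}
    for name, sub in frame.groupby("channel", sort=False):
        if name not in CHANNEL_VOCABULARY:
            raise GaitValidationError(f"{csv_path}: unknown channel {name!r}")
        sub = sub.sort_values("epoch_pct")
        if len(sub) != N_EPOCHS:
            raise GaitValidationError(
                f"{csv_path}: channel {name!r}: expected {N_EPOCHS} epochs, got {len(sub)}"
            )
        channels[str(name)] = AngleSeries(channel=str(name), values=sub["degrees"].to_numpy())
    try:
        events = GaitEvents(**meta["events"])
        return GaitCycle(
            cycle_id=str(meta["cycle_id"]),
            subject_id=str(meta["subject_id"]),
            side=str(meta["side"]),
            channels=channels,
            events=events,
            stride_time=float(meta["stride_time_s"]),
            stride_length=float(meta["stride_length_m"]),
            subject_height=float(meta["subject_height_m"]),
        )
    except KeyError as exc:
        raise GaitParseError(f"{sidecar_path}: missing sidecar field {exc}") from exc


_CLINICAL_COLUMNS = [
    "subject_id", "age", "sex", "gmfcs", "polyneuropathy",
    "abnormal_vep", "thin_corpus_callosum", "condition",
]


def write_clinical(records: Iterable[ClinicalRecord], path: Path) -> None:
    rows = []
    for r in records:
        row = {c: getattr(r, c) for c in _CLINICAL_COLUMNS}
        for flag in ("polyneuropathy", "abnormal_vep", "thin_corpus_callosum"):
            if row[flag] == "unknown":
                row[flag] = ""
        rows.append(row)
    pd.DataFrame(rows, columns=_CLINICAL_COLUMNS).to_csv(path, index=False)


def read_clinical(path: Path) -> list[ClinicalRecord]:
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _CLINICAL_COLUMNS if c not in frame.columns]
    if missing:
        raise GaitParseError(f"{path}: clinical table missing columns {missing}")
    records = []
    for _, row in frame.iterrows():
        kwargs = {c: row[c] for c in _CLINICAL_COLUMNS}
        kwargs["age"] = float(kwargs["age"])
        for flag in ("polyneuropathy", "abnormal_vep", "thin_corpus_callosum"):
            if kwargs[flag] == "":
                kwargs[flag] = "unknown"
        records.append(ClinicalRecord(**kwargs))
    return records


def write_cohort(cycles: Sequence[GaitCycle], records: Sequence[ClinicalRecord],
                 directory: Path) -> None:
    """Write a cohort (cycle files + clinical table) in the exchange format."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for cycle in cycles:
        write_cycle(cycle, directory)
    write_clinical(records, directory / "clinical.csv")


def read_cohort(directory: Path) -> tuple[list[GaitCycle], list[ClinicalRecord]]:
    """Read a cohort directory; validates every cycle and resolves subjects.

    Cycles failing validation are reported collectively in a single
    :class:`GaitValidationError` naming each offending file and rule.
    """
    directory = Path(directory)
    clinical_path = directory / "clinical.csv"
    records = read_clinical(clinical_path) if clinical_path.exists() else []
    known_subjects = {r.subject_id for r in records}
    cycles: list[GaitCycle] = []
    failures: list[str] = []
    for sidecar in sorted(directory.glob("*.json")):
        if sidecar.name == "manifest.json":
            continue
        try:
            cycle = read_cycle(sidecar)
        except (GaitParseError, GaitValidationError) as exc:
            failures.append(str(exc))
            continue
        if records and cycle.subject_id not in known_subjects:
            failures.append(
                f"{sidecar}: subject {cycle.subject_id!r} has no clinical record"
            )
            continue
        cycles.append(cycle)
    if failures:
        raise GaitValidationError(
            "cohort validation failed for {} file(s):\n{}".format(len(failures), "\n".join(failures))
        )
    return cycles, records
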