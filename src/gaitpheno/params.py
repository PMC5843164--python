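"""Interpretable gait parameters: 6 spatio-temporal + 37 kinematic values per cycle.

Every kinematic parameter is defined by an auditable (channel, window,
operator) rule.  Windows are phase intervals derived from the cycle's gait
events (half-open, in % of cycle); operators act on the epochs whose grid
position falls inside the window.  ``time_of_max``/``time_of_min`` report the
% of the *whole* cycle of the extremal epoch, ties broken toward the earliest
epoch so timing parameters are deterministic.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import EPOCH_GRID, GaitCycle, GaitValidationError, PhaseWindows, phase_windows

SPATIOTEMPORAL_NAMES = (
    "normalized_walking_speed",
    "cadence",
    "stance_pct",
    "first_double_support_pct",
    "single_support_pct",
    "second_double_support_pct",
)

_OPERATORS = ("value_at", "min", "max", "mean", "range", "time_of_max", "time_of_min")

#: window tokens: phase names, unions joined by '+', "cycle", or "event:<name>"
_WINDOW_TOKENS = (
    "cycle", "stance", "swing", "first_double_support", "single_support",
    "second_double_support", "terminal_swing",
    "first_double_support+single_support", "second_double_support+swing",
)


@dataclass(frozen=True)
class ExtractionRule:
    """One (parameter name -> channel, window, operator) extraction rule."""

    name: str
    channel: str
    window: str
    operator: str

    def __post_init__(self) -> None:
        if self.operator not in _OPERATORS:
            raise ValueError(f"rule {self.name}: unknown operator {self.operator!r}")
        if not (self.window in _WINDOW_TOKENS or self.window.startswith("event:")):
            raise ValueError(f"rule {self.name}: unknown window {self.window!r}")


def _rule(name: str, channel: str, window: str, operator: str) -> ExtractionRule:
    return ExtractionRule(name=name, channel=channel, window=window, operator=operator)


#: The 37 kinematic parameters in canonical (table) order.
KINEMATIC_RULES: tuple[ExtractionRule, ...] = (
    _rule("mean_pelvic_tilt", "pelvic_tilt", "cycle", "mean"),
    _rule("range_pelvic_tilt", "pelvic_tilt", "cycle", "range"),
    _rule("pelvic_rotation_at_initial_contact", "pelvic_rotation", "event:initial_contact", "value_at"),
    _rule("mean_pelvic_rotation", "pelvic_rotation", "cycle", "mean"),
    _rule("range_pelvic_rotation_in_second_double_support", "pelvic_rotation", "second_double_support", "range"),
    _rule("range_pelvic_rotation_in_terminal_swing", "pelvic_rotation", "terminal_swing", "range"),
    _rule("mean_pelvic_obliquity_in_stance", "pelvic_obliquity", "stance", "mean"),
    _rule("hip_flexion_at_initial_contact", "hip_flexion", "event:initial_contact", "value_at"),
    _rule("min_hip_flexion", "hip_flexion", "cycle", "min"),
    _rule("mean_hip_flexion_in_stance", "hip_flexion", "stance", "mean"),
    _rule("max_hip_flexion_in_swing", "hip_flexion", "swing", "max"),
    _rule("time_to_max_hip_flexion_in_swing", "hip_flexion", "swing", "time_of_max"),
    _rule("range_hip_flexion", "hip_flexion", "cycle", "range"),
    _rule("mean_hip_abduction_in_first_double_support_and_single_support",
          "hip_abduction", "first_double_support+single_support", "mean"),
    _rule("max_hip_abduction_in_swing", "hip_abduction", "swing", "max"),
    _rule("mean_hip_rotation_in_stance", "hip_rotation", "stance", "mean"),
    _rule("mean_hip_rotation_in_swing", "hip_rotation", "swing", "mean"),
    _rule("knee_flexion_at_initial_contact", "knee_flexion", "event:initial_contact", "value_at"),
    _rule("min_knee_flexion_in_stance", "knee_flexion", "stance", "min"),
    _rule("max_knee_flexion_in_first_double_support", "knee_flexion", "first_double_support", "max"),
    _rule("max_knee_flexion_in_single_support", "knee_flexion", "single_support", "max"),
    _rule("min_knee_flexion_in_single_support", "knee_flexion", "single_support", "min"),
    _rule("max_knee_flexion", "knee_flexion", "cycle", "max"),
    _rule("time_to_peak_knee_flexion", "knee_flexion", "cycle", "time_of_max"),
    _rule("range_knee_flexion_in_second_double_support_and_swing",
          "knee_flexion", "second_double_support+swing", "range"),
    _rule("range_knee_flexion", "knee_flexion", "cycle", "range"),
    _rule("dorsiflexion_at_initial_contact", "ankle_dorsiflexion", "event:initial_contact", "value_at"),
    _rule("max_ankle_dorsiflexion_in_stance", "ankle_dorsiflexion", "stance", "max"),
    _rule("min_ankle_dorsiflexion_in_stance", "ankle_dorsiflexion", "stance", "min"),
    _rule("range_ankle_dorsiflexion_in_stance", "ankle_dorsiflexion", "stance", "range"),
    _rule("mean_ankle_dorsiflexion_in_first_double_support", "ankle_dorsiflexion", "first_double_support", "mean"),
    _rule("mean_ankle_dorsiflexion_in_single_support", "ankle_dorsiflexion", "single_support", "mean"),
    _rule("mean_ankle_dorsiflexion_in_second_double_support", "ankle_dorsiflexion", "second_double_support", "mean"),
    _rule("max_ankle_dorsiflexion_in_swing", "ankle_dorsiflexion", "swing", "max"),
    _rule("min_ankle_dorsiflexion_in_swing", "ankle_dorsiflexion", "swing", "min"),
    _rule("range_ankle_dorsiflexion_in_swing", "ankle_dorsiflexion", "swing", "range"),
    _rule("mean_foot_progression_in_stance", "foot_progression", "stance", "mean"),
)

KINEMATIC_NAMES = tuple(r.name for r in KINEMATIC_RULES)
PARAMETER_NAMES = SPATIOTEMPORAL_NAMES + KINEMATIC_NAMES
assert len(PARAMETER_NAMES) == 43


def export_rule_table(path: Path) -> None:
    """Write the kinematic rule table as JSON so the mapping is auditable."""
    Path(path).write_text(json.dumps([asdict(r) for r in KINEMATIC_RULES], indent=1))


def _window_mask(window: str, phases: PhaseWindows) -> np.ndarray:
    if window == "cycle":
        return np.ones_like(EPOCH_GRID, dtype=bool)
    mask = np.zeros_like(EPOCH_GRID, dtype=bool)
    for token in window.split("+"):
        a, b = getattr(phases, token)
        mask |= (EPOCH_GRID >= a) & (EPOCH_GRID < b)
    return mask


def _apply_rule(rule: ExtractionRule, cycle: GaitCycle, phases: PhaseWindows) -> float:
    values = cycle.angles(rule.channel)
    if rule.window.startswith("event:"):
        event = rule.window.split(":", 1)[1]
        if event != "initial_contact":
            raise ValueError(f"rule {rule.name}: unsupported event {event!r}")
        return float(values[0])
    mask = _window_mask(rule.window, phases)
    window_vals = values[mask]
    if rule.operator == "mean":
        return float(window_vals.mean())
    if rule.operator == "min":
        return float(window_vals.min())
    if rule.operator == "max":
        return float(window_vals.max())
    if rule.operator == "range":
        return float(window_vals.max() - window_vals.min())
    if rule.operator in ("time_of_max", "time_of_min"):
        grid = EPOCH_GRID[mask]
        idx = int(np.argmax(window_vals) if rule.operator == "time_of_max" else np.argmin(window_vals))
        return float(grid[idx])
    raise ValueError(f"rule {rule.name}: unknown operator {rule.operator!r}")


def extract_spatiotemporal(cycle: GaitCycle) -> dict[str, float]:
    """Normalized walking speed (1/s), cadence (steps/s) and phase percentages.

    Walking speed is normalized by subject height: (stride_length /
    stride_time) / height.  Cadence counts two steps per stride.
    """
    phases = phase_windows(cycle.events)
    speed = cycle.stride_length / cycle.stride_time / cycle.subject_height
    return {
        "normalized_walking_speed": speed,
        "cadence": 2.0 / cycle.stride_time,
        "stance_pct": phases.stance[1] - phases.stance[0],
        "first_double_support_pct": phases.first_double_support[1] - phases.first_double_support[0],
        "single_support_pct": phases.single_support[1] - phases.single_support[0],
        "second_double_support_pct": phases.second_double_support[1] - phases.second_double_support[0],
    }


def extract_kinematic(cycle: GaitCycle,
                      rules: Sequence[ExtractionRule] = KINEMATIC_RULES) -> dict[str, float]:
    """Apply the kinematic rule table to one cycle."""
    phases = phase_windows(cycle.events)
    missing = sorted({r.channel for r in rules} - set(cycle.channels))
    if missing:
        affected = [r.name for r in rules if r.channel in missing]
        raise GaitValidationError(
            f"cycle {cycle.cycle_id}: missing channels {missing} required by parameters {affected}"
        )
    return {r.name: _apply_rule(r, cycle, phases) for r in rules}


def extract_parameters(cycle: GaitCycle) -> dict[str, float]:
    """All 43 parameters of one cycle, in canonical order."""
    out = extract_spatiotemporal(cycle)
    out.update(extract_kinematic(cycle))
    return out


def extract_matrix(cycles: Sequence[GaitCycle]) -> pd.DataFrame:
    """Cycle-by-parameter table (rows in input order, canonical column order)."""
    rows = []
    for cycle in cycles:
        try:
            rows.append(extract_parameters(cycle))
        except (GaitValidationError, ValueError) as exc:
            raise GaitValidationError(f"cycle {cycle.cycle_id}: {exc}") from exc
    frame = pd.DataFrame(rows, index=[c.cycle_id for c in cycles])
    frame.index.name = "cycle_id"
    return frame[list(PARAMETER_NAMES)]
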