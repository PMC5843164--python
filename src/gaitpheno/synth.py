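"""Synthetic paediatric gait cohorts with known ground truth.

A smooth healthy template (low-order harmonics and Gaussian landmark bumps
per channel, physiologic event timing, age-dependent speed and cadence) is
perturbed by six pattern operators that reproduce the qualitative signatures
of the published sagittal gait patterns in hereditary spastic paraplegia:

* **I** — close to normal: slightly increased anterior pelvic tilt, longer
  stance, mildly delayed knee-flexion peak, higher hip/knee flexion at
  initial contact;
* **II** — increased anterior pelvic tilt (with a "double hump"), globally
  increased hip flexion, increased knee flexion at initial contact, delayed
  knee-flexion peak;
* **III** — stiff/hyperextended knee: reduced hip extension, knee recurvatum
  in stance, decreased and delayed knee-flexion peak, slowed gait;
* **IV** — crouch-like: markedly increased knee flexion in stance and at
  initial contact, reduced hip extension, increased ankle dorsiflexion,
  attenuated and delayed knee-flexion peak, low speed and cadence;
* **V** — recurvatum-equinus: strong anterior pelvic tilt with double hump,
  knee recurvatum, pronounced ankle/forefoot plantarflexion (equinus),
  low speed;
* **VI** — jump-knee-like: increased hip and knee flexion at initial
  contact with a load-response knee bump, double-hump pelvic tilt, mild
  equinus, near-normal spatio-temporal performance.

Cycle-to-cycle structure mirrors a real instrumented-gait study: per-subject
random channel offsets, smooth within-cycle noise, event jitter, up to five
cycles per limb, asymmetric subjects using different patterns per limb, and
subject-level clinical features (age, sex, GMFCS, polyneuropathy, abnormal
VEP, thin corpus callosum) drawn from a per-pattern coupling table.  An
extreme stretched-stance "outlier" cycle can be planted to exercise
singleton handling downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .io import (
    CHANNEL_VOCABULARY,
    EPOCH_GRID,
    AngleSeries,
    ClinicalRecord,
    GaitCycle,
    GaitEvents,
)

_T = EPOCH_GRID  # 0 .. 100, 201 points


def _bump(mu: float, sigma: float) -> np.ndarray:
    """Gaussian bump on the cycle grid, wrapped at the 0/100 boundary."""
    out = np.zeros_like(_T)
    for shift in (-100.0, 0.0, 100.0):
        out += np.exp(-0.5 * ((_T - mu + shift) / sigma) ** 2)
    return out


def _harm(k: float, phase: float) -> np.ndarray:
    return np.cos(2.0 * np.pi * k * _T / 100.0 + phase)


@dataclass
class TemplateBundle:
    """Continuous healthy gait description before discretization into a cycle."""

    channels: dict[str, np.ndarray]
    events: GaitEvents
    stride_time: float
    stride_length: float
    subject_height: float


def healthy_template(age: float = 7.0) -> TemplateBundle:
    """Deterministic healthy gait template for a child of the given age.

    Landmarks: knee-flexion peak ~60 deg at ~70% of cycle, ankle push-off
    plantarflexion just before toe-off, stance ~60%, knee flexion at initial
    contact in the 0-10 deg band.  Cadence and height-normalized walking
    speed decline with age as in school-age cohorts (speed/height loses
    ~0.05 1/s per year).
    """
    channels = {
        "pelvic_tilt": 10.0 + 1.5 * _harm(2.0, 0.6),
        "hip_flexion": 11.0 + 23.0 * _harm(1.0, 2.0 * np.pi * 3.0 / 100.0),
        "knee_flexion": 4.0 + 14.0 * _bump(12.0, 7.0) + 56.0 * _bump(70.0, 8.5),
        "ankle_dorsiflexion": (-4.0 * _bump(3.0, 4.0) + 10.0 * _bump(42.0, 16.0)
                               - 20.0 * _bump(63.0, 5.5) + 3.0 * _bump(80.0, 12.0)),
        "forefoot_flexion": (-2.0 * _bump(3.0, 4.0) + 6.0 * _bump(42.0, 16.0)
                             - 25.0 * _bump(63.0, 6.0) + 2.0 * _bump(80.0, 12.0)),
        "pelvic_rotation": 5.0 * _harm(1.0, 0.3),
        "pelvic_obliquity": 2.0 * _harm(2.0, 0.8 - np.pi / 2.0),
        "hip_abduction": -2.0 + 6.0 * _bump(75.0, 12.0),
        "hip_rotation": 2.0 + 3.0 * _harm(1.0, 1.0 - np.pi / 2.0),
        "foot_progression": -8.0 + 2.0 * _harm(1.0, 0.5 - np.pi / 2.0),
    }
    cadence = 2.6 - 0.046 * age                     # steps/s
    stride_time = 2.0 / cadence
    height = 0.95 + 0.047 * age
    norm_speed = 1.35 - 0.05 * age                  # (m/s)/m = 1/s
    stride_length = norm_speed * height * stride_time
    events = GaitEvents(opposite_toe_off=10.0, opposite_initial_contact=50.0,
                        toe_off=60.0)
    return TemplateBundle(channels=channels, events=events, stride_time=stride_time,
                          stride_length=stride_length, subject_height=height)


@dataclass(frozen=True)
class PatternSpec:
    """Pure perturbation operators applied to the healthy template (severity 1).

    Magnitudes are degrees (offsets, bumps), % of cycle (peak delays,
    stance shift) or dimensionless multipliers (cadence/speed).
    """

    pattern: str
    pelvic_tilt_offset: float = 0.0
    double_hump_amp: float = 0.0            # 2nd-harmonic pelvic-tilt amplitude
    hip_offset: float = 0.0
    hip_extension_loss: float = 0.0         # bump at mid-stance raising min hip flexion
    hip_ic_extra: float = 0.0               # wrap bump at initial contact / late swing
    knee_ic_offset: float = 0.0             # wrap bump at initial contact
    knee_stance_offset: float = 0.0         # crouch / load-response bump in stance
    knee_recurvatum: float = 0.0            # negative bump at mid-stance
    knee_peak_delay: float = 0.0            # % of cycle, swing-peak time warp
    knee_peak_attenuation: float = 0.0      # degrees removed from the swing peak
    ankle_offset: float = 0.0               # equinus (<0) / dorsiflexion (>0) bias
    ankle_dorsi_stance_gain: float = 0.0    # extra stance dorsiflexion (crouch)
    ankle_pushoff_gain: float = 0.0         # deepens the push-off plantarflexion peak
    ankle_peak_delay: float = 0.0           # % of cycle, push-off time warp
    forefoot_offset: float = 0.0
    stance_shift: float = 0.0               # % of cycle added to toe-off
    cadence_factor: float = 1.0
    speed_factor: float = 1.0


#: Default pattern library (severity 1 magnitudes, 2-4 healthy SDs on their
#: signature parameters; anchors: ~+10 deg knee flexion at initial contact and
#: ~+6% knee-peak delay in the severe-GMFCS patterns, equinus offsets beyond
#: the healthy plantarflexion band).
PATTERN_LIBRARY: dict[str, PatternSpec] = {
    "I": PatternSpec("I", pelvic_tilt_offset=3.0, hip_offset=1.0, hip_ic_extra=4.0,
                     knee_ic_offset=4.0, knee_peak_delay=4.5, stance_shift=2.5,
                     cadence_factor=0.98, speed_factor=0.95),
    "II": PatternSpec("II", pelvic_tilt_offset=9.0, double_hump_amp=4.0, hip_offset=12.0,
                      knee_ic_offset=14.0, knee_peak_delay=4.0, stance_shift=2.0,
                      cadence_factor=0.97, speed_factor=0.93),
    "III": PatternSpec("III", pelvic_tilt_offset=3.0, hip_extension_loss=12.0,
                       knee_recurvatum=16.0, knee_peak_attenuation=22.0,
                       knee_peak_delay=8.0, ankle_pushoff_gain=8.0,
                       ankle_peak_delay=7.0, stance_shift=4.0,
                       cadence_factor=0.85, speed_factor=0.70),
    "IV": PatternSpec("IV", hip_extension_loss=12.0, knee_ic_offset=18.0,
                      knee_stance_offset=20.0, knee_peak_attenuation=14.0,
                      knee_peak_delay=8.0, ankle_offset=5.0,
                      ankle_dorsi_stance_gain=10.0, stance_shift=5.0,
                      cadence_factor=0.80, speed_factor=0.60),
    "V": PatternSpec("V", pelvic_tilt_offset=9.0, double_hump_amp=4.0,
                     hip_extension_loss=8.0, knee_recurvatum=14.0,
                     knee_peak_attenuation=15.0, ankle_offset=-16.0,
                     forefoot_offset=-14.0, ankle_peak_delay=6.0, stance_shift=5.0,
                     cadence_factor=0.80, speed_factor=0.55),
    "VI": PatternSpec("VI", pelvic_tilt_offset=7.0, double_hump_amp=3.0,
                      hip_ic_extra=9.0, knee_ic_offset=20.0, knee_stance_offset=8.0,
                      knee_peak_delay=6.0, ankle_offset=-8.0, forefoot_offset=-8.0,
                      stance_shift=1.0, cadence_factor=0.97, speed_factor=0.95),
}


def _warp_peak(values: np.ndarray, delay: float, center: float, width: float) -> np.ndarray:
    """Delay a landmark peak by a smooth local time warp (monotone for
    delay/width well below 1)."""
    if delay == 0.0:
        return values
    shifted_t = _T - delay * np.exp(-0.5 * ((_T - center) / width) ** 2)
    # periodic extension for interpolation at the boundaries
    tt = np.concatenate([_T - 100.0, _T, _T + 100.0])
    vv = np.concatenate([values, values, values])
    return np.interp(shifted_t, tt, vv)


def apply_pattern(template: TemplateBundle, spec: PatternSpec,
                  severity: float = 1.0) -> TemplateBundle:
    """Apply one pattern's operators to the healthy template.

    Operators run in a fixed order: constant offsets, harmonic modulation,
    peak time shifts, event-locked edits, then spatio-temporal scaling.
    Severity 0 is the identity; deviations grow monotonically with severity.
    """
    if spec.pattern not in PATTERN_LIBRARY and spec.pattern != "outlier":
        raise ValueError(f"unknown pattern id {spec.pattern!r}")
    if severity < 0:
        raise ValueError("severity must be >= 0")
    s = severity
    ch = {k: v.copy() for k, v in template.channels.items()}

    # 1. constant offsets
    ch["pelvic_tilt"] += s * spec.pelvic_tilt_offset
    ch["hip_flexion"] += s * spec.hip_offset
    ch["ankle_dorsiflexion"] += s * spec.ankle_offset
    ch["forefoot_flexion"] += s * spec.forefoot_offset

    # 2. harmonic modulation (pelvic "double hump")
    ch["pelvic_tilt"] += s * spec.double_hump_amp * _harm(2.0, -0.4)

    # 3. peak time shifts
    ch["knee_flexion"] = _warp_peak(ch["knee_flexion"], s * spec.knee_peak_delay, 70.0, 15.0)
    ch["ankle_dorsiflexion"] = _warp_peak(ch["ankle_dorsiflexion"], s * spec.ankle_peak_delay, 63.0, 10.0)
    ch["forefoot_flexion"] = _warp_peak(ch["forefoot_flexion"], s * spec.ankle_peak_delay, 63.0, 10.0)

    # 4. event-locked edits
    ch["hip_flexion"] += s * spec.hip_extension_loss * _bump(47.0, 14.0)
    ch["hip_flexion"] += s * spec.hip_ic_extra * _bump(0.0, 12.0)
    ch["knee_flexion"] += s * spec.knee_ic_offset * _bump(0.0, 8.0)
    ch["knee_flexion"] += s * spec.knee_stance_offset * _bump(25.0, 16.0)
    ch["knee_flexion"] -= s * spec.knee_recurvatum * _bump(40.0, 10.0)
    ch["knee_flexion"] -= s * spec.knee_peak_attenuation * _bump(70.0 + s * spec.knee_peak_delay, 8.5)
    ch["ankle_dorsiflexion"] += s * spec.ankle_dorsi_stance_gain * _bump(40.0, 15.0)
    ch["ankle_dorsiflexion"] -= s * spec.ankle_pushoff_gain * _bump(63.0 + s * spec.ankle_peak_delay, 6.0)
    ch["forefoot_flexion"] -= s * spec.ankle_pushoff_gain * _bump(63.0 + s * spec.ankle_peak_delay, 6.5)

    # 5. spatio-temporal effects
    ev = template.events
    stance_scale = (ev.toe_off + s * spec.stance_shift) / ev.toe_off
    events = GaitEvents(
        opposite_toe_off=min(99.0, ev.opposite_toe_off * stance_scale),
        opposite_initial_contact=min(99.3, ev.opposite_initial_contact * stance_scale),
        toe_off=min(99.6, ev.toe_off * stance_scale),
    )
    cadence_factor = 1.0 - s * (1.0 - spec.cadence_factor)
    speed_factor = 1.0 - s * (1.0 - spec.speed_factor)
    stride_time = template.stride_time / max(cadence_factor, 0.05)
    norm_speed = (template.stride_length / template.stride_time / template.subject_height)
    stride_length = norm_speed * speed_factor * template.subject_height * stride_time
    return TemplateBundle(channels=ch, events=events, stride_time=stride_time,
                          stride_length=stride_length, subject_height=template.subject_height)


def _outlier_bundle(template: TemplateBundle) -> TemplateBundle:
    """Extreme stretched-stance cycle (prolonged stance, all peaks delayed)."""
    stretched = {}
    # warp the whole cycle so that the original toe-off lands at 85%
    src = np.where(_T <= 85.0, _T * 60.0 / 85.0, 60.0 + (_T - 85.0) * 40.0 / 15.0)
    for name, vals in template.channels.items():
        stretched[name] = np.interp(src, _T, vals)
    stretched["pelvic_tilt"] = stretched["pelvic_tilt"] + 15.0
    events = GaitEvents(opposite_toe_off=14.0, opposite_initial_contact=71.0, toe_off=85.0)
    return TemplateBundle(channels=stretched, events=events,
                          stride_time=template.stride_time * 1.6,
                          stride_length=template.stride_length * 0.5,
                          subject_height=template.subject_height)


#: Per-pattern clinical coupling: P(GMFCS II-III), P(polyneuropathy),
#: P(abnormal VEP), P(thin corpus callosum), age range (years).
CLINICAL_COUPLING: dict[str, tuple[float, float, float, float, tuple[float, float]]] = {
    "I": (0.08, 0.30, 0.20, 0.15, (4.0, 17.0)),
    "II": (0.80, 0.35, 0.25, 0.40, (4.0, 14.0)),
    "III": (0.75, 0.65, 0.55, 0.60, (6.0, 16.8)),
    "IV": (0.80, 0.05, 0.05, 0.20, (7.7, 16.2)),
    "V": (0.90, 0.30, 0.05, 0.20, (13.0, 15.0)),
    "VI": (0.70, 0.30, 0.20, 0.20, (4.0, 5.1)),
}


@dataclass(frozen=True)
class CohortConfig:
    """Study-design knobs of the synthetic HSP cohort.

    Defaults emulate the published cohort structure: 26 subjects, six
    patterns with the published prevalence ordering, 65.4% of subjects using
    a single pattern, 27% a different pattern per limb and ~8% two patterns
    in one limb, up to five cycles per limb, and one planted stretched-stance
    outlier cycle.
    """

    n_subjects: int = 26
    pattern_weights: Mapping[str, float] = field(default_factory=lambda: {
        "I": 0.42, "II": 0.22, "III": 0.12, "IV": 0.12, "V": 0.05, "VI": 0.07,
    })
    usage_class_probs: tuple[float, float, float] = (0.654, 0.27, 0.076)
    min_cycles_per_limb: int = 3
    max_cycles_per_limb: int = 5
    subject_sd: float = 2.0          # per-channel subject random intercept (deg)
    cycle_noise_sd: float = 1.5      # smooth within-cycle noise (deg)
    event_jitter_sd: float = 0.8     # % of cycle
    severity_jitter_sd: float = 0.08
    include_outlier: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        w = sum(self.pattern_weights.values())
        if not np.isclose(w, 1.0):
            raise ValueError(f"pattern weights must sum to 1, got {w}")
        if not np.isclose(sum(self.usage_class_probs), 1.0):
            raise ValueError("usage class probabilities must sum to 1")
        if not (1 <= self.min_cycles_per_limb <= self.max_cycles_per_limb <= 5):
            raise ValueError("cycles per limb must satisfy 1 <= min <= max <= 5")


def _smooth_noise(rng: np.random.Generator, sd: float) -> np.ndarray:
    raw = rng.standard_normal(len(_T))
    smooth = gaussian_filter1d(raw, sigma=8.0, mode="wrap")
    std = smooth.std()
    return smooth * (sd / std) if std > 0 else smooth


def _bundle_to_cycle(bundle: TemplateBundle, cycle_id: str, subject_id: str,
                     side: str, rng: np.random.Generator, subject_offsets: Mapping[str, float],
                     noise_sd: float, event_jitter_sd: float) -> GaitCycle:
    channels = {}
    for name in CHANNEL_VOCABULARY:
        vals = bundle.channels[name] + subject_offsets[name] + _smooth_noise(rng, noise_sd)
        channels[name] = AngleSeries(channel=name, values=vals)
    ev = bundle.events
    for _ in range(20):  # rejection-sample jitter preserving event ordering
        jit = rng.normal(0.0, event_jitter_sd, size=3)
        oto, oic, to = ev.opposite_toe_off + jit[0], ev.opposite_initial_contact + jit[1], ev.toe_off + jit[2]
        if 0.0 < oto < oic < to < 100.0:
            break
    else:
        oto, oic, to = ev.opposite_toe_off, ev.opposite_initial_contact, ev.toe_off
    stride_time = bundle.stride_time * float(np.exp(rng.normal(0.0, 0.03)))
    stride_length = bundle.stride_length * float(np.exp(rng.normal(0.0, 0.03)))
    return GaitCycle(
        cycle_id=cycle_id, subject_id=subject_id, side=side, channels=channels,
        events=GaitEvents(opposite_toe_off=float(oto), opposite_initial_contact=float(oic),
                          toe_off=float(to)),
        stride_time=stride_time, stride_length=stride_length,
        subject_height=bundle.subject_height,
    )


def _draw_flag(rng: np.random.Generator, p: float) -> str:
    return "yes" if rng.random() < p else "no"


def generate_cohort(config: CohortConfig | None = None):
    """Generate an HSP cohort: (cycles, clinical records, ground-truth table).

    The ground truth is a DataFrame with one row per cycle (cycle_id,
    subject_id, side, pattern, usage class of the subject); the planted
    outlier cycle carries pattern label ``"outlier"``.
    """
    import pandas as pd

    config = config or CohortConfig()
    rng = np.random.default_rng(config.seed)
    patterns = list(config.pattern_weights)
    weights = np.array([config.pattern_weights[p] for p in patterns])

    cycles: list[GaitCycle] = []
    records: list[ClinicalRecord] = []
    truth_rows: list[dict] = []

    for s in range(config.n_subjects):
        subject_id = f"P{s + 1:02d}"
        usage = rng.choice(3, p=config.usage_class_probs)
        primary = str(rng.choice(patterns, p=weights))
        if usage == 0:
            side_patterns = {"left": [primary], "right": [primary]}
            usage_class = "single pattern"
        elif usage == 1:
            other = str(rng.choice([p for p in patterns if p != primary]))
            side_patterns = {"left": [primary], "right": [other]}
            usage_class = "different pattern per limb"
        else:
            other = str(rng.choice([p for p in patterns if p != primary]))
            mixed_side = str(rng.choice(["left", "right"]))
            plain_side = "right" if mixed_side == "left" else "left"
            side_patterns = {mixed_side: [primary, other], plain_side: [primary]}
            usage_class = "two patterns in one limb"

        gm_p, pnp_p, vep_p, tcc_p, (age_lo, age_hi) = CLINICAL_COUPLING[primary]
        age = float(rng.uniform(age_lo, age_hi))
        gmfcs = "I" if rng.random() >= gm_p else str(rng.choice(["II", "III"], p=[0.8, 0.2]))
        # GMFCS grades overall severity: II-III subjects express their pattern
        # more strongly than GMFCS-I subjects using the same pattern
        severity_mean = 0.92 if gmfcs == "I" else 1.12
        records.append(ClinicalRecord(
            subject_id=subject_id, age=round(age, 1),
            sex=str(rng.choice(["female", "male"])),
            gmfcs=gmfcs,
            polyneuropathy=_draw_flag(rng, pnp_p),
            abnormal_vep=_draw_flag(rng, vep_p),
            thin_corpus_callosum=_draw_flag(rng, tcc_p),
            condition="HSP",
        ))
        template = healthy_template(age=age)
        offsets = {name: float(rng.normal(0.0, config.subject_sd)) for name in CHANNEL_VOCABULARY}
        severity = float(np.clip(rng.normal(severity_mean, config.severity_jitter_sd), 0.85, 1.25))
        for side, pats in side_patterns.items():
            n_cyc = int(rng.integers(config.min_cycles_per_limb, config.max_cycles_per_limb + 1))
            # when a limb uses two patterns, split its cycles between them
            assignment = [pats[0]] * n_cyc
            if len(pats) == 2:
                n_second = max(1, n_cyc // 2)
                for i in range(n_second):
                    assignment[n_cyc - 1 - i] = pats[1]
            for k, pat in enumerate(assignment):
                bundle = apply_pattern(template, PATTERN_LIBRARY[pat], severity=severity)
                cid = f"{subject_id}_{side[0].upper()}{k + 1}"
                cycles.append(_bundle_to_cycle(bundle, cid, subject_id, side, rng, offsets,
                                               config.cycle_noise_sd, config.event_jitter_sd))
                truth_rows.append({"cycle_id": cid, "subject_id": subject_id, "side": side,
                                   "pattern": pat, "usage_class": usage_class})

    if config.include_outlier:
        subject_id = records[-1].subject_id
        template = healthy_template(age=records[-1].age)
        bundle = _outlier_bundle(template)
        offsets = {name: 0.0 for name in CHANNEL_VOCABULARY}
        cid = f"{subject_id}_OUT"
        cycles.append(_bundle_to_cycle(bundle, cid, subject_id, "left", rng, offsets,
                                       config.cycle_noise_sd, config.event_jitter_sd))
        truth_rows.append({"cycle_id": cid, "subject_id": subject_id, "side": "left",
                           "pattern": "outlier",
                           "usage_class": truth_rows[-1]["usage_class"]})

    truth = pd.DataFrame(truth_rows)
    return cycles, records, truth


def generate_healthy_cohort(n_subjects: int = 33, seed: int = 0,
                            min_cycles_per_limb: int = 3, max_cycles_per_limb: int = 5,
                            subject_sd: float = 2.0, cycle_noise_sd: float = 1.5):
    """Generate a healthy control cohort: (cycles, clinical records)."""
    rng = np.random.default_rng(seed)
    cycles: list[GaitCycle] = []
    records: list[ClinicalRecord] = []
    for s in range(n_subjects):
        subject_id = f"H{s + 1:02d}"
        age = float(rng.uniform(4.0, 16.0))
        records.append(ClinicalRecord(
            subject_id=subject_id, age=round(age, 1),
            sex=str(rng.choice(["female", "male"])),
            gmfcs="I", polyneuropathy="no", abnormal_vep="no",
            thin_corpus_callosum="no", condition="healthy",
        ))
        template = healthy_template(age=age)
        offsets = {name: float(rng.normal(0.0, subject_sd)) for name in CHANNEL_VOCABULARY}
        for side in ("left", "right"):
            n_cyc = int(rng.integers(min_cycles_per_limb, max_cycles_per_limb + 1))
            for k in range(n_cyc):
                cid = f"{subject_id}_{side[0].upper()}{k + 1}"
                cycles.append(_bundle_to_cycle(template, cid, subject_id, side, rng, offsets,
                                               cycle_noise_sd, 0.8))
    return cycles, records
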