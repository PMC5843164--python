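import numpy as np
import pandas as pd
import pytest

import gaitpheno as gp
from gaitpheno.params import extract_parameters
from gaitpheno.synth import (
    CLINICAL_COUPLING,
    PATTERN_LIBRARY,
    CohortConfig,
    _bundle_to_cycle,
    apply_pattern,
    generate_cohort,
    generate_healthy_cohort,
    healthy_template,
)


def _template_params(bundle, cycle_id="t"):
    channels = {name: gp.AngleSeries(channel=name, values=vals)
                for name, vals in bundle.channels.items()}
    cycle = gp.GaitCycle(cycle_id=cycle_id, subject_id="s", side="left",
                         channels=channels, events=bundle.events,
                         stride_time=bundle.stride_time,
                         stride_length=bundle.stride_length,
                         subject_height=bundle.subject_height)
    return extract_parameters(cycle)


class TestHealthyTemplate:
    def test_physiologic_landmarks(self):
        p = _template_params(healthy_template())
        assert 0.0 <= p["knee_flexion_at_initial_contact"] <= 10.0
        assert 55.0 <= p["max_knee_flexion"] <= 70.0
        assert 60.0 <= p["time_to_peak_knee_flexion"] <= 75.0
        assert p["min_ankle_dorsiflexion_in_stance"] < -5.0   # push-off plantarflexion
        assert p["stance_pct"] == pytest.approx(60.0, abs=2.0)

    def test_deterministic(self):
        a, b = healthy_template(age=9.0), healthy_template(age=9.0)
        for name in a.channels:
            assert np.array_equal(a.channels[name], b.channels[name])

    def test_speed_and_cadence_decline_with_age(self):
        young, old = healthy_template(age=5.0), healthy_template(age=15.0)
        speed = lambda t: t.stride_length / t.stride_time / t.subject_height
        assert speed(young) - speed(old) == pytest.approx(0.05 * 10, rel=1e-6)
        assert 2.0 / young.stride_time > 2.0 / old.stride_time


class TestApplyPattern:
    def test_severity_zero_is_identity(self):
        base = healthy_template()
        out = apply_pattern(base, PATTERN_LIBRARY["V"], severity=0.0)
        for name in base.channels:
            assert np.allclose(out.channels[name], base.channels[name])
        assert out.stride_time == pytest.approx(base.stride_time)
        assert out.events.toe_off == pytest.approx(base.events.toe_off)

    def test_unknown_pattern_rejected(self):
        with pytest.raises(ValueError):
            apply_pattern(healthy_template(), gp.PatternSpec("VII"), 1.0)

    def test_pattern_ii_signature_directions(self):
        base = _template_params(healthy_template())
        p = _template_params(apply_pattern(healthy_template(), PATTERN_LIBRARY["II"], 1.0))
        assert p["mean_pelvic_tilt"] > base["mean_pelvic_tilt"]
        assert p["hip_flexion_at_initial_contact"] > base["hip_flexion_at_initial_contact"]
        assert p["knee_flexion_at_initial_contact"] > base["knee_flexion_at_initial_contact"]

    def test_pattern_v_equinus_and_recurvatum(self):
        base = _template_params(healthy_template())
        p = _template_params(apply_pattern(healthy_template(), PATTERN_LIBRARY["V"], 1.0))
        assert p["min_ankle_dorsiflexion_in_stance"] < base["min_ankle_dorsiflexion_in_stance"]
        assert p["min_knee_flexion_in_stance"] < 0.0   # hyperextension
        assert p["mean_pelvic_tilt"] > base["mean_pelvic_tilt"]

    def test_pattern_iv_crouch_directions(self):
        base = _template_params(healthy_template())
        p = _template_params(apply_pattern(healthy_template(), PATTERN_LIBRARY["IV"], 1.0))
        assert p["min_knee_flexion_in_stance"] > base["min_knee_flexion_in_stance"]
        assert p["max_knee_flexion"] < base["max_knee_flexion"]
        assert p["time_to_peak_knee_flexion"] > base["time_to_peak_knee_flexion"]
        assert p["normalized_walking_speed"] < base["normalized_walking_speed"]

    @pytest.mark.parametrize("pattern", list(PATTERN_LIBRARY))
    def test_severity_monotone_deviation(self, pattern):
        """Signature-parameter deviation from the template never shrinks as
        severity grows."""
        base = _template_params(healthy_template())
        severities = [0.5, 1.0, 1.5]
        checks = {
            "I": ["mean_pelvic_tilt", "time_to_peak_knee_flexion"],
            "II": ["mean_pelvic_tilt", "hip_flexion_at_initial_contact",
                   "knee_flexion_at_initial_contact"],
            "III": ["min_knee_flexion_in_stance", "max_knee_flexion"],
            "IV": ["knee_flexion_at_initial_contact", "normalized_walking_speed"],
            "V": ["min_ankle_dorsiflexion_in_stance", "mean_pelvic_tilt"],
            "VI": ["knee_flexion_at_initial_contact", "hip_flexion_at_initial_contact"],
        }[pattern]
        devs = []
        for s in severities:
            p = _template_params(apply_pattern(healthy_template(), PATTERN_LIBRARY[pattern], s))
            devs.append([abs(p[k] - base[k]) for k in checks])
        devs = np.array(devs)
        assert np.all(np.diff(devs, axis=0) >= -1e-9)


class TestGenerateCohort:
    def test_single_subject_single_pattern(self):
        cfg = CohortConfig(n_subjects=1, pattern_weights={"III": 1.0},
                           usage_class_probs=(1.0, 0.0, 0.0),
                           min_cycles_per_limb=5, max_cycles_per_limb=5,
                           include_outlier=False, seed=0)
        cycles, records, truth = generate_cohort(cfg)
        assert len(cycles) == 10
        assert (truth["pattern"] == "III").all()
        assert len(records) == 1

    def test_all_cycles_pass_validation(self, small_cohort):
        cycles, _, _ = small_cohort
        for c in cycles:   # GaitCycle.__post_init__ re-validates
            gp.GaitCycle(cycle_id=c.cycle_id, subject_id=c.subject_id, side=c.side,
                         channels=c.channels, events=c.events, stride_time=c.stride_time,
                         stride_length=c.stride_length, subject_height=c.subject_height)

    def test_reproducible_given_seed(self):
        cfg = CohortConfig(n_subjects=4, seed=11)
        c1, r1, t1 = generate_cohort(cfg)
        c2, r2, t2 = generate_cohort(cfg)
        assert [c.cycle_id for c in c1] == [c.cycle_id for c in c2]
        for a, b in zip(c1, c2):
            assert np.array_equal(a.angles("knee_flexion"), b.angles("knee_flexion"))
        pd.testing.assert_frame_equal(t1, t2)

    def test_usage_class_fractions_near_configured(self):
        counts = {"single pattern": 0, "different pattern per limb": 0,
                  "two patterns in one limb": 0}
        n_subj = 0
        for seed in range(6):
            _, _, truth = generate_cohort(CohortConfig(n_subjects=26, seed=seed))
            per_subject = truth[truth["pattern"] != "outlier"].groupby(
                "subject_id")["usage_class"].first()
            for cls, n in per_subject.value_counts().items():
                counts[cls] += n
            n_subj += len(per_subject)
        frac = counts["single pattern"] / n_subj
        # binomial(156, 0.654) 3-sigma band
        assert abs(frac - 0.654) < 3 * np.sqrt(0.654 * 0.346 / n_subj)

    def test_outlier_planted_with_prolonged_stance(self, small_cohort):
        cycles, _, truth = small_cohort
        out_id = truth.loc[truth["pattern"] == "outlier", "cycle_id"].iloc[0]
        out_cycle = next(c for c in cycles if c.cycle_id == out_id)
        assert out_cycle.events.toe_off > 80.0

    def test_healthy_cohort_flags_clean(self, small_healthy):
        cycles, records = small_healthy
        assert all(r.condition == "healthy" for r in records)
        assert all(r.polyneuropathy == "no" for r in records)
        assert len({c.subject_id for c in cycles}) == len(records)

    def test_mild_pattern_near_healthy_severe_patterns_far(self):
        """Mild cycles sit within ~1 SD of healthy means for most parameters;
        crouch/equinus cycles deviate by multiple SDs on their signatures."""
        h_cycles, _ = generate_healthy_cohort(n_subjects=20, seed=3)
        hpm = gp.extract_matrix(h_cycles)
        ref = gp.HealthyReference.from_matrix(hpm)
        cfg = CohortConfig(n_subjects=8, pattern_weights={"I": 0.5, "IV": 0.25, "V": 0.25},
                           usage_class_probs=(1.0, 0.0, 0.0), include_outlier=False, seed=4)
        cycles, _, truth = generate_cohort(cfg)
        pm = gp.extract_matrix(cycles)
        z = gp.zscore_matrix(pm, ref).abs()
        lab = truth.set_index("cycle_id")["pattern"]
        mild = z.loc[lab[lab == "I"].index]
        if len(mild):
            assert (mild.median(axis=0) < 1.5).mean() > 0.6
        severe = z.loc[lab[lab.isin(["IV", "V"])].index]
        if len(severe):
            sig = ["knee_flexion_at_initial_contact", "min_ankle_dorsiflexion_in_stance",
                   "min_knee_flexion_in_stance", "normalized_walking_speed"]
            assert severe[sig].abs().max(axis=1).min() > 2.0
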