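"""Generator contracts: closed forms, determinism, built-in couplings."""

import numpy as np
import pytest

from scapkin import (GeneratorConfig, ScapkinError, generate_cohort,
                     generate_svic, generate_trial, minimum_jerk_segment,
                     svic_reference)
from scapkin.core import MUSCLES, PHASES
from scapkin.synthetic import (_wiggle, _wiggle_d1, _wiggle_d2,
                               minimum_jerk_acceleration, minimum_jerk_velocity)
from conftest import quiet_config


class TestMinimumJerkSegment:
    def test_midpoint_symmetry(self):
        seg = minimum_jerk_segment(2.0, 1.0, 100.0)
        assert seg.samples[50] == pytest.approx(1.0)
        assert seg.samples[0] == 0.0
        assert seg.samples[-1] == pytest.approx(2.0)

    def test_peak_velocity_closed_form(self):
        # v_max = 1.875 A / D at tau = 1/2
        amp, dur, rate = 0.45, 1.2, 2000.0
        seg = minimum_jerk_segment(amp, dur, rate)
        v = np.gradient(seg.samples, 1.0 / rate)
        assert np.max(v) == pytest.approx(1.875 * amp / dur, rel=1e-5)

    def test_peak_acceleration_location(self):
        # argmax of the acceleration at tau = (3 - sqrt(3)) / 6 ~ 0.21132
        amp, dur, rate = 0.45, 1.0, 2000.0
        seg = minimum_jerk_segment(amp, dur, rate)
        a = np.gradient(np.gradient(seg.samples, 1 / rate), 1 / rate)
        tau_peak = (5 + np.argmax(a[5:-5])) / (seg.n - 1)
        assert tau_peak == pytest.approx((3 - np.sqrt(3)) / 6, abs=2e-3)

    def test_zero_end_velocity_and_acceleration(self):
        tau = np.array([0.0, 1.0])
        assert np.allclose(minimum_jerk_velocity(tau, 1.0, 1.0), 0.0)
        assert np.allclose(minimum_jerk_acceleration(tau, 1.0, 1.0), 0.0)

    def test_invalid_arguments(self):
        with pytest.raises(ScapkinError):
            minimum_jerk_segment(1.0, 0.0, 100.0)
        with pytest.raises(ScapkinError):
            minimum_jerk_segment(1.0, 1.0, -5.0)


class TestWiggleDerivatives:
    """The perturbation primitive's analytic derivatives match numerics."""

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_first_and_second_derivative(self, k):
        u = np.linspace(0, 1, 20001)
        du = u[1] - u[0]
        w = _wiggle(u, k)
        assert np.allclose(np.gradient(w, du)[5:-5], _wiggle_d1(u, k)[5:-5],
                           atol=1e-4)
        assert np.allclose(np.gradient(_wiggle_d1(u, k), du)[5:-5],
                           _wiggle_d2(u, k)[5:-5], atol=1e-3)


class TestGenerateTrial:
    def test_determinism_bit_identical(self, default_cfg):
        r1, t1 = generate_trial(default_cfg, "S03", 2, "M1")
        r2, t2 = generate_trial(default_cfg, "S03", 2, "M1")
        assert r1.kin.equals(r2.kin) and r1.hf.equals(r2.hf)
        assert t1.segmentation == t2.segmentation
        assert t1.metrics.values == t2.metrics.values

    def test_noise_free_boundaries_on_sample_grid(self, quiet_trial, quiet_cfg):
        _, truth = quiet_trial
        detected = np.array(truth.segmentation.as_tuple())
        nominal = np.array(truth.nominal_boundaries)
        # interior kinematic events land within ~2 kinematic samples of the
        # construction boundaries (zero-phase smoothing bias documented)
        assert np.all(np.abs(detected[1:5] - nominal[1:5]) <= 0.04)
        # threshold events fire near the nominal movement start/end
        assert abs(detected[0] - nominal[0]) < 0.05
        assert abs(detected[5] - nominal[5]) < 0.05

    def test_shr_coupling_built_in(self, quiet_trial):
        _, truth = quiet_trial
        assert truth.metrics["shr"] == pytest.approx(1.5, abs=1e-9)

    def test_rom_ground_truth_matches_configured_amplitudes(self, quiet_trial,
                                                            quiet_cfg):
        _, truth = quiet_trial
        for i, phase in enumerate(PHASES):
            expected = quiet_cfg.rom_true["scap_ab_ad"][i]
            measured = truth.metrics[f"rom_scap_ab_ad_{phase}"]
            assert measured == pytest.approx(expected, rel=5e-3), phase

    def test_emg_plateau_recovered_for_narrow_transitions(self):
        # with near-instant transitions the phase mean equals the plateau
        cfg = quiet_config(seed=4)
        cfg = GeneratorConfig(**{**cfg.__dict__, "emg_transition_s": 0.01})
        _, truth = generate_trial(cfg, "S01", 1, "M0")
        for i, phase in enumerate(PHASES):
            level = cfg.emg_level_true["MT"][i]
            # residual deviation comes from the envelope block-mean and the
            # inclusive window edges, both O(|level step| / samples-per-phase)
            assert truth.metrics[f"emg_MT_{phase}"] == pytest.approx(
                level, abs=0.3), phase

    def test_trunk_peak_is_ground_truth(self, quiet_trial, quiet_cfg):
        _, truth = quiet_trial
        for dof, peak in quiet_cfg.trunk_peaks.items():
            assert truth.metrics[f"trunk_comp_{dof}"] == pytest.approx(
                peak, abs=1e-3), dof

    def test_rest_angles_recovered(self, quiet_trial, quiet_cfg):
        _, truth = quiet_trial
        for dof, value in quiet_cfg.scap_rest.items():
            assert truth.metrics[f"rest_{dof}"] == pytest.approx(value, abs=1e-6)

    def test_session_effect_applied_at_m1_only(self):
        from scapkin import EffectSpec
        eff = EffectSpec(emg={("MT", "drink"): -5.0})
        cfg = GeneratorConfig(**{**quiet_config(5).__dict__, "effect_delta": eff})
        _, t0 = generate_trial(cfg, "S01", 1, "M0")
        _, t1 = generate_trial(cfg, "S01", 1, "M1")
        assert t1.emg_levels[("MT", "drink")] - t0.emg_levels[("MT", "drink")] \
            == pytest.approx(-5.0)
        assert t1.emg_levels[("MT", "reaching")] == t0.emg_levels[("MT", "reaching")]

    def test_bad_phase_durations_rejected(self):
        with pytest.raises(ScapkinError, match="5 entries"):
            GeneratorConfig(phase_durations=(1.0, 1.0, 1.0))

    def test_rest_accel_well_inside_band(self, default_cfg):
        rec, _ = generate_trial(default_cfg, "S01", 1, "M0")
        rest = rec.hf["hand_accel"].to_numpy()[: int(5 * rec.hf_rate)]
        assert np.percentile(np.abs(rest), 99.9) < 0.3


class TestGenerateSvic:
    def test_noise_free_reference_equals_amplitude(self, quiet_cfg):
        rec = generate_svic(quiet_cfg, "UT")
        assert svic_reference(rec) == pytest.approx(
            quiet_cfg.svic_amplitude["UT"])

    def test_three_reps_of_five_seconds(self, default_cfg):
        rec = generate_svic(default_cfg, "LS")
        assert len(rec.repetitions) == 3
        assert all(r.duration == pytest.approx(5.0) for r in rec.repetitions)

    def test_seeded_reference_reproducible(self, default_cfg):
        r1 = svic_reference(generate_svic(default_cfg, "MT"))
        r2 = svic_reference(generate_svic(default_cfg, "MT"))
        assert r1 == r2

    def test_unknown_muscle_rejected(self, default_cfg):
        with pytest.raises(ScapkinError):
            generate_svic(default_cfg, "biceps")


class TestGenerateCohort:
    def test_structure_and_ledger(self):
        cfg = GeneratorConfig(seed=9, n_subjects=2, n_trials_per_subject=3)
        cohort = generate_cohort(cfg)
        assert sorted(cohort.trials) == [
            ("S01", "M0"), ("S01", "M1"), ("S02", "M0"), ("S02", "M1")]
        assert all(len(b) == 3 for b in cohort.trials.values())
        assert set(cohort.svic["S01"]) == set(MUSCLES)
        metric_rows = cohort.ledger[cohort.ledger.kind == "metric"]
        assert len(metric_rows) > 0

    def test_cohort_of_one_generates_but_stats_refuse(self):
        from scapkin import RunConfig, run_study
        cfg = GeneratorConfig(seed=9, n_subjects=1)
        cohort = generate_cohort(cfg)
        assert cohort.subjects == ["S01"]
        with pytest.raises(ScapkinError, match="at least 2 subjects"):
            run_study(RunConfig(generator=cfg), cohort=cohort)
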