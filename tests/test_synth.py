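import numpy as np
import pytest

from gazemend.correction import clean_recording, detect_artifacts
from gazemend.detection import BLINK, DISPLACEMENT, SPIKE, ArtifactInterval, compute_velocity, detect_blink_intervals
from gazemend.geometry import DEFAULT_GEOMETRY
from gazemend.synth import (
    ArtifactSpec,
    SynthError,
    generate_blink_protocol,
    generate_fixation_trace,
    generate_group_session,
    generate_spiral_trace,
    inject_artifacts,
    rmse,
    score_against_truth,
)


class TestFixationTrace:
    def test_zero_noise_is_constant(self):
        rec = generate_fixation_trace(1000, target=(100, 200), noise_sd=0.0, seed=0)
        assert np.all(rec.x == 100.0) and np.all(rec.y == 200.0)

    def test_same_seed_reproduces(self):
        a = generate_fixation_trace(2000, seed=42)
        b = generate_fixation_trace(2000, seed=42)
        assert np.array_equal(a.x, b.x) and np.array_equal(a.y, b.y)

    def test_sample_sd_consistent_with_parameter(self):
        rec = generate_fixation_trace(60_000, noise_sd=2.0, seed=3)
        assert rec.x.std() == pytest.approx(2.0, rel=0.05)
        assert rec.y.std() == pytest.approx(2.0, rel=0.05)


class TestSpiralTrace:
    def test_starts_at_screen_centre(self):
        rec = generate_spiral_trace(seed=0)
        assert rec.x[0] == pytest.approx(840.0) and rec.y[0] == pytest.approx(525.0)

    def test_radius_nondecreasing_and_on_screen(self):
        rec = generate_spiral_trace(seed=0)
        r = np.hypot(rec.x - 840.0, rec.y - 525.0)
        assert np.all(np.diff(r) >= -1e-9)
        assert rec.x.min() >= 0 and rec.x.max() < 1680
        assert rec.y.min() >= 0 and rec.y.max() < 1050

    def test_speed_stays_below_limit(self):
        rec = generate_spiral_trace(max_speed_px_per_ms=2.0)
        vel = compute_velocity(rec)
        assert np.nanmax(vel.speed[1:]) <= 2.0

    def test_cleaning_the_pure_spiral_is_identity(self):
        rec = generate_spiral_trace(seed=0)
        out, report = clean_recording(rec)
        assert out.equals(rec)
        assert report.all_zero()

    def test_overspeed_configuration_rejected(self):
        with pytest.raises(SynthError):
            generate_spiral_trace(duration_ms=2000, turns=20, max_speed_px_per_ms=1.0)


class TestBlinkProtocol:
    def test_twenty_blinks_in_twenty_seconds(self):
        truth = generate_blink_protocol(seed=1)
        assert len(truth.artifacts) == 20
        assert all(iv.kind == BLINK for iv in truth.artifacts)

    def test_detector_recovers_every_null_run(self):
        truth = generate_blink_protocol(noise_sd=0.0, seed=4)
        detected = detect_blink_intervals(truth.dirty)
        assert len(detected) == len(truth.artifacts)
        for d, g in zip(detected, truth.artifacts):
            assert d.start_ms == g.start_ms and d.end_ms == g.end_ms

    def test_cleaned_trace_has_no_invalid_samples(self):
        truth = generate_blink_protocol(seed=5)
        out, _ = clean_recording(truth.dirty)
        assert out.valid.all()

    def test_excessive_blink_rate_rejected(self):
        with pytest.raises(SynthError):
            generate_blink_protocol(blink_rate_hz=4.0)


class TestInjectArtifacts:
    def test_empty_spec_is_identity(self):
        clean = generate_fixation_trace(5000, seed=0)
        truth = inject_artifacts(clean, ArtifactSpec(), seed=1)
        assert truth.dirty.equals(clean)
        assert truth.artifacts == []

    def test_dirty_differs_only_inside_padded_truth(self):
        clean = generate_fixation_trace(30_000, noise_sd=0.0, seed=2)
        spec = ArtifactSpec(n_spikes=3, n_displacements=2, n_blinks=2, blink_excursion_ms=100.0)
        truth = inject_artifacts(clean, spec, seed=3)
        changed = (truth.dirty.x != clean.x) | (truth.dirty.y != clean.y) | ~truth.dirty.valid
        allowed = np.zeros(len(clean), bool)
        for iv in truth.artifacts:
            pad = spec.blink_excursion_ms if iv.kind == BLINK else 0.0
            allowed |= (clean.t >= iv.start_ms - pad) & (clean.t < iv.end_ms + pad)
        assert not np.any(changed & ~allowed)
        assert changed.any()

    def test_displacement_is_constant_offset(self):
        # per-interval difference oracle: inside a displacement the
        # dirty-minus-clean difference is one constant vector
        clean = generate_fixation_trace(20_000, noise_sd=0.0, seed=4)
        truth = inject_artifacts(clean, ArtifactSpec(n_displacements=2, disp_offset_px=80.0), seed=5)
        for iv in truth.artifacts:
            m = (clean.t >= iv.start_ms) & (clean.t < iv.end_ms)
            dx = truth.dirty.x[m] - clean.x[m]
            dy = truth.dirty.y[m] - clean.y[m]
            assert np.allclose(dx, dx[0]) and np.allclose(dy, dy[0])
            assert np.hypot(dx[0], dy[0]) == pytest.approx(80.0)

    def test_truth_and_clean_share_timestamps(self):
        clean = generate_fixation_trace(10_000, seed=6)
        truth = inject_artifacts(clean, ArtifactSpec(n_blinks=3), seed=7)
        assert np.array_equal(truth.clean.t, truth.dirty.t)

    def test_unplaceable_request_rejected(self):
        clean = generate_fixation_trace(3000, seed=8)
        with pytest.raises(SynthError):
            inject_artifacts(clean, ArtifactSpec(n_blinks=30), seed=9)

    def test_every_injection_is_detected_by_construction(self):
        clean = generate_fixation_trace(60_000, noise_sd=1.0, seed=10)
        truth = inject_artifacts(clean, ArtifactSpec(n_spikes=5, n_displacements=3, n_blinks=5), seed=11)
        score = score_against_truth(detect_artifacts(truth.dirty), truth.artifacts)
        assert score.precision == 1.0 and score.recall == 1.0


class TestGroupSession:
    def test_full_adherence_no_artifacts(self):
        sessions = generate_group_session(
            n_subjects=2,
            adherence={"AJ": 1.0, "NOAJ": 1.0, "Center": 1.0},
            trial_sd=0.0,
            subject_sd=0.0,
            noise_sd=0.0,
            rate_hz=100,
            seed=1,
        )
        assert len(sessions) == 2
        for s in sessions:
            assert s.dirty.equals(s.clean)
            assert s.clean.valid.all()

    def test_determinism_across_runs(self):
        a = generate_group_session(n_subjects=2, rate_hz=100, seed=9)
        b = generate_group_session(n_subjects=2, rate_hz=100, seed=9)
        for sa, sb in zip(a, b):
            assert np.array_equal(sa.clean.x, sb.clean.x)

    def test_genuine_motion_never_crosses_threshold(self):
        sessions = generate_group_session(n_subjects=1, rate_hz=1000, seed=3)
        vel = compute_velocity(sessions[0].clean)
        assert np.nanmax(vel.speed[1:]) < 40.0


class TestScoring:
    def test_perfect_detection(self):
        ivs = [ArtifactInterval(kind=SPIKE, start_ms=10.0, end_ms=12.0)]
        score = score_against_truth(ivs, ivs)
        assert score.precision == 1.0 and score.recall == 1.0

    def test_empty_detection_flagged(self):
        truth = [ArtifactInterval(kind=BLINK, start_ms=5.0, end_ms=50.0)]
        score = score_against_truth([], truth)
        assert score.recall == 0.0
        assert score.precision == 1.0 and score.precision_undefined

    def test_kind_mismatch_does_not_match(self):
        det = [ArtifactInterval(kind=SPIKE, start_ms=10.0, end_ms=12.0)]
        tru = [ArtifactInterval(kind=DISPLACEMENT, start_ms=10.0, end_ms=12.0)]
        score = score_against_truth(det, tru)
        assert score.n_matched == 0

    def test_rmse_zero_for_identical(self):
        rec = generate_fixation_trace(1000, seed=0)
        assert rmse(rec, rec.copy()) == 0.0
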