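import numpy as np
import pytest

from gazemend.correction import (
    UncorrectableError,
    clean_recording,
    correct_blink,
    correct_displacement,
    correct_spike,
)
from gazemend.detection import BLINK, DISPLACEMENT, SPIKE, ArtifactInterval, compute_velocity
from gazemend.synth import ArtifactSpec, generate_blink_protocol, generate_fixation_trace, inject_artifacts, rmse

from conftest import make_recording


def spike_interval(start, end):
    return ArtifactInterval(kind=SPIKE, start_ms=start, end_ms=end)


class TestCorrectSpike:
    def make_spiked(self):
        x = np.full(20, 840.0)
        y = np.full(20, 520.0)
        x[8:10] = 1500.0
        return make_recording(x, y)

    @pytest.mark.parametrize("mode", ["post", "pre", "bridge"])
    def test_constant_trace_recovered_in_any_mode(self, mode):
        rec = self.make_spiked()
        rec.x[10:] = 900.0  # post anchor differs from pre
        out = correct_spike(rec, spike_interval(8.0, 10.0), mode=mode)
        assert np.all(out.x[:8] == rec.x[:8])
        assert np.all(out.x[10:] == rec.x[10:])
        if mode == "post":
            assert np.all(out.x[8:10] == 900.0) and np.all(out.y[8:10] == 520.0)
        elif mode == "pre":
            assert np.all(out.x[8:10] == 840.0)
        else:
            assert np.all(np.diff(out.x[7:11]) == pytest.approx(np.diff(out.x[7:11])[0]))

    def test_out_of_interval_samples_untouched(self):
        rec = self.make_spiked()
        out = correct_spike(rec, spike_interval(8.0, 10.0))
        outside = np.ones(20, bool)
        outside[8:10] = False
        assert np.array_equal(out.x[outside], rec.x[outside])
        assert np.array_equal(out.t, rec.t)

    def test_spike_at_record_end_uncorrectable_in_post_mode(self):
        x = np.zeros(10)
        x[8:] = 500.0
        rec = make_recording(x)
        with pytest.raises(UncorrectableError):
            correct_spike(rec, spike_interval(8.0, 10.0), mode="post")

    def test_wrong_kind_rejected(self):
        rec = self.make_spiked()
        with pytest.raises(UncorrectableError):
            correct_spike(rec, ArtifactInterval(kind=BLINK, start_ms=8.0, end_ms=10.0))


class TestCorrectDisplacement:
    def test_constant_offset_on_ramp_recovered_exactly(self):
        # injection oracle: an additive offset preserves within-interval
        # derivatives, so reintegration from p0 restores the ramp exactly
        truth_x = np.arange(100) * 1.5
        x = truth_x.copy()
        x[40:70] += 100.0
        rec = make_recording(x)
        iv = ArtifactInterval(kind=DISPLACEMENT, start_ms=40.0, end_ms=70.0)
        out = correct_displacement(rec, iv)
        assert np.allclose(out.x, truth_x, atol=1e-9)

    def test_zero_offset_is_identity(self):
        rec = make_recording(np.arange(50) * 2.0)
        iv = ArtifactInterval(kind=DISPLACEMENT, start_ms=20.0, end_ms=30.0)
        out = correct_displacement(rec, iv)
        assert np.allclose(out.x, rec.x)

    def test_within_interval_motion_is_cumulated(self):
        # cumulative-sum oracle: corrected(t) follows p0 plus the raw
        # within-interval displacements d(t)
        x = np.zeros(60)
        inner = np.array([0.0, 2.0, 5.0, 3.0, 4.0])
        x[30:35] = 100.0 + inner  # offset plus known relative motion
        rec = make_recording(x)
        iv = ArtifactInterval(kind=DISPLACEMENT, start_ms=30.0, end_ms=35.0)
        out = correct_displacement(rec, iv)
        assert np.allclose(out.x[30:35], 0.0 + inner - inner[0])
        assert np.all(out.x[35:] == 0.0)  # raw data resume after the episode

    def test_unterminated_rejected(self):
        rec = make_recording(np.zeros(50))
        iv = ArtifactInterval(kind=DISPLACEMENT, start_ms=30.0, end_ms=40.0, note="unterminated")
        with pytest.raises(UncorrectableError):
            correct_displacement(rec, iv)


class TestCorrectBlink:
    def make_blinky(self, n=1000, slope=0.0):
        x = np.arange(n) * slope + 100.0
        valid = np.ones(n, bool)
        valid[400:500] = False
        x = np.where(valid, x, np.nan)
        return make_recording(x, np.full(n, 525.0), valid=valid), ArtifactInterval(
            kind=BLINK, start_ms=400.0, end_ms=500.0
        )

    def test_flat_anchors_give_flat_fill(self):
        rec, iv = self.make_blinky()
        out = correct_blink(rec, iv, pad_ms=200.0)
        assert np.all(out.valid)
        assert np.all(out.x[200:700] == 100.0)
        assert np.all(out.y[200:700] == 525.0)

    def test_linear_motion_fill_lies_on_the_line(self):
        # closed-form line oracle: anchors at t=199 and t=700 on the same
        # line, so every refilled sample must sit on it
        rec, iv = self.make_blinky(slope=0.8)
        out = correct_blink(rec, iv, pad_ms=200.0)
        expected = np.arange(1000) * 0.8 + 100.0
        assert np.allclose(out.x, expected, atol=1e-9)

    def test_padded_span_has_no_invalid_samples(self):
        rec, iv = self.make_blinky()
        out = correct_blink(rec, iv, pad_ms=200.0)
        span = (rec.t >= 200.0) & (rec.t < 700.0)
        assert out.valid[span].all()

    def test_boundary_gap_held_not_extrapolated(self):
        valid = np.ones(300, bool)
        valid[:80] = False
        x = np.where(valid, np.arange(300) * 1.0, np.nan)
        rec = make_recording(x, valid=valid)
        iv = ArtifactInterval(kind=BLINK, start_ms=0.0, end_ms=80.0)
        out = correct_blink(rec, iv, pad_ms=100.0)
        assert np.all(out.x[:180] == 180.0)  # first trusted value held

    def test_all_invalid_rejected(self):
        valid = np.zeros(50, bool)
        rec = make_recording(np.full(50, np.nan), valid=valid)
        with pytest.raises(UncorrectableError):
            correct_blink(rec, ArtifactInterval(kind=BLINK, start_ms=0.0, end_ms=50.0))


class TestCleanRecording:
    def test_identity_on_artifact_free_input(self):
        rec = generate_fixation_trace(5000, noise_sd=1.0, seed=4)
        out, report = clean_recording(rec)
        assert out.equals(rec)
        assert report.all_zero()

    def test_injected_counts_recovered(self):
        clean = generate_fixation_trace(30000, noise_sd=1.0, seed=9)
        truth = inject_artifacts(clean, ArtifactSpec(n_spikes=2, n_displacements=1, n_blinks=3), seed=10)
        _, report = clean_recording(truth.dirty)
        assert (report.n_blinks, report.n_spikes, report.n_displacements) == (3, 2, 1)

    def test_conservation_of_timebase(self):
        clean = generate_fixation_trace(10000, seed=12)
        truth = inject_artifacts(clean, ArtifactSpec(n_spikes=3, n_blinks=2), seed=13)
        out, _ = clean_recording(truth.dirty)
        assert len(out) == len(truth.dirty)
        assert np.array_equal(out.t, truth.dirty.t)

    @pytest.mark.parametrize("seed", range(4))
    def test_idempotence_on_randomized_injections(self, seed):
        clean = generate_fixation_trace(20000, noise_sd=1.0, seed=seed)
        truth = inject_artifacts(clean, ArtifactSpec(n_spikes=3, n_displacements=2, n_blinks=3), seed=seed + 50)
        once, _ = clean_recording(truth.dirty)
        twice, second_report = clean_recording(once)
        assert once.equals(twice)
        assert second_report.all_zero()

    def test_output_valid_and_subthreshold(self):
        truth = generate_blink_protocol(seed=2)
        out, report = clean_recording(truth.dirty)
        assert out.valid.all()
        vel = compute_velocity(out)
        assert np.nanmax(vel.speed[1:]) <= 40.0
        assert report.n_blinks == len(truth.artifacts)

    def test_noise_free_recovery_is_exact(self):
        clean = generate_fixation_trace(20000, noise_sd=0.0, seed=1)
        truth = inject_artifacts(clean, ArtifactSpec(n_spikes=3, n_displacements=2), seed=2)
        out, _ = clean_recording(truth.dirty)
        assert rmse(out, truth.clean) == pytest.approx(0.0, abs=1e-9)

    def test_recovery_improves_rmse_under_noise(self):
        clean = generate_fixation_trace(60000, noise_sd=1.0, seed=21)
        truth = inject_artifacts(clean, ArtifactSpec(n_spikes=5, n_displacements=3, n_blinks=5), seed=22)
        out, _ = clean_recording(truth.dirty)
        assert rmse(out, truth.clean) <= 0.2 * rmse(truth.dirty, truth.clean)
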