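import numpy as np
import pytest

from gazemend.paradigm import AJ, CENTER, NOAJ, assign_condition
from gazemend.quantify import AOI, QuantifyError, aoi_rate, default_aois, onscreen_rate, trial_rates
from gazemend.recording import GazeRecording
from gazemend.synth import generate_fixation_trace, generate_group_session

from conftest import make_recording


def center_labels(rec, schedule):
    return assign_condition(rec, schedule)


class TestOnscreenRate:
    def test_all_on_screen(self, geom, schedule):
        rec = generate_fixation_trace(1000, target=(840, 525), noise_sd=0.0, seed=0)
        labels = assign_condition(rec, schedule)
        assert onscreen_rate(rec, geom, labels, AJ) == 1.0

    def test_partial_off_screen_fraction(self, geom, schedule):
        x = np.full(10, 100.0)
        x[3] = 1700.0  # beyond the 1680 px right edge
        rec = make_recording(x, np.full(10, 100.0))
        labels = assign_condition(rec, schedule)
        assert onscreen_rate(rec, geom, labels, AJ) == pytest.approx(0.9)

    def test_invalid_samples_count_against(self, geom, schedule):
        x = np.full(10, 100.0)
        valid = np.ones(10, bool)
        valid[:5] = False
        x = np.where(valid, x, np.nan)
        rec = make_recording(x, np.full(10, 100.0), valid=valid)
        labels = assign_condition(rec, schedule)
        assert onscreen_rate(rec, geom, labels, AJ) == pytest.approx(0.5)

    def test_half_open_screen_bounds(self, geom, schedule):
        rec = make_recording([0.0, 1679.0, 1680.0], [0.0, 1049.0, 1050.0])
        labels = assign_condition(rec, schedule)
        assert onscreen_rate(rec, geom, labels, AJ) == pytest.approx(2 / 3)

    def test_empty_condition_rejected(self, geom, schedule):
        rec = generate_fixation_trace(100, seed=0)  # only reaches the first AJ block
        labels = assign_condition(rec, schedule)
        with pytest.raises(QuantifyError):
            onscreen_rate(rec, geom, labels, CENTER)


class TestAoiRate:
    def test_full_screen_aoi_equals_onscreen_rate(self, geom, schedule):
        rng = np.random.default_rng(3)
        n = 5000
        rec = make_recording(rng.uniform(-50, 1730, n), rng.uniform(0, 1050, n))
        labels = assign_condition(rec, schedule)
        whole = [AOI("screen", 0, geom.width_px, 0, geom.height_px, condition=AJ)]
        assert aoi_rate(rec, whole, labels, AJ) == pytest.approx(onscreen_rate(rec, geom, labels, AJ))

    def test_uniform_samples_hit_area_fraction(self, geom, schedule):
        # Monte Carlo oracle: an AOI covering 25% of the screen catches
        # ~25% of uniform samples, within 3 binomial sigmas
        rng = np.random.default_rng(42)
        n = 10_000
        rec = make_recording(rng.uniform(0, 1680, n), rng.uniform(0, 1050, n))
        labels = assign_condition(rec, schedule)
        quarter = [AOI("q", 0, 840, 0, 525, condition=AJ)]
        rate = aoi_rate(rec, quarter, labels, AJ)
        sigma = np.sqrt(0.25 * 0.75 / n)
        assert abs(rate - 0.25) <= 3 * sigma

    def test_half_open_box_edges(self, schedule):
        aoi = [AOI("box", 100, 200, 100, 200, condition=AJ)]
        rec = make_recording([100.0, 200.0], [100.0, 200.0])
        labels = assign_condition(rec, schedule)
        assert aoi_rate(rec, aoi, labels, AJ) == pytest.approx(0.5)

    def test_side_matched_aois(self, schedule, geom):
        # gaze parked on the left object box for the whole first AJ block;
        # only the left-side trials count it as task adherence
        rec = generate_fixation_trace(25_000, target=(420, 525), noise_sd=0.0, seed=0)
        labels = assign_condition(rec, schedule)
        rate = aoi_rate(rec, default_aois(geom), labels, AJ)
        sides = [tr.side for tr in schedule.blocks[0].trials]
        assert rate == pytest.approx(sides.count("left") / len(sides))

    def test_missing_aoi_config_rejected(self, schedule):
        rec = generate_fixation_trace(1000, seed=0)
        labels = assign_condition(rec, schedule)
        with pytest.raises(QuantifyError):
            aoi_rate(rec, [AOI("c", 0, 1, 0, 1, condition=CENTER)], labels, AJ)


class TestTrialRates:
    def test_full_adherence_gives_unit_rates(self, schedule, geom):
        sessions = generate_group_session(
            n_subjects=1,
            adherence={AJ: 1.0, NOAJ: 1.0, CENTER: 1.0},
            trial_sd=0.0,
            subject_sd=0.0,
            noise_sd=0.0,
            rate_hz=100,
            seed=5,
        )
        df = trial_rates(sessions[0].clean, schedule, default_aois(geom))
        # saccade-like ramps between dwell targets spend a few samples per
        # trial in transit outside the AOI, so rates sit just below 1
        assert (df["rate"] >= 0.98).all()
        assert len(df[df["condition"] == CENTER]) == 4
        assert len(df[df["condition"] == AJ]) == 5

    def test_decaying_adherence_gives_monotone_rates(self, schedule, geom):
        # generator-parameter oracle: linear decay per temporal position
        # must appear as strictly decreasing Center trial rates
        sessions = generate_group_session(
            n_subjects=1,
            adherence={AJ: 0.9, NOAJ: 0.9, CENTER: 0.9},
            decay_per_trial={CENTER: 0.15},
            trial_sd=0.0,
            subject_sd=0.0,
            noise_sd=0.0,
            rate_hz=100,
            seed=6,
        )
        df = trial_rates(sessions[0].clean, schedule, default_aois(geom))
        center = df[df["condition"] == CENTER].sort_values("position")["rate"].to_numpy()
        assert np.all(np.diff(center) < 0)
        assert center[0] - center[-1] == pytest.approx(0.45, abs=0.03)

    def test_rates_invariant_to_subsampling(self, schedule, geom):
        sessions = generate_group_session(n_subjects=1, rate_hz=200, noise_sd=0.0, seed=7)
        rec = sessions[0].clean
        df_full = trial_rates(rec, schedule, default_aois(geom))
        half = GazeRecording(
            t=rec.t[::2], x=rec.x[::2], y=rec.y[::2], valid=rec.valid[::2], sampling_rate_hz=100
        )
        df_half = trial_rates(half, schedule, default_aois(geom))
        merged = df_full.merge(df_half, on=["condition", "position"], suffixes=("_f", "_h"))
        assert np.allclose(merged["rate_f"], merged["rate_h"], atol=0.05)
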