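"""Suppression ratios, pooling, effect sizes, intermodulation indices."""

import numpy as np
import pytest

from ssvepdyn.spectral import AmplitudeTimeCourse
from ssvepdyn.metrics import (suppression_ratio, pool_timecourses,
                              window_effect_size, intermodulation_timecourse,
                              SuppressionTimeCourse)
from ssvepdyn.epochs_io import average_channels
from ssvepdyn.pipeline import PipelineConfig, analyze_recording
from ssvepdyn.synthetic import generate_dataset

from conftest import fast_config

GRID = np.arange(0.0, 5.0, 0.1)


def amp_course(values, f=5.0, pid="P0"):
    values = np.broadcast_to(values, GRID.shape).astype(float)
    return AmplitudeTimeCourse(times=GRID.copy(), amplitudes=values, frequency=f,
                               participant_id=pid)


def db_course(values, pid="P0", mask="monocular"):
    values = np.broadcast_to(values, GRID.shape).astype(float)
    return SuppressionTimeCourse(times=GRID.copy(), ratio_db=values.copy(),
                                 frequency=5.0, mask_type=mask, participant_id=pid)


class TestSuppressionRatio:
    def test_identical_courses_give_zero_db(self):
        tc = amp_course(2.0)
        np.testing.assert_allclose(
            suppression_ratio(tc, amp_course(2.0)).ratio_db, 0.0, atol=1e-12)

    def test_half_amplitude_mask_gives_six_db(self):
        r = suppression_ratio(amp_course(2.0), amp_course(1.0))
        np.testing.assert_allclose(r.ratio_db, 20 * np.log10(2), atol=1e-12)
        assert r.ratio_db[0] == pytest.approx(6.0206, abs=1e-4)

    def test_one_db_point(self):
        r = suppression_ratio(amp_course(1.122), amp_course(1.0))
        np.testing.assert_allclose(r.ratio_db, 1.000, atol=1e-3)

    def test_antisymmetry_is_exact(self):
        rng = np.random.default_rng(1)
        a = amp_course(rng.uniform(0.5, 3.0, GRID.size))
        b = amp_course(rng.uniform(0.5, 3.0, GRID.size))
        np.testing.assert_array_equal(suppression_ratio(a, b).ratio_db,
                                      -suppression_ratio(b, a).ratio_db)

    def test_floor_keeps_ratio_finite(self):
        r = suppression_ratio(amp_course(1.0), amp_course(0.0), floor=1e-3)
        assert np.all(np.isfinite(r.ratio_db))
        assert r.ratio_db[0] == pytest.approx(60.0)

    def test_grid_mismatch_rejected(self):
        short = AmplitudeTimeCourse(times=GRID[:-1], amplitudes=np.ones(GRID.size - 1),
                                    frequency=5.0)
        with pytest.raises(ValueError, match="grid"):
            suppression_ratio(amp_course(1.0), short)

    def test_raw_ratio_column_matches_db(self):
        r = suppression_ratio(amp_course(2.0), amp_course(1.0))
        np.testing.assert_allclose(r.ratio, 2.0, atol=1e-12)


class TestPooling:
    def test_identity_mean_and_commutativity(self):
        a, b = db_course(2.0), db_course(0.0, mask="dichoptic")
        np.testing.assert_allclose(pool_timecourses([a, a]).ratio_db, a.ratio_db)
        np.testing.assert_allclose(pool_timecourses([a, b]).ratio_db, 1.0)
        np.testing.assert_allclose(pool_timecourses([a, b]).ratio_db,
                                   pool_timecourses([b, a]).ratio_db)

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            pool_timecourses([])

    def test_window_mean_linear_in_pooling(self):
        # pooling then windowed effect equals the mean of the window means
        rng = np.random.default_rng(2)
        courses = [db_course(rng.normal(size=GRID.size)) for _ in range(4)]
        pooled = pool_timecourses(courses)
        sel = (GRID >= 1.0) & (GRID < 2.0)
        assert pooled.ratio_db[sel].mean() == pytest.approx(
            np.mean([c.ratio_db[sel].mean() for c in courses]), abs=1e-12)


class TestWindowEffectSize:
    def participant_courses(self, diffs):
        courses = []
        for i, d in enumerate(diffs):
            vals = np.where(GRID >= 2.5, d, 0.0)
            courses.append(db_course(vals, pid=f"P{i}"))
        return courses

    def test_hand_computed_paired_d(self):
        # diffs {0.2, 0.4, 0.6}: mean 0.4, sd 0.2 -> d = 2.0
        res = window_effect_size(self.participant_courses([0.2, 0.4, 0.6]),
                                 early=(0.0, 1.0), late=(3.0, 4.0))
        assert res.cohen_d == pytest.approx(2.0, abs=1e-12)
        np.testing.assert_allclose(res.participant_means_early, 0.0)
        np.testing.assert_allclose(res.participant_means_late, [0.2, 0.4, 0.6])

    def test_zero_differences_degenerate(self):
        res = window_effect_size(self.participant_courses([0.0, 0.0, 0.0]),
                                 early=(0.0, 1.0), late=(3.0, 4.0))
        assert res.degenerate
        assert res.cohen_d == 0.0

    def test_sign_flip_negates_d(self):
        courses = self.participant_courses([0.2, 0.4, 0.6])
        flipped = [db_course(-c.ratio_db, pid=c.participant_id) for c in courses]
        d_pos = window_effect_size(courses, (0, 1), (3, 4)).cohen_d
        d_neg = window_effect_size(flipped, (0, 1), (3, 4)).cohen_d
        assert d_neg == pytest.approx(-d_pos)

    def test_pooled_flavor_and_validation(self):
        courses = self.participant_courses([0.2, 0.4, 0.6])
        pooled = window_effect_size(courses, (0, 1), (3, 4), flavor="pooled")
        assert pooled.cohen_d == pytest.approx(0.4 / np.sqrt(0.02), abs=1e-9)
        with pytest.raises(ValueError, match="overlap"):
            window_effect_size(courses, (0.0, 2.0), (1.0, 3.0))
        with pytest.raises(ValueError, match="2 participants"):
            window_effect_size(courses[:1], (0, 1), (3, 4))


class TestIntermodulation:
    def test_plaid_equal_to_baseline_gives_zero(self):
        im = intermodulation_timecourse(amp_course(1.5, f=12.0),
                                        [amp_course(1.5, f=12.0)])
        np.testing.assert_allclose(im.index, 0.0, atol=1e-12)

    def test_double_baseline_gives_one(self):
        im = intermodulation_timecourse(amp_course(3.0, f=12.0),
                                        [amp_course(1.5, f=12.0),
                                         amp_course(1.5, f=12.0)])
        np.testing.assert_allclose(im.index, 1.0, atol=1e-12)

    def test_simulated_im_positive_during_stimulation_only(self):
        cfg = fast_config(n_participants=1, n_trials_per_condition=40,
                          im_gain=0.5, seed=5)
        recs, _ = generate_dataset(cfg)
        analysis = analyze_recording(recs[0], PipelineConfig(
            simulation=cfg, include_intermodulation=True, step_s=0.05))
        im = analysis.im_courses[0]
        stim = (im.times >= 1.0) & (im.times <= cfg.trial_duration - 1.0)
        iti = im.times < -0.6
        assert im.index[stim].mean() > 1.0       # strong tagged 12 Hz response
        assert abs(im.index[iti].mean()) < 0.5   # noise-only before onset
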