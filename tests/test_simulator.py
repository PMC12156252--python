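"""Scene simulator: diagnostic rules, trajectories, rendering, cohorts."""

import numpy as np
import pytest

from helpers import independent_labels, landmark_row_px, scene_with_descents

from popsono.organs import ENTEROCELE_REGION, ORGANS
from popsono.simulate import (
    PathologyProfile,
    SceneConfig,
    apply_diagnostic_rules,
    generate_cohort,
    iter_cohort,
    labels_from_descents,
    measure_descents,
    render_confidence_maps,
    simulate_patient,
)

SCALE = 0.5


def descents(**overrides):
    base = {
        "bladder_descent_mm": -4.5,
        "urethra_descent_mm": 3.0,
        "fundus_distance_reduction_mm": 0.0,
        "cervix_descent_mm": -6.0,
        "rectum_descent_mm": 4.5,
        "enterocele_descent_mm": -1.5,
    }
    base.update(overrides)
    return base


class TestDiagnosticThresholds:
    """Inclusive mm thresholds, exercised exactly at the boundary."""

    @pytest.mark.parametrize(
        "bladder_mm, expected", [(9.9, 0), (10.0, 1), (10.1, 1), (0.0, 0)]
    )
    def test_cystocele_threshold_is_inclusive_at_10mm(self, bladder_mm, expected):
        labels = labels_from_descents(
            descents(bladder_descent_mm=bladder_mm), False, False
        )
        assert labels["cystocele"] == expected

    def test_uterine_prolapse_vs_cervical_elongation_partition(self):
        # >= 15 mm fundus-distance loss: uterine prolapse
        up = labels_from_descents(
            descents(fundus_distance_reduction_mm=15.0), False, False
        )
        assert up["uterine_prolapse"] == 1 and up["cervical_elongation"] == 0
        # < 15 mm loss but cervix descending >= 15 mm: cervical elongation
        ce = labels_from_descents(
            descents(fundus_distance_reduction_mm=14.0, cervix_descent_mm=15.0),
            False,
            False,
        )
        assert ce["uterine_prolapse"] == 0 and ce["cervical_elongation"] == 1
        just_below = labels_from_descents(
            descents(fundus_distance_reduction_mm=14.9, cervix_descent_mm=14.9),
            False,
            False,
        )
        assert just_below["uterine_prolapse"] == 0
        assert just_below["cervical_elongation"] == 0

    def test_rectocele_requires_herniation_flag(self):
        without = labels_from_descents(descents(rectum_descent_mm=20.0), False, False)
        assert without["rectocele"] == 0
        with_flag = labels_from_descents(descents(rectum_descent_mm=20.0), True, False)
        assert with_flag["rectocele"] == 1

    def test_enterocele_requires_abdominal_content_flag(self):
        without = labels_from_descents(
            descents(enterocele_descent_mm=18.0), False, False
        )
        assert without["enterocele"] == 0
        with_flag = labels_from_descents(
            descents(enterocele_descent_mm=18.0), False, True
        )
        assert with_flag["enterocele"] == 1

    def test_cystourethrocele_needs_both_bladder_and_urethra(self):
        bladder_only = labels_from_descents(
            descents(bladder_descent_mm=12.0), False, False
        )
        assert bladder_only["cystourethrocele"] == 0
        both = labels_from_descents(
            descents(bladder_descent_mm=12.0, urethra_descent_mm=10.0), False, False
        )
        assert both["cystourethrocele"] == 1
        # urethral descent alone is not a cystourethrocele
        urethra_only = labels_from_descents(
            descents(urethra_descent_mm=12.0), False, False
        )
        assert urethra_only["cystourethrocele"] == 0

    def test_any_prolapse_is_or_of_the_six(self):
        healthy = labels_from_descents(descents(), False, False)
        assert healthy["any_prolapse"] == 0
        one = labels_from_descents(descents(bladder_descent_mm=11.0), False, False)
        assert one["any_prolapse"] == 1


class TestRulesOnTrajectories:
    def test_measured_descents_match_constructed_scene(self):
        trajs = scene_with_descents(bladder_mm=20.0, rectum_mm=17.0)
        d = measure_descents(trajs, SCALE)
        assert d["bladder_descent_mm"] == pytest.approx(20.0, abs=1e-9)
        assert d["rectum_descent_mm"] == pytest.approx(17.0, abs=1e-9)

    def test_bladder_descent_below_landmark_marks_cystocele(self):
        truth = apply_diagnostic_rules(
            scene_with_descents(bladder_mm=20.0), False, False, SCALE
        )
        assert truth.labels["cystocele"] == 1

    def test_fundus_reduction_drives_uterine_prolapse(self):
        truth = apply_diagnostic_rules(
            scene_with_descents(fundus_reduction_mm=16.0), False, False, SCALE
        )
        assert truth.labels["uterine_prolapse"] == 1

    def test_missing_pubis_landmark_is_fatal(self):
        trajs = scene_with_descents()
        del trajs["pubis"]
        with pytest.raises(ValueError, match="pubis"):
            measure_descents(trajs, SCALE)

    def test_nonpositive_scale_rejected(self):
        with pytest.raises(ValueError):
            measure_descents(scene_with_descents(), 0.0)


class TestSimulatePatient:
    def test_healthy_profile_yields_all_negative_labels(self):
        video = simulate_patient(
            SceneConfig(n_frames=100), PathologyProfile.healthy(), seed=11
        )
        assert all(v == 0 for v in video.ground_truth.labels.values())

    def test_cystocele_profile_yields_positive_label_and_target_descent(self):
        profile = PathologyProfile(cystocele=True, bladder_descent_mm=20.0)
        video = simulate_patient(SceneConfig(n_frames=120), profile, seed=5)
        assert video.ground_truth.labels["cystocele"] == 1
        # measured descent matches the profile target within rendering noise
        assert video.ground_truth.descents["bladder_descent_mm"] == pytest.approx(
            20.0, abs=2.0
        )

    def test_same_seed_is_byte_identical(self):
        cfg = SceneConfig(n_frames=(100, 140))
        profile = PathologyProfile(uterine_prolapse=True, fundus_descent_mm=25.0)
        a = simulate_patient(cfg, profile, seed=42)
        b = simulate_patient(cfg, profile, seed=42)
        assert a.ground_truth.labels == b.ground_truth.labels
        for organ in ORGANS:
            assert a.maps[organ].tobytes() == b.maps[organ].tobytes()

    def test_trajectories_descend_monotonically_up_to_jitter(self):
        profile = PathologyProfile(cystocele=True, bladder_descent_mm=18.0)
        video = simulate_patient(SceneConfig(n_frames=150), profile, seed=2)
        row = video.trajectories["bladder"].center_row
        # the smoothed trend (jitter has sd 1 px) must be monotone
        smooth = np.convolve(row, np.ones(15) / 15, mode="valid")
        assert np.all(np.diff(smooth) > -0.25)
        assert row[-1] > row[0]

    def test_rest_frame_matches_healthy_layout(self):
        video = simulate_patient(
            SceneConfig(n_frames=100), PathologyProfile.healthy(), seed=7
        )
        bladder = video.trajectories["bladder"]
        assert bladder.center_row[0] == pytest.approx(20.0 / SCALE)
        assert bladder.center_col[0] == pytest.approx(24.0 / SCALE)

    def test_negative_descent_profile_rejected(self):
        with pytest.raises(ValueError):
            PathologyProfile(cystocele=True, bladder_descent_mm=-1.0)

    def test_conflicting_uterine_flags_rejected(self):
        with pytest.raises(ValueError):
            PathologyProfile(uterine_prolapse=True, cervical_elongation=True)


class TestRendering:
    @pytest.fixture()
    def quiet_config(self):
        return SceneConfig(n_frames=3, center_jitter_px=0.0, speckle_sd=0.0)

    def test_maps_in_unit_interval_and_region_nonempty(self, quiet_config):
        trajs = scene_with_descents(n_frames=3)
        maps = render_confidence_maps(trajs, quiet_config)
        for organ in ORGANS:
            m = maps[organ]
            assert m.min() >= 0.0 and m.max() <= 1.0
            assert (m > 0.5).any(axis=(1, 2)).all()

    def test_peak_equals_healthy_peak_at_reference_position(self, quiet_config):
        trajs = scene_with_descents(n_frames=3)
        maps = render_confidence_maps(trajs, quiet_config, anomaly_degradation=0.5)
        # the vagina never moves in this scene: zero displacement, full peak
        assert maps["vagina"].max() == pytest.approx(quiet_config.healthy_peak)

    def test_degradation_zero_keeps_full_peak_despite_displacement(self, quiet_config):
        trajs = scene_with_descents(bladder_mm=25.0, n_frames=3)
        maps = render_confidence_maps(trajs, quiet_config, anomaly_degradation=0.0)
        assert maps["bladder"][-1].max() == pytest.approx(quiet_config.healthy_peak)

    def test_displaced_organ_loses_confidence_with_degradation(self, quiet_config):
        trajs = scene_with_descents(bladder_mm=10.0, n_frames=3)
        maps = render_confidence_maps(trajs, quiet_config, anomaly_degradation=0.5)
        rest, valsalva = maps["bladder"][0], maps["bladder"][-1]
        mean_in = lambda m: m[m > 0.5].mean()  # noqa: E731
        assert mean_in(valsalva) < mean_in(rest)

    def test_mean_region_confidence_monotone_in_displacement(self, quiet_config):
        means = []
        for disp in (0.0, 6.0, 12.0, 18.0):
            trajs = scene_with_descents(bladder_mm=-4.5 + disp, n_frames=2)
            maps = render_confidence_maps(trajs, quiet_config, anomaly_degradation=0.5)
            m = maps["bladder"][-1]
            means.append(m[m > 0.5].mean())
        assert all(a >= b for a, b in zip(means, means[1:]))

    def test_strongly_displaced_organ_can_vanish_from_its_region(self, quiet_config):
        # with degradation 0.5 a 30 mm displacement halves the peak below
        # the 0.5 region threshold: the network "loses" the organ entirely
        trajs = scene_with_descents(bladder_mm=27.0, n_frames=2)
        maps = render_confidence_maps(trajs, quiet_config, anomaly_degradation=0.5)
        assert not (maps["bladder"][-1] > 0.5).any()

    def test_region_centroid_near_true_center_without_noise(self, quiet_config):
        trajs = scene_with_descents(n_frames=3)
        maps = render_confidence_maps(trajs, quiet_config)
        for organ in ORGANS:
            mask = maps[organ][0] > 0.5
            rr, cc = np.nonzero(mask)
            traj = trajs[organ]
            assert abs(rr.mean() - traj.center_row[0]) < 2.0
            assert abs(cc.mean() - traj.center_col[0]) < 2.0

    def test_landmark_constant_across_frames(self):
        video = simulate_patient(
            SceneConfig(n_frames=80), PathologyProfile.healthy(), seed=1
        )
        pubis = video.trajectories["pubis"]
        assert np.ptp(pubis.center_row) == 0.0
        assert np.ptp(pubis.center_col) == 0.0


class TestCohort:
    def test_zero_prevalence_cohort_is_all_healthy(self):
        cfg = SceneConfig(n_frames=60)
        _videos, labels = generate_cohort(
            6, prevalence={"pop": 0.0}, config=cfg, seed=9
        )
        assert (labels[list(labels.columns[1:8])] == 0).all().all()

    def test_cohort_labels_reproducible_for_fixed_seed(self):
        cfg = SceneConfig(
            n_frames=60, frame_height=64, frame_width=64, mm_per_pixel=1.0
        )
        _v1, t1 = generate_cohort(8, config=cfg, seed=123)
        _v2, t2 = generate_cohort(8, config=cfg, seed=123)
        assert t1.equals(t2)

    def test_too_small_cohort_rejected(self):
        with pytest.raises(ValueError):
            list(iter_cohort(1, seed=0))

    def test_rule_faithfulness_on_simulated_cohort(self):
        """Stored labels match an independent re-application of the rules."""
        cfg = SceneConfig(n_frames=(60, 90))
        for video in iter_cohort(20, config=cfg, seed=77):
            redo = independent_labels(
                video.ground_truth.descents,
                video.profile.herniation_flag,
                video.profile.abdominal_content_flag,
            )
            assert redo == video.ground_truth.labels, video.patient_id

    def test_label_totals_track_configured_prevalences(self):
        # cohort of 188 with the default mix: expected totals around the
        # composition of a referral population (sampling error allowed).
        # Streamed at a coarse raster to keep the test light.
        cfg = SceneConfig(
            n_frames=60, frame_height=64, frame_width=64, mm_per_pixel=1.0
        )
        totals = {t: 0 for t in (
            "cystocele",
            "cystourethrocele",
            "uterine_prolapse",
            "cervical_elongation",
            "rectocele",
            "enterocele",
        )}
        for video in iter_cohort(188, config=cfg, seed=2024):
            for t in totals:
                totals[t] += video.ground_truth.labels[t]
        expected = {
            "cystocele": 67,
            "cystourethrocele": 13,
            "uterine_prolapse": 41,
            "cervical_elongation": 36,
            "rectocele": 24,
            "enterocele": 9,
        }
        for target, exp in expected.items():
            p = exp / 188
            sd = np.sqrt(188 * p * (1 - p))
            assert abs(totals[target] - exp) <= 3 * sd + 1, target

    def test_landmark_helper_agrees_with_package(self):
        video = simulate_patient(
            SceneConfig(n_frames=60), PathologyProfile.healthy(), seed=3
        )
        from popsono.simulate import landmark_row

        assert landmark_row(video.trajectories["pubis"]) == pytest.approx(
            landmark_row_px()
        )

    def test_enterocele_region_tracked_but_not_rendered(self):
        video = simulate_patient(
            SceneConfig(n_frames=60), PathologyProfile.healthy(), seed=3
        )
        assert ENTEROCELE_REGION in video.trajectories
        assert ENTEROCELE_REGION not in video.maps
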