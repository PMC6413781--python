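import numpy as np
import pandas as pd
import pytest

from pigmentrial.imaging import IrisGeometry, annulus_mask
from pigmentrial.reflectometry import m_index
from pigmentrial.synthetic import (
    CohortTruth,
    TruthValidationError,
    generate_cohort,
    render_ti_image,
    simulate_trajectories,
    truth_from_dict,
    truth_to_dict,
)


class TestTruthValidation:
    @pytest.mark.parametrize(
        "kwargs,field",
        [
            ({"sd_intercept": -1.0}, "sd_intercept"),
            ({"grader_noise_sd": -0.1}, "grader_noise_sd"),
            ({"visit_months": (3, 6)}, "visit_months"),
            ({"visit_months": (0, 6, 3)}, "visit_months"),
            ({"n_graders": 1}, "n_graders"),
            ({"images_per_eye_visit": 0}, "images_per_eye_visit"),
        ],
    )
    def test_invalid_fields_named_in_error(self, kwargs, field):
        with pytest.raises(TruthValidationError, match=field):
            CohortTruth(**kwargs).validate()

    def test_yaml_round_trip(self):
        truth = CohortTruth(seed=42, n_participants=3)
        assert truth_from_dict(truth_to_dict(truth)) == truth


class TestRenderTIImage:
    def test_zero_score_dark_annulus(self, default_geometry):
        img = render_ti_image(0.0, default_geometry, noise_sd=0.0)
        mask = annulus_mask(default_geometry, *img.pixels.shape[:2])
        assert (img.pixels[:, :, 0][mask] == 0).all()

    def test_saturated_score(self, default_geometry):
        img = render_ti_image(8.0, default_geometry, noise_sd=0.0)
        mask = annulus_mask(default_geometry, *img.pixels.shape[:2])
        assert (img.pixels[:, :, 0][mask] == 255).all()

    def test_pupil_is_saturated_red_reflex(self, default_geometry):
        img = render_ti_image(2.0, default_geometry, noise_sd=0.0)
        h, w = img.pixels.shape[:2]
        yy, xx = np.mgrid[0:h, 0:w]
        rr = np.hypot(xx - default_geometry.center_x, yy - default_geometry.center_y)
        assert (img.pixels[:, :, 0][rr <= default_geometry.pupil_radius] == 255).all()
        assert (img.pixels[:, :, 0][rr > default_geometry.iris_radius] == 0).all()

    def test_score_out_of_range_rejected(self, default_geometry):
        with pytest.raises(ValueError):
            render_ti_image(8.5, default_geometry)

    def test_geometry_outside_image_rejected(self, default_geometry):
        from pigmentrial.imaging import GeometryError

        with pytest.raises(GeometryError):
            render_ti_image(4.0, default_geometry, size=(100, 100))


class TestGenerateCohort:
    def test_seeded_determinism(self):
        truth = CohortTruth(seed=7)
        a, b = generate_cohort(truth), generate_cohort(truth)
        pd.testing.assert_frame_equal(a.grades, b.grades)
        pd.testing.assert_frame_equal(a.hair, b.hair)
        pd.testing.assert_frame_equal(a.acuity, b.acuity)
        assert all(
            np.array_equal(x.pixels, y.pixels) for x, y in zip(a.images, b.images)
        )
        assert all(
            np.array_equal(x.pr, y.pr) for x, y in zip(a.spectra, b.spectra)
        )

    def test_different_seeds_differ(self):
        a = generate_cohort(CohortTruth(seed=1))
        b = generate_cohort(CohortTruth(seed=2))
        assert not a.grades["grade"].equals(b.grades["grade"])

    def test_noise_free_grades_equal_rounded_latent(self, noise_free_bundle):
        merged = noise_free_bundle.grades.merge(
            noise_free_bundle.latent, on=["participant", "eye", "visit_month"]
        )
        assert np.allclose(merged["grade"], np.round(merged["latent"], 1))

    def test_grades_reference_existing_images(self, noisy_bundle):
        image_keys = {
            (i.participant, i.eye, i.visit_month, i.image_index)
            for i in noisy_bundle.images
        }
        grade_keys = set(
            map(
                tuple,
                noisy_bundle.grades[
                    ["participant", "eye", "visit_month", "image_index"]
                ].drop_duplicates().itertuples(index=False),
            )
        )
        assert grade_keys == image_keys

    def test_design_shape(self, noisy_bundle):
        t = noisy_bundle.truth
        n_ev = t.n_participants * 2 * len(t.visit_months)
        assert len(noisy_bundle.images) == n_ev * t.images_per_eye_visit
        assert len(noisy_bundle.grades) == n_ev * t.images_per_eye_visit * t.n_graders
        assert set(noisy_bundle.grades["grade"]) <= {
            round(x / 10, 1) for x in range(81)
        }

    def test_spectrum_synthesis_inverts_m_index(self):
        from pigmentrial.synthetic import _synth_spectrum

        for m in (0.0, 5.5, 20.0, 35.0, 60.0):
            s = _synth_spectrum(m, "inner_bicep", 1, "P001", 0)
            assert m_index(s) == pytest.approx(m, abs=1e-9)

    def test_noise_free_replicates_recover_site_truth(self):
        from dataclasses import replace

        from pigmentrial.reflectometry import summarize_all
        from pigmentrial.synthetic import SiteReflectanceTruth

        truth = CohortTruth(
            seed=3, n_participants=2, visit_months=(0, 12),
            fixed_visit_effects={0: 0.0, 12: 1.0},
            reflectometry_truth={
                "inner_bicep": SiteReflectanceTruth(
                    baseline_m=20.0, effect_12=1.72,
                    participant_sd=0.0, replicate_sd=0.0,
                )
            },
        )
        bundle = generate_cohort(truth)
        table = summarize_all(bundle.spectra).set_index(["participant", "visit_month"])
        assert table.loc[("P001", 0), "m_index"] == pytest.approx(20.0, abs=1e-9)
        assert table.loc[("P001", 12), "m_index"] == pytest.approx(21.72, abs=1e-9)

    def test_second_baseline_adds_earlier_visit(self):
        truth = CohortTruth(seed=5, second_baseline=True)
        bundle = generate_cohort(truth)
        assert bundle.latent["visit_month"].min() == -1
        assert 0 in set(bundle.latent["visit_month"])


class TestDistributionalSanity:
    def test_baseline_panel_sd_matches_analytic(self):
        # single baseline visit, one image per eye-visit, 500 participants
        truth = CohortTruth(
            seed=11, n_participants=500, visit_months=(0,),
            fixed_visit_effects={0: 0.0}, images_per_eye_visit=1,
            image_size=64, iris_radius=24.0, pupil_radius=7.0,
        )
        bundle = generate_cohort(truth)
        from pigmentrial.panel import panel_scores

        ps = panel_scores(bundle.grades)
        per_participant = ps.groupby("participant")["panel_score"].mean()
        # grader bias is a common shift across participants; only the
        # intercept and averaged grader noise spread participants
        analytic_sd = np.sqrt(
            truth.sd_intercept**2
            + truth.grader_noise_sd**2 / (truth.n_graders * 2)
        )
        assert per_participant.std(ddof=1) == pytest.approx(analytic_sd, rel=0.10)

    def test_directional_change_recovers_generating_effect(self):
        # large cohort, small noise: downstream mean change at month 12
        # within +/-0.1 of the generating value 1.0
        truth = CohortTruth(
            seed=21, n_participants=200, visit_months=(0, 12),
            fixed_visit_effects={0: 0.0, 12: 1.0},
            sd_intercept=0.5, sd_slope=0.005,
            grader_bias_sd=0.05, grader_noise_sd=0.1,
            latent_baseline_mean=3.0,
        )
        latent = simulate_trajectories(truth, np.random.default_rng(truth.seed))
        ds = latent.rename(columns={"latent": "value"})
        from pigmentrial.longitudinal import change_from_baseline

        cs = change_from_baseline(ds, 12)
        ou = cs.summary.set_index("group").loc["OU", "directional_mean"]
        assert ou == pytest.approx(1.0, abs=0.1)
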