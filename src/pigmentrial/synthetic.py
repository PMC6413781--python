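"""Synthetic pilot-trial cohort with known ground truth.

Generates every input the pipeline consumes — iris TI photographs,
grader tables, reflectance spectra, hair chemistry and visual-acuity
letters — from an explicit truth object and a seed, so that every
downstream estimate can be checked against the generating value.

The latent pigmentation model is a per-eye, per-visit score on the 0–8
transillumination scale:

    L(i, e, t) = baseline_mean + b_i + slope_i * t + effect_t,  clamped to [0, 8]

with participant random intercepts b_i ~ N(0, sd_intercept^2), random
slopes slope_i ~ N(0, sd_slope^2) per month, and fixed per-visit mean
changes effect_t. Graders see L plus a grader-specific bias and
per-observation noise, clamped and rounded to one decimal. Images encode
L in the red channel of the iris annulus, with a saturated-red pupil
mimicking the retinal red reflex, so the automated scorer recovers L.
Reflectance spectra are built by inverting the melanin-index formula for
a target M value; hair markers follow lognormal baselines with an
additive treatment-period shift.

Default truth values reproduce the reference study's design (5
participants, both eyes, visits at months 0–18, 18 graders, 2 images per
eye-visit) and its observed effect sizes as generating values.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from .imaging import IrisGeometry, TIImage
from .reflectometry import (
    WAVELENGTH_GRID,
    ReflectanceSpectrum,
    m_index_to_band_pr,
    spectra_to_frame,
)

EYES = ("OD", "OS")


class TruthValidationError(ValueError):
    """A CohortTruth field violates its invariant."""


@dataclass(frozen=True)
class SiteReflectanceTruth:
    """True M-index trajectory for one body site.

    ``effect_12`` is the true mean M change at month 12, ramped linearly
    from baseline and held constant thereafter.
    """

    baseline_m: float
    effect_12: float
    participant_sd: float = 3.0
    replicate_sd: float = 0.5
    n_replicates: int = 5


@dataclass(frozen=True)
class HairMarkerTruth:
    """Lognormal baseline and treatment-period shift for one marker.

    ``meanlog``/``sdlog`` parameterize the baseline concentration (ng/mg);
    the true mean shift ramps to ``shift_12`` at month 12 and returns to
    ``shift_end`` by the final visit, with per-visit change noise."""

    meanlog: float
    sdlog: float
    shift_12: float
    shift_end: float
    change_sd: float


@dataclass(frozen=True)
class AcuityTruth:
    """Visual-acuity letters-read generator (per eye)."""

    baseline_mean: float = 50.0
    sd_intercept: float = 8.0
    eye_sd: float = 2.0
    residual_sd: float = 2.0
    #: anchor months -> true mean letters gained (linear in between)
    visit_effects: Mapping[int, float] = field(
        default_factory=lambda: {0: 0.0, 3: 1.5, 6: 2.5, 9: 3.5, 12: 4.6, 15: 5.0, 18: 6.0}
    )


def _default_reflectometry_truth() -> dict[str, SiteReflectanceTruth]:
    return {
        "forehead": SiteReflectanceTruth(baseline_m=23.0, effect_12=1.0),
        "inner_forearm": SiteReflectanceTruth(baseline_m=21.0, effect_12=1.0),
        "outer_forearm": SiteReflectanceTruth(baseline_m=25.0, effect_12=3.4),
        "inner_bicep": SiteReflectanceTruth(baseline_m=20.0, effect_12=1.72),
        "lower_back": SiteReflectanceTruth(baseline_m=22.0, effect_12=1.0),
        "hair": SiteReflectanceTruth(baseline_m=35.0, effect_12=17.3, participant_sd=5.0),
    }


def _default_hair_truth() -> dict[str, HairMarkerTruth]:
    # moment-matched lognormal baselines: PTCA mean 26.22 sd 20.59,
    # 4-AHP mean 13.28 sd 19.66 ng/mg
    return {
        "ptca": HairMarkerTruth(
            meanlog=3.026, sdlog=0.693, shift_12=7.62, shift_end=0.52, change_sd=6.43
        ),
        "ahp4": HairMarkerTruth(
            meanlog=2.006, sdlog=1.077, shift_12=-5.92, shift_end=-5.24, change_sd=11.68
        ),
    }


@dataclass(frozen=True)
class CohortTruth:
    """Ground-truth parameters for one synthetic cohort."""

    n_participants: int = 5
    visit_months: tuple[int, ...] = (0, 3, 6, 9, 12, 15, 18)
    latent_baseline_mean: float = 3.0
    sd_intercept: float = 1.0
    sd_slope: float = 0.04
    fixed_visit_effects: Mapping[int, float] = field(
        default_factory=lambda: {0: 0.0, 3: 0.3, 6: 0.5, 9: 0.8, 12: 1.0, 15: 1.0, 18: 1.0}
    )
    grader_bias_sd: float = 0.3
    grader_noise_sd: float = 0.5
    n_graders: int = 18
    images_per_eye_visit: int = 2
    reflectometry_truth: Mapping[str, SiteReflectanceTruth] = field(
        default_factory=_default_reflectometry_truth
    )
    hair_truth: Mapping[str, HairMarkerTruth] = field(default_factory=_default_hair_truth)
    acuity_truth: AcuityTruth = field(default_factory=AcuityTruth)
    # image rendering
    image_size: int = 160
    iris_radius: float = 64.0
    pupil_radius: float = 19.0
    image_noise_sd: float = 2.0
    # collapse the protocol's 2 baseline visits to month 0 by default; set
    # True to add a second baseline at month -1 and exercise the
    # earliest-baseline rule
    second_baseline: bool = False
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "sd_intercept", "sd_slope", "grader_bias_sd", "grader_noise_sd",
            "image_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise TruthValidationError(f"{name} must be >= 0")
        months = list(self.visit_months)
        if months != sorted(set(months)):
            raise TruthValidationError("visit_months must be strictly increasing")
        if 0 not in months:
            raise TruthValidationError("visit_months must include 0")
        if self.n_graders < 2:
            raise TruthValidationError("n_graders must be >= 2")
        if self.images_per_eye_visit < 1:
            raise TruthValidationError("images_per_eye_visit must be >= 1")
        if self.n_participants < 1:
            raise TruthValidationError("n_participants must be >= 1")
        missing = [m for m in months if m >= 0 and m not in self.fixed_visit_effects]
        if missing:
            raise TruthValidationError(
                f"fixed_visit_effects missing months {missing}"
            )

    @property
    def all_visit_months(self) -> tuple[int, ...]:
        if self.second_baseline:
            return (-1,) + tuple(self.visit_months)
        return tuple(self.visit_months)

    def visit_effect(self, month: int) -> float:
        return 0.0 if month < 0 else float(self.fixed_visit_effects[month])

    def geometry(self) -> IrisGeometry:
        c = (self.image_size - 1) / 2.0
        return IrisGeometry(
            center_x=c, center_y=c,
            iris_radius=self.iris_radius, pupil_radius=self.pupil_radius,
        )


@dataclass
class SyntheticBundle:
    """Everything one synthetic trial produces, plus its generating truth."""

    images: list[TIImage]
    grades: pd.DataFrame
    spectra: list[ReflectanceSpectrum]
    hair: pd.DataFrame
    acuity: pd.DataFrame
    latent: pd.DataFrame
    truth: CohortTruth


def _round_grade(values: np.ndarray) -> np.ndarray:
    return np.round(np.clip(values, 0.0, 8.0), 1)


def render_ti_image(
    latent_score: float,
    geometry: IrisGeometry,
    size: tuple[int, int] = (160, 160),
    noise_sd: float = 0.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    participant: str = "sim",
    eye: str = "OD",
    visit_month: int = 0,
    image_index: int = 1,
) -> TIImage:
    """Render a TI photograph whose annulus red channel encodes a score.

    The iris annulus gets red mean ``latent_score/8 * 255`` plus optional
    zero-mean Gaussian noise; the pupil disk is saturated red (the retinal
    red reflex); the background is dark. Green and blue carry arbitrary
    low values so that red-only measurement can be verified.
    """
    if not 0.0 <= latent_score <= 8.0:
        raise ValueError(f"latent_score must be in [0, 8], got {latent_score}")
    h, w = size
    geometry.check_bounds(h, w)
    if rng is None:
        rng = np.random.default_rng(seed)

    yy, xx = np.mgrid[0:h, 0:w]
    rr = np.hypot(xx - geometry.center_x, yy - geometry.center_y)
    pupil = rr <= geometry.pupil_radius
    annulus = (rr > geometry.pupil_radius) & (rr <= geometry.iris_radius)

    red = np.zeros((h, w), dtype=float)
    level = latent_score / 8.0 * 255.0
    if noise_sd > 0:
        red[annulus] = level + rng.normal(0.0, noise_sd, size=int(annulus.sum()))
    else:
        red[annulus] = level
    red[pupil] = 255.0

    px = np.zeros((h, w, 3), dtype=np.uint8)
    px[:, :, 0] = np.clip(np.round(red), 0, 255).astype(np.uint8)
    px[:, :, 1] = 10
    px[:, :, 2] = 5
    return TIImage(
        pixels=px, geometry=geometry, participant=participant, eye=eye,
        visit_month=visit_month, image_index=image_index,
    )


def simulate_trajectories(truth: CohortTruth, rng: np.random.Generator) -> pd.DataFrame:
    """Latent eye-visit scores L(i, e, t) for every participant."""
    b = rng.normal(0.0, truth.sd_intercept, size=truth.n_participants)
    s = rng.normal(0.0, truth.sd_slope, size=truth.n_participants)
    rows = []
    for i in range(truth.n_participants):
        pid = f"P{i + 1:03d}"
        for eye in EYES:
            for t in truth.all_visit_months:
                latent = (
                    truth.latent_baseline_mean + b[i] + s[i] * t + truth.visit_effect(t)
                )
                rows.append(
                    {
                        "participant": pid,
                        "eye": eye,
                        "visit_month": int(t),
                        "latent": float(np.clip(latent, 0.0, 8.0)),
                    }
                )
    return pd.DataFrame(rows)


def simulate_outcome_panel(
    n_participants: int,
    visit_months: Sequence[int],
    fixed_visit_effects: Mapping[int, float],
    baseline_mean: float = 3.0,
    sd_intercept: float = 1.0,
    sd_slope: float = 0.02,
    residual_sd: float = 0.3,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Participant-level longitudinal outcome (no eyes, no clamping).

    A light-weight generator for estimator-recovery studies: random
    intercept + slope trajectories with i.i.d. residual noise, returned as
    a tidy table ready for :func:`pigmentrial.longitudinal.fit_longitudinal`.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    b = rng.normal(0.0, sd_intercept, size=n_participants)
    s = rng.normal(0.0, sd_slope, size=n_participants)
    rows = []
    for i in range(n_participants):
        for t in visit_months:
            value = (
                baseline_mean + b[i] + s[i] * t + float(fixed_visit_effects.get(t, 0.0))
                + rng.normal(0.0, residual_sd)
            )
            rows.append(
                {"participant": f"P{i + 1:04d}", "visit_month": int(t), "value": value}
            )
    return pd.DataFrame(rows)


def _synth_spectrum(
    m: float, site: str, replicate: int, participant: str, visit_month: int
) -> ReflectanceSpectrum:
    """Spectrum whose melanin-band reflectance encodes M = m exactly.

    Wavelengths outside the 640–670 nm band follow an arbitrary smooth
    ramp; the index depends only on the band values."""
    band_pr = m_index_to_band_pr(m)
    frac = (WAVELENGTH_GRID - 400.0) / 300.0
    pr = band_pr * (0.7 + 0.35 * frac)
    band = (WAVELENGTH_GRID >= 640) & (WAVELENGTH_GRID <= 670)
    pr[band] = band_pr
    return ReflectanceSpectrum(
        pr=pr, site=site, replicate=replicate,
        participant=participant, visit_month=visit_month,
    )


def generate_cohort(truth: CohortTruth) -> SyntheticBundle:
    """Generate the full synthetic bundle; deterministic given the seed."""
    truth.validate()
    ss = np.random.SeedSequence(truth.seed)
    rng_traj, rng_grades, rng_images, rng_spectra, rng_hair, rng_acuity = (
        np.random.default_rng(child) for child in ss.spawn(6)
    )

    latent = simulate_trajectories(truth, rng_traj)
    geometry = truth.geometry()
    participants = sorted(latent["participant"].unique())

    # grader panel: fixed per-grader bias, fresh noise per image grade
    grader_ids = [f"G{g + 1:02d}" for g in range(truth.n_graders)]
    bias = rng_grades.normal(0.0, truth.grader_bias_sd, size=truth.n_graders)

    grade_rows = []
    images: list[TIImage] = []
    for _, row in latent.iterrows():
        ln = row["latent"]
        for j in range(1, truth.images_per_eye_visit + 1):
            images.append(
                render_ti_image(
                    ln, geometry, size=(truth.image_size, truth.image_size),
                    noise_sd=truth.image_noise_sd, rng=rng_images,
                    participant=row["participant"], eye=row["eye"],
                    visit_month=int(row["visit_month"]), image_index=j,
                )
            )
            noise = rng_grades.normal(0.0, truth.grader_noise_sd, size=truth.n_graders)
            grades = _round_grade(ln + bias + noise)
            for g, gid in enumerate(grader_ids):
                grade_rows.append(
                    {
                        "participant": row["participant"],
                        "eye": row["eye"],
                        "visit_month": int(row["visit_month"]),
                        "grader_id": gid,
                        "image_index": j,
                        "grade": grades[g],
                    }
                )
    grades_df = pd.DataFrame(grade_rows)

    # reflectance spectra: per-participant site offsets constant over visits
    spectra: list[ReflectanceSpectrum] = []
    for site, st in truth.reflectometry_truth.items():
        offsets = rng_spectra.normal(0.0, st.participant_sd, size=len(participants))
        for ip, pid in enumerate(participants):
            for t in truth.all_visit_months:
                ramp = st.effect_12 * min(max(t, 0), 12) / 12.0
                site_m = st.baseline_m + offsets[ip] + ramp
                for rep in range(1, st.n_replicates + 1):
                    m_rep = site_m + rng_spectra.normal(0.0, st.replicate_sd)
                    spectra.append(_synth_spectrum(m_rep, site, rep, pid, int(t)))

    # hair chemistry: lognormal baseline plus shifted, noisy follow-ups
    hair_rows = []
    months = np.array([0.0, 12.0, 18.0])
    for pid in participants:
        base = {
            m: float(rng_hair.lognormal(ht.meanlog, ht.sdlog))
            for m, ht in truth.hair_truth.items()
        }
        for t in truth.all_visit_months:
            rec = {"participant": pid, "visit_month": int(t)}
            for m, ht in truth.hair_truth.items():
                if t <= 0:
                    value = base[m]
                else:
                    shift = float(np.interp(t, months, [0.0, ht.shift_12, ht.shift_end]))
                    value = base[m] + shift + rng_hair.normal(0.0, ht.change_sd)
                rec[m] = max(value, 0.0)
            hair_rows.append(rec)
    hair_df = pd.DataFrame(hair_rows)

    # visual acuity letters read, per eye
    at = truth.acuity_truth
    anchor_m = np.array(sorted(at.visit_effects))
    anchor_e = np.array([at.visit_effects[m] for m in anchor_m])
    acuity_rows = []
    for pid in participants:
        bi = rng_acuity.normal(0.0, at.sd_intercept)
        for eye in EYES:
            ue = rng_acuity.normal(0.0, at.eye_sd)
            for t in truth.all_visit_months:
                eff = float(np.interp(max(t, 0), anchor_m, anchor_e))
                letters = (
                    at.baseline_mean + bi + ue + eff
                    + rng_acuity.normal(0.0, at.residual_sd)
                )
                acuity_rows.append(
                    {
                        "participant": pid,
                        "eye": eye,
                        "visit_month": int(t),
                        "letters": int(round(np.clip(letters, 0, 100))),
                    }
                )
    acuity_df = pd.DataFrame(acuity_rows)

    return SyntheticBundle(
        images=images, grades=grades_df, spectra=spectra,
        hair=hair_df, acuity=acuity_df, latent=latent, truth=truth,
    )


# ---------------------------------------------------------------------------
# On-disk bundle

def truth_to_dict(truth: CohortTruth) -> dict:
    d = asdict(truth)
    d["visit_months"] = list(truth.visit_months)
    d["fixed_visit_effects"] = {int(k): float(v) for k, v in truth.fixed_visit_effects.items()}
    d["acuity_truth"]["visit_effects"] = {
        int(k): float(v) for k, v in truth.acuity_truth.visit_effects.items()
    }
    return d


def truth_from_dict(d: dict) -> CohortTruth:
    d = dict(d)
    d["visit_months"] = tuple(d["visit_months"])
    d["reflectometry_truth"] = {
        k: SiteReflectanceTruth(**v) for k, v in d["reflectometry_truth"].items()
    }
    d["hair_truth"] = {k: HairMarkerTruth(**v) for k, v in d["hair_truth"].items()}
    d["acuity_truth"] = AcuityTruth(**d["acuity_truth"])
    return CohortTruth(**d)


def write_bundle(bundle: SyntheticBundle, outdir: str | Path) -> Path:
    """Write images (PNG), tables (CSV), truth (YAML) and a manifest."""
    outdir = Path(outdir)
    (outdir / "images").mkdir(parents=True, exist_ok=True)

    geom_rows = []
    for img in bundle.images:
        fname = (
            f"{img.participant}_{img.eye}_m{img.visit_month:+03d}_i{img.image_index}.png"
        ).replace("+", "p").replace("-", "n")
        iio.imwrite(outdir / "images" / fname, img.pixels)
        g = img.geometry
        geom_rows.append(
            {
                "filename": fname,
                "participant": img.participant,
                "eye": img.eye,
                "visit_month": img.visit_month,
                "image_index": img.image_index,
                "center_x": g.center_x,
                "center_y": g.center_y,
                "iris_radius": g.iris_radius,
                "pupil_radius": g.pupil_radius,
            }
        )
    pd.DataFrame(geom_rows).to_csv(outdir / "geometry.csv", index=False)
    bundle.grades.to_csv(outdir / "grades.csv", index=False)
    spectra_to_frame(bundle.spectra).to_csv(outdir / "spectra.csv", index=False)
    bundle.hair.to_csv(outdir / "hair.csv", index=False)
    bundle.acuity.to_csv(outdir / "acuity.csv", index=False)
    bundle.latent.to_csv(outdir / "latent_truth.csv", index=False)
    with open(outdir / "truth.yaml", "w") as fh:
        yaml.safe_dump(truth_to_dict(bundle.truth), fh, sort_keys=True)

    manifest = {
        "seed": bundle.truth.seed,
        "n_images": len(bundle.images),
        "n_grades": len(bundle.grades),
        "n_spectra": len(bundle.spectra),
        "files": sorted(
            str(p.relative_to(outdir)) for p in outdir.rglob("*") if p.is_file()
        ),
    }
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return outdir
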