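"""Melanin (M) index from diffuse reflectance spectra.

Diffuse reflectance spectrophotometry measures percent reflectance (PR)
relative to a white standard at 10-nm steps across the visible spectrum
(400–700 nm). Melanin absorbs strongly and smoothly in the red band, so a
log-reciprocal summary of reflectance at 640–670 nm quantifies melanin
content while being insensitive to haemoglobin (erythema) absorption at
shorter wavelengths:

    band = ((PR_650 + PR_660 + 0.5*PR_640 + 0.5*PR_670) / 3) / 100
    M    = 100 * log10(1 / band)

A perfect reflector (PR = 100 everywhere) gives M = 0; lower reflectance
in the melanin band gives higher M. Scaling the band reflectances by 10
shifts M by exactly -100 (log-linearity).

Measurements are replicated (typically 5x) per body site; replicate M
values are averaged per participant x visit x site. Instrument sessions
are bracketed by white-standard and light-trap calibration scans, checked
here against configurable tolerances.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

#: canonical wavelength grid, nm
WAVELENGTH_GRID = np.arange(400, 701, 10)

#: body sites measured in the trial protocol (hair processed identically)
SITES = (
    "forehead",
    "inner_forearm",
    "outer_forearm",
    "inner_bicep",
    "lower_back",
    "hair",
)

MELANIN_BAND = (640, 650, 660, 670)


class SpectrumError(ValueError):
    """Invalid or incomplete reflectance spectrum."""


@dataclass(frozen=True)
class ReflectanceSpectrum:
    """One replicate reflectance scan on the 400–700 nm / 10 nm grid.

    ``pr`` holds percent reflectance per wavelength; values slightly above
    100 are tolerated (specular highlights against the white standard).
    """

    pr: np.ndarray
    site: str
    replicate: int
    participant: str
    visit_month: int
    wavelengths: np.ndarray = field(default_factory=lambda: WAVELENGTH_GRID.copy())

    def __post_init__(self) -> None:
        pr = np.asarray(self.pr, dtype=float)
        wl = np.asarray(self.wavelengths, dtype=float)
        object.__setattr__(self, "pr", pr)
        object.__setattr__(self, "wavelengths", wl)
        if pr.shape != wl.shape:
            raise SpectrumError("pr and wavelengths must have matching shape")
        if not np.array_equal(wl, WAVELENGTH_GRID):
            raise SpectrumError("wavelength grid must be 400–700 nm in 10 nm steps")
        if np.any(pr < 0) or not np.all(np.isfinite(pr)):
            raise SpectrumError("percent reflectance must be finite and >= 0")

    def at(self, wavelength: int) -> float:
        idx = int((wavelength - 400) // 10)
        if not 0 <= idx < len(self.pr) or self.wavelengths[idx] != wavelength:
            raise SpectrumError(f"wavelength {wavelength} nm not on grid")
        return float(self.pr[idx])


@dataclass(frozen=True)
class MIndexRecord:
    """Aggregated melanin index for one participant x visit x site."""

    m_index: float
    site: str
    participant: str
    visit_month: int
    n_replicates: int


def m_index(spectrum: ReflectanceSpectrum) -> float:
    """Melanin index of a single spectrum.

    Raises
    ------
    SpectrumError
        If the weighted melanin-band reflectance is non-positive (the
        log-reciprocal is undefined).
    """
    pr640, pr650, pr660, pr670 = (spectrum.at(w) for w in MELANIN_BAND)
    band = ((pr650 + pr660 + 0.5 * pr640 + 0.5 * pr670) / 3.0) / 100.0
    if band <= 0:
        raise SpectrumError("non-positive reflectance at melanin wavelengths")
    return float(100.0 * np.log10(1.0 / band))


def m_index_to_band_pr(m: float) -> float:
    """Percent reflectance that, set uniformly over 640–670 nm, yields M = m."""
    return float(100.0 * 10.0 ** (-m / 100.0))


def summarize_site(
    records: Sequence[ReflectanceSpectrum],
    aggregate: Literal["mean-m", "mean-spectrum"] = "mean-m",
) -> MIndexRecord:
    """Collapse the replicates of one participant x visit x site to one M index.

    ``mean-m`` (default) averages per-replicate M values — M is the analyzed
    quantity. ``mean-spectrum`` averages the spectra pointwise first and takes
    the M index of the mean spectrum; the two differ by Jensen's inequality
    when replicates vary.
    """
    if not records:
        raise SpectrumError("no replicates to summarize")
    keys = {(s.participant, s.visit_month, s.site) for s in records}
    if len(keys) != 1:
        raise SpectrumError(f"mixed groups in replicate set: {sorted(keys)}")
    participant, visit_month, site = next(iter(keys))
    if aggregate == "mean-m":
        m = float(np.mean([m_index(s) for s in records]))
    elif aggregate == "mean-spectrum":
        mean_pr = np.mean([s.pr for s in records], axis=0)
        m = m_index(
            ReflectanceSpectrum(
                pr=mean_pr, site=site, replicate=0,
                participant=participant, visit_month=visit_month,
            )
        )
    else:
        raise ValueError(f"unknown aggregate mode {aggregate!r}")
    return MIndexRecord(
        m_index=m, site=site, participant=participant,
        visit_month=visit_month, n_replicates=len(records),
    )


def summarize_all(
    spectra: Iterable[ReflectanceSpectrum],
    aggregate: Literal["mean-m", "mean-spectrum"] = "mean-m",
) -> pd.DataFrame:
    """M-index table over all participant x visit x site groups."""
    groups: dict[tuple, list[ReflectanceSpectrum]] = {}
    for s in spectra:
        groups.setdefault((s.participant, s.visit_month, s.site), []).append(s)
    rows = []
    for key in sorted(groups):
        rec = summarize_site(groups[key], aggregate=aggregate)
        rows.append(
            {
                "participant": rec.participant,
                "visit_month": rec.visit_month,
                "site": rec.site,
                "m_index": rec.m_index,
                "n_replicates": rec.n_replicates,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class CalibrationReport:
    passed: bool
    white_deviations: pd.DataFrame
    dark_deviations: pd.DataFrame
    tolerance: float


def calibration_check(
    white_ref: ReflectanceSpectrum,
    dark_ref: ReflectanceSpectrum,
    tolerance: float = 2.0,
) -> CalibrationReport:
    """Check a session's white-standard and light-trap scans.

    The white standard should read ~100 % and the light trap ~0 % at every
    wavelength; deviations beyond ``tolerance`` percentage points fail the
    session. Per-wavelength deviations are reported either way.
    """
    def _dev(spec: ReflectanceSpectrum, target: float) -> pd.DataFrame:
        dev = spec.pr - target
        return pd.DataFrame(
            {
                "wavelength_nm": spec.wavelengths.astype(int),
                "pr": spec.pr,
                "deviation": dev,
                "out_of_tolerance": np.abs(dev) > tolerance,
            }
        )

    white = _dev(white_ref, 100.0)
    dark = _dev(dark_ref, 0.0)
    passed = not (white["out_of_tolerance"].any() or dark["out_of_tolerance"].any())
    return CalibrationReport(
        passed=bool(passed),
        white_deviations=white,
        dark_deviations=dark,
        tolerance=tolerance,
    )


# ---------------------------------------------------------------------------
# CSV I/O

_ID_COLS = ["participant", "visit_month", "site", "replicate"]


def spectra_to_frame(spectra: Iterable[ReflectanceSpectrum]) -> pd.DataFrame:
    """Wide table: identifier columns plus one ``pr_<nm>`` column per wavelength."""
    rows = []
    for s in spectra:
        row = {
            "participant": s.participant,
            "visit_month": s.visit_month,
            "site": s.site,
            "replicate": s.replicate,
        }
        row.update({f"pr_{int(w)}": v for w, v in zip(s.wavelengths, s.pr)})
        rows.append(row)
    return pd.DataFrame(rows)


def read_spectra_csv(path) -> list[ReflectanceSpectrum]:
    """Read spectra from CSV, wide (``pr_400``..``pr_700``) or long
    (``wavelength``, ``pr``) layout, auto-detected from the header."""
    df = pd.read_csv(path)
    if "wavelength" in df.columns:  # long layout
        spectra = []
        for key, grp in df.groupby(_ID_COLS, sort=True):
            grp = grp.sort_values("wavelength")
            spectra.append(
                ReflectanceSpectrum(
                    pr=grp["pr"].to_numpy(float),
                    wavelengths=grp["wavelength"].to_numpy(float),
                    participant=str(key[0]),
                    visit_month=int(key[1]),
                    site=str(key[2]),
                    replicate=int(key[3]),
                )
            )
        return spectra
    pr_cols = [f"pr_{int(w)}" for w in WAVELENGTH_GRID]
    missing = [c for c in pr_cols if c not in df.columns]
    if missing:
        raise SpectrumError(f"missing wavelength columns: {missing[:3]}...")
    return [
        ReflectanceSpectrum(
            pr=row[pr_cols].to_numpy(float),
            participant=str(row["participant"]),
            visit_month=int(row["visit_month"]),
            site=str(row["site"]),
            replicate=int(row["replicate"]),
        )
        for _, row in df.iterrows()
    ]
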