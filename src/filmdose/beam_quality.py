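"""Beam-quality characterisation for kilovoltage x-ray beams.

A polyenergetic beam is dosimetrically matched to a monoenergetic one
through the half-value layer (HVL): the absorber thickness that halves
the transmitted intensity.  For a monoenergetic beam HVL = ln 2 / mu and
the first and second HVLs coincide; beam hardening in a polyenergetic
beam stretches the second HVL, which the homogeneity factor
HF = HVL1/HVL2 quantifies (HF = 1 for a single energy, < 1 otherwise).

The module provides

* closed-form and spectrum-based HVL computation against a tabulated
  mass-attenuation coefficient mu/rho(E),
* the effective energy of a beam (the monoenergetic energy with the
  same first HVL),
* piecewise-linear interpolation of chamber calibration coefficients
  (or any beam-quality-dependent factor) versus HVL.

Lengths are handled in cm internally; HVLs cross the API in mm.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "AttenuationTable",
    "Spectrum",
    "BeamQuality",
    "CalibrationPoint",
    "aluminum_table",
    "load_attenuation_table",
    "load_calibration_points",
    "hvl_monoenergetic",
    "transmission",
    "hvl_from_spectrum",
    "homogeneity_factor",
    "effective_energy",
    "interpolate_vs_hvl",
]

MM_PER_CM = 10.0

# Relative tolerance of the bracketed root finds and the bracket cap,
# expressed as a multiple of a crude HVL estimate.
_ROOT_RTOL = 1e-9
_MAX_HVL_MULTIPLES = 50.0


@dataclass(frozen=True)
class AttenuationTable:
    """Tabulated mass-attenuation coefficient mu/rho(E) for one material.

    Parameters
    ----------
    material:
        Identifier, e.g. ``"aluminum"``.
    density:
        Bulk density in g/cm^3.
    energies_kev:
        Strictly increasing photon energies in keV.
    mu_over_rho:
        Mass-attenuation coefficients in cm^2/g, one per energy.

    Interpolation between grid points is log-log linear, the usual
    convention for attenuation data.
    """

    material: str
    density: float
    energies_kev: np.ndarray
    mu_over_rho: np.ndarray

    def __post_init__(self) -> None:
        e = np.asarray(self.energies_kev, dtype=float)
        m = np.asarray(self.mu_over_rho, dtype=float)
        if e.ndim != 1 or e.size < 2:
            raise ValueError("attenuation table needs at least 2 rows")
        if e.size != m.size:
            raise ValueError("energy and mu/rho columns differ in length")
        if np.any(np.diff(e) <= 0):
            raise ValueError("energies must be strictly increasing")
        if np.any(m <= 0) or self.density <= 0:
            raise ValueError("mu/rho and density must be positive")
        object.__setattr__(self, "energies_kev", e)
        object.__setattr__(self, "mu_over_rho", m)

    def mu_over_rho_at(self, energy_kev: float | np.ndarray) -> np.ndarray:
        """Log-log interpolated mu/rho (cm^2/g) at ``energy_kev``."""
        e = np.asarray(energy_kev, dtype=float)
        lo, hi = self.energies_kev[0], self.energies_kev[-1]
        bad = (e < lo) | (e > hi)
        if np.any(bad):
            off = np.atleast_1d(e)[np.atleast_1d(bad)][0]
            raise ValueError(
                f"energy {off:g} keV outside {self.material} table "
                f"range [{lo:g}, {hi:g}] keV"
            )
        out = np.exp(
            np.interp(np.log(e), np.log(self.energies_kev), np.log(self.mu_over_rho))
        )
        return out if out.ndim else float(out)

    def mu_linear_at(self, energy_kev: float | np.ndarray) -> np.ndarray:
        """Linear attenuation coefficient mu (1/cm) at ``energy_kev``."""
        return self.mu_over_rho_at(energy_kev) * self.density


@dataclass(frozen=True)
class Spectrum:
    """Discrete photon spectrum: energy bins with relative fluence weights."""

    energies_kev: np.ndarray
    fluence: np.ndarray

    def __post_init__(self) -> None:
        e = np.asarray(self.energies_kev, dtype=float)
        f = np.asarray(self.fluence, dtype=float)
        if e.ndim != 1 or e.size == 0 or e.size != f.size:
            raise ValueError("spectrum needs matching non-empty energy/fluence arrays")
        if e.size > 1 and np.any(np.diff(e) <= 0):
            raise ValueError("spectrum energies must be strictly increasing")
        if np.any(f < 0) or not np.any(f > 0):
            raise ValueError("fluence must be non-negative with at least one positive bin")
        object.__setattr__(self, "energies_kev", e)
        object.__setattr__(self, "fluence", f)

    @classmethod
    def monoenergetic(cls, energy_kev: float) -> "Spectrum":
        return cls(np.array([energy_kev]), np.array([1.0]))


@dataclass
class BeamQuality:
    """A beam's quality descriptors: HVLs, homogeneity factor, effective energy."""

    label: str
    hvl1_mm: float
    hvl2_mm: float | None = None
    effective_energy_kev: float | None = None
    material: str = "Al"

    def __post_init__(self) -> None:
        if self.hvl1_mm <= 0:
            raise ValueError("hvl1 must be positive")
        if self.hvl2_mm is not None and self.hvl2_mm <= 0:
            raise ValueError("hvl2 must be positive")

    @property
    def homogeneity_factor(self) -> float | None:
        if self.hvl2_mm is None:
            return None
        return homogeneity_factor(self.hvl1_mm, self.hvl2_mm)


@dataclass(frozen=True)
class CalibrationPoint:
    """One chamber air-kerma calibration point: (kVp, HVL, N_K)."""

    kvp: float
    hvl_mm: float
    n_k: float  # cGy/nC
    material: str = "Al"

    def __post_init__(self) -> None:
        if min(self.kvp, self.hvl_mm, self.n_k) <= 0:
            raise ValueError("kvp, hvl and n_k must all be positive")


def load_attenuation_table(csv_path: str | Path, sidecar_path: str | Path) -> AttenuationTable:
    """Read a mu/rho table from ``energy_kev,mu_over_rho_cm2_g`` CSV + JSON sidecar."""
    df = pd.read_csv(csv_path)
    meta = json.loads(Path(sidecar_path).read_text())
    return AttenuationTable(
        material=meta["material"],
        density=float(meta["density_g_cm3"]),
        energies_kev=df["energy_kev"].to_numpy(float),
        mu_over_rho=df["mu_over_rho_cm2_g"].to_numpy(float),
    )


def aluminum_table() -> AttenuationTable:
    """The bundled aluminum mu/rho table (10-300 keV, NIST compilation values)."""
    data = resources.files("filmdose.data")
    with resources.as_file(data / "aluminum_mu_over_rho.csv") as csv_p, resources.as_file(
        data / "aluminum.json"
    ) as json_p:
        return load_attenuation_table(csv_p, json_p)


def load_calibration_points(csv_path: str | Path) -> list[CalibrationPoint]:
    """Read chamber calibration points from ``kvp,hvl_mm,material,n_k_cgy_per_nc`` CSV."""
    df = pd.read_csv(csv_path)
    return [
        CalibrationPoint(
            kvp=float(r.kvp),
            hvl_mm=float(r.hvl_mm),
            n_k=float(r.n_k_cgy_per_nc),
            material=str(r.material),
        )
        for r in df.itertuples()
    ]


def bundled_nk_points() -> list[CalibrationPoint]:
    """The bundled NEL2515/3 chamber N_K points (100, 125, 250 kVp)."""
    with resources.as_file(resources.files("filmdose.data") / "nel2515_nk.csv") as p:
        return load_calibration_points(p)


def hvl_monoenergetic(mass_attenuation: float, density: float) -> float:
    """Closed-form HVL (mm) of a monoenergetic beam: ln 2 / (mu/rho * rho).

    Parameters are the mass-attenuation coefficient in cm^2/g and the
    absorber density in g/cm^3.
    """
    if mass_attenuation <= 0 or density <= 0:
        raise ValueError("mass_attenuation and density must be positive")
    return np.log(2.0) / (mass_attenuation * density) * MM_PER_CM


def transmission(
    spectrum: Spectrum, table: AttenuationTable, thickness_mm: float
) -> float:
    """Fluence-weighted narrow-beam transmission through ``thickness_mm`` of absorber.

    Returns the fluence-weighted mean of exp(-mu(E) * t) over the
    spectrum bins; exactly 1 at zero thickness and strictly decreasing
    in thickness.
    """
    if thickness_mm < 0:
        raise ValueError("thickness must be non-negative")
    mu = table.mu_linear_at(spectrum.energies_kev)  # 1/cm
    t_cm = thickness_mm / MM_PER_CM
    w = spectrum.fluence / spectrum.fluence.sum()
    return float(np.sum(w * np.exp(-np.atleast_1d(mu) * t_cm)))


def _solve_thickness(
    spectrum: Spectrum, table: AttenuationTable, target: float
) -> float:
    """Thickness (mm) at which transmission drops to ``target``."""
    # crude scale: HVL of the fluence-weighted mean mu
    mu = np.atleast_1d(table.mu_linear_at(spectrum.energies_kev))
    w = spectrum.fluence / spectrum.fluence.sum()
    scale_mm = np.log(2.0) / float(np.sum(w * mu)) * MM_PER_CM
    t_max = _MAX_HVL_MULTIPLES * scale_mm
    if transmission(spectrum, table, t_max) > target:
        raise ValueError(
            f"transmission target {target:g} not bracketed within {t_max:g} mm"
        )
    return brentq(
        lambda t: transmission(spectrum, table, t) - target,
        0.0,
        t_max,
        rtol=_ROOT_RTOL,
    )


def hvl_from_spectrum(
    spectrum: Spectrum,
    table: AttenuationTable,
    which: Literal["first", "second"] = "first",
) -> float:
    """First or second HVL (mm) of a spectrum in the table's material.

    The first HVL is the thickness at which transmission reaches 1/2;
    the second is the additional thickness from 1/2 to 1/4.  Both are
    located by bracketed root finding on the exact transmission curve.
    """
    t_half = _solve_thickness(spectrum, table, 0.5)
    if which == "first":
        return t_half
    if which == "second":
        t_quarter = _solve_thickness(spectrum, table, 0.25)
        return t_quarter - t_half
    raise ValueError(f"which must be 'first' or 'second', got {which!r}")


def homogeneity_factor(hvl1_mm: float, hvl2_mm: float) -> float:
    """Homogeneity factor HF = HVL1/HVL2; 1 for a monoenergetic beam."""
    if hvl1_mm <= 0 or hvl2_mm <= 0:
        raise ValueError("HVLs must be positive")
    return hvl1_mm / hvl2_mm


def effective_energy(hvl_mm: float, table: AttenuationTable) -> float:
    """Energy (keV) of the monoenergetic beam with first HVL ``hvl_mm``.

    Solved monotonically on the table's energy range; HVL(E) increases
    with E because mu/rho falls with energy over the kilovoltage range.
    """
    e_lo, e_hi = table.energies_kev[0], table.energies_kev[-1]

    def resid(e: float) -> float:
        return hvl_monoenergetic(float(table.mu_over_rho_at(e)), table.density) - hvl_mm

    r_lo, r_hi = resid(e_lo), resid(e_hi)
    if r_lo * r_hi > 0:
        lo_mm = hvl_monoenergetic(float(table.mu_over_rho_at(e_lo)), table.density)
        hi_mm = hvl_monoenergetic(float(table.mu_over_rho_at(e_hi)), table.density)
        raise ValueError(
            f"HVL {hvl_mm:g} mm outside achievable range "
            f"[{lo_mm:.3g}, {hi_mm:.3g}] mm for {table.material}"
        )
    return brentq(resid, e_lo, e_hi, rtol=_ROOT_RTOL)


def interpolate_vs_hvl(
    points: Sequence[tuple[float, float]] | Iterable[tuple[float, float]],
    query_hvl: float,
) -> float:
    """Piecewise-linear interpolation of a quantity tabulated against HVL.

    Used for chamber N_K coefficients and water-to-air mass
    energy-absorption ratios.  Extrapolation is refused.
    """
    pts = sorted((float(h), float(v)) for h, v in points)
    if len(pts) < 2:
        raise ValueError("need at least 2 points to interpolate")
    hvls = np.array([p[0] for p in pts])
    vals = np.array([p[1] for p in pts])
    if np.any(np.diff(hvls) <= 0):
        raise ValueError("HVL abscissae must be distinct")
    if not (hvls[0] <= query_hvl <= hvls[-1]):
        raise ValueError(
            f"query HVL {query_hvl:g} mm outside interpolation hull "
            f"[{hvls[0]:g}, {hvls[-1]:g}] mm (no extrapolation)"
        )
    return float(np.interp(query_hvl, hvls, vals))
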