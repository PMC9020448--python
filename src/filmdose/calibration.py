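"""TG-61 dose-to-water and the NetOD -> dose calibration curve.

Delivered dose is computed with the in-air kilovoltage formalism

    D_w = M * N_K * B_w * P_stem * [(mu_en/rho)_air^w]_air,

where M is the corrected chamber reading (nC), N_K the air-kerma
calibration coefficient (cGy/nC), B_w the backscatter factor (unity for
film suspended in air), P_stem the stem correction, and the last factor
the water-to-air mean mass energy-absorption ratio for the beam quality.

The film response is calibrated with a third-order polynomial forced
through the origin,

    Dose(cGy) = a1*netOD + a2*netOD^2 + a3*netOD^3,

fitted by least squares.  The curve is lot-specific: a curve measured
for one film lot does not transfer to another.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .beam_quality import BeamQuality

__all__ = [
    "TG61Inputs",
    "CalibrationCurve",
    "CalibrationDataset",
    "tg61_dose",
    "fit_calibration",
    "dose_from_netod",
    "netod_from_dose",
    "compare_curves",
]

logger = logging.getLogger(__name__)

# Water-to-air mean mass energy-absorption ratio interpolated for
# HVL 9.0 mm Al (the 60 keV equivalent beam).
MU_EN_RATIO_HVL9_MMAL = 1.0535

_INVERSION_XTOL = 1e-10


@dataclass(frozen=True)
class TG61Inputs:
    """Inputs to the in-air kilovoltage dose equation.

    ``m_reading`` must already be corrected for temperature, pressure,
    ion recombination and electrometer accuracy.  ``b_w`` defaults to 1
    (film suspended in air: no phantom backscatter); ``p_stem`` defaults
    to 1 (measurement field equals calibration field).
    """

    m_reading: float  # nC
    n_k: float  # cGy/nC
    mu_en_ratio: float = MU_EN_RATIO_HVL9_MMAL
    b_w: float = 1.0
    p_stem: float = 1.0

    def __post_init__(self) -> None:
        if self.m_reading < 0:
            raise ValueError("chamber reading must be non-negative")
        if min(self.n_k, self.mu_en_ratio, self.b_w, self.p_stem) <= 0:
            raise ValueError("all TG-61 factors must be positive")


@dataclass
class CalibrationCurve:
    """Origin-constrained cubic mapping NetOD to dose (cGy).

    ``valid_net_od`` is the NetOD interval on which the fit is trusted;
    evaluation outside it raises in strict mode because cubic
    extrapolation is unphysical.  ``lot`` identifies the film lot the
    curve was measured for.
    """

    label: str
    a1: float
    a2: float
    a3: float
    hvl_mm: float | None = None
    lot: str = ""
    valid_net_od: tuple[float, float] = (0.0, 0.65)

    def __post_init__(self) -> None:
        lo, hi = self.valid_net_od
        if not (0 <= lo < hi):
            raise ValueError("valid_net_od must satisfy 0 <= low < high")

    def dose(self, net_od: float | np.ndarray) -> float | np.ndarray:
        x = np.asarray(net_od, dtype=float)
        out = self.a1 * x + self.a2 * x**2 + self.a3 * x**3
        return float(out) if out.ndim == 0 else out

    def derivative(self, net_od: float) -> float:
        """dDose/dNetOD at ``net_od`` (cGy per unit NetOD)."""
        x = float(net_od)
        return self.a1 + 2 * self.a2 * x + 3 * self.a3 * x**2

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "label": self.label,
                    "hvl_mm": self.hvl_mm,
                    "lot": self.lot,
                    "a1": self.a1,
                    "a2": self.a2,
                    "a3": self.a3,
                    "valid_net_od": list(self.valid_net_od),
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationCurve":
        d = json.loads(Path(path).read_text())
        return cls(
            label=d["label"],
            a1=d["a1"],
            a2=d["a2"],
            a3=d["a3"],
            hvl_mm=d.get("hvl_mm"),
            lot=d.get("lot", ""),
            valid_net_od=tuple(d["valid_net_od"]),
        )


@dataclass
class CalibrationDataset:
    """Measured (NetOD, dose) pairs for one beam quality."""

    net_od: np.ndarray
    dose_cgy: np.ndarray
    sd_net_od: np.ndarray | None = None
    sd_dose_cgy: np.ndarray | None = None
    beam: BeamQuality | None = None
    lot: str = ""

    def __post_init__(self) -> None:
        x = np.asarray(self.net_od, dtype=float)
        d = np.asarray(self.dose_cgy, dtype=float)
        if x.size != d.size or x.size < 4:
            raise ValueError("need >=4 (net_od, dose) points to identify 3 coefficients")
        if np.any(d < 0):
            raise ValueError("doses must be non-negative")
        self.net_od, self.dose_cgy = x, d

    @classmethod
    def from_csv(cls, path: str | Path, **kw) -> "CalibrationDataset":
        df = pd.read_csv(path)
        return cls(
            net_od=df["net_od"].to_numpy(float),
            dose_cgy=df["dose_cgy"].to_numpy(float),
            sd_net_od=df["sd_net_od"].to_numpy(float) if "sd_net_od" in df else None,
            sd_dose_cgy=df["sd_dose_cgy"].to_numpy(float) if "sd_dose_cgy" in df else None,
            **kw,
        )

    def to_csv(self, path: str | Path) -> None:
        n = self.net_od.size
        pd.DataFrame(
            {
                "net_od": self.net_od,
                "sd_net_od": self.sd_net_od if self.sd_net_od is not None else np.zeros(n),
                "dose_cgy": self.dose_cgy,
                "sd_dose_cgy": self.sd_dose_cgy if self.sd_dose_cgy is not None else np.zeros(n),
            }
        ).to_csv(path, index=False)


def tg61_dose(inputs: TG61Inputs) -> float:
    """Absorbed dose to water in air (cGy): M * N_K * B_w * P_stem * mu_en_ratio."""
    return (
        inputs.m_reading
        * inputs.n_k
        * inputs.b_w
        * inputs.p_stem
        * inputs.mu_en_ratio
    )


def fit_calibration(
    dataset: CalibrationDataset,
    label: str = "",
    weighted: bool = False,
    valid_margin: float = 1.05,
) -> CalibrationCurve:
    """Least-squares fit of the origin-constrained cubic to a calibration set.

    The design matrix has columns (x, x^2, x^3) and no intercept, so the
    curve passes through the origin by construction.  ``weighted`` uses
    1/sd_dose^2 weights for sensitivity checks; the default is the plain
    unweighted fit.  The validity range is [0, max fitted NetOD * 1.05].
    """
    x = dataset.net_od
    y = dataset.dose_cgy
    if np.ptp(x) == 0:
        raise ValueError("all NetOD values identical: rank-deficient design")
    X = np.column_stack([x, x**2, x**3])
    if weighted:
        if dataset.sd_dose_cgy is None or np.any(dataset.sd_dose_cgy <= 0):
            raise ValueError("weighted fit requires positive sd_dose_cgy for every point")
        w = 1.0 / dataset.sd_dose_cgy
        X = X * w[:, None]
        y = y * w
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < 3:
        raise ValueError("rank-deficient design: NetOD values do not span a cubic")
    beam = dataset.beam
    return CalibrationCurve(
        label=label or (beam.label if beam else ""),
        a1=float(coef[0]),
        a2=float(coef[1]),
        a3=float(coef[2]),
        hvl_mm=beam.hvl1_mm if beam else None,
        lot=dataset.lot,
        valid_net_od=(0.0, float(x.max() * valid_margin)),
    )


def dose_from_netod(
    curve: CalibrationCurve, net_od: float, strict: bool = True
) -> float:
    """Evaluate the calibration cubic at ``net_od``.

    Outside ``curve.valid_net_od`` this raises in strict mode and logs a
    warning otherwise.
    """
    lo, hi = curve.valid_net_od
    if not (lo <= net_od <= hi):
        msg = (
            f"NetOD {net_od:g} outside calibration range [{lo:g}, {hi:g}] "
            f"of curve {curve.label!r}"
        )
        if strict:
            raise ValueError(msg)
        logger.warning(msg)
    return float(curve.dose(net_od))


def netod_from_dose(curve: CalibrationCurve, dose_cgy: float) -> float:
    """Invert the calibration cubic on its monotone valid branch.

    Bisection-based bracketing root find to 1e-10 absolute tolerance in
    NetOD.  Doses outside the image of the valid range are refused.
    """
    lo, hi = curve.valid_net_od
    d_lo, d_hi = float(curve.dose(lo)), float(curve.dose(hi))
    if not (d_lo <= dose_cgy <= d_hi):
        raise ValueError(
            f"dose {dose_cgy:g} cGy outside attainable range "
            f"[{d_lo:g}, {d_hi:g}] cGy of curve {curve.label!r}"
        )
    if dose_cgy == d_lo:
        return lo
    if dose_cgy == d_hi:
        return hi
    return brentq(lambda x: float(curve.dose(x)) - dose_cgy, lo, hi, xtol=_INVERSION_XTOL)


def compare_curves(
    c1: CalibrationCurve,
    c2: CalibrationCurve,
    dose_range_cgy: tuple[float, float],
    n_grid: int = 201,
) -> float:
    """Maximum relative dose difference between two curves at equal NetOD.

    The dose range is mapped through ``c1`` to a NetOD grid; both curves
    are evaluated there and the maximum of |D1 - D2| / mean(D1, D2) is
    returned.  Used to quantify energy dependence of the film response.
    """
    lo_d, hi_d = dose_range_cgy
    if lo_d >= hi_d:
        raise ValueError("dose range must be increasing")
    x_lo = netod_from_dose(c1, lo_d)
    x_hi = netod_from_dose(c1, hi_d)
    lo2, hi2 = c2.valid_net_od
    if x_hi < lo2 or x_lo > hi2:
        raise ValueError("curves have disjoint NetOD validity ranges over this dose range")
    xs = np.linspace(max(x_lo, lo2), min(x_hi, hi2), n_grid)
    d1 = np.asarray(c1.dose(xs))
    d2 = np.asarray(c2.dose(xs))
    mean = 0.5 * (d1 + d2)
    if np.any(mean <= 0):
        xs = xs[mean > 0]
        d1, d2, mean = d1[mean > 0], d2[mean > 0], mean[mean > 0]
    return float(np.max(np.abs(d1 - d2) / mean))
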