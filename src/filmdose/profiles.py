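"""Beam-characterisation quantities from dose maps and depth series.

Covers the measurements used to characterise a focused narrow beam:

* tissue-maximum ratio (TMR): dose (or dose rate) at each depth divided
  by the maximum over the series,
* central-axis profiles extracted from 2-D film dose maps,
* focal-spot size as the full width at half maximum (FWHM) of a
  profile, with linear interpolation at the half-max crossings,
* heterogeneity ratios: focal-spot dose rate with a bone-equivalent
  insert in the stack divided by the rate without it.

No smoothing or resampling is applied before TMR; measurement noise can
make the raw series non-monotonic, and the analysis reports it as read.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DoseMap",
    "DepthSeries",
    "HeterogeneityPair",
    "tmr",
    "central_axis_profile",
    "fwhm",
    "heterogeneity_ratio",
    "fit_tmr_polynomial",
]


@dataclass
class DoseMap:
    """A 2-D film-measured dose (or dose-rate) map.

    ``doses`` is indexed (row, col); for a vertical film the row axis is
    depth (longitudinal) and the column axis lateral, for a horizontal
    film both axes are lateral.  ``origin`` is the (row, col) pixel of
    the beam axis; ``pixel_pitch_cm`` the physical pixel spacing.
    """

    doses: np.ndarray
    pixel_pitch_cm: float
    origin: tuple[int, int]
    axes_labels: tuple[str, str] = ("longitudinal", "lateral")
    rate_mode: bool = False  # True when values are cGy/min rather than cGy

    def __post_init__(self) -> None:
        d = np.asarray(self.doses, dtype=float)
        if d.ndim != 2 or d.size == 0:
            raise ValueError("doses must be a non-empty 2-D grid")
        if np.any(d < 0):
            raise ValueError("doses must be non-negative")
        if self.pixel_pitch_cm <= 0:
            raise ValueError("pixel pitch must be positive")
        self.doses = d

    def to_csv(self, csv_path: str | Path, sidecar_path: str | Path | None = None) -> None:
        np.savetxt(csv_path, self.doses, delimiter=",")
        sidecar = Path(sidecar_path) if sidecar_path else Path(csv_path).with_suffix(".json")
        sidecar.write_text(
            json.dumps(
                {
                    "pixel_pitch_cm": self.pixel_pitch_cm,
                    "origin": list(self.origin),
                    "axes_labels": list(self.axes_labels),
                    "rate_mode": self.rate_mode,
                }
            )
        )

    @classmethod
    def from_csv(cls, csv_path: str | Path, sidecar_path: str | Path | None = None) -> "DoseMap":
        sidecar = Path(sidecar_path) if sidecar_path else Path(csv_path).with_suffix(".json")
        meta = json.loads(sidecar.read_text())
        return cls(
            doses=np.loadtxt(csv_path, delimiter=",", ndmin=2),
            pixel_pitch_cm=float(meta["pixel_pitch_cm"]),
            origin=tuple(meta["origin"]),
            axes_labels=tuple(meta.get("axes_labels", ("longitudinal", "lateral"))),
            rate_mode=bool(meta.get("rate_mode", False)),
        )


@dataclass
class DepthSeries:
    """On-axis focal-spot dose rate versus depth in water."""

    depths_cm: np.ndarray
    values: np.ndarray  # cGy/min (or cGy in integrated mode)

    def __post_init__(self) -> None:
        d = np.asarray(self.depths_cm, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if d.size == 0 or d.size != v.size:
            raise ValueError("depths and values must match and be non-empty")
        if d.size > 1 and np.any(np.diff(d) <= 0):
            raise ValueError("depths must be strictly increasing")
        if np.any(v < 0):
            raise ValueError("dose values must be non-negative")
        self.depths_cm, self.values = d, v

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"depth_cm": self.depths_cm, "value": self.values}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "DepthSeries":
        df = pd.read_csv(path)
        return cls(df["depth_cm"].to_numpy(float), df["value"].to_numpy(float))


@dataclass(frozen=True)
class HeterogeneityPair:
    """Focal-spot dose rates measured with and without a heterogeneity insert."""

    with_insert: float
    without_insert: float
    geometry_tag: str = "upstream-attenuation"  # or "interface-backscatter"

    def __post_init__(self) -> None:
        if self.with_insert <= 0 or self.without_insert <= 0:
            raise ValueError("dose rates must be positive")


def tmr(series: DepthSeries) -> list[tuple[float, float]]:
    """Tissue-maximum ratio: each value divided by the series maximum.

    The maximum maps to exactly 1.  An all-zero series has no maximum
    and is refused.
    """
    vmax = series.values.max()
    if vmax <= 0:
        raise ValueError("all-zero depth series: TMR undefined")
    ratios = series.values / vmax
    return list(zip(series.depths_cm.tolist(), ratios.tolist()))


def central_axis_profile(dose_map: DoseMap, half_width_px: int = 0) -> np.ndarray:
    """Longitudinal profile through the beam axis of a vertical-film dose map.

    Extracts the column through ``origin``; with ``half_width_px`` > 0 the
    profile is the lateral average over ±half_width_px columns.
    """
    rows, cols = dose_map.doses.shape
    _, c0 = dose_map.origin
    if not (0 <= c0 < cols):
        raise ValueError(f"origin column {c0} outside grid with {cols} columns")
    lo = max(0, c0 - half_width_px)
    hi = min(cols, c0 + half_width_px + 1)
    return dose_map.doses[:, lo:hi].mean(axis=1)


def fwhm(profile: Sequence[float], pitch_cm: float) -> float:
    """Full width at half maximum of a peaked 1-D profile, in cm.

    The half-max crossings on each side of the peak are located by
    linear interpolation between the bracketing samples.  Profiles that
    do not fall below half maximum on both sides have no FWHM.
    """
    p = np.asarray(profile, dtype=float)
    if pitch_cm <= 0:
        raise ValueError("pitch must be positive")
    if p.size < 3:
        raise ValueError("profile too short for a width measurement")
    i_max = int(np.argmax(p))
    half = p[i_max] / 2.0

    def crossing(idx_from: int, step: int) -> float:
        i = i_max
        while 0 <= i + step < p.size:
            j = i + step
            if p[j] <= half:
                # linear interpolation between i (above) and j (at/below)
                frac = (p[i] - half) / (p[i] - p[j])
                return i + step * frac
            i = j
        raise ValueError("profile does not fall below half maximum on both sides")

    left = crossing(i_max, -1)
    right = crossing(i_max, +1)
    return float((right - left) * pitch_cm)


def heterogeneity_ratio(pair: HeterogeneityPair) -> float:
    """Dose-rate ratio with insert / without insert.

    < 1 for upstream attenuation by a denser slab; > 1 for backscatter
    enhancement at an interface just downstream of the film.
    """
    if pair.without_insert == 0:
        raise ValueError("zero reference dose rate")
    return pair.with_insert / pair.without_insert


def fit_tmr_polynomial(
    series: DepthSeries, order: int = 2
) -> tuple[np.ndarray, np.ndarray]:
    """Polynomial fit to the TMR curve; returns (coefficients, standard errors).

    Coefficients are in increasing-power order.  The fit is a
    convenience for summarising the depth trend; TMR itself is always
    reported unsmoothed.
    """
    pts = tmr(series)
    d = np.array([p[0] for p in pts])
    r = np.array([p[1] for p in pts])
    if d.size <= order + 1:
        raise ValueError("not enough depths for the requested polynomial order")
    coef, cov = np.polyfit(d, r, order, cov=True)
    return coef[::-1], np.sqrt(np.diag(cov))[::-1]
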