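"""Quadrature uncertainty budgets for film dosimetry.

Components are relative uncertainties in percent, each with a coverage
factor k (k = 2 corresponds to ~95% confidence for a normal quantity).
Combination rescales every component to a common coverage factor and
adds in quadrature; combining values already expanded at k = 2 directly
is identical to combining at k = 1 and then expanding, and the explicit
normalisation keeps both routes equal.

Typical optical-density budget: film non-uniformity 1.6%, scanner-bed
non-uniformity 0.8%, scanner drift 0.1% (all k = 2) -> 1.8% (k = 2).
Typical delivered-dose budget: standards-lab chain 1.50%, electrometer
0.13%, setup 0.5%, beam-output reproducibility 0.4% -> 1.64% (k = 2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .calibration import CalibrationCurve

__all__ = [
    "UncertaintyComponent",
    "UncertaintyBudget",
    "quadrature_combine",
    "film_homogeneity",
    "dose_uncertainty",
]


@dataclass(frozen=True)
class UncertaintyComponent:
    """One named relative-uncertainty component (percent at coverage factor k)."""

    name: str
    value_percent: float
    k: float = 2.0

    def __post_init__(self) -> None:
        if self.value_percent < 0:
            raise ValueError("uncertainty value must be non-negative")
        if self.k <= 0:
            raise ValueError("coverage factor must be positive")

    def rescaled(self, target_k: float) -> float:
        """Value in percent re-expressed at ``target_k``."""
        return self.value_percent * target_k / self.k


@dataclass
class UncertaintyBudget:
    """A list of components with their quadrature combination at a stated k."""

    components: list[UncertaintyComponent]
    k: float = 2.0

    @property
    def combined_percent(self) -> float:
        return quadrature_combine(self.components, self.k)

    def to_csv(self, path: str | Path) -> None:
        rows = [(c.name, c.value_percent, c.k) for c in self.components]
        rows.append(("TOTAL", self.combined_percent, self.k))
        pd.DataFrame(rows, columns=["name", "value_percent", "k"]).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, k: float = 2.0) -> "UncertaintyBudget":
        df = pd.read_csv(path)
        df = df[df["name"] != "TOTAL"]
        comps = [
            UncertaintyComponent(str(r.name), float(r.value_percent), float(r.k))
            for r in df.itertuples()
        ]
        return cls(components=comps, k=k)


def quadrature_combine(
    components: Sequence[UncertaintyComponent], target_k: float = 2.0
) -> float:
    """Root-sum-square of components, each rescaled to ``target_k``.

    Returns the combined relative uncertainty in percent at ``target_k``.
    No rounding is applied; round only for presentation.
    """
    if not components:
        raise ValueError("cannot combine an empty component list")
    return math.sqrt(sum(c.rescaled(target_k) ** 2 for c in components))


def film_homogeneity(od_values: Sequence[float], target_k: float = 2.0) -> float:
    """Expanded relative OD spread (percent) across equally-exposed film pieces.

    The pieces are a sample of the sheet, so the sample (n-1) standard
    deviation is used: result = target_k * SD/mean * 100.
    """
    vals = np.asarray(od_values, dtype=float)
    if vals.size < 2:
        raise ValueError("need at least 2 pieces")
    mean = vals.mean()
    if mean == 0:
        raise ValueError("zero mean OD: relative spread undefined")
    return float(target_k * vals.std(ddof=1) / abs(mean) * 100.0)


def dose_uncertainty(
    curve: CalibrationCurve,
    net_od: float,
    sd_net_od: float,
    dose_budget_percent_k2: float = 0.0,
) -> float:
    """Relative k=2 uncertainty (percent) of a film-measured dose.

    Propagates the NetOD standard deviation through the calibration
    slope, expands by k = 2, and combines in quadrature with the
    delivered-dose budget (already at k = 2):

        u_OD% = |dD/dx| * sd_net_od * 2 / D * 100.

    Because the cubic's relative slope falls with NetOD, a fixed
    absolute OD noise produces larger relative dose uncertainty at low
    dose — dose readings near background are the least certain.
    """
    if sd_net_od < 0 or dose_budget_percent_k2 < 0:
        raise ValueError("uncertainties must be non-negative")
    d = float(curve.dose(net_od))
    if d == 0:
        raise ValueError("relative uncertainty undefined at zero dose")
    od_part = abs(curve.derivative(net_od)) * sd_net_od * 2.0 / d * 100.0
    return math.sqrt(od_part**2 + dose_budget_percent_k2**2)
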