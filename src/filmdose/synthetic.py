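"""Synthetic film scans, calibration sets, dose maps and heterogeneity scenarios.

Every input the measurement pipeline needs can be generated here with
known ground truth, so all stages are testable without physical films.

The scanner/film forward model inverts the readout chain: a target dose
is mapped through the truth calibration curve to a NetOD, perturbed by
the film and scanner non-uniformity terms, and converted to a
post-exposure red-channel intensity

    I_post = I_opq + (I_unexposed - I_opq) * 10**(-NetOD),

with per-pixel white noise added on top.  Noise decomposes into a
per-piece scalar film factor, a smooth low-frequency scanner-bed field
(2-D cosine with random phase), a per-scan drift gain, and white pixel
noise; the scalar magnitudes default to a typical measured budget
(film 1.6%, bed 0.8%, drift 0.1%, all expanded at k = 2).

The beam model is a parametric analytic surrogate — a Gaussian focal
spot with stated FWHMs, exponential attenuation in water and a conical
convergence factor — not a physics simulation.  Its role is to exercise
the pipeline against closed-form truth.  ``surface_dose_rate`` is the
on-axis focal-spot amplitude extrapolated to zero water depth, so the
focal dose rate with the spot at depth d is surface_dose_rate*exp(-mu*d).

All randomness flows through named substreams of a single seed, so
adding a new generator never perturbs existing outputs and identical
(seed, label) pairs reproduce bit-for-bit.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .calibration import CalibrationCurve, netod_from_dose
from .profiles import DepthSeries, DoseMap, HeterogeneityPair
from .scan_processing import FilmPiece, ScanImage, save_scan

__all__ = [
    "RngSpec",
    "ScannerModel",
    "FilmModel",
    "BeamModel",
    "default_truth_curve",
    "generate_calibration_set",
    "generate_beam_dosemap",
    "generate_depth_series",
    "generate_heterogeneity_pair",
    "render_film_scan",
    "generate_opaque_scan",
]

FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # 2.3548
_LN2x4 = 4.0 * np.log(2.0)


@dataclass(frozen=True)
class RngSpec:
    """Deterministic named random substreams derived from one integer seed."""

    seed: int
    stream_label: str = ""

    def stream(self, label: str = "") -> np.random.Generator:
        full = f"{self.stream_label}/{label}" if label else self.stream_label
        key = zlib.crc32(full.encode("utf-8"))
        return np.random.default_rng(np.random.SeedSequence(entropy=self.seed, spawn_key=(key,)))

    def child(self, label: str) -> "RngSpec":
        full = f"{self.stream_label}/{label}" if self.stream_label else label
        return RngSpec(seed=self.seed, stream_label=full)


@dataclass(frozen=True)
class ScannerModel:
    """Flatbed transmission scanner: geometry, dynamic range and noise terms.

    Percent noise terms are expanded relative uncertainties at k = 2 and
    perturb NetOD multiplicatively; ``pixel_noise_sd`` is additive white
    noise in raw counts on every pixel of every scan.
    """

    bit_depth: int = 16
    dpi: float = 72.0
    i_unexposed: float = 40000.0
    i_opq: float = 1000.0
    pixel_noise_sd: float = 80.0
    bed_nonuniformity_pct_k2: float = 0.8
    drift_pct_k2: float = 0.1

    def __post_init__(self) -> None:
        if not (0 <= self.i_opq < self.i_unexposed < 2**self.bit_depth):
            raise ValueError("require 0 <= i_opq < i_unexposed < 2**bit_depth")
        if min(self.pixel_noise_sd, self.bed_nonuniformity_pct_k2, self.drift_pct_k2) < 0:
            raise ValueError("noise terms must be non-negative")

    def quiet(self) -> "ScannerModel":
        """A noise-free copy (exact round trips)."""
        return replace(self, pixel_noise_sd=0.0, bed_nonuniformity_pct_k2=0.0, drift_pct_k2=0.0)


@dataclass(frozen=True)
class FilmModel:
    """Film response: the truth calibration curve plus uniformity terms (% k=2)."""

    truth_curve: CalibrationCurve
    film_nonuniformity_pct_k2: float = 1.6
    piece_to_piece_pct_k2: float = 0.0

    def __post_init__(self) -> None:
        if min(self.film_nonuniformity_pct_k2, self.piece_to_piece_pct_k2) < 0:
            raise ValueError("percent terms must be non-negative")

    def quiet(self) -> "FilmModel":
        return replace(self, film_nonuniformity_pct_k2=0.0, piece_to_piece_pct_k2=0.0)


def default_truth_curve() -> CalibrationCurve:
    """The 60 keV-equivalent (HVL 9.0 mm Al) cubic used as generator truth."""
    return CalibrationCurve(
        label="180 kVp",
        a1=897.6,
        a2=-123.5,
        a3=4639.0,
        hvl_mm=9.0,
        lot="synthetic",
        valid_net_od=(0.0, 0.65),
    )


@dataclass(frozen=True)
class BeamModel:
    """Analytic converging-beam surrogate.

    A Gaussian focal spot (FWHMs in mm) sits at ``focal_depth_cm`` in
    water; the lateral width grows away from focus with the cone
    half-angle, and the on-axis amplitude follows the inverse-area
    convergence factor times exponential attenuation exp(-mu*depth).
    ``attenuation_mu_cm`` defaults to water at 60 keV; the default
    surface amplitude puts ~30 cGy/min at 5 cm depth.
    """

    focal_depth_cm: float = 5.0
    focal_fwhm_lateral_mm: float = 3.0
    focal_fwhm_longitudinal_mm: float = 3.0
    surface_dose_rate: float = 84.0  # cGy/min on axis at zero water depth
    attenuation_mu_cm: float = 0.206  # 1/cm, water at 60 keV
    cone_half_angle_deg: float = 30.0

    def __post_init__(self) -> None:
        vals = (
            self.focal_depth_cm,
            self.focal_fwhm_lateral_mm,
            self.focal_fwhm_longitudinal_mm,
            self.surface_dose_rate,
            self.attenuation_mu_cm,
            self.cone_half_angle_deg,
        )
        if min(vals) <= 0:
            raise ValueError("all beam parameters must be positive")

    def lateral_fwhm_cm(self, z_cm: float | np.ndarray) -> np.ndarray:
        """Lateral FWHM (cm) of the converging cone at depth z."""
        w0 = self.focal_fwhm_lateral_mm / 10.0
        spread = 2.0 * np.tan(np.radians(self.cone_half_angle_deg))
        return w0 + spread * np.abs(np.asarray(z_cm, float) - self.focal_depth_cm)

    def dose_rate(self, z_cm, x_cm):
        """Closed-form dose rate (cGy/min) at depth z, lateral offset x."""
        z = np.asarray(z_cm, dtype=float)
        x = np.asarray(x_cm, dtype=float)
        w = self.lateral_fwhm_cm(z)
        w0 = self.focal_fwhm_lateral_mm / 10.0
        f_long = self.focal_fwhm_longitudinal_mm / 10.0
        cone = (w0 / w) ** 2
        gauss_lat = np.exp(-_LN2x4 * (x / w) ** 2)
        gauss_long = np.exp(-_LN2x4 * ((z - self.focal_depth_cm) / f_long) ** 2)
        out = (
            self.surface_dose_rate
            * np.exp(-self.attenuation_mu_cm * np.maximum(z, 0.0))
            * cone
            * gauss_lat
            * gauss_long
        )
        return float(out) if out.ndim == 0 else out

    def focal_dose_rate(self, depth_cm: float) -> float:
        """On-axis focal-spot dose rate with the spot at ``depth_cm`` of water."""
        return self.surface_dose_rate * float(np.exp(-self.attenuation_mu_cm * depth_cm))


def _bed_field(shape: tuple[int, int], sd_rel: float, rng: np.random.Generator) -> np.ndarray:
    """Smooth multiplicative scanner-bed field with spatial relative SD ``sd_rel``.

    A product of two low-frequency cosines with random phases; the
    product of two unit cosines has variance 1/4, so the amplitude is
    2*sd_rel.
    """
    if sd_rel == 0:
        return np.zeros(shape)
    rows, cols = shape
    fr, fc = rng.uniform(0.5, 1.5, size=2)  # cycles per image side
    pr, pc = rng.uniform(0, 2 * np.pi, size=2)
    r = np.arange(rows)[:, None] / max(rows - 1, 1)
    c = np.arange(cols)[None, :] / max(cols - 1, 1)
    return 2.0 * sd_rel * np.cos(2 * np.pi * fr * r + pr) * np.cos(2 * np.pi * fc * c + pc)


def _rgb_from_red(red: np.ndarray, scanner: ScannerModel) -> np.ndarray:
    """Stack RGB planes; green/blue are fixed scaled copies of red.

    The scaling makes a channel-selection bug produce visibly wrong
    NetOD values instead of silently matching the red channel.
    """
    vmax = 2**scanner.bit_depth - 1
    red = np.clip(red, 0.0, vmax)
    green = np.clip(0.8 * red, 0.0, vmax)
    blue = np.clip(0.6 * red, 0.0, vmax)
    return np.stack([red, green, blue], axis=2)


def _render_scan(
    netod_map: np.ndarray,
    scanner: ScannerModel,
    rng: np.random.Generator,
    role: str,
    drift_gain: float = 1.0,
    quantize: bool = False,
) -> ScanImage:
    """One scan from a per-pixel NetOD map (all-zero map = pre-exposure scan)."""
    span = scanner.i_unexposed - scanner.i_opq
    red = scanner.i_opq + drift_gain * span * 10.0 ** (-netod_map)
    if scanner.pixel_noise_sd > 0:
        red = red + rng.normal(0.0, scanner.pixel_noise_sd, size=red.shape)
    vmax = 2**scanner.bit_depth - 1
    red = np.clip(red, 0.0, vmax)
    if quantize:
        red = np.rint(red)
    return ScanImage(
        pixels=_rgb_from_red(red, scanner),
        dpi=scanner.dpi,
        bit_depth=scanner.bit_depth,
        acquisition_role=role,
    )


def generate_opaque_scan(
    scanner: ScannerModel, shape: tuple[int, int], rng: RngSpec, quantize: bool = False
) -> ScanImage:
    """Blank scan with the bed covered: reads the stray-light level I_opq."""
    g = rng.stream("opaque")
    red = np.full(shape, scanner.i_opq, dtype=float)
    if scanner.pixel_noise_sd > 0:
        red = red + g.normal(0.0, scanner.pixel_noise_sd, size=shape)
    red = np.clip(red, 0.0, 2**scanner.bit_depth - 1)
    if quantize:
        red = np.rint(red)
    return ScanImage(
        pixels=_rgb_from_red(red, scanner),
        dpi=scanner.dpi,
        bit_depth=scanner.bit_depth,
        acquisition_role="opaque",
    )


def render_film_scan(
    dose_map: DoseMap,
    film: FilmModel,
    scanner: ScannerModel,
    rng: RngSpec,
    n_scans: int = 1,
    quantize: bool = False,
) -> tuple[list[ScanImage], list[ScanImage]]:
    """Render a dose map to (pre-scans, post-scans) through the truth curve.

    Per-pixel NetOD is the truth-curve inversion of the dose, perturbed
    by the film factor and bed field; intensities follow the scanner
    forward model.  With all noise terms zero the post scan is an exact
    function of the dose map (pre equals the unexposed level).
    """
    doses = dose_map.doses
    flat = np.unique(doses)
    lut = {d: netod_from_dose(film.truth_curve, float(d)) for d in flat}
    netod_true = np.vectorize(lut.get)(doses).astype(float)

    g_piece = rng.stream("piece")
    film_sd = film.film_nonuniformity_pct_k2 / 200.0
    p2p_sd = film.piece_to_piece_pct_k2 / 200.0
    scalar = 0.0
    if film_sd > 0:
        scalar += g_piece.normal(0.0, film_sd)
    if p2p_sd > 0:
        scalar += g_piece.normal(0.0, p2p_sd)
    bed = _bed_field(doses.shape, scanner.bed_nonuniformity_pct_k2 / 200.0, rng.stream("bed"))
    netod_px = netod_true * (1.0 + scalar + bed)
    if np.any(netod_px < 0):
        netod_px = np.clip(netod_px, 0.0, None)

    drift_sd = scanner.drift_pct_k2 / 200.0
    pre, post = [], []
    zeros = np.zeros_like(netod_px)
    for i in range(n_scans):
        pre.append(_render_scan(zeros, scanner, rng.stream(f"pre{i}"), "pre", 1.0, quantize))
        gain = 1.0
        if drift_sd > 0:
            gain = 1.0 + rng.stream(f"drift{i}").normal(0.0, drift_sd)
        post.append(
            _render_scan(netod_px, scanner, rng.stream(f"post{i}"), "post", gain, quantize)
        )
    # guard against saturation: post net signal must stay positive
    for s in post:
        if np.any(s.pixels[:, :, 0] >= 2**scanner.bit_depth - 0.5) and quantize:
            raise OverflowError("rendered intensity saturates the scanner bit depth")
    return pre, post


def generate_calibration_set(
    film: FilmModel,
    scanner: ScannerModel,
    doses_cgy: Sequence[float],
    replicates: int = 2,
    rng: RngSpec | None = None,
    n_scans: int = 3,
    piece_px: int = 64,
    out_dir: str | Path | None = None,
    quantize: bool = False,
) -> tuple[list[FilmPiece], float, dict]:
    """Render a full calibration exposure series.

    For each (dose level, replicate) a film piece is rendered with
    ``n_scans`` repeat pre- and post-exposure scans of ``piece_px``
    square pixels.  Returns (pieces, i_opq, manifest); the manifest maps
    piece ids to ground-truth dose and NetOD.  With ``out_dir`` set the
    scans are also written as TIFFs named
    ``<pieceID>_<pre|post|opq>_<scan#>.tif`` plus ``manifest.json``.
    """
    rng = rng or RngSpec(seed=0)
    lo_d = float(film.truth_curve.dose(film.truth_curve.valid_net_od[0]))
    hi_d = float(film.truth_curve.dose(film.truth_curve.valid_net_od[1]))
    for d in doses_cgy:
        if not (lo_d <= d <= hi_d):
            raise ValueError(f"dose {d:g} cGy outside truth-curve range [{lo_d:g}, {hi_d:g}]")

    pieces: list[FilmPiece] = []
    manifest: dict = {"pieces": {}, "i_opq": scanner.i_opq, "dpi": scanner.dpi}
    shape = (piece_px, piece_px)
    for d in doses_cgy:
        for r in range(1, replicates + 1):
            pid = f"D{d:07.1f}_r{r}"
            sub = rng.child(pid)
            dm = DoseMap(
                doses=np.full(shape, float(d)),
                pixel_pitch_cm=2.54 / scanner.dpi,
                origin=(piece_px // 2, piece_px // 2),
            )
            pre, post = render_film_scan(dm, film, scanner, sub, n_scans, quantize)
            pieces.append(
                FilmPiece(
                    piece_id=pid,
                    pre=pre,
                    post=post,
                    delivered_dose_cgy=float(d),
                    scan_delay_hours=24.0,
                )
            )
            manifest["pieces"][pid] = {
                "dose_cgy": float(d),
                "net_od_true": netod_from_dose(film.truth_curve, float(d)),
            }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        opq = generate_opaque_scan(scanner, shape, rng.child("opq"), quantize=True)
        save_scan(opq, out / "blank_opq_1.tif")
        for p in pieces:
            for i, s in enumerate(p.pre, start=1):
                save_scan(_quantized(s), out / f"{p.piece_id}_pre_{i}.tif")
            for i, s in enumerate(p.post, start=1):
                save_scan(_quantized(s), out / f"{p.piece_id}_post_{i}.tif")
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return pieces, scanner.i_opq, manifest


def _quantized(scan: ScanImage) -> ScanImage:
    return ScanImage(
        pixels=np.rint(scan.pixels).astype(np.uint16),
        dpi=scan.dpi,
        bit_depth=scan.bit_depth,
        acquisition_role=scan.acquisition_role,
    )


def generate_beam_dosemap(
    beam: BeamModel,
    film_plane: str = "vertical",
    plane_position_cm: float = 0.0,
    extent_cm: float = 2.0,
    pitch_cm: float = 0.01,
) -> DoseMap:
    """Deterministic analytic dose map on a film plane.

    ``vertical`` planes contain the beam axis and return a
    (depth x lateral) map spanning [0, extent] in depth; ``horizontal``
    planes are perpendicular to the axis at ``plane_position_cm`` depth
    and return a (lateral x lateral) map centred on the axis.
    """
    if extent_cm <= 0 or pitch_cm <= 0:
        raise ValueError("extent and pitch must be positive")
    n = int(round(extent_cm / pitch_cm)) + 1
    if n < 8:
        raise ValueError("degenerate extent: fewer than 8 pixels across the map")
    w_f = beam.focal_fwhm_lateral_mm / 10.0
    if w_f / pitch_cm < 8:
        raise ValueError("pitch too coarse: need >=8 pixels per focal FWHM")
    if film_plane == "vertical":
        z = np.linspace(0.0, extent_cm, n)
        half = extent_cm / 2.0
        x = np.linspace(-half, half, n)
        zz, xx = np.meshgrid(z, x, indexing="ij")
        doses = beam.dose_rate(zz, xx)
        origin = (int(np.argmin(np.abs(z - beam.focal_depth_cm))), int(np.argmin(np.abs(x))))
        return DoseMap(
            doses=doses,
            pixel_pitch_cm=pitch_cm,
            origin=origin,
            axes_labels=("longitudinal", "lateral"),
            rate_mode=True,
        )
    if film_plane == "horizontal":
        half = extent_cm / 2.0
        x = np.linspace(-half, half, n)
        xx, yy = np.meshgrid(x, x, indexing="ij")
        r = np.hypot(xx, yy)
        doses = beam.dose_rate(np.full_like(r, plane_position_cm), r)
        c = int(np.argmin(np.abs(x)))
        return DoseMap(
            doses=doses,
            pixel_pitch_cm=pitch_cm,
            origin=(c, c),
            axes_labels=("lateral", "lateral"),
            rate_mode=True,
        )
    raise ValueError(f"film_plane must be 'vertical' or 'horizontal', got {film_plane!r}")


def generate_depth_series(beam: BeamModel, depths_cm: Sequence[float]) -> DepthSeries:
    """On-axis focal-spot dose rate with the spot placed at each depth.

    The phantom is moved longitudinally so the water path to the focus
    equals each requested depth; the series is surface_dose_rate *
    exp(-mu * d), whose TMR is the normalised exponential.
    """
    d = np.asarray(depths_cm, dtype=float)
    if np.any(d < 0):
        raise ValueError("depths must be non-negative")
    return DepthSeries(depths_cm=d, values=np.array([beam.focal_dose_rate(x) for x in d]))


def generate_heterogeneity_pair(
    beam: BeamModel,
    insert_attenuation_factor: float = 0.87,
    interface_enhancement: float = 1.2,
    geometry_tag: str = "upstream-attenuation",
    reference_depth_cm: float = 5.0,
) -> HeterogeneityPair:
    """Focal-spot dose-rate pair with/without a bone-equivalent insert.

    ``upstream-attenuation``: the insert sits upstream of the focus and
    scales the rate by ``insert_attenuation_factor``.
    ``interface-backscatter``: the insert sits just downstream of the
    film and scales the rate by ``interface_enhancement``.
    """
    if insert_attenuation_factor <= 0 or interface_enhancement <= 0:
        raise ValueError("factors must be positive")
    without = beam.focal_dose_rate(reference_depth_cm)
    if geometry_tag == "upstream-attenuation":
        with_insert = without * insert_attenuation_factor
    elif geometry_tag == "interface-backscatter":
        with_insert = without * interface_enhancement
    else:
        raise ValueError(f"unknown geometry tag {geometry_tag!r}")
    return HeterogeneityPair(
        with_insert=with_insert, without_insert=without, geometry_tag=geometry_tag
    )
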