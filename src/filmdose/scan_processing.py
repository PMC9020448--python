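"""Film-scan readout: ROI statistics and net optical density.

A film piece is scanned on a flatbed transmission scanner before and
after exposure (48-bit RGB TIFF, 16 bits per channel).  Only the red
channel carries the dosimetric signal.  The transmitted-light intensity
is the mean red-channel pixel value over a small centred region of
interest (ROI), and the net optical density is

    NetOD = log10( (I_pre - I_opq) / (I_post - I_opq) ),

where I_opq is the stray-light reading taken with the scanner bed
covered.  Repeat scans are pooled; the ROI standard deviation
propagates into the NetOD uncertainty by first-order Taylor expansion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile

__all__ = [
    "ScanImage",
    "ROIStats",
    "FilmPiece",
    "NetODResult",
    "red_channel",
    "center_roi",
    "roi_stats",
    "average_scans",
    "net_od",
    "measure_piece",
    "load_scan",
    "save_scan",
]

CM_PER_INCH = 2.54


@dataclass
class ScanImage:
    """One scanner acquisition: an RGB intensity raster plus geometry metadata.

    ``pixels`` has shape (rows, cols, 3) with integer counts in
    [0, 2**bit_depth - 1].  ``acquisition_role`` records whether the scan
    is a pre-exposure, post-exposure or opaque (blank) acquisition.
    """

    pixels: np.ndarray
    dpi: float
    bit_depth: int = 16
    acquisition_role: str = "pre"  # pre | post | opaque

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError("pixels must be (rows, cols, 3)")
        if px.shape[0] == 0 or px.shape[1] == 0:
            raise ValueError("image grid must be non-empty")
        if self.dpi <= 0:
            raise ValueError("dpi must be positive")
        if self.acquisition_role not in ("pre", "post", "opaque"):
            raise ValueError(f"unknown acquisition_role {self.acquisition_role!r}")
        vmax = 2**self.bit_depth - 1
        if px.min() < 0 or px.max() > vmax:
            raise ValueError(f"intensities must lie in [0, {vmax}]")
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass(frozen=True)
class ROIStats:
    """Mean/SD of transmitted intensity over a pixel window."""

    mean_intensity: float
    sd_intensity: float
    n_pixels: int
    window: tuple[slice, slice]

    def __post_init__(self) -> None:
        if self.sd_intensity < 0:
            raise ValueError("sd must be non-negative")


@dataclass
class FilmPiece:
    """A physical film piece with its pre- and post-exposure scans.

    ``orientation_tag`` records the grain-orientation marker; it must
    agree across all scans of the piece (polarisation effects make
    rotated rescans incomparable).  ``scan_delay_hours`` is the
    exposure-to-readout delay, validated against a window around the
    24 h self-development wait when provided.
    """

    piece_id: str
    pre: list[ScanImage] = field(default_factory=list)
    post: list[ScanImage] = field(default_factory=list)
    orientation_tag: str = "bottom-right"
    delivered_dose_cgy: float | None = None
    scan_delay_hours: float | None = None

    def validate(self, delay_window_hours: tuple[float, float] = (22.0, 26.0)) -> None:
        if not self.pre or not self.post:
            raise ValueError(f"piece {self.piece_id}: need >=1 pre and >=1 post scan")
        ref = self.pre[0]
        for s in self.pre + self.post:
            if s.shape != ref.shape or s.dpi != ref.dpi or s.bit_depth != ref.bit_depth:
                raise ValueError(f"piece {self.piece_id}: scan geometry mismatch")
        if self.scan_delay_hours is not None:
            lo, hi = delay_window_hours
            if not (lo <= self.scan_delay_hours <= hi):
                raise ValueError(
                    f"piece {self.piece_id}: scan delay {self.scan_delay_hours:g} h "
                    f"outside [{lo:g}, {hi:g}] h readout window"
                )


@dataclass(frozen=True)
class NetODResult:
    """Net optical density with its propagated standard deviation."""

    net_od: float
    sd_net_od: float
    i_pre: float
    i_post: float
    i_opq: float

    def __post_init__(self) -> None:
        if self.i_pre - self.i_opq <= 0 or self.i_post - self.i_opq <= 0:
            raise ValueError("net signals must be positive")
        if self.sd_net_od < 0:
            raise ValueError("sd must be non-negative")


def red_channel(image: ScanImage) -> np.ndarray:
    """The red plane of an RGB scan, unchanged (no rescaling)."""
    if image.pixels.ndim != 3 or image.pixels.shape[2] != 3:
        raise ValueError("expected a 3-channel RGB image")
    return image.pixels[:, :, 0]


def center_roi(
    image_shape: tuple[int, int], dpi: float, side_cm: float = 0.5
) -> tuple[slice, slice]:
    """Centred square ROI window of physical side ``side_cm``.

    The side in pixels is round(side_cm / 2.54 * dpi).  The window is
    centred; when the leftover margin is odd the extra pixel goes to the
    high-index side (window biased to the low index).
    """
    n = round(side_cm / CM_PER_INCH * dpi)
    if n < 1:
        raise ValueError("ROI side rounds to zero pixels")
    rows, cols = image_shape
    if n > rows or n > cols:
        raise ValueError(f"{n}-pixel ROI does not fit inside {rows}x{cols} image")
    r0 = (rows - n) // 2
    c0 = (cols - n) // 2
    return slice(r0, r0 + n), slice(c0, c0 + n)


def roi_stats(grid: np.ndarray, window: tuple[slice, slice]) -> ROIStats:
    """Arithmetic mean and population SD of a 2-D intensity grid over a window."""
    patch = np.asarray(grid, dtype=float)[window]
    if patch.size == 0:
        raise ValueError("empty ROI window")
    return ROIStats(
        mean_intensity=float(patch.mean()),
        sd_intensity=float(patch.std(ddof=0)),
        n_pixels=int(patch.size),
        window=window,
    )


def average_scans(
    scans: Sequence[ScanImage], window: tuple[slice, slice]
) -> tuple[float, float]:
    """Pool repeat scans: mean of per-scan ROI means, SD from total variance.

    The returned SD combines the mean within-scan variance with the
    population variance of the per-scan means, which for equal-size
    windows equals the population SD over all pixels pooled together.
    """
    if not scans:
        raise ValueError("need at least one scan")
    ref = scans[0]
    for s in scans[1:]:
        if s.shape != ref.shape or s.dpi != ref.dpi or s.bit_depth != ref.bit_depth:
            raise ValueError("scan geometry mismatch")
    stats = [roi_stats(red_channel(s), window) for s in scans]
    means = np.array([st.mean_intensity for st in stats])
    within_var = np.mean([st.sd_intensity**2 for st in stats])
    between_var = means.var(ddof=0)
    return float(means.mean()), float(math.sqrt(within_var + between_var))


def net_od(
    i_pre: float,
    i_post: float,
    i_opq: float = 0.0,
    sd_pre: float = 0.0,
    sd_post: float = 0.0,
    sd_opq: float = 0.0,
) -> NetODResult:
    """Net optical density from pre/post/opaque intensities.

    NetOD = log10((I_pre - I_opq)/(I_post - I_opq)); the SD is the
    first-order propagation of the three input SDs.
    """
    num = i_pre - i_opq
    den = i_post - i_opq
    if num <= 0 or den <= 0:
        raise ValueError(
            "non-positive net signal: film saturated or darker than the opaque reading"
        )
    value = math.log10(num / den)
    ln10 = math.log(10.0)
    d_pre = 1.0 / (ln10 * num)
    d_post = -1.0 / (ln10 * den)
    d_opq = (1.0 / den - 1.0 / num) / ln10
    sd = math.sqrt((d_pre * sd_pre) ** 2 + (d_post * sd_post) ** 2 + (d_opq * sd_opq) ** 2)
    return NetODResult(net_od=value, sd_net_od=sd, i_pre=i_pre, i_post=i_post, i_opq=i_opq)


def measure_piece(
    piece: FilmPiece,
    i_opq: float = 0.0,
    roi_side_cm: float = 0.5,
    sd_opq: float = 0.0,
    delay_window_hours: tuple[float, float] | None = None,
) -> NetODResult:
    """Full readout of one film piece: red channel -> centred ROI -> pooled scans -> NetOD."""
    piece.validate(delay_window_hours) if delay_window_hours is not None else piece.validate()
    window = center_roi(piece.pre[0].shape, piece.pre[0].dpi, roi_side_cm)
    i_pre, sd_pre = average_scans(piece.pre, window)
    i_post, sd_post = average_scans(piece.post, window)
    return net_od(i_pre, i_post, i_opq, sd_pre, sd_post, sd_opq)


def save_scan(image: ScanImage, path: str | Path) -> None:
    """Write an RGB scan as an uncompressed 16-bit-per-channel TIFF."""
    arr = image.pixels.astype(np.uint16)
    tifffile.imwrite(
        str(path),
        arr,
        photometric="rgb",
        resolution=(image.dpi, image.dpi),
        compression=None,
    )


def load_scan(path: str | Path, acquisition_role: str = "pre", dpi: float | None = None) -> ScanImage:
    """Read a 16-bit RGB TIFF scan; dpi from the file's resolution tags unless given."""
    with tifffile.TiffFile(str(path)) as tf:
        page = tf.pages[0]
        arr = page.asarray()
        if dpi is None:
            res = page.tags.get("XResolution")
            if res is not None:
                num, den = res.value
                dpi = num / den
            else:
                raise ValueError(f"{path}: no resolution tag; pass dpi explicitly")
    return ScanImage(pixels=arr, dpi=float(dpi), bit_depth=16, acquisition_role=acquisition_role)
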