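"""ROI placement and CNR/FOM measurement on phantom images.

The phantom carries a 15 x 15 mm, 0.2-mm-thick aluminum square; image
quality is summarized by CNR = |MPV_Al - MPV_PMMA| / SD_PMMA, with the
signal mean taken in a guarded square inside the insert and the background
mean/SD in a rectangular frame around it, and by the figure of merit
FOM = CNR^2 / MGD (per-projection MGD for DBT, where the CNR comes from the
0-degree projection only).

Image convention: row 0 is the chest-wall edge, columns are lateral with the
detector centred; geometry is specified in mm and converted to half-open
pixel intervals via the (effective) pixel pitch, rounding toward the ROI
interior so a nominal ROI never spills outside its mm bounds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .design import PhantomSpec

__all__ = [
    "RoiConfig",
    "RoiGeometry",
    "ROIStats",
    "IQResult",
    "place_rois",
    "measure_rois",
    "compute_cnr",
    "compute_fom",
    "measure_iq",
]


@dataclass(frozen=True)
class RoiConfig:
    """ROI dimensioning (mm). Defaults: 10-mm signal square inside the 15-mm
    insert (2.5-mm guard against edge blur), background frame starting 2.5 mm
    outside the insert and 5 mm wide."""

    inner_side_mm: float = 10.0
    band_gap_mm: float = 2.5
    band_width_mm: float = 5.0
    pooled_sd: bool = False  # pool insert + background pixels for the noise term


@dataclass(frozen=True)
class RoiGeometry:
    """Pixel-space ROI geometry: half-open [start, stop) index intervals."""

    inner_rows: tuple[int, int]
    inner_cols: tuple[int, int]
    band_outer_rows: tuple[int, int]
    band_outer_cols: tuple[int, int]
    band_hole_rows: tuple[int, int]
    band_hole_cols: tuple[int, int]
    pixel_pitch_um: float
    pooled_sd: bool = False


def _interior_interval(center_px: float, half_px: float, n: int) -> tuple[int, int]:
    start = math.ceil(center_px - half_px)
    stop = math.floor(center_px + half_px)
    if not (0 <= start < stop <= n):
        raise ValueError(
            f"ROI interval [{start}, {stop}) outside image axis of length {n}"
        )
    return start, stop


def _exterior_interval(center_px: float, half_px: float, n: int) -> tuple[int, int]:
    start = math.floor(center_px - half_px)
    stop = math.ceil(center_px + half_px)
    if not (0 <= start < stop <= n):
        raise ValueError(
            f"ROI interval [{start}, {stop}) outside image axis of length {n}"
        )
    return start, stop


def place_rois(
    image: np.ndarray,
    phantom: PhantomSpec,
    pixel_pitch_um: float,
    config: RoiConfig | None = None,
) -> RoiGeometry:
    """Place the signal and background ROIs around the configured insert.

    The insert centre comes from ``phantom.insert_offset_mm`` (depth from the
    chest-wall edge, lateral offset from the detector midline).
    """
    config = config or RoiConfig()
    if image.ndim != 2:
        raise ValueError("expected a 2-D image")
    n_rows, n_cols = image.shape
    pitch_mm = pixel_pitch_um / 1000.0
    depth_mm, lateral_mm = phantom.insert_offset_mm
    # pixel i spans [i, i+1) * pitch; mm coordinate -> fractional pixel index
    center_row = depth_mm / pitch_mm
    center_col = n_cols / 2.0 + lateral_mm / pitch_mm

    inner_half = config.inner_side_mm / 2.0 / pitch_mm
    hole_half = (phantom.insert_side_mm / 2.0 + config.band_gap_mm) / pitch_mm
    outer_half = hole_half + config.band_width_mm / pitch_mm

    inner_rows = _interior_interval(center_row, inner_half, n_rows)
    inner_cols = _interior_interval(center_col, inner_half, n_cols)
    # the hole grows outward so the band never touches the insert footprint
    hole_rows = _exterior_interval(center_row, hole_half, n_rows)
    hole_cols = _exterior_interval(center_col, hole_half, n_cols)
    outer_rows = _interior_interval(center_row, outer_half, n_rows)
    outer_cols = _interior_interval(center_col, outer_half, n_cols)
    return RoiGeometry(
        inner_rows=inner_rows,
        inner_cols=inner_cols,
        band_outer_rows=outer_rows,
        band_outer_cols=outer_cols,
        band_hole_rows=hole_rows,
        band_hole_cols=hole_cols,
        pixel_pitch_um=pixel_pitch_um,
        pooled_sd=config.pooled_sd,
    )


@dataclass(frozen=True)
class ROIStats:
    mpv_al: float
    mpv_pmma: float
    sd_pmma: float
    n_pixels_inner: int
    n_pixels_band: int


def measure_rois(image: np.ndarray, geom: RoiGeometry) -> ROIStats:
    """MPV over the insert ROI; MPV and sample SD (ddof=1) over the band."""
    img = np.asarray(image, dtype=np.float64)
    r0, r1 = geom.inner_rows
    c0, c1 = geom.inner_cols
    inner = img[r0:r1, c0:c1]
    R0, R1 = geom.band_outer_rows
    C0, C1 = geom.band_outer_cols
    h0, h1 = geom.band_hole_rows
    g0, g1 = geom.band_hole_cols
    outer = img[R0:R1, C0:C1]
    mask = np.ones(outer.shape, dtype=bool)
    mask[h0 - R0:h1 - R0, g0 - C0:g1 - C0] = False
    band = outer[mask]
    if inner.size <= 1 or band.size <= 1:
        raise ValueError("degenerate ROI: need more than one pixel per region")
    noise_pixels = np.concatenate([band, inner.ravel()]) if geom.pooled_sd else band
    return ROIStats(
        mpv_al=float(inner.mean()),
        mpv_pmma=float(band.mean()),
        sd_pmma=float(noise_pixels.std(ddof=1)),
        n_pixels_inner=int(inner.size),
        n_pixels_band=int(band.size),
    )


def compute_cnr(stats: ROIStats) -> float:
    """CNR = |MPV_Al - MPV_PMMA| / SD_PMMA (orientation-free)."""
    if stats.sd_pmma == 0:
        raise ValueError("SD_PMMA is zero: CNR undefined")
    return abs(stats.mpv_al - stats.mpv_pmma) / stats.sd_pmma


def compute_fom(cnr: float, mgd_basis_mgy: float) -> float:
    """FOM = CNR^2 / MGD; for DBT the basis is MGD per projection and the
    CNR that of the 0-degree projection."""
    if mgd_basis_mgy <= 0:
        raise ValueError("MGD basis must be positive")
    if cnr < 0:
        raise ValueError("CNR must be non-negative")
    return cnr * cnr / mgd_basis_mgy


@dataclass(frozen=True)
class IQResult:
    stats: ROIStats
    cnr: float
    fom: float
    source_sub_kind: str
    mgd_basis: str  # "full" for DM/CEM, "per-projection" for DBT


def measure_iq(
    image: np.ndarray,
    phantom: PhantomSpec,
    pixel_pitch_um: float,
    mgd_basis_mgy: float,
    sub_kind: str = "DM",
    config: RoiConfig | None = None,
) -> IQResult:
    """End-to-end ROI placement, CNR and FOM for one image."""
    geom = place_rois(image, phantom, pixel_pitch_um, config=config)
    stats = measure_rois(image, geom)
    cnr = compute_cnr(stats)
    return IQResult(
        stats=stats,
        cnr=cnr,
        fom=compute_fom(cnr, mgd_basis_mgy),
        source_sub_kind=sub_kind,
        mgd_basis="per-projection" if sub_kind == "DBT_PROJECTION" else "full",
    )
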