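"""Sliding-window tumor-stroma ratio quantification engine.

The tumor region of a slide is processed systematically with a circular
region of interest (ROI, 1-mm diameter by default, mimicking a microscope
viewing field) slid on a regular grid with 70% overlap between neighbouring
positions. Each candidate ROI passes two eligibility tests before it is
scored:

(i)  composition: background must stay below 10% of the disc, necrotic
     debris below 20%, and mucin below 30% (strict inequalities; artifact-
     excluded pixels count toward background);
(ii) four-quadrant test: tumor epithelium must be present in all four
     axis-aligned quadrants of the disc, so that the ROI genuinely samples
     the tumor rather than its margin.

For every eligible ROI the TSR is computed as

    TSR = area_stroma / (area_stroma + area_tumor)

over tumor stroma and tumor epithelium pixels only; all other tumor-
associated tissue classes are excluded from the formula. The slide-level
score is the *hotspot*: the maximum TSR over all eligible ROIs, i.e. the
region with the highest stroma content. A slide with no eligible ROI is
reported as non-assessable.

Geometry conventions: coordinates are 0-based pixels with x = column and
y = row; pixel centers sit at integer coordinates; a pixel belongs to a disc
when its center lies strictly within ``diameter_px / 2`` of the ROI center.
Physical parameters are converted to pixels via the mask's micron-per-pixel
resolution and rounded to the nearest integer (floor 1); the categorical
mask itself is never resampled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .mask_io import ROLES, ArtifactMask, LabelMask, apply_artifact_exclusion

__all__ = [
    "RoiParams",
    "RoiRecord",
    "SlideResult",
    "TsrUndefinedError",
    "diameter_px_for",
    "stride_px_for",
    "tumor_analysis_region",
    "roi_grid",
    "roi_composition",
    "composition_eligibility",
    "quadrant_test",
    "compute_tsr",
    "quantify_slide",
    "classify_tsr",
    "STROMA_LOW",
    "STROMA_HIGH",
]

STROMA_LOW = "stroma_low"
STROMA_HIGH = "stroma_high"

_BG = ROLES.index("background")
_TUM = ROLES.index("tumor_epithelium")
_STR = ROLES.index("tumor_stroma")
_NEC = ROLES.index("necrosis")
_MUC = ROLES.index("mucin")
_EXC = ROLES.index("excluded")


class TsrUndefinedError(ValueError):
    """TSR requested for a region with no tumor epithelium and no stroma."""


@dataclass(frozen=True)
class RoiParams:
    """Parameters of the ROI engine.

    diameter_um : physical ROI diameter in microns (default 1000 = 1 mm).
    overlap_fraction : fractional overlap between neighbouring window
        positions, in [0, 1); 0.70 means the stride is 30% of the diameter.
    max_background_fraction / max_necrosis_fraction / max_mucin_fraction :
        strict upper bounds on the allowed disc content of background
        (including artifact-excluded pixels), necrotic debris, and mucin.
    min_tumor_pixels_per_quadrant : minimum tumor-epithelium pixels required
        in each of the four disc quadrants.
    """

    diameter_um: float = 1000.0
    overlap_fraction: float = 0.70
    max_background_fraction: float = 0.10
    max_necrosis_fraction: float = 0.20
    max_mucin_fraction: float = 0.30
    min_tumor_pixels_per_quadrant: int = 1

    def __post_init__(self) -> None:
        if not self.diameter_um > 0:
            raise ValueError("diameter_um must be positive")
        if not (0 <= self.overlap_fraction < 1):
            raise ValueError("overlap_fraction must be in [0, 1)")
        for name in ("max_background_fraction", "max_necrosis_fraction", "max_mucin_fraction"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must be in (0, 1]")
        if self.min_tumor_pixels_per_quadrant < 1:
            raise ValueError("min_tumor_pixels_per_quadrant must be >= 1")

    def to_dict(self) -> dict:
        return {
            "diameter_um": self.diameter_um,
            "overlap_fraction": self.overlap_fraction,
            "max_background_fraction": self.max_background_fraction,
            "max_necrosis_fraction": self.max_necrosis_fraction,
            "max_mucin_fraction": self.max_mucin_fraction,
            "min_tumor_pixels_per_quadrant": self.min_tumor_pixels_per_quadrant,
        }


def diameter_px_for(params: RoiParams, mpp: float) -> int:
    """ROI diameter in pixels: nearest integer, floor 1."""
    return max(1, int(round(params.diameter_um / mpp)))


def stride_px_for(params: RoiParams, mpp: float) -> int:
    """Grid stride in pixels: round((1 - overlap) * diameter_px), floor 1."""
    d = diameter_px_for(params, mpp)
    return max(1, int(round((1.0 - params.overlap_fraction) * d)))


@dataclass
class RoiRecord:
    """One candidate analysis disc with composition, verdicts, and TSR."""

    center: tuple[int, int]  # (x, y) pixels
    diameter_px: int
    composition: dict[str, float]
    composition_pass: bool
    quadrant_pass: bool
    tsr: float | None  # defined iff composition_pass and quadrant_pass

    @property
    def eligible(self) -> bool:
        return self.composition_pass and self.quadrant_pass


@dataclass
class SlideResult:
    """Slide-level outcome of the hotspot TSR quantification."""

    slide_id: str
    params: RoiParams
    assessable: bool
    tsr_percent: float | None
    class_label: str | None
    chosen_roi: RoiRecord | None
    n_candidates: int
    n_eligible: int


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------


def _disc_stencil(diameter_px: int) -> tuple[np.ndarray, np.ndarray, int]:
    """Boolean disc stencil, per-pixel quadrant ids, and half-width.

    The stencil covers the square window ``[c - half, c + half]`` in both
    axes; ``half = ceil(d/2) - 1`` is the largest pixel offset strictly
    inside the disc radius. Quadrants split at the center lines; pixels on a
    line go to the right/lower quadrant.
    """
    r = diameter_px / 2.0
    half = math.ceil(r) - 1
    offs = np.arange(-half, half + 1)
    dx = offs[np.newaxis, :]
    dy = offs[:, np.newaxis]
    stencil = (dx * dx + dy * dy) < r * r
    quad = np.zeros((2 * half + 1, 2 * half + 1), dtype=np.int64)
    quad += (dx >= 0).astype(np.int64)  # right half +1
    quad += 2 * (dy >= 0).astype(np.int64)  # lower half +2
    return stencil, quad, half


def tumor_analysis_region(
    mask: LabelMask, params: RoiParams
) -> tuple[int, int, int, int] | None:
    """Bounding box of tumor epithelium, dilated by one ROI radius.

    Returns ``(x0, y0, x1, y1)`` inclusive pixel bounds clipped to the mask
    extent, or ``None`` when the mask contains no tumor epithelium.
    """
    tumor_code = mask.classmap.roles["tumor_epithelium"]
    ys, xs = np.nonzero(mask.data == tumor_code)
    if xs.size == 0:
        return None
    r = diameter_px_for(params, mask.mpp) / 2.0
    x0 = max(0, int(math.floor(xs.min() - r)))
    y0 = max(0, int(math.floor(ys.min() - r)))
    x1 = min(mask.width - 1, int(math.ceil(xs.max() + r)))
    y1 = min(mask.height - 1, int(math.ceil(ys.max() + r)))
    return (x0, y0, x1, y1)


def _axis_centers(start: int, stop: int, extent: int, radius: float, half: int, stride: int) -> list[int]:
    lo = half  # smallest center with the whole disc in bounds
    hi = extent - 1 - half
    c0 = max(int(math.ceil(start + radius)), lo)
    out = []
    c = c0
    while c <= min(stop, hi):
        out.append(c)
        c += stride
    return out


def roi_grid(
    region: tuple[int, int, int, int],
    params: RoiParams,
    mask_extent: tuple[int, int],
    mpp: float = 1.0,
) -> list[tuple[int, int]]:
    """Candidate ROI centers on the sliding-window grid, row-major order.

    Centers step by ``stride_px`` starting from the smallest admissible
    position at least one radius into the region; only centers whose full
    disc lies inside the mask extent are kept. ``mask_extent`` is
    ``(height, width)``.
    """
    x0, y0, x1, y1 = region
    height, width = mask_extent
    d = diameter_px_for(params, mpp)
    stride = stride_px_for(params, mpp)
    r = d / 2.0
    half = math.ceil(r) - 1
    xs = _axis_centers(x0, x1, width, r, half, stride)
    ys = _axis_centers(y0, y1, height, r, half, stride)
    return [(x, y) for y in ys for x in xs]


def roi_composition(
    mask: LabelMask, center: tuple[int, int], diameter_px: int
) -> dict[str, float]:
    """Fraction of disc area per class role; fractions sum to 1.

    The disc must lie fully inside the mask.
    """
    stencil, _, half = _disc_stencil(diameter_px)
    cx, cy = center
    if cx - half < 0 or cy - half < 0 or cx + half >= mask.width or cy + half >= mask.height:
        raise ValueError(f"ROI disc at {center} extends outside the mask")
    table = mask.classmap.role_lookup()
    window = table[mask.data[cy - half : cy + half + 1, cx - half : cx + half + 1]]
    vals = window[stencil]
    counts = np.bincount(vals, minlength=len(ROLES))
    total = vals.size
    return {role: counts[i] / total for i, role in enumerate(ROLES)}


def composition_eligibility(composition: dict[str, float], params: RoiParams) -> bool:
    """Strict content thresholds; artifact-excluded pixels count as background."""
    background_effective = composition["background"] + composition["excluded"]
    return (
        background_effective < params.max_background_fraction
        and composition["necrosis"] < params.max_necrosis_fraction
        and composition["mucin"] < params.max_mucin_fraction
    )


def quadrant_test(
    mask: LabelMask, center: tuple[int, int], diameter_px: int, params: RoiParams
) -> bool:
    """True iff every disc quadrant holds enough tumor-epithelium pixels."""
    stencil, quad, half = _disc_stencil(diameter_px)
    cx, cy = center
    if cx - half < 0 or cy - half < 0 or cx + half >= mask.width or cy + half >= mask.height:
        raise ValueError(f"ROI disc at {center} extends outside the mask")
    tumor_code = mask.classmap.roles["tumor_epithelium"]
    window = mask.data[cy - half : cy + half + 1, cx - half : cx + half + 1]
    tumor = (window == tumor_code) & stencil
    qcounts = np.bincount(quad[tumor], minlength=4)
    return bool((qcounts >= params.min_tumor_pixels_per_quadrant).all())


def compute_tsr(composition: dict[str, float]) -> float:
    """TSR = stroma / (stroma + tumor), ignoring all other tissue classes."""
    stroma = composition["tumor_stroma"]
    tumor = composition["tumor_epithelium"]
    denom = stroma + tumor
    if denom <= 0:
        raise TsrUndefinedError("no tumor epithelium or stroma in region")
    return stroma / denom


def classify_tsr(tsr_percent: float, cutoff_percent: float = 77.0) -> str:
    """Stroma-high iff TSR% strictly exceeds the cut-off; equal is stroma-low."""
    if not (0.0 <= tsr_percent <= 100.0):
        raise ValueError(f"tsr_percent must be in [0, 100], got {tsr_percent}")
    return STROMA_HIGH if tsr_percent > cutoff_percent else STROMA_LOW


# ---------------------------------------------------------------------------
# Slide-level pipeline
# ---------------------------------------------------------------------------


def quantify_slide(
    mask: LabelMask,
    artifacts: ArtifactMask | None = None,
    params: RoiParams | None = None,
    *,
    cutoff_percent: float = 77.0,
) -> tuple[SlideResult, list[RoiRecord]]:
    """Run the full hotspot TSR pipeline on one slide.

    Steps: artifact exclusion, tumor analysis region, sliding-window grid,
    per-ROI composition / eligibility / TSR, then hotspot selection (maximum
    TSR over eligible ROIs; ties break to the first ROI in row-major scan
    order). A slide with no eligible ROI is returned non-assessable.
    """
    params = params or RoiParams()
    if artifacts is not None:
        mask = apply_artifact_exclusion(mask, artifacts)

    d = diameter_px_for(params, mask.mpp)
    region = tumor_analysis_region(mask, params)
    centers = (
        [] if region is None else roi_grid(region, params, (mask.height, mask.width), mask.mpp)
    )

    stencil, quad, half = _disc_stencil(d)
    flat_stencil = stencil.ravel()
    quad_flat = quad.ravel()[flat_stencil]
    table = mask.classmap.role_lookup()
    role_img = table[mask.data]
    disc_area = int(flat_stencil.sum())
    min_q = params.min_tumor_pixels_per_quadrant

    records: list[RoiRecord] = []
    best: RoiRecord | None = None
    n_eligible = 0
    for cx, cy in centers:
        window = role_img[cy - half : cy + half + 1, cx - half : cx + half + 1]
        vals = window.ravel()[flat_stencil]
        counts = np.bincount(vals, minlength=len(ROLES))
        composition = {role: counts[i] / disc_area for i, role in enumerate(ROLES)}
        comp_ok = composition_eligibility(composition, params)
        qcounts = np.bincount(quad_flat[vals == _TUM], minlength=4)
        quad_ok = bool((qcounts >= min_q).all())
        tsr = None
        if comp_ok and quad_ok:
            # integer pixel counts keep the division exact w.r.t. any
            # count-based reference; equals compute_tsr(composition)
            denom = int(counts[_STR]) + int(counts[_TUM])
            if denom <= 0:
                raise TsrUndefinedError("no tumor epithelium or stroma in region")
            tsr = int(counts[_STR]) / denom
            n_eligible += 1
        rec = RoiRecord(
            center=(cx, cy),
            diameter_px=d,
            composition=composition,
            composition_pass=comp_ok,
            quadrant_pass=quad_ok,
            tsr=tsr,
        )
        records.append(rec)
        if tsr is not None and (best is None or tsr > best.tsr):
            best = rec

    assessable = n_eligible >= 1
    tsr_percent = best.tsr * 100.0 if assessable else None
    result = SlideResult(
        slide_id=mask.slide_id,
        params=params,
        assessable=assessable,
        tsr_percent=tsr_percent,
        class_label=classify_tsr(tsr_percent, cutoff_percent) if assessable else None,
        chosen_roi=best,
        n_candidates=len(records),
        n_eligible=n_eligible,
    )
    return result, records
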