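"""Synthetic label masks and survival cohorts with known ground truth.

The mask generator emulates the structure of a multi-class tissue
segmentation of a colon tumor section: a spatially varying stroma/tumor
mixture (smoothed random field), pockets of necrosis, mucin, and background,
optional artifact overlays, and a planted stroma *hotspot* — a disc whose
stroma:tumor pixel ratio is painted exactly at a target value by
deterministic dithering. Because the background field is capped strictly
below the hotspot target, the hotspot is the unique ground-truth maximum and
the sliding-window engine's recovered TSR can be checked against it.

The cohort generator draws TSR scores from a two-component mixture (about
65% stroma-low / 35% stroma-high around a 77% cut-off, matching typical
automated-TSR cohorts) and event times from an exponential baseline whose
hazard is multiplied by a fixed ratio above the true cut-off — a pure
threshold effect. Overall survival is coupled to disease-free survival by a
positive increment for a configurable fraction of recurrences, so OS events
are a subset-with-delay of DFS events. Administrative plus uniform censoring
is applied. All draws flow from a single seed; the returned ground-truth
record embeds the seed and parameters for provenance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, zoom

from .mask_io import DEFAULT_CLASS_MAP, ArtifactMask, ClassMap, LabelMask

__all__ = [
    "MaskSimParams",
    "CohortSimParams",
    "MaskSimResult",
    "simulate_mask",
    "simulate_cohort",
]


@dataclass(frozen=True)
class MaskSimParams:
    """Parameters of the synthetic label-mask generator.

    The stroma field is smoothed Gaussian noise rescaled into
    ``[field_min, field_max]``; ``field_max`` must stay strictly below the
    hotspot target so the planted hotspot is the unique maximum. Pocket
    counts/sizes control necrosis, mucin, background, and artifact discs
    painted over the field (never overlapping the hotspot).
    """

    width: int = 2000
    height: int = 2000
    mpp: float = 1.0
    field_min: float = 0.25
    field_max: float = 0.65
    field_smoothness_px: float = 250.0
    hotspot_center: tuple[int, int] | None = None  # (x, y); None = random placement
    hotspot_diameter_um: float = 1500.0
    hotspot_target: float = 0.80
    n_necrosis_pockets: int = 2
    n_mucin_pockets: int = 2
    n_background_pockets: int = 2
    n_artifact_pockets: int = 0
    pocket_radius_px: tuple[int, int] = (60, 150)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError("mask dimensions must be >= 1")
        if not self.mpp > 0:
            raise ValueError("mpp must be positive")
        if not (0 <= self.field_min <= self.field_max <= 1):
            raise ValueError("field bounds must satisfy 0 <= min <= max <= 1")
        if not self.field_max < self.hotspot_target <= 1:
            raise ValueError("hotspot target must strictly exceed the field maximum")
        r = self.hotspot_diameter_um / self.mpp / 2.0
        if 2 * r > min(self.width, self.height):
            raise ValueError("hotspot disc does not fit inside the mask")
        if self.hotspot_center is not None:
            cx, cy = self.hotspot_center
            if not (r <= cx <= self.width - 1 - r and r <= cy <= self.height - 1 - r):
                raise ValueError("hotspot disc extends outside the mask")


@dataclass
class MaskSimResult:
    mask: LabelMask
    artifacts: ArtifactMask | None
    truth: dict


def _disc_indices(cx: int, cy: int, radius: float, shape: tuple[int, int]):
    half = math.ceil(radius) - 1
    ys = np.arange(max(0, cy - half), min(shape[0], cy + half + 1))
    xs = np.arange(max(0, cx - half), min(shape[1], cx + half + 1))
    dy = (ys - cy)[:, None]
    dx = (xs - cx)[None, :]
    inside = dx * dx + dy * dy < radius * radius
    yy, xx = np.nonzero(inside)
    return ys[0] + yy, xs[0] + xx


def _dither_pattern(n: int, target: float) -> np.ndarray:
    """Boolean vector of length n with exactly floor(n*target) True values,
    interleaved evenly (error-diffusion along the index)."""
    k = np.arange(n, dtype=np.int64)
    return np.floor((k + 1) * target) > np.floor(k * target)


def simulate_mask(params: MaskSimParams) -> MaskSimResult:
    """Generate a label mask with a planted maximum-stroma hotspot.

    Each pixel is tumor stroma with probability given by the local field
    value, else tumor epithelium; pockets are painted over the field; the
    hotspot disc is painted last with an exact stroma:tumor pixel ratio.
    Returns the mask, the artifact overlay (if requested), and a ground-truth
    record with the hotspot's true TSR and geometry.
    """
    rng = np.random.default_rng(params.seed)
    cmap: ClassMap = DEFAULT_CLASS_MAP
    h, w = params.height, params.width
    shape = (h, w)

    # Smooth stroma-probability field in [field_min, field_max]. Generated on
    # a coarse grid and bilinearly upsampled: equivalent low-pass structure at
    # a fraction of the filtering cost of full-resolution smoothing.
    cell = 16
    coarse = rng.standard_normal((h // cell + 2, w // cell + 2))
    smooth = gaussian_filter(coarse, sigma=params.field_smoothness_px / cell, mode="reflect")
    smooth = zoom(smooth, cell, order=1)[:h, :w]
    lo, hi = smooth.min(), smooth.max()
    span = hi - lo if hi > lo else 1.0
    fld = params.field_min + (smooth - lo) / span * (params.field_max - params.field_min)

    stroma_code = cmap.roles["tumor_stroma"]
    tumor_code = cmap.roles["tumor_epithelium"]
    data = np.where(rng.random(shape) < fld, stroma_code, tumor_code).astype(np.uint8)

    # Hotspot geometry (decided before pockets so pockets can avoid it).
    r_hot = params.hotspot_diameter_um / params.mpp / 2.0
    if params.hotspot_center is None:
        margin = int(math.ceil(r_hot)) + 1
        hx = int(rng.integers(margin, w - margin))
        hy = int(rng.integers(margin, h - margin))
    else:
        hx, hy = params.hotspot_center

    def place_pockets(n: int, code: int | None, target: np.ndarray) -> int:
        placed = 0
        attempts = 0
        while placed < n and attempts < 50 * max(n, 1):
            attempts += 1
            rad_hi = min(params.pocket_radius_px[1], min(w, h) // 2 - 1)
            rad_lo = min(params.pocket_radius_px[0], rad_hi)
            if rad_hi < 1:
                break
            rad = int(rng.integers(rad_lo, rad_hi + 1))
            px = int(rng.integers(rad, w - rad))
            py = int(rng.integers(rad, h - rad))
            if math.hypot(px - hx, py - hy) <= rad + r_hot:
                continue  # keep the hotspot pristine
            yy, xx = _disc_indices(px, py, rad, shape)
            if code is None:
                target[yy, xx] = True
            else:
                target[yy, xx] = code
            placed += 1
        return placed

    place_pockets(params.n_necrosis_pockets, cmap.roles["necrosis"], data)
    place_pockets(params.n_mucin_pockets, cmap.roles["mucin"], data)
    place_pockets(params.n_background_pockets, cmap.roles["background"], data)

    artifacts = None
    if params.n_artifact_pockets > 0:
        art = np.zeros(shape, dtype=bool)
        place_pockets(params.n_artifact_pockets, None, art)
        artifacts = ArtifactMask(data=art)

    # Paint the hotspot with an exact stroma:tumor pixel ratio.
    yy, xx = _disc_indices(hx, hy, r_hot, shape)
    n_disc = yy.size
    pattern = _dither_pattern(n_disc, params.hotspot_target)
    data[yy, xx] = np.where(pattern, stroma_code, tumor_code).astype(np.uint8)
    true_tsr = float(pattern.sum()) / n_disc

    mask = LabelMask(
        data=data,
        mpp=params.mpp,
        slide_id=f"synthetic-{params.seed}",
        classmap=cmap,
    )
    truth = {
        "hotspot_tsr": true_tsr,
        "hotspot_tsr_percent": 100.0 * true_tsr,
        "hotspot_center": (hx, hy),
        "hotspot_diameter_px": 2.0 * r_hot,
        "hotspot_disc_pixels": int(n_disc),
        "seed": params.seed,
        "params": asdict(params),
    }
    return MaskSimResult(mask=mask, artifacts=artifacts, truth=truth)


# ---------------------------------------------------------------------------
# Survival cohorts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortSimParams:
    """Parameters of the synthetic survival-cohort generator.

    TSR scores come from a two-component normal mixture clipped to
    [0, 100]; with the defaults roughly 35% of patients exceed the 77%
    cut-off. The hazard is exponential (``baseline_rate`` per month,
    calibrated to about an 82% 3-year event-free rate below the cut-off) and
    is multiplied by ``hazard_ratio`` for scores above ``true_cutoff``.
    Covariates (age, stage) are always drawn; their hazard effects default
    to zero so the threshold effect is the only systematic signal unless a
    study of confounding switches them on.
    """

    n: int = 1000
    mixture_weights: tuple[float, float] = (0.65, 0.35)
    mixture_means: tuple[float, float] = (62.0, 84.0)
    mixture_sds: tuple[float, float] = (10.0, 6.0)
    true_cutoff: float = 77.0
    hazard_ratio: float = 2.5
    baseline_rate: float = 0.0055  # events per month below the cut-off
    admin_censor_months: float = 60.0
    censoring_fraction: float = 0.30  # fraction given an extra uniform censor time
    death_after_recurrence_fraction: float = 0.55
    os_increment_mean_months: float = 12.0
    age_log_hr_per_decade: float = 0.0
    stage3_log_hr: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if not self.hazard_ratio > 0:
            raise ValueError("hazard_ratio must be positive")
        if not self.baseline_rate > 0:
            raise ValueError("baseline_rate must be positive")
        if not (0 <= self.censoring_fraction <= 1):
            raise ValueError("censoring_fraction must be in [0, 1]")
        if not (0 <= self.death_after_recurrence_fraction <= 1):
            raise ValueError("death_after_recurrence_fraction must be in [0, 1]")


def simulate_cohort(params: CohortSimParams) -> tuple[pd.DataFrame, dict]:
    """Generate a per-patient cohort table with a TSR threshold effect.

    Returns the cohort DataFrame (columns ``id``, ``tsr_percent``,
    ``dfs_months``, ``dfs_event``, ``os_months``, ``os_event``, ``age``,
    ``stage``) and a ground-truth record. ``censoring_fraction = 1.0`` is the
    degenerate everyone-censored-immediately case: zero events, so that
    downstream analyses raise their documented errors.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n

    comp = rng.random(n) < params.mixture_weights[1]
    means = np.where(comp, params.mixture_means[1], params.mixture_means[0])
    sds = np.where(comp, params.mixture_sds[1], params.mixture_sds[0])
    tsr = np.clip(rng.normal(means, sds), 0.0, 100.0)

    age = rng.normal(67.0, 10.0, n)
    stage = rng.choice([2, 3], size=n)

    high = tsr > params.true_cutoff
    log_hr = (
        np.log(params.hazard_ratio) * high
        + params.age_log_hr_per_decade * (age - 67.0) / 10.0
        + params.stage3_log_hr * (stage == 3)
    )
    rate = params.baseline_rate * np.exp(log_hr)
    event_time = rng.exponential(1.0 / rate)

    if params.censoring_fraction >= 1.0:
        censor_time = np.full(n, 1e-9)
    else:
        censor_time = np.full(n, params.admin_censor_months)
        extra = rng.random(n) < params.censoring_fraction
        uniform_censor = rng.uniform(0.0, params.admin_censor_months, n)
        censor_time[extra] = np.minimum(censor_time[extra], uniform_censor[extra])

    dfs_event = (event_time <= censor_time).astype(int)
    dfs_months = np.minimum(event_time, censor_time)

    # OS couples to DFS: a fraction of recurrences is followed by death after
    # a positive exponential increment; everyone else is censored for OS at
    # their DFS follow-up end.
    dies = (dfs_event == 1) & (rng.random(n) < params.death_after_recurrence_fraction)
    os_increment = rng.exponential(params.os_increment_mean_months, n)
    os_months = np.where(dies, dfs_months + os_increment, np.maximum(dfs_months, censor_time))
    os_event = np.zeros(n, dtype=int)
    death_by_admin = dies & (dfs_months + os_increment <= params.admin_censor_months)
    os_event[death_by_admin] = 1
    os_months = np.where(
        dies & ~death_by_admin, params.admin_censor_months, os_months
    )
    if params.censoring_fraction >= 1.0:
        os_months = np.full(n, 1e-9)
        os_event[:] = 0

    cohort = pd.DataFrame(
        {
            "id": [f"P{i:05d}" for i in range(n)],
            "tsr_percent": np.round(tsr, 4),
            "dfs_months": np.round(dfs_months, 6),
            "dfs_event": dfs_event,
            "os_months": np.round(os_months, 6),
            "os_event": os_event,
            "age": np.round(age, 2),
            "stage": stage,
        }
    )
    truth = {
        "true_cutoff": params.true_cutoff,
        "hazard_ratio": params.hazard_ratio,
        "n_high": int(high.sum()),
        "n_events_dfs": int(dfs_event.sum()),
        "n_events_os": int(os_event.sum()),
        "seed": params.seed,
        "params": asdict(params),
    }
    return cohort, truth
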