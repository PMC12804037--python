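"""Reading and writing tissue segmentation label masks and pipeline results.

A label mask is a single-channel indexed raster (PNG or TIFF) in which each
pixel carries a tissue class code. The semantics of the codes live in a JSON
class map sidecar, which designates which codes play the roles the pipeline
cares about (background, tumor epithelium, tumor stroma, necrosis, mucin,
excluded). All remaining codes are treated as "other" tumor-associated
tissue. Artifact masks are same-shape binary rasters marking artificially
altered slide areas; applying one relabels those pixels to the excluded code
so downstream eligibility tests can reject heavily artifacted regions.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
from PIL import Image

__all__ = [
    "ROLES",
    "ClassMap",
    "LabelMask",
    "ArtifactMask",
    "DEFAULT_CLASS_MAP",
    "read_class_map",
    "read_label_mask",
    "write_label_mask",
    "read_artifact_mask",
    "apply_artifact_exclusion",
    "write_slide_result",
    "read_slide_result",
    "export_roi_overlay",
    "write_batch_tsv",
    "file_sha256",
]

#: Designated class roles. "other" collects every code without a designated role.
ROLES = (
    "background",
    "tumor_epithelium",
    "tumor_stroma",
    "necrosis",
    "mucin",
    "excluded",
    "other",
)

_DESIGNATED = ROLES[:-1]


class MaskIOError(ValueError):
    """Raised for malformed masks, class maps, or result files."""


@dataclass(frozen=True)
class ClassMap:
    """Mapping from integer class codes to tissue class names and roles.

    Parameters
    ----------
    names : mapping of code -> class name (codes unique by construction).
    roles : mapping of role -> code for the designated roles; every other
        code is tagged "other".
    """

    names: Mapping[int, str]
    roles: Mapping[str, int]

    def __post_init__(self) -> None:
        missing = [r for r in _DESIGNATED if r not in self.roles]
        if missing:
            raise MaskIOError(f"class map missing designated roles: {missing}")
        codes = [self.roles[r] for r in _DESIGNATED]
        if len(set(codes)) != len(codes):
            raise MaskIOError("designated roles must map to distinct codes")
        for role, code in self.roles.items():
            if code not in self.names:
                raise MaskIOError(f"role {role!r} maps to code {code} absent from names")

    @property
    def codes(self) -> set[int]:
        return set(self.names)

    def role_of(self, code: int) -> str:
        for role in _DESIGNATED:
            if self.roles[role] == code:
                return role
        return "other"

    def role_lookup(self) -> np.ndarray:
        """uint8 code -> role index table (into ROLES), 256 entries.

        Codes absent from the map point at role "other"; reads validate codes
        before this table is ever consulted.
        """
        table = np.full(256, ROLES.index("other"), dtype=np.int64)
        for role in _DESIGNATED:
            table[self.roles[role]] = ROLES.index(role)
        return table

    def to_dict(self) -> dict:
        return {
            "classes": {str(c): n for c, n in sorted(self.names.items())},
            "roles": {r: self.roles[r] for r in _DESIGNATED},
        }


#: Default shipped vocabulary: ten tissue classes plus background, with 255
#: reserved for artifact-excluded pixels. User maps may add further codes.
DEFAULT_CLASS_MAP = ClassMap(
    names={
        0: "background",
        1: "tumor_epithelium",
        2: "tumor_stroma",
        3: "necrosis",
        4: "mucin",
        5: "smooth_muscle",
        6: "mucosa",
        7: "submucosa",
        8: "adventitial",
        9: "lymphocytic",
        10: "bleeding",
        255: "excluded",
    },
    roles={
        "background": 0,
        "tumor_epithelium": 1,
        "tumor_stroma": 2,
        "necrosis": 3,
        "mucin": 4,
        "excluded": 255,
    },
)


@dataclass
class LabelMask:
    """A 2-D grid of tissue class codes with physical resolution.

    Attributes
    ----------
    data : uint8 array, shape (height, width); one class code per pixel.
    mpp : microns per pixel (square pixels), finite and > 0.
    slide_id : identifier for the originating slide.
    classmap : the ClassMap giving the codes their meaning.
    """

    data: np.ndarray
    mpp: float
    slide_id: str
    classmap: ClassMap = field(default_factory=lambda: DEFAULT_CLASS_MAP)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2 or self.data.shape[0] < 1 or self.data.shape[1] < 1:
            raise MaskIOError("label mask must be a 2-D raster with dimensions >= 1")
        if not (math.isfinite(self.mpp) and self.mpp > 0):
            raise MaskIOError(f"mpp must be finite and positive, got {self.mpp}")
        present = set(np.unique(self.data).tolist())
        unknown = present - self.classmap.codes
        if unknown:
            raise MaskIOError(f"unknown class code(s) in mask: {sorted(unknown)}")
        self.data = self.data.astype(np.uint8, copy=False)

    @property
    def height(self) -> int:
        return int(self.data.shape[0])

    @property
    def width(self) -> int:
        return int(self.data.shape[1])


@dataclass
class ArtifactMask:
    """Boolean raster flagging artificially altered pixels (True = artifact)."""

    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 2:
            raise MaskIOError("artifact mask must be 2-D")


def read_class_map(path: str | Path) -> ClassMap:
    """Read a JSON class map sidecar ({"classes": {code: name}, "roles": {...}})."""
    path = Path(path)
    if not path.exists():
        raise MaskIOError(f"class map not found: {path}")
    payload = json.loads(path.read_text())
    try:
        names = {int(c): str(n) for c, n in payload["classes"].items()}
        roles = {str(r): int(c) for r, c in payload["roles"].items()}
    except (KeyError, TypeError, ValueError) as exc:
        raise MaskIOError(f"malformed class map {path}: {exc}") from exc
    return ClassMap(names=names, roles=roles)


def write_class_map(classmap: ClassMap, path: str | Path) -> None:
    Path(path).write_text(json.dumps(classmap.to_dict(), indent=2, sort_keys=True) + "\n")


def _read_raster(path: Path) -> np.ndarray:
    if not path.exists():
        raise MaskIOError(f"mask file not found: {path}")
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        arr = tifffile.imread(str(path))
    else:
        with Image.open(path) as img:
            if img.mode not in ("L", "P", "I", "1"):
                raise MaskIOError(
                    f"{path}: expected a single-channel indexed raster, got mode {img.mode!r}"
                )
            arr = np.asarray(img)
    if arr.ndim != 2:
        raise MaskIOError(f"{path}: expected a single-channel raster, got shape {arr.shape}")
    return arr


def read_label_mask(
    path: str | Path,
    classmap_path: str | Path | None = None,
    *,
    classmap: ClassMap | None = None,
    mpp: float | None = None,
    slide_id: str | None = None,
) -> LabelMask:
    """Read and validate a label mask raster with its class map.

    ``mpp`` is taken from a ``<mask>.meta.json`` sidecar when present, else
    from the ``mpp`` argument; supplying neither is an error. Unknown codes
    in the raster raise.
    """
    path = Path(path)
    arr = _read_raster(path)
    if classmap is None:
        classmap = read_class_map(classmap_path) if classmap_path else DEFAULT_CLASS_MAP
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    if mpp is None:
        mpp = meta.get("mpp")
    if mpp is None:
        raise MaskIOError(f"{path}: mpp not supplied and no metadata sidecar found")
    if slide_id is None:
        slide_id = meta.get("slide_id", path.stem)
    return LabelMask(data=arr, mpp=float(mpp), slide_id=str(slide_id), classmap=classmap)


def write_label_mask(mask: LabelMask, path: str | Path) -> None:
    """Write a label mask as an 8-bit single-channel PNG/TIFF plus metadata sidecar."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        tifffile.imwrite(str(path), mask.data)
    else:
        Image.fromarray(mask.data, mode="L").save(path)
    meta = {"mpp": mask.mpp, "slide_id": mask.slide_id}
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps(meta, indent=2, sort_keys=True) + "\n"
    )


def read_artifact_mask(path: str | Path) -> ArtifactMask:
    """Read a binary artifact raster (nonzero = artifact)."""
    arr = _read_raster(Path(path))
    return ArtifactMask(data=arr != 0)


def apply_artifact_exclusion(mask: LabelMask, artifacts: ArtifactMask) -> LabelMask:
    """Relabel artifact pixels to the designated excluded code.

    All other pixels are unchanged; the operation is idempotent and conserves
    the total pixel count.
    """
    if artifacts.data.shape != mask.data.shape:
        raise MaskIOError(
            f"artifact mask shape {artifacts.data.shape} != label mask shape {mask.data.shape}"
        )
    out = mask.data.copy()
    out[artifacts.data] = mask.classmap.roles["excluded"]
    return LabelMask(data=out, mpp=mask.mpp, slide_id=mask.slide_id, classmap=mask.classmap)


# ---------------------------------------------------------------------------
# Result serialization
# ---------------------------------------------------------------------------


def _roi_to_dict(roi) -> dict:
    return {
        "center_x": int(roi.center[0]),
        "center_y": int(roi.center[1]),
        "diameter_px": float(roi.diameter_px),
        "composition": {k: float(v) for k, v in sorted(roi.composition.items())},
        "composition_pass": bool(roi.composition_pass),
        "quadrant_pass": bool(roi.quadrant_pass),
        "tsr": None if roi.tsr is None else float(roi.tsr),
    }


def write_slide_result(result, path: str | Path, *, provenance: dict | None = None) -> None:
    """Write a slide-level TSR result as stable, sorted-key JSON.

    The file round-trips losslessly: write -> read -> write is byte-identical.
    """
    payload = {
        "slide_id": result.slide_id,
        "assessable": bool(result.assessable),
        "tsr_percent": None if result.tsr_percent is None else float(result.tsr_percent),
        "class_label": result.class_label,
        "n_candidates": int(result.n_candidates),
        "n_eligible": int(result.n_eligible),
        "params": result.params.to_dict(),
        "chosen_roi": None if result.chosen_roi is None else _roi_to_dict(result.chosen_roi),
    }
    if provenance is not None:
        payload["provenance"] = provenance
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_slide_result(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def write_result_dict(payload: dict, path: str | Path) -> None:
    """Re-serialize a result dict with the same stable formatting as
    :func:`write_slide_result`, so read -> write round-trips byte-identically."""
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def _circle_polygon(cx: float, cy: float, radius: float, n_vertices: int = 64) -> list:
    pts = []
    for k in range(n_vertices):
        theta = 2.0 * math.pi * k / n_vertices
        pts.append([cx + radius * math.cos(theta), cy + radius * math.sin(theta)])
    pts.append(pts[0])  # close the ring
    return [pts]


def export_roi_overlay(result, rois, path: str | Path) -> None:
    """Export eligible ROIs as a GeoJSON FeatureCollection of discretized circles.

    Coordinates are 0-based pixels, x = column, y = row. Each feature carries
    ``tsr_percent`` and ``chosen`` properties; the hotspot is flagged exactly
    once.
    """
    features = []
    chosen = result.chosen_roi
    for roi in rois:
        if roi.tsr is None:
            continue
        is_chosen = chosen is not None and tuple(roi.center) == tuple(chosen.center)
        features.append(
            {
                "type": "Feature",
                "geometry": {
                    "type": "Polygon",
                    "coordinates": _circle_polygon(
                        roi.center[0], roi.center[1], roi.diameter_px / 2.0
                    ),
                },
                "properties": {
                    "tsr_percent": round(roi.tsr * 100.0, 6),
                    "chosen": bool(is_chosen),
                },
            }
        )
    collection = {"type": "FeatureCollection", "features": features}
    Path(path).write_text(json.dumps(collection, indent=2, sort_keys=True) + "\n")


def write_batch_tsv(results, path: str | Path) -> None:
    """Write one row per slide: id, tsr_percent, class_label, n_eligible, assessable."""
    lines = ["slide_id\ttsr_percent\tclass_label\tn_eligible\tassessable"]
    for res in results:
        tsr = "" if res.tsr_percent is None else f"{res.tsr_percent:.4f}"
        label = "" if res.class_label is None else res.class_label
        lines.append(
            f"{res.slide_id}\t{tsr}\t{label}\t{res.n_eligible}\t{str(res.assessable).lower()}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
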