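"""Naive double-loop reference implementation of the ROI engine.

Deliberately written with explicit Python loops and per-pixel distance
checks, independent of the vectorized engine, so the engine can be verified
against it exactly on small masks.
"""

import math


def naive_quantify(mask, params):
    """Return (eligible dict center->tsr, hotspot (center, tsr) or None,
    all candidate centers in scan order)."""
    data = mask.data
    h, w = data.shape
    cm = mask.classmap
    tumor_code = cm.roles["tumor_epithelium"]
    stroma_code = cm.roles["tumor_stroma"]
    bg_code = cm.roles["background"]
    nec_code = cm.roles["necrosis"]
    muc_code = cm.roles["mucin"]
    exc_code = cm.roles["excluded"]

    d = max(1, round(params.diameter_um / mask.mpp))
    stride = max(1, round((1.0 - params.overlap_fraction) * d))
    r = d / 2.0
    half = math.ceil(r) - 1

    # tumor bounding box by full scan
    xs, ys = [], []
    for y in range(h):
        for x in range(w):
            if data[y, x] == tumor_code:
                xs.append(x)
                ys.append(y)
    if not xs:
        return {}, None, []
    x0 = max(0, math.floor(min(xs) - r))
    y0 = max(0, math.floor(min(ys) - r))
    x1 = min(w - 1, math.ceil(max(xs) + r))
    y1 = min(h - 1, math.ceil(max(ys) + r))

    def axis_centers(start, stop, extent):
        c = max(math.ceil(start + r), half)
        out = []
        while c <= min(stop, extent - 1 - half):
            out.append(c)
            c += stride
        return out

    cxs = axis_centers(x0, x1, w)
    cys = axis_centers(y0, y1, h)

    # disc offsets, computed once per diameter by brute-force distance check
    offsets = []
    for dy in range(-half, half + 1):
        for dx in range(-half, half + 1):
            if dx * dx + dy * dy < r * r:
                offsets.append((dx, dy))
    area = len(offsets)

    eligible = {}
    hotspot = None
    centers = []
    for cy in cys:
        for cx in cxs:
            centers.append((cx, cy))
            counts = {"bg": 0, "tum": 0, "str": 0, "nec": 0, "muc": 0, "exc": 0}
            quad_tumor = [0, 0, 0, 0]
            for dx, dy in offsets:
                code = data[cy + dy, cx + dx]
                if code == bg_code:
                    counts["bg"] += 1
                elif code == tumor_code:
                    counts["tum"] += 1
                    q = (1 if dx >= 0 else 0) + (2 if dy >= 0 else 0)
                    quad_tumor[q] += 1
                elif code == stroma_code:
                    counts["str"] += 1
                elif code == nec_code:
                    counts["nec"] += 1
                elif code == muc_code:
                    counts["muc"] += 1
                elif code == exc_code:
                    counts["exc"] += 1
            comp_ok = (
                (counts["bg"] + counts["exc"]) / area < params.max_background_fraction
                and counts["nec"] / area < params.max_necrosis_fraction
                and counts["muc"] / area < params.max_mucin_fraction
            )
            quad_ok = all(q >= params.min_tumor_pixels_per_quadrant for q in quad_tumor)
            if comp_ok and quad_ok:
                tsr = counts["str"] / (counts["str"] + counts["tum"])
                eligible[(cx, cy)] = tsr
                if hotspot is None or tsr > hotspot[1]:
                    hotspot = ((cx, cy), tsr)
    return eligible, hotspot, centers
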