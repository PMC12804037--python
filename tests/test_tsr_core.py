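"""ROI engine: geometry, eligibility, TSR, hotspot selection, invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tsrquant import (
    ArtifactMask,
    LabelMask,
    RoiParams,
    classify_tsr,
    composition_eligibility,
    compute_tsr,
    quadrant_test,
    quantify_slide,
    roi_composition,
    roi_grid,
    tumor_analysis_region,
)
from tsrquant.mask_io import ClassMap
from tsrquant.tsr_core import (
    STROMA_HIGH,
    STROMA_LOW,
    TsrUndefinedError,
    diameter_px_for,
    stride_px_for,
)

from conftest import BG, CM, MUC, NEC, STR, TUM, make_mask
from naive_reference import naive_quantify


def comp(**kwargs):
    base = {r: 0.0 for r in ("background", "tumor_epithelium", "tumor_stroma",
                             "necrosis", "mucin", "excluded", "other")}
    base.update(kwargs)
    rest = 1.0 - sum(base.values())
    base["tumor_stroma"] += rest  # pad to sum 1 with stroma
    return base


class TestParams:
    def test_defaults_match_protocol(self):
        p = RoiParams()
        assert p.diameter_um == 1000.0
        assert p.overlap_fraction == 0.70
        assert (p.max_background_fraction, p.max_necrosis_fraction,
                p.max_mucin_fraction) == (0.10, 0.20, 0.30)

    def test_stride_is_30_percent_of_diameter(self):
        assert stride_px_for(RoiParams(), mpp=1.0) == 300

    def test_zero_overlap_tiles(self):
        p = RoiParams(overlap_fraction=0.0)
        assert stride_px_for(p, mpp=1.0) == diameter_px_for(p, mpp=1.0)

    def test_mpp_scaling(self):
        assert diameter_px_for(RoiParams(), mpp=2.0) == 500
        assert diameter_px_for(RoiParams(diameter_um=1.0), mpp=4.0) == 1  # floor 1

    @pytest.mark.parametrize("kwargs", [
        {"diameter_um": 0}, {"overlap_fraction": 1.0}, {"overlap_fraction": -0.1},
        {"max_background_fraction": 0.0}, {"max_mucin_fraction": 1.5},
        {"min_tumor_pixels_per_quadrant": 0},
    ])
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            RoiParams(**kwargs)


class TestAnalysisRegion:
    def test_no_tumor_gives_empty_region(self):
        assert tumor_analysis_region(make_mask(np.zeros((50, 50))), RoiParams()) is None

    def test_single_tumor_pixel_dilated_box(self):
        data = np.zeros((2000, 2000), dtype=np.uint8)
        data[50, 50] = TUM
        region = tumor_analysis_region(make_mask(data), RoiParams())
        assert region == (0, 0, 550, 550)

    def test_tumor_everywhere_gives_full_extent(self):
        mask = make_mask(np.full((300, 400), TUM))
        assert tumor_analysis_region(mask, RoiParams(diameter_um=100)) == (0, 0, 399, 299)


class TestRoiGrid:
    def test_documented_grid(self):
        centers = roi_grid((0, 0, 1599, 999), RoiParams(), (1000, 1600), 1.0)
        assert centers == [(500, 500), (800, 500), (1100, 500)]

    def test_row_major_order(self):
        centers = roi_grid((0, 0, 199, 199), RoiParams(diameter_um=100), (200, 200), 1.0)
        ys = [c[1] for c in centers]
        assert ys == sorted(ys)

    def test_empty_when_disc_does_not_fit(self):
        assert roi_grid((0, 0, 9, 9), RoiParams(diameter_um=100), (10, 10), 1.0) == []

    def test_brute_force_admissibility(self):
        """Every returned center's full disc is in bounds; no admissible
        grid position is skipped."""
        params = RoiParams(diameter_um=64, overlap_fraction=0.70)
        extent = (150, 170)
        centers = roi_grid((0, 0, 169, 149), params, extent, 1.0)
        d = diameter_px_for(params, 1.0)
        stride = stride_px_for(params, 1.0)
        r = d / 2.0
        half = math.ceil(r) - 1
        for cx, cy in centers:
            assert cx - half >= 0 and cy - half >= 0
            assert cx + half <= extent[1] - 1 and cy + half <= extent[0] - 1
        xs = sorted({c[0] for c in centers})
        assert all(b - a == stride for a, b in zip(xs, xs[1:]))


class TestComposition:
    def test_uniform_stroma_disc(self, uniform_stroma_mask):
        c = roi_composition(uniform_stroma_mask, (60, 60), 100)
        assert c["tumor_stroma"] == 1.0
        assert sum(c.values()) == pytest.approx(1.0, abs=1e-12)

    def test_half_plane_split(self):
        data = np.full((200, 200), TUM, dtype=np.uint8)
        data[:, :100] = STR  # left half stroma
        c = roi_composition(make_mask(data), (100, 100), 150)
        area = sum(1 for dy in range(-74, 75) for dx in range(-74, 75)
                   if dx * dx + dy * dy < 75.0 ** 2)
        tol = 2.0 / math.sqrt(area)
        assert c["tumor_stroma"] == pytest.approx(0.5, abs=tol)
        assert c["tumor_epithelium"] == pytest.approx(0.5, abs=tol)

    def test_out_of_bounds_disc_rejected(self, uniform_stroma_mask):
        with pytest.raises(ValueError, match="outside"):
            roi_composition(uniform_stroma_mask, (5, 60), 100)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_composition_sums_to_one(self, seed):
        rng = np.random.default_rng(seed)
        codes = np.array([0, 1, 2, 3, 4, 5, 255], dtype=np.uint8)
        data = rng.choice(codes, size=(64, 64))
        c = roi_composition(make_mask(data), (32, 32), 40)
        assert sum(c.values()) == pytest.approx(1.0, abs=1e-9)
        assert all(v >= 0 for v in c.values())


class TestEligibility:
    def test_all_strictly_below_passes(self):
        assert composition_eligibility(
            comp(background=0.05, necrosis=0.10, mucin=0.10), RoiParams())

    @pytest.mark.parametrize("kwargs", [
        {"background": 0.10}, {"necrosis": 0.20}, {"mucin": 0.30}, {"mucin": 0.35},
    ])
    def test_boundary_and_above_fail(self, kwargs):
        assert not composition_eligibility(comp(**kwargs), RoiParams())

    def test_excluded_counts_as_background(self):
        assert not composition_eligibility(comp(background=0.05, excluded=0.05), RoiParams())
        assert composition_eligibility(comp(background=0.05, excluded=0.04), RoiParams())


class TestQuadrantTest:
    def test_uniform_tumor_passes(self):
        mask = make_mask(np.full((60, 60), TUM))
        assert quadrant_test(mask, (30, 30), 40, RoiParams())

    def test_tumor_upper_half_fails(self):
        data = np.full((60, 60), STR, dtype=np.uint8)
        data[:30, :] = TUM
        assert not quadrant_test(make_mask(data), (30, 30), 40, RoiParams())

    def test_one_pixel_per_quadrant_passes(self):
        data = np.full((60, 60), STR, dtype=np.uint8)
        for x, y in [(20, 20), (40, 20), (20, 40), (40, 40)]:
            data[y, x] = TUM
        assert quadrant_test(make_mask(data), (30, 30), 40, RoiParams())

    def test_on_line_pixels_go_to_right_lower(self):
        # a single tumor pixel exactly on the vertical line through the
        # center belongs to the right quadrants only
        data = np.full((60, 60), STR, dtype=np.uint8)
        data[20, 30] = TUM  # x == cx, upper half -> upper-right quadrant
        data[40, 30] = TUM  # lower-right
        data[30, 20] = TUM  # y == cy is lower -> lower-left
        assert not quadrant_test(make_mask(data), (30, 30), 40, RoiParams())
        data[20, 20] = TUM  # upper-left added -> all four occupied
        assert quadrant_test(make_mask(data), (30, 30), 40, RoiParams())


class TestComputeTsr:
    @pytest.mark.parametrize("stroma,tumor,expected", [
        (750, 250, 0.75), (0, 100, 0.0), (77, 23, 0.77),
    ])
    def test_direct_arithmetic(self, stroma, tumor, expected):
        total = 2000.0
        c = comp()
        c["tumor_stroma"] = stroma / total
        c["tumor_epithelium"] = tumor / total
        c["other"] = 1.0 - (stroma + tumor) / total
        assert compute_tsr(c) == pytest.approx(expected)

    def test_zero_denominator_raises(self):
        c = comp()
        c["tumor_stroma"] = 0.0
        c["other"] = 1.0
        with pytest.raises(TsrUndefinedError):
            compute_tsr(c)


class TestClassify:
    def test_boundary_is_stroma_low(self):
        assert classify_tsr(77.0) == STROMA_LOW

    def test_just_above_is_stroma_high(self):
        assert classify_tsr(77.01) == STROMA_HIGH
        assert classify_tsr(np.nextafter(77.0, 100.0)) == STROMA_HIGH

    def test_visual_cutoff(self):
        assert classify_tsr(40.0, cutoff_percent=50.0) == STROMA_LOW
        assert classify_tsr(50.5, cutoff_percent=50.0) == STROMA_HIGH

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_tsr(101.0)


def random_small_mask(seed, size=96):
    """Random tissue mask biased toward tumor/stroma with pockets."""
    rng = np.random.default_rng(seed)
    codes = np.array([BG, TUM, STR, NEC, MUC, 5, 255], dtype=np.uint8)
    probs = np.array([0.04, 0.38, 0.44, 0.05, 0.04, 0.03, 0.02])
    data = rng.choice(codes, size=(size, size), p=probs)
    # a couple of solid pockets to create composition failures
    for _ in range(2):
        cx, cy, r = rng.integers(10, size - 10), rng.integers(10, size - 10), rng.integers(5, 12)
        yy, xx = np.ogrid[:size, :size]
        data[(xx - cx) ** 2 + (yy - cy) ** 2 < r * r] = rng.choice([BG, NEC, MUC])
    return make_mask(data)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(5))
    def test_engine_matches_naive_reference(self, seed):
        mask = random_small_mask(seed)
        params = RoiParams(diameter_um=32, overlap_fraction=0.70)
        result, rois = quantify_slide(mask, None, params)
        eligible_naive, hotspot_naive, centers_naive = naive_quantify(mask, params)
        assert [r.center for r in rois] == centers_naive
        eligible_engine = {r.center: r.tsr for r in rois if r.tsr is not None}
        assert eligible_engine == eligible_naive  # exact float equality
        if hotspot_naive is None:
            assert not result.assessable
        else:
            assert result.chosen_roi.center == hotspot_naive[0]
            assert result.tsr_percent == hotspot_naive[1] * 100.0


class TestQuantifySlide:
    def test_all_background_not_assessable(self):
        result, rois = quantify_slide(make_mask(np.zeros((100, 100))),
                                      None, RoiParams(diameter_um=40))
        assert not result.assessable
        assert result.tsr_percent is None and result.class_label is None
        assert result.n_eligible == 0

    def test_fully_artifacted_not_assessable(self, mixed_mask):
        art = ArtifactMask(np.ones((200, 200), dtype=bool))
        result, _ = quantify_slide(mixed_mask, art, RoiParams(diameter_um=60))
        assert not result.assessable

    def test_hotspot_tie_breaks_to_first_row_major(self):
        # two identical pure-stroma+tumor halves -> equal TSR everywhere;
        # the first grid ROI must be chosen
        data = np.full((120, 240), STR, dtype=np.uint8)
        data[::5, ::5] = TUM
        result, rois = quantify_slide(make_mask(data), None, RoiParams(diameter_um=100))
        eligible = [r for r in rois if r.tsr is not None]
        top = max(r.tsr for r in eligible)
        firsts = [r for r in eligible if r.tsr == top]
        assert result.chosen_roi.center == firsts[0].center

    def test_translation_equivariance(self):
        # interior content (no region clipping at the mask border) shifted
        # by one stride gives an identical hotspot
        params = RoiParams(diameter_um=24, overlap_fraction=0.5)
        stride = stride_px_for(params, 1.0)
        rng = np.random.default_rng(11)
        patch = np.where(rng.random((50, 50)) < 0.6, STR, TUM).astype(np.uint8)
        base = np.full((120, 120), BG, dtype=np.uint8)
        base[35:85, 35:85] = patch
        shifted = np.full((120 + stride, 120 + stride), BG, dtype=np.uint8)
        shifted[35 + stride:85 + stride, 35 + stride:85 + stride] = patch
        r1, _ = quantify_slide(make_mask(base), None, params)
        r2, _ = quantify_slide(make_mask(shifted), None, params)
        assert r1.assessable and r2.assessable
        assert r1.tsr_percent == r2.tsr_percent
        c1, c2 = r1.chosen_roi.center, r2.chosen_roi.center
        assert (c2[0] - c1[0], c2[1] - c1[1]) == (stride, stride)

    def test_class_code_remap_invariance(self):
        mask = random_small_mask(5)
        perm = {0: 7, 1: 3, 2: 9, 3: 0, 4: 1, 5: 2, 255: 4}
        remapped_names = {perm[c]: n for c, n in CM.names.items() if c in perm}
        remapped_roles = {r: perm[c] for r, c in CM.roles.items()}
        cm2 = ClassMap(names=remapped_names, roles=remapped_roles)
        lut = np.zeros(256, dtype=np.uint8)
        for old, new in perm.items():
            lut[old] = new
        mask2 = LabelMask(data=lut[mask.data], mpp=1.0, slide_id="remap", classmap=cm2)
        params = RoiParams(diameter_um=32)
        r1, rois1 = quantify_slide(mask, None, params)
        r2, rois2 = quantify_slide(mask2, None, params)
        assert r1.tsr_percent == r2.tsr_percent
        assert [x.tsr for x in rois1] == [x.tsr for x in rois2]

    def test_determinism(self):
        mask = random_small_mask(3)
        params = RoiParams(diameter_um=32)
        r1, rois1 = quantify_slide(mask, None, params)
        r2, rois2 = quantify_slide(mask, None, params)
        assert r1 == r2 and rois1 == rois2

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=15, deadline=None)
    def test_tsr_bounded_and_defined_iff_eligible(self, seed):
        mask = random_small_mask(seed, size=64)
        _, rois = quantify_slide(mask, None, RoiParams(diameter_um=24))
        for r in rois:
            assert (r.tsr is not None) == (r.composition_pass and r.quadrant_pass)
            if r.tsr is not None:
                assert 0.0 <= r.tsr <= 1.0
            assert sum(r.composition.values()) == pytest.approx(1.0, abs=1e-9)

    def test_artifact_monotonicity_nested_discs(self):
        mask = random_small_mask(21, size=120)
        params = RoiParams(diameter_um=40)
        yy, xx = np.ogrid[:120, :120]
        counts = []
        for radius in (0, 15, 30, 45):
            art = ArtifactMask((xx - 60) ** 2 + (yy - 60) ** 2 < radius ** 2)
            res, _ = quantify_slide(mask, art, params)
            counts.append(res.n_eligible)
        assert all(b <= a for a, b in zip(counts, counts[1:]))
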