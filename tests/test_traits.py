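import numpy as np
import pytest

from rootpouch import (BinaryMask, RootModelParams, SceneParams, TraitConfig,
                       clean_image, count_tips, detect_junction, generate_model,
                       measure_all, measure_architecture, measure_morphology,
                       render_scene, skeletonize)
from rootpouch.traits import NoForegroundError, _hull_area_px

from .oracles import gift_wrap_hull, shoelace_area


def _bar(h, w, shape=(60, 140), at=(20, 10)):
    m = np.zeros(shape, bool)
    m[at[0]:at[0] + h, at[1]:at[1] + w] = True
    return m


class TestSkeletonize:
    def test_horizontal_bar(self):
        sk = skeletonize(_bar(5, 100), min_spur_px=0)
        assert len(sk.endpoints) == 2
        assert len(sk.branch_points) == 0

    def test_plus_sign(self):
        m = np.zeros((61, 61), bool)
        m[28:33, 5:56] = True
        m[5:56, 28:33] = True
        sk = skeletonize(m, min_spur_px=0)
        assert len(sk.endpoints) == 4
        assert len(sk.branch_points) >= 1

    def test_interior_radius_of_9px_bar(self):
        m = _bar(9, 120, shape=(40, 140))
        sk = skeletonize(m, min_spur_px=0)
        interior = sk.coords[(sk.coords[:, 1] > 30) & (sk.coords[:, 1] < 110)]
        radii = sk.radius_px[interior[:, 0], interior[:, 1]]
        assert np.all(np.abs(radii - 4.5) <= 0.5 + 1e-9)

    def test_empty_mask_errors(self):
        with pytest.raises(NoForegroundError, match="no foreground"):
            skeletonize(np.zeros((10, 10), bool))

    def test_spur_pruning(self):
        m = _bar(3, 100, shape=(60, 140), at=(30, 10))
        m[27:30, 50] = True  # 3-px spur off the bar
        pruned = skeletonize(m, min_spur_px=5)
        kept = skeletonize(m, min_spur_px=1)
        assert len(pruned.endpoints) == 2
        assert len(kept.endpoints) == 3

    def test_skeleton_subset_of_mask(self):
        rng = np.random.default_rng(1)
        m = _bar(7, 90)
        sk = skeletonize(m, min_spur_px=3)
        assert not (sk.mask & ~m).any()


class TestDetectJunction:
    def test_vertical_bar(self):
        m = np.zeros((50, 30), bool)
        m[10:45, 12:15] = True
        assert detect_junction(m)[0] == 10

    def test_tie_break_deterministic(self):
        m = np.zeros((20, 21), bool)
        m[5, 4] = True
        m[5, 16] = True
        m[6:15, 4:17] = True  # centroid col = 10, both top pixels equidistant
        r, c = detect_junction(m)
        assert r == 5
        assert c == 4  # equidistant from centroid: smaller column wins

    def test_render_junction_matches_manifest(self, small_render, small_model):
        img, manifest = small_render
        _, mask = clean_image(img)
        r, c = detect_junction(mask)
        jr, jc = manifest.junction_px
        assert abs(r - jr) <= 3
        # column resolves anywhere on the flat tap top: half a stroke width
        half_w = small_model.segments[0].widths_mm[0] / 10.0 * 100.0 / 2.0
        assert abs(c - jc) <= half_w + 1

    def test_empty_errors(self):
        with pytest.raises(NoForegroundError):
            detect_junction(np.zeros((5, 5), bool))


class TestCountTips:
    def test_single_path(self):
        m = np.zeros((60, 20), bool)
        m[5:55, 8:11] = True
        sk = skeletonize(m, 5)
        assert count_tips(sk, detect_junction(m)) == 1

    def test_debris_false_tips_cleaned_vs_raw(self, small_model):
        from rootpouch import CleaningConfig, segment_foreground
        scene = SceneParams(image_size_px=(1200, 800), pixels_per_cm=100.0,
                            debris_count=30, debris_area_px=(20, 150), seed=77)
        img, _ = render_scene(small_model, scene)
        cfg = CleaningConfig()
        raw = segment_foreground(img, cfg)
        _, cleaned = clean_image(img, cfg)
        t_raw = count_tips(skeletonize(raw, 5), detect_junction(raw))
        t_clean = count_tips(skeletonize(cleaned, 5), detect_junction(cleaned))
        truth = small_model.truth.TRT
        assert t_clean == truth
        # each debris blob is at least one false tip, some register as two
        assert truth + 30 <= t_raw <= truth + 60


class TestMeasureMorphology:
    def test_horizontal_bar_trl(self):
        # a 1-px bar IS its own skeleton: 101 axial pixels = 100 steps
        m = _bar(1, 101, shape=(40, 160))
        sk = skeletonize(m, min_spur_px=0)
        out = measure_morphology(sk, scale=100.0)
        assert out["TRL"] == pytest.approx(1.0, abs=1e-9)

    def test_single_diameter_class(self):
        # 12-px-wide bar at 100 px/cm = 1.2 mm diameter -> class 3 only
        m = _bar(12, 130, shape=(50, 150))
        sk = skeletonize(m, min_spur_px=8)  # prune corner diagonals
        out = measure_morphology(sk, scale=100.0)
        assert out["TSA3"] == pytest.approx(out["TSA"], rel=0.05)
        assert out["TSA1"] <= 0.02 * out["TSA"]

    def test_bad_scale(self):
        sk = skeletonize(_bar(5, 50), 0)
        with pytest.raises(ValueError):
            measure_morphology(sk, scale=-1.0)

    def test_recovery_against_generator(self, small_model, small_render):
        img, _ = small_render
        _, mask = clean_image(img)
        rec = measure_all(mask, pixels_per_cm=100.0)
        t = small_model.truth
        assert rec.TRL == pytest.approx(t.TRL, rel=0.05)
        assert rec.TSA == pytest.approx(t.TSA, rel=0.10)


class TestMeasureArchitecture:
    def test_solid_rectangle_solidity(self):
        m = _bar(30, 80, shape=(60, 100))
        sk = skeletonize(m, 0)
        out = measure_architecture(m, sk, detect_junction(m), 100.0)
        assert out["SOL"] == pytest.approx(1.0, abs=1e-9)

    def test_vertical_bar_copm_rdi(self):
        m = np.zeros((1100, 60), bool)
        m[50:1051, 27:33] = True  # 10 cm at 100 px/cm
        sk = skeletonize(m, 0)
        out = measure_architecture(m, sk, detect_junction(m), 100.0)
        assert out["COPM"] == pytest.approx(5.0, abs=0.05)
        assert out["RDI"] == pytest.approx(2.0 / 3.0, abs=0.02)

    @pytest.mark.parametrize("seed", range(5))
    def test_hull_matches_gift_wrap_oracle(self, seed):
        rng = np.random.default_rng(seed)
        m = np.zeros((80, 80), bool)
        for _ in range(6):  # random union of blocks
            r, c = rng.integers(5, 60, 2)
            h, w = rng.integers(4, 18, 2)
            m[r:r + h, c:c + w] = True
        corners = np.concatenate([np.argwhere(m) + off for off in
                                  ((-.5, -.5), (-.5, .5), (.5, -.5), (.5, .5))])
        oracle = shoelace_area(gift_wrap_hull(corners))
        assert _hull_area_px(m) == pytest.approx(oracle, rel=1e-9)

    def test_degenerate_hull(self):
        m = np.zeros((10, 10), bool)
        m[4, 4] = True
        with pytest.raises(ValueError, match="degenerate hull"):
            _hull_area_px(m)


class TestMeasureAll:
    def test_full_record_from_raw_image(self, small_model, small_render):
        img, _ = small_render
        rec = measure_all(img)
        t = small_model.truth
        assert rec.TRT == t.TRT
        assert rec.TRL == pytest.approx(t.TRL, rel=0.05)
        assert rec.COPM == pytest.approx(t.COPM, rel=0.05)
        assert rec.RDI == pytest.approx(t.RDI, abs=0.05)
        assert rec.TCA == pytest.approx(t.TCA, rel=0.05)

    def test_all_background_errors(self):
        from rootpouch import PouchImage
        img = PouchImage(np.zeros((60, 60, 3), np.uint8), 100.0)
        with pytest.warns(UserWarning):
            with pytest.raises(NoForegroundError):
                measure_all(img)

    def test_deterministic(self, small_render):
        img, _ = small_render
        assert measure_all(img) == measure_all(img)

    def test_mask_requires_scale(self):
        with pytest.raises(ValueError, match="pixels_per_cm"):
            measure_all(BinaryMask(_bar(5, 60)))


class TestInvariants:
    def test_class_tsa_sums_to_tsa(self, small_render):
        img, _ = small_render
        _, mask = clean_image(img)
        sk = skeletonize(mask, 5)
        from rootpouch.traits import _per_pixel_geometry
        _, ell, d = _per_pixel_geometry(sk, 100.0)
        total = np.pi * (d / 10.0 * ell).sum()
        by_class = sum(
            np.pi * (d / 10.0 * ell)[(d >= lo) & (d < lo + 0.5)].sum()
            for lo in np.arange(0.0, d.max() + 0.5, 0.5))
        assert by_class == pytest.approx(total, rel=1e-9)

    def test_debris_monotonicity(self, small_model):
        base = dict(image_size_px=(1200, 800), pixels_per_cm=100.0, seed=90)
        img0, _ = render_scene(small_model, SceneParams(**base))
        imgd, _ = render_scene(small_model, SceneParams(
            **base, debris_count=25, debris_area_px=(20, 150)))
        from rootpouch import CleaningConfig, segment_foreground
        cfg = CleaningConfig()
        m0 = segment_foreground(img0, cfg)
        md = segment_foreground(imgd, cfg)
        r0 = measure_all(m0, pixels_per_cm=100.0)
        rd = measure_all(md, pixels_per_cm=100.0)
        assert rd.TRT >= r0.TRT
        assert rd.TRL >= r0.TRL
        assert rd.TCA >= r0.TCA

    def test_scale_equivariance(self, small_model):
        recs = []
        for scale in (100.0, 200.0):
            scene = SceneParams(image_size_px=(int(12 * scale), int(8 * scale)),
                                pixels_per_cm=scale, seed=91)
            img, _ = render_scene(small_model, scene)
            _, mask = clean_image(img)
            recs.append(measure_all(mask, pixels_per_cm=scale))
        assert recs[1].TRL == pytest.approx(recs[0].TRL, rel=0.02)
        assert recs[1].TCA == pytest.approx(recs[0].TCA, rel=0.02)
        assert recs[1].COPM == pytest.approx(recs[0].COPM, rel=0.02)

    def test_rdi_sol_bounds(self, small_render):
        img, _ = small_render
        rec = measure_all(img)
        assert 0.0 <= rec.RDI <= 1.0
        assert 0.0 < rec.SOL <= 1.0
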