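"""Descriptor battery: geometry extraction, size/shape/intensity/texture."""

import math

import numpy as np
import pytest

from nucleomorph import morphometry as M
from nucleomorph.synth import LabeledScene, make_boundary
from skimage.draw import polygon as draw_polygon

from conftest import disk_mask, scene_from_mask

PSZ = 0.25


def geometry(mask, psz=PSZ, image=None):
    return M.geometry_from_mask(mask, psz, image=image)


def rect_mask(width, height, pad=3):
    m = np.zeros((height + 2 * pad, width + 2 * pad), bool)
    m[pad : pad + height, pad : pad + width] = True
    return m


class TestGeometryExtraction:
    def test_missing_label_names_it(self, disk10_scene):
        with pytest.raises(KeyError, match="7"):
            M.extract_geometry(disk10_scene, 7)

    def test_two_component_label_rejected(self):
        labels = np.zeros((20, 20), np.uint16)
        labels[2:8, 2:8] = 1
        labels[12:18, 12:18] = 1
        scene = LabeledScene(
            image=np.zeros((20, 20, 3), np.uint8), labels=labels, pixel_size_um=PSZ
        )
        with pytest.raises(M.DegenerateNucleusError, match="component"):
            M.extract_geometry(scene, 1)

    def test_tiny_region_rejected(self):
        labels = np.zeros((10, 10), np.uint16)
        labels[4:6, 4:6] = 1  # 4 px < 10 px minimum
        scene = LabeledScene(
            image=np.zeros((10, 10, 3), np.uint8), labels=labels, pixel_size_um=PSZ
        )
        with pytest.raises(M.DegenerateNucleusError, match="area"):
            M.extract_geometry(scene, 1)

    def test_disk_area_within_2pct(self, disk10_scene):
        geom = M.extract_geometry(disk10_scene, 1)
        assert geom.area_px == pytest.approx(np.pi * 100, rel=0.02)


class TestPixelEnumerationOracle:
    """Area, centroid, bounding box and chain perimeter on tiny toy masks
    against exhaustive pixel enumeration / hand-derived chain codes."""

    @pytest.mark.parametrize("width,height", [(5, 4), (12, 10), (4, 3), (10, 2)])
    def test_rectangles(self, width, height):
        mask = rect_mask(width, height)
        geom = geometry(mask)
        # Exhaustive enumeration oracle.
        pix = [(r, c) for r in range(mask.shape[0]) for c in range(mask.shape[1]) if mask[r, c]]
        assert geom.area_px == len(pix)
        assert geom.centroid[0] == pytest.approx(sum(p[0] for p in pix) / len(pix))
        assert geom.centroid[1] == pytest.approx(sum(p[1] for p in pix) / len(pix))
        size = M.size_features(geom)
        assert size["nuclear_area"] == len(pix) * PSZ**2
        assert size["box_width"] == width * PSZ
        assert size["box_height"] == height * PSZ
        # Rectangle chain code: all axial, 2(w-1) + 2(h-1) steps.
        raw_steps = 2 * (width - 1) + 2 * (height - 1)
        assert size["perimeter2"] == pytest.approx(raw_steps * PSZ)
        assert size["perimeter3"] == pytest.approx(
            (0.948 * raw_steps + math.pi) * PSZ
        )
        assert size["perimeter_length"] == pytest.approx(size["perimeter3"] / 2)

    def test_diagonal_staircase_chain(self):
        # 12-px diagonal line: every pixel is traversed twice, all moves
        # diagonal -> raw chain length 22 * sqrt(2).
        mask = np.zeros((14, 14), bool)
        for i in range(12):
            mask[i + 1, i + 1] = True
        geom = geometry(mask)
        size = M.size_features(geom)
        assert size["perimeter2"] == pytest.approx(22 * math.sqrt(2) * PSZ)

    def test_l_shape_chain(self):
        # 5x5 square minus its 2x2 top-right corner: rectilinear boundary
        # through pixel centers walks 16 axial steps.
        mask = np.zeros((9, 9), bool)
        mask[2:7, 2:7] = True
        mask[2:4, 5:7] = False
        geom = geometry(mask)
        assert geom.area_px == 21
        size = M.size_features(geom)
        # 14 axial steps plus one diagonal cutting the concave corner
        # (8-connected chains take the shortcut at re-entrant corners).
        assert size["perimeter2"] == pytest.approx((14 + math.sqrt(2)) * PSZ)


class TestSizeFeatures:
    def test_disk_radii_and_diameters(self, disk10_scene):
        geom = M.extract_geometry(disk10_scene, 1)
        size = M.size_features(geom)
        tol = 1 * PSZ  # +-1 px
        assert abs(size["radius_max"] - 2.5) <= tol
        assert abs(size["radius_min"] - 2.5) <= tol
        assert abs(size["diameter_mean"] - 5.0) <= 2 * tol

    def test_rectangle_moments_oracle(self):
        mask = rect_mask(20, 10)
        geom = geometry(mask)
        size = M.size_features(geom)
        assert size["box_width"] == 20 * PSZ
        assert size["box_height"] == 10 * PSZ
        # Moment oracle on the exact rectangle: discrete uniform variances
        # (w^2-1)/12 and (h^2-1)/12, axes 4*sqrt(var).
        expect_major = 4 * math.sqrt((20**2 - 1) / 12) * PSZ
        expect_minor = 4 * math.sqrt((10**2 - 1) / 12) * PSZ
        assert size["axis_major"] == pytest.approx(expect_major, rel=1e-9)
        assert size["axis_minor"] == pytest.approx(expect_minor, rel=1e-9)
        shape = M.shape_features(geom)
        assert shape["aspect"] == pytest.approx(2.0, rel=0.02)
        assert shape["area_per_box"] == pytest.approx(1.0)
        # Ferets: caliper extent equals the bbox along the axes and the
        # diagonal at 45 degrees; length is the maximal caliper.
        assert size["length"] >= size["box_width"]

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_convex_perimeter_bounded_by_outline(self, seed):
        poly = make_boundary(25, 0.25, seed=seed)
        side = 71
        rr, cc = draw_polygon(poly[:, 1] + 35, poly[:, 0] + 35, shape=(side, side))
        mask = np.zeros((side, side), bool)
        mask[rr, cc] = True
        size = M.size_features(geometry(mask))
        assert size["perimeter_convex"] <= size["perimeter3"] * 1.02 + 2 * PSZ

    def test_scale_equivariance(self):
        mask = disk_mask(15)
        f1 = M.size_features(geometry(mask, psz=0.25))
        f2 = M.size_features(geometry(mask, psz=0.5))
        for key, val in f1.items():
            if key == "nuclear_area":
                assert f2[key] == pytest.approx(4 * val)
            elif key == "perimeter_ratio":
                assert f2[key] == pytest.approx(val)
            else:
                assert f2[key] == pytest.approx(2 * val)

    def test_rotation_robustness(self):
        mask = disk_mask(12)
        base = M.size_features(geometry(mask))
        for k in (1, 2, 3):
            rot = M.size_features(geometry(np.rot90(mask, k)))
            for key, val in base.items():
                assert rot[key] == pytest.approx(val), key
        # Ellipse within 2% under an arbitrary rotation.
        yy, xx = np.mgrid[0:81, 0:81].astype(float)
        for ang, store in ((0.0, {}), (0.53, {})):
            ca, sa = np.cos(ang), np.sin(ang)
            u = (xx - 40) * ca + (yy - 40) * sa
            v = -(xx - 40) * sa + (yy - 40) * ca
            emask = (u / 30) ** 2 + (v / 15) ** 2 <= 1
            store.update(M.size_features(geometry(emask)))
            if ang == 0.0:
                ref = dict(store)
        for key in ("axis_major", "axis_minor", "feret_mean", "perimeter_ellipse"):
            assert store[key] == pytest.approx(ref[key], rel=0.02), key


class TestShapeFeatures:
    def test_smooth_disk_limits(self, disk30_scene):
        geom = M.extract_geometry(disk30_scene, 1)
        shape = M.shape_features(geom)
        assert 1.0 <= shape["roundness"] <= 1.05
        assert 1.0 <= shape["fractal_dimension"] <= 1.05
        assert shape["radius_ratio"] >= 1.0

    def test_bright_hole_count(self):
        mask = disk_mask(10)
        image = np.full(mask.shape + (3,), 100, np.uint8)
        c = mask.shape[0] // 2
        image[c, c - 1 : c + 2] = 220  # one interior 3-px bright blob
        geom = geometry(mask, image=image)
        shape = M.shape_features(geom)
        assert shape["holes"] == 1
        flat = M.shape_features(geometry(mask, image=np.full(mask.shape + (3,), 100, np.uint8)))
        assert flat["holes"] == 0

    def test_fractal_dimension_increases_with_roughness(self):
        # Direct box-count oracle on generated chains: rough boundaries
        # occupy more small boxes relative to large ones.
        means = {}
        for rough in (0.0, 0.3):
            fds = []
            for s in range(50):
                poly = make_boundary(30, rough, seed=1000 + s)
                side = 91
                rr, cc = draw_polygon(
                    poly[:, 1] + 45, poly[:, 0] + 45, shape=(side, side)
                )
                msk = np.zeros((side, side), bool)
                msk[rr, cc] = True
                fds.append(
                    M.box_counting_dimension(geometry(msk).boundary)
                )
            means[rough] = np.mean(fds)
        assert means[0.3] > means[0.0]

    def test_fractal_dimension_monotone_in_roughness(self):
        means = []
        for rough in (0.0, 0.1, 0.2, 0.3):
            fds = []
            for s in range(50):
                poly = make_boundary(30, rough, seed=1000 + s)
                side = 91
                rr, cc = draw_polygon(
                    poly[:, 1] + 45, poly[:, 0] + 45, shape=(side, side)
                )
                msk = np.zeros((side, side), bool)
                msk[rr, cc] = True
                fds.append(M.box_counting_dimension(geometry(msk).boundary))
            means.append(np.mean(fds))
        assert all(b >= a for a, b in zip(means, means[1:])), means

    def test_short_boundary_flagged_missing(self):
        mask = disk_mask(3)  # bbox 7 -> fewer than 4 scales
        shape = M.shape_features(geometry(mask))
        assert math.isnan(shape["fractal_dimension"])


class TestIntensityFeatures:
    def test_uniform_field(self, disk10_scene):
        geom = M.extract_geometry(disk10_scene, 1)
        feats = M.intensity_features(disk10_scene, geom)
        assert feats["gray_mean"] == feats["gray_min"] == feats["gray_max"] == 100
        assert feats["gray_std"] == 0
        assert feats["od_mean"] == 156
        assert feats["iod"] == pytest.approx(156 * geom.area_px * PSZ**2)
        assert feats["gray_sum"] == pytest.approx(100 * geom.area_px)

    def test_channel_means(self):
        mask = disk_mask(8)
        image = np.zeros(mask.shape + (3,), np.uint8)
        image[:, :, 0] = 150
        image[:, :, 1] = 90
        image[:, :, 2] = 120
        scene = scene_from_mask(mask, image=image)
        geom = M.extract_geometry(scene, 1)
        feats = M.intensity_features(scene, geom)
        assert feats["gray_red"] == 150
        assert feats["gray_green"] == 90
        assert feats["gray_blue"] == 120
        assert feats["gray_mean"] == pytest.approx(120)


class TestTextureFeatures:
    def test_uniform_nucleus(self, disk30_scene):
        geom = M.extract_geometry(disk30_scene, 1)
        feats = M.texture_features(disk30_scene, geom)
        assert feats["heterogeneity"] == 0
        assert feats["clumpiness"] == 0
        assert feats["margination"] == pytest.approx(1 / 3)

    def test_margination_peripheral_doubling(self):
        # OD doubled exactly on the measured peripheral band (outer third of
        # the radius): closed form (2m) / (3 * (14/9) m) = 3/7, checked
        # against a direct pixel-sum oracle with analytic band membership.
        radius = 30
        mask = disk_mask(radius)
        c = mask.shape[0] // 2
        yy, xx = np.mgrid[0 : mask.shape[0], 0 : mask.shape[1]]
        dist = np.hypot(yy - c, xx - c)
        band = mask & (dist >= (2 / 3) * (radius + 0.5))
        image = np.zeros(mask.shape + (3,), np.uint8)
        image[mask] = 256 - 60  # OD 60 inside
        image[band] = 256 - 120  # OD doubled on the band
        scene = scene_from_mask(mask, image=image)
        geom = M.extract_geometry(scene, 1)
        feats = M.texture_features(scene, geom)
        od = 256.0 - image[:, :, 0].astype(float)
        oracle = od[band].mean() / (3 * od[mask].mean())
        assert feats["margination"] == pytest.approx(oracle, abs=0.01)
        assert feats["margination"] == pytest.approx(3 / 7, abs=0.02)

    def test_heterogeneity_and_clumpiness(self):
        mask = disk_mask(12)
        image = np.full(mask.shape + (3,), 100, np.uint8)
        c = mask.shape[0] // 2
        image[c - 2 : c + 2, c - 2 : c + 2] = 140  # one 4x4 deviant clump
        scene = scene_from_mask(mask, image=image)
        geom = M.extract_geometry(scene, 1)
        feats = M.texture_features(scene, geom)
        n_px = geom.area_px
        assert feats["heterogeneity"] == pytest.approx(16 / n_px)
        assert 0 < feats["clumpiness"] <= 1  # interior of the clump survives
        # Isolated single deviants are erased by majority erosion.
        image2 = np.full(mask.shape + (3,), 100, np.uint8)
        for dr, dc in [(-5, -5), (5, 5), (-5, 5), (5, -5)]:
            image2[c + dr, c + dc] = 140
        scene2 = scene_from_mask(mask, image=image2)
        feats2 = M.texture_features(scene2, M.extract_geometry(scene2, 1))
        assert feats2["clumpiness"] == 0

    def test_small_nucleus_flagged(self):
        mask = disk_mask(3)  # 29 px < 30 px texture minimum
        scene = scene_from_mask(mask)
        feats = M.texture_features(scene, M.extract_geometry(scene, 1))
        assert all(math.isnan(v) for v in feats.values())


class TestExtractTable:
    def test_table_shape_invariants_and_determinism(self):
        from nucleomorph.synth import CohortSpec, generate_cohort

        spec = CohortSpec(
            n_samples_per_grade=(1, 1, 1), nuclei_per_sample=5,
            seed=8, image_size=256,
        )
        cohort = generate_cohort(spec)
        table = M.extract_table(cohort)
        assert len(table) == 15
        assert list(table.columns[:3]) == ["sample_id", "nucleus_id", "grade_group"]
        assert list(table.columns[3:]) == M.FEATURE_COLUMNS
        assert not table.duplicated(["sample_id", "nucleus_id"]).any()
        # Descriptor-vector invariants.
        assert (table["radius_min"] <= table["radius_max"]).all()
        assert (table["diameter_min"] <= table["diameter_mean"]).all()
        assert (table["diameter_mean"] <= table["diameter_max"]).all()
        assert (table["gray_min"] <= table["gray_mean"]).all()
        assert (table["gray_mean"] <= table["gray_max"]).all()
        assert (table["nuclear_area"] > 0).all()
        assert (table["radius_ratio"] >= 1).all()
        assert (table["aspect"] >= 1).all()
        fd = table["fractal_dimension"].dropna()
        assert fd.between(1, 2).all()
        assert table["heterogeneity"].dropna().between(0, 1).all()
        assert (table["area_per_box"] > 0).all() and (table["area_per_box"] <= 1).all()
        again = M.extract_table(cohort)
        assert table.equals(again)

    def test_grade_ordering_of_mean_area(self):
        from nucleomorph.synth import CohortSpec, generate_cohort

        spec = CohortSpec(
            n_samples_per_grade=(6, 6, 6), nuclei_per_sample=40,
            seed=21, image_size=640,
        )
        table = M.extract_table(generate_cohort(spec))
        means = table.groupby("grade_group")["nuclear_area"].mean()
        assert means["G13"] < means["G4"] < means["G5"]
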