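"""Cell axes, circularity, marker scores, positivity, 3-D counts, budding."""

import warnings

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Polygon as ShapelyPolygon

from organoquant.morphometrics import (
    classify_budding,
    count_nuclei_3d,
    measure_cell_axes,
    nucleus_circularity,
    per_cell_marker_intensity,
    positive_fraction_2d,
)
from organoquant.segmentation import LabelMap
from organoquant.synthetic import ellipse_polygon, generate_positivity_scene


def seg_row(cell, role, x0, y0, x1, y1, excluded=False):
    return {"image": "img", "cell_id": cell, "role": role,
            "x0": x0, "y0": y0, "x1": x1, "y1": y1, "excluded": excluded}


class TestCellAxes:
    def test_segment_length_times_pixel_size(self):
        ann = pd.DataFrame([seg_row(0, "lateral", 0, 0, 0, 30)])
        out = measure_cell_axes(ann, pixel_size=1.0)
        assert out.loc[0, "lateral_um"] == 30.0

    def test_length_width_ratio(self):
        ann = pd.DataFrame([
            seg_row(0, "lateral", 0, 0, 0, 30),
            seg_row(0, "width", 0, 0, 10, 0),
        ])
        out = measure_cell_axes(ann, pixel_size=0.5)
        assert out.loc[0, "length_width"] == pytest.approx(3.0)

    def test_excluded_cell_absent_and_logged(self, caplog):
        import logging

        ann = pd.DataFrame([
            seg_row(0, "lateral", 0, 0, 0, 10),
            seg_row(1, "lateral", 0, 0, 0, 10, excluded=True),
        ])
        with caplog.at_level(logging.INFO):
            out = measure_cell_axes(ann, pixel_size=1.0)
        assert list(out["cell_id"]) == [0]
        assert any("excluding" in m for m in caplog.messages)

    def test_missing_role_yields_nan_statistic(self):
        ann = pd.DataFrame([seg_row(0, "lateral", 0, 0, 0, 10)])
        out = measure_cell_axes(ann, pixel_size=1.0)
        assert np.isnan(out.loc[0, "apical_um"])
        assert np.isnan(out.loc[0, "length_width"])


class TestCircularity:
    def test_regular_64_gon_near_one(self):
        poly = ellipse_polygon((0, 0), (50, 50), n_vertices=64)
        assert nucleus_circularity(poly) >= 0.995

    def test_ellipse_matches_shapely_oracle(self):
        """2:1 ellipse polygon against an independent area/perimeter oracle."""
        poly = ellipse_polygon((5, 7), (40, 20), angle=0.3, n_vertices=256)
        sh = ShapelyPolygon(poly)
        expected = 4 * np.pi * sh.area / sh.length**2
        assert nucleus_circularity(poly) == pytest.approx(expected, rel=1e-12)

    def test_rotation_and_scale_invariance(self):
        poly = ellipse_polygon((0, 0), (30, 12), n_vertices=128)
        base = nucleus_circularity(poly)
        for angle, scale in [(0.7, 2.5), (2.1, 0.3)]:
            rot = np.array([[np.cos(angle), -np.sin(angle)],
                            [np.sin(angle), np.cos(angle)]])
            assert nucleus_circularity(scale * poly @ rot.T) == pytest.approx(
                base, abs=1e-9)

    def test_degenerate_sliver_approaches_zero(self):
        t = np.linspace(0, 2 * np.pi, 64, endpoint=False)
        poly = np.column_stack([50 * np.cos(t), 1e-3 * np.sin(t)])
        assert 0 < nucleus_circularity(poly) < 1e-3

    def test_self_intersecting_rejected_naming_edges(self):
        bowtie = np.array([[0, 0], [10, 10], [10, 0], [0, 10],
                           [0, 5], [0, 4], [0, 3], [0, 2]], dtype=float)
        with pytest.raises(ValueError, match="edges"):
            nucleus_circularity(bowtie)

    def test_too_few_vertices_rejected(self):
        with pytest.raises(ValueError, match=">= 8 vertices"):
            nucleus_circularity(np.array([[0, 0], [1, 0], [0, 1]], dtype=float))

    def test_mask_branch_disk_close_to_one(self):
        rr, cc = np.mgrid[0:101, 0:101]
        disk = (rr - 50) ** 2 + (cc - 50) ** 2 <= 40**2
        assert 0.95 <= nucleus_circularity(disk) <= 1.02


class TestMarkerIntensity:
    @staticmethod
    def masks():
        nuc = np.zeros((20, 20), dtype=np.int32)
        ring = np.zeros_like(nuc)
        nuc[4:8, 4:8] = 1
        ring[4:8, 9:12] = 1
        nuc[12:16, 4:8] = 2
        ring[12:16, 9:12] = 2
        return LabelMap(nuc), LabelMap(ring)

    def test_uniform_image_scores_twice_value(self):
        nuc, ring = self.masks()
        out = per_cell_marker_intensity(np.full((20, 20), 7.0), nuc, ring)
        assert np.allclose(out["per_cell_intensity"], 14.0)

    def test_nuclear_confined_marker(self):
        nuc, ring = self.masks()
        img = np.where(nuc.labels > 0, 5.0, 0.0)
        out = per_cell_marker_intensity(img, nuc, ring)
        assert np.allclose(out["per_cell_intensity"], 5.0)

    def test_missing_ring_flagged_nuclear_only(self):
        nuc, _ = self.masks()
        out = per_cell_marker_intensity(np.full((20, 20), 3.0), nuc,
                                        LabelMap(np.zeros((20, 20), dtype=np.int32)))
        assert out["ring_missing"].all()
        assert np.allclose(out["per_cell_intensity"], 3.0)

    def test_graded_marker_preserves_rank_order(self):
        rng = np.random.default_rng(4)
        nuc = np.zeros((20, 500), dtype=np.int32)
        ring = np.zeros_like(nuc)
        levels = rng.permutation(50) + 1.0
        img = np.zeros((20, 500))
        for k in range(50):
            c = 10 * k
            nuc[4:8, c + 2 : c + 6] = k + 1
            ring[4:8, c + 6 : c + 9] = k + 1
            img[:, c : c + 10] = levels[k]
        out = per_cell_marker_intensity(img, LabelMap(nuc), LabelMap(ring))
        assert np.array_equal(np.argsort(out["per_cell_intensity"]), np.argsort(levels))


class TestPositivity:
    @staticmethod
    def labelled_scene(n, fraction, seed=0, noise=0.0):
        from organoquant.segmentation import SegmentationParams, segment_nuclei

        dye, marker, truth = generate_positivity_scene(n, fraction, seed=seed,
                                                       noise_sd=noise)
        nuclei = segment_nuclei(dye, SegmentationParams(smoothing_sigma=0))
        return marker, nuclei, truth

    def test_zero_fraction_scores_zero(self):
        marker, nuclei, _ = self.labelled_scene(50, 0.0)
        res = positive_fraction_2d(marker, nuclei, threshold=100.0)
        assert (res.positives, res.total, res.fraction) == (0, 50, 0.0)

    def test_clean_separation_exact_count(self):
        marker, nuclei, truth = self.labelled_scene(200, 0.35, seed=3)
        res = positive_fraction_2d(marker, nuclei)
        assert (res.positives, res.total) == (70, 200)
        assert res.fraction == pytest.approx(0.35)

    def test_no_nuclei_fraction_missing(self):
        res = positive_fraction_2d(np.ones((8, 8)), np.zeros((8, 8), dtype=np.int32))
        assert res.total == 0 and np.isnan(res.fraction)

    def test_monotone_transform_invariance_with_otsu(self):
        marker, nuclei, _ = self.labelled_scene(100, 0.4, seed=1)
        r1 = positive_fraction_2d(marker, nuclei)
        r2 = positive_fraction_2d(np.sqrt(marker) * 3 + 5, nuclei)
        assert r1.positives == r2.positives

    def test_overlapping_distributions_small_mean_error(self):
        """d'=2 class overlap, Otsu-on-means rule, 200 nuclei per scene:
        mean |fraction error| over 100 simulated scenes stays < 0.05."""
        rng = np.random.default_rng(0)
        n = 200
        nuc = np.zeros((20, 10 * n), dtype=np.int32)
        for k in range(n):
            nuc[5:15, 10 * k + 2 : 10 * k + 8] = k + 1
        errs = []
        for _ in range(100):
            pos = rng.random(n) < 0.5
            means = np.where(pos, rng.normal(200, 25, n), rng.normal(150, 25, n))
            img = means[np.clip(nuc - 1, 0, None)] * (nuc > 0)
            res = positive_fraction_2d(img, LabelMap(nuc))
            errs.append(abs(res.fraction - pos.mean()))
        assert np.mean(errs) < 0.05


class TestCount3D:
    @staticmethod
    def spheres(centers, radius, shape):
        zz, yy, xx = np.mgrid[0 : shape[0], 0 : shape[1], 0 : shape[2]]
        vol = np.zeros(shape)
        for z0, y0, x0 in centers:
            vol[(zz - z0) ** 2 + (yy - y0) ** 2 + (xx - x0) ** 2 <= radius**2] = 1000.0
        return vol

    def test_disjoint_spheres_counted(self):
        centers = [(8, 10 + 14 * i, 10 + 14 * j) for i in range(2) for j in range(5)]
        vol = self.spheres(centers, 4, (16, 40, 80))
        assert count_nuclei_3d(vol, threshold=10).total == 10

    def test_touching_spheres_split_by_watershed(self):
        vol = self.spheres([(10, 10, 8), (10, 10, 17)], 4, (20, 20, 26))
        res = count_nuclei_3d(vol, threshold=10, watershed_split=True)
        assert res.total == 2

    def test_empty_volume_zero(self):
        assert count_nuclei_3d(np.zeros((4, 8, 8)), threshold=10).total == 0

    def test_single_plane_falls_back_with_warning(self):
        vol = self.spheres([(0, 10, 10)], 4, (1, 24, 24))
        with pytest.warns(UserWarning, match="single-plane"):
            res = count_nuclei_3d(vol, threshold=10, min_volume=5)
        assert res.total == 1

    def test_2d_and_3d_agree_on_single_plane(self):
        from organoquant.segmentation import SegmentationParams, segment_nuclei

        dye, marker, truth = generate_positivity_scene(25, 0.4, seed=2)
        nuclei = segment_nuclei(dye, SegmentationParams(smoothing_sigma=0))
        res2d = positive_fraction_2d(marker, nuclei)
        with pytest.warns(UserWarning):
            res3d = count_nuclei_3d(dye[None], marker=marker[None], threshold=10,
                                    min_volume=20)
        assert res3d.total == res2d.total == 25
        assert res3d.positives == res2d.positives

    def test_marker_positive_subset(self):
        centers = [(8, 10, 10 + 14 * j) for j in range(4)]
        vol = self.spheres(centers, 4, (16, 20, 60))
        marker = np.zeros_like(vol)
        marker[:, :, :20] = 500.0  # first sphere positive
        res = count_nuclei_3d(vol, marker=marker, threshold=10, marker_threshold=100)
        assert (res.total, res.positives) == (4, 1)


class TestBudding:
    def test_generated_disk_is_spherical(self):
        from organoquant.synthetic import generate_silhouette

        label, sol = classify_budding(generate_silhouette("spherical", size=60)[0])
        assert label == "spherical" and sol > 0.97

    def test_generated_four_lobe_is_budding(self):
        from organoquant.synthetic import generate_silhouette

        label, sol = classify_budding(
            generate_silhouette("budding", size=60, n_lobes=4, seed=1)[0])
        assert label == "budding" and sol < 0.92

    def test_manual_label_overrides_but_solidity_reported(self):
        from organoquant.synthetic import generate_silhouette

        mask, _ = generate_silhouette("spherical", size=40)
        label, sol = classify_budding(mask, manual_label="budding")
        assert label == "budding" and sol > 0.97

    def test_disconnected_mask_uses_largest_component(self):
        mask = np.zeros((60, 120), dtype=bool)
        rr, cc = np.mgrid[0:60, 0:120]
        mask[(rr - 30) ** 2 + (cc - 30) ** 2 <= 20**2] = True
        mask[(rr - 30) ** 2 + (cc - 90) ** 2 <= 5**2] = True
        with pytest.warns(UserWarning, match="disconnected"):
            label, sol = classify_budding(mask)
        assert label == "spherical"
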