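import numpy as np
import pytest
from shapely.geometry import Point, box

from morphomsi import fixtures
from morphomsi.annotations import AnnotationSet
from morphomsi.classifier import Detection, DetectionSet
from morphomsi.registration import AffineTransform2D
from morphomsi.rois import (ROISet, build_roi_types, dearray, mark_valid,
                            tile_to_msi, tiles_as_polygons, transfer_labels)
from morphomsi.spectra import MSIDataset


IDENT_UM = AffineTransform2D.identity()   # detections already in μm


def det(geometry, label=None, px=1.0):
    return DetectionSet([Detection(geometry, "cell_rich", geometry.area * px * px,
                                   label=label)], px)


class TestROISet:
    def test_overlapping_labels_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            ROISet("PC", {"PTC": {(0, 0)}, "FA": {(0, 0), (1, 1)}})

    def test_unknown_type_rejected(self):
        with pytest.raises(ValueError, match="roi_type"):
            ROISet("XX")


class TestDearray:
    def test_fixture_centers_recovered(self, tiny_phantom, tiny_scene):
        grid = dearray(tiny_scene.image, tiny_phantom.image_px_size_um, 1, 1)
        assert len(grid) == 1
        core = grid.cores[0]
        planted_px = np.array(tiny_phantom.cores[0].center_um) / tiny_phantom.image_px_size_um
        assert np.linalg.norm(np.array(core.center_px) - planted_px) < 2.0
        assert core.row_label == "A" and core.col_label == "1"

    def test_blank_image_rejected(self):
        blank = np.full((100, 100, 3), 250, dtype=np.uint8)
        with pytest.raises(ValueError, match="no tissue"):
            dearray(blank, 0.44, 1, 1)

    def test_center_override_applied_verbatim(self, tiny_phantom, tiny_scene):
        grid = dearray(tiny_scene.image, tiny_phantom.image_px_size_um, 1, 1,
                       center_overrides={"A1": (42.0, 43.0)})
        assert grid.cores[0].center_px == (42.0, 43.0)

    def test_unexpected_grid_size_warns(self, tiny_phantom, tiny_scene):
        with pytest.warns(UserWarning, match="differs from expected"):
            grid = dearray(tiny_scene.image, tiny_phantom.image_px_size_um, 2, 2)
        assert not grid.grid_matches_expected


class TestTransferLabels:
    def test_containment_labels_directly(self):
        pat = AnnotationSet()
        pat.add(box(0, 0, 100, 100), "PTC")
        out = transfer_labels(det(box(10, 10, 20, 20)), pat)
        assert len(out) == 1
        assert out.detections[0].label == "PTC"

    def test_straddling_detection_split_in_area_ratio(self):
        pat = AnnotationSet()
        pat.add(box(0, 0, 70, 100), "PTC")      # covers 70% of the detection
        pat.add(box(70, 0, 200, 100), "normal")
        out = transfer_labels(det(box(0, 0, 100, 50)), pat)
        areas = {d.label: d.geometry.area for d in out}
        assert set(areas) == {"PTC", "normal"}
        assert areas["PTC"] / areas["normal"] == pytest.approx(70 / 30, rel=1e-6)

    def test_detection_outside_annotations_dropped(self):
        pat = AnnotationSet()
        pat.add(box(0, 0, 10, 10), "PTC")
        out = transfer_labels(det(box(50, 50, 60, 60)), pat)
        assert len(out) == 0

    def test_empty_annotations_drop_all_with_warning(self):
        with pytest.warns(UserWarning, match="empty"):
            out = transfer_labels(det(box(0, 0, 5, 5)), AnnotationSet())
        assert len(out) == 0

    def test_exact_tie_goes_to_lexicographically_smaller(self):
        pat = AnnotationSet()
        pat.add(box(0, 0, 10, 10), "PTC")
        pat.add(box(0, 0, 10, 10), "FA")    # identical overlapping annotations
        out = transfer_labels(det(box(2, 2, 8, 8)), pat)
        assert {d.label for d in out} == {"FA"}


class TestTileToMsi:
    def test_exact_grid_cell_gives_one_spot(self):
        cell = box(40.0, 60.0, 60.0, 80.0)   # the (2, 3) cell
        roi = tile_to_msi(det(cell, label="PTC"), IDENT_UM, pitch_um=20.0, buffer_um=0.0)
        assert roi.entries == {"PTC": {(2, 3)}}

    def test_circle_matches_bruteforce_center_count(self):
        circle = Point(110.0, 90.0).buffer(50.0, 256)
        roi = tile_to_msi(det(circle, label="FA"), IDENT_UM, pitch_um=20.0, buffer_um=0.0)
        # independent enumeration of grid centers inside the circle
        count = 0
        for i in range(0, 20):
            for j in range(0, 20):
                cx, cy = (i + 0.5) * 20.0, (j + 0.5) * 20.0
                if (cx - 110.0) ** 2 + (cy - 90.0) ** 2 < 50.0 ** 2:
                    count += 1
        assert roi.n_spots() == count

    def test_empty_detections_empty_roi(self):
        roi = tile_to_msi(DetectionSet([], 1.0), IDENT_UM)
        assert roi.n_spots() == 0

    def test_degenerate_transform_rejected(self):
        with pytest.raises(ValueError):
            AffineTransform2D(np.zeros((2, 2)), np.zeros(2))

    def test_restriction_to_measured_spots(self):
        cell = box(0.0, 0.0, 60.0, 20.0)     # spots (0,0),(1,0),(2,0)
        ds = MSIDataset(np.array([[0, 0], [2, 0]]), np.array([700.0, 701.0]),
                        np.ones((2, 2)))
        roi = tile_to_msi(det(cell, label="x"), IDENT_UM, buffer_um=0.0, msi=ds)
        assert roi.entries["x"] == {(0, 0), (2, 0)}

    def test_tiles_export_merges_squares(self):
        roi = ROISet("PC", {"PTC": {(0, 0), (1, 0)}})
        anns = tiles_as_polygons(roi, pitch_um=20.0)
        assert len(anns) == 1
        geom = anns.annotations[0].geometry
        assert geom.area == pytest.approx(2 * 400.0)


@pytest.fixture(scope="module")
def tiny_pipeline(tiny_phantom, tiny_scene, tiny_model, tiny_cube):
    ds, gt = tiny_cube
    grid = dearray(tiny_scene.image, tiny_phantom.image_px_size_um, 1, 1)
    return grid, ds, gt


class TestBuildRoiTypes:
    def test_pat_equals_fc_when_polygons_are_core_circles(self, tiny_phantom, tiny_pipeline):
        grid, ds, _ = tiny_pipeline
        px = tiny_phantom.image_px_size_um
        core = tiny_phantom.cores[0]
        pat = AnnotationSet(provenance="pathologist")
        pat.add(Point(np.array(core.center_um) / px).buffer(core.radius_um / px, 256),
                core.diagnosis_label)
        rois = build_roi_types(grid, pat, DetectionSet([], px),
                               tiny_phantom.planted_transform, ds)
        assert rois["PAT"].all_spots() == rois["FC"].all_spots()

    def test_fc_count_matches_grid_in_circle(self, tiny_phantom, tiny_pipeline):
        grid, ds, _ = tiny_pipeline
        pat = AnnotationSet()
        px = tiny_phantom.image_px_size_um
        core = tiny_phantom.cores[0]
        pat.add(Point(np.array(core.center_um) / px).buffer(core.radius_um / px, 64),
                core.diagnosis_label)
        rois = build_roi_types(grid, pat, DetectionSet([], px),
                               tiny_phantom.planted_transform, ds)
        # oracle: measured spot centers within the detected core circle
        t = tiny_phantom.planted_transform
        c_um = t.apply(np.array(grid.cores[0].center_px))
        r_um = grid.cores[0].radius_px * px
        centers = ds.spot_centers_um()
        expect = int(np.sum(np.sum((centers - c_um) ** 2, axis=1) <= r_um ** 2))
        assert rois["FC"].n_spots() == expect

    def test_pc_subset_of_fc(self, tiny_phantom, tiny_scene, tiny_pipeline):
        grid, ds, _ = tiny_pipeline
        # detections: the true rim mask polygons
        from morphomsi.classifier import vectorize_mask
        dets = vectorize_mask(tiny_scene.masks["cell_rich"],
                              tiny_phantom.image_px_size_um)
        labeled = transfer_labels(dets, tiny_scene.pathologist)
        rois = build_roi_types(grid, tiny_scene.pathologist, labeled,
                               tiny_phantom.planted_transform, ds)
        assert rois["PC"].all_spots() <= rois["FC"].all_spots()

    def test_no_valid_cores_rejected(self, tiny_phantom, tiny_pipeline):
        grid, ds, _ = tiny_pipeline
        far = AffineTransform2D(tiny_phantom.planted_transform.linear,
                                np.array([1e6, 1e6]))
        with pytest.raises(ValueError, match="valid cores"):
            build_roi_types(grid, AnnotationSet(), DetectionSet([], 0.44), far, ds)

    def test_mark_valid_flags_cores_with_spots(self, tiny_phantom, tiny_pipeline):
        grid, ds, _ = tiny_pipeline
        mark_valid(grid, tiny_phantom.planted_transform, ds)
        assert grid.cores[0].valid
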