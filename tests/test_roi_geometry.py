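import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sgrt_autoroi.errors import (DegenerateGeometryError, InvalidInputError,
                                 InvalidParameterError)
from sgrt_autoroi.roi import (BodySilhouette, BreastContour, GridSpec,
                              ROIRegion, ShiftConfig, build_roi, chest_width,
                              generate_aroi_body, generate_aroi_breast,
                              rasterize, si_bounds_from_breast,
                              si_bounds_from_joints, silhouette_from_polygon)

from conftest import brute_force_rasterize, rect_silhouette

CFG = ShiftConfig()
JOINTS = {"LeftCollar": (45.0, 40.0, 1400.0), "RightCollar": (-45.0, 40.0, 1400.0),
          "Spine2": (0.0, 0.0, 1150.0)}


class TestSIBounds:
    def test_joint_bounds_with_default_shifts(self):
        assert si_bounds_from_joints(JOINTS, CFG) == (1410.0, 1120.0)

    def test_zero_shifts_reproduce_joint_coordinates(self):
        cfg = ShiftConfig(upper_shift_mm=0.0, lower_shift_mm=0.0)
        assert si_bounds_from_joints(JOINTS, cfg) == (1400.0, 1150.0)

    def test_collar_aggregation_uses_mean(self):
        joints = dict(JOINTS, LeftCollar=(45.0, 40.0, 1410.0),
                      RightCollar=(-45.0, 40.0, 1390.0))
        assert si_bounds_from_joints(joints, CFG)[0] == 1410.0

    @settings(derandomize=True, max_examples=25)
    @given(delta=st.floats(-500, 500))
    def test_translation_equivariance(self, delta):
        shifted = {k: (v[0], v[1], v[2] + delta) for k, v in JOINTS.items()}
        u0, l0 = si_bounds_from_joints(JOINTS, CFG)
        u1, l1 = si_bounds_from_joints(shifted, CFG)
        assert u1 == pytest.approx(u0 + delta)
        assert l1 == pytest.approx(l0 + delta)

    def test_missing_joint_rejected(self):
        with pytest.raises(InvalidInputError):
            si_bounds_from_joints({"LeftCollar": (0, 0, 1400)}, CFG)

    def test_inverted_bounds_rejected(self):
        joints = dict(JOINTS, Spine2=(0.0, 0.0, 1500.0))
        with pytest.raises(DegenerateGeometryError):
            si_bounds_from_joints(joints, CFG)

    def test_breast_eval_extensions(self):
        contour = BreastContour(1300.0, 1150.0, "left", "breast_eval")
        assert si_bounds_from_breast(contour, CFG) == (1327.0, 1138.0)

    def test_ptv_extensions_negative_superior(self):
        contour = BreastContour(1350.0, 1150.0, "left", "PTV")
        assert si_bounds_from_breast(contour, CFG) == (1326.0, 1133.0)

    def test_zero_extensions_reproduce_contour(self):
        cfg = ShiftConfig(breast_eval_sup_mm=0.0, breast_eval_inf_mm=0.0)
        contour = BreastContour(1300.0, 1150.0, "left", "breast_eval")
        assert si_bounds_from_breast(contour, cfg) == (1300.0, 1150.0)


class TestChestWidth:
    def test_rectangle_width_independent_of_bounds(self):
        sil = rect_silhouette(width_mm=300.0)
        for upper, lower in [(1400, 1100), (1300, 1000), (1450, 950)]:
            assert chest_width(sil, upper, lower).width_mm == pytest.approx(300.0)

    def test_trapezoid_width_matches_closed_form(self):
        # half-width grows linearly from 50 mm at z=1000 to 150 mm at z=1400
        poly = [[-50, 1000], [50, 1000], [150, 1400], [-150, 1400]]
        sil = silhouette_from_polygon(poly, spacing_mm=0.5)
        upper, lower = 1380.0, 1020.0
        mid = 0.5 * (upper + lower)  # 1200 -> half-width 100
        expected = 2 * (50 + 100 * (mid - 1000) / 400)
        assert chest_width(sil, upper, lower).width_mm == pytest.approx(expected, abs=1.0)

    def test_width_equals_pixel_count_oracle(self):
        sil = rect_silhouette(width_mm=220.0, spacing=2.0)
        cw = chest_width(sil, 1400.0, 1100.0)
        row = sil.row_for_z(1250.0)
        assert cw.width_mm == pytest.approx(sil.mask[row].sum() * sil.spacing_mm)

    def test_empty_midline_row_rejected(self):
        sil = rect_silhouette(z_lo=900.0, z_hi=1500.0)
        with pytest.raises(DegenerateGeometryError):
            chest_width(sil, 2500.0, 2100.0)


class TestBuildROI:
    def test_lateral_extent_is_three_quarters_of_width(self):
        sil = rect_silhouette(width_mm=320.0)
        cw = chest_width(sil, 1400.0, 1100.0)
        roi = build_roi(1400.0, 1100.0, cw, "left", CFG)
        x_min, _, x_max, _ = roi.bounds()
        assert x_max - x_min == pytest.approx(240.0)
        assert x_max == pytest.approx(cw.x_max_mm)  # anchored at ipsilateral edge

    def test_zero_retraction_gives_plain_rectangle(self):
        cfg = ShiftConfig(retraction_mm=0.0)
        cw = chest_width(rect_silhouette(), 1400.0, 1100.0)
        roi = build_roi(1400.0, 1100.0, cw, "left", cfg)
        assert len(roi.polygon) == 4

    def test_chamfer_removes_half_square_triangle(self):
        cw = chest_width(rect_silhouette(width_mm=320.0), 1400.0, 1100.0)
        rect = build_roi(1400.0, 1100.0, cw, "left", ShiftConfig(retraction_mm=0.0))
        chamfered = build_roi(1400.0, 1100.0, cw, "left", CFG)
        assert len(chamfered.polygon) == 5
        assert rect.area_mm2() - chamfered.area_mm2() == pytest.approx(80.0 ** 2 / 2)

    def test_chamfer_points_lie_on_rectangle_edges(self):
        cw = chest_width(rect_silhouette(width_mm=320.0), 1400.0, 1100.0)
        roi = build_roi(1400.0, 1100.0, cw, "left", CFG)
        lm = roi.landmarks
        assert lm["chamfer_side_x"] == pytest.approx(lm["x_ipsi"])
        assert lm["chamfer_side_z"] == pytest.approx(lm["upper_z"] - 80.0)
        assert lm["chamfer_top_x"] == pytest.approx(lm["x_ipsi"] - 80.0)
        assert lm["chamfer_top_z"] == pytest.approx(lm["upper_z"])

    def test_oversized_retraction_falls_back_to_rectangle(self):
        cfg = ShiftConfig(retraction_mm=500.0)
        cw = chest_width(rect_silhouette(width_mm=320.0), 1400.0, 1100.0)
        with pytest.warns(UserWarning):
            roi = build_roi(1400.0, 1100.0, cw, "left", cfg)
        assert len(roi.polygon) == 4

    def test_landmarks_rebuild_polygon_exactly(self):
        for laterality in ("left", "right"):
            cw = chest_width(rect_silhouette(width_mm=320.0), 1400.0, 1100.0)
            roi = build_roi(1400.0, 1100.0, cw, laterality, CFG)
            lm = roi.landmarks
            rebuilt = ROIRegion.from_landmarks(lm["upper_z"], lm["lower_z"],
                                               lm["x_ipsi"], lm["x_contra"],
                                               laterality, lm["retraction_mm"])
            np.testing.assert_array_equal(roi.polygon, rebuilt.polygon)

    def test_upper_shift_monotonically_grows_area(self):
        sil = rect_silhouette(width_mm=320.0)
        areas = []
        for upper_shift in (0.0, 10.0, 20.0, 30.0):
            cfg = ShiftConfig(upper_shift_mm=upper_shift)
            roi = generate_aroi_body(sil, joints=JOINTS, cfg=cfg)
            areas.append(roi.area_mm2())
        assert np.all(np.diff(areas) > 0)

    def test_retraction_monotonically_shrinks_area(self):
        sil = rect_silhouette(width_mm=320.0)
        areas = []
        for retraction in (0.0, 40.0, 80.0, 120.0):
            cfg = ShiftConfig(retraction_mm=retraction)
            roi = generate_aroi_body(sil, joints=JOINTS, cfg=cfg)
            areas.append(roi.area_mm2())
        assert np.all(np.diff(areas) < 0)

    def test_invalid_laterality_and_fraction(self):
        cw = chest_width(rect_silhouette(), 1400.0, 1100.0)
        with pytest.raises(InvalidParameterError):
            build_roi(1400.0, 1100.0, cw, "bilateral", CFG)
        with pytest.raises(InvalidParameterError):
            build_roi(1400.0, 1100.0, cw, "left", ShiftConfig(lr_fraction=0.0))


class TestMirror:
    def test_mirrored_inputs_give_mirrored_roi(self):
        sil = rect_silhouette(width_mm=300.0, x_center=20.0)
        left = generate_aroi_body(sil, joints=JOINTS, laterality="left", cfg=CFG)
        mirrored_joints = {k: (-v[0], v[1], v[2]) for k, v in JOINTS.items()}
        right = generate_aroi_body(sil.mirrored(), joints=mirrored_joints,
                                   laterality="right", cfg=CFG)
        flipped = right.polygon * np.array([-1.0, 1.0])
        assert left.shapely().symmetric_difference(
            ROIRegion(flipped, "left", "body").shapely()).area < 1e-6

    def test_mirror_through_breast_contour(self):
        sil = rect_silhouette(width_mm=300.0)
        c_left = BreastContour(1300.0, 1150.0, "left", "breast_eval")
        c_right = BreastContour(1300.0, 1150.0, "right", "breast_eval")
        left = generate_aroi_breast(sil, c_left, CFG)
        right = generate_aroi_breast(sil.mirrored(), c_right, CFG)
        flipped = right.polygon * np.array([-1.0, 1.0])
        assert left.shapely().symmetric_difference(
            ROIRegion(flipped, "left", "breast").shapely()).area < 1e-6


class TestRasterize:
    def test_square_pixel_count(self):
        roi = ROIRegion(polygon=np.array([[0.0, 0.0], [100.0, 0.0],
                                          [100.0, 100.0], [0.0, 100.0]]),
                        laterality="left", provenance="body")
        grid = GridSpec(x0_mm=0.0, z_top_mm=100.0, spacing_mm=1.0,
                        n_rows=100, n_cols=100)
        assert rasterize(roi, grid).sum() == 10_000

    def test_mask_area_close_to_polygon_area(self):
        cw = chest_width(rect_silhouette(width_mm=320.0), 1400.0, 1100.0)
        roi = build_roi(1400.0, 1100.0, cw, "left", CFG)
        grid = GridSpec.around([roi.bounds()], spacing_mm=1.0)
        mask = rasterize(roi, grid)
        assert mask.sum() == pytest.approx(roi.area_mm2(), rel=0.01)

    def test_polygon_outside_grid_rejected(self):
        roi = ROIRegion(polygon=np.array([[0.0, 0.0], [50.0, 0.0], [50.0, 50.0]]),
                        laterality="left", provenance="body")
        grid = GridSpec(x0_mm=100.0, z_top_mm=40.0, spacing_mm=1.0,
                        n_rows=10, n_cols=10)
        with pytest.raises(InvalidInputError):
            rasterize(roi, grid)

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_matches_brute_force_point_in_polygon(self, seed):
        rng = np.random.default_rng(seed)
        # random convex polygon from points on an ellipse
        angles = np.sort(rng.uniform(0, 2 * np.pi, rng.integers(3, 8)))
        pts = np.column_stack([17.3 * np.cos(angles) + 20.0,
                               13.7 * np.sin(angles) + 25.0])
        roi = ROIRegion(polygon=pts, laterality="left", provenance="body")
        grid = GridSpec(x0_mm=0.0, z_top_mm=45.0, spacing_mm=1.0,
                        n_rows=45, n_cols=45)
        np.testing.assert_array_equal(rasterize(roi, grid),
                                      brute_force_rasterize(pts, grid))


class TestContoursAndSilhouettes:
    def test_breast_contour_validation(self):
        with pytest.raises(InvalidInputError):
            BreastContour(1100.0, 1200.0, "left", "breast_eval")
        with pytest.raises(InvalidParameterError):
            BreastContour(1300.0, 1200.0, "up", "breast_eval")
        with pytest.raises(InvalidParameterError):
            BreastContour(1300.0, 1200.0, "left", "nodes")

    def test_silhouette_validation(self):
        sil = rect_silhouette()
        sil.validate()
        empty = BodySilhouette.from_mask(np.zeros((5, 5), bool), 1.0, 0.0, 5.0)
        with pytest.raises(InvalidInputError):
            empty.validate()
        split = np.zeros((5, 5), bool)
        split[0, 0] = split[4, 4] = True
        with pytest.raises(InvalidInputError):
            BodySilhouette.from_mask(split, 1.0, 0.0, 5.0).validate()

    def test_silhouette_from_body_is_single_component(self, scaled_body):
        sil = BodySilhouette.from_body(scaled_body)
        sil.validate()
        assert sil.mask.any()

    def test_roi_json_round_trip(self, tmp_path):
        cw = chest_width(rect_silhouette(width_mm=320.0), 1400.0, 1100.0)
        roi = build_roi(1400.0, 1100.0, cw, "left", CFG)
        path = tmp_path / "roi.json"
        roi.to_json(path)
        back = ROIRegion.from_json(path)
        np.testing.assert_allclose(back.polygon, roi.polygon)
        assert back.laterality == roi.laterality
        assert back.provenance == roi.provenance


def _write_rtstruct(path, structures):
    import pydicom
    from pydicom.dataset import Dataset, FileDataset, FileMetaDataset
    from pydicom.uid import ImplicitVRLittleEndian, generate_uid

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.UID("1.2.840.10008.5.1.4.1.1.481.3")
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ImplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTSTRUCT"
    ssr, rcs = [], []
    for number, (name, slices) in enumerate(structures.items(), start=1):
        item = Dataset()
        item.ROINumber = number
        item.ROIName = name
        item.ReferencedFrameOfReferenceUID = generate_uid()
        ssr.append(item)
        roi = Dataset()
        roi.ReferencedROINumber = number
        contours = []
        for z, pts in slices:
            c = Dataset()
            c.ContourGeometricType = "CLOSED_PLANAR"
            c.NumberOfContourPoints = len(pts)
            c.ContourData = [float(v) for x, y in pts for v in (x, y, z)]
            contours.append(c)
        roi.ContourSequence = contours
        rcs.append(roi)
    ds.StructureSetROISequence = ssr
    ds.ROIContourSequence = rcs
    ds.save_as(str(path), enforce_file_format=True)


class TestDicomIngestion:
    def test_breast_contour_extent_from_rtstruct(self, tmp_path):
        from sgrt_autoroi.roi import breast_contour_from_dicom
        square = [(-60, 0), (60, 0), (60, 80), (-60, 80)]
        slices = [(z, square) for z in (1150.0, 1200.0, 1250.0, 1300.0)]
        path = tmp_path / "rs.dcm"
        _write_rtstruct(path, {"Breast_L": slices})
        contour = breast_contour_from_dicom(path, "breast_l", "left", "breast_eval")
        assert contour.superior_z_mm == 1300.0
        assert contour.inferior_z_mm == 1150.0
        with pytest.raises(InvalidInputError):
            breast_contour_from_dicom(path, "Breast_R", "right")

    def test_body_silhouette_from_rtstruct(self, tmp_path):
        from sgrt_autoroi.roi import silhouette_from_dicom
        slices = [(z, [(-150, -80), (150, -80), (150, 80), (-150, 80)])
                  for z in np.arange(1000.0, 1404.0, 4.0)]
        path = tmp_path / "rs.dcm"
        _write_rtstruct(path, {"BODY": slices})
        sil = silhouette_from_dicom(path, "BODY", spacing_mm=2.0)
        sil.validate()
        cw = chest_width(sil, 1350.0, 1050.0)
        assert cw.width_mm == pytest.approx(300.0, abs=2 * sil.spacing_mm)
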