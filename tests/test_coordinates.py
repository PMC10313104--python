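"""Radial / circumferential / long-axis coordinate fields and their oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import analytic_polar, circular_abs_diff
from myoatlas import compute_coordinates, make_annulus_study
from myoatlas.coordinates import (CoordinateError, circumferential_coordinate,
                                  exclude_lvot, junction_angle_difference,
                                  longaxis_coordinate, radial_coordinate,
                                  slice_annotation_difference)


def annulus_mask(grid, endo, epi):
    half = (grid - 1) / 2
    rho, _ = analytic_polar(grid, 1)
    return (rho >= endo) & (rho <= epi)


# ---------------------------------------------------------------------------
# analytic annulus oracle
# ---------------------------------------------------------------------------

class TestAnalyticAnnulus:
    def test_fields_match_closed_form(self, annulus_study):
        cm = compute_coordinates(annulus_study, oversample=4)
        rho, theta = analytic_polar(64, 4)
        r_true = (rho - 10) / 10.0
        c_true = ((theta - np.pi / 2) % (2 * np.pi)) / (2 * np.pi)
        v = cm.valid[4]
        assert np.abs(cm.r[4][v] - r_true[v]).max() < 0.02
        assert circular_abs_diff(cm.c[4][v], c_true[v]).max() < 1 / 720

    def test_oversample_scales_grid(self, annulus_study):
        cm = compute_coordinates(annulus_study, oversample=4)
        assert cm.r.shape[1:] == (256, 256)
        assert cm.oversample == 4

    def test_c_increases_anticlockwise_from_junction(self, annulus_study):
        cm = compute_coordinates(annulus_study, oversample=2)
        rho, theta = analytic_polar(64, 2)
        v = cm.valid[0]
        # sort by analytic anticlockwise angle from the junction (at 90 deg)
        ang = ((theta - np.pi / 2) % (2 * np.pi))[v]
        order = np.argsort(ang)
        c_sorted = cm.c[0][v][order]
        assert (np.diff(c_sorted) >= -1e-9).all()

    def test_single_seam_on_junction_ray(self, annulus_study):
        cm = compute_coordinates(annulus_study, oversample=2)
        v = cm.valid[0]
        _, theta = analytic_polar(64, 2)
        away_from_seam = v & (circular_abs_diff(
            ((theta - np.pi / 2) % (2 * np.pi)) / (2 * np.pi), 0.0) > 0.02)
        c = cm.c[0]
        # along each row, jumps of ~1 only occur near the junction ray
        jumps = np.abs(np.diff(np.where(away_from_seam, c, np.nan), axis=1))
        assert np.nanmax(jumps, initial=0.0) < 0.5

    def test_error_strictly_decreases_with_oversampling(self):
        study = make_annulus_study(endo_radius=10, epi_radius=13,
                                   grid_size=48, n_slices=3)
        errs = []
        for osf in (1, 2, 4):
            cm = compute_coordinates(study, oversample=osf)
            rho, _ = analytic_polar(48, osf)
            r_true = (rho - 10) / 3.0
            v = cm.valid[1]
            errs.append(np.abs(cm.r[1][v] - r_true[v]).max())
        assert errs[0] > errs[1] > errs[2]

    def test_translation_invariance_and_rotation_equivariance(self):
        base = make_annulus_study(grid_size=64, n_slices=2,
                                  junction_angle_deg=30)
        cm0 = compute_coordinates(base, oversample=2)
        # translate: roll labels, contours and junction by whole pixels
        shifted = make_annulus_study(grid_size=64, n_slices=2,
                                     junction_angle_deg=30)
        shifted.labels = np.roll(shifted.labels, (3, -2), axis=(1, 2))
        for role, polys in shifted.contours.polygons.items():
            shifted.contours.polygons[role] = [
                (k, v + np.array([-2.0, 3.0])) for k, v in polys]
        for k in shifted.landmarks.junction:
            shifted.landmarks.junction[k] = \
                shifted.landmarks.junction[k] + np.array([-2.0, 3.0])
        cm1 = compute_coordinates(shifted, oversample=2)
        r0 = cm0.r[0][cm0.valid[0]]
        r1 = cm1.r[0][cm1.valid[0]]
        assert cm0.valid.sum() == cm1.valid.sum()
        np.testing.assert_allclose(np.sort(r0), np.sort(r1), atol=1e-9)
        # rotating the anatomy together with the junction leaves c unchanged
        rot = make_annulus_study(grid_size=64, n_slices=2,
                                 junction_angle_deg=120)
        cm2 = compute_coordinates(rot, oversample=2)
        c0 = np.sort(cm0.c[0][cm0.valid[0]])
        c2 = np.sort(cm2.c[0][cm2.valid[0]])
        assert circular_abs_diff(c0, c2).max() < 2e-3


# ---------------------------------------------------------------------------
# individual field operations
# ---------------------------------------------------------------------------

class TestRadial:
    def test_analytic_midwall_and_boundaries(self):
        mask = annulus_mask(64, 10, 20)
        endo = make_annulus_study().contours.on_slice("endocardium", 0)[0]
        epi = make_annulus_study().contours.on_slice("epicardium", 0)[0]
        r = radial_coordinate(mask, endo, epi)
        rho, _ = analytic_polar(64, 1)
        assert np.abs(r[mask] - (rho[mask] - 10) / 10).max() < 0.001
        mid = mask & (np.abs(rho - 15) < 0.05)
        assert np.abs(r[mid] - 0.5).max() < 0.01
        near_endo = mask & (rho < 10.6)
        assert np.nanmax(r[near_endo]) < 0.08
        near_epi = mask & (rho > 19.4)
        assert np.nanmin(r[near_epi]) > 0.92

    def test_mask_only_path_matches_analytic(self):
        mask = annulus_mask(64, 10, 20)
        r = radial_coordinate(mask)
        rho, _ = analytic_polar(64, 1)
        v = mask & np.isfinite(r)
        assert np.abs(r[v] - (rho[v] - 10) / 10).max() < 0.08


class TestCircumferential:
    def test_junction_ray_and_opposite(self):
        mask = annulus_mask(64, 10, 20)
        center = (31.5, 31.5)
        c = circumferential_coordinate(mask, (53.5, 31.5), center)  # junction at 0 deg
        rho, theta = analytic_polar(64, 1)
        on_ray = mask & (np.abs(theta) < np.radians(2))
        assert np.nanmax(np.minimum(c[on_ray], 1 - c[on_ray])) < 0.01
        opposite = mask & (np.abs(np.abs(theta) - np.pi) < np.radians(2))
        assert np.abs(c[opposite] - 0.5).max() < 0.01

    def test_junction_at_90_matches_formula(self):
        mask = annulus_mask(64, 10, 20)
        c = circumferential_coordinate(mask, (31.5, 9.5), (31.5, 31.5))
        _, theta = analytic_polar(64, 1)
        c_true = ((theta - np.pi / 2) % (2 * np.pi)) / (2 * np.pi)
        assert circular_abs_diff(c[mask], c_true[mask]).max() < 1 / 720

    def test_junction_on_center_rejected(self):
        mask = annulus_mask(64, 10, 20)
        with pytest.raises(CoordinateError):
            circumferential_coordinate(mask, (31.5, 31.5), (31.5, 31.5))


class TestLongAxis:
    @pytest.mark.parametrize("slice_index,apex,base,expected", [
        (0, 0.0, 16.0, 0.0),
        (8, 0.0, 16.0, 0.5),
        (7, -1.0, 15.0, 0.5),
        (10, 16.0, 0.0, 0.375),     # base-to-apex stack ordering
    ])
    def test_linear_normalization(self, slice_index, apex, base, expected):
        assert longaxis_coordinate(slice_index, apex, base) == pytest.approx(expected)

    def test_equal_indices_rejected(self):
        with pytest.raises(CoordinateError):
            longaxis_coordinate(3, 5.0, 5.0)

    def test_out_of_range_slices_excluded(self):
        study = make_annulus_study(n_slices=6)
        study.landmarks.apex_index = 1.0
        study.landmarks.base_index = 4.0
        cm = compute_coordinates(study, oversample=1)
        assert cm.valid_slices() == [1, 2, 3, 4]
        assert np.isnan(cm.slice_z[0]) and np.isnan(cm.slice_z[5])


class TestLVOT:
    def test_30_degree_wedge_removes_expected_fraction(self):
        mask = annulus_mask(64, 10, 20)
        center = np.array([31.5, 31.5])
        p1 = center + 25 * np.array([np.cos(np.radians(40)),
                                     -np.sin(np.radians(40))])
        p2 = center + 25 * np.array([np.cos(np.radians(70)),
                                     -np.sin(np.radians(70))])
        out = exclude_lvot(mask, np.stack([p1, p2]), center)
        removed = 1 - out.sum() / mask.sum()
        assert removed == pytest.approx(30 / 360, abs=0.01)

    def test_absent_pair_leaves_mask_unchanged(self):
        study = make_annulus_study(n_slices=2)
        cm = compute_coordinates(study, oversample=1)
        assert cm.valid.sum() > 0      # no LVOT pair anywhere: nothing removed

    def test_opposite_landmarks_ambiguous(self):
        mask = annulus_mask(64, 10, 20)
        center = np.array([31.5, 31.5])
        with pytest.raises(CoordinateError, match="ambiguous"):
            exclude_lvot(mask, np.stack([center + [25, 0], center - [25, 0]]),
                         center)

    def test_identical_landmarks_rejected(self):
        mask = annulus_mask(64, 10, 20)
        with pytest.raises(CoordinateError):
            exclude_lvot(mask, np.array([[50.0, 31.5], [50.0, 31.5]]),
                         (31.5, 31.5))


# ---------------------------------------------------------------------------
# study-level errors
# ---------------------------------------------------------------------------

class TestStudyLevel:
    def test_missing_junction_raises(self):
        study = make_annulus_study(n_slices=3)
        del study.landmarks.junction[1]
        with pytest.raises(CoordinateError, match="junction"):
            compute_coordinates(study, oversample=1)

    def test_degenerate_slice_dropped(self):
        study = make_annulus_study(n_slices=3)
        study.contours = None
        study.labels[1] = 0
        study.labels[1, 5, 5] = 1          # single myocardial pixel
        cm = compute_coordinates(study, oversample=1)
        assert 1 not in cm.valid_slices()


# ---------------------------------------------------------------------------
# annotation-reproducibility metrics
# ---------------------------------------------------------------------------

class TestAnnotationDifferences:
    def test_identical_annotations_zero(self):
        assert junction_angle_difference((10, 3), (10, 3), (0, 0)) == 0.0

    def test_wraparound(self):
        center = (0.0, 0.0)
        a = (np.cos(np.radians(10)), -np.sin(np.radians(10)))
        b = (np.cos(np.radians(350)), -np.sin(np.radians(350)))
        assert junction_angle_difference(a, b, center) == pytest.approx(-20.0)

    @settings(max_examples=200, deadline=None)
    @given(st.floats(0, 359.99), st.floats(0, 359.99))
    def test_matches_atan2_oracle(self, ang_a, ang_b):
        center = np.array([5.0, -3.0])
        a = center + 7 * np.array([np.cos(np.radians(ang_a)),
                                   -np.sin(np.radians(ang_a))])
        b = center + 2 * np.array([np.cos(np.radians(ang_b)),
                                   -np.sin(np.radians(ang_b))])
        got = junction_angle_difference(a, b, center)
        expected = (ang_b - ang_a + 180) % 360 - 180
        if expected == -180:
            expected = 180
        assert got == pytest.approx(expected, abs=1e-9)
        assert -180 < got <= 180

    def test_point_on_center_rejected(self):
        with pytest.raises(CoordinateError):
            junction_angle_difference((0, 0), (1, 1), (0, 0))

    @pytest.mark.parametrize("a,b,expected", [(5, 5, 0), (5, 7, -2), (-1, 0, -1)])
    def test_slice_differences(self, a, b, expected):
        assert slice_annotation_difference(a, b) == expected
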