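"""Reference geometry, coordinate-matched warping, and lattice resampling."""

import numpy as np
import pytest

from myoatlas import (build_reference_geometry, compute_coordinates,
                      make_annulus_study, resample_to_lattice, warp_to_reference,
                      warp_values)
from myoatlas.atlas import (AtlasConfigError, StandardizedPattern, WarpError,
                            lattice_cell_mask)
from myoatlas.io import MYO_BIT, Landmarks, SegmentedStudy


class TestReferenceGeometry:
    def test_default_constants(self):
        ref = build_reference_geometry()
        assert ref.n_slices == 21
        assert ref.myo_mask.shape == (21, 80, 80)
        assert ref.endo_radii[-1] == pytest.approx(30.0)
        assert ref.epi_radii[-1] == pytest.approx(50.0)

    def test_radii_taper_monotonically_toward_apex(self):
        ref = build_reference_geometry()
        assert (np.diff(ref.endo_radii) >= 0).all()
        assert (np.diff(ref.epi_radii) >= 0).all()
        assert (ref.epi_radii > ref.endo_radii).all()
        assert ref.endo_radii[0] > 0          # wall present at the apex

    def test_reference_coordinates_satisfy_invariants(self):
        ref = build_reference_geometry(endo_radius=6, epi_radius=10,
                                       n_slices=5, grid_size=24)
        cm = ref.cmap
        v = cm.valid
        assert np.nanmin(cm.r[v]) >= 0 and np.nanmax(cm.r[v]) <= 1
        assert np.nanmin(cm.c[v]) >= 0 and np.nanmax(cm.c[v]) < 1
        for k in range(5):
            zk = cm.z[k][cm.valid[k]]
            assert np.allclose(zk, k / 4)

    def test_miniature_geometry(self):
        ref = build_reference_geometry(endo_radius=3, epi_radius=5,
                                       n_slices=2, grid_size=12)
        assert ref.myo_mask.shape == (2, 12, 12)
        assert ref.myo_mask.any()

    @pytest.mark.parametrize("kwargs", [
        {"endo_radius": 50, "epi_radius": 30},
        {"n_slices": 1},
        {"endo_radius": 30, "epi_radius": 50, "grid_size": 40},
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(AtlasConfigError):
            build_reference_geometry(**kwargs)


def reference_self_study(ref):
    """Turn the reference geometry itself into an infarct-free study."""
    labels = (ref.myo_mask * MYO_BIT).astype(np.uint8)
    half = (ref.grid_size - 1) / 2
    junction = {k: (half, half - ref.epi_radii[k] - 1)
                for k in range(ref.n_slices)}
    lm = Landmarks(junction=junction, apex_index=0.0,
                   base_index=ref.n_slices - 1.0)
    return SegmentedStudy(labels=labels, spacing=(1.0, 1.0), landmarks=lm,
                          subject_id="reference")


class TestWarp:
    def test_reference_self_warp_is_zero_with_full_coverage(self, ref_small):
        study = reference_self_study(ref_small)
        cm = compute_coordinates(study, oversample=2)
        pat = warp_to_reference(study, cm, ref_small)
        assert isinstance(pat, StandardizedPattern)
        np.testing.assert_array_equal(pat.coverage_mask, ref_small.myo_mask)
        inf = pat.channels["infarct"]
        assert np.nanmax(np.abs(inf[~np.isnan(inf)])) == 0.0

    def test_r_channel_round_trip(self, annulus_study, ref_small):
        cm = compute_coordinates(annulus_study, oversample=2)
        pat = warp_values(cm, {"r": cm.r}, ref_small, clip_range=None)
        got = pat.channels["r"]
        cov = ~np.isnan(got)
        mae = np.mean(np.abs(got[cov] - ref_small.cmap.r[cov]))
        assert mae < 0.03

    def test_constant_channel_warps_to_constant(self, annulus_study, ref_small):
        cm = compute_coordinates(annulus_study, oversample=2)
        pat = warp_values(cm, {"k": np.full_like(cm.r, 0.37)}, ref_small,
                          clip_range=None)
        vals = pat.channels["k"]
        vals = vals[~np.isnan(vals)]
        assert np.abs(vals - 0.37).max() < 1e-6

    def test_values_stay_inside_input_range(self, annulus_study, ref_small):
        cm = compute_coordinates(annulus_study, oversample=2)
        rng = np.random.default_rng(0)
        field = np.where(cm.valid, rng.uniform(0.2, 0.8, cm.r.shape), np.nan)
        pat = warp_values(cm, {"x": field}, ref_small, clip_range=None)
        vals = pat.channels["x"]
        vals = vals[~np.isnan(vals)]
        assert vals.min() >= 0.2 - 1e-9 and vals.max() <= 0.8 + 1e-9

    def test_no_extrapolation_beyond_acquired_range(self, ref_small):
        study = make_annulus_study(n_slices=9)
        study.landmarks.apex_index = -1.0      # slice z = (k+1)/10 in [0.1, 0.9]
        study.landmarks.base_index = 9.0
        cm = compute_coordinates(study, oversample=2)
        pat = warp_to_reference(study, cm, ref_small)
        missing = [k for k in range(ref_small.n_slices)
                   if np.isnan(pat.channels["infarct"][k]).all()]
        z = ref_small.slice_z
        expected = [k for k in range(ref_small.n_slices)
                    if z[k] < 0.1 - 1e-12 or z[k] > 0.9 + 1e-12]
        assert missing == expected

    def test_coverage_grows_with_acquired_range(self, ref_small):
        def coverage(apex, base):
            study = make_annulus_study(n_slices=9)
            study.landmarks.apex_index = apex
            study.landmarks.base_index = base
            cm = compute_coordinates(study, oversample=1)
            return warp_to_reference(study, cm, ref_small).coverage_mask

        narrow = coverage(-3.0, 11.0)
        wide = coverage(-0.5, 8.5)
        assert np.all(narrow <= wide)
        assert wide.sum() > narrow.sum()

    def test_single_slice_subject_rejected(self, ref_small):
        study = make_annulus_study(n_slices=1, apex_index=-4.0, base_index=4.0)
        cm = compute_coordinates(study, oversample=1)
        with pytest.raises(WarpError, match="2 valid slices"):
            warp_to_reference(study, cm, ref_small)


class TestLattice:
    def test_uniform_channel_fills_covered_cells(self, ref_small):
        ones = np.where(ref_small.myo_mask, 1.0, np.nan)
        pat = StandardizedPattern(channels={"infarct": ones},
                                  coverage_mask=ref_small.myo_mask)
        lat = resample_to_lattice(pat, ref_small)["infarct"]
        observed = ~np.isnan(lat)
        assert observed.sum() > 0
        assert np.allclose(lat[observed], 1.0)
        np.testing.assert_array_equal(observed,
                                      lattice_cell_mask(ref_small))

    def test_quarter_wedge_occupies_six_bins(self, ref_small):
        c = ref_small.cmap.c
        wedge = np.where(ref_small.myo_mask,
                         ((c >= 0) & (c < 0.25)).astype(float), np.nan)
        lat = resample_to_lattice(StandardizedPattern(
            channels={"infarct": wedge}, coverage_mask=ref_small.myo_mask),
            ref_small)["infarct"]
        per_slice = np.nansum(lat, axis=2) > 0
        for k in range(ref_small.n_slices):
            assert per_slice[:, k].sum() == 6

    def test_cell_means_match_bruteforce(self, ref_small):
        rng = np.random.default_rng(1)
        vals = np.where(ref_small.myo_mask,
                        rng.uniform(size=ref_small.myo_mask.shape), np.nan)
        pat = StandardizedPattern(channels={"infarct": vals},
                                  coverage_mask=ref_small.myo_mask)
        n_c, n_r = 8, 5
        lat = resample_to_lattice(pat, ref_small, n_c=n_c, n_r=n_r)["infarct"]
        cmr = ref_small.cmap
        for ci, zi, ri in [(0, 5, 0), (3, 10, 2), (7, 3, 4), (5, 8, 1)]:
            cz = np.nan_to_num(cmr.c[zi], nan=-1.0)
            rz = np.nan_to_num(cmr.r[zi], nan=-1.0)
            sel = ref_small.myo_mask[zi] & \
                (np.minimum((cz * n_c).astype(int), n_c - 1) == ci) & \
                (np.minimum((rz * n_r).astype(int), n_r - 1) == ri)
            if sel.sum() == 0:
                assert np.isnan(lat[ci, zi, ri])
            else:
                assert lat[ci, zi, ri] == pytest.approx(
                    np.nanmean(vals[zi][sel]), abs=1e-12)
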