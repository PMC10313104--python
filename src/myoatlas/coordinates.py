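"""Normalized myocardial coordinates: radial, circumferential, long-axis.

Every myocardial pixel of a subject receives three values in [0, 1]:

* ``r`` — radial position across the wall, 0 at the endocardium, 1 at the
  epicardium, computed as ``d_endo / (d_endo + d_epi)`` from unsigned
  distances to the two wall boundaries;
* ``c`` — circumferential position, 0 on the ray from the cavity center to
  the LV-RV junction, increasing anticlockwise (image plane with y up),
  periodic in [0, 1);
* ``z`` — long-axis position, 0 at the endocardial apex and 1 at the mitral
  level, linear in the slice index (apex/base indices may be extrapolated
  outside the acquired stack).

Fields are estimated on an in-plane oversampled grid (factor 4 by default)
so that thin walls covered by few pixels still yield smooth coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io import SegmentedStudy, polygon_mask

logger = logging.getLogger("myoatlas")

TWO_PI = 2.0 * np.pi


class CoordinateError(Exception):
    """Raised when coordinates cannot be defined on a slice or study."""


@dataclass
class CoordinateMap:
    """Per-pixel (r, c, z) fields on the oversampled grid.

    Arrays have shape ``(n_slices, ny * oversample, nx * oversample)``;
    values are NaN outside ``valid``.  ``slice_z[k]`` is the long-axis value
    shared by all pixels of slice ``k`` (NaN for slices outside [0, 1] or
    dropped slices).
    """

    r: np.ndarray
    c: np.ndarray
    z: np.ndarray
    valid: np.ndarray
    slice_z: np.ndarray
    oversample: int

    @property
    def n_slices(self) -> int:
        return self.r.shape[0]

    def valid_slices(self) -> list[int]:
        return [k for k in range(self.n_slices) if self.valid[k].any()]


# ---------------------------------------------------------------------------
# single-field operations
# ---------------------------------------------------------------------------

def longaxis_coordinate(slice_index: float, apex_index: float,
                        base_index: float) -> float:
    """Linear apex-to-base normalization of a (possibly fractional) slice index."""
    if apex_index == base_index:
        raise CoordinateError("apex_index must differ from base_index")
    return (slice_index - apex_index) / (base_index - apex_index)


def _pixel_angles(shape: tuple[int, int], center: np.ndarray) -> np.ndarray:
    """Anticlockwise angle (y up, i.e. against the row index) about ``center``."""
    ys, xs = np.mgrid[0:shape[0], 0:shape[1]]
    return np.arctan2(-(ys - center[1]), xs - center[0])


def _point_angle(point, center) -> float:
    d = np.asarray(point, float) - np.asarray(center, float)
    if np.hypot(*d) == 0:
        raise CoordinateError("point coincides with the cavity center")
    return float(np.arctan2(-d[1], d[0]))


def circumferential_coordinate(myo_mask_slice: np.ndarray, junction_point,
                               cavity_center, chirality: int = 1) -> np.ndarray:
    """Angle-based circumferential coordinate in [0, 1).

    ``chirality=+1`` is anticlockwise with y up (the default convention);
    ``-1`` flips it for mirrored acquisitions.
    """
    theta = _pixel_angles(myo_mask_slice.shape, np.asarray(cavity_center, float))
    theta_j = _point_angle(junction_point, cavity_center)
    c = (chirality * (theta - theta_j)) % TWO_PI / TWO_PI
    c = np.where(c >= 1.0, 0.0, c)  # numerical wrap of the seam
    out = np.full(myo_mask_slice.shape, np.nan)
    out[myo_mask_slice] = c[myo_mask_slice]
    return out


def _dist_to_polyline(points: np.ndarray, poly: np.ndarray) -> np.ndarray:
    """Unsigned distance from each (x, y) point to a closed polyline."""
    p = np.asarray(points, float)
    v = np.asarray(poly, float)
    if len(v) > 1 and np.allclose(v[0], v[-1]):
        v = v[:-1]
    a = v
    b = np.roll(v, -1, axis=0)
    e = b - a                                   # (m, 2)
    L2 = np.maximum((e ** 2).sum(1), 1e-300)
    d = p[:, None, :] - a[None, :, :]           # (n, m, 2)
    t = np.clip((d * e[None]).sum(-1) / L2[None], 0.0, 1.0)
    proj = a[None] + t[..., None] * e[None]
    return np.sqrt(((p[:, None, :] - proj) ** 2).sum(-1)).min(1)


def radial_coordinate(myo_mask_slice: np.ndarray,
                      endo_contour: np.ndarray | None = None,
                      epi_contour: np.ndarray | None = None) -> np.ndarray:
    """Two-distance radial coordinate r = d_endo / (d_endo + d_epi).

    With explicit contour polygons, distances are exact point-to-polyline
    distances.  Without them, distances are Euclidean distance transforms to
    the cavity and to the outside of the wall, shifted by half a pixel to
    approximate the inter-pixel boundary.  Pixels where both distances
    vanish (touching contours) are NaN.
    """
    mask = np.asarray(myo_mask_slice, bool)
    out = np.full(mask.shape, np.nan)
    if not mask.any():
        return out
    if endo_contour is not None and epi_contour is not None:
        ys, xs = np.nonzero(mask)
        pts = np.stack([xs, ys], axis=1).astype(float)
        d_endo = _dist_to_polyline(pts, endo_contour)
        d_epi = _dist_to_polyline(pts, epi_contour)
        denom = d_endo + d_epi
        vals = np.where(denom > 0, d_endo / np.maximum(denom, 1e-300), np.nan)
        out[ys, xs] = vals
        return out
    filled = ndimage.binary_fill_holes(mask)
    cavity = filled & ~mask
    if not cavity.any():
        raise CoordinateError("wall mask has no enclosed cavity")
    # EDT measures center-to-center; shift by half a pixel toward the
    # inter-pixel boundary, clipping at zero.
    d_endo = np.maximum(ndimage.distance_transform_edt(~cavity) - 0.5, 0.0)
    d_epi = np.maximum(ndimage.distance_transform_edt(filled) - 0.5, 0.0)
    denom = d_endo + d_epi
    with np.errstate(invalid="ignore"):
        r = np.where(denom > 0, d_endo / np.maximum(denom, 1e-300), np.nan)
    out[mask] = r[mask]
    return out


def exclude_lvot(myo_mask_slice: np.ndarray, lvot_pair: np.ndarray,
                 cavity_center) -> np.ndarray:
    """Remove the angular wedge between the two LV-outflow-tract landmarks.

    The wedge is the *shorter* angular interval between the landmark rays;
    exactly opposite landmarks are ambiguous and raise.
    """
    pair = np.asarray(lvot_pair, float).reshape(2, 2)
    if np.allclose(pair[0], pair[1]):
        raise CoordinateError("LVOT landmarks are identical")
    a0 = _point_angle(pair[0], cavity_center)
    a1 = _point_angle(pair[1], cavity_center)
    width = (a1 - a0) % TWO_PI
    if abs(width - np.pi) < 1e-9:
        raise CoordinateError(
            "LVOT landmarks are diametrically opposite; the excluded side is "
            "ambiguous — provide an explicit side flag by reordering landmarks")
    if width > np.pi:           # go the short way round
        a0, a1 = a1, a0
        width = TWO_PI - width
    theta = _pixel_angles(myo_mask_slice.shape, np.asarray(cavity_center, float))
    in_wedge = ((theta - a0) % TWO_PI) <= width
    return np.asarray(myo_mask_slice, bool) & ~in_wedge


# ---------------------------------------------------------------------------
# whole-study coordinates
# ---------------------------------------------------------------------------

def _upsample_mask(mask: np.ndarray, factor: int) -> np.ndarray:
    """Subpixel mask upsampling: linear interpolation of the indicator,
    thresholded at 0.5, which places the boundary midway between opposite
    native pixel centers instead of on a native pixel edge."""
    if factor == 1:
        return mask.copy()
    smooth = ndimage.zoom(mask.astype(float), factor, order=1,
                          grid_mode=True, mode="grid-constant")
    return smooth > 0.5


def _polygon_centroid(verts: np.ndarray) -> np.ndarray:
    """Area centroid of a simple polygon (shoelace formula)."""
    v = np.asarray(verts, float)
    if len(v) > 1 and np.allclose(v[0], v[-1]):
        v = v[:-1]
    x, y = v[:, 0], v[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    area = cross.sum() / 2.0
    if abs(area) < 1e-12:
        return v.mean(axis=0)
    cx = ((x + xn) * cross).sum() / (6.0 * area)
    cy = ((y + yn) * cross).sum() / (6.0 * area)
    return np.array([cx, cy])


def _fine_point(point: np.ndarray, factor: int) -> np.ndarray:
    """Map a native-grid (x, y) location to the oversampled grid."""
    return np.asarray(point, float) * factor + (factor - 1) / 2.0


def compute_coordinates(study: SegmentedStudy, oversample: int = 4,
                        chirality: int = 1) -> CoordinateMap:
    """Compute (r, c, z) for every myocardial pixel of a study.

    Masks are nearest-neighbor upsampled in-plane by ``oversample``; slices
    whose long-axis value falls outside [0, 1] (beyond the annotated apex or
    mitral level) are excluded from the valid mask, as are degenerate slices
    whose wall encloses no cavity.
    """
    if oversample < 1:
        raise ValueError("oversample must be >= 1")
    lm = study.landmarks
    n_slices = study.n_slices
    ny, nx = study.labels.shape[1:]
    fy, fx = ny * oversample, nx * oversample
    r = np.full((n_slices, fy, fx), np.nan)
    c = np.full((n_slices, fy, fx), np.nan)
    z = np.full((n_slices, fy, fx), np.nan)
    valid = np.zeros((n_slices, fy, fx), dtype=bool)
    slice_z = np.full(n_slices, np.nan)
    myo = study.mask("myocardium")
    for k in study.myocardium_slices():
        zk = longaxis_coordinate(k, lm.apex_index, lm.base_index)
        if not (0.0 <= zk <= 1.0):
            logger.info("slice %d: z=%.3f outside [0,1]; excluded", k, zk)
            continue
        if k not in lm.junction:
            raise CoordinateError(f"slice {k} has myocardium but no junction landmark")
        endo_polys = study.contours.on_slice("endocardium", k) \
            if study.contours is not None else []
        epi_polys = study.contours.on_slice("epicardium", k) \
            if study.contours is not None else []
        use_polys = bool(endo_polys and epi_polys)
        if use_polys:
            # rasterize the contours directly at the fine grid
            endo_f = [_fine_point(np.asarray(v, float), oversample)
                      for v in endo_polys]
            epi_f = [_fine_point(np.asarray(v, float), oversample)
                     for v in epi_polys]
            endo_in = np.zeros((fy, fx), dtype=bool)
            for v in endo_f:
                endo_in |= polygon_mask(v, (fy, fx))
            epi_in = np.zeros((fy, fx), dtype=bool)
            for v in epi_f:
                epi_in |= polygon_mask(v, (fy, fx))
            mask = epi_in & ~endo_in
            cavity = endo_in
            center = _polygon_centroid(endo_f[0])
        else:
            mask = _upsample_mask(myo[k], oversample)
            filled = ndimage.binary_fill_holes(mask)
            cavity = filled & ~mask
            if cavity.any():
                cy, cx = ndimage.center_of_mass(cavity)
                center = np.array([cx, cy])      # (x, y) in fine coordinates
        if mask.sum() <= oversample ** 2:    # single native pixel
            logger.warning("slice %d: degenerate (single-pixel) myocardium dropped", k)
            continue
        if not cavity.any():
            logger.warning("slice %d: wall encloses no cavity; slice dropped", k)
            continue
        junction_fine = _fine_point(lm.junction[k], oversample)
        if np.allclose(junction_fine, center):
            raise CoordinateError(f"slice {k}: junction coincides with cavity center")
        if k in lm.lvot_pair:
            pair_fine = np.stack([_fine_point(p, oversample)
                                  for p in lm.lvot_pair[k]])
            mask = exclude_lvot(mask, pair_fine, center)
        if use_polys:
            # EDT against the fine-rasterized contour regions: the half-pixel
            # boundary bias shrinks as 1/oversample
            d_endo = np.maximum(
                ndimage.distance_transform_edt(~cavity) - 0.5, 0.0)
            d_epi = np.maximum(
                ndimage.distance_transform_edt(epi_in) - 0.5, 0.0)
            denom = d_endo + d_epi
            with np.errstate(invalid="ignore"):
                rk = np.where(denom > 0, d_endo / np.maximum(denom, 1e-300),
                              np.nan)
            rk = np.where(mask, rk, np.nan)
        else:
            rk = radial_coordinate(mask)
        ck = circumferential_coordinate(mask, junction_fine, center, chirality)
        ok = mask & np.isfinite(rk) & np.isfinite(ck)
        r[k][ok] = rk[ok]
        c[k][ok] = ck[ok]
        z[k][ok] = zk
        valid[k] = ok
        slice_z[k] = zk
    if not valid.any():
        raise CoordinateError("no slice yields valid coordinates")
    return CoordinateMap(r=r, c=c, z=z, valid=valid, slice_z=slice_z,
                         oversample=oversample)


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def save_coordinate_map(cmap: CoordinateMap, path) -> None:
    """Persist a coordinate map as a 4-channel NIfTI (r, c, z, validity)
    plus a JSON sidecar carrying the oversample factor and per-slice z."""
    import json
    from pathlib import Path

    import nibabel as nib
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    stack = np.stack([cmap.r, cmap.c, cmap.z,
                      cmap.valid.astype(float)], axis=-1)
    vol = np.ascontiguousarray(stack.transpose(2, 1, 0, 3))
    nib.save(nib.Nifti1Image(vol.astype(np.float32), affine=np.eye(4)),
             str(path / "coords.nii"))
    sidecar = {"oversample": cmap.oversample,
               "slice_z": [None if np.isnan(z) else float(z)
                           for z in cmap.slice_z]}
    (path / "coords.json").write_text(json.dumps(sidecar, indent=1))


def load_coordinate_map(path) -> CoordinateMap:
    import json
    from pathlib import Path

    import nibabel as nib
    path = Path(path)
    meta = json.loads((path / "coords.json").read_text())
    vol = np.asanyarray(nib.load(str(path / "coords.nii")).dataobj)
    stack = np.ascontiguousarray(vol.transpose(2, 1, 0, 3)).astype(float)
    valid = stack[..., 3] > 0.5
    r, c, z = (np.where(valid, stack[..., i], np.nan) for i in range(3))
    slice_z = np.array([np.nan if v is None else v for v in meta["slice_z"]])
    return CoordinateMap(r=r, c=c, z=z, valid=valid, slice_z=slice_z,
                         oversample=int(meta["oversample"]))


# ---------------------------------------------------------------------------
# annotation-reproducibility metrics
# ---------------------------------------------------------------------------

def junction_angle_difference(junction_a, junction_b, cavity_center) -> float:
    """Signed angle (degrees, in (-180, 180]) between two junction rays.

    Rays join each annotation to the LV cavity center.  The value is the
    rotation carrying the first ray onto the second, anticlockwise (y up)
    positive: rays at 10 deg and 350 deg differ by -20 deg.
    """
    ta = _point_angle(junction_a, cavity_center)
    tb = _point_angle(junction_b, cavity_center)
    d = np.degrees(tb - ta)
    d = (d + 180.0) % 360.0 - 180.0
    if d == -180.0:
        d = 180.0
    return float(d)


def slice_annotation_difference(index_a: float, index_b: float) -> float:
    """Difference between two annotated slice indices (a - b)."""
    return index_a - index_b
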