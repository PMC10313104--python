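"""Common reference geometry and coordinate-matched lesion transport.

All subjects are standardized onto one semi-ellipsoidal left ventricle:
maximal endocardial/epicardial radii of 30/50 pixels at the base, 21 slices
of 80x80 pixels, per-slice radii shrinking toward the apex along an ellipse
quarter-arc.  A subject's lesion channels are transported onto this target
by matching normalized (r, c, z) coordinates: each reference myocardial
pixel looks up its coordinates among the subject's scattered coordinate
samples and takes a barycentric-linear interpolation of the channel values
there.  No extrapolation is performed beyond the subject's acquired
long-axis range.

Note the stated default radii slightly exceed the half-width of the 80 px
grid, so the outer wall of the most basal slices is clipped at the four
grid-edge midpoints (it survives in the corners); all downstream statistics
are missing-data aware.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import LinearNDInterpolator
from scipy.spatial import cKDTree

from .coordinates import TWO_PI, CoordinateMap
from .io import LESION_CHANNELS, SegmentedStudy

logger = logging.getLogger("myoatlas")


class AtlasConfigError(ValueError):
    """Invalid reference-geometry configuration."""


class WarpError(Exception):
    """Subject cannot be standardized (too little coverage)."""


# ---------------------------------------------------------------------------
# reference geometry
# ---------------------------------------------------------------------------

@dataclass
class ReferenceGeometry:
    """The common semi-ellipsoid target with its own coordinate map."""

    endo_radius: float
    epi_radius: float
    n_slices: int
    grid_size: int
    apex_scale: float
    endo_radii: np.ndarray        # per-slice (apex -> base)
    epi_radii: np.ndarray
    slice_z: np.ndarray           # z of slice k = k / (n_slices - 1)
    myo_mask: np.ndarray          # (n_slices, grid, grid)
    cmap: CoordinateMap = field(repr=False, default=None)

    @property
    def center(self) -> np.ndarray:
        half = (self.grid_size - 1) / 2.0
        return np.array([half, half])


def build_reference_geometry(endo_radius: float = 30.0, epi_radius: float = 50.0,
                             n_slices: int = 21, grid_size: int = 80,
                             apex_scale: float = 0.25,
                             junction_angle_deg: float = 90.0) -> ReferenceGeometry:
    """Build the reference semi-ellipsoid (defaults: 30/50 px, 21 slices, 80x80).

    Per-slice radii follow ``R(z) = R_base * sqrt(1 - ((1 - z) * a)^2)`` with
    ``a`` chosen so the apical slice keeps ``apex_scale`` of the basal radius
    (wall present on every slice).  The reference junction ray points
    straight up in the image (segment 0 of a Bull's eye is anchored there).
    """
    if not endo_radius < epi_radius:
        raise AtlasConfigError(
            f"endo_radius ({endo_radius}) must be < epi_radius ({epi_radius})")
    if n_slices < 2:
        raise AtlasConfigError("n_slices must be >= 2")
    if not 0.0 < apex_scale < 1.0:
        raise AtlasConfigError("apex_scale must be in (0, 1)")
    half_diag = (grid_size - 1) / 2.0 * np.sqrt(2.0)
    if epi_radius > half_diag:
        raise AtlasConfigError(
            f"grid of {grid_size} px cannot represent an epicardial radius of "
            f"{epi_radius} px (half-diagonal {half_diag:.1f})")
    a = np.sqrt(1.0 - apex_scale ** 2)
    slice_z = np.arange(n_slices) / (n_slices - 1)
    scale = np.sqrt(1.0 - ((1.0 - slice_z) * a) ** 2)
    endo_radii = endo_radius * scale
    epi_radii = epi_radius * scale
    half = (grid_size - 1) / 2.0
    ys, xs = np.mgrid[0:grid_size, 0:grid_size].astype(float)
    rho = np.hypot(xs - half, ys - half)
    theta = np.arctan2(-(ys - half), xs - half)
    theta_j = np.radians(junction_angle_deg)
    c2d = ((theta - theta_j) % TWO_PI) / TWO_PI
    c2d = np.where(c2d >= 1.0, 0.0, c2d)
    myo = np.zeros((n_slices, grid_size, grid_size), dtype=bool)
    r = np.full(myo.shape, np.nan)
    c = np.full(myo.shape, np.nan)
    z = np.full(myo.shape, np.nan)
    for k in range(n_slices):
        m = (rho >= endo_radii[k]) & (rho <= epi_radii[k])
        myo[k] = m
        with np.errstate(invalid="ignore"):
            rk = (rho - endo_radii[k]) / (epi_radii[k] - endo_radii[k])
        r[k][m] = np.clip(rk[m], 0.0, 1.0)
        c[k][m] = c2d[m]
        z[k][m] = slice_z[k]
    cmap = CoordinateMap(r=r, c=c, z=z, valid=myo.copy(), slice_z=slice_z.copy(),
                         oversample=1)
    return ReferenceGeometry(endo_radius=endo_radius, epi_radius=epi_radius,
                             n_slices=n_slices, grid_size=grid_size,
                             apex_scale=apex_scale, endo_radii=endo_radii,
                             epi_radii=epi_radii, slice_z=slice_z,
                             myo_mask=myo, cmap=cmap)


# ---------------------------------------------------------------------------
# standardized patterns
# ---------------------------------------------------------------------------

@dataclass
class StandardizedPattern:
    """Lesion channels resampled onto the reference geometry.

    ``channels[name]`` has the reference shape; values in [0, 1] on covered
    reference myocardium, NaN where missing.  ``coverage_mask`` marks the
    reference myocardial pixels whose z lies inside the subject's acquired
    long-axis range (values are never extrapolated beyond it).
    """

    channels: dict[str, np.ndarray]
    coverage_mask: np.ndarray
    subject_id: str = "subject"

    def covered_fraction(self) -> float:
        total = np.count_nonzero(~np.isnan(next(iter(self.channels.values())))) \
            if self.channels else 0
        return total / max(int(self.coverage_mask.sum()), 1)


class _PlaneInterpolator:
    """Scattered linear interpolation of one subject slice in (r, c) space.

    Samples within ``seam_margin`` of the circumferential 0/1 seam are
    duplicated one period away so interpolation wraps; query points outside
    the convex hull fall back to the nearest sample within ``hull_cap``
    coordinate distance, beyond which they are missing (NaN).
    """

    def __init__(self, r, c, vals, seam_margin: float, hull_cap: float):
        pts = np.stack([r, c], axis=1)
        low = c < seam_margin
        high = c > 1.0 - seam_margin
        self.pts = np.concatenate([pts, pts[low] + [0.0, 1.0],
                                   pts[high] - [0.0, 1.0]])
        self.vals = np.concatenate([vals, vals[low], vals[high]])
        self.hull_cap = hull_cap
        self._interp = None
        self._tree = None

    def __call__(self, q: np.ndarray) -> np.ndarray:
        if self._interp is None:
            self._interp = LinearNDInterpolator(self.pts, self.vals)
        res = np.atleast_2d(self._interp(q))
        holes = np.isnan(res[:, 0])
        if holes.any():
            if self._tree is None:
                self._tree = cKDTree(self.pts)
            dist, idx = self._tree.query(q[holes])
            fill = self.vals[idx].copy()
            fill[dist > self.hull_cap] = np.nan
            res[holes] = fill
        return res


def warp_values(cmap: CoordinateMap, channels: dict[str, np.ndarray],
                ref: ReferenceGeometry, seam_margin: float = 0.1,
                hull_cap: float = 0.1, clip_range: tuple | None = (0.0, 1.0),
                subject_id: str = "subject") -> StandardizedPattern:
    """Transport arbitrary per-pixel scalar fields onto the reference.

    ``channels`` maps names to arrays on the subject's oversampled grid
    (same shape as ``cmap.r``).  The subject's coordinate samples form
    scattered (r, c) clouds on discrete z planes (one per acquired slice);
    each covered reference myocardial pixel is resolved by scattered linear
    interpolation within the two bracketing planes, blended linearly in z —
    piecewise-linear interpolation adapted to the slice-structured scatter.
    Circumferential periodicity is handled by sample duplication around the
    0/1 seam.  Reference pixels with z beyond the subject's acquired range
    are never extrapolated; points outside the in-plane convex hull fall
    back to the nearest sample within ``hull_cap`` coordinate distance.
    """
    vslices = cmap.valid_slices()
    if len(vslices) < 2:
        raise WarpError(f"subject {subject_id}: needs >= 2 valid slices, "
                        f"got {len(vslices)}")
    names = list(channels)
    fields = [np.asarray(channels[n], float) for n in names]
    plane_z = np.array([cmap.slice_z[k] for k in vslices])
    order = np.argsort(plane_z)
    plane_z = plane_z[order]
    planes = []
    for idx in order:
        k = vslices[idx]
        sel = cmap.valid[k]
        vals = np.stack([f[k][sel] for f in fields], axis=1)
        planes.append(_PlaneInterpolator(cmap.r[k][sel], cmap.c[k][sel], vals,
                                         seam_margin, hull_cap))
    z_lo, z_hi = plane_z[0], plane_z[-1]
    coverage = ref.myo_mask & (ref.cmap.z >= z_lo - 1e-12) & \
        (ref.cmap.z <= z_hi + 1e-12)
    out = {name: np.full(ref.myo_mask.shape, np.nan) for name in names}
    for kr in range(ref.n_slices):
        m = coverage[kr]
        if not m.any():
            continue
        zr = ref.slice_z[kr]
        q = np.stack([ref.cmap.r[kr][m], ref.cmap.c[kr][m]], axis=1)
        i = int(np.clip(np.searchsorted(plane_z, zr) - 1, 0, len(plane_z) - 2))
        z0, z1 = plane_z[i], plane_z[i + 1]
        if zr <= z0 + 1e-12:
            res = planes[i](q)
        elif zr >= z1 - 1e-12:
            res = planes[i + 1](q)
        else:
            w = (zr - z0) / (z1 - z0)
            res = (1.0 - w) * planes[i](q) + w * planes[i + 1](q)
        if clip_range is not None:
            res = np.clip(res, *clip_range)
        for j, name in enumerate(names):
            out[name][kr][m] = res[:, j]
    return StandardizedPattern(channels=out, coverage_mask=coverage,
                               subject_id=subject_id)


def warp_to_reference(study: SegmentedStudy, cmap: CoordinateMap,
                      ref: ReferenceGeometry, channels=LESION_CHANNELS,
                      seam_margin: float = 0.1, hull_cap: float = 0.1,
                      rebinarize: bool = False) -> StandardizedPattern:
    """Transport a subject's lesion channels onto the reference geometry.

    Binary channels are interpolated as real values, yielding partial-volume
    values in [0, 1] that downstream group averaging consumes directly;
    ``rebinarize`` thresholds them at 0.5 for sensitivity analyses.
    """
    fields = {name: _upsample_channel(study, name, cmap.oversample).astype(float)
              for name in channels}
    pattern = warp_values(cmap, fields, ref, seam_margin=seam_margin,
                          hull_cap=hull_cap, subject_id=study.subject_id)
    if rebinarize:
        for name, ch in pattern.channels.items():
            sel = ~np.isnan(ch)
            ch[sel] = (ch[sel] >= 0.5).astype(float)
    return pattern


def save_pattern(pattern: StandardizedPattern, path) -> None:
    """Persist a standardized pattern: one NIfTI per channel (NaN = missing)
    plus the coverage mask and a JSON sidecar."""
    import json
    from pathlib import Path

    import nibabel as nib
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for name, ch in pattern.channels.items():
        vol = np.ascontiguousarray(ch.transpose(2, 1, 0)).astype(np.float32)
        nib.save(nib.Nifti1Image(vol, affine=np.eye(4)),
                 str(path / f"{name}.nii"))
    cov = np.ascontiguousarray(
        pattern.coverage_mask.transpose(2, 1, 0)).astype(np.uint8)
    nib.save(nib.Nifti1Image(cov, affine=np.eye(4)), str(path / "coverage.nii"))
    (path / "pattern.json").write_text(json.dumps(
        {"subject_id": pattern.subject_id,
         "channels": sorted(pattern.channels)}, indent=1))


def load_pattern(path) -> StandardizedPattern:
    import json
    from pathlib import Path

    import nibabel as nib
    path = Path(path)
    meta = json.loads((path / "pattern.json").read_text())
    channels = {}
    for name in meta["channels"]:
        vol = np.asanyarray(nib.load(str(path / f"{name}.nii")).dataobj)
        channels[name] = np.ascontiguousarray(
            vol.transpose(2, 1, 0)).astype(float)
    cov = np.asanyarray(nib.load(str(path / "coverage.nii")).dataobj)
    coverage = np.ascontiguousarray(cov.transpose(2, 1, 0)) > 0
    return StandardizedPattern(channels=channels, coverage_mask=coverage,
                               subject_id=meta["subject_id"])


def _upsample_channel(study: SegmentedStudy, name: str, factor: int) -> np.ndarray:
    mask = study.mask(name)
    if factor == 1:
        return mask
    return np.stack([np.kron(mask[k], np.ones((factor, factor), dtype=bool))
                     for k in range(study.n_slices)])


# ---------------------------------------------------------------------------
# analysis lattice
# ---------------------------------------------------------------------------

def coordinate_bins(r: np.ndarray, c: np.ndarray, n_c: int, n_r: int):
    """Map (r, c) values to lattice bin indices (right edges inclusive)."""
    cb = np.minimum((c * n_c).astype(int), n_c - 1)
    rb = np.minimum((r * n_r).astype(int), n_r - 1)
    return cb, rb


def resample_to_lattice(pattern: StandardizedPattern, ref: ReferenceGeometry,
                        n_c: int = 24, n_r: int = 20) -> dict[str, np.ndarray]:
    """Average channel values into (c-bin, z-slice, r-bin) lattice cells.

    Returns one ``(n_c, n_z, n_r)`` array per channel with NaN marking cells
    whose reference pixels are all missing (or that contain no reference
    myocardium at all).
    """
    n_z = ref.n_slices
    myo = ref.myo_mask
    cb, rb = coordinate_bins(ref.cmap.r[myo], ref.cmap.c[myo], n_c, n_r)
    zb = np.nonzero(myo)[0]
    flat = (cb * n_z + zb) * n_r + rb
    size = n_c * n_z * n_r
    out = {}
    for name, ch in pattern.channels.items():
        v = ch[myo]
        ok = ~np.isnan(v)
        sums = np.bincount(flat[ok], weights=v[ok], minlength=size)
        counts = np.bincount(flat[ok], minlength=size)
        with np.errstate(invalid="ignore"):
            cell = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        out[name] = cell.reshape(n_c, n_z, n_r)
    return out


def lattice_cell_mask(ref: ReferenceGeometry, n_c: int = 24,
                      n_r: int = 20) -> np.ndarray:
    """Boolean (n_c, n_z, n_r) mask of cells containing reference myocardium."""
    n_z = ref.n_slices
    myo = ref.myo_mask
    cb, rb = coordinate_bins(ref.cmap.r[myo], ref.cmap.c[myo], n_c, n_r)
    zb = np.nonzero(myo)[0]
    flat = (cb * n_z + zb) * n_r + rb
    counts = np.bincount(flat, minlength=n_c * n_z * n_r)
    return (counts > 0).reshape(n_c, n_z, n_r)
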