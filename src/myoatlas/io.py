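"""Reading, rasterizing, validating and persisting segmented LV studies.

A *study* is one subject's short-axis stack of segmented structures:
endocardium, epicardium, infarct (from LGE), and early/late microvascular
obstruction (MVO, from EGE/LGE).  Contours arrive either from a CVI42
workspace XML export (``.cvi42wsx``) or from the package's own study-bundle
format (NIfTI label volume + JSON sidecar).  Label volumes use a bitmask
encoding so that nesting constraints (infarct inside myocardium, MVO inside
infarct) are cheap to check and enforce.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from lxml import etree

logger = logging.getLogger("myoatlas")

# ---------------------------------------------------------------------------
# label encoding and shared constants
# ---------------------------------------------------------------------------

MYO_BIT = 1
INFARCT_BIT = 2
EARLY_MVO_BIT = 4
LATE_MVO_BIT = 8

LESION_CHANNELS = ("infarct", "early_mvo", "late_mvo")
CHANNEL_BITS = {"infarct": INFARCT_BIT, "early_mvo": EARLY_MVO_BIT,
                "late_mvo": LATE_MVO_BIT}

WALL_ROLES = ("endocardium", "epicardium")
CONTOUR_ROLES = WALL_ROLES + LESION_CHANNELS

#: the four culprit-territory levels used throughout the cohort analyses
TERRITORIES = ("LAD mid", "LAD proximal", "LCX", "RCA")

BUNDLE_SCHEMA_VERSION = 1


class StudyIOError(Exception):
    """Base error for study input/output problems."""


class EmptyStudyError(StudyIOError):
    """Workspace or volume contains no usable wall contours."""


class GeometryError(StudyIOError):
    """Contour geometry violates the annular-wall assumptions."""


class BundleError(StudyIOError):
    """Study bundle is incomplete or has an incompatible schema."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class ContourSet:
    """Per-slice polygons keyed by role.

    ``polygons[role]`` is a list of ``(slice_index, vertices)`` where
    vertices is an ``(n, 2)`` float array of ``(x, y)`` pixel coordinates
    (continuous, 0-based, x = column, y = row).
    """

    polygons: dict[str, list[tuple[int, np.ndarray]]] = field(default_factory=dict)

    def add(self, role: str, slice_index: int, vertices) -> None:
        vertices = np.asarray(vertices, dtype=float)
        if vertices.ndim != 2 or vertices.shape[1] != 2 or len(vertices) < 3:
            raise GeometryError(
                f"polygon for role {role!r} on slice {slice_index} needs >= 3 "
                f"(x, y) vertices, got shape {vertices.shape}")
        self.polygons.setdefault(role, []).append((int(slice_index), vertices))

    def on_slice(self, role: str, slice_index: int) -> list[np.ndarray]:
        return [v for s, v in self.polygons.get(role, []) if s == slice_index]

    def slices(self) -> list[int]:
        out = {s for polys in self.polygons.values() for s, _ in polys}
        return sorted(out)

    def n_polygons(self, role: str | None = None) -> int:
        if role is not None:
            return len(self.polygons.get(role, []))
        return sum(len(v) for v in self.polygons.values())

    def check(self) -> None:
        """Raise on invariant violations (simplicity, lesion-without-wall)."""
        if not any(self.polygons.get(r) for r in WALL_ROLES):
            raise EmptyStudyError("no endocardium/epicardium contour anywhere")
        for role, polys in self.polygons.items():
            for s, verts in polys:
                if not _is_simple_polygon(verts):
                    raise GeometryError(
                        f"{role} polygon on slice {s} is self-intersecting")
        wall_slices = {s for r in WALL_ROLES for s, _ in self.polygons.get(r, [])}
        for role in LESION_CHANNELS:
            for s, _ in self.polygons.get(role, []):
                has_endo = any(t == s for t, _ in self.polygons.get("endocardium", []))
                has_epi = any(t == s for t, _ in self.polygons.get("epicardium", []))
                if not (has_endo and has_epi):
                    raise GeometryError(
                        f"{role} polygon on slice {s} without wall contours "
                        f"(wall slices: {sorted(wall_slices)})")


@dataclass
class Landmarks:
    """Per-slice anatomical landmarks and long-axis anchors.

    ``junction[k]`` is the (x, y) LV-RV junction point on slice ``k`` (or
    ``None``); ``lvot_pair[k]`` an optional pair of (x, y) points bracketing
    the LV outflow tract.  ``apex_index``/``base_index`` are real-valued
    slice positions of the endocardial apex and the mitral level; they may
    lie outside the acquired range (extrapolated by the annotator).
    """

    junction: dict[int, np.ndarray] = field(default_factory=dict)
    lvot_pair: dict[int, np.ndarray] = field(default_factory=dict)
    apex_index: float = 0.0
    base_index: float = 1.0

    def __post_init__(self):
        if self.apex_index == self.base_index:
            raise ValueError("apex_index must differ from base_index")
        self.junction = {int(k): np.asarray(v, float) for k, v in self.junction.items()
                         if v is not None}
        self.lvot_pair = {int(k): np.asarray(v, float).reshape(2, 2)
                          for k, v in self.lvot_pair.items() if v is not None}


@dataclass
class SegmentedStudy:
    """One subject: bitmask label volume, spacing, landmarks, covariates.

    ``labels`` has shape ``(n_slices, ny, nx)``; bit 0 is myocardium, bit 1
    infarct, bit 2 early MVO, bit 3 late MVO.  ``spacing`` is
    ``(pixel_mm, slice_mm)`` (in-plane pixels are isotropic).
    """

    labels: np.ndarray
    spacing: tuple[float, float]
    landmarks: Landmarks
    subject_id: str = "subject"
    covariates: dict = field(default_factory=dict)
    #: source polygons when the study was rasterized in-session; they allow
    #: subpixel-accurate coordinates (bundles read from disk carry none)
    contours: "ContourSet | None" = field(default=None, repr=False)

    @property
    def n_slices(self) -> int:
        return self.labels.shape[0]

    def mask(self, channel: str) -> np.ndarray:
        if channel == "myocardium":
            bit = MYO_BIT
        else:
            bit = CHANNEL_BITS[channel]
        return (self.labels & bit) > 0

    def myocardium_slices(self) -> list[int]:
        return [k for k in range(self.n_slices) if self.mask("myocardium")[k].any()]


@dataclass
class ValidationReport:
    passed: bool
    missing_junction_slices: list[int]
    lesion_outside_parent: dict[str, int]
    empty_myocardium: bool
    apex_base_ok: bool
    notes: list[str]

    def __str__(self):  # pragma: no cover - convenience
        status = "PASS" if self.passed else "FAIL"
        return f"ValidationReport[{status}] " + "; ".join(self.notes) if self.notes \
            else f"ValidationReport[{status}]"


# ---------------------------------------------------------------------------
# polygon geometry helpers
# ---------------------------------------------------------------------------

def _cross2(u, v) -> float:
    return u[0] * v[1] - u[1] * v[0]


def _segments_intersect(p1, p2, p3, p4) -> bool:
    """Proper intersection test for open segments p1p2 and p3p4."""
    d1 = _cross2(p4 - p3, p1 - p3)
    d2 = _cross2(p4 - p3, p2 - p3)
    d3 = _cross2(p2 - p1, p3 - p1)
    d4 = _cross2(p2 - p1, p4 - p1)
    return ((d1 > 0) != (d2 > 0)) and ((d3 > 0) != (d4 > 0))


def _is_simple_polygon(verts: np.ndarray) -> bool:
    """True when no two non-adjacent edges properly intersect (after closure)."""
    v = np.asarray(verts, float)
    # drop an explicitly repeated closing vertex
    if len(v) > 1 and np.allclose(v[0], v[-1]):
        v = v[:-1]
    n = len(v)
    if n < 3:
        return False
    edges = [(v[i], v[(i + 1) % n]) for i in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            if j == i or (j + 1) % n == i or (i + 1) % n == j:
                continue  # adjacent edges share a vertex
            if _segments_intersect(*edges[i], *edges[j]):
                return False
    return True


def polygon_mask(vertices: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Even-odd rasterization of a polygon onto pixel centers.

    Pixel centers sit at integer coordinates; a center exactly on a polygon
    edge is IN (deterministic tie-break).  ``shape`` is (ny, nx).
    """
    v = np.asarray(vertices, float)
    if len(v) > 1 and np.allclose(v[0], v[-1]):
        v = v[:-1]
    ny, nx = shape
    out = np.zeros(shape, dtype=bool)
    x0 = max(int(np.floor(v[:, 0].min())), 0)
    x1 = min(int(np.ceil(v[:, 0].max())), nx - 1)
    y0 = max(int(np.floor(v[:, 1].min())), 0)
    y1 = min(int(np.ceil(v[:, 1].max())), ny - 1)
    if x1 < x0 or y1 < y0:
        return out
    ys, xs = np.mgrid[y0:y1 + 1, x0:x1 + 1]
    px = xs.ravel().astype(float)
    py = ys.ravel().astype(float)
    a = v
    b = np.roll(v, -1, axis=0)
    ax, ay = a[:, 0][:, None], a[:, 1][:, None]      # (E, 1)
    bx, by = b[:, 0][:, None], b[:, 1][:, None]
    inside = np.zeros(px.shape, dtype=bool)
    on_edge = np.zeros(px.shape, dtype=bool)
    # chunk pixels to bound the (E, P) broadcast size
    chunk = max(1, int(4e6 / max(len(v), 1)))
    for s in range(0, len(px), chunk):
        cx = px[s:s + chunk][None, :]
        cy = py[s:s + chunk][None, :]
        # even-odd crossing count for a leftward ray
        cond = (ay > cy) != (by > cy)
        with np.errstate(divide="ignore", invalid="ignore"):
            xint = ax + (cy - ay) * (bx - ax) / (by - ay)
        inside[s:s + chunk] = (cond & (cx < xint)).sum(axis=0) % 2 == 1
        # exact on-edge membership
        ex, ey = bx - ax, by - ay
        L2 = np.maximum(ex * ex + ey * ey, 1e-300)
        t = np.clip(((cx - ax) * ex + (cy - ay) * ey) / L2, 0.0, 1.0)
        d2 = (cx - (ax + t * ex)) ** 2 + (cy - (ay + t * ey)) ** 2
        on_edge[s:s + chunk] = (d2 <= 1e-18).any(axis=0)
    out[y0:y1 + 1, x0:x1 + 1] = (inside | on_edge).reshape(ys.shape)
    return out


def _role_mask(contours: ContourSet, role: str, slice_index: int,
               shape: tuple[int, int]) -> np.ndarray:
    m = np.zeros(shape, dtype=bool)
    for verts in contours.on_slice(role, slice_index):
        m |= polygon_mask(verts, shape)
    return m


# ---------------------------------------------------------------------------
# CVI42 workspace XML
# ---------------------------------------------------------------------------

HASH_NS = "http://www.circlecvi.com/cvi42/Workspace/Hash/"
_KEY_ATTR = f"{{{HASH_NS}}}key"

#: contour element names (lower-cased) of the v5 workspace dialect.  Unknown
#: names are skipped with a warning; extend this map for other exports.
CVI42_ROLE_MAP = {
    "saendocardialcontour": "endocardium",
    "saepicardialcontour": "epicardium",
    "saenhancementcontour": "infarct",
    "saenhancementreferencecontour": None,        # remote-myocardium ROI
    "saearlynoreflowareacontour": "early_mvo",
    "sanoreflowareacontour": "late_mvo",
}

_SLICE_KEY_RE = re.compile(r"(?:^|::)(\d+)$")


def _hash_key(el) -> str | None:
    return el.get(_KEY_ATTR) or el.get("key")


def parse_cvi42_workspace(xml_path) -> ContourSet:
    """Parse contours from a CVI42-style workspace XML file.

    Recognized contour roles (``sa*Contour`` elements of the v5 dialect) are
    collected with their slice assignment; unrecognized roles are skipped
    with a logged warning.  Raises :class:`EmptyStudyError` when no wall
    contour exists and :class:`GeometryError` on lesion-without-wall slices.
    """
    try:
        tree = etree.parse(str(xml_path))
    except (etree.XMLSyntaxError, OSError) as exc:
        raise StudyIOError(f"cannot parse workspace XML {xml_path}: {exc}") from exc

    contours = ContourSet()
    root = tree.getroot()
    for el in root.iter():
        key = _hash_key(el)
        if key is None:
            continue
        lowered = key.lower().split("::")[0]
        if not lowered.endswith("contour"):
            continue
        if lowered not in CVI42_ROLE_MAP:
            logger.warning("skipping unrecognized contour role %r", key)
            continue
        role = CVI42_ROLE_MAP[lowered]
        if role is None:
            continue
        slice_index = _find_slice_index(el)
        if slice_index is None:
            logger.warning("contour %r without resolvable slice index; skipped", key)
            continue
        pts = _read_points(el)
        if pts is None or len(pts) < 3:
            logger.warning("contour %r on slice %d has <3 points; skipped",
                           key, slice_index)
            continue
        contours.add(role, slice_index, pts)
    contours.check()
    return contours


def _find_slice_index(el) -> int | None:
    node = el.getparent()
    while node is not None:
        key = _hash_key(node)
        if key is not None:
            m = _SLICE_KEY_RE.search(key)
            if m:
                return int(m.group(1))
        node = node.getparent()
    return None


def _read_points(contour_el) -> np.ndarray | None:
    subpixel = 1.0
    points_el = None
    for child in contour_el:
        key = (_hash_key(child) or etree.QName(child).localname or "").lower()
        if key == "points":
            points_el = child
        elif key in ("subpixelresolution", "pointssubpixelresolution"):
            try:
                subpixel = float(child.text)
            except (TypeError, ValueError):
                pass
    if points_el is None:
        return None
    pts = []
    for pt in points_el:
        x = y = None
        for item in pt:
            key = (_hash_key(item) or etree.QName(item).localname or "").lower()
            if key == "x":
                x = float(item.text)
            elif key == "y":
                y = float(item.text)
        if x is not None and y is not None:
            pts.append((x, y))
    if not pts:
        return None
    return np.asarray(pts, float) / subpixel


CVI42_WRITE_NAMES = {
    "endocardium": "saendocardialContour",
    "epicardium": "saepicardialContour",
    "infarct": "saenhancementContour",
    "early_mvo": "saearlyNoReflowAreaContour",
    "late_mvo": "sanoReflowAreaContour",
}


def write_cvi42_workspace(contours: ContourSet, xml_path,
                          subpixel_resolution: int = 4) -> None:
    """Write contours in the v5-like workspace dialect understood by
    :func:`parse_cvi42_workspace` (fixture/export writer).

    Point coordinates are stored multiplied by ``subpixel_resolution`` as in
    CVI42 exports; powers of two round-trip exactly in binary floats.
    """
    nsmap = {"Hash": HASH_NS}
    root = etree.Element("Workspace", nsmap=nsmap, version="5.0")
    study_states = etree.SubElement(root, f"{{{HASH_NS}}}item",
                                    {_KEY_ATTR: "StudyMapStates"})
    image_states = etree.SubElement(study_states, f"{{{HASH_NS}}}item",
                                    {_KEY_ATTR: "ImageStates"})
    by_slice: dict[int, list[tuple[str, np.ndarray]]] = {}
    for role, polys in contours.polygons.items():
        for s, verts in polys:
            by_slice.setdefault(s, []).append((role, verts))
    for s in sorted(by_slice):
        img = etree.SubElement(image_states, f"{{{HASH_NS}}}item",
                               {_KEY_ATTR: f"slice::{s}"})
        cont = etree.SubElement(img, f"{{{HASH_NS}}}item", {_KEY_ATTR: "Contours"})
        counters: dict[str, int] = {}
        for role, verts in by_slice[s]:
            name = CVI42_WRITE_NAMES[role]
            idx = counters.get(role, 0)
            counters[role] = idx + 1
            key = name if idx == 0 else f"{name}::{idx}"
            cel = etree.SubElement(cont, f"{{{HASH_NS}}}item", {_KEY_ATTR: key})
            pel = etree.SubElement(cel, f"{{{HASH_NS}}}item", {_KEY_ATTR: "Points"})
            for x, y in np.asarray(verts, float) * subpixel_resolution:
                pt = etree.SubElement(pel, "Point")
                xe = etree.SubElement(pt, f"{{{HASH_NS}}}item", {_KEY_ATTR: "x"})
                xe.text = repr(float(x))
                ye = etree.SubElement(pt, f"{{{HASH_NS}}}item", {_KEY_ATTR: "y"})
                ye.text = repr(float(y))
            sub = etree.SubElement(cel, f"{{{HASH_NS}}}item",
                                   {_KEY_ATTR: "SubpixelResolution"})
            sub.text = str(subpixel_resolution)
    etree.ElementTree(root).write(str(xml_path), xml_declaration=True,
                                  encoding="utf-8", pretty_print=True)


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------

def rasterize_study(contours: ContourSet, landmarks: Landmarks,
                    grid_shape: tuple[int, int, int],
                    spacing: tuple[float, float] = (1.0, 1.0),
                    subject_id: str = "subject",
                    covariates: dict | None = None) -> SegmentedStudy:
    """Digitize contour polygons into a bitmask label volume.

    Myocardium = inside epicardium and outside endocardium (pixel-center,
    even-odd rule); lesion bits are intersected with their parent structure
    (infarct with myocardium, MVO with infarct).  ``grid_shape`` is
    ``(n_slices, ny, nx)``.
    """
    n_slices, ny, nx = grid_shape
    for role, polys in contours.polygons.items():
        for s, verts in polys:
            if s >= n_slices:
                raise GeometryError(
                    f"{role} polygon on slice {s} outside grid of {n_slices} slices")
            if (verts[:, 0].min() < -0.5 or verts[:, 0].max() > nx - 0.5 or
                    verts[:, 1].min() < -0.5 or verts[:, 1].max() > ny - 0.5):
                raise GeometryError(
                    f"{role} polygon on slice {s} exceeds the {ny}x{nx} grid")
    labels = np.zeros(grid_shape, dtype=np.uint8)
    for k in range(n_slices):
        endo = _role_mask(contours, "endocardium", k, (ny, nx))
        epi = _role_mask(contours, "epicardium", k, (ny, nx))
        if not epi.any() and not endo.any():
            continue
        if endo.any() and not epi.any():
            raise GeometryError(f"slice {k}: endocardium without epicardium")
        if np.any(endo & ~epi):
            raise GeometryError(
                f"slice {k}: endocardial contour not inside epicardial contour")
        myo = epi & ~endo
        labels[k][myo] |= MYO_BIT
        infarct = _role_mask(contours, "infarct", k, (ny, nx))
        clipped = int(np.count_nonzero(infarct & ~myo))
        if clipped and infarct.any():
            logger.warning("slice %d: %d infarct pixels outside myocardium clipped",
                           k, clipped)
        infarct &= myo
        labels[k][infarct] |= INFARCT_BIT
        for role, bit in (("early_mvo", EARLY_MVO_BIT), ("late_mvo", LATE_MVO_BIT)):
            m = _role_mask(contours, role, k, (ny, nx))
            outside = int(np.count_nonzero(m & ~infarct))
            if outside and m.any():
                logger.warning("slice %d: %d %s pixels outside infarct clipped",
                               k, outside, role)
            labels[k][m & infarct] |= bit
    study = SegmentedStudy(labels=labels, spacing=tuple(spacing),
                           landmarks=landmarks, subject_id=subject_id,
                           covariates=dict(covariates or {}), contours=contours)
    if not study.myocardium_slices():
        raise EmptyStudyError("rasterized study has no myocardium on any slice")
    return study


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_study(study: SegmentedStudy, clip: bool = True) -> ValidationReport:
    """Check a study against the nesting/landmark invariants.

    Lesion bits outside their parent structure are counted in the report and
    (when ``clip``) removed from the label volume afterwards.  Always
    returns a report; never raises.
    """
    notes: list[str] = []
    myo = study.mask("myocardium")
    infarct = study.mask("infarct")
    outside = {
        "infarct": int(np.count_nonzero(infarct & ~myo)),
        "early_mvo": int(np.count_nonzero(study.mask("early_mvo") & ~infarct)),
        "late_mvo": int(np.count_nonzero(study.mask("late_mvo") & ~infarct)),
    }
    if clip:
        study.labels[~myo] &= ~np.uint8(INFARCT_BIT)
        infarct = study.mask("infarct")
        study.labels[~infarct] &= ~np.uint8(EARLY_MVO_BIT | LATE_MVO_BIT)
    myo_slices = study.myocardium_slices()
    empty = len(myo_slices) == 0
    missing_junction = [k for k in myo_slices if k not in study.landmarks.junction]
    lm = study.landmarks
    apex_base_ok = (lm.apex_index != lm.base_index and
                    min(lm.apex_index, lm.base_index) < study.n_slices and
                    max(lm.apex_index, lm.base_index) > -1)
    if empty:
        notes.append("no myocardium on any slice")
    if missing_junction:
        notes.append(f"junction landmark missing on slices {missing_junction}")
    for role, n in outside.items():
        if n:
            notes.append(f"{n} {role} pixels outside parent structure (clipped)")
    if not apex_base_ok:
        notes.append("apex/base indices do not bracket the acquired stack")
    if not infarct.any():
        notes.append("no infarct")
    passed = (not empty and not missing_junction and apex_base_ok and
              all(n == 0 for n in outside.values()))
    return ValidationReport(passed=passed,
                            missing_junction_slices=missing_junction,
                            lesion_outside_parent=outside,
                            empty_myocardium=empty,
                            apex_base_ok=apex_base_ok,
                            notes=notes)


# ---------------------------------------------------------------------------
# study bundles (NIfTI label volume + JSON sidecar)
# ---------------------------------------------------------------------------

def write_bundle(study: SegmentedStudy, path) -> None:
    """Persist a study as ``<path>/labels.nii`` + ``<path>/study.json``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    px, sz = study.spacing
    # NIfTI expects (x, y, z); in-memory layout is (slice, row, col)
    vol = np.ascontiguousarray(study.labels.transpose(2, 1, 0)).astype(np.uint8)
    img = nib.Nifti1Image(vol, affine=np.diag([px, px, sz, 1.0]))
    nib.save(img, str(path / "labels.nii"))
    lm = study.landmarks
    sidecar = {
        "schema_version": BUNDLE_SCHEMA_VERSION,
        "subject_id": study.subject_id,
        "spacing_mm": [float(px), float(sz)],
        "junction": [lm.junction[k].tolist() if k in lm.junction else None
                     for k in range(study.n_slices)],
        "lvot": [lm.lvot_pair[k].ravel().tolist() if k in lm.lvot_pair else None
                 for k in range(study.n_slices)],
        "apex_index": float(lm.apex_index),
        "base_index": float(lm.base_index),
        "covariates": _jsonable(study.covariates),
    }
    (path / "study.json").write_text(json.dumps(sidecar, indent=1))


def read_bundle(path) -> SegmentedStudy:
    """Read a study bundle written by :func:`write_bundle`."""
    path = Path(path)
    nii = path / "labels.nii"
    sidecar = path / "study.json"
    for p, what in ((nii, "label volume (labels.nii)"),
                    (sidecar, "landmark sidecar (study.json)")):
        if not p.exists():
            raise BundleError(f"bundle {path} is missing its {what}")
    meta = json.loads(sidecar.read_text())
    version = meta.get("schema_version")
    if version != BUNDLE_SCHEMA_VERSION:
        raise BundleError(
            f"bundle schema version {version!r} != supported {BUNDLE_SCHEMA_VERSION}")
    vol = np.asanyarray(nib.load(str(nii)).dataobj).astype(np.uint8)
    labels = np.ascontiguousarray(vol.transpose(2, 1, 0))
    junction = {k: v for k, v in enumerate(meta["junction"]) if v is not None}
    lvot = {k: np.asarray(v, float).reshape(2, 2)
            for k, v in enumerate(meta["lvot"]) if v is not None}
    lm = Landmarks(junction=junction, lvot_pair=lvot,
                   apex_index=meta["apex_index"], base_index=meta["base_index"])
    return SegmentedStudy(labels=labels, spacing=tuple(meta["spacing_mm"]),
                          landmarks=lm, subject_id=meta.get("subject_id", path.name),
                          covariates=meta.get("covariates", {}))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


# ---------------------------------------------------------------------------
# DICOM series geometry
# ---------------------------------------------------------------------------

def dicom_series_geometry(source) -> dict:
    """Grid shape and spacing of a short-axis DICOM series (one file/slice).

    ``source`` is a directory or an iterable of file paths.  Returns
    ``{"grid_shape": (n_slices, ny, nx), "spacing": (pixel_mm, slice_mm)}``
    suitable for :func:`rasterize_study`.  Slices are ordered by
    SliceLocation (falling back to InstanceNumber).
    """
    import pydicom
    src = Path(source) if not isinstance(source, (list, tuple)) else source
    paths = sorted(p for p in src.iterdir() if p.is_file()) \
        if isinstance(src, Path) else [Path(p) for p in src]
    if not paths:
        raise StudyIOError(f"no DICOM files under {source}")
    slices = []
    for p in paths:
        try:
            ds = pydicom.dcmread(str(p), stop_before_pixels=True)
        except Exception as exc:   # noqa: BLE001 - skip non-DICOM files
            logger.warning("skipping unreadable DICOM %s: %s", p, exc)
            continue
        key = float(getattr(ds, "SliceLocation",
                            getattr(ds, "InstanceNumber", len(slices))))
        slices.append((key, ds))
    if not slices:
        raise StudyIOError(f"no readable DICOM slices under {source}")
    slices.sort(key=lambda t: t[0])
    ds0 = slices[0][1]
    ny, nx = int(ds0.Rows), int(ds0.Columns)
    px = float(ds0.PixelSpacing[0]) if "PixelSpacing" in ds0 else 1.0
    if len(slices) > 1:
        locs = [k for k, _ in slices]
        slice_mm = float(np.median(np.diff(locs)))
    else:
        slice_mm = float(getattr(ds0, "SpacingBetweenSlices",
                                 getattr(ds0, "SliceThickness", 1.0)))
    return {"grid_shape": (len(slices), ny, nx), "spacing": (px, slice_mm)}


# ---------------------------------------------------------------------------
# cohort tables
# ---------------------------------------------------------------------------

def validate_cohort(table: pd.DataFrame) -> pd.DataFrame:
    if "subject_id" not in table.columns:
        raise StudyIOError("cohort table needs a 'subject_id' column")
    if table["subject_id"].duplicated().any():
        dup = table.loc[table["subject_id"].duplicated(), "subject_id"].tolist()
        raise StudyIOError(f"duplicate subject_ids in cohort table: {dup}")
    if "territory" in table.columns:
        bad = set(table["territory"].dropna()) - set(TERRITORIES)
        if bad:
            raise StudyIOError(
                f"unknown territories {sorted(bad)}; expected one of {TERRITORIES}")
    return table


def read_cohort_table(path) -> pd.DataFrame:
    return validate_cohort(pd.read_csv(path))


def write_cohort_table(table: pd.DataFrame, path) -> None:
    validate_cohort(table).to_csv(path, index=False)
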