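"""Synthetic cohort generation with known ground truth.

The trial data behind this pipeline are not publicly available, so every
downstream stage is validated on simulated subjects: stacked near-circular
annular myocardium slices tapering toward the apex, wedge-shaped infarcts
per coronary territory with controllable circumferential center/extent,
transmural depth and slice span, optional MVO cores nested inside the
infarct, and configurable treatment-arm effects.  Ground-truth lesion
parameters are recorded per subject so the pipeline's measurements can be
compared against what was injected.

Two kinds of generators coexist:

* deterministic phantom builders (:func:`make_annulus_study`,
  :func:`make_wedge_study`) with perfectly circular walls and analytically
  known coordinates, used as oracles;
* the stochastic cohort sampler (:func:`generate_cohort`) driven by a
  :class:`CohortSpec`, with per-subject random streams keyed by
  ``(master seed, subject index)`` so cohorts are reproducible and adding
  subjects never perturbs existing ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coordinates import TWO_PI
from .io import (EARLY_MVO_BIT, INFARCT_BIT, LATE_MVO_BIT, MYO_BIT,
                 ContourSet, Landmarks, SegmentedStudy, rasterize_study)

logger = logging.getLogger("myoatlas")


# ---------------------------------------------------------------------------
# deterministic phantoms
# ---------------------------------------------------------------------------

def _polar_grid(grid_size: int, center: tuple[float, float]):
    ys, xs = np.mgrid[0:grid_size, 0:grid_size].astype(float)
    rho = np.hypot(xs - center[0], ys - center[1])
    theta = np.arctan2(-(ys - center[1]), xs - center[0])
    return rho, theta


def make_annulus_study(endo_radius: float = 10.0, epi_radius: float = 20.0,
                       grid_size: int = 64, n_slices: int = 9,
                       junction_angle_deg: float = 90.0,
                       apex_index: float | None = None,
                       base_index: float | None = None,
                       spacing: tuple[float, float] = (1.0, 5.0),
                       subject_id: str = "phantom") -> SegmentedStudy:
    """Perfectly circular annular wall, identical on every slice.

    The analytic coordinates of a pixel at polar position (rho, theta) about
    the grid center are ``r = (rho - endo) / (epi - endo)`` and
    ``c = (theta - junction_angle) / 2 pi  (mod 1)``, which makes this
    phantom the oracle for the coordinate and warp modules.
    """
    if apex_index is None:
        apex_index = -0.5
    if base_index is None:
        base_index = n_slices - 0.5
    half = (grid_size - 1) / 2.0
    rho, _ = _polar_grid(grid_size, (half, half))
    myo = (rho >= endo_radius) & (rho <= epi_radius)
    labels = np.zeros((n_slices, grid_size, grid_size), dtype=np.uint8)
    labels[:, myo] = MYO_BIT
    phi = np.radians(junction_angle_deg)
    jp = np.array([half + (epi_radius + 1.0) * np.cos(phi),
                   half - (epi_radius + 1.0) * np.sin(phi)])
    lm = Landmarks(junction={k: jp.copy() for k in range(n_slices)},
                   apex_index=apex_index, base_index=base_index)
    # analytic circular contours (256-gon: sagitta < 0.002 px) give the
    # coordinate module subpixel-exact wall boundaries
    ang = np.linspace(0.0, TWO_PI, 256, endpoint=False)
    contours = ContourSet()
    for k in range(n_slices):
        for role, radius in (("endocardium", endo_radius),
                             ("epicardium", epi_radius)):
            contours.add(role, k, np.stack([half + radius * np.cos(ang),
                                            half - radius * np.sin(ang)], axis=1))
    return SegmentedStudy(labels=labels, spacing=spacing, landmarks=lm,
                          subject_id=subject_id, contours=contours)


def make_wedge_study(endo_radius: float = 24.0, epi_radius: float = 29.0,
                     grid_size: int = 64, n_slices: int = 10,
                     junction_angle_deg: float = 90.0,
                     wedge_c: tuple[float, float] = (0.25, 0.5),
                     wedge_depth: float = 0.6,
                     wedge_z: tuple[float, float] = (0.25, 0.7),
                     mvo_rel: float = 0.0,
                     spacing: tuple[float, float] = (1.0, 5.0),
                     subject_id: str = "wedge") -> SegmentedStudy:
    """Uniform-thickness annulus carrying an analytically placed wedge infarct.

    The infarct occupies circumferential interval ``wedge_c`` (in c units
    anticlockwise from the junction), radial depth ``r <= wedge_depth``
    (subendocardial growth) and long-axis span ``wedge_z``; with
    ``mvo_rel`` > 0 a concentric MVO core of that relative size is nested
    inside.  Slice k has long-axis value ``(k - apex) / (base - apex)`` for
    apex/base at the stack ends (-0.5, n - 0.5).
    """
    study = make_annulus_study(endo_radius, epi_radius, grid_size, n_slices,
                               junction_angle_deg, spacing=spacing,
                               subject_id=subject_id)
    half = (grid_size - 1) / 2.0
    rho, theta = _polar_grid(grid_size, (half, half))
    myo = study.mask("myocardium")[0]
    r = np.where(myo, (rho - endo_radius) / (epi_radius - endo_radius), np.nan)
    phi = np.radians(junction_angle_deg)
    c = ((theta - phi) % TWO_PI) / TWO_PI
    lm = study.landmarks
    c_lo, c_hi = wedge_c
    in_c = _in_circular_interval(c, c_lo, c_hi)
    for k in range(n_slices):
        z = (k - lm.apex_index) / (lm.base_index - lm.apex_index)
        if not (wedge_z[0] <= z <= wedge_z[1]):
            continue
        infarct = myo & in_c & (r <= wedge_depth + 1e-12)
        study.labels[k][infarct] |= INFARCT_BIT
        if mvo_rel > 0:
            span = (c_hi - c_lo) % 1.0
            mid = (c_lo + span / 2.0) % 1.0
            core_c = _in_circular_interval(
                c, (mid - span * mvo_rel / 2) % 1.0, (mid + span * mvo_rel / 2) % 1.0)
            core = infarct & core_c & (r <= wedge_depth * mvo_rel + 1e-12)
            study.labels[k][core] |= EARLY_MVO_BIT
            study.labels[k][core] |= LATE_MVO_BIT
    return study


def _in_circular_interval(c: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Membership of circumferential values in the interval lo -> hi (ccw)."""
    width = (hi - lo) % 1.0
    if width == 0:
        width = 1.0
    return ((c - lo) % 1.0) <= width + 1e-12


# ---------------------------------------------------------------------------
# cohort specification
# ---------------------------------------------------------------------------

@dataclass
class AnatomyPrior:
    """Priors for the myocardial anatomy of one synthetic subject."""

    grid_size: int = 64
    endo_radius_mean: float = 12.0      # basal endocardial radius, px
    endo_radius_sd: float = 1.2
    wall_mean: float = 5.5              # basal wall thickness, px
    wall_sd: float = 0.6
    n_slices_mean: float = 17.0         # acquired short-axis slices
    n_slices_sd: float = 2.0
    n_slices_range: tuple[int, int] = (6, 26)
    junction_angle_range: tuple[float, float] = (100.0, 150.0)  # deg, y up
    coverage_prob: float = 0.5          # prob. that apex/base lie OUTSIDE the stack
    extra_slices_mean: float = 1.0      # extrapolated distance when outside
    extra_slices_sd: float = 0.8
    #: uniform placement ranges (in slices) of apex/base when inside the stack
    apex_offset_range: tuple[float, float] = (-0.45, 0.3)
    base_offset_range: tuple[float, float] = (-0.3, 0.45)
    apex_scale: float = 0.45            # apical radius fraction of the basal one
    contour_jitter_sd: float = 0.5      # px, low-order harmonic wall deformation
    center_drift_sd: float = 0.4        # px, per-slice cavity center drift
    pixel_mm: float = 1.5625
    slice_mm: float = 5.0


@dataclass
class LesionPrior:
    """Priors for the wedge lesion of one territory."""

    center_mean: float = 0.5            # circumferential units
    center_sd: float = 0.03
    center_uniform: bool = False        # ignore the mean, draw uniformly
    extent_mean: float = 0.3
    extent_sd: float = 0.05
    depth_mean: float = 0.6
    depth_sd: float = 0.12
    #: per-slice transmural-depth heterogeneity along the long axis (real
    #: lesions are not uniformly deep from apex to base)
    depth_zvar_sd: float = 0.08
    #: within-slice circumferential depth modulation (low-order harmonics,
    #: independent per slice): patchy transmurality along the wedge
    depth_cvar_sd: float = 0.0
    z_lo_mean: float = 0.15
    z_hi_mean: float = 0.85
    z_sd: float = 0.08
    edge_taper: float = 0.35            # fraction of the half-width that tapers
    mvo_prob: float = 0.75              # early MVO core present
    late_given_early: float = 0.8       # late MVO core given early
    mvo_rel_size: float = 0.5
    late_mvo_rel: float = 0.75
    absent_prob: float = 0.0            # subject has no infarct at all


@dataclass
class ArmEffect:
    """Additive lesion-parameter deltas applied to the *delayed* arm."""

    depth_delta: float = 0.0
    extent_delta: float = 0.0
    c_window: tuple[float, float] | None = None   # restrict depth_delta to c-range


def default_territory_priors() -> dict[str, LesionPrior]:
    """Territory-specific wedge priors (anterior junction convention).

    Circumferential centers — LAD anterior/anteroseptal 0.17, LCX lateral
    0.46, RCA inferior/inferoseptal 0.79 — are a documented convention;
    extents/depths/spans are set so simulated global descriptors land in the
    range reported for reperfused STEMI cohorts.
    """
    return {
        "LAD mid": LesionPrior(center_mean=0.17, extent_mean=0.32,
                               depth_mean=0.62, z_lo_mean=0.05, z_hi_mean=0.62),
        "LAD proximal": LesionPrior(center_mean=0.17, extent_mean=0.40,
                                    depth_mean=0.68, z_lo_mean=0.05,
                                    z_hi_mean=0.92),
        "LCX": LesionPrior(center_mean=0.46, extent_mean=0.27, depth_mean=0.63,
                           z_lo_mean=0.25, z_hi_mean=0.9),
        "RCA": LesionPrior(center_mean=0.79, extent_mean=0.31, depth_mean=0.57,
                           z_lo_mean=0.2, z_hi_mean=0.95),
    }


def default_territory_mix() -> dict[str, float]:
    # culprit-territory frequencies of a reperfused STEMI trial cohort
    return {"LAD mid": 25 / 123, "LAD proximal": 20 / 123,
            "LCX": 17 / 123, "RCA": 61 / 123}


@dataclass
class CohortSpec:
    """Everything needed to generate a reproducible two-arm cohort."""

    n_arm_a: int = 65                   # immediate stenting
    n_arm_b: int = 58                   # delayed stenting
    territory_mix: dict[str, float] = field(default_factory=default_territory_mix)
    anatomy: AnatomyPrior = field(default_factory=AnatomyPrior)
    lesions: dict[str, LesionPrior] = field(default_factory=default_territory_priors)
    arm_effect: ArmEffect = field(default_factory=ArmEffect)
    label_flip_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        total = sum(self.territory_mix.values())
        if not np.isclose(total, 1.0):
            self.territory_mix = {k: v / total for k, v in self.territory_mix.items()}
        for t in self.territory_mix:
            if t not in self.lesions:
                raise ValueError(f"territory {t!r} has no lesion prior")


# ---------------------------------------------------------------------------
# anatomy sampling
# ---------------------------------------------------------------------------

@dataclass
class AnatomyTruth:
    """Generative ground truth of one subject's anatomy."""

    centers: np.ndarray          # (n_slices, 2) cavity centers (x, y)
    junction_angles: np.ndarray  # (n_slices,) radians, y-up convention
    endo_base: float
    epi_base: float
    harmonics: np.ndarray        # (2, n_harm, 2): surface x (amp, phase)
    slice_scale: np.ndarray
    slice_z: np.ndarray
    apex_index: float
    base_index: float

    def radii(self, k: int, theta: np.ndarray):
        """(R_endo, R_epi) as functions of angle on slice k."""
        s = self.slice_scale[k]
        r_endo = np.full_like(theta, self.endo_base, dtype=float)
        r_epi = np.full_like(theta, self.epi_base, dtype=float)
        for surf, base, r in ((0, self.endo_base, r_endo),
                              (1, self.epi_base, r_epi)):
            for m, (amp, phase) in enumerate(self.harmonics[surf], start=2):
                r += amp * np.cos(m * theta + phase)
        r_endo *= s
        r_epi *= s
        r_epi = np.maximum(r_epi, r_endo + 1.2)
        return np.maximum(r_endo, 2.0), r_epi


def sample_anatomy(spec: CohortSpec, rng: np.random.Generator,
                   subject_id: str = "synthetic",
                   max_tries: int = 20) -> tuple[SegmentedStudy, AnatomyTruth]:
    """Draw one myocardium-only study (landmarks included) from the priors."""
    prior = spec.anatomy
    for _ in range(max_tries):
        endo = rng.normal(prior.endo_radius_mean, prior.endo_radius_sd)
        wall = rng.normal(prior.wall_mean, prior.wall_sd)
        if endo > 4.0 and wall > 2.0 and \
                endo + wall < (prior.grid_size - 4) / 2.0:
            break
    else:
        raise ValueError("anatomy priors are infeasible (wall thickness <= 0 "
                         "or wall exceeding the grid after resampling)")
    n_slices = int(np.clip(round(rng.normal(prior.n_slices_mean, prior.n_slices_sd)),
                           *prior.n_slices_range))
    apex_out = rng.random() < prior.coverage_prob
    base_out = rng.random() < prior.coverage_prob
    extra = lambda: max(0.2, rng.normal(prior.extra_slices_mean,
                                        prior.extra_slices_sd))
    apex_index = -extra() if apex_out else rng.uniform(*prior.apex_offset_range)
    base_index = (n_slices - 1 + extra()) if base_out \
        else (n_slices - 1 + rng.uniform(*prior.base_offset_range))
    slice_z = (np.arange(n_slices) - apex_index) / (base_index - apex_index)
    a = np.sqrt(1.0 - prior.apex_scale ** 2)
    zc = np.clip(slice_z, 0.0, 1.0)
    slice_scale = np.sqrt(np.maximum(1.0 - ((1.0 - zc) * a) ** 2, 0.0))
    jitter = prior.contour_jitter_sd
    harmonics = np.zeros((2, 3, 2))
    if jitter > 0:
        harmonics[:, :, 0] = rng.normal(0.0, jitter / np.sqrt(3.0), size=(2, 3))
        harmonics[:, :, 1] = rng.uniform(0, TWO_PI, size=(2, 3))
    else:
        harmonics[:, :, 1] = rng.uniform(0, TWO_PI, size=(2, 3))
    half = (prior.grid_size - 1) / 2.0
    centers = np.full((n_slices, 2), half) + \
        rng.normal(0.0, prior.center_drift_sd, size=(n_slices, 2))
    phi0 = np.radians(rng.uniform(*prior.junction_angle_range))
    junction_angles = phi0 + np.radians(rng.normal(0.0, 2.0, size=n_slices))
    truth = AnatomyTruth(centers=centers, junction_angles=junction_angles,
                         endo_base=endo, epi_base=endo + wall,
                         harmonics=harmonics, slice_scale=slice_scale,
                         slice_z=slice_z, apex_index=apex_index,
                         base_index=base_index)
    contours = ContourSet()
    theta = np.linspace(0.0, TWO_PI, 96, endpoint=False)
    junction = {}
    for k in range(n_slices):
        if not (0.0 <= slice_z[k] <= 1.0):
            continue
        r_endo, r_epi = truth.radii(k, theta)
        cx, cy = centers[k]
        for role, rr in (("endocardium", r_endo), ("epicardium", r_epi)):
            verts = np.stack([cx + rr * np.cos(theta),
                              cy - rr * np.sin(theta)], axis=1)
            contours.add(role, k, verts)
        phi = junction_angles[k]
        re_j = np.interp(phi % TWO_PI, theta, r_epi, period=TWO_PI)
        junction[k] = np.array([cx + (re_j + 0.7) * np.cos(phi),
                                cy - (re_j + 0.7) * np.sin(phi)])
    lm = Landmarks(junction=junction, apex_index=apex_index,
                   base_index=base_index)
    study = rasterize_study(contours, lm,
                            (n_slices, prior.grid_size, prior.grid_size),
                            spacing=(prior.pixel_mm, prior.slice_mm),
                            subject_id=subject_id)
    return study, truth


# ---------------------------------------------------------------------------
# lesion sampling
# ---------------------------------------------------------------------------

@dataclass
class LesionTruth:
    territory: str
    center: float
    extent: float
    depth: float
    z_lo: float
    z_hi: float
    has_infarct: bool
    has_early_mvo: bool
    has_late_mvo: bool
    depth_delta: float = 0.0
    c_window: tuple[float, float] | None = None


def _taper_profile(u: np.ndarray, edge_taper: float) -> np.ndarray:
    """Depth multiplier across the wedge half-width u in [-1, 1].

    Flat over the central plateau, cosine fall-off to 0 over the outer
    ``edge_taper`` fraction of the half-width.
    """
    out = np.ones_like(u, dtype=float)
    if edge_taper <= 0:
        return out
    au = np.abs(u)
    lo = 1.0 - edge_taper
    ramp = (au - lo) / edge_taper
    sel = au > lo
    out[sel] = np.cos(np.clip(ramp[sel], 0.0, 1.0) * np.pi / 2.0)
    return out


def sample_lesion(study: SegmentedStudy, truth: AnatomyTruth, territory: str,
                  prior: LesionPrior, rng: np.random.Generator,
                  arm_effect: ArmEffect | None = None) -> LesionTruth:
    """Inject a wedge infarct (plus optional MVO cores) into a study in place.

    The infarct is the set of myocardial pixels whose generative coordinates
    satisfy ``|c - center| <= extent/2`` (circularly), ``z`` inside the
    slice span and ``r`` below a depth profile that tapers toward the wedge
    edges (subendocardium-outward growth); MVO cores are concentric
    sub-wedges, so nesting holds by construction.
    """
    if rng.random() < prior.absent_prob:
        return LesionTruth(territory=territory, center=np.nan, extent=0.0,
                           depth=0.0, z_lo=np.nan, z_hi=np.nan,
                           has_infarct=False, has_early_mvo=False,
                           has_late_mvo=False)
    if prior.center_uniform:
        center = rng.uniform(0.0, 1.0)
    else:
        center = (rng.normal(prior.center_mean, prior.center_sd)) % 1.0
    extent = float(np.clip(rng.normal(prior.extent_mean, prior.extent_sd),
                           0.05, 1.0))
    depth = float(np.clip(rng.normal(prior.depth_mean, prior.depth_sd),
                          0.05, 1.0))
    z_lo = rng.normal(prior.z_lo_mean, prior.z_sd)
    z_hi = rng.normal(prior.z_hi_mean, prior.z_sd)
    z_lo, z_hi = sorted((z_lo, z_hi))
    z_hi = max(z_hi, z_lo + 0.1)
    depth_delta = 0.0
    c_window = None
    if arm_effect is not None:
        extent = float(np.clip(extent + arm_effect.extent_delta, 0.05, 1.0))
        depth_delta = arm_effect.depth_delta
        c_window = arm_effect.c_window
    has_early = rng.random() < prior.mvo_prob
    has_late = has_early and rng.random() < prior.late_given_early
    grid = study.labels.shape[1]
    myo_all = study.mask("myocardium")
    depth_z = rng.normal(0.0, prior.depth_zvar_sd, size=study.n_slices) \
        if prior.depth_zvar_sd > 0 else np.zeros(study.n_slices)
    n_harm = 3
    if prior.depth_cvar_sd > 0:
        c_amps = rng.normal(0.0, prior.depth_cvar_sd / np.sqrt(n_harm),
                            size=(study.n_slices, n_harm))
        c_phases = rng.uniform(0.0, TWO_PI, size=(study.n_slices, n_harm))
    else:
        c_amps = np.zeros((study.n_slices, n_harm))
        c_phases = np.zeros((study.n_slices, n_harm))
    for k in range(study.n_slices):
        z = truth.slice_z[k]
        if not (z_lo <= z <= z_hi) or not myo_all[k].any():
            continue
        depth_k = float(np.clip(depth + depth_z[k], 0.05, 1.0))
        cx, cy = truth.centers[k]
        rho, theta = _polar_grid(grid, (cx, cy))
        r_endo, r_epi = truth.radii(k, theta)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (rho - r_endo) / (r_epi - r_endo)
        c = ((theta - truth.junction_angles[k]) % TWO_PI) / TWO_PI
        dc = (c - center + 0.5) % 1.0 - 0.5          # circular offset from center
        u = dc / (extent / 2.0)
        mod = np.zeros_like(c)
        for m in range(n_harm):
            mod += c_amps[k, m] * np.cos(TWO_PI * (m + 1) * c + c_phases[k, m])
        depth_eff = np.clip(depth_k + mod, 0.05, 1.0) * \
            _taper_profile(u, prior.edge_taper)
        if depth_delta and c_window is not None:
            in_win = _in_circular_interval(c, *c_window)
            depth_eff = np.where(in_win, np.clip(depth_eff + depth_delta, 0, 1),
                                 depth_eff)
        elif depth_delta:
            depth_eff = np.clip(depth_eff + depth_delta, 0.0, 1.0)
        infarct = myo_all[k] & (np.abs(u) <= 1.0) & (r <= depth_eff)
        study.labels[k][infarct] |= INFARCT_BIT
        if has_early:
            core = infarct & (np.abs(u) <= prior.mvo_rel_size) & \
                (r <= depth_eff * prior.mvo_rel_size)
            study.labels[k][core] |= EARLY_MVO_BIT
            if has_late:
                late = core & (np.abs(u) <= prior.mvo_rel_size *
                               prior.late_mvo_rel) & \
                    (r <= depth_eff * prior.mvo_rel_size * prior.late_mvo_rel)
                study.labels[k][late] |= LATE_MVO_BIT
    return LesionTruth(territory=territory, center=center, extent=extent,
                       depth=depth, z_lo=z_lo, z_hi=z_hi,
                       has_infarct=bool(study.mask("infarct").any()),
                       has_early_mvo=bool(study.mask("early_mvo").any()),
                       has_late_mvo=bool(study.mask("late_mvo").any()),
                       depth_delta=depth_delta, c_window=c_window)


def _apply_label_noise(study: SegmentedStudy, rate: float,
                       rng: np.random.Generator) -> None:
    if rate <= 0:
        return
    myo = study.mask("myocardium")
    flips = myo & (rng.random(study.labels.shape) < rate)
    study.labels[flips] ^= INFARCT_BIT
    infarct = study.mask("infarct")
    study.labels[~infarct] &= ~np.uint8(EARLY_MVO_BIT | LATE_MVO_BIT)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

@dataclass
class SyntheticCohort:
    studies: list[SegmentedStudy]
    truths: list[LesionTruth]
    table: pd.DataFrame
    spec: CohortSpec


ARM_LABELS = ("immediate", "delayed")


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate a full two-arm cohort with covariates and ground truth."""
    n_total = spec.n_arm_a + spec.n_arm_b
    territories = list(spec.territory_mix)
    probs = np.array([spec.territory_mix[t] for t in territories])
    studies, truths, rows = [], [], []
    for i in range(n_total):
        rng = np.random.default_rng([spec.seed, i])
        arm = ARM_LABELS[0] if i < spec.n_arm_a else ARM_LABELS[1]
        territory = territories[rng.choice(len(territories), p=probs)]
        sid = f"sub-{i:04d}"
        study, anatomy = sample_anatomy(spec, rng, subject_id=sid)
        effect = spec.arm_effect if arm == ARM_LABELS[1] else None
        truth = sample_lesion(study, anatomy, territory, spec.lesions[territory],
                              rng, arm_effect=effect)
        _apply_label_noise(study, spec.label_flip_rate, rng)
        covs = {
            "treatment": arm,
            "territory": territory,
            "age": float(np.clip(rng.normal(58.0, 11.0), 25, 90)),
            "sex": "male" if rng.random() < 0.8 else "female",
            "bmi": float(np.clip(rng.normal(26.3, 3.6), 16, 45)),
            "lvef": float(np.clip(rng.normal(52.0, 9.0), 20, 75)),
            "diabetes": bool(rng.random() < 0.15),
            "smoking": bool(rng.random() < 0.45),
            "delay_to_pci_h": float(np.clip(rng.normal(4.0, 2.0), 0.5, 24)),
        }
        study.covariates.update(covs)
        studies.append(study)
        truths.append(truth)
        rows.append({"subject_id": sid, **covs})
    table = pd.DataFrame(rows)
    return SyntheticCohort(studies=studies, truths=truths, table=table, spec=spec)


def null_cohort_spec(n_per_arm: int = 30, seed: int = 0,
                     n_slices: int = 9, grid_size: int = 48) -> CohortSpec:
    """A reduced-size null cohort: both arms drawn from the same generator.

    The calibration phantom must make per-location test replicates close to
    exchangeable and independent: lesions cover most of the circumference
    (continuous occupancy variation at nearly every cell, little
    zero-inflation) and transmural depth varies as a spatially decorrelated
    field (small global component, strong per-slice and circumferential
    modulation), so a chance arm imbalance in one subject parameter does
    not shift every location's test coherently.
    """
    anatomy = AnatomyPrior(grid_size=grid_size, endo_radius_mean=10.0,
                           endo_radius_sd=1.0, wall_mean=5.0, wall_sd=0.5,
                           n_slices_mean=n_slices, n_slices_sd=0.0,
                           n_slices_range=(n_slices, n_slices),
                           coverage_prob=0.0, contour_jitter_sd=0.4)
    lesion = LesionPrior(center_uniform=True, extent_mean=0.9, extent_sd=0.06,
                         depth_mean=0.5, depth_sd=0.05, depth_zvar_sd=0.1,
                         depth_cvar_sd=0.18, edge_taper=0.3,
                         z_lo_mean=0.05, z_hi_mean=0.95, z_sd=0.04,
                         mvo_prob=0.0)
    return CohortSpec(n_arm_a=n_per_arm, n_arm_b=n_per_arm,
                      territory_mix={"RCA": 1.0}, anatomy=anatomy,
                      lesions={"RCA": lesion}, seed=seed)


def effect_cohort_spec(n_per_arm: int = 60, seed: int = 0,
                       depth_delta: float = 0.2,
                       wedge_c: tuple[float, float] = (0.25, 0.5),
                       wedge_z: tuple[float, float] = (0.2, 0.8),
                       n_slices: int = 9,
                       grid_size: int = 48) -> CohortSpec:
    """A cohort with a known localized transmurality difference between arms.

    Arm A lesions are wedges at a fixed circumferential window; arm B
    receives an additional ``depth_delta`` of transmural depth over the
    same window, so the set of truly affected lattice cells is known.
    """
    anatomy = AnatomyPrior(grid_size=grid_size, endo_radius_mean=10.0,
                           endo_radius_sd=1.0, wall_mean=5.0, wall_sd=0.5,
                           n_slices_mean=n_slices, n_slices_sd=0.0,
                           n_slices_range=(n_slices, n_slices),
                           coverage_prob=0.0, contour_jitter_sd=0.4)
    center = (wedge_c[0] + wedge_c[1]) / 2.0
    extent = wedge_c[1] - wedge_c[0]
    lesion = LesionPrior(center_mean=center, center_sd=0.015,
                         extent_mean=extent, extent_sd=0.02,
                         depth_mean=0.45, depth_sd=0.12,
                         z_lo_mean=wedge_z[0], z_hi_mean=wedge_z[1], z_sd=0.03,
                         edge_taper=0.0, mvo_prob=0.0)
    effect = ArmEffect(depth_delta=depth_delta, c_window=wedge_c)
    return CohortSpec(n_arm_a=n_per_arm, n_arm_b=n_per_arm,
                      territory_mix={"LCX": 1.0}, anatomy=anatomy,
                      lesions={"LCX": lesion}, arm_effect=effect, seed=seed)
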