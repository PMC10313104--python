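"""Group-level pattern estimation and per-location statistical comparison.

All operations consume analysis lattices shaped ``(n_c, n_z, n_r)`` —
circumferential bin x reference slice x radial bin — with NaN marking
missing cells (uncovered by the subject's acquisition).  Per-location
summaries collapse the radial axis: *location* is the maximum of the
pattern along the wall, *transmurality* its mean.  Two treatment groups are
compared at every (c, z) location with a two-sample Hotelling T-squared
test whose feature vector is the radial profile; p-values are mapped to a
Bull's eye (21 rings from apex to base, 24 segments anticlockwise from the
LV-RV junction) and are reported raw, without multiple-testing correction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

logger = logging.getLogger("myoatlas")


class StatsError(Exception):
    pass


# ---------------------------------------------------------------------------
# group summaries
# ---------------------------------------------------------------------------

@dataclass
class GroupPatternSummary:
    mean: np.ndarray          # (n_c, n_z, n_r)
    variability: np.ndarray   # across-subject sample sd, same shape
    n_per_cell: np.ndarray
    n_subjects: int
    label: str = ""


def group_average(patterns: list[np.ndarray], label: str = "",
                  min_coverage: float = 0.5) -> GroupPatternSummary:
    """Per-cell mean and sample standard deviation across subjects.

    A cell observed in at most ``min_coverage`` of the subjects is flagged
    missing.  Raises on an empty pattern list or inconsistent shapes.
    """
    if not patterns:
        raise StatsError("group_average needs at least one pattern")
    stack = np.stack([np.asarray(p, float) for p in patterns])
    n = len(patterns)
    obs = ~np.isnan(stack)
    count = obs.sum(0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(stack, axis=0)
        sd = np.nanstd(stack, axis=0, ddof=1) if n > 1 else np.zeros_like(mean)
    low = count < min_coverage * n
    mean[low] = np.nan
    sd[low | (count < 2)] = np.nan
    if n == 1:
        sd = np.where(np.isnan(mean), np.nan, 0.0)
    return GroupPatternSummary(mean=mean, variability=sd, n_per_cell=count,
                               n_subjects=n, label=label)


def location_map(lattice: np.ndarray) -> np.ndarray:
    """Per-(c, z) maximum of the pattern along the radial direction."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmax(np.asarray(lattice, float), axis=-1)


def transmurality_map(lattice: np.ndarray) -> np.ndarray:
    """Per-(c, z) mean of the pattern along the radial direction."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(np.asarray(lattice, float), axis=-1)


def variability_map(patterns: list[np.ndarray]) -> np.ndarray:
    """Across-subject sd of per-subject transmurality at each (c, z)."""
    tm = np.stack([transmurality_map(p) for p in patterns])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanstd(tm, axis=0, ddof=1)


# ---------------------------------------------------------------------------
# Hotelling T-squared map
# ---------------------------------------------------------------------------

@dataclass
class PValueMap:
    """Per-(c, z) two-group comparison results.

    ``p`` in (0, 1] where tested, NaN where missing; ``statistic`` is the
    Hotelling T-squared value; ``rank`` the effective feature dimension
    (covariance rank, 0 when nothing varies); ``n_a``/``n_b`` the subjects
    entering the test at each location.
    """

    p: np.ndarray
    statistic: np.ndarray
    rank: np.ndarray
    n_a: np.ndarray
    n_b: np.ndarray
    alpha: float = 0.05

    @property
    def tested(self) -> np.ndarray:
        return ~np.isnan(self.p)


def hotelling_t2(xa: np.ndarray, xb: np.ndarray,
                 rank_tol: float = 1e-8) -> tuple[float, float, int]:
    """Two-sample Hotelling T-squared with pseudo-inverse regularization.

    Returns ``(T2, p, rank)``.  The pooled covariance is inverted on its
    numerical rank (eigenvalues above ``rank_tol`` times the largest); the
    F transform uses that rank as the effective dimension.  Degenerate
    cases: identical means with zero covariance give (0, 1, 0); distinct
    means with zero covariance give an infinite statistic and the smallest
    positive p.
    """
    xa = np.atleast_2d(np.asarray(xa, float))
    xb = np.atleast_2d(np.asarray(xb, float))
    na, nb = len(xa), len(xb)
    n = na + nb
    if na < 2 or nb < 2:
        raise StatsError("hotelling_t2 needs >= 2 subjects per group")
    d = xa.mean(0) - xb.mean(0)
    sa = np.cov(xa, rowvar=False, ddof=1)
    sb = np.cov(xb, rowvar=False, ddof=1)
    pooled = np.atleast_2d(((na - 1) * sa + (nb - 1) * sb) / (n - 2))
    evals, evecs = np.linalg.eigh(pooled)
    top = evals[-1]
    if top <= 0:
        if np.allclose(d, 0.0):
            return 0.0, 1.0, 0
        return np.inf, float(np.nextafter(0, 1)), 0
    keep = evals > rank_tol * top
    q = int(keep.sum())
    q = min(q, n - 2)                     # keep the F transform well defined
    keep_idx = np.argsort(evals)[::-1][:q]
    inv = (evecs[:, keep_idx] / evals[keep_idx]) @ evecs[:, keep_idx].T
    t2 = float(na * nb / n * d @ inv @ d)
    t2 = max(t2, 0.0)
    f_stat = (n - q - 1) / (q * (n - 2)) * t2
    p = float(sps.f.sf(f_stat, q, n - q - 1))
    return t2, max(p, np.nextafter(0, 1)), q


def hotelling_map(group_a: list[np.ndarray], group_b: list[np.ndarray],
                  min_per_group: int = 3, mode: str = "profile",
                  alpha: float = 0.05) -> PValueMap:
    """Per-location Hotelling comparison of two groups of lattices.

    ``mode='profile'`` uses the radial profile (n_r values) as the feature
    vector at each (c, z) location; ``mode='transmurality'`` uses the scalar
    per-subject transmurality instead.  Subjects missing any feature at a
    location are dropped there; locations with fewer than ``min_per_group``
    complete subjects in either group are missing.
    """
    if mode not in ("profile", "transmurality"):
        raise ValueError(f"unknown mode {mode!r}")
    if not group_a or not group_b:
        raise StatsError("both groups must be non-empty")
    a = np.stack([np.asarray(p, float) for p in group_a])
    b = np.stack([np.asarray(p, float) for p in group_b])
    if mode == "transmurality":
        a = np.stack([transmurality_map(p)[..., None] for p in group_a])
        b = np.stack([transmurality_map(p)[..., None] for p in group_b])
    n_c, n_z = a.shape[1], a.shape[2]
    p_map = np.full((n_c, n_z), np.nan)
    t_map = np.full((n_c, n_z), np.nan)
    rank = np.zeros((n_c, n_z), dtype=int)
    n_a = np.zeros((n_c, n_z), dtype=int)
    n_b = np.zeros((n_c, n_z), dtype=int)
    for ci in range(n_c):
        for zi in range(n_z):
            xa = a[:, ci, zi, :]
            xb = b[:, ci, zi, :]
            xa = xa[~np.isnan(xa).any(axis=1)]
            xb = xb[~np.isnan(xb).any(axis=1)]
            if len(xa) < min_per_group or len(xb) < min_per_group:
                continue
            t2, p, q = hotelling_t2(xa, xb)
            p_map[ci, zi] = p
            t_map[ci, zi] = t2
            rank[ci, zi] = q
            n_a[ci, zi] = len(xa)
            n_b[ci, zi] = len(xb)
    if np.isnan(p_map).all():
        raise StatsError(
            f"no location has >= {min_per_group} complete subjects per group")
    return PValueMap(p=p_map, statistic=t_map, rank=rank, n_a=n_a, n_b=n_b,
                     alpha=alpha)


def significant_fraction(pmap: PValueMap, alpha: float = 0.05,
                         tested_only: bool = False) -> float:
    """Percentage of myocardial locations with p below ``alpha``.

    With ``tested_only`` the denominator is restricted to locations where a
    non-degenerate test was actually performed (covariance rank >= 1);
    otherwise all non-missing locations count (degenerate locations carry
    p = 1 and can only deflate the fraction).
    """
    sel = pmap.tested
    if tested_only:
        sel = sel & (pmap.rank >= 1)
    n = int(sel.sum())
    if n == 0:
        raise StatsError("p-value map has no usable locations")
    return 100.0 * int((pmap.p[sel] < alpha).sum()) / n


# ---------------------------------------------------------------------------
# Bull's eye summaries
# ---------------------------------------------------------------------------

@dataclass
class BullsEye:
    """Ring x segment polar summary (apex at the center, base outermost).

    ``values[k, s]`` is ring ``k`` (reference slice ``k``; ring 0 at the
    apex) and segment ``s`` (segment 0 starting at the LV-RV junction,
    anticlockwise).  NaN marks missing cells.
    """

    values: np.ndarray
    metric: str = ""
    log_scale: bool = False

    @property
    def n_rings(self) -> int:
        return self.values.shape[0]

    @property
    def n_segments(self) -> int:
        return self.values.shape[1]


def bullseye_summarize(map2d: np.ndarray, metric: str = "",
                       log_scale: bool = False) -> BullsEye:
    """Arrange a per-(c, z) map into the ring/segment Bull's eye grid."""
    m = np.asarray(map2d, float)
    if m.ndim != 2:
        raise StatsError(f"expected a 2D (n_c, n_z) map, got shape {m.shape}")
    return BullsEye(values=m.T.copy(), metric=metric, log_scale=log_scale)


def plot_bullseye(be: BullsEye, ax=None, cmap: str = "viridis",
                  vmin: float | None = None, vmax: float | None = None):
    """Render a Bull's eye as a polar heatmap (log color scale for p-values)."""
    import matplotlib.pyplot as plt
    from matplotlib.colors import LogNorm

    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"})
    n_rings, n_seg = be.values.shape
    theta = np.linspace(0, 2 * np.pi, n_seg + 1)
    radii = np.arange(n_rings + 1)
    vals = np.ma.masked_invalid(be.values)
    norm = None
    if be.log_scale:
        vmin_ = vmin if vmin is not None else max(np.nanmin(be.values), 1e-6)
        vmax_ = vmax if vmax is not None else 1.0
        norm = LogNorm(vmin=vmin_, vmax=vmax_)
    mesh = ax.pcolormesh(theta, radii, vals, cmap=cmap, norm=norm,
                         vmin=None if norm else vmin, vmax=None if norm else vmax)
    ax.set_theta_zero_location("N")   # junction ray up
    ax.set_theta_direction(1)         # segments increase anticlockwise
    ax.set_yticks([])
    ax.set_xticks([])
    ax.set_title(be.metric)
    plt.colorbar(mesh, ax=ax, shrink=0.8)
    return ax
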