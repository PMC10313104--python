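"""Validation experiments: the package checking itself against oracles.

Every function runs a self-contained experiment — analytic phantoms,
independent brute-force oracles, or simulated null/effect cohorts — and
returns plain numbers.  The experiments mirror how a methods paper would
validate such a pipeline: coordinate accuracy on analytic anatomies, warp
round trips, agreement of the F-transformed Hotelling p-value with
permutation testing, type-I error control, recovery of injected effects,
analytic global descriptors, realignment accuracy, and embedding sanity.

Problem sizes are scaled for desk-top runtimes (miniature reference
geometry, reduced oversampling and radial resolution for the cohort-level
studies); docs/methods.md records the sizes and why they suffice.
"""

from __future__ import annotations

import numpy as np

from .atlas import build_reference_geometry, warp_to_reference, warp_values
from .coordinates import compute_coordinates
from .descriptors import compute_globals
from .embedding import (circular_difference, embed_tsne, infarct_center,
                        realign_to_lad)
from .pipeline import compute_cohort_lattices
from .stats import hotelling_map, hotelling_t2, significant_fraction
from .synthetic import (effect_cohort_spec, generate_cohort,
                        make_annulus_study, make_wedge_study, null_cohort_spec)


def small_reference():
    """Miniature reference geometry shared by the cohort-level experiments."""
    return build_reference_geometry(endo_radius=12, epi_radius=19,
                                    n_slices=11, grid_size=44,
                                    apex_scale=0.45)


# ---------------------------------------------------------------------------
# coordinates
# ---------------------------------------------------------------------------

def _analytic_polar(grid_size, oversample):
    half = (grid_size - 1) / 2.0
    coarse = (np.arange(grid_size * oversample) - (oversample - 1) / 2.0) \
        / oversample
    ys, xs = np.meshgrid(coarse, coarse, indexing="ij")
    return np.hypot(xs - half, ys - half), np.arctan2(-(ys - half), xs - half)


def coordinate_benchmark() -> dict:
    """Max abs (r, c) error on an analytic annulus, and the oversampling
    error curve on a 3-pixel-thick annulus."""
    study = make_annulus_study(endo_radius=10, epi_radius=20, grid_size=64,
                               n_slices=3)
    cm = compute_coordinates(study, oversample=4)
    rho, theta = _analytic_polar(64, 4)
    r_true = (rho - 10) / 10.0
    c_true = ((theta - np.pi / 2) % (2 * np.pi)) / (2 * np.pi)
    v = cm.valid[1]
    r_err = float(np.abs(cm.r[1][v] - r_true[v]).max())
    dc = np.abs(cm.c[1][v] - c_true[v]) % 1.0
    c_err = float(np.minimum(dc, 1 - dc).max())
    thin = make_annulus_study(endo_radius=10, epi_radius=13, grid_size=48,
                              n_slices=3)
    curve = []
    for osf in (1, 2, 4):
        cmo = compute_coordinates(thin, oversample=osf)
        rho_o, _ = _analytic_polar(48, osf)
        vt = cmo.valid[1]
        curve.append(float(np.abs(cmo.r[1][vt] - (rho_o[vt] - 10) / 3).max()))
    return {"r_max_err": r_err, "c_max_err": c_err,
            "thin_annulus_err_by_oversample": curve}


# ---------------------------------------------------------------------------
# warp
# ---------------------------------------------------------------------------

def warp_roundtrip_benchmark(ref=None) -> dict:
    """Warp a subject's own r field and a constant onto the reference."""
    if ref is None:
        ref = small_reference()
    study = make_annulus_study(endo_radius=10, epi_radius=20, grid_size=64,
                               n_slices=9)
    cm = compute_coordinates(study, oversample=2)
    pat = warp_values(cm, {"r": cm.r, "k": np.full_like(cm.r, 0.37)}, ref,
                      clip_range=None)
    r = pat.channels["r"]
    cov = ~np.isnan(r)
    mae = float(np.mean(np.abs(r[cov] - ref.cmap.r[cov])))
    k = pat.channels["k"]
    const_dev = float(np.nanmax(np.abs(k[~np.isnan(k)] - 0.37)))
    bounds_ok = bool(np.nanmin(r[cov]) >= -1e-9 and np.nanmax(r[cov]) <= 1 + 1e-9)
    return {"r_mae": mae, "const_dev": const_dev, "bounds_ok": bounds_ok}


def no_extrapolation_check(ref=None) -> dict:
    """Missing reference slices for a subject acquired over z in [0.1, 0.9]."""
    if ref is None:
        ref = small_reference()
    study = make_annulus_study(n_slices=9)
    study.landmarks.apex_index = -1.0       # slice z = (k + 1) / 10
    study.landmarks.base_index = 9.0
    cm = compute_coordinates(study, oversample=2)
    pat = warp_to_reference(study, cm, ref)
    missing = [k for k in range(ref.n_slices)
               if np.isnan(pat.channels["infarct"][k]).all()]
    expected = [k for k in range(ref.n_slices)
                if ref.slice_z[k] < 0.1 - 1e-12 or ref.slice_z[k] > 0.9 + 1e-12]
    return {"missing_slices": missing, "expected_missing": expected,
            "exact_match": missing == expected}


# ---------------------------------------------------------------------------
# Hotelling oracles
# ---------------------------------------------------------------------------

def hotelling_univariate_benchmark(n_instances: int = 50, seed: int = 0) -> float:
    """Max |difference| between the d=1 Hotelling p and the two-sided t-test p."""
    from scipy import stats as sps
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_instances):
        a = rng.normal(size=(rng.integers(4, 12), 1))
        b = rng.normal(rng.uniform(-1, 1), 1.0, size=(rng.integers(4, 12), 1))
        t2, p, _ = hotelling_t2(a, b)
        t, pt = sps.ttest_ind(a[:, 0], b[:, 0])
        worst = max(worst, abs(t2 - t ** 2), abs(p - pt))
    return float(worst)


def _permutation_t2_null(X: np.ndarray, na: int, n_draws: int,
                         rng: np.random.Generator) -> np.ndarray:
    """Brute-force label-permutation null of the two-sample T^2 statistic,
    computed from sums and cross-products (independent of hotelling_t2)."""
    n, d = X.shape
    nb = n - na
    XX = np.einsum("ni,nj->nij", X, X).reshape(n, d * d)
    order = np.argsort(rng.random((n_draws, n)), axis=1)
    G = np.zeros((n_draws, n))
    np.put_along_axis(G, order[:, :na], 1.0, axis=1)
    sumA = G @ X
    sqA = (G @ XX).reshape(-1, d, d)
    mA = sumA / na
    mB = (X.sum(0) - sumA) / nb
    SA = sqA - na * np.einsum("bi,bj->bij", mA, mA)
    SB = (XX.sum(0).reshape(d, d) - sqA) - nb * np.einsum("bi,bj->bij", mB, mB)
    Sp = (SA + SB) / (n - 2)
    diff = mA - mB
    sol = np.linalg.solve(Sp, diff[..., None])[..., 0]
    return na * nb / n * np.einsum("bi,bi->b", diff, sol)


def hotelling_permutation_benchmark(n_instances: int = 20,
                                    n_per_group: int = 24, n_features: int = 3,
                                    n_draws: int = 20000,
                                    seed: int = 0) -> dict:
    """F-based p versus a label-permutation oracle on small Gaussian instances.

    Instance sizes are chosen so the F approximation error (which shrinks as
    1/n) sits below the Monte-Carlo resolution of the oracle; each instance
    reports |p_F - p_perm| in units of the Monte-Carlo standard error.
    """
    zs, pairs = [], []
    for inst in range(n_instances):
        rng = np.random.default_rng([seed, inst])
        X = rng.normal(size=(2 * n_per_group, n_features))
        t2_obs, p_f, _ = hotelling_t2(X[:n_per_group], X[n_per_group:])
        t2p = _permutation_t2_null(X, n_per_group, n_draws, rng)
        p_perm = (np.count_nonzero(t2p >= t2_obs - 1e-12) + 1) / (n_draws + 1)
        se = np.sqrt(max(p_f * (1 - p_f), 1e-12) / n_draws)
        zs.append(abs(p_f - p_perm) / se)
        pairs.append((float(p_f), float(p_perm), float(se)))
    return {"max_z": float(max(zs)), "z_scores": [float(z) for z in zs],
            "pairs": pairs}


# ---------------------------------------------------------------------------
# cohort-level studies
# ---------------------------------------------------------------------------

def _arm_lattices(cohort, ref, oversample, n_r):
    lats = compute_cohort_lattices(cohort.studies, ref, oversample=oversample,
                                   n_r=n_r)
    arms = dict(zip(cohort.table.subject_id, cohort.table.treatment))
    ga = [v for k, v in lats.items() if arms[k] == "immediate"]
    gb = [v for k, v in lats.items() if arms[k] == "delayed"]
    return ga, gb, lats


def type_one_error_study(n_cohorts: int = 24, n_per_arm: int = 30,
                         seed: int = 0, oversample: int = 1,
                         n_r: int = 3) -> dict:
    """Per-location rejection rate at alpha = 0.05 under the null.

    Pools the tested locations (covariance rank >= 1) of ``n_cohorts``
    independent null cohorts in which both treatment arms share the same
    generator.
    """
    ref = small_reference()
    rates, total, rejected = [], 0, 0
    for rep in range(n_cohorts):
        spec = null_cohort_spec(n_per_arm=n_per_arm,
                                seed=(seed * 1009 + rep) % 2 ** 31)
        cohort = generate_cohort(spec)
        ga, gb, _ = _arm_lattices(cohort, ref, oversample, n_r)
        pm = hotelling_map(ga, gb)
        sel = pm.tested & (pm.rank >= 1)
        total += int(sel.sum())
        rejected += int((pm.p[sel] < 0.05).sum())
        rates.append(float((pm.p[sel] < 0.05).mean()))
    return {"rate": rejected / total, "n_cells": total,
            "per_cohort_rates": rates,
            "significant_fraction_pct": 100.0 * rejected / total}


def effect_recovery_study(n_per_arm: int = 60, seed: int = 0,
                          depth_delta: float = 0.2,
                          oversample: int = 1, n_r: int = 6) -> dict:
    """Dice overlap between the p < 0.05 region and an injected wedge effect."""
    ref = small_reference()
    wedge_c = (0.25, 0.5)
    wedge_z = (0.2, 0.8)
    spec = effect_cohort_spec(n_per_arm=n_per_arm,
                              seed=(seed * 2003 + 1) % 2 ** 31,
                              depth_delta=depth_delta, wedge_c=wedge_c,
                              wedge_z=wedge_z)
    cohort = generate_cohort(spec)
    ga, gb, _ = _arm_lattices(cohort, ref, oversample, n_r)
    pm = hotelling_map(ga, gb)
    detected = pm.tested & (pm.p < 0.05)
    n_c, n_z = detected.shape
    wedge = np.zeros_like(detected)
    for ci in range(n_c):
        for zi in range(n_z):
            cc = (ci + 0.5) / n_c
            zz = zi / (n_z - 1)
            wedge[ci, zi] = (wedge_c[0] <= cc <= wedge_c[1]) and \
                (wedge_z[0] <= zz <= wedge_z[1])
    inter = int((detected & wedge).sum())
    dice = 2.0 * inter / max(int(detected.sum()) + int(wedge.sum()), 1)
    return {"dice": float(dice), "n_detected": int(detected.sum()),
            "n_wedge_cells": int(wedge.sum()),
            "significant_fraction_pct": significant_fraction(pm)}


# ---------------------------------------------------------------------------
# descriptors / realignment / embedding
# ---------------------------------------------------------------------------

def wedge_descriptor_check() -> dict:
    """Analytic wedge (extent 25%, depth 60%, half the slices) descriptors."""
    study = make_wedge_study()
    d = compute_globals(study)
    return {"infarct_area_pct": float(d.infarct_area_pct),
            "transmurality_pct": float(d.transmurality_pct),
            "endocardial_surface_pct": float(d.endocardial_surface_pct),
            "expected": {"infarct_area_pct": 7.5, "transmurality_pct": 60.0,
                         "endocardial_surface_pct": 12.5}}


def _wedge_lattice(center, extent=0.3, depth=0.6, zspan=(0.0, 1.0),
                   noise=0.0, rng=None, n_c=24, n_z=11, n_r=8):
    lat = np.zeros((n_c, n_z, n_r))
    for ci in range(n_c):
        cc = (ci + 0.5) / n_c
        if abs(circular_difference(cc, center)) <= extent / 2:
            for zi in range(n_z):
                zz = zi / (n_z - 1)
                if zspan[0] <= zz <= zspan[1]:
                    lat[ci, zi, :int(round(depth * n_r))] = 1.0
    if noise and rng is not None:
        lat = np.clip(lat + rng.normal(0, noise, lat.shape), 0, 1)
    return lat


def realignment_study(seed: int = 0, n_per_territory: int = 10) -> dict:
    """Post-realignment distance of every territory's mean center to LAD."""
    rng = np.random.default_rng(seed)
    pats, terrs = [], []
    for terr, ctr in [("LAD mid", 0.17), ("LAD proximal", 0.17),
                      ("LCX", 0.46), ("RCA", 0.79)]:
        for _ in range(n_per_territory):
            pats.append(_wedge_lattice(ctr + rng.normal(0, 0.02),
                                       noise=0.05, rng=rng))
            terrs.append(terr)
    rotated, rotations = realign_to_lad(pats, terrs)
    lad = infarct_center(np.mean(
        [p for p, t in zip(rotated, terrs) if t.startswith("LAD")], axis=0))
    max_offset = 0.0
    for terr in set(terrs):
        ctr = infarct_center(np.mean(
            [p for p, t in zip(rotated, terrs) if t == terr], axis=0))
        max_offset = max(max_offset, abs(circular_difference(ctr, lad)))
    mass_ok = all(np.isclose(np.nansum(a), np.nansum(b), rtol=0, atol=1e-9)
                  for a, b in zip(pats, rotated))
    return {"max_center_offset": float(max_offset),
            "mass_preserved": bool(mass_ok), "rotations": rotations}


def embedding_study(seed: int = 0, n_per_cluster: int = 12) -> dict:
    """Silhouette of constructed territory clusters and duplicate co-location."""
    from scipy.spatial.distance import cdist
    from sklearn.metrics import silhouette_score
    rng = np.random.default_rng(seed)
    pats, labels = [], []
    shapes = {"A": (0.17, 0.5, 0.9, (0.0, 0.6)),
              "B": (0.46, 0.25, 0.5, (0.3, 0.9)),
              "C": (0.79, 0.33, 0.8, (0.2, 1.0))}
    for lab, (c, e, d, zs) in shapes.items():
        for _ in range(n_per_cluster):
            pats.append(_wedge_lattice(c + rng.normal(0, 0.01), e, d, zs,
                                       noise=0.05, rng=rng))
            labels.append(lab)
    emb = embed_tsne(pats, seed=seed)
    sil = float(silhouette_score(emb.coords, labels))
    dup = pats + [p.copy() for p in pats]
    emb2 = embed_tsne(dup, seed=seed)
    xy = emb2.coords
    n = len(pats)
    D = cdist(xy, xy)
    np.fill_diagonal(D, np.inf)
    good = sum(1 for i in range(2 * n)
               if D[i, (i + n) % (2 * n)] <= D[i].min() + 1e-9)
    return {"silhouette": sil, "duplicate_nn_fraction": good / (2 * n)}
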