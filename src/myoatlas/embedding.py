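"""Circumferential realignment and t-SNE population embedding.

Standardized infarct patterns still live in a high-dimensional space; to
inspect population structure they are (i) rotated around the circumference
so the average infarct center of each culprit territory coincides with the
LAD territory's center — isolating pattern *shape* from lesion location —
and (ii) embedded in two dimensions with t-SNE (perplexity 10, PCA
initialization), each point one subject, colored by clinical covariates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import procrustes
from sklearn.manifold import TSNE

logger = logging.getLogger("myoatlas")


class EmbeddingError(Exception):
    pass


class ZeroMassError(EmbeddingError):
    """Pattern has no infarct mass; it cannot be realigned."""


# ---------------------------------------------------------------------------
# circumferential centers and realignment
# ---------------------------------------------------------------------------

def infarct_center(lattice: np.ndarray) -> float:
    """Intensity-weighted circular mean of the circumferential coordinate.

    Lattice cells act as point masses at their circumferential bin centers;
    the phasor sum handles the 0/1 seam.  Returns a value in [0, 1).
    """
    lat = np.asarray(lattice, float)
    n_c = lat.shape[0]
    w = np.nansum(lat.reshape(n_c, -1), axis=1)
    total = w.sum()
    if total <= 0:
        raise ZeroMassError("lattice has zero infarct mass")
    ang = 2 * np.pi * (np.arange(n_c) + 0.5) / n_c
    phasor = np.sum(w * np.exp(1j * ang))
    if np.abs(phasor) == 0:
        # perfectly balanced mass: conventional center at 0
        return 0.0
    return float(np.angle(phasor) % (2 * np.pi) / (2 * np.pi))


def circular_difference(a: float, b: float) -> float:
    """Shortest signed circular difference a - b, in (-0.5, 0.5]."""
    d = (a - b) % 1.0
    if d > 0.5:
        d -= 1.0
    return d


def realign_to_lad(patterns: list[np.ndarray], territories: list[str],
                   lad_prefix: str = "LAD"):
    """Rotate patterns so every territory's mean infarct center matches LAD's.

    Rotations are integer circumferential bin shifts (mass-preserving, no
    re-interpolation), one shift per territory:
    ``round((center_LAD - center_territory) * n_c)`` bins.  Subjects with
    zero infarct pass through unrotated with a warning, as do territories
    with no infarct-bearing subjects.  Returns ``(rotated, rotations)``
    where ``rotations`` maps territory -> rotation in circumferential units
    in [0, 1).
    """
    if len(patterns) != len(territories):
        raise EmbeddingError("patterns and territories must align")
    n_c = np.asarray(patterns[0]).shape[0]
    centers: dict[str, list[float]] = {}
    subject_centers: list[float | None] = []
    for lat, terr in zip(patterns, territories):
        try:
            ctr = infarct_center(lat)
        except ZeroMassError:
            logger.warning("subject with zero infarct mass left unrotated")
            subject_centers.append(None)
            continue
        subject_centers.append(ctr)
        centers.setdefault(terr, []).append(ctr)

    def group_center(vals: list[float]) -> float:
        ph = np.sum(np.exp(2j * np.pi * np.asarray(vals)))
        return float(np.angle(ph) % (2 * np.pi) / (2 * np.pi))

    lad_centers = [c for t, v in centers.items() if t.startswith(lad_prefix)
                   for c in v]
    if not lad_centers:
        raise EmbeddingError(f"no {lad_prefix}-territory subject with infarct")
    lad_center = group_center(lad_centers)
    rotations: dict[str, float] = {}
    shifts: dict[str, int] = {}
    for terr in set(territories):
        if terr.startswith(lad_prefix):
            rotations[terr] = 0.0
            shifts[terr] = 0
            continue
        if terr not in centers or not centers[terr]:
            logger.warning("territory %s has zero total infarct; passed through",
                           terr)
            rotations[terr] = 0.0
            shifts[terr] = 0
            continue
        delta = circular_difference(lad_center, group_center(centers[terr]))
        shift = int(np.round(delta * n_c))
        shifts[terr] = shift
        rotations[terr] = (shift / n_c) % 1.0
    rotated = [np.roll(np.asarray(lat, float), shifts[terr], axis=0)
               for lat, terr in zip(patterns, territories)]
    return rotated, rotations


# ---------------------------------------------------------------------------
# t-SNE embedding
# ---------------------------------------------------------------------------

@dataclass
class EmbeddingResult:
    coords: np.ndarray                  # (n_subjects, n_components)
    perplexity: float
    n_components: int
    init: str
    seed: int
    rotations: dict = field(default_factory=dict)
    stability_disparity: float | None = None


def embed_tsne(patterns: list[np.ndarray], perplexity: float = 10.0,
               n_components: int = 2, init: str = "pca", seed: int = 0,
               n_stability: int = 0,
               rotations: dict | None = None) -> EmbeddingResult:
    """Two-dimensional t-SNE embedding of flattened lattice patterns.

    Missing cells are imputed as 0 (absence of lesion); the distance metric
    is Euclidean on the flattened lattice.  Deterministic for a given seed.
    With ``n_stability`` > 0, the embedding is re-run under different seeds
    and the mean pairwise Procrustes disparity is reported as a stability
    measure.
    """
    n = len(patterns)
    if n < 3 * perplexity:
        raise EmbeddingError(
            f"t-SNE with perplexity {perplexity} needs >= {int(3 * perplexity)} "
            f"subjects, got {n}")
    X = np.stack([np.nan_to_num(np.asarray(p, float), nan=0.0).ravel()
                  for p in patterns])

    def run(s):
        return TSNE(n_components=n_components, perplexity=perplexity,
                    init=init, random_state=s).fit_transform(X)

    coords = run(seed)
    disparity = None
    if n_stability > 0:
        runs = [coords] + [run(seed + 1 + i) for i in range(n_stability)]
        disps = [procrustes(runs[i], runs[j])[2]
                 for i in range(len(runs)) for j in range(i + 1, len(runs))]
        disparity = float(np.mean(disps))
    return EmbeddingResult(coords=coords, perplexity=perplexity,
                           n_components=n_components, init=init, seed=seed,
                           rotations=dict(rotations or {}),
                           stability_disparity=disparity)


# ---------------------------------------------------------------------------
# covariate-colored scatter panels
# ---------------------------------------------------------------------------

def plot_colored(embedding: EmbeddingResult, covariates, fig=None,
                 max_categories: int = 12):
    """One scatter panel per covariate column, colored by its values.

    Continuous covariates use a sequential colormap, categorical ones a
    discrete palette with a legend; missing values are drawn gray.
    ``covariates`` is a pandas DataFrame aligned with the embedded subjects.
    """
    import matplotlib.pyplot as plt
    import pandas as pd

    cov = pd.DataFrame(covariates)
    n_panels = cov.shape[1]
    ncols = min(3, max(n_panels, 1))
    nrows = int(np.ceil(n_panels / ncols))
    if fig is None:
        fig, axes = plt.subplots(nrows, ncols,
                                 figsize=(4 * ncols, 3.5 * nrows), squeeze=False)
    else:
        axes = np.array(fig.subplots(nrows, ncols, squeeze=False))
    xy = embedding.coords
    for ax in axes.ravel()[n_panels:]:
        ax.axis("off")
    for ax, col in zip(axes.ravel(), cov.columns):
        series = cov[col]
        missing = series.isna().to_numpy()
        if missing.all():
            logger.warning("covariate %r entirely missing; gray panel", col)
            ax.scatter(xy[:, 0], xy[:, 1], c="0.6", s=18)
        elif (series.dtype.kind in "OUSb"
              or series.nunique(dropna=True) <= max_categories
              and series.dtype.kind not in "fc"):
            levels = sorted(series.dropna().unique().tolist())
            palette = plt.get_cmap("tab10")
            for i, lev in enumerate(levels):
                sel = (series == lev).to_numpy()
                ax.scatter(xy[sel, 0], xy[sel, 1], s=18,
                           color=palette(i % 10), label=str(lev))
            if missing.any():
                ax.scatter(xy[missing, 0], xy[missing, 1], c="0.6", s=18,
                           label="missing")
            ax.legend(fontsize=6, markerscale=0.8)
        else:
            vals = series.to_numpy(float)
            sc = ax.scatter(xy[~missing, 0], xy[~missing, 1], c=vals[~missing],
                            cmap="viridis", s=18)
            if missing.any():
                ax.scatter(xy[missing, 0], xy[missing, 1], c="0.6", s=18)
            fig.colorbar(sc, ax=ax, shrink=0.8)
        ax.set_title(str(col), fontsize=9)
        ax.set_xticks([])
        ax.set_yticks([])
    fig.tight_layout()
    return fig
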