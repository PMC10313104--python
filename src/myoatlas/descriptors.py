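"""Global lesion descriptors and subgroup comparisons.

Five per-subject descriptors summarize a lesion pattern, each in percent:

* infarct / early-MVO / late-MVO area — lesion extent relative to the whole
  myocardium;
* transmurality — average infarcted fraction of the wall thickness over the
  infarcted myocardium only (preserved columns excluded);
* endocardial surface area — fraction of (c, z) wall columns whose
  subendocardial layer is infarcted, a surrogate of the area at risk.

Descriptors are computed both in the subject's native geometry and after
standardization onto the reference, with identical column-based definitions
so the two modes are directly comparable.  Subgroups are compared with the
Mann-Whitney U-test (continuous) and Fisher's exact test (categorical),
reported as median (IQR) or counts (%).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .atlas import ReferenceGeometry, StandardizedPattern, coordinate_bins, \
    resample_to_lattice
from .coordinates import CoordinateMap
from .io import LESION_CHANNELS, SegmentedStudy
from .stats import StatsError

#: a lattice cell counts as lesion-bearing when its occupancy reaches this
#: value; 0.5 makes binary native data and soft standardized data agree.
BEARING_THRESHOLD = 0.5


@dataclass
class GlobalDescriptors:
    infarct_area_pct: float
    early_mvo_area_pct: float
    late_mvo_area_pct: float
    transmurality_pct: float        # NaN when no infarct exists
    endocardial_surface_pct: float
    geometry: str                   # "native" | "standardized"
    subject_id: str = "subject"

    def as_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "geometry": self.geometry,
            "infarct_area_pct": self.infarct_area_pct,
            "early_mvo_area_pct": self.early_mvo_area_pct,
            "late_mvo_area_pct": self.late_mvo_area_pct,
            "transmurality_pct": self.transmurality_pct,
            "endocardial_surface_pct": self.endocardial_surface_pct,
        }


DESCRIPTOR_NAMES = ("infarct_area_pct", "early_mvo_area_pct",
                    "late_mvo_area_pct", "transmurality_pct",
                    "endocardial_surface_pct")


# ---------------------------------------------------------------------------
# native lattice (subject's own geometry binned by its coordinates)
# ---------------------------------------------------------------------------

def build_native_lattice(study: SegmentedStudy, cmap: CoordinateMap,
                         n_c: int = 24, n_r: int = 20) -> dict[str, np.ndarray]:
    """Bin a subject's own pixels into (c, slice, r) cells by its coordinates.

    Returns one ``(n_c, n_valid_slices, n_r)`` array per lesion channel
    (cell mean occupancy, NaN where the cell holds no myocardium) plus a
    ``"myocardium"`` entry with per-cell pixel counts.
    """
    vslices = cmap.valid_slices()
    n_z = len(vslices)
    if n_z == 0:
        raise ValueError("coordinate map has no valid slices")
    size = n_c * n_z * n_r
    sums = {name: np.zeros(size) for name in LESION_CHANNELS}
    counts = np.zeros(size)
    os_ = cmap.oversample
    for zi, k in enumerate(vslices):
        sel = cmap.valid[k]
        cb, rb = coordinate_bins(cmap.r[k][sel], cmap.c[k][sel], n_c, n_r)
        flat = (cb * n_z + zi) * n_r + rb
        counts += np.bincount(flat, minlength=size)
        for name in LESION_CHANNELS:
            fine = np.kron(study.mask(name)[k],
                           np.ones((os_, os_), dtype=bool)) if os_ > 1 \
                else study.mask(name)[k]
            sums[name] += np.bincount(flat, weights=fine[sel].astype(float),
                                      minlength=size)
    out = {}
    with np.errstate(invalid="ignore"):
        for name in LESION_CHANNELS:
            cell = np.where(counts > 0, sums[name] / np.maximum(counts, 1), np.nan)
            out[name] = cell.reshape(n_c, n_z, n_r)
    out["myocardium"] = counts.reshape(n_c, n_z, n_r)
    return out


def _column_descriptors(infarct_lattice: np.ndarray) -> tuple[float, float]:
    """(transmurality_pct, endocardial_surface_pct) from an infarct lattice.

    A wall column is infarct-bearing when any of its radial cells reaches
    ``BEARING_THRESHOLD`` occupancy; its transmurality is the mean occupancy
    over its observed radial cells.  The endocardial surface counts columns
    whose innermost *observed* radial cell reaches the threshold.
    """
    lat = np.asarray(infarct_lattice, float)
    n_c, n_z, n_r = lat.shape
    observed = ~np.isnan(lat)
    col_has_myo = observed.any(axis=-1)
    n_cols = int(col_has_myo.sum())
    if n_cols == 0:
        return np.nan, np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        col_max = np.nanmax(lat, axis=-1)
        col_frac = np.nanmean(lat, axis=-1)
    bearing = col_has_myo & (col_max >= BEARING_THRESHOLD)
    if bearing.any():
        transmurality = 100.0 * float(np.nanmean(col_frac[bearing]))
    else:
        transmurality = np.nan
    # innermost observed radial cell per column
    inner_idx = np.argmax(observed, axis=-1)
    inner_val = np.take_along_axis(lat, inner_idx[..., None], axis=-1)[..., 0]
    endo_bearing = col_has_myo & (inner_val >= BEARING_THRESHOLD)
    endo_surface = 100.0 * int(endo_bearing.sum()) / n_cols
    return transmurality, endo_surface


# ---------------------------------------------------------------------------
# per-subject descriptors
# ---------------------------------------------------------------------------

def compute_globals(source, *, cmap: CoordinateMap | None = None,
                    ref: ReferenceGeometry | None = None,
                    n_c: int = 24, n_r: int = 20,
                    oversample: int = 4) -> GlobalDescriptors:
    """Compute the five global descriptors for a subject.

    Pass a :class:`SegmentedStudy` for the native mode (label-pixel counting
    for the areas, coordinate-binned columns for transmurality and
    endocardial surface), or a :class:`StandardizedPattern` with the
    reference geometry for the standardized mode (soft channel values
    integrated over covered reference myocardium).

    Native-mode columns are binned with *mask-consistent* coordinates
    (derived from the stored label masks at ``oversample``, ignoring any
    attached contour polygons) so the wall samples and the digitized lesion
    masks share the same boundary discretization; a precomputed ``cmap``
    overrides this.
    """
    if isinstance(source, SegmentedStudy):
        if cmap is None:
            from dataclasses import replace

            from .coordinates import compute_coordinates
            bare = replace(source, contours=None)
            cmap = compute_coordinates(bare, oversample=oversample)
        myo_n = int(np.count_nonzero(source.mask("myocardium")))
        if myo_n == 0:
            raise ValueError("study has an empty myocardium")
        areas = {name: 100.0 * np.count_nonzero(source.mask(name)) / myo_n
                 for name in LESION_CHANNELS}
        lat = build_native_lattice(source, cmap, n_c=n_c, n_r=n_r)
        transmurality, endo = _column_descriptors(lat["infarct"])
        if not source.mask("infarct").any():
            transmurality = np.nan
        return GlobalDescriptors(
            infarct_area_pct=areas["infarct"],
            early_mvo_area_pct=areas["early_mvo"],
            late_mvo_area_pct=areas["late_mvo"],
            transmurality_pct=transmurality,
            endocardial_surface_pct=endo,
            geometry="native", subject_id=source.subject_id)
    if isinstance(source, StandardizedPattern):
        if ref is None:
            raise ValueError("standardized mode needs the ReferenceGeometry")
        any_ch = next(iter(source.channels.values()))
        covered = ~np.isnan(any_ch)
        n_cov = int(covered.sum())
        if n_cov == 0:
            raise ValueError("pattern covers no reference myocardium")
        areas = {name: 100.0 * float(np.nansum(ch)) / n_cov
                 for name, ch in source.channels.items()}
        lat = resample_to_lattice(source, ref, n_c=n_c, n_r=n_r)
        transmurality, endo = _column_descriptors(lat["infarct"])
        if np.nansum(source.channels["infarct"]) == 0:
            transmurality = np.nan
        return GlobalDescriptors(
            infarct_area_pct=areas.get("infarct", np.nan),
            early_mvo_area_pct=areas.get("early_mvo", np.nan),
            late_mvo_area_pct=areas.get("late_mvo", np.nan),
            transmurality_pct=transmurality,
            endocardial_surface_pct=endo,
            geometry="standardized", subject_id=source.subject_id)
    raise TypeError(f"cannot compute descriptors for {type(source).__name__}")


# ---------------------------------------------------------------------------
# subgroup comparisons
# ---------------------------------------------------------------------------

@dataclass
class GroupComparison:
    p: float
    statistic: float
    kind: str
    summary_a: str
    summary_b: str


def _median_iqr(x: np.ndarray) -> str:
    q1, med, q3 = np.nanpercentile(x, [25, 50, 75])
    return f"{med:.1f} ({q1:.1f}-{q3:.1f})"


def compare_groups(values_a, values_b, kind: str = "continuous") -> GroupComparison:
    """Two-sided subgroup comparison.

    ``kind='continuous'``: Mann-Whitney U-test (normal approximation with
    tie correction) on two samples, summarized as median (IQR).
    ``kind='categorical'``: Fisher's exact test on a 2x2 count table
    ``[[a_pos, a_neg], [b_pos, b_neg]]``, summarized as counts (%).
    """
    if kind == "continuous":
        a = np.asarray(values_a, float)
        b = np.asarray(values_b, float)
        a = a[~np.isnan(a)]
        b = b[~np.isnan(b)]
        if len(a) < 2 or len(b) < 2:
            raise StatsError("continuous comparison needs >= 2 values per group")
        pooled = np.concatenate([a, b])
        if np.all(pooled == pooled[0]):
            # all observations tied: no evidence of a difference
            return GroupComparison(p=1.0, statistic=len(a) * len(b) / 2.0,
                                   kind=kind, summary_a=_median_iqr(a),
                                   summary_b=_median_iqr(b))
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        return GroupComparison(p=float(res.pvalue), statistic=float(res.statistic),
                               kind=kind, summary_a=_median_iqr(a),
                               summary_b=_median_iqr(b))
    if kind == "categorical":
        table = np.asarray(values_a if values_b is None else [values_a, values_b],
                           dtype=float)
        if table.shape != (2, 2):
            raise StatsError("categorical comparison needs a 2x2 count table")
        odds, p = sps.fisher_exact(table, alternative="two-sided")
        sums = table.sum(axis=1)
        if np.any(sums == 0):
            raise StatsError("categorical comparison has an empty group")
        summ = [f"{int(row[0])} ({100 * row[0] / row.sum():.1f})" for row in table]
        return GroupComparison(p=float(p), statistic=float(odds), kind=kind,
                               summary_a=summ[0], summary_b=summ[1])
    raise ValueError(f"unknown comparison kind {kind!r}")


def descriptor_table(df: pd.DataFrame, arm_col: str = "treatment",
                     territory_col: str = "territory",
                     alpha: float = 0.05) -> pd.DataFrame:
    """Median (IQR) per descriptor x territory x arm x geometry, with p-values.

    ``df`` holds one row per subject and geometry with the five descriptor
    columns plus arm/territory labels (as produced by
    :meth:`GlobalDescriptors.as_dict` merged with the cohort table).
    Single-arm strata leave the p column empty; p < alpha rows are flagged.
    """
    rows = []
    arms = sorted(df[arm_col].dropna().unique().tolist())
    for geometry in sorted(df["geometry"].unique()):
        sub = df[df["geometry"] == geometry]
        for desc in DESCRIPTOR_NAMES:
            for terr in sorted(sub[territory_col].dropna().unique()):
                cell = sub[sub[territory_col] == terr]
                rec = {"geometry": geometry, "descriptor": desc, "territory": terr}
                groups = [cell.loc[cell[arm_col] == arm, desc].to_numpy(float)
                          for arm in arms]
                for arm, vals in zip(arms, groups):
                    ok = vals[~np.isnan(vals)]
                    rec[str(arm)] = _median_iqr(ok) if len(ok) else ""
                if len(arms) == 2 and all((~np.isnan(g)).sum() >= 2 for g in groups):
                    cmp_ = compare_groups(groups[0], groups[1], "continuous")
                    rec["p"] = cmp_.p
                    rec["significant"] = cmp_.p < alpha
                else:
                    rec["p"] = np.nan
                    rec["significant"] = False
                rows.append(rec)
    return pd.DataFrame(rows)
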