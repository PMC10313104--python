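"""End-to-end orchestration: ingest -> standardize -> analyze -> report.

A run executes, for every readable study: validation, coordinate
computation, warping onto the reference geometry and lattice resampling;
then group-level statistics per culprit territory (mean pattern,
transmurality/location/variability Bull's eyes, per-location Hotelling
p-map between treatment arms, fraction of significant locations), the five
global descriptors before/after standardization, and the realigned t-SNE
population embedding.  Every number written to the run directory is
reproducible from the manifest (full configuration, package version, seeds,
per-subject inclusion/exclusion log) plus the inputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .atlas import build_reference_geometry, resample_to_lattice, warp_to_reference
from .coordinates import compute_coordinates
from .descriptors import compute_globals, descriptor_table
from .embedding import ZeroMassError, embed_tsne, plot_colored, realign_to_lad
from .io import read_bundle, validate_study, write_cohort_table
from .stats import (bullseye_summarize, group_average, hotelling_map,
                    location_map, plot_bullseye, significant_fraction,
                    transmurality_map, variability_map)

logger = logging.getLogger("myoatlas")


@dataclass
class RunConfig:
    """All tunable parameters of a pipeline run (defaults = study values)."""

    input_dir: str | None = None
    output_dir: str = "myoatlas-run"
    # reference geometry
    ref_endo_radius: float = 30.0
    ref_epi_radius: float = 50.0
    ref_n_slices: int = 21
    ref_grid_size: int = 80
    # analysis lattice
    n_c: int = 24
    n_r: int = 20
    # coordinates
    oversample: int = 4
    chirality: int = 1
    # statistics
    alpha: float = 0.05
    hotelling_mode: str = "profile"
    group_by: str = "treatment"
    territory_col: str = "territory"
    # embedding
    perplexity: float = 10.0
    n_components: int = 2
    tsne_init: str = "pca"
    seed: int = 0
    make_figures: bool = True

    def reference(self):
        return build_reference_geometry(self.ref_endo_radius, self.ref_epi_radius,
                                        self.ref_n_slices, self.ref_grid_size)


class PipelineError(Exception):
    pass


def compute_cohort_lattices(studies, ref, oversample: int = 4, n_c: int = 24,
                            n_r: int = 20, channel: str = "infarct") -> dict:
    """Standardize a list of studies and return per-subject analysis lattices.

    Convenience wrapper for cohort-level experiments: coordinates -> warp ->
    lattice for every study, keyed by subject id.  Failing subjects are
    skipped with a logged warning.
    """
    out = {}
    for study in studies:
        try:
            cmap = compute_coordinates(study, oversample=oversample)
            pattern = warp_to_reference(study, cmap, ref)
            out[study.subject_id] = resample_to_lattice(
                pattern, ref, n_c=n_c, n_r=n_r)[channel]
        except Exception as exc:   # noqa: BLE001
            logger.warning("subject %s skipped: %s", study.subject_id, exc)
    return out


def load_studies(input_dir) -> list:
    """Read every study bundle found under ``input_dir`` (sorted)."""
    root = Path(input_dir)
    out = []
    for p in sorted(root.iterdir()):
        if (p / "study.json").exists():
            out.append(p)
    return out


def run_pipeline(config: RunConfig, studies: list | None = None) -> Path:
    """Execute the full analysis; returns the run directory.

    ``studies`` may be given directly (list of SegmentedStudy) or loaded
    from ``config.input_dir`` bundles.  Per-subject failures are logged to
    the manifest and skipped; the run aborts only when no subject survives.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    ref = config.reference()
    inclusion: list[dict] = []
    lattices: dict[str, np.ndarray] = {}
    desc_rows: list[dict] = []
    meta_rows: list[dict] = []

    if studies is None:
        if config.input_dir is None:
            raise PipelineError("neither studies nor input_dir given")
        sources = load_studies(config.input_dir)
        if not sources:
            raise PipelineError(f"no study bundles under {config.input_dir}")
    else:
        sources = studies

    for src in sources:
        sid = getattr(src, "subject_id", None) or Path(str(src)).name
        try:
            study = read_bundle(src) if not hasattr(src, "labels") else src
            sid = study.subject_id
            report = validate_study(study)
            cmap = compute_coordinates(study, oversample=config.oversample,
                                       chirality=config.chirality)
            pattern = warp_to_reference(study, cmap, ref)
            lat = resample_to_lattice(pattern, ref, n_c=config.n_c, n_r=config.n_r)
            lattices[sid] = lat["infarct"]
            for mode_src, kwargs in ((study, {"oversample": config.oversample}),
                                     (pattern, {"ref": ref})):
                desc = compute_globals(mode_src, n_c=config.n_c, n_r=config.n_r,
                                       **kwargs)
                desc_rows.append({**desc.as_dict(), **study.covariates})
            meta_rows.append({"subject_id": sid, **study.covariates})
            inclusion.append({"subject_id": sid, "included": True,
                              "validation_passed": report.passed,
                              "notes": report.notes})
        except Exception as exc:    # noqa: BLE001 - per-subject resilience
            logger.warning("subject %s excluded: %s", sid, exc)
            inclusion.append({"subject_id": str(sid), "included": False,
                              "reason": f"{type(exc).__name__}: {exc}"})
    if not lattices:
        raise PipelineError("no subject could be processed")

    meta = pd.DataFrame(meta_rows)
    write_cohort_table(meta, out / "cohort.csv")
    desc_df = pd.DataFrame(desc_rows)
    desc_df.to_csv(out / "descriptors.csv", index=False)
    table = descriptor_table(desc_df, arm_col=config.group_by,
                             territory_col=config.territory_col,
                             alpha=config.alpha)
    table.to_csv(out / "descriptor_table.csv", index=False)

    group_stats = _group_analysis(meta, lattices, config, out)
    embedding_info = _embedding_analysis(meta, lattices, config, out)

    manifest = {
        "package_version": __version__,
        "config": dataclasses.asdict(config),
        "reference_geometry": {
            "endo_radius_px": config.ref_endo_radius,
            "epi_radius_px": config.ref_epi_radius,
            "n_slices": config.ref_n_slices,
            "grid": [config.ref_grid_size, config.ref_grid_size],
        },
        "embedding": embedding_info,
        "n_included": int(sum(r["included"] for r in inclusion)),
        "n_excluded": int(sum(not r["included"] for r in inclusion)),
        "subjects": inclusion,
        "group_stats": group_stats,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return out


def _group_analysis(meta: pd.DataFrame, lattices: dict, config: RunConfig,
                    out: Path) -> dict:
    stats_out = {}
    arms = sorted(meta[config.group_by].dropna().unique().tolist())
    terr_values = sorted(meta[config.territory_col].dropna().unique().tolist()) \
        if config.territory_col in meta else ["all"]
    be_dir = out / "bullseye"
    be_dir.mkdir(exist_ok=True)
    for terr in terr_values:
        sel = meta if terr == "all" else meta[meta[config.territory_col] == terr]
        pats = [lattices[s] for s in sel["subject_id"] if s in lattices]
        if not pats:
            continue
        summary = group_average(pats, label=str(terr))
        entry = {"n": len(pats)}
        slug = str(terr).replace(" ", "_")
        for metric, map2d in (("location", location_map(summary.mean)),
                              ("transmurality", transmurality_map(summary.mean)),
                              ("variability", variability_map(pats))):
            be = bullseye_summarize(map2d, metric=f"{terr} {metric}")
            _save_bullseye(be, be_dir / f"{slug}_{metric}", config.make_figures)
        if len(arms) == 2:
            ga = [lattices[s] for s, g in zip(sel["subject_id"],
                                              sel[config.group_by])
                  if g == arms[0] and s in lattices]
            gb = [lattices[s] for s, g in zip(sel["subject_id"],
                                              sel[config.group_by])
                  if g == arms[1] and s in lattices]
            if len(ga) >= 3 and len(gb) >= 3:
                try:
                    pmap = hotelling_map(ga, gb, mode=config.hotelling_mode,
                                         alpha=config.alpha)
                    be = bullseye_summarize(pmap.p, metric=f"{terr} p-value",
                                            log_scale=True)
                    _save_bullseye(be, be_dir / f"{slug}_pvalue",
                                   config.make_figures)
                    entry["significant_fraction_pct"] = significant_fraction(
                        pmap, alpha=config.alpha)
                    entry["n_arms"] = [len(ga), len(gb)]
                except Exception as exc:   # noqa: BLE001
                    logger.warning("territory %s: group comparison failed: %s",
                                   terr, exc)
        stats_out[str(terr)] = entry
    return stats_out


def _embedding_analysis(meta: pd.DataFrame, lattices: dict, config: RunConfig,
                        out: Path) -> dict:
    ids, pats, terrs = [], [], []
    for sid, terr in zip(meta["subject_id"], meta.get(
            config.territory_col, pd.Series(["all"] * len(meta)))):
        if sid not in lattices:
            continue
        lat = lattices[sid]
        if np.nansum(lat) <= 0:
            logger.warning("subject %s has no infarct; excluded from embedding",
                           sid)
            continue
        ids.append(sid)
        pats.append(lat)
        terrs.append(terr)
    info = {"n_embedded": len(ids), "perplexity": config.perplexity,
            "n_components": config.n_components, "init": config.tsne_init,
            "seed": config.seed}
    if len(ids) < 3 * config.perplexity:
        logger.warning("too few subjects (%d) for t-SNE at perplexity %s; "
                       "embedding skipped", len(ids), config.perplexity)
        info["skipped"] = True
        return info
    try:
        rotated, rotations = realign_to_lad(pats, terrs)
    except ZeroMassError:
        rotated, rotations = pats, {}
    except Exception as exc:   # noqa: BLE001 - e.g. no LAD subjects
        logger.warning("realignment skipped: %s", exc)
        rotated, rotations = pats, {}
    emb = embed_tsne(rotated, perplexity=config.perplexity,
                     n_components=config.n_components, init=config.tsne_init,
                     seed=config.seed, rotations=rotations)
    df = pd.DataFrame({"subject_id": ids,
                       "dim1": emb.coords[:, 0], "dim2": emb.coords[:, 1]})
    df.to_csv(out / "embedding.csv", index=False)
    info["rotations"] = {k: float(v) for k, v in rotations.items()}
    if config.make_figures:
        cov = meta.set_index("subject_id").loc[ids]
        keep = [c for c in cov.columns if c != "subject_id"]
        fig = plot_colored(emb, cov[keep])
        fig.savefig(out / "embedding.png", dpi=110)
        import matplotlib.pyplot as plt
        plt.close(fig)
    return info


def _save_bullseye(be, stem: Path, make_figure: bool) -> None:
    pd.DataFrame(be.values).to_csv(f"{stem}.csv", index=False)
    if make_figure:
        import matplotlib
        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt
        ax = plot_bullseye(be)
        ax.figure.savefig(f"{stem}.png", dpi=110)
        plt.close(ax.figure)
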