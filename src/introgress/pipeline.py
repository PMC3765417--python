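"""End-to-end orchestration: read, QC, statistics, estimation, reports.

``run_pipeline`` executes the full analysis on a study dataset and writes TSV
reports: per-sample summary statistics, the temporal F_ST / exclusion table,
the introgression-estimate table, global F_ST + isolation-by-distance per era
and panel, pairwise F_ST matrices, and plot-coordinate CSVs for the PCA
views.  A run manifest records the package version, master seed and
configuration, and every stochastic stage receives a seed derived from the
master seed and the stage/river labels, so a re-run under the same master
seed reproduces all reports byte-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from ._seeds import child_seed
from .assignment import exclusion_summary
from .diffstats import (
    fst_permutation_test,
    global_fst_bootstrap,
    mantel_ibd,
    pairwise_fst_matrix,
    pca_fst,
    pca_individuals,
    wc_theta,
)
from .estimators import AbcConfig, FixedGridConfig, estimate_all_populations
from .genodata import DataError, StudyDataset, qc_filter, subset_panel
from .sumstats import sample_summary_table

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Knobs of a full pipeline run (reduced defaults suit small fixtures)."""

    out_dir: str = "results"
    seed: int = 0
    locus_min_coverage: float = 0.90
    individual_min_coverage: float = 0.75
    alpha: float = 0.05
    panels: tuple[str, ...] = ("all", "diagnostic", "random")
    estimate_panel: str = "diagnostic"
    methods: tuple[str, ...] = ("abc", "fixed_grid")
    scenarios: tuple[str, ...] = ("farmed", "neighbour")
    n_perm: int = 199
    n_boot: int = 200
    n_mc_exclusion: int = 1000
    abc: AbcConfig = field(default_factory=lambda: AbcConfig(n_sim_per_iter=200, max_iter=8))
    grid: FixedGridConfig = field(default_factory=lambda: FixedGridConfig(replicates_per_value=10))
    run_exclusion: bool = True
    run_estimation: bool = True


def _config_hash(cfg: PipelineConfig) -> str:
    payload = dataclasses.asdict(cfg)
    payload.pop("out_dir", None)  # output location is not part of the analysis
    payload = json.dumps(
        payload, default=lambda o: getattr(o, "tolist", lambda: str(o))(),
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(data: StudyDataset, cfg: PipelineConfig) -> dict:
    """Run every analysis stage and write the report bundle.

    Returns a dict of stage name -> DataFrame (or path for coordinate files).
    Stages failing for one river are logged and skipped; independent stages
    still complete.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}

    data, qc_report = qc_filter(data, cfg.locus_min_coverage, cfg.individual_min_coverage)
    qc_report.to_csv(out / "qc_report.tsv", sep="\t", index=False)
    results["qc"] = qc_report

    # Table-1-style summary statistics
    summary = sample_summary_table(data, alpha=cfg.alpha)
    summary.to_csv(out / "summary_stats.tsv", sep="\t", index=False)
    results["summary"] = summary

    # Table-2-style temporal F_ST per river and panel
    rows = []
    for river in data.rivers:
        hist = data.get(river, "historical")
        contemp = data.get(river, "contemporary")
        row = {"river": river}
        for panel in cfg.panels:
            try:
                ds = subset_panel(data, panel)
                h, c = ds.get(river, "historical"), ds.get(river, "contemporary")
                row[f"theta_{panel}"] = wc_theta(h, c).theta
            except DataError as exc:
                logger.warning("temporal theta %s/%s: %s", river, panel, exc)
                row[f"theta_{panel}"] = np.nan
        row["p_perm"] = fst_permutation_test(
            hist, contemp, n_perm=cfg.n_perm, seed=child_seed(cfg.seed, "perm", river)
        )
        rows.append(row)
    temporal = pd.DataFrame(rows)
    temporal.to_csv(out / "temporal_fst.tsv", sep="\t", index=False)
    results["temporal_fst"] = temporal

    # pairwise matrices + PCoA coordinates per panel
    for panel in cfg.panels:
        try:
            theta_m, _ = pairwise_fst_matrix(data, panel=panel)
        except DataError as exc:
            logger.warning("pairwise matrix %s: %s", panel, exc)
            continue
        theta_m.to_csv(out / f"pairwise_fst_{panel}.tsv", sep="\t")
        coords, expl = pca_fst(theta_m)
        coords.iloc[:, :4].assign(explained_1=expl[0], explained_2=expl[1]).to_csv(
            out / f"pcoa_{panel}.csv"
        )
        results[f"pairwise_{panel}"] = theta_m

    # Table-5-style global F_ST + IBD per era and panel
    rows = []
    for panel in cfg.panels:
        for era in ("historical", "contemporary"):
            try:
                ds = subset_panel(data, panel)
            except DataError:
                continue
            era_samples = [s for s in ds.samples if s.era == era]
            if len(era_samples) < 2:
                continue
            g = global_fst_bootstrap(
                era_samples, n_boot=cfg.n_boot,
                seed=child_seed(cfg.seed, "globalfst", panel, era), locus_set=panel,
            )
            row = {"panel": panel, "era": era, "global_fst": g.theta, "sd": g.sd,
                   "ci_low": g.ci_low, "ci_high": g.ci_high}
            if data.distances is not None:
                theta_m, _ = pairwise_fst_matrix(
                    StudyDataset(era_samples, data.pop_meta, None, data.name),
                    panel="all",
                )
                rivers = [s.river for s in era_samples]
                geo = data.distances.loc[rivers, rivers]
                r, p = mantel_ibd(
                    theta_m.values, geo.values, n_perm=max(cfg.n_perm, 99),
                    seed=child_seed(cfg.seed, "mantel", panel, era),
                )
                row.update({"ibd_r": r, "ibd_p": p})
            else:
                logger.warning("no distance matrix: IBD skipped for %s/%s", panel, era)
            rows.append(row)
    spatio = pd.DataFrame(rows)
    spatio.to_csv(out / "global_fst_ibd.tsv", sep="\t", index=False)
    results["global_fst_ibd"] = spatio

    # individual-genotype PCA coordinates (wild + farmed)
    try:
        coords, centroids, expl = pca_individuals(data.samples)
        coords.to_csv(out / "pca_individuals.csv", index=False)
        centroids.to_csv(out / "pca_centroids.csv", index=False)
        results["pca_individuals"] = coords
    except DataError as exc:
        logger.warning("individual PCA skipped: %s", exc)

    # exclusion tests
    if cfg.run_exclusion:
        excl = exclusion_summary(
            data, n_mc=cfg.n_mc_exclusion, seed=child_seed(cfg.seed, "exclusion"),
            include_farmed=data.farmed is not None,
        )
        excl.to_csv(out / "exclusion.tsv", sep="\t", index=False)
        results["exclusion"] = excl

    # introgression estimation
    if cfg.run_estimation and data.farmed is not None:
        scenarios = cfg.scenarios
        if data.distances is None and "neighbour" in scenarios:
            logger.warning("no distance matrix: neighbour scenario skipped")
            scenarios = tuple(s for s in scenarios if s != "neighbour")
        est = estimate_all_populations(
            data, methods=cfg.methods, scenarios=scenarios,
            panel=cfg.estimate_panel, abc_cfg=cfg.abc, grid_cfg=cfg.grid,
            seed=child_seed(cfg.seed, "estimate"), ci_boot=cfg.n_boot,
        )
        est.to_csv(out / "introgression_estimates.tsv", sep="\t", index=False)
        results["estimates"] = est

    manifest = {
        "package_version": __version__,
        "seed": cfg.seed,
        "config_hash": _config_hash(cfg),
        "n_samples": len(data.samples),
        "n_loci": len(data.loci),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    results["manifest"] = manifest
    return results
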