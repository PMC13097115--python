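"""End-to-end orchestration: load/simulate a cohort, run every analysis stage,
and write a deterministic TSV/JSON report bundle.

Stage order follows the analysis narrative: clinical univariate -> clinical
PCA -> lipid ANOVA -> lipid clustering -> cytokine ANOVA -> cytokine
clustering -> OPLS-DA -> ratio screen -> validation contrast.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .anova import analyze_panel, significant_analytes, twoway_anova, protected_lsd, CONTRAST_PAIRS
from .cluster import cluster_center_scores, gap_statistic, kmeans_partition, zscore_analytes
from .cohort import CohortTable
from .errors import ConfigurationError, LipokineError
from .oplsda import loocv_classification_error, oplsda_fit
from .pca import pca_variability
from .ratios import build_ratio_features, filter_screen, stratified_ratio_correlation, volcano_table
from .synth import GeneratorConfig, generate_cohort
from .validate import validate_panel

log = logging.getLogger("lipokine")


@dataclass
class PipelineConfig:
    cohort_csv: str | None = None
    generator: GeneratorConfig | None = None
    out_dir: str = "lipokine_out"
    seed: int = 0
    alpha: float = 0.05
    boxcox: str = "auto"
    k_max: int = 8
    b_refs: int = 100
    n_ortho: int = 1
    oplsda_groups: tuple = ("Dx-White", "Dx-AA")
    endpoints: tuple = ("clin_hba1c", "clin_homa_ir")
    run_validation: bool = True

    def validate(self) -> None:
        if self.cohort_csv is None and self.generator is None:
            raise ConfigurationError("either cohort_csv or a generator config is required")
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha must be in (0, 1)")
        if self.boxcox not in ("auto", "always", "never"):
            raise ConfigurationError("boxcox must be auto|always|never")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["oplsda_groups"] = list(self.oplsda_groups)
        d["endpoints"] = list(self.endpoints)
        if self.generator is not None:
            d["generator"] = self.generator.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if d.get("generator") is not None:
            d["generator"] = GeneratorConfig.from_dict(d["generator"])
        if "oplsda_groups" in d:
            d["oplsda_groups"] = tuple(d["oplsda_groups"])
        if "endpoints" in d:
            d["endpoints"] = tuple(d["endpoints"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")


def _cluster_stage(
    cohort: CohortTable,
    panel: str,
    panel_result: pd.DataFrame,
    cfg: PipelineConfig,
    out: Path,
    manifest: dict,
) -> None:
    sig = significant_analytes(panel_result, cfg.alpha)
    manifest[f"{panel}_significant"] = sig
    if len(sig) < max(4, cfg.k_max + 1):
        log.info("%s: only %d significant analytes; clustering skipped", panel, len(sig))
        return
    feats = zscore_analytes(cohort.panel(panel)[sig])
    gap = gap_statistic(feats, k_max=min(cfg.k_max, len(sig) - 1), b_refs=cfg.b_refs, seed=cfg.seed)
    model = kmeans_partition(feats, gap.k_star, seed=cfg.seed)
    centers = cluster_center_scores(model, cohort.panel(panel)[sig])
    _write_tsv(
        pd.DataFrame({"k": gap.k_grid, "gap": gap.gap, "sk": gap.sk, "log_wk": gap.log_wk}),
        out / f"{panel}_gap.tsv",
    )
    _write_tsv(
        pd.DataFrame({"analyte": list(model.assignment), "cluster": list(model.assignment.values())}),
        out / f"{panel}_clusters.tsv",
    )
    _write_tsv(centers, out / f"{panel}_cluster_centers.tsv", index=True)
    # four-group comparison of each cluster-center score
    rows = []
    race = cohort.race.to_numpy()
    disease = cohort.disease.to_numpy()
    for col in centers.columns:
        rec = twoway_anova(centers[col].to_numpy(), race, disease, analyte=col)
        comps = protected_lsd(rec, alpha=cfg.alpha)
        row = {
            "cluster": col, "omnibus_p": rec.omnibus_p,
            "p_race": rec.p_race, "p_disease": rec.p_disease, "p_interaction": rec.p_interaction,
        }
        for (a, b), c in zip(CONTRAST_PAIRS, comps):
            row[f"p_{a}_vs_{b}".replace("-", "")] = c.p_raw
        rows.append(row)
    _write_tsv(pd.DataFrame(rows), out / f"{panel}_cluster_center_anova.tsv")
    manifest[f"{panel}_k_star"] = int(gap.k_star)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all applicable stages; returns the run manifest (also written
    to ``<out_dir>/manifest.json``)."""
    cfg = config
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "stages": [],
    }

    # --- input ---------------------------------------------------------
    if cfg.cohort_csv is not None:
        cohort = CohortTable.from_csv(cfg.cohort_csv)
        log.info("loaded cohort from %s (%d subjects)", cfg.cohort_csv, cohort.n_subjects)
    else:
        gen = cfg.generator
        cohort, truth = generate_cohort(gen)
        cohort.to_csv(out / "cohort.csv")
        truth.to_json(out / "truth.json")
        manifest["stages"].append("simulate")
        log.info("simulated cohort with seed %d (%d subjects)", gen.seed, cohort.n_subjects)

    # --- clinical ------------------------------------------------------
    if cohort.has_panel("clinical"):
        clin_result = analyze_panel(cohort, "clinical", alpha=cfg.alpha, boxcox=cfg.boxcox)
        _write_tsv(clin_result, out / "clinical_anova.tsv")
        manifest["stages"].append("clinical_anova")
        manifest["boxcox_applied"] = {
            a: bool(b) for a, b in zip(clin_result["analyte"], clin_result["boxcox_applied"])
        }
        try:
            pca = pca_variability(cohort.panel("clinical"))
            _write_tsv(pca.cos2, out / "clinical_pca_cos2.tsv", index=True)
            _write_tsv(pca.contribution_pct, out / "clinical_pca_contributions.tsv", index=True)
            _write_tsv(
                pca.explained_variance_fraction.rename("fraction").to_frame(),
                out / "clinical_pca_variance.tsv", index=True,
            )
            manifest["stages"].append("clinical_pca")
        except LipokineError as exc:
            log.warning("clinical PCA skipped: %s", exc)

    # --- analyte panels -------------------------------------------------
    panel_results: dict[str, pd.DataFrame] = {}
    for panel in ("lipid", "cytokine"):
        if not cohort.has_panel(panel):
            log.info("no %s panel; downstream %s stages skipped", panel, panel)
            continue
        result = analyze_panel(cohort, panel, alpha=cfg.alpha, boxcox=cfg.boxcox)
        panel_results[panel] = result
        _write_tsv(result, out / f"{panel}_anova.tsv")
        manifest["stages"].append(f"{panel}_anova")
        manifest.setdefault("boxcox_applied", {}).update(
            {a: bool(b) for a, b in zip(result["analyte"], result["boxcox_applied"])}
        )
        _cluster_stage(cohort, panel, result, cfg, out, manifest)

        # OPLS-DA on the significant analytes, contrasting the configured groups
        sig = significant_analytes(result, cfg.alpha)
        grp = cohort.group
        sel = grp.isin(cfg.oplsda_groups).to_numpy()
        if len(sig) >= 2 and sel.sum() >= 4:
            X = cohort.panel(panel)[sig].loc[sel]
            labels = grp[sel].to_numpy()
            try:
                model = oplsda_fit(X, labels, n_ortho=cfg.n_ortho)
                err = loocv_classification_error(X, labels, n_ortho=cfg.n_ortho)
                ranking = model.feature_scores_lv1.reindex(
                    model.feature_scores_lv1.abs().sort_values(ascending=False).index
                )
                rank_df = ranking.rename("lv1_loading").rename_axis("analyte").reset_index()
                rank_df["top10"] = rank_df.index < 10
                _write_tsv(rank_df, out / f"{panel}_oplsda_ranking.tsv")
                (out / f"{panel}_oplsda_summary.json").write_text(
                    json.dumps(
                        {
                            "r2cal": model.r2cal,
                            "loocv_error": err,
                            "n_ortho": model.n_ortho,
                            "groups": list(cfg.oplsda_groups),
                            "n_features": len(sig),
                        },
                        indent=2, sort_keys=True,
                    )
                )
                manifest["stages"].append(f"{panel}_oplsda")
            except LipokineError as exc:
                log.warning("%s OPLS-DA skipped: %s", panel, exc)

    # --- ratio screen ---------------------------------------------------
    if cohort.has_panel("lipid") and cohort.has_panel("cytokine"):
        feats = build_ratio_features(cohort.panel("lipid"), cohort.panel("cytokine"))
        for endpoint in cfg.endpoints:
            if endpoint not in cohort.data.columns:
                log.warning("endpoint %s missing; ratio screen for it skipped", endpoint)
                continue
            screen = stratified_ratio_correlation(
                feats, cohort.data[endpoint], cohort.race, alpha=cfg.alpha,
                endpoint_name=endpoint,
            )
            tag = endpoint.removeprefix("clin_")
            _write_tsv(screen, out / f"ratio_screen_{tag}_full.tsv")
            _write_tsv(filter_screen(screen), out / f"ratio_screen_{tag}_filtered.tsv")
            _write_tsv(volcano_table(screen), out / f"ratio_volcano_{tag}.tsv")
            manifest["stages"].append(f"ratio_screen_{tag}")
    else:
        log.info("ratio screen skipped: needs both lipid and cytokine panels")

    # --- validation -----------------------------------------------------
    if cfg.run_validation and cohort.has_panel("clinical") and {"bmi", "age"} <= set(cohort.data.columns):
        val = validate_panel(cohort)
        _write_tsv(val, out / "validation_contrasts.tsv")
        manifest["stages"].append("validation")

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return manifest
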