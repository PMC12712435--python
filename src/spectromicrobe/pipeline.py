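"""End-to-end orchestration: synthetic data (or CSV inputs) through spectral
preparation, microbial derivation, plot aggregation, association statistics
and the PLSR ensemble, producing a machine-readable run report.

Stage order mirrors the analysis sequence the package implements:
ingest -> spectra preparation -> microbial responses -> core-to-plot
aggregation and temporal alignment -> association statistics -> ensemble
PLSR per response. Identical config + seed reproduces identical artifacts.
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
from .association_stats import pca_leading_axes, spearman_matrix, varpart_with_tests
from .errors import ConfigError, SpectroMicrobeError
from .microbial_derive import filter_taxa, plfa_groups, rarefy, richness
from .plot_aggregate import AlignmentRule, aggregate_cores, align_observations
from .plsr_ensemble import baseline_index_model, run_plsr_workflow
from .spectra_prep import (
    DEFAULT_KEEP_RANGES,
    NDVI,
    NDWI,
    SpectraMatrix,
    compute_index,
    prepare_spectra,
)
from .synthetic_neon import SyntheticConfig, generate_dataset

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Resolved configuration for a full run; defaults follow the study design
    this package models (60 d window, NDVI 0.4, 5000 reads, 5% outliers,
    70/30 splits, 200 models, 999 permutations)."""

    seed: int = 0
    synth: dict = field(default_factory=dict)   # SyntheticConfig overrides
    input_dir: str | None = None                # read CSVs instead of synth
    out_dir: str | None = None
    responses: list[str] = field(default_factory=lambda: ["gram_positive", "total_plfa"])
    ndvi_threshold: float = 0.4
    keep_ranges: list = field(default_factory=lambda: [list(r) for r in DEFAULT_KEEP_RANGES])
    rarefaction_depth: int = 5000
    max_offset_days: int = 60
    cross_table_offset_days: int = 120
    aggregation_method: str = "shrinkage"
    n_models: int = 200
    outlier_fraction: float = 0.05
    outlier_runs: int = 200
    calibration_fraction: float = 0.7
    press_permutations: int = 200
    max_components: int | None = None
    n_permutations: int = 999
    run_varpart: bool = True
    run_correlations: bool = True
    run_plsr: bool = True

    def validate(self) -> None:
        if not (0 < self.calibration_fraction < 1):
            raise ConfigError("calibration_fraction must be in (0, 1)")
        if not (0 <= self.outlier_fraction < 1):
            raise ConfigError("outlier_fraction must be in [0, 1)")
        if self.rarefaction_depth < 1:
            raise ConfigError("rarefaction_depth must be >= 1")
        if self.n_models < 1:
            raise ConfigError("n_models must be >= 1")
        if self.n_permutations < 1:
            raise ConfigError("n_permutations must be >= 1")
        if self.max_offset_days <= 0 or self.cross_table_offset_days <= 0:
            raise ConfigError("alignment offsets must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {', '.join(sorted(unknown))}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _json_safe(obj):
    if isinstance(obj, dict):
        return {str(k): _json_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_safe(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (pd.Timestamp,)):
        return str(obj.date())
    return obj


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all configured stages and return the run report (a dict).

    Artifacts (CSV tables, report JSON, markdown summary) are written to
    ``config.out_dir`` when set.
    """
    config.validate()
    report: dict = {
        "version": __version__,
        "config": _json_safe(config.to_dict()),
        "stages": {},
    }
    seeds = np.random.SeedSequence(config.seed).spawn(6)
    sub = [int(s.generate_state(1)[0] % (2**31)) for s in seeds]

    # ---- stage: data -------------------------------------------------------
    if config.input_dir:
        indir = Path(config.input_dir)
        spectra = SpectraMatrix.read_csv(indir / "spectra.csv")
        lipids = pd.read_csv(indir / "lipids.csv")
        asv_counts = pd.read_csv(indir / "asv_counts.tsv", sep="\t", index_col="sample_id")
        taxonomy = pd.read_csv(indir / "taxonomy.tsv", sep="\t").fillna("")
        foliar = pd.read_csv(indir / "foliar.csv")
        soil = pd.read_csv(indir / "soil.csv")
        climate = pd.read_csv(indir / "climate.csv")
        plot_meta = pd.read_csv(indir / "plot_meta.csv")
        report["stages"]["data"] = {"source": str(indir), "n_plots": len(spectra.plot_ids)}
    else:
        synth_cfg = SyntheticConfig(**{"seed": sub[0], **config.synth})
        ds = generate_dataset(synth_cfg)
        spectra, lipids = ds.spectra, ds.lipids
        asv_counts, taxonomy = ds.asv_counts, ds.taxonomy
        foliar, soil, climate, plot_meta = ds.foliar, ds.soil, ds.climate, ds.plot_meta
        report["stages"]["data"] = {
            "source": "synthetic",
            "n_plots": synth_cfg.n_plots,
            "signal_fraction": synth_cfg.signal_fraction,
        }

    # ---- stage: spectra ----------------------------------------------------
    prepped, ndvi_excl = prepare_spectra(
        spectra,
        ndvi_threshold=config.ndvi_threshold,
        keep_ranges=[tuple(r) for r in config.keep_ranges],
    )
    ndvi_vals = compute_index(spectra.clip_negative(), NDVI)
    ndwi_vals = compute_index(spectra.clip_negative(), NDWI)
    index_df = pd.DataFrame(
        {"ndvi": ndvi_vals, "ndwi": ndwi_vals}, index=spectra.plot_ids
    )
    report["stages"]["spectra"] = {
        "n_in": len(spectra.plot_ids),
        "n_out": len(prepped.plot_ids),
        "n_bands_out": len(prepped.grid),
        "exclusions": _json_safe(ndvi_excl.to_dict(orient="records")),
    }
    if not prepped.plot_ids:
        report["stages"]["spectra"]["failed"] = "no plots survive the NDVI filter"
        return report

    # ---- stage: microbes ---------------------------------------------------
    plfa_cores = plfa_groups(lipids)
    core_long = plfa_cores.reset_index().melt(
        id_vars="sample_id", var_name="variable", value_name="value"
    )
    core_long["plot_id"] = core_long["sample_id"].str.rsplit("_C", n=1).str[0]
    plfa_plot = aggregate_cores(core_long, method=config.aggregation_method)

    filtered, removed_taxa = filter_taxa(asv_counts, taxonomy)
    rarefied, dropped_samples = rarefy(
        filtered, depth=config.rarefaction_depth, seed=sub[1]
    )
    rich = richness(rarefied)
    rich_long = rich.reset_index()
    rich_long.columns = ["sample_id", "value"]
    rich_long["variable"] = "richness"
    rich_long["plot_id"] = rich_long["sample_id"].str.rsplit("_C", n=1).str[0]
    rich_plot = aggregate_cores(rich_long, method="mean")
    report["stages"]["microbes"] = {
        "n_core_samples": len(plfa_cores),
        "n_asv_removed_taxa": len(removed_taxa),
        "n_samples_below_depth": len(dropped_samples),
        "n_samples_rarefied": len(rarefied),
    }

    # ---- stage: alignment --------------------------------------------------
    rule = AlignmentRule(config.max_offset_days, config.cross_table_offset_days)
    candidates = plot_meta[["plot_id", "image_date", "soil_date"]]
    other = {"foliar": foliar[["plot_id", "date"]]}
    kept, align_excl = align_observations(candidates, other, rule)
    aligned_plots = [p for p in prepped.plot_ids if p in set(kept["plot_id"])]
    report["stages"]["alignment"] = {
        "n_candidates": len(candidates),
        "n_kept": len(kept),
        "n_excluded": len(align_excl),
        "n_plots_modelled": len(aligned_plots),
    }
    if not aligned_plots:
        report["stages"]["alignment"]["failed"] = "no plots survive temporal alignment"
        return report

    # assemble the joined plot frame
    responses_plot = plfa_plot.join(rich_plot, how="left")
    responses_plot["fb_ratio"] = (
        responses_plot["saprophytic_fungi"] + responses_plot["am_fungi"]
    ) / (
        responses_plot["gram_positive"]
        + responses_plot["gram_negative"]
        + responses_plot["actinomycetes"]
    )
    frame = responses_plot.loc[[p for p in aligned_plots if p in responses_plot.index]]

    # ---- stage: associations -----------------------------------------------
    if config.run_varpart or config.run_correlations:
        foliar_p = foliar.set_index("plot_id")[
            [c for c in foliar.columns if c not in ("plot_id", "date")]
        ]
        soil_p = aggregate_cores(soil, method=config.aggregation_method)
        climate_p = climate.set_index("plot_id")[["mat", "map", "latitude", "longitude"]]
        lc = pd.get_dummies(
            plot_meta.set_index("plot_id")["land_cover"], drop_first=True, dtype=float
        )
        common = frame.index.intersection(foliar_p.index).intersection(
            soil_p.index
        ).intersection(climate_p.index).intersection(lc.index)
        frame_c = frame.loc[common].dropna()
        common = frame_c.index
        report["stages"]["associations"] = {"n_complete_case": len(common)}
        if config.run_varpart and len(common) > 25:
            groups = {
                "foliar_traits": pca_leading_axes(foliar_p.loc[common]).scores,
                "soil": pca_leading_axes(soil_p.loc[common]).scores,
                "climate_location": pca_leading_axes(climate_p.loc[common]).scores,
                "land_cover": lc.loc[common],
            }
            part = varpart_with_tests(
                frame_c.to_numpy(), groups, n_perm=config.n_permutations, seed=sub[2]
            )
            report["stages"]["associations"]["varpart"] = _json_safe(
                part.to_frame().to_dict(orient="records")
            )
            report["stages"]["associations"]["varpart_tests"] = {
                g: {"F": t.f_statistic, "p": t.p_value, "n_perm": t.n_permutations}
                for g, t in part.tests.items()
            }
        if config.run_correlations and len(common) >= 10:
            corr = spearman_matrix(foliar_p.loc[common], frame_c)
            report["stages"]["associations"]["n_significant_correlations"] = int(
                corr["significant"].sum()
            )

    # ---- stage: plsr -------------------------------------------------------
    if config.run_plsr:
        plsr_report = {}
        X_index = pd.Index(prepped.plot_ids)
        for ri, resp in enumerate(config.responses):
            if resp not in frame.columns:
                plsr_report[resp] = {"failed": "response not available"}
                continue
            y_series = frame[resp].dropna()
            plots = [p for p in prepped.plot_ids if p in y_series.index]
            rows = X_index.get_indexer(plots)
            X = prepped.reflectance[rows]
            y = y_series.loc[plots].to_numpy()
            try:
                wf = run_plsr_workflow(
                    X, y,
                    seed=sub[3] + ri,
                    n_models=config.n_models,
                    outlier_fraction=config.outlier_fraction,
                    outlier_runs=config.outlier_runs,
                    calibration_fraction=config.calibration_fraction,
                    press_permutations=config.press_permutations,
                    max_components=config.max_components,
                    response_name=resp,
                )
            except SpectroMicrobeError as exc:
                plsr_report[resp] = {"failed": str(exc)}
                continue
            idx = index_df.loc[plots]
            ndvi_metrics, _, _ = baseline_index_model(idx["ndvi"].to_numpy(), y)
            ndwi_metrics, _, _ = baseline_index_model(idx["ndwi"].to_numpy(), y)
            plsr_report[resp] = {
                "n_plots": len(y),
                "n_outliers_removed": int(len(wf.screen.removed_indices)),
                "n_components": wf.selection.n_components,
                "n_models": wf.ensemble.n_models,
                "metrics": dataclasses.asdict(wf.metrics),
                "ndvi_baseline_r2": ndvi_metrics.r2,
                "ndwi_baseline_r2": ndwi_metrics.r2,
                "n_informative_wavelengths": int(wf.informative_mask.sum()),
            }
            if config.out_dir:
                outdir = Path(config.out_dir)
                outdir.mkdir(parents=True, exist_ok=True)
                wf.predictions.to_csv(outdir / f"predictions_{resp}.csv", index_label="row")
                pd.DataFrame(
                    {
                        "wavelength_nm": prepped.wavelengths,
                        "coefficient_mean": wf.coefficients_mean,
                        "coefficient_sd": wf.coefficients_sd,
                        "vip": wf.vip,
                        "informative": wf.informative_mask,
                    }
                ).to_csv(outdir / f"coefficients_{resp}.csv", index=False)
        report["stages"]["plsr"] = plsr_report

    if config.out_dir:
        outdir = Path(config.out_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(json.dumps(_json_safe(report), indent=2))
        (outdir / "report.md").write_text(_markdown_summary(report))
    return report


def _markdown_summary(report: dict) -> str:
    lines = ["# Pipeline run report", ""]
    for stage, info in report["stages"].items():
        lines.append(f"## {stage}")
        if stage == "plsr":
            for resp, res in info.items():
                if "failed" in res:
                    lines.append(f"- **{resp}**: failed ({res['failed']})")
                    continue
                m = res["metrics"]
                lines.append(
                    f"- **{resp}**: R2={m['r2']:.3f}, NRMSE={m['nrmse']:.3f}, "
                    f"bias={m['bias']:.3f} (n={m['n']}, {res['n_components']} components, "
                    f"{res['n_models']} members)"
                )
        else:
            for key, val in info.items():
                if isinstance(val, (int, float, str)):
                    lines.append(f"- {key}: {val}")
        lines.append("")
    return "\n".join(lines)
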