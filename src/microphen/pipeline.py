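"""End-to-end orchestration of the association analysis.

Sequences the stages — QC -> calibration -> diversity -> indicator ->
differential abundance -> change-point hit calling — on real (file-based)
or synthetic inputs, and writes every stage output plus a machine-readable
JSON summary. Also provides the cross-experiment hit intersection used to
shortlist taxa that associate with plant performance in more than one
assay.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import _io, calibration, changepoint, diffabund, diversity, indicator, qc
from . import synthetic

log = logging.getLogger("microphen")

ALL_STAGES = ("qc", "calibration", "diversity", "indicator", "diffabund", "changepoint")


@dataclass
class PipelineConfig:
    """Parameters and file paths for one pipeline run."""

    mode: str = "phenotyper"
    counts: str | None = None
    taxonomy: str | None = None
    metadata: str | None = None
    soil: str | None = None
    phenotypes: str | None = None
    outdir: str = "microphen_out"
    seed: int = 0
    stages: Sequence[str] = ALL_STAGES
    # qc
    min_depth: float = 10_000
    ref_depth: float | None = None
    min_count: float = 100
    max_count: float = 200_000
    drop_flags: Sequence[str] = ("plastid", "unknown")
    # calibration
    spatial_model: str = "poly2"
    n_soil_pcs: int = 3
    genotype_col: str | None = None
    # diversity
    permanova_terms: Sequence[str] | None = None
    n_perm: int = 1000
    # indicator
    indicator_group: str | None = None
    indicator_subset: dict | None = None
    indval_n_perm: int = 999
    # diffabund
    diffabund_term: str = "watering"
    diffabund_max_otus: int = 100
    # changepoint
    pheno_cols: Sequence[str] | None = None
    alpha: float = 0.05
    n_boot: int = 1000
    min_above: int = 5

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        doc.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**doc)

    def validate(self) -> None:
        if self.mode not in {"phenotyper", "field"}:
            raise ValueError("mode must be 'phenotyper' or 'field'")
        for p in (self.counts, self.taxonomy, self.metadata, self.soil, self.phenotypes):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class PipelineResult:
    summary: dict
    tables: dict = dc_field(default_factory=dict)


def _load_inputs(config: PipelineConfig):
    counts = _io.read_counts(config.counts)
    metadata = _io.read_table_tsv(config.metadata)
    taxonomy = _io.read_taxonomy_tsv(config.taxonomy) if config.taxonomy else None
    soil = _io.read_table_tsv(config.soil) if config.soil else None
    phenos = _io.read_table_tsv(config.phenotypes) if config.phenotypes else None
    return counts, taxonomy, metadata, soil, phenos


def run_pipeline(
    config: PipelineConfig,
    counts: pd.DataFrame | None = None,
    taxonomy: pd.DataFrame | None = None,
    metadata: pd.DataFrame | None = None,
    soil: pd.DataFrame | None = None,
    phenotypes: pd.DataFrame | None = None,
    write: bool = True,
) -> PipelineResult:
    """Execute the configured stages; tables may be passed in-memory or
    read from the files named in the config. Deterministic given the seed."""
    config.validate()
    if counts is None:
        counts, taxonomy, metadata, soil, phenotypes = _load_inputs(config)
    if counts.shape[0] == 0 or counts.shape[1] == 0:
        raise qc.EmptyResultError("empty count table")
    metadata = metadata.loc[counts.index.intersection(metadata.index)]
    summary: dict = {"config": {k: (list(v) if isinstance(v, tuple) else v)
                                for k, v in vars(config).items()},
                     "stages": {}}
    tables: dict = {}
    stage = "start"
    try:
        rel = None
        kept_counts = counts
        if "qc" in config.stages:
            stage = "qc"
            t0 = time.perf_counter()
            kept = qc.filter_samples_by_depth(counts, config.min_depth)
            rescaled = qc.rescale_counts(kept, config.ref_depth)
            surviving = qc.filter_otus_by_bounds(rescaled, config.min_count, config.max_count)
            kept_counts = kept.loc[:, surviving]
            if taxonomy is not None:
                kept_counts = qc.remove_taxa(kept_counts, taxonomy, config.drop_flags)
            rel = qc.proportional_scale(kept_counts)
            metadata = metadata.loc[rel.index]
            summary["stages"]["qc"] = {
                "n_samples_in": int(counts.shape[0]), "n_otus_in": int(counts.shape[1]),
                "n_samples_out": int(rel.shape[0]), "n_otus_out": int(rel.shape[1]),
                "elapsed_s": round(time.perf_counter() - t0, 3),
            }
            tables["relative_abundance"] = rel
            log.info("qc: %s -> %s samples, %s -> %s OTUs",
                     counts.shape[0], rel.shape[0], counts.shape[1], rel.shape[1])
        if rel is None:
            rel = qc.proportional_scale(counts)

        cal_abund, cal_phenos = rel, phenotypes
        if "calibration" in config.stages:
            stage = "calibration"
            t0 = time.perf_counter()
            pcs = None
            if soil is not None:
                plot_col = "plot_id" if "plot_id" in metadata.columns else None
                soil_aligned = (
                    soil.loc[metadata[plot_col]].set_index(metadata.index)
                    if plot_col else soil.loc[metadata.index]
                )
                pcs = calibration.soil_pca(soil_aligned, k=config.n_soil_pcs)
            coords = metadata[["row", "col"]] if {"row", "col"} <= set(metadata.columns) else None
            cal_abund = calibration.calibrate_response(
                rel, pcs=pcs, coordinates=coords, spatial_model=config.spatial_model
            ).residuals
            rec = {"soil_pcs": None if pcs is None else pcs.explained_variance.tolist()}
            if phenotypes is not None:
                phen = phenotypes.loc[phenotypes.index.intersection(metadata.index)]
                pcs_p = None
                if pcs is not None:
                    pcs_p = calibration.SoilPCs(
                        scores=pcs.scores.loc[phen.index],
                        explained_variance=pcs.explained_variance,
                    )
                coords_p = coords.loc[phen.index] if coords is not None else None
                cal_phenos = calibration.calibrate_response(
                    phen, pcs=pcs_p, coordinates=coords_p, spatial_model=config.spatial_model
                ).residuals
                if config.genotype_col and config.genotype_col in metadata.columns:
                    cal_phenos = calibration.adjust_genotype(
                        cal_phenos, metadata.loc[cal_phenos.index, config.genotype_col]
                    ).residuals
            summary["stages"]["calibration"] = {
                **rec, "spatial_model": config.spatial_model,
                "elapsed_s": round(time.perf_counter() - t0, 3),
            }
            tables["calibrated_abundance"] = cal_abund
            if cal_phenos is not None:
                tables["calibrated_phenotypes"] = cal_phenos

        if "diversity" in config.stages:
            stage = "diversity"
            t0 = time.perf_counter()
            sh = diversity.shannon_per_sample(rel)
            tables["shannon"] = sh.to_frame()
            terms = list(config.permanova_terms) if config.permanova_terms else None
            if terms is None:
                terms = ["watering*microbe_treatment"] if config.mode == "phenotyper" \
                    else ["watering*genotype"]
            dist = diversity.bray_curtis(rel)
            perm = diversity.permanova(
                dist, metadata, terms, n_perm=config.n_perm, seed=config.seed
            )
            tables["permanova"] = perm
            summary["stages"]["diversity"] = {
                "mean_shannon": float(sh.mean()),
                "permanova": perm.drop(columns=["ss"]).to_dict("records"),
                "elapsed_s": round(time.perf_counter() - t0, 3),
            }

        if "indicator" in config.stages:
            stage = "indicator"
            t0 = time.perf_counter()
            group_col = config.indicator_group or (
                "microbe_treatment" if "microbe_treatment" in metadata.columns else "watering"
            )
            subset = config.indicator_subset
            if subset is None and "watering" in metadata.columns:
                subset = {"watering": "drought"}
            mask = pd.Series(True, index=metadata.index)
            for col, val in (subset or {}).items():
                mask &= metadata[col] == val
            sub_rel = rel.loc[mask[mask].index]
            iv = indicator.indval_test(
                sub_rel, metadata.loc[sub_rel.index, group_col],
                n_perm=config.indval_n_perm, seed=config.seed,
            )
            tables["indval"] = iv
            sets = indicator.indicator_sets(iv, alpha=config.alpha)
            summary["stages"]["indicator"] = {
                "group": group_col,
                "n_significant": int((iv["p_value"] < config.alpha).sum()),
                "exclusive_counts": sets["exclusive_counts"],
                "elapsed_s": round(time.perf_counter() - t0, 3),
            }

        if "diffabund" in config.stages:
            stage = "diffabund"
            t0 = time.perf_counter()
            prevalence = (kept_counts > 0).mean().sort_values(ascending=False)
            top = prevalence.index[: config.diffabund_max_otus]
            da = diffabund.test_differential(
                kept_counts[top], metadata, config.diffabund_term,
                alpha=config.alpha,
                group_col="compartment" if "compartment" in metadata.columns else None,
                library_size=kept_counts.sum(axis=1),
            )
            tables["diffabund"] = da
            summary["stages"]["diffabund"] = {
                "n_tested": int(len(da)),
                "n_enriched": int((da["direction"] == "enriched").sum()),
                "n_depleted": int((da["direction"] == "depleted").sum()),
                "elapsed_s": round(time.perf_counter() - t0, 3),
            }

        if "changepoint" in config.stages and cal_phenos is not None:
            stage = "changepoint"
            t0 = time.perf_counter()
            pheno_cols = tuple(config.pheno_cols or cal_phenos.columns[:2])
            drought_ids = (
                metadata.index[metadata["watering"] == "drought"]
                if "watering" in metadata.columns else metadata.index
            )
            ab = cal_abund.loc[cal_abund.index.intersection(drought_ids)]
            ph = cal_phenos.loc[ab.index]
            fits = changepoint.changepoint_scan(
                ab, ph, pheno_cols=pheno_cols, min_above=config.min_above,
                n_boot=config.n_boot, seed=config.seed,
            )
            tables["changepoint_fits"] = fits
            f1 = fits[fits["phenotype"] == pheno_cols[0]]
            f2 = fits[fits["phenotype"] == pheno_cols[1]]
            hits = changepoint.call_hits(f1, f2, alpha=config.alpha, taxonomy=taxonomy)
            tables["hits"] = hits
            summary["stages"]["changepoint"] = {
                "phenotypes": list(pheno_cols),
                "n_otus_scanned": int(fits["otu_id"].nunique()) if len(fits) else 0,
                "n_hits": int(len(hits)),
                "n_negative": int((hits["direction"] == "negative").sum()) if len(hits) else 0,
                "n_positive": int((hits["direction"] == "positive").sum()) if len(hits) else 0,
                "hits": hits.to_dict("records"),
                "elapsed_s": round(time.perf_counter() - t0, 3),
            }
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        log.error("pipeline halted at stage %r: %s", stage, exc)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    summary["seed"] = config.seed
    if write:
        write_report(summary, tables, config.outdir)
    return PipelineResult(summary=summary, tables=tables)


def write_report(summary: dict, tables: dict, outdir: str | Path) -> Path:
    """Persist all stage tables as TSV plus the JSON summary."""
    if not tables and not summary.get("stages"):
        raise ValueError("no stage output to report")
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for name, tab in tables.items():
        tab.to_csv(out / f"{name}.tsv", sep="\t")
    path = out / "summary.json"
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, default=_json_default, sort_keys=True)
    return path


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (set, tuple)):
        return sorted(obj) if isinstance(obj, set) else list(obj)
    return str(obj)


def intersect_hits(
    hits_a: pd.DataFrame,
    hits_b: pd.DataFrame,
    key_rank: str = "genus",
    labels: tuple[str, str] = ("experiment_a", "experiment_b"),
) -> pd.DataFrame:
    """Taxa called in the same direction in two experiments.

    Keys on a taxonomy rank (default genus, as cross-assay comparisons are
    made between OTU universes that do not share identifiers) or on
    ``otu_id``; entries must match in both key and direction.
    """
    for df, lab in ((hits_a, labels[0]), (hits_b, labels[1])):
        if key_rank != "otu_id" and key_rank not in df.columns:
            raise KeyError(f"hit list {lab!r} lacks taxonomy column {key_rank!r}")
    def keyset(df):
        keys = df[key_rank] if key_rank != "otu_id" else df["otu_id"]
        return set(zip(keys.astype(str), df["direction"]))
    common = keyset(hits_a) & keyset(hits_b)
    rows = [
        {"key": k, "direction": d, "present_in": list(labels)}
        for k, d in sorted(common) if k and k != "nan"
    ]
    return pd.DataFrame(rows) if rows else pd.DataFrame(columns=["key", "direction", "present_in"])


def run_synthetic(
    mode: str = "phenotyper",
    seed: int = 0,
    outdir: str | Path = "microphen_out",
    n_otus: int = 500,
    n_blocks: int = 8,
    n_replicates: int = 6,
    config: PipelineConfig | None = None,
    write: bool = True,
) -> tuple[PipelineResult, synthetic.SyntheticExperiment]:
    """Simulate an experiment and run the full pipeline on it."""
    exp = synthetic.simulate_experiment(
        mode=mode, seed=seed, n_otus=n_otus, n_blocks=n_blocks, n_replicates=n_replicates
    )
    planted = [c.otu_id for c in exp.truth.causal_otus] + list(
        exp.truth.otu_treatment_effects
    )
    taxonomy = synthetic.synthetic_taxonomy(exp.counts.columns, seed=seed, protect=planted)
    if config is None:
        config = PipelineConfig(mode=mode, outdir=str(outdir), seed=seed)
    if mode == "field":
        config.genotype_col = "genotype"
    result = run_pipeline(
        config,
        counts=exp.counts,
        taxonomy=taxonomy,
        metadata=exp.layout,
        soil=exp.soil,
        phenotypes=exp.phenotypes,
        write=write,
    )
    return result, exp
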