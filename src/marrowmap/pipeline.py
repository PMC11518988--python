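"""End-to-end orchestration of the spatial and expression arms.

The spatial arm runs per-biopsy: densities -> immune-phenotype calls
-> T/B interaction graphs -> networks and lymphoid-aggregate calls ->
group comparisons.  The expression arm runs: signature scores ->
region-type comparisons -> NNLS deconvolution -> CD4:CD8 ratios ->
correlation of the M2-predominance score with estimated T cell
abundance.  Every artifact is written as a delimited table (hulls as
GeoJSON) under the configured output directory, a log echoes all
parameters, and a markdown report summarizes the run.  Reruns with the
same config and seed reproduce identical tables.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from ._util import Undefined
from .cellmap import CellMap, density_table, read_cellmap, read_manifest, write_cellmap
from .deconvolution import build_signature_matrix, nnls_deconvolve
from .networks import (aggregates_table, detect_lymphoid_aggregates,
                       extract_networks, graph_for_phenotype, hulls_geojson,
                       networks_table, summarize_networks)
from .signatures import (KIND_RATIO, default_signatures, load_signatures,
                         compare_scores_by_region, read_expression_matrix,
                         score_signatures)
from .simulate import (default_reference_profiles, simulate_cohort,
                       simulate_region_dataset)
from .stats import (ALPHA_DEFAULT, ALPHA_SPATIAL, LABEL_INFILTRATED,
                    classify_immune_phenotype, kruskal_dunn, mann_whitney,
                    spearman_ci)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Single config driving both pipeline arms."""

    output_dir: str = "marrowmap_out"
    # spatial arm inputs
    manifest: str | None = None           # sample_id, group, tissue_area_mm2, cells_path
    cells_dir: str | None = None          # fallback: <cells_dir>/<sample_id>.csv
    # expression arm inputs
    expression_matrix: str | None = None
    region_annotations: str | None = None
    signatures_config: str | None = None  # None -> packaged defaults
    reference_profiles: str | None = None  # None -> synthetic default panel
    # parameters
    delta_um: float = 10.0
    n_min: int = 10
    n_large: int = 100
    coloc_delta_um: float = 20.0
    alpha_spatial: float = ALPHA_SPATIAL
    alpha_default: float = ALPHA_DEFAULT
    top_k_markers: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("delta_um", "n_min", "n_large", "coloc_delta_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("alpha_spatial", "alpha_default"):
            if not 0 < getattr(self, name) < 1:
                raise ValueError(f"{name} must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    def echo(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def _setup_output(config: PipelineConfig) -> Path:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logging.getLogger("marrowmap").addHandler(handler)
    logger.info("marrowmap %s; parameters: %s", __version__,
                json.dumps(config.echo(), default=str))
    return out


def _load_cellmaps(config: PipelineConfig) -> list[CellMap]:
    if config.manifest is None:
        raise PipelineError("load_cellmaps", "no manifest configured")
    manifest_path = Path(config.manifest)
    if not manifest_path.exists():
        raise PipelineError("load_cellmaps", f"manifest not found: {manifest_path}")
    manifest = read_manifest(manifest_path)
    maps = []
    for row in manifest.itertuples(index=False):
        if getattr(row, "cells_path", None) and isinstance(row.cells_path, str):
            path = manifest_path.parent / row.cells_path
        elif config.cells_dir:
            path = Path(config.cells_dir) / f"{row.sample_id}.csv"
        else:
            raise PipelineError("load_cellmaps",
                                f"no cells_path for sample {row.sample_id}")
        metadata = {"subgroup": getattr(row, "subgroup", None)}
        try:
            maps.append(read_cellmap(path, tissue_area_mm2=row.tissue_area_mm2,
                                     group=row.group, metadata=metadata))
        except (ValueError, FileNotFoundError) as exc:
            raise PipelineError("load_cellmaps", str(exc)) from exc
    return maps


def run_spatial_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run the spatial arm; returns the written artifact paths."""
    out = _setup_output(config)
    maps = _load_cellmaps(config)

    densities = density_table(maps)
    aml = densities[densities["group"] == "AML"].set_index("sample_id")["density_T"]
    controls = densities[densities["group"] == "CONTROL"]["density_T"]
    if controls.empty:
        raise PipelineError("phenotype_calls", "no CONTROL samples in manifest")
    cutoff, calls = classify_immune_phenotype(aml.to_dict(), controls)
    calls_df = pd.DataFrame([{"sample_id": c.sample_id, "metric": c.metric,
                              "cutoff": c.cutoff, "label": c.label} for c in calls])

    all_networks, all_aggregates, summaries, hull_features = [], [], [], []
    for m in maps:
        try:
            t_graph = graph_for_phenotype(m, "T", delta_um=config.delta_um)
            b_graph = graph_for_phenotype(m, "B", delta_um=config.delta_um)
            t_nets = extract_networks(t_graph, config.n_min, config.n_large)
            b_nets = extract_networks(b_graph, config.n_min, config.n_large)
            aggs = detect_lymphoid_aggregates(t_nets, b_nets,
                                              coloc_delta_um=config.coloc_delta_um,
                                              n_min=config.n_min)
        except ValueError as exc:
            raise PipelineError("networks", f"sample {m.sample_id}: {exc}") from exc
        all_networks.append(networks_table(t_nets + b_nets, m.sample_id))
        all_aggregates.extend(
            aggregates_table(aggs, m.sample_id).to_dict("records"))
        summaries.append(summarize_networks(m, t_nets, aggs, n_min=config.n_min))
        hull_features.extend(hulls_geojson(
            [n for n in t_nets + b_nets if n.size >= config.n_min],
            m.sample_id)["features"])

    summary_df = pd.DataFrame([s.__dict__ for s in summaries])

    # group comparisons
    label_by_sample = dict(zip(calls_df["sample_id"], calls_df["label"]))
    group_of = {}
    for m in maps:
        if m.group == "CONTROL":
            group_of[m.sample_id] = "CONTROL"
        else:
            group_of[m.sample_id] = ("INFILTRATED"
                                     if label_by_sample[m.sample_id] == LABEL_INFILTRATED
                                     else "DEPLETED")
    summary_df["comparison_group"] = summary_df["sample_id"].map(group_of)
    comparisons = []
    mw = mann_whitney(aml, controls, alpha=config.alpha_default)
    mw.groups = ("AML", "CONTROL")
    mw.test = "mann_whitney_density_T"
    comparisons.append(mw.row())
    present = {g: summary_df.loc[summary_df["comparison_group"] == g,
                                 "networks_per_mm2"].to_numpy()
               for g in ("INFILTRATED", "DEPLETED", "CONTROL")
               if (summary_df["comparison_group"] == g).any()}
    if len(present) >= 2:
        kd = kruskal_dunn(present, alpha=config.alpha_default)
        kd.omnibus.test = "kruskal_networks_per_mm2"
        comparisons.extend(kd.rows())

    paths = {}
    paths["densities"] = out / "densities.csv"
    densities.to_csv(paths["densities"], index=False)
    paths["phenotype_calls"] = out / "phenotype_calls.csv"
    calls_df.to_csv(paths["phenotype_calls"], index=False)
    paths["networks"] = out / "networks.csv"
    pd.concat(all_networks, ignore_index=True).to_csv(paths["networks"], index=False)
    paths["aggregates"] = out / "aggregates.csv"
    agg_columns = ["sample_id", "t_network_id", "label", "b_network_id",
                   "colocalization_distance_um", "mixing_score", "n_t", "n_b"]
    pd.DataFrame(all_aggregates, columns=agg_columns).to_csv(
        paths["aggregates"], index=False)
    paths["network_summary"] = out / "network_summary.csv"
    summary_df.to_csv(paths["network_summary"], index=False)
    paths["hulls"] = out / "network_hulls.geojson"
    paths["hulls"].write_text(json.dumps(
        {"type": "FeatureCollection", "features": hull_features}, indent=1))
    paths["comparisons"] = out / "comparisons_spatial.csv"
    pd.DataFrame(comparisons).to_csv(paths["comparisons"], index=False)
    meta = {"cutoff_cells_per_mm2": cutoff, "parameters": config.echo()}
    paths["spatial_meta"] = out / "spatial_meta.json"
    paths["spatial_meta"].write_text(json.dumps(meta, indent=1, default=str))
    paths["report"] = make_report(out)
    return paths


def run_expression_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run the expression arm; returns the written artifact paths."""
    out = _setup_output(config)
    if config.expression_matrix is None or config.region_annotations is None:
        raise PipelineError("load_expression",
                            "expression_matrix and region_annotations required")
    try:
        matrix = read_expression_matrix(config.expression_matrix)
        annotations = pd.read_csv(config.region_annotations, sep=None, engine="python")
    except (ValueError, FileNotFoundError) as exc:
        raise PipelineError("load_expression", str(exc)) from exc

    signatures = (load_signatures(config.signatures_config)
                  if config.signatures_config else default_signatures())
    missing = [s.name for s in signatures
               if not (set(s.genes) | set(s.set_up) | set(s.set_down))
               & set(matrix.index)]
    if missing:
        raise PipelineError("signature_scores",
                            f"matrix lacks all genes of signatures: {missing}")
    try:
        scores = score_signatures(matrix, signatures)
    except ValueError as exc:
        raise PipelineError("signature_scores", str(exc)) from exc

    comparisons = []
    for sig in signatures:
        try:
            kd = compare_scores_by_region(scores[sig.name], annotations,
                                          alpha=config.alpha_spatial)
        except ValueError as exc:
            raise PipelineError("region_comparisons", f"{sig.name}: {exc}") from exc
        for row in kd.rows():
            row["signature"] = sig.name
            comparisons.append(row)

    reference = (pd.read_csv(config.reference_profiles, index_col=0)
                 if config.reference_profiles else default_reference_profiles())
    try:
        sig_matrix = build_signature_matrix(reference, top_k=config.top_k_markers)
        deconv = nnls_deconvolve(matrix, sig_matrix)
    except ValueError as exc:
        raise PipelineError("deconvolution", str(exc)) from exc
    tidy = deconv.tidy()
    ratios = (deconv.cd4_cd8_ratio()
              if {"T_CD4", "T_CD8"} <= set(deconv.coefficients.columns) else None)

    # correlation of the M2-predominance score with estimated T abundance
    correlation_rows = []
    ratio_sigs = [s for s in signatures if s.kind == KIND_RATIO]
    t_cols = [c for c in ("T_CD4", "T_CD8") if c in deconv.coefficients.columns]
    if ratio_sigs and t_cols:
        t_abundance = deconv.coefficients[t_cols].sum(axis=1)
        for sig in ratio_sigs:
            res = spearman_ci(scores[sig.name], t_abundance.loc[scores.index],
                              alpha=config.alpha_default)
            if isinstance(res, Undefined):
                logger.warning("correlation %s vs T abundance undefined: %s",
                               sig.name, res.reason)
                continue
            row = res.row()
            row["comparison"] = f"{sig.name}_vs_T_abundance"
            correlation_rows.append(row)

    paths = {}
    paths["scores"] = out / "signature_scores.csv"
    scores.rename_axis("region_id").to_csv(paths["scores"])
    paths["comparisons"] = out / "comparisons_expression.csv"
    pd.DataFrame(comparisons).to_csv(paths["comparisons"], index=False)
    paths["deconvolution"] = out / "deconvolution.csv"
    tidy.to_csv(paths["deconvolution"], index=False)
    if ratios is not None:
        paths["cd4_cd8"] = out / "cd4_cd8_ratio.csv"
        merged = ratios.rename_axis("region_id").reset_index()
        merged = merged.merge(annotations[["region_id", "region_type"]],
                              on="region_id", how="left")
        merged.to_csv(paths["cd4_cd8"], index=False)
    paths["correlations"] = out / "correlations.csv"
    pd.DataFrame(correlation_rows).to_csv(paths["correlations"], index=False)
    paths["expression_meta"] = out / "expression_meta.json"
    paths["expression_meta"].write_text(
        json.dumps({"parameters": config.echo(),
                    "signatures": [s.name for s in signatures]},
                   indent=1, default=str))
    paths["report"] = make_report(out)
    return paths


def simulate_inputs(config: PipelineConfig,
                    n_infiltrated: int = 5, n_depleted: int = 5,
                    n_control: int = 4,
                    n_regions: dict | None = None,
                    effect_sizes: dict | None = None) -> dict[str, Path]:
    """Write a complete synthetic input set under the output directory."""
    out = _setup_output(config)
    cells_dir = out / "cells"
    cells_dir.mkdir(exist_ok=True)
    cohort = simulate_cohort(n_infiltrated, n_depleted, n_control, seed=config.seed)
    manifest_rows = []
    for cellmap, _truth in cohort:
        write_cellmap(cellmap, cells_dir / f"{cellmap.sample_id}.csv")
        manifest_rows.append({"sample_id": cellmap.sample_id, "group": cellmap.group,
                              "tissue_area_mm2": cellmap.tissue_area_mm2,
                              "subgroup": cellmap.metadata.get("sim_kind", ""),
                              "cells_path": f"cells/{cellmap.sample_id}.csv"})
    manifest = out / "manifest.csv"
    pd.DataFrame(manifest_rows).to_csv(manifest, index=False)

    dataset = simulate_region_dataset(n_regions=n_regions, effect_sizes=effect_sizes,
                                      seed=config.seed + 1)
    expr_path = out / "regions_expression.csv"
    dataset.expression.rename_axis("gene").to_csv(expr_path)
    ann_path = out / "region_annotations.csv"
    dataset.annotations.to_csv(ann_path, index=False)
    truth_path = out / "region_true_proportions.csv"
    dataset.true_proportions.to_csv(truth_path)
    ref_path = out / "reference_profiles.csv"
    default_reference_profiles().rename_axis("gene").to_csv(ref_path)
    return {"manifest": manifest, "expression": expr_path,
            "annotations": ann_path, "true_proportions": truth_path,
            "reference_profiles": ref_path, "cells_dir": cells_dir}


def make_report(out_dir: str | Path) -> Path:
    """Regenerate the markdown report from the saved tables.

    Deterministic in the table contents: regeneration from unchanged
    artifacts produces identical text.
    """
    out = Path(out_dir)
    lines = ["# marrowmap run report", ""]

    meta_path = out / "spatial_meta.json"
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        lines += [f"Immune-phenotype cutoff: {meta['cutoff_cells_per_mm2']:.1f} "
                  "cells/mm^2 (median CD3+ T cell density of controls)", ""]
    calls_path = out / "phenotype_calls.csv"
    if calls_path.exists():
        calls = pd.read_csv(calls_path)
        n_inf = int((calls["label"] == LABEL_INFILTRATED).sum())
        lines += ["## Immune phenotypes",
                  f"- {n_inf}/{len(calls)} AML samples immune-infiltrated "
                  f"({100 * n_inf // max(len(calls), 1)}% by integer division; "
                  "see densities.csv)", ""]
    summary_path = out / "network_summary.csv"
    if summary_path.exists():
        s = pd.read_csv(summary_path)
        lines += ["## T cell networks",
                  f"- networks (n >= 10) per sample: median "
                  f"{s['n_networks'].median():.1f}",
                  f"- large networks (n >= 100) total: {int(s['n_large_networks'].sum())}",
                  f"- lymphoid aggregates total: {int(s['n_lymphoid_aggregates'].sum())}",
                  f"- T-dominant large networks total: {int(s['n_t_dominant_large'].sum())}",
                  ""]
        if s["n_lymphoid_aggregates"].sum() == 0:
            lines += ["- no lymphoid aggregates detected in this cohort", ""]
    for name, title in (("comparisons_spatial.csv", "Spatial comparisons"),
                        ("comparisons_expression.csv", "Expression comparisons")):
        path = out / name
        if path.exists():
            table = pd.read_csv(path)
            lines += [f"## {title}", "", table.to_string(index=False), ""]
    corr_path = out / "correlations.csv"
    if corr_path.exists():
        table = pd.read_csv(corr_path)
        if len(table):
            lines += ["## Score vs T-abundance correlations", "",
                      table.to_string(index=False), ""]
    report = out / "report.md"
    report.write_text("\n".join(lines) + "\n")
    return report
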