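# marrowmap

Spatial and transcriptomic analysis of the bone-marrow (BM) immune
microenvironment, built for studies of T cell infiltration in acute
myeloid leukemia (AML) and similar marrow pathologies.

Clinical immunology and hemato-oncology groups working with
immunohistochemistry cell maps and panel-based expression data
(nCounter-style bulk panels, GeoMx-style region profiles) can use it
to:

* quantify area-normalized cell densities (cells/mm²) from cell
  coordinate tables and classify biopsies as **immune-infiltrated**
  vs **immune-depleted** against the median of non-leukemic controls;
* detect **T cell networks** — connected components of the Delaunay
  triangulation of T cell centroids pruned at an interaction radius
  δ = 10 μm — with size thresholds at 10 (network) and 100 (large
  network) cells, and call **lymphoid aggregates (LAs)**: large T cell
  networks colocalized with a dense B cell network, scored for T/B
  intermixing;
* score expression matrices with an **M2-predominance score**
  s_M2 = log₂(mean M2 genes + ε) − log₂(mean M1 genes + ε) (s_M2 > 0
  means anti-inflammatory M2-like macrophages predominate) and with
  tertiary-lymphoid-structure (TLS) signatures (12-gene chemokine,
  follicular-helper-T, TLS imprint) as mean z of log₂(x+1);
* estimate cell-type abundances by **non-negative least squares
  (NNLS)** against a marker-gene signature matrix
  (min‖Sθ − m‖₂, θ ≥ 0), including compartment-restricted
  sub-deconvolution (B subsets, CD8 states) and CD4:CD8 ratios;
* compare groups with the Mann–Whitney U test, Kruskal–Wallis +
  Dunn's post-hoc comparisons, and Spearman correlation with a
  Fisher-z confidence interval (α = 0.01 for region-level comparisons,
  0.05 otherwise);
* generate fully ground-truthed **synthetic data** for all of the
  above: Poisson background + Gaussian planted aggregates for cell
  maps, noisy mixtures of reference profiles for expression, and
  four-group region datasets (LA / MIXED1 / MIXED2 / CONTROL).

## Worked example

```python
import marrowmap as mm

# one immune-infiltrated biopsy: dispersed T/B cells plus a dense
# mixed T/B aggregate and a T-only aggregate
config = mm.CellMapSimConfig(
    background_intensity={"T": 1500, "T_CD8": 1000, "B": 600},  # cells/mm^2
    aggregates=[
        mm.AggregateSpec({"T": 0.5, "T_CD8": 0.2, "B": 0.3}, n_cells=200,
                         dispersion_sigma_um=18.0),
        mm.AggregateSpec({"T": 0.7, "T_CD8": 0.28, "B": 0.02}, n_cells=130,
                         dispersion_sigma_um=15.0),
    ],
    seed=11,
)
biopsy, truth = mm.simulate_cellmap(config, sample_id="AML001")

print(f"CD3+ T cell density: {mm.compute_density(biopsy, 'T'):.0f} cells/mm^2")
cutoff, calls = mm.classify_immune_phenotype(
    {"AML001": mm.compute_density(biopsy, "T")},
    control_values=[905.0, 1071.0, 1133.0, 1296.0, 2040.0])
print(f"cutoff {cutoff:.0f} cells/mm^2 -> {calls[0].label}")

t_nets = mm.extract_networks(mm.graph_for_phenotype(biopsy, "T"))
b_nets = mm.extract_networks(mm.graph_for_phenotype(biopsy, "B"))
agg_calls = mm.detect_lymphoid_aggregates(t_nets, b_nets)
summary = mm.summarize_networks(biopsy, t_nets, agg_calls)
print(f"T cell networks (n>=10): {summary.n_networks}, "
      f"large: {summary.n_large_networks}, LAs: {summary.n_lymphoid_aggregates}")
```

prints

```
CD3+ T cell density: 2865 cells/mm^2
cutoff 1133 cells/mm^2 -> IMMUNE_INFILTRATED
T cell networks (n>=10): 2, large: 2, LAs: 1
```

The biopsy's T cell density is far above the control median, so it is
called immune-infiltrated; both planted aggregates are recovered as
large networks, and the one with interleaved B cells is called a
lymphoid aggregate (the other stays T-dominant).

On the expression side, a default synthetic region dataset (35 LA, 48
MIXED1, 44 MIXED2, 16 control regions) scored with the default
signatures:

```python
dataset = mm.simulate_region_dataset(seed=3)
scores = mm.score_signatures(dataset.expression, mm.default_signatures())
kd = mm.compare_scores_by_region(scores["TLS_imprint"], dataset.annotations)
print(f"Kruskal-Wallis H={kd.omnibus.statistic:.1f}, p={kd.omnibus.pvalue:.2e}")
```

prints `Kruskal-Wallis H=80.6, p=2.32e-17`: the TLS-imprint score is
strongly enriched in LA regions, and the per-type mean M2-predominance
score is negative only in LA regions (M1-skewed), matching the planted
effects.

## Command line

```sh
marrowmap simulate --out run --seed 7          # synthetic cohort + regions
marrowmap spatial --config cfg.yaml            # densities -> phenotypes -> networks
marrowmap expression --config cfg.yaml         # scores -> comparisons -> deconvolution
marrowmap report --out run                     # regenerate run/report.md
```

A single YAML config (see `PipelineConfig`) names the inputs (sample
manifest with per-sample tissue areas, expression matrix, region
annotations, optional signature config and reference profiles) and the
parameters (δ, size thresholds, colocalization radius, α levels,
seed).

## Documentation

`docs/methods.md` describes the models, the default parameters and
their rationale, what the synthetic generators do and do not emulate,
and known limitations.
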