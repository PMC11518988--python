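# Methods

This note documents the models and procedures implemented in
`marrowmap`, the defaults and why they were chosen, what the synthetic
generators emulate, and the package's known limitations. It states no
empirical result that the test suite or `scripts/acceptance.py` does
not itself compute.

## Cell maps and densities

A cell map is one biopsy's table of cell centroids (μm; origin
top-left, y increasing downward), phenotype calls from a declared
vocabulary (`T`, `T_CD8`, `B`, `TREG`, `OTHER`), optional boolean
marker flags (checkpoint receptors PD-1/LAG3/TIM-3, granzyme B,
FOXP3, …), and the analyzed tissue area in mm². The area is an
*input*: segmentation and exclusion of non-tissue (e.g. adipocyte
lobules) happen upstream and are out of scope, so the manifest area is
taken as authoritative.

Densities are `count / area` in cells/mm², with the exact identity
`density × area = integer count`. The phenotype hierarchy is
deliberately minimal: CD3⁺ T cell density counts both `T` and `T_CD8`
because CD8⁺ T cells are CD3⁺.

Cohort fractions are reported as whole-number percentages rounded
half-up (22/72 → 30.56 → 31), implemented in exact integer arithmetic
to avoid floating-point ties.

Conditional marker fractions (e.g. the fraction of CD8⁺ T cells
carrying ≥2 checkpoint receptors that are GZMB⁺, optionally restricted
to aggregate members) return an explicit undefined-with-reason object
when no cell satisfies the condition, rather than 0 or NaN.

## Interaction graphs, networks and lymphoid aggregates

Directly interacting cells are defined by centroid-to-centroid
distance ≤ δ, with δ = 10 μm inclusive. A nuclear-boundary distance
would need segmentation masks, which the cell-table representation
does not carry; centroid distance is the standard proxy.

The default graph is the **Delaunay triangulation pruned at δ**: the
Delaunay edge set restricted to edges of length ≤ δ. A pure distance
graph (all pairs ≤ δ) is available as a mode, and is the automatic
fallback for degenerate inputs (n < 3 or collinear points, where the
triangulation is undefined but the two graphs coincide in practice).
The pruned Delaunay graph is always a subgraph of the distance graph
at the same δ, so each of its connected components lies inside exactly
one distance-graph component; both modes are exposed and the mode used
is recorded in outputs because the two can differ on dense maps.
Exact duplicate coordinates are rejected by default; an optional
deterministic, seeded jitter (±0.1 μm) can be enabled for data
exported by pipelines that round coordinates.

Connected components of the graph partition the cells. Components
with ≥ N_min = 10 cells are *networks* (below that, dispersed cells),
with ≥ N_large = 100 cells *large networks*; both thresholds are
inclusive. Convex hulls are computed per component; hulls of
collinear components are degenerate with area 0 but still usable for
distance tests.

A large T cell network is called a **lymphoid aggregate** when a dense
B cell network (built with the same δ and N_min) is colocalized:
intersecting convex hulls, or minimum member-to-member distance
≤ 2δ = 20 μm (inclusive). The two-interaction-radii rule is a package
choice — no quantitative colocalization criterion is established for
marrow — and the threshold is configurable. Otherwise the network is
*T-dominant*.

The **mixing score** quantifies T/B intermixing inside an aggregate:
the fraction of B cells whose k = 5 nearest aggregate members (T and B
pooled, self excluded) include ≥1 T cell. Values near 1 indicate T
and B cells mixed throughout (immature-TLS-like); values toward 0
indicate a zonated layout with an inner B core ringed by T cells
(mature-TLS-like). It is a descriptive index, not a maturity stage.

Network counts are summarized per sample as networks (n ≥ 10) per mm²
plus raw counts of large networks, LAs and T-dominant large networks;
both normalized and raw counts are exported because either convention
may be wanted downstream.

## Immune-phenotype classification and statistics

The infiltration cutoff is the median CD3⁺ T cell density (or
estimated T score) of the non-leukemic controls; a sample is
immune-infiltrated iff its metric is **strictly above** the cutoff.
The tie-goes-to-depleted rule is the conservative reading of
"above the median".

* **Mann–Whitney U**: exact null enumeration when both groups have
  ≤ 8 observations and no ties; otherwise the normal approximation
  with tie and continuity corrections (scipy backend).
* **Kruskal–Wallis + Dunn**: tie-corrected H (defined as H = 0, p = 1
  when every observation is tied); Dunn z statistics from pooled mean
  ranks with tie-corrected variance, two-sided p multiplied by the
  number of pairwise comparisons (Bonferroni) and capped at 1. The
  Bonferroni flavour is the common implementation of Dunn's test; no
  installed library provides one, so it is implemented here from the
  standard formulas.
* **Spearman correlation**: average ranks for ties; 95% CI by the
  Fisher z transform with SE 1/√(n−3). For r = −0.75 at n = 23 this
  closed form gives [−0.89, −0.49]; commercial packages sometimes
  print a last-digit difference ([−0.89, −0.48]) from alternative CI
  constructions, and we document the Fisher-z choice rather than
  reverse-engineer another. The p-value is an exact permutation
  enumeration for n ≤ 8 (8! arrangements) and the t approximation
  above — full enumeration beyond n = 8 costs factorially more while
  the t approximation is already accurate there.

Significance thresholds are configuration: α = 0.01 for region-level
(spatial transcriptomics) comparisons, compensating for multiple
regions measured per biopsy, α = 0.05 otherwise.

## Signature scoring

Expression matrices are linear-scale, non-negative normalized values
(panel-style counts, O(10–10⁴)).

* **M2-predominance score**: s_M2 = log₂(mean(M2 genes) + ε) −
  log₂(mean(M1 genes) + ε) per sample, ε = 1 on the linear scale.
  s_M2 > 0 ⇔ M2-like mean exceeds M1-like mean; swapping the sets
  negates the score, and the score is invariant to global rescaling of
  the matrix when ε is scaled accordingly. The ratio-of-means form
  with this sign convention is the package's formulation; the M1/M2
  gene memberships ship as editable config.
* **TLS signatures** (12-gene chemokine, Tfh, TLS imprint): per gene,
  z-standardize log₂(x+1) across samples (zero-variance genes dropped
  and logged); score = mean z over retained genes. Mean-of-z was
  chosen over enrichment-style statistics for transparency and exact
  invariances (gene order, genes outside the signature); the log
  transform stabilizes the right-skewed linear scale.

The shipped gene lists are **package defaults matched to the synthetic
reference panel**, not authoritative published lists; real analyses
should supply their own signature config (the exact published
memberships live in the signatures' original references).

## NNLS deconvolution

The signature matrix is built from reference profiles by ranking each
type's genes on log₂ fold change of that type's mean over the maximum
of all other types' means and taking the top k (default 50; the small
synthetic panel uses 10), then taking the union of selections. A
condition-number estimate is attached and values above ~10⁴ warn
about collinear references.

Each mixture m is deconvolved by active-set NNLS:
θ = argmin‖Sθ − m‖₂ s.t. θ ≥ 0 on the gene intersection (warning
below 50% coverage of signature genes, failure below 10%). The raw
coefficient is the *absolute abundance score* on normalized
expression — a package definition — and proportions are θ/Σθ.
Properties relied on by the tests: noiseless identifiability for
full-column-rank S, scale equivariance (mixture × c ⇒ θ × c,
proportions unchanged), and residual monotonicity when adding columns.
SVR-based deconvolution (CIBERSORTx-style) is intentionally not
re-implemented; NNLS is the documented estimator here.

Compartment-restricted deconvolution re-fits against one compartment's
subtype profiles (B: naive/germinal-center/memory/plasmablast; CD8:
naive/CTL/MAIT/dysfunctional) plus a pooled "other" column, and
renormalizes within the compartment. Subtypes below a floor of 0.01
are zeroed and their mass reported as "unassigned"; zero compartment
signal yields undefined proportions with a flag. CD4:CD8 ratio is
θ_CD4/θ_CD8, undefined (NaN) when θ_CD8 = 0.

## Synthetic data

The generators define the study conditions for all tests:

* **Cell maps**: per-phenotype background counts ~ Poisson(intensity ×
  area) with uniform positions; planted aggregates are isotropic
  Gaussian scatters (Thomas-process offspring) around a centre — the
  simplest planted-cluster model with a single dispersion parameter.
  A minimum cell spacing (default 4 μm; nuclei cannot overlap) is
  enforced by resampling with a budget of 100 retries per cell;
  spacing conflicts and out-of-field draws relocate cells but never
  change counts, so background counts stay exactly Poisson.
  Exhausting the budget is an explicit failure. Dense planted
  aggregates used in the recovery tests (≥100 cells at σ = 4 μm) are
  geometrically incompatible with 4 μm spacing (the Gaussian core
  cannot hold 100 non-overlapping nuclei), so those simulations use a
  1 μm spacing, read as marker-centroid rather than nucleus-centroid
  separation inside maximally dense aggregates.
* **Expression mixtures**: sample = library_scale × (S·p), perturbed
  by mean-corrected multiplicative lognormal noise (factor
  exp(σZ − σ²/2), unit mean, default σ = 0.2 — matching the positive
  skew of panel data while keeping planted values unbiased targets) or
  additive Gaussian noise; values clipped at 0.
* **Region datasets**: the default design is 35 LA, 48 MIXED1, 44
  MIXED2 and 16 control regions with ~126–826 cells per region
  (lognormal around 335), multiple regions per biopsy; MIXED1 regions
  share biopsies with LA regions, MIXED2 and control regions come from
  aggregate-free biopsies. Region compositions are Dirichlet draws
  (concentration 200) around a shared baseline (blast-dominated
  marrow); LA regions multiply T/B/plasma/M1 content by 1 + effect
  (defaults: 3× CD4 T, 4× CD8 T, 3× B and plasma, 2× M1) before
  renormalization, so effect 0 makes all four region types
  exchangeable — the basis of the null-calibration tests. The CD8
  elevation exceeds the CD4 one so LA regions show a depressed
  CD4:CD8 ratio.
* **Reference panels**: the genes × cell-types matrices
  (microenvironment panel, B subtypes, CD8 states) are synthetic —
  real marker gene *names* with invented linear-scale values
  structured as high-in-own-type / low-elsewhere. The dysfunctional
  CD8 profile co-expresses checkpoint-receptor genes with reduced
  cytotoxicity genes.

What the simulations do **not** emulate: real marrow spatial
statistics (published cell maps do not characterize marrow
cellularity point processes, so intensities are package defaults, not
estimates), anisotropic or lobulated tissue geometry, spatial
autocorrelation of expression within regions, batch effects,
platform-specific normalization artifacts, and raw images or reads.
Passing tests therefore certify the algorithms' correctness and
calibration under controlled conditions — not performance on any
particular cohort.

## Numerical and design choices

* Coordinates in μm, densities in cells/mm², conversion fixed at
  1 mm² = 10⁶ μm².
* All thresholds (δ, N_min, N_large, colocalization radius, α levels)
  are inclusive where stated and carried in configuration, echoed in
  outputs and logs.
* Determinism: every stochastic routine takes an integer seed;
  identical config + seed reproduce byte-identical outputs (asserted
  in tests). Child seeds are drawn below 2³¹.
* Networks are ordered by decreasing size with id-based tie-breaks;
  aggregate calls attach the closest qualifying B network.
* The deconvolution API follows the model/results idiom
  (`NNLSDeconvolution(...).fit()` → results with `summary()`) because
  it is the one component that is literally a model fitted to data;
  the spatial and scoring stages are plain functions over containers.
* Problem sizes in tests and the acceptance script (e.g. 25-point maps
  against the O(n⁴) circumcircle oracle, 2000-replicate calibrations,
  50-mixture recovery studies) were chosen as the smallest sizes at
  which the checked properties are statistically meaningful.

## Known limitations

* The LA colocalization rule and mixing score are package definitions;
  no ground-truth maturity staging (germinal-center detection,
  zonation morphology) is attempted.
* NNLS absolute scores are comparable within a normalization scheme
  only; no cross-platform calibration is provided.
* The Dunn adjustment is Bonferroni; no FDR machinery beyond the two
  configured α levels.
* Survival analysis, differential expression, pathway enrichment and
  UMAP embeddings are out of scope; use dedicated tools on the
  exported tables.
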