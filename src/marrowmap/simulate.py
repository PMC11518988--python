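"""Synthetic bone-marrow data with known ground truth.

Three generators make every downstream stage testable without patient
data:

* :func:`simulate_cellmap` — biopsy cell maps: background cells from a
  homogeneous Poisson process per phenotype plus planted aggregates
  drawn as isotropic Gaussian scatters (Thomas-process offspring)
  around a centre, with a minimum cell spacing enforced by resampling.
* :func:`simulate_expression_mixtures` — bulk-style expression as
  ``library_scale * (signature_matrix @ proportions)`` perturbed by a
  mean-corrected lognormal (or additive Gaussian) noise model.
* :func:`simulate_region_dataset` — spatial-transcriptomics-style
  region profiles in four groups (LA / MIXED1 / MIXED2 / CONTROL) with
  T/B/plasma/M1-macrophage content elevated in LA regions by stated
  effect sizes, and multiple regions per biopsy.

All generators are deterministic given (config, seed).  Intensities
and mixing proportions are package defaults chosen to resemble
marrow-biopsy cellularity and panel-scale normalized counts; the
spatial statistics of real marrow are not estimated from data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple

import numpy as np
import pandas as pd

from ._util import check_seed
from .cellmap import MARKER_PREFIX, T_PHENOTYPES, CellMap

DEFAULT_MIN_SPACING_UM = 4.0     # nuclei cannot overlap
DEFAULT_RETRY_BUDGET = 100       # resampling attempts per cell

#: Region-group design: 35 LA, 48 + 44 mixed, 16 control regions.
DEFAULT_N_REGIONS: dict[str, int] = {"LA": 35, "MIXED1": 48, "MIXED2": 44,
                                     "CONTROL": 16}

#: Multiplicative elevation (fold-change = 1 + effect) of LA-region
#: cell content relative to the shared baseline mixture.
DEFAULT_REGION_EFFECTS: dict[str, float] = {
    "T_CD4": 2.0, "T_CD8": 3.0, "B": 2.0, "PLASMA": 2.0, "MAC_M1": 1.0}

#: Shared baseline cell-type composition of a marrow region.
BASELINE_REGION_PROPORTIONS: dict[str, float] = {
    "BLAST": 0.66, "T_CD4": 0.10, "T_CD8": 0.05, "B": 0.05,
    "PLASMA": 0.02, "MAC_M1": 0.04, "MAC_M2": 0.08}


# ---------------------------------------------------------------------------
# cell maps
# ---------------------------------------------------------------------------

@dataclass
class AggregateSpec:
    """One planted cell aggregate."""

    phenotype_mix: dict[str, float]
    n_cells: int
    dispersion_sigma_um: float
    center: tuple[float, float] | str = "random"

    def __post_init__(self) -> None:
        total = sum(self.phenotype_mix.values())
        if not math.isclose(total, 1.0, abs_tol=1e-6):
            raise ValueError(f"phenotype mix fractions sum to {total}, expected 1")
        if any(f < 0 for f in self.phenotype_mix.values()):
            raise ValueError("negative phenotype fraction")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if not self.dispersion_sigma_um > 0:
            raise ValueError("dispersion_sigma_um must be > 0")


@dataclass
class CellMapSimConfig:
    """Configuration of one simulated cell map."""

    field_width_um: float = 1000.0
    field_height_um: float = 1000.0
    background_intensity: dict[str, float] = field(default_factory=dict)  # cells/mm^2
    aggregates: list[AggregateSpec] = field(default_factory=list)
    min_cell_spacing_um: float = DEFAULT_MIN_SPACING_UM
    marker_probs: dict[str, float] = field(default_factory=dict)
    seed: int = 0
    retry_budget: int = DEFAULT_RETRY_BUDGET

    def __post_init__(self) -> None:
        if self.field_width_um <= 0 or self.field_height_um <= 0:
            raise ValueError("field dimensions must be > 0")
        if any(v < 0 for v in self.background_intensity.values()):
            raise ValueError("background intensities must be >= 0")
        if self.min_cell_spacing_um < 0:
            raise ValueError("min_cell_spacing_um must be >= 0")
        check_seed(self.seed)

    @property
    def area_mm2(self) -> float:
        return self.field_width_um * self.field_height_um / 1e6


@dataclass
class GroundTruth:
    """Planted truth of a simulated cell map."""

    aggregate_id: pd.Series          # per cell_id; 0 = background
    intended_class: dict[int, str]   # per aggregate id
    true_density: dict[str, float]   # realized cells/mm^2 per phenotype


class SpacingError(RuntimeError):
    """Raised when the retry budget cannot satisfy the minimum spacing."""


def _place_points(sampler, n: int, existing: list[np.ndarray],
                  spacing: float, budget: int,
                  bounds: tuple[float, float]) -> np.ndarray:
    """Place ``n`` points from ``sampler`` respecting spacing and field bounds."""
    width, height = bounds
    placed: list[np.ndarray] = []

    def ok(p: np.ndarray) -> bool:
        if not (0 <= p[0] <= width and 0 <= p[1] <= height):
            return False
        if spacing <= 0:
            return True
        for block in existing:
            if len(block) and np.min(np.hypot(*(block - p).T)) < spacing:
                return False
        if placed and np.min(np.hypot(*(np.array(placed) - p).T)) < spacing:
            return False
        return True

    for _ in range(n):
        for attempt in range(budget + 1):
            p = sampler()
            if ok(p):
                placed.append(p)
                break
        else:
            raise SpacingError(
                f"could not place a cell after {budget} retries; the field is "
                "too crowded for the requested spacing")
    return np.array(placed, dtype=float).reshape(-1, 2)


def simulate_cellmap(config: CellMapSimConfig,
                     sample_id: str = "SIM",
                     group: str = "AML") -> tuple[CellMap, GroundTruth]:
    """Simulate one biopsy cell map.

    Background cell counts per phenotype are Poisson with mean
    ``intensity * area``; positions are uniform over the field.
    Aggregate cells are Gaussian scatters (sd ``dispersion_sigma_um``)
    around the aggregate centre; draws outside the field or closer
    than ``min_cell_spacing_um`` to an accepted cell are resampled
    (spacing conflicts relocate cells but never change counts).
    Aggregates are placed before background.  Exhausting the retry
    budget raises :class:`SpacingError`.
    """
    rng = np.random.default_rng(config.seed)
    width, height = config.field_width_um, config.field_height_um
    bounds = (width, height)
    spacing, budget = config.min_cell_spacing_um, config.retry_budget

    blocks: list[np.ndarray] = []
    phenotypes: list[str] = []
    agg_ids: list[int] = []
    intended: dict[int, str] = {}

    for k, agg in enumerate(config.aggregates, start=1):
        if agg.center == "random":
            margin = min(3 * agg.dispersion_sigma_um, width / 2, height / 2)
            cx = rng.uniform(margin, width - margin)
            cy = rng.uniform(margin, height - margin)
        else:
            cx, cy = agg.center
        mix_phens = list(agg.phenotype_mix)
        counts = rng.multinomial(agg.n_cells, [agg.phenotype_mix[p] for p in mix_phens])
        agg_coords = []
        for phen, cnt in zip(mix_phens, counts):
            if cnt == 0:
                continue
            pts = _place_points(
                lambda: rng.normal((cx, cy), agg.dispersion_sigma_um),
                cnt, blocks + [np.vstack(agg_coords)] if agg_coords else blocks,
                spacing, budget, bounds)
            agg_coords.append(pts)
            phenotypes.extend([phen] * cnt)
            agg_ids.extend([k] * cnt)
        if agg_coords:
            blocks.append(np.vstack(agg_coords))
        else:
            blocks.append(np.empty((0, 2)))
        n_t = sum(c for p, c in zip(mix_phens, counts) if p in T_PHENOTYPES)
        n_b = sum(c for p, c in zip(mix_phens, counts) if p == "B")
        if n_t >= 100:
            intended[k] = "lymphoid_aggregate" if n_b >= 10 else "large_network"
        elif n_t >= 10:
            intended[k] = "network"
        else:
            intended[k] = "below_threshold"

    for phen in config.background_intensity:
        n_bg = int(rng.poisson(config.background_intensity[phen] * config.area_mm2))
        pts = _place_points(
            lambda: rng.uniform((0.0, 0.0), (width, height)),
            n_bg, blocks, spacing, budget, bounds)
        blocks.append(pts)
        phenotypes.extend([phen] * n_bg)
        agg_ids.extend([0] * n_bg)

    coords = np.vstack(blocks) if blocks else np.empty((0, 2))
    cell_ids = [f"{sample_id}_c{i}" for i in range(len(coords))]
    cells = pd.DataFrame({"cell_id": cell_ids,
                          "x_um": coords[:, 0], "y_um": coords[:, 1],
                          "phenotype": phenotypes})
    for marker, prob in config.marker_probs.items():
        cells[MARKER_PREFIX + marker] = rng.random(len(cells)) < prob

    cellmap = CellMap(sample_id=sample_id, group=group, cells=cells,
                      tissue_area_mm2=config.area_mm2,
                      metadata={"simulated": True, "seed": config.seed})
    density = {
        p: int((cells["phenotype"].isin(T_PHENOTYPES if p == "T" else (p,))).sum())
        / config.area_mm2
        for p in set(phenotypes) | {"T"}
    }
    truth = GroundTruth(
        aggregate_id=pd.Series(agg_ids, index=cell_ids, name="aggregate_id"),
        intended_class=intended,
        true_density=density)
    return cellmap, truth


# ---------------------------------------------------------------------------
# expression mixtures
# ---------------------------------------------------------------------------

@dataclass
class MixtureSimConfig:
    """Configuration of simulated expression mixtures."""

    signature: pd.DataFrame          # genes x cell types, linear scale
    true_proportions: pd.DataFrame   # samples x cell types
    library_scale: float = 1.0
    noise_model: str = "none"        # "none" | "lognormal" | "gaussian"
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.signature.to_numpy() < 0).any():
            raise ValueError("signature matrix contains negative values")
        props = self.true_proportions
        missing = set(props.columns) - set(self.signature.columns)
        if missing:
            raise ValueError(f"proportions name unknown cell types: {sorted(missing)}")
        values = props.to_numpy(dtype=float)
        if (values < 0).any():
            raise ValueError("proportions must be >= 0")
        if not np.allclose(values.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("proportions must sum to 1 per sample")
        if self.library_scale <= 0:
            raise ValueError("library_scale must be > 0")
        if self.noise_model not in ("none", "lognormal", "gaussian"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        check_seed(self.seed)


def simulate_expression_mixtures(config: MixtureSimConfig,
                                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate expression mixtures from known proportions.

    Each sample is ``library_scale * (S @ p)``; lognormal noise
    multiplies each entry by ``exp(sd * Z - sd^2 / 2)`` (unit mean, so
    planted values remain unbiased targets), Gaussian noise adds
    ``N(0, sd)`` in expression units.  Values are clipped at 0.
    Returns ``(expression genes x samples, true proportions)``.
    """
    rng = np.random.default_rng(config.seed)
    s = config.signature[config.true_proportions.columns].to_numpy(dtype=float)
    p = config.true_proportions.to_numpy(dtype=float)
    expr = config.library_scale * (s @ p.T)
    if config.noise_model == "lognormal" and config.noise_sd > 0:
        sd = config.noise_sd
        expr = expr * np.exp(rng.normal(-0.5 * sd * sd, sd, size=expr.shape))
    elif config.noise_model == "gaussian" and config.noise_sd > 0:
        expr = expr + rng.normal(0.0, config.noise_sd, size=expr.shape)
    expr = np.clip(expr, 0.0, None)
    matrix = pd.DataFrame(expr, index=config.signature.index,
                          columns=config.true_proportions.index)
    return matrix, config.true_proportions.copy()


# ---------------------------------------------------------------------------
# reference panel (synthetic)
# ---------------------------------------------------------------------------

#: Cell types of the synthetic reference panel.
REFERENCE_CELL_TYPES = ("T_CD4", "T_CD8", "B", "PLASMA", "MAC_M1", "MAC_M2", "BLAST")

# per-gene expression (linear scale) across the 7 reference types:
# (T_CD4, T_CD8, B, PLASMA, MAC_M1, MAC_M2, BLAST)
_PANEL: dict[str, tuple[float, ...]] = {
    # pan-T
    "CD3D":   (180, 180, 2, 2, 2, 2, 2),
    "CD3E":   (170, 170, 2, 2, 2, 2, 2),
    "CD2":    (140, 140, 2, 2, 2, 2, 2),
    "TRAC":   (160, 160, 2, 2, 2, 2, 2),
    "LTB":    (60, 40, 70, 10, 5, 5, 5),
    # CD4 / follicular-helper programme
    "CD4":    (150, 5, 2, 2, 40, 40, 10),
    "IL7R":   (130, 60, 5, 2, 5, 5, 2),
    "CCR7":   (90, 30, 50, 2, 2, 2, 2),
    "CD40LG": (110, 10, 2, 2, 2, 2, 2),
    "ICOS":   (120, 20, 2, 2, 2, 2, 2),
    "PDCD1":  (80, 60, 2, 2, 2, 2, 2),
    "SH2D1A": (90, 70, 5, 2, 2, 2, 2),
    "TIGIT":  (85, 55, 2, 2, 2, 2, 2),
    "CD200":  (70, 10, 20, 2, 2, 2, 5),
    "BTLA":   (75, 15, 25, 2, 2, 2, 2),
    "IL21":   (60, 5, 2, 2, 2, 2, 2),
    # CD8 / cytotoxicity
    "CD8A":   (2, 190, 2, 2, 2, 2, 2),
    "CD8B":   (2, 170, 2, 2, 2, 2, 2),
    "GZMK":   (5, 120, 2, 2, 2, 2, 2),
    "NKG7":   (5, 130, 2, 2, 2, 2, 2),
    "CCL5":   (20, 150, 5, 2, 10, 5, 2),
    "PRF1":   (5, 90, 2, 2, 5, 2, 2),
    # B cells
    "MS4A1":  (2, 2, 190, 10, 2, 2, 2),
    "CD79A":  (2, 2, 180, 60, 2, 2, 2),
    "CD79B":  (2, 2, 170, 40, 2, 2, 2),
    "CD19":   (2, 2, 150, 30, 2, 2, 2),
    "CXCL13": (30, 2, 90, 2, 2, 2, 2),
    "SELL":   (60, 40, 80, 2, 10, 5, 10),
    # plasma cells
    "IGHG1":  (2, 2, 10, 200, 2, 2, 2),
    "IGHG3":  (2, 2, 8, 170, 2, 2, 2),
    "IGKC":   (2, 2, 30, 200, 2, 2, 2),
    "JCHAIN": (2, 2, 10, 190, 2, 2, 2),
    "MZB1":   (2, 2, 8, 180, 2, 2, 2),
    "SDC1":   (2, 2, 2, 140, 2, 2, 5),
    "CD38":   (30, 30, 20, 150, 20, 10, 30),
    # M1-like macrophages (pro-inflammatory, chemokine-rich)
    "IL1B":   (2, 2, 2, 2, 170, 20, 5),
    "TNF":    (10, 10, 5, 2, 150, 15, 2),
    "CD80":   (2, 2, 5, 2, 120, 10, 2),
    "SOCS1":  (10, 10, 5, 2, 110, 15, 5),
    "CXCL9":  (2, 2, 2, 2, 180, 10, 2),
    "CXCL10": (2, 2, 2, 2, 170, 12, 2),
    "CXCL11": (2, 2, 2, 2, 140, 8, 2),
    "CCL2":   (2, 2, 2, 2, 130, 40, 2),
    "CCL3":   (2, 2, 2, 2, 150, 30, 5),
    "CCL4":   (2, 2, 2, 2, 140, 30, 5),
    "CCL8":   (2, 2, 2, 2, 110, 35, 2),
    "LAMP3":  (5, 2, 30, 2, 60, 5, 2),
    # M2-like macrophages (anti-inflammatory)
    "CD163":  (2, 2, 2, 2, 20, 180, 2),
    "MRC1":   (2, 2, 2, 2, 15, 170, 2),
    "MSR1":   (2, 2, 2, 2, 25, 160, 2),
    "STAB1":  (2, 2, 2, 2, 20, 140, 2),
    "CCL18":  (2, 2, 2, 2, 10, 150, 2),
    "CCL22":  (2, 2, 2, 2, 30, 120, 2),
    "CD68":   (2, 2, 2, 2, 140, 140, 10),
    # stromal/homeostatic chemokines (modelled as B/lymphoid-niche genes)
    "CCL19":  (10, 2, 70, 2, 10, 5, 2),
    "CCL21":  (5, 2, 40, 2, 2, 2, 2),
    # leukemic blasts / myeloid progenitors
    "KIT":    (2, 2, 2, 2, 2, 2, 160),
    "CD34":   (2, 2, 2, 2, 2, 2, 180),
    "FLT3":   (2, 2, 2, 2, 5, 2, 150),
    "MYB":    (5, 5, 10, 2, 2, 2, 140),
    "MPO":    (2, 2, 2, 2, 10, 5, 170),
    # housekeeping
    "ACTB":   (200, 200, 200, 200, 200, 200, 200),
    "GAPDH":  (180, 180, 180, 180, 180, 180, 180),
    "B2M":    (190, 190, 190, 190, 150, 150, 160),
}


def default_reference_profiles() -> pd.DataFrame:
    """Synthetic genes x cell-types reference panel (linear scale).

    A package-invented stand-in for reference expression profiles of
    marrow microenvironment populations; gene names are real markers
    but the values are synthetic.
    """
    return pd.DataFrame.from_dict(_PANEL, orient="index",
                                  columns=list(REFERENCE_CELL_TYPES)).astype(float)


#: Synthetic B-cell subtype reference (genes x subtypes, linear scale).
_B_SUBTYPE_PANEL: dict[str, tuple[float, ...]] = {
    # (B_NAIVE, B_GC, B_MEMORY, PLASMABLAST)
    "MS4A1":    (150, 140, 150, 10),
    "CD79A":    (150, 150, 150, 60),
    "CD19":     (130, 130, 130, 30),
    "IGHD":     (160, 5, 5, 2),
    "TCL1A":    (140, 60, 5, 2),
    "SELL":     (90, 10, 40, 5),
    "AICDA":    (2, 170, 2, 2),
    "MKI67":    (2, 160, 5, 40),
    "BCL6":     (10, 150, 10, 2),
    "RGS13":    (2, 120, 2, 2),
    "CD27":     (2, 30, 140, 120),
    "TNFRSF13B": (5, 5, 130, 40),
    "AIM2":     (5, 10, 110, 5),
    "MZB1":     (2, 5, 10, 190),
    "JCHAIN":   (2, 5, 10, 180),
    "XBP1":     (10, 20, 20, 160),
    "IGHG1":    (2, 10, 40, 170),
    "PRDM1":    (2, 5, 15, 150),
}

#: Synthetic CD8 T cell state reference (genes x states, linear scale).
#: The dysfunctional state co-expresses checkpoint-receptor genes and
#: has reduced cytotoxicity genes.
_CD8_STATE_PANEL: dict[str, tuple[float, ...]] = {
    # (CD8_NAIVE, CD8_CTL, CD8_MAIT, CD8_DYSFUNCTIONAL)
    "CD8A":     (150, 150, 130, 150),
    "CD3D":     (150, 150, 150, 150),
    "CCR7":     (160, 10, 20, 10),
    "SELL":     (150, 20, 30, 15),
    "TCF7":     (140, 20, 30, 20),
    "IL7R":     (130, 30, 90, 20),
    "GZMB":     (2, 170, 30, 20),
    "PRF1":     (5, 160, 40, 25),
    "GNLY":     (2, 150, 60, 15),
    "NKG7":     (5, 150, 80, 40),
    "GZMK":     (5, 90, 100, 60),
    "SLC4A10":  (2, 2, 170, 2),
    "KLRB1":    (5, 20, 160, 10),
    "ZBTB16":   (5, 5, 140, 5),
    "PDCD1":    (2, 20, 10, 170),
    "LAG3":     (2, 25, 10, 160),
    "HAVCR2":   (2, 30, 15, 150),
    "TIGIT":    (5, 25, 10, 140),
    "TOX":      (5, 15, 10, 130),
}


def default_b_subtype_profiles() -> pd.DataFrame:
    """Synthetic B-cell compartment reference (naive, germinal-center,
    memory, plasmablast subtypes)."""
    return pd.DataFrame.from_dict(
        _B_SUBTYPE_PANEL, orient="index",
        columns=["B_NAIVE", "B_GC", "B_MEMORY", "PLASMABLAST"]).astype(float)


def default_cd8_state_profiles() -> pd.DataFrame:
    """Synthetic CD8 T cell state reference (naive, cytotoxic, MAIT,
    dysfunctional)."""
    return pd.DataFrame.from_dict(
        _CD8_STATE_PANEL, orient="index",
        columns=["CD8_NAIVE", "CD8_CTL", "CD8_MAIT",
                 "CD8_DYSFUNCTIONAL"]).astype(float)


# ---------------------------------------------------------------------------
# region datasets
# ---------------------------------------------------------------------------

class RegionDataset(NamedTuple):
    expression: pd.DataFrame         # genes x regions
    annotations: pd.DataFrame        # region_id, biopsy_id, region_type, cell_count
    true_proportions: pd.DataFrame   # regions x cell types


def simulate_region_dataset(n_regions: Mapping[str, int] | None = None,
                            effect_sizes: Mapping[str, float] | None = None,
                            seed: int = 0,
                            noise_sd: float = 0.2,
                            library_scale: float = 1.0,
                            concentration: float = 200.0,
                            regions_per_biopsy: int = 4,
                            signature: pd.DataFrame | None = None) -> RegionDataset:
    """Simulate a four-group spatial-transcriptomics region dataset.

    Region cell-type proportions are Dirichlet draws around a shared
    baseline; in LA regions the T/B/plasma/M1 content is first
    multiplied by ``1 + effect`` per ``effect_sizes`` entry (effect 0
    makes all four region types exchangeable).  Expression is a noisy
    mixture of the reference profiles.  MIXED1 regions share biopsies
    with LA regions; MIXED2 and CONTROL regions come from biopsies
    without aggregates.
    """
    n_regions = dict(DEFAULT_N_REGIONS if n_regions is None else n_regions)
    effects = dict(DEFAULT_REGION_EFFECTS if effect_sizes is None else effect_sizes)
    if any(n < 1 for n in n_regions.values()):
        bad = {k: v for k, v in n_regions.items() if v < 1}
        raise ValueError(f"n_regions must be >= 1 for every requested type: {bad}")
    if any(e < 0 for e in effects.values()):
        raise ValueError("effect sizes must be >= 0")
    check_seed(seed)
    rng = np.random.default_rng(seed)
    if signature is None:
        signature = default_reference_profiles()
    types = list(signature.columns)
    base = np.array([BASELINE_REGION_PROPORTIONS.get(t, 0.0) for t in types])
    base = base / base.sum()

    la_base = base.copy()
    for t, e in effects.items():
        if t in types:
            la_base[types.index(t)] *= (1.0 + e)
    la_base = la_base / la_base.sum()

    # LA and MIXED1 regions are assigned round-robin to a shared pool of
    # "LA biopsies" so every such biopsy carries at least one LA region;
    # MIXED2 and CONTROL regions get their own biopsy pools.
    n_la = n_regions.get("LA", 0)
    n_m1 = n_regions.get("MIXED1", 0)
    n_lab = max(1, math.ceil((n_la + n_m1) / regions_per_biopsy))
    if n_la and n_m1:
        n_lab = min(n_lab, n_la, n_m1)
    n_m2b = max(1, math.ceil(n_regions.get("MIXED2", 0) / regions_per_biopsy))
    n_ctb = max(1, math.ceil(n_regions.get("CONTROL", 0) / regions_per_biopsy))

    rows = []
    props = []
    region_index = 0
    for region_type in ("LA", "MIXED1", "MIXED2", "CONTROL"):
        if region_type not in n_regions:
            continue
        n = n_regions[region_type]
        target = la_base if region_type == "LA" else base
        for i in range(n):
            region_index += 1
            rid = f"R{region_index:03d}"
            if region_type in ("LA", "MIXED1"):
                bid = f"LAB{i % n_lab + 1:02d}"
            elif region_type == "MIXED2":
                bid = f"M2B{i % n_m2b + 1:02d}"
            else:
                bid = f"CTB{i % n_ctb + 1:02d}"
            p = rng.dirichlet(concentration * target)
            props.append(p)
            cell_count = int(np.clip(round(rng.lognormal(math.log(335.0), 0.35)),
                                     126, 826))
            rows.append({"region_id": rid, "biopsy_id": bid,
                         "region_type": region_type, "cell_count": cell_count})

    annotations = pd.DataFrame(rows)
    true_props = pd.DataFrame(props, index=annotations["region_id"], columns=types)
    mix_config = MixtureSimConfig(
        signature=signature, true_proportions=true_props,
        library_scale=library_scale, noise_model="lognormal" if noise_sd > 0 else "none",
        noise_sd=noise_sd, seed=int(rng.integers(2 ** 31)))
    expression, _ = simulate_expression_mixtures(mix_config)
    return RegionDataset(expression=expression, annotations=annotations,
                         true_proportions=true_props)


# ---------------------------------------------------------------------------
# cohort of cell maps
# ---------------------------------------------------------------------------

def cohort_cellmap_config(kind: str, seed: int) -> CellMapSimConfig:
    """Default per-sample simulation config for the synthetic cohort.

    ``kind`` is ``infiltrated`` (T-rich AML with planted aggregates,
    some with colocalizing B cells), ``depleted`` (T-poor AML) or
    ``control`` (non-leukemic, T density around the canonical
    ~1100 cells/mm^2 control median).
    """
    rng = np.random.default_rng(seed)
    if kind == "infiltrated":
        aggregates = [
            AggregateSpec({"T": 0.50, "T_CD8": 0.20, "B": 0.30}, n_cells=200,
                          dispersion_sigma_um=18.0),
            AggregateSpec({"T": 0.70, "T_CD8": 0.28, "B": 0.02}, n_cells=130,
                          dispersion_sigma_um=15.0),
        ]
        intensity = {"T": 1500.0, "T_CD8": 1000.0, "B": 600.0, "OTHER": 500.0}
    elif kind == "depleted":
        aggregates = []
        intensity = {"T": 160.0, "T_CD8": 90.0, "B": 80.0, "OTHER": 500.0}
    elif kind == "control":
        aggregates = [AggregateSpec({"T": 0.7, "T_CD8": 0.3}, n_cells=30,
                                    dispersion_sigma_um=15.0)]
        intensity = {"T": 660.0, "T_CD8": 440.0, "B": 250.0, "OTHER": 500.0}
    else:
        raise ValueError(f"unknown cohort kind {kind!r}")
    return CellMapSimConfig(background_intensity=intensity, aggregates=aggregates,
                            seed=int(rng.integers(2 ** 31)))


def simulate_cohort(n_infiltrated: int = 5, n_depleted: int = 5,
                    n_control: int = 4, seed: int = 0,
                    ) -> list[tuple[CellMap, GroundTruth]]:
    """Simulate a small cohort of cell maps (AML + non-leukemic controls)."""
    check_seed(seed)
    rng = np.random.default_rng(seed)
    out = []
    specs = ([("infiltrated", "AML")] * n_infiltrated
             + [("depleted", "AML")] * n_depleted
             + [("control", "CONTROL")] * n_control)
    for i, (kind, group) in enumerate(specs, start=1):
        config = cohort_cellmap_config(kind, seed=int(rng.integers(2 ** 31)))
        sample_id = f"{'AML' if group == 'AML' else 'CTRL'}{i:03d}"
        cellmap, truth = simulate_cellmap(config, sample_id=sample_id, group=group)
        cellmap.metadata["sim_kind"] = kind
        out.append((cellmap, truth))
    return out
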