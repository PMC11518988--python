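"""Cell-coordinate maps and area-normalized density quantification.

A :class:`CellMap` holds one biopsy's cell centroids (in micrometres,
origin top-left, y increasing downward), their phenotype calls from a
declared vocabulary, optional per-cell marker flags (e.g. immune
checkpoint receptors or granzyme B), and the analyzed tissue area in
mm^2.  Densities are reported in cells/mm^2; the analyzed area is an
input from the upstream image-analysis step, never computed here.

The default phenotype vocabulary is hierarchical in one respect: CD8+
T cells (``T_CD8``) are CD3+ and therefore count toward the total T
cell density.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Default phenotype vocabulary.
PHENOTYPES: tuple[str, ...] = ("T", "T_CD8", "B", "TREG", "OTHER")

#: Phenotypes counted as CD3+ T cells (CD8+ cells are CD3+).
T_PHENOTYPES: tuple[str, ...] = ("T", "T_CD8")

#: Column prefix marking a 0/1 marker-flag column in cell tables.
MARKER_PREFIX = "marker_"

REQUIRED_COLUMNS = ("sample_id", "x_um", "y_um", "phenotype")

#: 1 mm^2 in um^2; coordinates are um, densities cells/mm^2.
UM2_PER_MM2 = 1e6


@dataclass
class CellMap:
    """One sample's cell map.

    Parameters
    ----------
    sample_id : str
        Unique sample (biopsy) identifier.
    group : str
        Cohort group, e.g. ``"AML"`` or ``"CONTROL"``.
    cells : pandas.DataFrame
        One row per cell with columns ``cell_id``, ``x_um``, ``y_um``,
        ``phenotype`` and any number of ``marker_<NAME>`` boolean
        columns.
    tissue_area_mm2 : float
        Analyzed tissue area in mm^2 (> 0); supplied by the upstream
        segmentation, used for density normalization.
    metadata : dict
        Free-form annotations (e.g. cytogenetic subgroup).
    """

    sample_id: str
    group: str
    cells: pd.DataFrame
    tissue_area_mm2: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.tissue_area_mm2 > 0:
            raise ValueError(
                f"tissue_area_mm2 must be > 0, got {self.tissue_area_mm2}"
            )
        cells = self.cells
        for col in ("cell_id", "x_um", "y_um", "phenotype"):
            if col not in cells.columns:
                raise ValueError(f"cells table missing column {col!r}")
        if cells["cell_id"].duplicated().any():
            dup = cells.loc[cells["cell_id"].duplicated(), "cell_id"].iloc[0]
            raise ValueError(f"duplicate cell_id {dup!r} in sample {self.sample_id}")
        xy = cells[["x_um", "y_um"]].to_numpy(dtype=float)
        if not np.isfinite(xy).all():
            bad = int(np.where(~np.isfinite(xy).all(axis=1))[0][0])
            raise ValueError(f"non-finite coordinate in row {bad}")

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def marker_names(self) -> list[str]:
        return [
            c[len(MARKER_PREFIX):]
            for c in self.cells.columns
            if c.startswith(MARKER_PREFIX)
        ]

    def coordinates(self, phenotypes: Sequence[str] | None = None) -> pd.DataFrame:
        """Return ``cell_id, x_um, y_um`` rows, optionally restricted to
        a set of phenotypes."""
        cells = self.cells
        if phenotypes is not None:
            cells = cells[cells["phenotype"].isin(phenotypes)]
        return cells[["cell_id", "x_um", "y_um"]].reset_index(drop=True)

    def density(self, phenotype: str) -> float:
        return compute_density(self, phenotype)


def _phenotype_mask(cells: pd.DataFrame, phenotype: str) -> pd.Series:
    # "T" means CD3+, which includes the CD8+ subset.
    if phenotype == "T":
        return cells["phenotype"].isin(T_PHENOTYPES)
    return cells["phenotype"] == phenotype


def compute_density(cellmap: CellMap, phenotype: str) -> float:
    """Area-normalized abundance of a phenotype in cells/mm^2.

    ``phenotype="T"`` counts both ``T`` and ``T_CD8`` cells (CD8+ T
    cells are CD3+).  Exact identity: the returned density times the
    tissue area reproduces the integer count.
    """
    count = int(_phenotype_mask(cellmap.cells, phenotype).sum())
    return count / cellmap.tissue_area_mm2


def density_table(cellmaps: Iterable[CellMap],
                  phenotypes: Sequence[str] = ("T", "T_CD8", "B")) -> pd.DataFrame:
    """Tidy per-sample density table (cells/mm^2) for several maps."""
    rows = []
    for m in cellmaps:
        row: dict = {"sample_id": m.sample_id, "group": m.group,
                     "tissue_area_mm2": m.tissue_area_mm2}
        for p in phenotypes:
            row[f"density_{p}"] = compute_density(m, p)
        rows.append(row)
    return pd.DataFrame(rows)


def cohort_percentage(numerator: int, denominator: int) -> int:
    """Whole-number percentage, rounded half-up.

    Matches the convention of reporting cohort fractions such as
    11/19 -> 58 and 22/72 -> 31 (30.56 rounds up).  Exact integer
    arithmetic; no floating-point ties.
    """
    numerator = int(numerator)
    denominator = int(denominator)
    if denominator <= 0:
        raise ValueError("denominator must be > 0")
    if not 0 <= numerator <= denominator:
        raise ValueError("need 0 <= numerator <= denominator")
    return (200 * numerator + denominator) // (2 * denominator)


def read_cellmap(path: str | Path,
                 tissue_area_mm2: float,
                 vocabulary: Sequence[str] = PHENOTYPES,
                 group: str = "AML",
                 metadata: Mapping | None = None) -> CellMap:
    """Read one sample's cell table from delimited text.

    The file must have a header with columns ``sample_id, x_um, y_um,
    phenotype`` and may carry any number of ``marker_*`` columns (0/1).
    The delimiter (comma or tab) is auto-detected.  Phenotype tokens
    not in ``vocabulary`` are mapped to ``OTHER``; the number of such
    remappings is logged and stored in ``metadata['n_unknown_phenotype']``.
    """
    path = Path(path)
    try:
        table = pd.read_csv(path, sep=None, engine="python")
    except Exception as exc:  # noqa: BLE001 - re-raise with file context
        raise ValueError(f"could not parse cell table {path}: {exc}") from exc
    for col in REQUIRED_COLUMNS:
        if col not in table.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    samples = table["sample_id"].unique() if len(table) else np.array([path.stem])
    if len(samples) > 1:
        raise ValueError(f"{path}: expected one sample per file, found {list(samples)}")
    sample_id = str(samples[0])
    for col in ("x_um", "y_um"):
        coerced = pd.to_numeric(table[col], errors="coerce") if len(table) else table[col]
        bad = coerced.isna() if len(table) else pd.Series(dtype=bool)
        if len(table) and bad.any():
            row = int(np.where(bad)[0][0])
            raise ValueError(f"{path}: non-numeric coordinate in column {col}, row {row}")
        table[col] = coerced.astype(float) if len(table) else table[col]

    vocab = set(vocabulary)
    unknown = ~table["phenotype"].isin(vocab) if len(table) else pd.Series(dtype=bool)
    n_unknown = int(unknown.sum()) if len(table) else 0
    if n_unknown:
        logger.warning("%s: %d cell(s) with phenotype outside vocabulary mapped to OTHER",
                       path, n_unknown)
        table.loc[unknown, "phenotype"] = "OTHER"

    if "cell_id" not in table.columns:
        table.insert(0, "cell_id", [f"{sample_id}_c{i}" for i in range(len(table))])
    marker_cols = [c for c in table.columns if c.startswith(MARKER_PREFIX)]
    for c in marker_cols:
        table[c] = table[c].astype(int).astype(bool)
    keep = ["cell_id", "x_um", "y_um", "phenotype", *marker_cols]
    meta = dict(metadata or {})
    meta["n_unknown_phenotype"] = n_unknown
    return CellMap(sample_id=sample_id, group=group,
                   cells=table[keep].reset_index(drop=True),
                   tissue_area_mm2=float(tissue_area_mm2), metadata=meta)


def write_cellmap(cellmap: CellMap, path: str | Path) -> Path:
    """Write a cell table as CSV (coordinates to 6 decimals).

    ``read_cellmap(write_cellmap(m), m.tissue_area_mm2)`` reproduces
    coordinates to 6 decimals and all labels and flags exactly.
    """
    path = Path(path)
    out = cellmap.cells.copy()
    out.insert(0, "sample_id", cellmap.sample_id)
    marker_cols = [c for c in out.columns if c.startswith(MARKER_PREFIX)]
    for c in marker_cols:
        out[c] = out[c].astype(int)
    out.to_csv(path, index=False, float_format="%.6f")
    return path


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a sample manifest (sample_id, group, tissue_area_mm2[, subgroup, cells_path])."""
    manifest = pd.read_csv(path, sep=None, engine="python")
    for col in ("sample_id", "group", "tissue_area_mm2"):
        if col not in manifest.columns:
            raise ValueError(f"{path}: manifest missing column {col!r}")
    if (manifest["tissue_area_mm2"] <= 0).any():
        bad = manifest.loc[manifest["tissue_area_mm2"] <= 0, "sample_id"].iloc[0]
        raise ValueError(f"{path}: non-positive tissue area for sample {bad}")
    return manifest


@dataclass(frozen=True)
class MarkerFraction:
    """Result of a conditional marker fraction query."""

    fraction: float | None
    n_condition: int
    n_positive: int
    reason: str | None = None

    def __bool__(self) -> bool:
        return self.fraction is not None


def conditional_marker_fraction(cellmap: CellMap,
                                cell_selector: Sequence[str] | str,
                                marker_set: Sequence[str],
                                min_positive: int,
                                target_marker: str,
                                restrict_to_cell_ids: Iterable | None = None,
                                ) -> MarkerFraction:
    """Fraction of conditioned cells positive for a target marker.

    Among cells of the selector phenotype(s) (optionally restricted to
    an aggregate's member cell ids) that are positive for at least
    ``min_positive`` of ``marker_set`` (e.g. >=2 of {PD1, LAG3, TIM3}),
    return the fraction positive for ``target_marker`` (e.g. GZMB).
    When no cell satisfies the condition the fraction is undefined and
    the result carries ``n_condition == 0`` with a reason.
    """
    if min_positive < 1:
        raise ValueError("min_positive must be >= 1")
    if isinstance(cell_selector, str):
        cell_selector = (cell_selector,)
    available = set(cellmap.marker_names)
    for m in [*marker_set, target_marker]:
        if m not in available:
            raise ValueError(f"unknown marker {m!r}; sample carries {sorted(available)}")
    cells = cellmap.cells
    mask = cells["phenotype"].isin(cell_selector)
    if restrict_to_cell_ids is not None:
        mask &= cells["cell_id"].isin(set(restrict_to_cell_ids))
    selected = cells[mask]
    flags = selected[[MARKER_PREFIX + m for m in marker_set]].to_numpy(dtype=bool)
    meets = flags.sum(axis=1) >= min_positive
    n_condition = int(meets.sum())
    if n_condition == 0:
        return MarkerFraction(None, 0, 0, reason="no cells satisfy the marker condition")
    target = selected.loc[meets, MARKER_PREFIX + target_marker].to_numpy(dtype=bool)
    n_positive = int(target.sum())
    return MarkerFraction(n_positive / n_condition, n_condition, n_positive)
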