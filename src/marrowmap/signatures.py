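"""Gene-signature scoring of expression matrices.

Expression matrices are genes x samples/regions tables of linear-scale,
non-negative normalized values (panel-based counts are O(10-1e4)).
Two kinds of scores are supported:

* **Ratio-pair scores** such as the M2-predominance score: the log2
  ratio of the mean expression of an "up" gene set (M2-like macrophage
  genes) over a "down" set (M1-like genes), with a pseudocount.  A
  score above 0 indicates M2 predominance, below 0 M1 predominance.
* **Single-set z-mean scores** used for tertiary-lymphoid-structure
  (TLS) signatures (the 12-gene chemokine, follicular-helper-T and
  TLS-imprint signatures): each gene's log2(x+1) profile is
  z-standardized across samples and the score is the mean z over the
  signature's genes present in the matrix.

Gene lists ship as an editable config; the packaged defaults are
package choices matched to the synthetic reference panel, not
authoritative published lists.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .stats import ALPHA_SPATIAL, KruskalDunnResult, kruskal_dunn

logger = logging.getLogger(__name__)

REGION_TYPES = ("LA", "MIXED1", "MIXED2", "CONTROL")

KIND_SINGLE = "single_set"
KIND_RATIO = "ratio_pair"


@dataclass(frozen=True)
class GeneSignature:
    """A named gene set, or a ratio pair of disjoint up/down sets."""

    name: str
    kind: str = KIND_SINGLE
    genes: tuple[str, ...] = ()
    set_up: tuple[str, ...] = ()     # ratio_pair: numerator (e.g. M2)
    set_down: tuple[str, ...] = ()   # ratio_pair: denominator (e.g. M1)

    def __post_init__(self) -> None:
        if self.kind == KIND_SINGLE:
            if not self.genes:
                raise ValueError(f"signature {self.name!r}: empty gene list")
        elif self.kind == KIND_RATIO:
            if not self.set_up or not self.set_down:
                raise ValueError(f"signature {self.name!r}: both ratio sets required")
            overlap = set(self.set_up) & set(self.set_down)
            if overlap:
                raise ValueError(
                    f"signature {self.name!r}: ratio sets overlap: {sorted(overlap)}")
        else:
            raise ValueError(f"signature {self.name!r}: unknown kind {self.kind!r}")


@dataclass
class ScoreResult:
    """Per-sample scores for one signature."""

    signature: str
    scores: pd.Series               # index = sample/region ids
    n_genes_used: int
    dropped_genes: tuple[str, ...] = ()


def load_signatures(path: str | Path) -> list[GeneSignature]:
    """Load signatures from a YAML config.

    Schema: a top-level ``signatures`` list of mappings with keys
    ``name``, ``kind`` (``single_set`` | ``ratio_pair``) and either
    ``genes`` or ``set_up``/``set_down``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    if not isinstance(payload, dict) or "signatures" not in payload:
        raise ValueError(f"{path}: expected a top-level 'signatures' list")
    out = []
    for entry in payload["signatures"]:
        out.append(GeneSignature(
            name=str(entry["name"]),
            kind=str(entry.get("kind", KIND_SINGLE)),
            genes=tuple(entry.get("genes", ())),
            set_up=tuple(entry.get("set_up", ())),
            set_down=tuple(entry.get("set_down", ())),
        ))
    return out


def default_signatures() -> list[GeneSignature]:
    """The packaged default signature config (synthetic-panel defaults)."""
    with resources.as_file(
            resources.files("marrowmap.config") / "default_signatures.yaml") as p:
        return load_signatures(p)


def _validate_matrix(matrix: pd.DataFrame) -> None:
    if matrix.index.duplicated().any():
        dup = matrix.index[matrix.index.duplicated()][0]
        raise ValueError(f"duplicate gene id {dup!r}")
    if (matrix.to_numpy() < 0).any():
        raise ValueError("expression matrix contains negative values")


def m2_predominance_score(matrix: pd.DataFrame,
                          m2_genes: Sequence[str],
                          m1_genes: Sequence[str],
                          pseudocount: float = 1.0) -> ScoreResult:
    """Macrophage-polarization score per sample.

    ``s_M2 = log2(mean(M2 genes) + eps) - log2(mean(M1 genes) + eps)``
    on linear-scale values.  s_M2 > 0 indicates M2 (anti-inflammatory)
    predominance, s_M2 < 0 M1 predominance; swapping the two sets
    negates the score.
    """
    _validate_matrix(matrix)
    m2_present = [g for g in m2_genes if g in matrix.index]
    m1_present = [g for g in m1_genes if g in matrix.index]
    for label, requested, present in (("M2", m2_genes, m2_present),
                                      ("M1", m1_genes, m1_present)):
        if not present:
            raise ValueError(
                f"no {label} genes present in matrix; missing: {sorted(requested)}")
    m2_mean = matrix.loc[m2_present].mean(axis=0)
    m1_mean = matrix.loc[m1_present].mean(axis=0)
    scores = np.log2(m2_mean + pseudocount) - np.log2(m1_mean + pseudocount)
    dropped = tuple(sorted((set(m2_genes) - set(m2_present))
                           | (set(m1_genes) - set(m1_present))))
    return ScoreResult(signature="M2_predominance", scores=scores.rename("s_M2"),
                       n_genes_used=len(m2_present) + len(m1_present),
                       dropped_genes=dropped)


def signature_zscore(matrix: pd.DataFrame, signature: GeneSignature) -> ScoreResult:
    """Mean-of-z signature score per sample.

    Each signature gene's ``log2(x + 1)`` profile is z-standardized
    across samples; the score is the mean z over retained genes.
    Genes absent from the matrix or with zero variance are dropped
    (logged); if none remain the score is undefined.
    """
    if signature.kind != KIND_SINGLE:
        raise ValueError("signature_zscore requires a single_set signature")
    _validate_matrix(matrix)
    if matrix.shape[1] < 2:
        raise ValueError("need >= 2 samples to z-standardize")
    present = [g for g in signature.genes if g in matrix.index]
    if not present:
        raise ValueError(
            f"signature {signature.name!r}: no genes present in matrix")
    logx = np.log2(matrix.loc[present].astype(float) + 1.0)
    sd = logx.std(axis=1, ddof=1)
    keep = sd > 0
    dropped = tuple(sorted(set(signature.genes) - set(np.array(present)[keep.to_numpy()])))
    if dropped:
        logger.info("signature %s: dropped %d gene(s) (absent or zero variance)",
                    signature.name, len(dropped))
    if not keep.any():
        return ScoreResult(signature=signature.name,
                           scores=pd.Series(np.nan, index=matrix.columns),
                           n_genes_used=0, dropped_genes=dropped)
    z = logx.loc[keep.index[keep]].sub(logx.loc[keep.index[keep]].mean(axis=1), axis=0)
    z = z.div(sd[keep], axis=0)
    scores = z.mean(axis=0).rename(signature.name)
    return ScoreResult(signature=signature.name, scores=scores,
                       n_genes_used=int(keep.sum()), dropped_genes=dropped)


def score_signatures(matrix: pd.DataFrame,
                     signatures: Sequence[GeneSignature],
                     pseudocount: float = 1.0) -> pd.DataFrame:
    """Score several signatures; returns samples x signatures table."""
    cols = {}
    for sig in signatures:
        if sig.kind == KIND_RATIO:
            res = m2_predominance_score(matrix, sig.set_up, sig.set_down,
                                        pseudocount=pseudocount)
            cols[sig.name] = res.scores
        else:
            cols[sig.name] = signature_zscore(matrix, sig).scores
    return pd.DataFrame(cols)


def compare_scores_by_region(scores: pd.Series,
                             annotations: pd.DataFrame,
                             alpha: float = ALPHA_SPATIAL) -> KruskalDunnResult:
    """Kruskal-Wallis + Dunn comparison of a score across region types.

    ``annotations`` needs columns ``region_id`` and ``region_type``;
    region-level comparisons default to alpha = 0.01 to account for
    multiple regions measured per biopsy.
    """
    for col in ("region_id", "region_type"):
        if col not in annotations.columns:
            raise ValueError(f"annotations missing column {col!r}")
    ann = annotations.set_index("region_id")
    common = scores.index.intersection(ann.index)
    if len(common) < len(scores):
        logger.warning("compare_scores_by_region: %d scored ids lack annotations",
                       len(scores) - len(common))
    types = ann.loc[common, "region_type"]
    groups = {t: scores.loc[common][types == t].to_numpy()
              for t in pd.unique(types)}
    if len(groups) < 2:
        raise ValueError("need >= 2 region types present")
    return kruskal_dunn(groups, alpha=alpha)


def read_expression_matrix(path: str | Path,
                           genes_path: str | Path | None = None,
                           samples_path: str | Path | None = None) -> pd.DataFrame:
    """Read a genes x samples matrix.

    Delimited text with gene ids in the first column, or MatrixMarket
    (``.mtx``) with companion one-column gene and sample index files.
    """
    path = Path(path)
    if path.suffix == ".mtx":
        from scipy.io import mmread
        if genes_path is None or samples_path is None:
            raise ValueError("MatrixMarket input needs gene and sample index files")
        loaded = mmread(path)
        values = loaded.toarray() if hasattr(loaded, "toarray") else np.asarray(loaded)
        genes = [line.strip() for line in Path(genes_path).read_text().splitlines() if line.strip()]
        samples = [line.strip() for line in Path(samples_path).read_text().splitlines() if line.strip()]
        matrix = pd.DataFrame(values, index=genes, columns=samples)
    else:
        matrix = pd.read_csv(path, sep=None, engine="python", index_col=0)
    _validate_matrix(matrix)
    return matrix


def write_expression_matrix(matrix: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    matrix.to_csv(path)
    return path
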