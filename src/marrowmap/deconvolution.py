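"""Reference-based cell-type deconvolution by non-negative least squares.

A signature matrix S (marker genes x cell types, linear-scale
reference means) is fit to each mixture profile m by solving

    minimize ||S theta - m||_2   subject to   theta >= 0

with an active-set NNLS solver.  The raw coefficient theta_k is the
cell type's *absolute abundance score* on normalized expression;
proportions are theta / sum(theta).  Scaling a mixture by c > 0 scales
the scores by c and leaves proportions unchanged.

Compartment-restricted sub-deconvolution re-fits a mixture against the
subtype profiles of one compartment (e.g. B cell subsets: memory B,
plasmablast, naive B, germinal-center B; or CD8 T cell states: naive,
cytotoxic, MAIT, dysfunctional) plus a pooled "other" column, then
renormalizes within the compartment; subtypes below a floor are
reported as 0 with the remainder labelled "unassigned".
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import nnls

logger = logging.getLogger(__name__)

#: Gene-overlap fractions triggering a warning / a hard failure.
COVERAGE_WARN = 0.5
COVERAGE_FAIL = 0.1

#: Condition-number threshold above which the signature matrix is
#: flagged as near-collinear.
CONDITION_WARN = 1e4

DEFAULT_SUBTYPE_FLOOR = 0.01


@dataclass
class SignatureMatrix:
    """Marker genes x cell types reference matrix."""

    data: pd.DataFrame                      # genes x types, linear scale
    markers: dict[str, tuple[str, ...]] = field(default_factory=dict)
    condition: float = float("nan")

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            raise ValueError("duplicate genes in signature matrix")
        if (self.data.to_numpy() < 0).any():
            raise ValueError("signature matrix contains negative values")

    @property
    def genes(self) -> pd.Index:
        return self.data.index

    @property
    def cell_types(self) -> list[str]:
        return list(self.data.columns)


def build_signature_matrix(profiles: Mapping[str, pd.DataFrame] | pd.DataFrame,
                           top_k: int = 50,
                           pseudocount: float = 1.0) -> SignatureMatrix:
    """Select marker genes and assemble a signature matrix.

    ``profiles`` is either a genes x types table of reference means or
    a mapping cell type -> genes x replicates table (averaged here).
    For each type, genes are ranked by the log2 fold change of that
    type's mean over the maximum of all other types' means, and the
    ``top_k`` genes are selected; the union of selections forms the
    rows.  A condition-number estimate of the resulting matrix is
    attached; values above ~1e4 warn about collinear references.
    """
    if isinstance(profiles, Mapping):
        means = pd.DataFrame({t: df.mean(axis=1) for t, df in profiles.items()})
    else:
        means = profiles.astype(float)
    if means.shape[1] < 2:
        raise ValueError("need >= 2 cell types")
    if means.empty:
        raise ValueError("empty reference profiles")
    if (means.to_numpy() < 0).any():
        raise ValueError("reference profiles contain negative values")

    markers: dict[str, tuple[str, ...]] = {}
    selected: set[str] = set()
    values = means.to_numpy(dtype=float)
    for j, cell_type in enumerate(means.columns):
        others = np.delete(values, j, axis=1).max(axis=1)
        lfc = np.log2(values[:, j] + pseudocount) - np.log2(others + pseudocount)
        order = np.argsort(-lfc, kind="stable")[:top_k]
        chosen = tuple(means.index[order])
        markers[cell_type] = chosen
        selected.update(chosen)

    rows = sorted(selected)
    data = means.loc[rows]
    condition = float(np.linalg.cond(data.to_numpy(dtype=float)))
    if condition > CONDITION_WARN:
        warnings.warn(
            f"signature matrix is near-collinear (condition {condition:.3g}); "
            "deconvolution estimates may be unstable", stacklevel=2)
    return SignatureMatrix(data=data, markers=markers, condition=condition)


class NNLSDeconvolution:
    """NNLS deconvolution model for one or more mixture profiles.

    Parameters
    ----------
    mixtures : pandas.Series or pandas.DataFrame
        Linear-scale expression: one profile (Series, genes index) or
        genes x samples.
    signature : SignatureMatrix or pandas.DataFrame
        Reference matrix, genes x cell types.
    """

    def __init__(self, mixtures: pd.Series | pd.DataFrame,
                 signature: SignatureMatrix | pd.DataFrame):
        if isinstance(mixtures, pd.Series):
            mixtures = mixtures.to_frame(mixtures.name or "sample")
        if isinstance(signature, pd.DataFrame):
            signature = SignatureMatrix(data=signature)
        self.mixtures = mixtures
        self.signature = signature
        common = signature.genes.intersection(mixtures.index)
        coverage = len(common) / len(signature.genes)
        if coverage == 0:
            raise ValueError("mixture and signature matrix share no genes")
        if coverage < COVERAGE_FAIL:
            raise ValueError(
                f"only {coverage:.1%} of signature genes present in mixture")
        if coverage < COVERAGE_WARN:
            warnings.warn(
                f"only {coverage:.1%} of signature genes present in mixture",
                stacklevel=2)
        self.common_genes = common
        self.coverage = coverage

    def fit(self) -> "DeconvolutionResults":
        s = self.signature.data.loc[self.common_genes].to_numpy(dtype=float)
        types = self.signature.cell_types
        coefs = {}
        residuals = {}
        for sample in self.mixtures.columns:
            m = self.mixtures.loc[self.common_genes, sample].to_numpy(dtype=float)
            theta, rnorm = nnls(s, m)
            coefs[sample] = theta
            residuals[sample] = rnorm
        coefficients = pd.DataFrame(coefs, index=types).T
        coefficients.index.name = "sample"
        return DeconvolutionResults(model=self, coefficients=coefficients,
                                    residual_norm=pd.Series(residuals, name="residual"))


@dataclass
class DeconvolutionResults:
    """Fitted NNLS coefficients and derived quantities."""

    model: NNLSDeconvolution
    coefficients: pd.DataFrame      # samples x cell types (absolute scores)
    residual_norm: pd.Series

    @property
    def total_signal(self) -> pd.Series:
        return self.coefficients.sum(axis=1)

    @property
    def zero_signal(self) -> pd.Series:
        """Boolean per sample: NNLS found no non-zero coefficient."""
        return self.total_signal == 0

    @property
    def proportions(self) -> pd.DataFrame:
        """theta / sum(theta); NaN rows where total signal is zero."""
        total = self.total_signal
        props = self.coefficients.div(total.where(total > 0), axis=0)
        return props

    def cd4_cd8_ratio(self, cd4: str = "T_CD4", cd8: str = "T_CD8") -> pd.Series:
        return cd4_cd8_ratio(self, cd4=cd4, cd8=cd8)

    def tidy(self) -> pd.DataFrame:
        """Long-format table: sample, cell_type, coefficient, proportion, residual."""
        long = self.coefficients.stack().rename("coefficient").reset_index()
        long.columns = ["sample", "cell_type", "coefficient"]
        props = self.proportions.stack(future_stack=True).rename("proportion").reset_index()
        long["proportion"] = props["proportion"]
        long = long.merge(self.residual_norm.rename("residual"),
                          left_on="sample", right_index=True)
        return long

    def summary(self) -> str:
        lines = ["NNLS deconvolution results",
                 f"  mixtures: {self.coefficients.shape[0]}, "
                 f"cell types: {self.coefficients.shape[1]}, "
                 f"genes used: {len(self.model.common_genes)} "
                 f"({self.model.coverage:.0%} of signature)",
                 f"  signature condition estimate: {self.model.signature.condition:.3g}",
                 ""]
        table = self.proportions.round(3)
        table["residual"] = self.residual_norm.round(3)
        lines.append(table.to_string())
        if self.zero_signal.any():
            zero = list(self.coefficients.index[self.zero_signal])
            lines.append(f"  WARNING: zero total signal for samples {zero}")
        return "\n".join(lines)


def nnls_deconvolve(mixtures: pd.Series | pd.DataFrame,
                    signature: SignatureMatrix | pd.DataFrame) -> DeconvolutionResults:
    """Functional wrapper: ``NNLSDeconvolution(mixtures, signature).fit()``."""
    return NNLSDeconvolution(mixtures, signature).fit()


@dataclass
class CompartmentSpec:
    """A compartment (e.g. B cells) with >= 2 member subtypes."""

    name: str
    subtype_profiles: pd.DataFrame          # genes x subtypes, linear scale
    other_profiles: pd.DataFrame | None = None   # genes x non-compartment types

    def __post_init__(self) -> None:
        if self.subtype_profiles.shape[1] < 2:
            raise ValueError(f"compartment {self.name!r}: need >= 2 subtypes")
        if (self.subtype_profiles.to_numpy() < 0).any():
            raise ValueError(f"compartment {self.name!r}: negative reference values")


def compartment_proportions(mixtures: pd.Series | pd.DataFrame,
                            spec: CompartmentSpec,
                            floor: float = DEFAULT_SUBTYPE_FLOOR,
                            ) -> pd.DataFrame:
    """Within-compartment subtype proportions by restricted NNLS.

    The design matrix holds the compartment's subtype profiles plus,
    when provided, one aggregate "OTHER" column (mean of the
    non-compartment reference profiles) absorbing out-of-compartment
    signal.  Subtype coefficients are renormalized within the
    compartment; subtypes below ``floor`` are zeroed and their mass
    reported as ``unassigned``.  Samples with zero compartment signal
    get NaN proportions (flagged in the ``defined`` column).
    """
    design = spec.subtype_profiles.copy()
    subtypes = list(design.columns)
    if spec.other_profiles is not None:
        other = spec.other_profiles.reindex(design.index).fillna(0.0).mean(axis=1)
        design["OTHER"] = other
    results = nnls_deconvolve(mixtures, SignatureMatrix(data=design))
    theta = results.coefficients[subtypes]
    total = theta.sum(axis=1)
    props = theta.div(total.where(total > 0), axis=0)
    small = props.lt(floor) & props.gt(0)
    unassigned = props.where(small, 0.0).sum(axis=1)
    props = props.where(~small, 0.0)
    props["unassigned"] = unassigned
    props["defined"] = total > 0
    return props


def cd4_cd8_ratio(result: DeconvolutionResults,
                  cd4: str = "T_CD4", cd8: str = "T_CD8") -> pd.Series:
    """Per-sample CD4:CD8 abundance ratio theta_CD4 / theta_CD8.

    NaN where theta_CD8 = 0 (ratio undefined); missing cell types are
    an error.
    """
    for name in (cd4, cd8):
        if name not in result.coefficients.columns:
            raise ValueError(f"cell type {name!r} not in deconvolution result")
    num = result.coefficients[cd4]
    den = result.coefficients[cd8]
    ratio = num / den.where(den > 0)
    return ratio.rename("cd4_cd8_ratio")
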