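"""Single-marker regression and the SNP x nearest-CpG interaction model.

Both models are ordinary least squares with the usual two-sided t-tests
(standard-error divisor n - p).  The interaction model

    Y = b0 + b1*g + b2*m + b12*(g*m) + covariates + e

regresses the response on a SNP dosage g, the methylation beta value m of
the SNP's nearest CpG, and their raw (uncentered) product.  Under the
attenuation mechanism Y = b*g*(1 - m) + ... this parameterization
recovers (b1, b2, b12) = (b, 0, -b): the SNP's full effect in an
unmethylated region and its complete suppression at full methylation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .core_data import MarkerAnnotation, MarkerMatrix, SampleTable
from .exceptions import ConfigurationError, DataError
from .roi_builder import nearest_marker

logger = logging.getLogger(__name__)

_RANK_TOL_COND = 1e10  # condition number beyond which we call it collinear


@dataclass(frozen=True)
class TermResult:
    estimate: float
    stderr: float
    p_value: float


@dataclass(frozen=True)
class InteractionFit:
    """Per-term OLS output for a single-marker or interaction model."""

    region: str
    terms: dict[str, TermResult]   # keyed: intercept, snp, cpg, snp_x_cpg,
    # marker, plus covariate names
    residual_df: int
    r_squared: float
    rss: float
    degenerate: bool = False       # collinear/constant input; p-values = 1

    def p(self, term: str) -> float:
        return self.terms[term].p_value


def _ols_terms(y: np.ndarray, X: np.ndarray,
               names: list[str], region: str) -> InteractionFit:
    model = sm.OLS(y, X)
    fit = model.fit()
    terms = {
        name: TermResult(estimate=float(fit.params[j]),
                         stderr=float(fit.bse[j]),
                         p_value=float(fit.pvalues[j]))
        for j, name in enumerate(names)
    }
    return InteractionFit(
        region=region,
        terms=terms,
        residual_df=int(fit.df_resid),
        r_squared=float(fit.rsquared),
        rss=float(fit.ssr),
    )


def _degenerate_fit(region: str, names: list[str], n: int,
                    reason: str) -> InteractionFit:
    logger.warning("region %s: degenerate regression (%s); p-values set to 1",
                   region, reason)
    terms = {name: TermResult(np.nan, np.nan, 1.0) for name in names}
    return InteractionFit(region=region, terms=terms,
                          residual_df=max(n - len(names), 0),
                          r_squared=np.nan, rss=np.nan, degenerate=True)


def _check_rank(X: np.ndarray, names: list[str]) -> str | None:
    """Return the name of a collinear column, or None if full rank."""
    if np.linalg.matrix_rank(X) == X.shape[1] and \
            np.linalg.cond(X) < _RANK_TOL_COND:
        return None
    full_rank = np.linalg.matrix_rank(X)
    for j in range(X.shape[1] - 1, 0, -1):
        if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == full_rank:
            return names[j]
    return names[-1]


def fit_single_marker_regression(table: SampleTable,
                                 marker: MarkerMatrix,
                                 region: str = "") -> InteractionFit:
    """OLS of the response on intercept + covariates + one marker.

    The marker term's two-sided t-test p-value is the single-marker
    analogue of the 0-kbp kernel test.  A marker constant after alignment
    (or collinear with a covariate) yields a degenerate result with p = 1
    and a warning rather than an error, so region scans never abort.
    """
    if marker.m != 1:
        raise ConfigurationError("single-marker regression needs exactly "
                                 f"one marker column, got {marker.m}")
    if tuple(marker.sample_ids) != tuple(table.sample_ids):
        raise DataError("marker not row-aligned with samples")
    x = marker.values[:, 0]
    names = ["intercept", *table.covariates.columns, "marker"]
    region = region or marker.marker_ids[0]
    if np.ptp(x) == 0:
        return _degenerate_fit(region, names, table.n, "constant marker")
    X = np.column_stack([table.design_matrix(), x])
    bad = _check_rank(X, names)
    if bad is not None:
        return _degenerate_fit(region, names, table.n,
                               f"collinear term {bad!r}")
    return _ols_terms(table.response, X, names, region)


def fit_interaction_model(table: SampleTable, snp: MarkerMatrix,
                          cpg: MarkerMatrix,
                          center_inputs: bool = False,
                          region: str = "") -> InteractionFit:
    """OLS with SNP, CpG and their product alongside the covariates.

    ``center_inputs=True`` mean-centers g and m before forming the
    product; this changes what the main effects estimate (effects at the
    sample means rather than at g = 0, m = 0) and is off by default.
    """
    for mat, label in ((snp, "snp"), (cpg, "cpg")):
        if mat.m != 1:
            raise ConfigurationError(
                f"{label} input must have exactly one column, got {mat.m}")
        if tuple(mat.sample_ids) != tuple(table.sample_ids):
            raise DataError(f"{label} matrix not row-aligned with samples")
    g = snp.values[:, 0].astype(float)
    m = cpg.values[:, 0].astype(float)
    names = ["intercept", *table.covariates.columns,
             "snp", "cpg", "snp_x_cpg"]
    region = region or f"{snp.marker_ids[0]}x{cpg.marker_ids[0]}"
    if np.ptp(g) == 0:
        return _degenerate_fit(region, names, table.n, "constant SNP dosage")
    if np.ptp(m) == 0:
        return _degenerate_fit(region, names, table.n,
                               "constant methylation")
    if center_inputs:
        g = g - g.mean()
        m = m - m.mean()
    X = np.column_stack([table.design_matrix(), g, m, g * m])
    bad = _check_rank(X, names)
    if bad is not None:
        return _degenerate_fit(region, names, table.n,
                               f"collinear term {bad!r}")
    return _ols_terms(table.response, X, names, region)


def pair_snp_with_nearest_cpg(snp_id: str, annotation: MarkerAnnotation,
                              cpg_universe: list[str] | tuple[str, ...],
                              ) -> str:
    """Nearest same-chromosome CpG to a SNP, lower position on ties."""
    if not cpg_universe:
        raise ConfigurationError("empty CpG universe")
    return nearest_marker(snp_id, annotation, cpg_universe)
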