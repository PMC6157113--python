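r"""Variance-component kernel score test (KST) for marker regions.

Model
-----
For a continuous response :math:`Y` (here post-treatment log-triglyceride)
the semiparametric model is

.. math:: Y = X b + h(Z) + \varepsilon,

where :math:`X` holds the fixed covariates (intercept, pre-treatment
log-triglyceride, age), :math:`Z` is the ``n x m`` matrix of region
markers and :math:`h` lies in the RKHS induced by the linear kernel
:math:`K = Z Z^T`.  The null hypothesis is that the marker variance
component vanishes, :math:`h \equiv 0`.

The score statistic is

.. math:: Q = \frac{r^T K r}{2 \hat\sigma^2},

with :math:`r` the residuals and :math:`\hat\sigma^2` the maximum-
likelihood error variance (RSS / n) of the covariate-only null model.
Under the null, :math:`Q` is distributed as a weighted sum of independent
one-degree chi-squares whose weights are the non-zero eigenvalues of
:math:`P K P / (2\hat\sigma^2)` with :math:`P = I - X(X^TX)^{-1}X^T`.
Tail probabilities are computed by numerically inverting the
characteristic function of that mixture (Imhof's formulation of the
Davies approach); a Satterthwaite-style moment-matching chi-square is the
flagged fallback if the inversion misbehaves.  A seeded residual-
permutation p-value is provided as an independent validation oracle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import integrate, stats

from .core_data import MarkerMatrix, SampleTable
from .exceptions import ConfigurationError, DataError

logger = logging.getLogger(__name__)

#: relative eigenvalue cutoff for the mixture spectrum
DEFAULT_EIGEN_TOL = 1e-10
#: absolute accuracy target for the characteristic-function inversion
DEFAULT_ACCURACY = 1e-6


# ---------------------------------------------------------------------------
# null model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NullModelFit:
    """Covariate-only OLS fit reused by every region test.

    ``error_variance`` is the maximum-likelihood estimate RSS/n by
    default; ``reml=True`` at fit time selects the unbiased RSS/(n-p)
    divisor instead.
    """

    coefficients: np.ndarray     # (p,) including intercept
    column_names: tuple[str, ...]
    fitted: np.ndarray           # (n,)
    residuals: np.ndarray        # (n,)
    error_variance: float
    design: np.ndarray           # (n, p), kept for projections
    n: int
    p: int

    def __post_init__(self) -> None:
        if self.error_variance <= 0:
            raise DataError("degenerate null fit: error variance is zero")
        scale = max(1.0, float(np.abs(self.design).max()),
                    float(np.abs(self.residuals).max()))
        ortho = np.abs(self.design.T @ self.residuals).max()
        if ortho > 1e-8 * scale * self.n:
            raise DataError(
                f"residuals not orthogonal to covariates (|X'r| = {ortho:.2e})"
            )


def fit_null_model(table: SampleTable, reml: bool = False) -> NullModelFit:
    """OLS of the response on intercept + covariates.

    Raises a data error when the design is rank deficient (naming the
    collinear column) or the fit is exact (zero residual variance).
    """
    X = table.design_matrix()
    y = table.response
    n, p = X.shape
    if n <= p:
        raise DataError(f"need n > p, got n={n}, p={p}")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        name = _collinear_column(X, table.design_columns)
        raise DataError(f"design matrix rank deficient: column {name!r} "
                        "is collinear with the others")
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    resid = y - fitted
    rss = float(resid @ resid)
    if rss <= 1e-12 * max(1.0, float(y @ y)):
        raise DataError("degenerate fit: response is an exact linear "
                        "function of the covariates")
    denom = n - p if reml else n
    sigma2 = rss / denom
    return NullModelFit(
        coefficients=beta,
        column_names=table.design_columns,
        fitted=fitted,
        residuals=resid,
        error_variance=sigma2,
        design=X,
        n=n,
        p=p,
    )


def _collinear_column(X: np.ndarray, names: tuple[str, ...]) -> str:
    for j in range(1, X.shape[1]):
        sub = np.delete(X, j, axis=1)
        if np.linalg.matrix_rank(sub) == np.linalg.matrix_rank(X):
            return names[j]
    return names[0]


# ---------------------------------------------------------------------------
# kernel
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KernelMatrix:
    """Linear-kernel similarity matrix K = Z'Z'^T for one region.

    ``Z_used`` retains the (optionally column-centered) marker matrix so
    the eigen-spectrum can be obtained from the m x m Gram form when
    m < n.
    """

    K: np.ndarray                # (n, n), symmetric PSD
    Z_used: np.ndarray           # (n, m)
    source_region: str
    m: int
    centered: bool

    def __post_init__(self) -> None:
        if not np.array_equal(self.K, self.K.T):
            raise DataError("kernel matrix is not exactly symmetric")
        w = np.linalg.eigvalsh(self.K)
        if w[0] < -1e-8 * max(w[-1], 1.0):
            raise DataError(
                f"kernel not positive semidefinite (min eig {w[0]:.2e})"
            )


def build_linear_kernel(Z: MarkerMatrix, centering: bool = True,
                        region_name: str = "") -> KernelMatrix:
    """K = Z'Z'^T with optional (default) column mean-centering of Z.

    With an intercept in the null model, centering does not change the
    test: the projection P annihilates column means.  It is on by default
    so the kernel measures marker covariance rather than raw cross
    products.
    """
    if Z.m < 1:
        raise ConfigurationError(
            f"region {region_name or Z.marker_ids}: no usable markers"
        )
    Zv = np.asarray(Z.values, dtype=float)
    if centering:
        Zv = Zv - Zv.mean(axis=0, keepdims=True)
    K = Zv @ Zv.T
    K = (K + K.T) / 2.0  # exact symmetry
    return KernelMatrix(K=K, Z_used=Zv,
                        source_region=region_name or "region",
                        m=Z.m, centered=centering)


# ---------------------------------------------------------------------------
# score statistic and null spectrum
# ---------------------------------------------------------------------------

def score_statistic(null: NullModelFit, kernel: KernelMatrix) -> float:
    r"""Q = r^T K r / (2 sigma^2), equal to ||Z'^T r||^2 / (2 sigma^2)."""
    r = null.residuals
    if kernel.K.shape[0] != null.n:
        raise ValueError(
            f"kernel dimension {kernel.K.shape[0]} != n = {null.n}"
        )
    # factorized form: numerically cheaper and exactly non-negative
    v = kernel.Z_used.T @ r
    return float(v @ v) / (2.0 * null.error_variance)


@dataclass(frozen=True)
class NullDistribution:
    """Weights of the chi-square(1) mixture governing Q under the null."""

    eigenvalues: np.ndarray  # descending, all > 0
    tol: float

    @property
    def k(self) -> int:
        return int(self.eigenvalues.size)


def null_spectrum(null: NullModelFit, kernel: KernelMatrix,
                  tol: float = DEFAULT_EIGEN_TOL) -> NullDistribution:
    """Mixture weights: eigenvalues of P K P / 2, P the covariate projection.

    Under the null the residuals are r = P eps with Var(eps) = sigma^2,
    so r'Kr/(2 sigma_hat^2) is distributed as
    sum_i [sigma^2 eig_i(PKP) / (2 sigma_hat^2)] chi^2_1; substituting
    the estimate for sigma^2 cancels the variance and leaves weights
    eig(PKP)/2.  They are computed from whichever of the n x n
    (projected kernel) or m x m (Gram matrix of the projected markers)
    forms is smaller; the two are similar matrices and share non-zero
    eigenvalues.  Weights below ``tol`` times the largest are truncated.
    """
    X = null.design
    if kernel.m < null.n:
        # m x m route: (PZ)' (PZ)
        PZ = kernel.Z_used - X @ np.linalg.lstsq(X, kernel.Z_used,
                                                 rcond=None)[0]
        G = PZ.T @ PZ
        w = np.linalg.eigvalsh((G + G.T) / 2.0)
    else:
        # n x n route: P K P
        PK = kernel.K - X @ np.linalg.lstsq(X, kernel.K, rcond=None)[0]
        PKP = PK - (X @ np.linalg.lstsq(X, PK.T, rcond=None)[0]).T
        w = np.linalg.eigvalsh((PKP + PKP.T) / 2.0)
    w = w / 2.0
    w = np.sort(w)[::-1]
    # degenerate if the whole spectrum is numerical noise relative to the
    # kernel's own scale (markers inside the covariate column space)
    kernel_scale = max(float(np.trace(kernel.K)) / 2.0, 1e-300)
    if w.size == 0 or w[0] <= tol * kernel_scale:
        return NullDistribution(eigenvalues=np.empty(0), tol=tol)
    keep = w > tol * w[0]
    return NullDistribution(eigenvalues=w[keep], tol=tol)


# ---------------------------------------------------------------------------
# mixture-of-chi-squares tail probability
# ---------------------------------------------------------------------------

def _phase(u: float, lam: np.ndarray) -> float:
    return 0.5 * float(np.sum(np.arctan(lam * u)))


def _amplitude(u: float, lam: np.ndarray) -> float:
    return float(np.exp(0.25 * np.sum(np.log1p((lam * u) ** 2))))


def _imhof_head(u: float, lam: np.ndarray, q: float) -> float:
    return np.sin(_phase(u, lam) - 0.5 * q * u) / (u * _amplitude(u, lam))


def _imhof_tail_sin(u: float, lam: np.ndarray) -> float:
    return np.sin(_phase(u, lam)) / (u * _amplitude(u, lam))


def _imhof_tail_cos(u: float, lam: np.ndarray) -> float:
    return np.cos(_phase(u, lam)) / (u * _amplitude(u, lam))


def _moment_match_pvalue(q: float, lam: np.ndarray) -> float:
    """Satterthwaite scaled chi-square matching mean and variance."""
    s1 = float(lam.sum())
    s2 = float((lam ** 2).sum())
    scale = s2 / s1
    dof = s1 ** 2 / s2
    return float(stats.chi2.sf(q / scale, dof))


def pvalue_mixture_chisq(q: float, dist: NullDistribution,
                         accuracy: float = DEFAULT_ACCURACY,
                         ) -> tuple[float, str]:
    r"""P(sum_i lambda_i chi^2_1 > q) by characteristic-function inversion.

    Returns ``(p, method)`` with ``method`` one of ``"davies"`` (the
    Imhof-form numerical inversion succeeded within the accuracy target)
    or ``"moment_match"`` (fallback).  The upper-tail probability is

    .. math::
       P(Q > q) = \tfrac12 + \frac1\pi \int_0^\infty
                  \frac{\sin\theta(u)}{u\,\rho(u)}\,du,

    with :math:`\theta(u) = \tfrac12\sum_i \arctan(\lambda_i u)
    - \tfrac12 q u` and :math:`\rho(u) = \prod_i (1+\lambda_i^2u^2)^{1/4}`.
    """
    if not np.isfinite(q):
        raise ValueError(f"non-finite statistic q = {q!r}")
    if dist.k < 1:
        raise ValueError("empty null spectrum; degenerate region")
    lam = np.asarray(dist.eigenvalues, dtype=float)
    if q <= 0:
        return 1.0, "davies"
    # rescale so the largest weight is 1; the tail probability is
    # invariant and the integrator sees a well-conditioned problem
    scale = float(lam.max())
    lam = lam / scale
    q = q / scale
    # split at u = 1: adaptive quadrature for the head, QUADPACK's
    # Fourier integrator for the oscillatory algebraic tail, using
    # sin(phi - qu/2) = sin(phi)cos(qu/2) - cos(phi)sin(qu/2)
    cut = 1.0
    eps = accuracy / 10.0
    try:
        with np.errstate(all="ignore"):
            head, e1 = integrate.quad(
                _imhof_head, 0.0, cut, args=(lam, q),
                epsabs=eps, limit=200)
            t_sin, e2 = integrate.quad(
                _imhof_tail_sin, cut, np.inf, args=(lam,),
                weight="cos", wvar=q / 2.0, epsabs=eps, limit=500)
            t_cos, e3 = integrate.quad(
                _imhof_tail_cos, cut, np.inf, args=(lam,),
                weight="sin", wvar=q / 2.0, epsabs=eps, limit=500)
        p = 0.5 + (head + t_sin - t_cos) / np.pi
        abserr = e1 + e2 + e3
        ok = np.isfinite(p) and abserr < accuracy and \
            -accuracy <= p <= 1.0 + accuracy
    except Exception:  # integration blow-up
        ok = False
    if not ok:
        p = _moment_match_pvalue(q, lam)
        logger.warning("characteristic-function inversion failed at q=%.4g "
                       "(k=%d); using moment-matching fallback", q, dist.k)
        return float(np.clip(p, 0.0, 1.0)), "moment_match"
    return float(np.clip(p, 0.0, 1.0)), "davies"


def exact_ratio_pvalue(dist: NullDistribution, n_minus_p: int, q: float,
                       variance_denominator: int,
                       accuracy: float = DEFAULT_ACCURACY,
                       ) -> tuple[float, bool]:
    r"""Exact Gaussian tail of Q accounting for the estimated variance.

    Q compares a quadratic form to the *estimated* error variance, so its
    exact null tail is not the plug-in mixture but

    .. math::
       P(Q > q) = P\bigl(\varepsilon' P (K - c I) P \varepsilon > 0\bigr),
       \qquad c = 2 q / d,

    with d the variance divisor (n for ML, n - p for REML).  The weights
    are :math:`\eta_i - c` for the non-zero eigenvalues
    :math:`\eta_i = 2\lambda_i` of PKP and :math:`-c` with multiplicity
    n - p - k, and the tail at threshold zero is obtained by the same
    characteristic-function inversion.  Returns ``(p, ok)``; ``ok`` False
    means the caller should fall back to the plug-in mixture.
    """
    if q <= 0:
        return 1.0, True
    c = 2.0 * q / variance_denominator
    eta = 2.0 * np.asarray(dist.eigenvalues, dtype=float)
    w = np.concatenate([eta - c, np.full(n_minus_p - eta.size, -c)])
    w = w[np.abs(w) > 1e-14 * np.abs(w).max()]
    if (w > 0).all():
        return 1.0, True
    if (w < 0).all():
        return 0.0, True
    w = w / np.abs(w).max()

    def integrand(u: float) -> float:
        theta = 0.5 * np.sum(np.arctan(w * u))
        rho = np.exp(0.25 * np.sum(np.log1p((w * u) ** 2)))
        return np.sin(theta) / (u * rho)

    try:
        with np.errstate(all="ignore"):
            val, abserr = integrate.quad(integrand, 0.0, np.inf,
                                         epsabs=accuracy / 10.0, limit=400)
    except Exception:
        return np.nan, False
    p = 0.5 + val / np.pi
    if not np.isfinite(p) or abserr > accuracy or \
            not -accuracy <= p <= 1.0 + accuracy:
        return np.nan, False
    return float(np.clip(p, 0.0, 1.0)), True


# ---------------------------------------------------------------------------
# end-to-end region test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KSTResult:
    """Per-region test output with full provenance."""

    region: str
    Q: float
    p_value: float
    method_used: str      # davies | moment_match | degenerate
    k: int                # retained spectrum size
    m: int                # markers used
    n: int                # samples

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")
        if self.Q < 0:
            raise ValueError(f"negative score statistic {self.Q}")


def kst_region_test(table: SampleTable, Z_region: MarkerMatrix,
                    centering: bool = True, reml: bool = False,
                    eigen_tol: float = DEFAULT_EIGEN_TOL,
                    accuracy: float = DEFAULT_ACCURACY,
                    region_name: str = "region",
                    null: NullModelFit | None = None) -> KSTResult:
    """Full kernel score test of one region against the response.

    The p-value is the exact Gaussian tail accounting for the estimated
    error variance (:func:`exact_ratio_pvalue`, a Davies-type inversion,
    flagged ``davies``); the plug-in mixture over the spectrum alone is
    the large-n limit and serves as the first fallback, with moment
    matching behind it.  A pre-computed ``null`` fit may be passed to
    amortize the covariate regression across regions.  If the projected
    kernel has no retained eigenvalue (markers collinear with the
    covariates) the region is degenerate and p = 1 is reported with a
    warning.
    """
    if tuple(Z_region.sample_ids) != tuple(table.sample_ids):
        raise DataError("marker matrix is not row-aligned with the samples; "
                        "run align_samples first")
    if null is None:
        null = fit_null_model(table, reml=reml)
    kernel = build_linear_kernel(Z_region, centering=centering,
                                 region_name=region_name)
    Q = score_statistic(null, kernel)
    dist = null_spectrum(null, kernel, tol=eigen_tol)
    if dist.k == 0:
        logger.warning("region %s: all mixture weights below cutoff; "
                       "degenerate result p = 1", region_name)
        return KSTResult(region=region_name, Q=Q, p_value=1.0,
                         method_used="degenerate", k=0, m=Z_region.m,
                         n=table.n)
    denom = int(round(float(null.residuals @ null.residuals)
                      / null.error_variance))
    p, ok = exact_ratio_pvalue(dist, null.n - null.p, Q, denom,
                               accuracy=accuracy)
    if ok:
        method = "davies"
    else:
        logger.warning("region %s: exact inversion failed; using the "
                       "plug-in mixture", region_name)
        p, method = pvalue_mixture_chisq(Q, dist, accuracy=accuracy)
    return KSTResult(region=region_name, Q=Q, p_value=p, method_used=method,
                     k=dist.k, m=Z_region.m, n=table.n)


def permutation_pvalue(table: SampleTable, Z_region: MarkerMatrix,
                       n_perm: int = 999, seed: int | None = None,
                       centering: bool = True, reml: bool = False,
                       null: NullModelFit | None = None) -> float:
    """Residual-permutation p-value for the region score statistic.

    Permutes the null-model residuals with a seeded generator and
    recomputes the full statistic per permutation against the fixed
    kernel (Freedman-Lane style: the permuted residuals are re-projected
    onto the covariate complement and the error variance re-estimated, so
    each permuted Q is the same functional of the permuted data as the
    observed Q is of the data).  Returns the add-one estimate
    ``(1 + #{Q_perm >= Q_obs}) / (1 + n_perm)``.  Serves as an
    assumption-light oracle for the analytic mixture p-value.
    """
    if n_perm < 100:
        raise ConfigurationError("n_perm must be at least 100")
    if null is None:
        null = fit_null_model(table, reml=reml)
    kernel = build_linear_kernel(Z_region, centering=centering)
    q_obs = score_statistic(null, kernel)
    rng = np.random.default_rng(seed)
    r = null.residuals
    denom = int(round(float(r @ r) / null.error_variance))  # n or n - p
    # (n, n_perm) block of permuted residuals
    R = rng.permuted(
        np.broadcast_to(r, (n_perm, r.size)).copy(), axis=1).T
    X = null.design
    R -= X @ np.linalg.lstsq(X, R, rcond=None)[0]   # re-project
    s2 = (R ** 2).sum(axis=0) / denom               # re-estimated variance
    V = kernel.Z_used.T @ R                         # (m, n_perm)
    q_perm = (V ** 2).sum(axis=0) / (2.0 * s2)
    exceed = int(np.sum(q_perm >= q_obs - 1e-12))
    return (1 + exceed) / (1 + n_perm)
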