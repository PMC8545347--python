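"""Null-model GLM fitting and weighted-projection linear algebra.

The scan amortizes all covariate adjustment into a single covariate-only
GLM fit (the "null model"): for each variant, the per-variant design
``[G, G*C, G*S]`` is projected onto the weighted orthogonal complement of
the covariate span, after which one-step estimates, model-based and
heteroskedasticity-robust (HC0 sandwich) covariances, and chi-square
p-values follow from small dense linear algebra.

For the identity-link gaussian family this projection (Frisch-Waugh-Lovell)
reproduces the full-model OLS fit exactly; for the logit family it is a
one-step approximation at the null-model working weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import linalg as sla
from scipy.special import expit, logit
from scipy.stats import chi2

__all__ = [
    "ModelFamily",
    "GAUSSIAN",
    "BINOMIAL_LOGIT",
    "get_family",
    "PhenotypeTable",
    "NullModelFit",
    "SingularDesignError",
    "fit_null_model",
    "project_out_covariates",
    "model_based_covariance",
    "robust_covariance",
    "score_statistic",
    "chisq_pvalue",
]

# Smallest positive double; p-values are floored here, never reported as 0.
_TINY_P = 5e-324


class SingularDesignError(np.linalg.LinAlgError):
    """Raised when a cross-product matrix is (numerically) singular."""


@dataclass(frozen=True)
class ModelFamily:
    """A GLM family: link, inverse link and mean-variance function.

    Two families are supported: gaussian with identity link (continuous
    outcomes) and binomial with logit link (0/1 outcomes). The working
    weight at mean ``mu`` is ``variance_fn(mu)`` for binomial and 1 for
    gaussian.
    """

    name: str
    link: Callable[[np.ndarray], np.ndarray]
    inverse_link: Callable[[np.ndarray], np.ndarray]
    variance_fn: Callable[[np.ndarray], np.ndarray]

    @property
    def is_gaussian(self) -> bool:
        return self.name == "gaussian_identity"


GAUSSIAN = ModelFamily(
    name="gaussian_identity",
    link=lambda mu: np.asarray(mu, dtype=float),
    inverse_link=lambda eta: np.asarray(eta, dtype=float),
    variance_fn=lambda mu: np.ones_like(np.asarray(mu, dtype=float)),
)

BINOMIAL_LOGIT = ModelFamily(
    name="binomial_logit",
    link=logit,
    inverse_link=expit,
    variance_fn=lambda mu: mu * (1.0 - mu),
)

_FAMILIES = {
    "gaussian": GAUSSIAN,
    "gaussian_identity": GAUSSIAN,
    "binomial": BINOMIAL_LOGIT,
    "binomial_logit": BINOMIAL_LOGIT,
}


def get_family(name: str | ModelFamily) -> ModelFamily:
    """Resolve a family by name ('gaussian' or 'binomial')."""
    if isinstance(name, ModelFamily):
        return name
    try:
        return _FAMILIES[name.lower()]
    except KeyError:
        raise ValueError(
            f"unknown family {name!r}; choose 'gaussian' or 'binomial'"
        ) from None


@dataclass
class PhenotypeTable:
    """Aligned outcome, covariate matrix and exposure bookkeeping.

    ``X`` carries a leading intercept column. ``exposure_names`` (q >= 1 at
    scan time) label the covariate columns whose products with the genotype
    form the tested interaction block S; ``int_covariate_names`` (c >= 0)
    label the columns forming the adjusted-but-untested interaction
    covariate block C. The two label sets must be disjoint subsets of
    ``covariate_names``.
    """

    sample_ids: np.ndarray
    y: np.ndarray
    X: np.ndarray
    covariate_names: list[str]
    exposure_names: list[str] = field(default_factory=list)
    int_covariate_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids)
        self.y = np.asarray(self.y, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        n, p = self.X.shape
        if self.y.shape != (n,):
            raise ValueError("outcome length does not match covariate rows")
        if len(self.covariate_names) != p:
            raise ValueError("covariate_names length does not match X columns")
        if not np.all(np.isfinite(self.X)) or not np.all(np.isfinite(self.y)):
            raise ValueError("missing/non-finite values in outcome or covariates")
        named = set(self.covariate_names)
        for label, names in (
            ("exposure", self.exposure_names),
            ("interaction-covariate", self.int_covariate_names),
        ):
            missing = [c for c in names if c not in named]
            if missing:
                raise ValueError(f"{label} column(s) not among covariates: {missing}")
        overlap = set(self.exposure_names) & set(self.int_covariate_names)
        if overlap:
            raise ValueError(
                f"columns listed as both exposure and interaction covariate: {sorted(overlap)}"
            )
        _check_full_rank(self.X, self.covariate_names)

    @classmethod
    def from_arrays(
        cls,
        y: np.ndarray,
        covariates: dict[str, np.ndarray],
        exposure_names: Sequence[str] = (),
        int_covariate_names: Sequence[str] = (),
        sample_ids: Sequence | None = None,
    ) -> "PhenotypeTable":
        """Assemble a table from named covariate vectors, prepending an intercept."""
        y = np.asarray(y, dtype=float)
        n = y.shape[0]
        names = ["intercept"] + list(covariates)
        X = np.column_stack(
            [np.ones(n)] + [np.asarray(v, dtype=float) for v in covariates.values()]
        )
        if sample_ids is None:
            sample_ids = np.arange(n).astype(str)
        return cls(
            sample_ids=np.asarray(sample_ids),
            y=y,
            X=X,
            covariate_names=names,
            exposure_names=list(exposure_names),
            int_covariate_names=list(int_covariate_names),
        )

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    def column_index(self, names: Sequence[str]) -> np.ndarray:
        return np.array([self.covariate_names.index(c) for c in names], dtype=int)


def _check_full_rank(X: np.ndarray, names: Sequence[str]) -> None:
    """Raise naming the collinear columns when X is rank deficient."""
    n, p = X.shape
    if n < p:
        raise ValueError(f"more covariates ({p}) than samples ({n})")
    _, R, piv = sla.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(n, p) * np.finfo(float).eps if diag.size else 0.0
    rank = int(np.sum(diag > tol))
    if rank < p:
        bad = sorted(names[j] for j in piv[rank:])
        raise ValueError(f"covariate matrix is rank deficient; collinear columns: {bad}")


@dataclass
class NullModelFit:
    """Artifacts of the covariate-only fit reused across every variant.

    ``weights`` are the GLM working weights at the fitted means (all ones
    for gaussian, mu*(1-mu) for logit); ``dispersion`` is RSS/(n-p) for
    gaussian and fixed at 1 for binomial; ``xtwx_inv`` is (X'WX)^-1.
    """

    family: ModelFamily
    beta_X: np.ndarray
    mu: np.ndarray
    weights: np.ndarray
    residuals: np.ndarray
    dispersion: float
    xtwx_inv: np.ndarray
    X: np.ndarray
    converged: bool
    n_iter: int
    separation: bool = False


def fit_null_model(
    pheno: PhenotypeTable,
    family: ModelFamily | str,
    tol: float = 1e-8,
    max_iter: int = 30,
) -> NullModelFit:
    """Fit the covariate-only null model Y ~ X.

    Gaussian is a single weighted-least-squares pass; binomial runs IRLS
    from beta = 0 (intercept at logit of the outcome mean) until the
    largest coefficient change drops below ``tol``. Non-convergence is
    reported on the returned fit (``converged=False``) with a warning, so
    the caller still holds the last iterate.
    """
    family = get_family(family)
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    X, y = pheno.X, pheno.y
    n, p = X.shape

    if family.is_gaussian:
        xtx = X.T @ X
        beta = _solve_spd(xtx, X.T @ y, what="covariate cross-product")
        mu = X @ beta
        resid = y - mu
        rss = float(resid @ resid)
        dispersion = rss / (n - p) if n > p else 0.0
        return NullModelFit(
            family=family,
            beta_X=beta,
            mu=mu,
            weights=np.ones(n),
            residuals=resid,
            dispersion=dispersion,
            xtwx_inv=_inv_spd(xtx, what="covariate cross-product"),
            X=X,
            converged=True,
            n_iter=1,
        )

    classes = np.unique(y)
    if not np.array_equal(classes, np.array([0.0, 1.0])):
        raise ValueError(
            f"binomial outcome must contain both classes coded 0/1; saw {classes}"
        )
    beta = np.zeros(p)
    beta[0] = logit(y.mean())
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = expit(eta)
        w = mu * (1.0 - mu)
        z = eta + (y - mu) / np.maximum(w, 1e-300)
        xtwx = X.T @ (w[:, None] * X)
        beta_new = _solve_spd(xtwx, X.T @ (w * z), what="weighted cross-product")
        step = np.max(np.abs(beta_new - beta))
        beta = beta_new
        if step < tol:
            converged = True
            break
    eta = X @ beta
    mu = expit(eta)
    w = mu * (1.0 - mu)
    separation = bool(np.any(mu < 1e-10) or np.any(mu > 1 - 1e-10))
    if not converged:
        warnings.warn(
            f"IRLS did not converge in {max_iter} iterations (last max step > {tol:g})",
            RuntimeWarning,
            stacklevel=2,
        )
    if separation:
        warnings.warn(
            "fitted probabilities numerically 0 or 1 (possible separation)",
            RuntimeWarning,
            stacklevel=2,
        )
    xtwx = X.T @ (w[:, None] * X)
    return NullModelFit(
        family=family,
        beta_X=beta,
        mu=mu,
        weights=w,
        residuals=y - mu,
        dispersion=1.0,
        xtwx_inv=_inv_spd(xtwx, what="weighted covariate cross-product"),
        X=X,
        converged=converged,
        n_iter=it,
        separation=separation,
    )


def project_out_covariates(
    M: np.ndarray, fit: NullModelFit, X: np.ndarray | None = None
) -> np.ndarray:
    """W-weighted residualization of M on the covariate span.

    Returns ``M - X (X'WX)^-1 X'W M``, whose columns are W-orthogonal to X.
    The operation is idempotent.
    """
    if X is None:
        X = fit.X
    M = np.asarray(M, dtype=float)
    squeeze = M.ndim == 1
    if squeeze:
        M = M[:, None]
    if M.shape[0] != X.shape[0]:
        raise ValueError(
            f"row mismatch: M has {M.shape[0]} rows, covariates have {X.shape[0]}"
        )
    coef = fit.xtwx_inv @ (X.T @ (fit.weights[:, None] * M))
    out = M - X @ coef
    return out[:, 0] if squeeze else out


def model_based_covariance(D_proj: np.ndarray, fit: NullModelFit) -> np.ndarray:
    """Model-based covariance of one-step estimates: phi * (D'WD)^-1."""
    A = D_proj.T @ (fit.weights[:, None] * D_proj)
    return fit.dispersion * _inv_spd(A, what="projected-design cross-product")


def robust_covariance(
    D_proj: np.ndarray,
    fit: NullModelFit,
    residuals: np.ndarray | None = None,
) -> np.ndarray:
    """HC0 sandwich covariance (D'WD)^-1 D' diag(e^2) D (D'WD)^-1.

    ``residuals`` defaults to the null-fit raw residuals y - mu; callers
    that have per-variant (one-step-updated) residuals pass them here, which
    for the gaussian family reproduces the textbook HC0 of the full model.
    No small-sample correction is applied.
    """
    e = fit.residuals if residuals is None else np.asarray(residuals, dtype=float)
    A = D_proj.T @ (fit.weights[:, None] * D_proj)
    A_inv = _inv_spd(A, what="projected-design cross-product")
    De = D_proj * e[:, None]
    B = De.T @ De
    return A_inv @ B @ A_inv


def score_statistic(
    D_proj: np.ndarray, fit: NullModelFit, robust: bool = False
) -> float:
    """Score-form chi-square statistic for the projected block.

    U = D~'(y - mu); variance phi * D~'WD~ under the model, or
    D~' diag((y-mu)^2) D~ for the robust form. The scan itself reports the
    Wald-in-projected-space form (one-step estimates), which coincides with
    this score form up to the variance convention; both are exposed so
    either convention can be computed.
    """
    U = D_proj.T @ fit.residuals
    if robust:
        De = D_proj * fit.residuals[:, None]
        V = De.T @ De
    else:
        V = fit.dispersion * (D_proj.T @ (fit.weights[:, None] * D_proj))
    return float(U @ _solve_spd(V, U, what="score variance"))


def chisq_pvalue(stat: float, df: int) -> float:
    """Upper-tail chi-square p-value, computed in log space.

    Tiny negative statistics from round-off (>= -1e-8) are clamped to zero
    with a warning; the returned p is floored at the smallest positive
    double so 0 is never emitted.
    """
    if df < 1:
        raise ValueError("df must be a positive integer")
    if stat < 0:
        if stat >= -1e-8:
            warnings.warn(
                f"clamping slightly negative statistic {stat:g} to 0",
                RuntimeWarning,
                stacklevel=2,
            )
            stat = 0.0
        else:
            raise ValueError(f"negative chi-square statistic: {stat}")
    logp = chi2.logsf(stat, df)
    return float(max(np.exp(logp), _TINY_P))


def _solve_spd(A: np.ndarray, b: np.ndarray, what: str = "matrix") -> np.ndarray:
    try:
        c = sla.cho_factor(A, lower=True)
    except (np.linalg.LinAlgError, sla.LinAlgError) as exc:
        raise SingularDesignError(f"{what} is singular") from exc
    return sla.cho_solve(c, b)


def _inv_spd(A: np.ndarray, what: str = "matrix") -> np.ndarray:
    return _solve_spd(A, np.eye(A.shape[0]), what=what)
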