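"""Per-variant interaction, joint and marginal tests, and the scan driver.

For each variant with dosage vector g the engine builds the design
``D = [g | g*C | g*S]`` (C: interaction covariates, adjusted but never
tested; S: tested exposures), residualizes it on the covariates at the
null-fit working weights, and forms one-step estimates

    beta_hat = (D~' W D~)^-1 D~' (y - mu_hat)

with model-based or HC0-robust covariance. Three p-values are reported:

* interaction — q-df Wald quadratic form on the S block,
* joint — (q+1)-df quadratic form on (G, S) jointly,
* marginal — 1-df test of g in a model with no interaction terms
  (g residualized alone).

The scan never uses randomness and emits results in input order, so output
is identical for any worker count.
"""

from __future__ import annotations

import math
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Iterator, Sequence

import numpy as np

from .glm import (
    ModelFamily,
    NullModelFit,
    PhenotypeTable,
    SingularDesignError,
    chisq_pvalue,
    fit_null_model,
    get_family,
    project_out_covariates,
    robust_covariance,
)

__all__ = [
    "VariantRecord",
    "ScanConfig",
    "VariantResult",
    "VariantStatus",
    "ScanSummary",
    "qc_variant",
    "build_variant_design",
    "test_variant",
    "joint_statistic",
    "interaction_statistic",
    "run_scan",
]


class VariantStatus(str, Enum):
    OK = "ok"
    SKIPPED_MAF = "skipped_maf"
    SKIPPED_MISSING = "skipped_missing"
    SINGULAR = "singular"


@dataclass
class VariantRecord:
    """One variant: metadata plus per-sample effect-allele dosages.

    Dosages are expected effect-allele counts in [0, 2]; missing values are
    NaN. ``info_score`` is an optional imputation-quality pass-through.
    """

    variant_id: str
    chrom: str
    pos: int
    non_effect_allele: str
    effect_allele: str
    dosages: np.ndarray
    info_score: float | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        d = self.dosages[~np.isnan(self.dosages)]
        if d.size and (d.min() < -1e-6 or d.max() > 2 + 1e-6):
            raise ValueError(
                f"{self.variant_id}: dosages outside [0, 2] "
                f"(range {d.min():g}..{d.max():g})"
            )


@dataclass
class ScanConfig:
    """Scan-wide configuration: family, tested blocks, filters, reporting."""

    family: ModelFamily | str = "gaussian"
    exposure_names: Sequence[str] = ()
    int_covariate_names: Sequence[str] = ()
    robust: bool = True
    maf_min: float = 0.005
    max_missing_rate: float = 0.05
    alpha_report: float = 5e-8
    n_workers: int = 1

    def __post_init__(self) -> None:
        self.family = get_family(self.family)
        self.exposure_names = list(self.exposure_names)
        self.int_covariate_names = list(self.int_covariate_names)
        if not 0 <= self.maf_min < 0.5:
            raise ValueError("maf_min must lie in [0, 0.5)")
        if not 0 <= self.max_missing_rate < 1:
            raise ValueError("max_missing_rate must lie in [0, 1)")
        if self.n_workers < 1:
            raise ValueError("n_workers must be >= 1")

    @property
    def q(self) -> int:
        return len(self.exposure_names)

    @property
    def c(self) -> int:
        return len(self.int_covariate_names)


@dataclass
class VariantResult:
    """Estimates, covariance blocks and the three p-values for one variant."""

    variant_id: str
    chrom: str
    pos: int
    non_effect_allele: str
    effect_allele: str
    status: VariantStatus
    n_samples: int = 0
    af: float = math.nan
    beta_marginal: float = math.nan
    se_marginal: float = math.nan
    robust_se_marginal: float = math.nan
    beta_g: float = math.nan
    beta_c: np.ndarray = field(default_factory=lambda: np.array([]))
    beta_s: np.ndarray = field(default_factory=lambda: np.array([]))
    cov_model: np.ndarray | None = None
    cov_robust: np.ndarray | None = None
    p_marginal: float = math.nan
    p_interaction: float = math.nan
    p_joint: float = math.nan

    @property
    def tested(self) -> bool:
        return self.status is VariantStatus.OK


@dataclass
class ScanSummary:
    n_variants: int = 0
    n_tested: int = 0
    n_skipped_maf: int = 0
    n_skipped_missing: int = 0
    n_singular: int = 0
    n_significant: int = 0
    alpha_report: float = 5e-8

    def update(self, res: VariantResult) -> None:
        self.n_variants += 1
        if res.status is VariantStatus.OK:
            self.n_tested += 1
            if res.p_interaction < self.alpha_report:
                self.n_significant += 1
        elif res.status is VariantStatus.SKIPPED_MAF:
            self.n_skipped_maf += 1
        elif res.status is VariantStatus.SKIPPED_MISSING:
            self.n_skipped_missing += 1
        else:
            self.n_singular += 1


def qc_variant(
    v: VariantRecord, cfg: ScanConfig
) -> tuple[np.ndarray | None, float, int, VariantStatus]:
    """Missingness and MAF filtering with mean imputation.

    Returns ``(clean_dosages, af, n_non_missing, status)``; the dosage
    vector is None when the variant is skipped. ``af`` is the effect-allele
    frequency; the filter compares min(af, 1-af) against ``maf_min``.
    """
    d = np.asarray(v.dosages, dtype=float)
    miss = np.isnan(d)
    n_obs = int((~miss).sum())
    if n_obs == 0:
        return None, math.nan, 0, VariantStatus.SKIPPED_MISSING
    miss_rate = miss.mean()
    af = float(d[~miss].sum() / (2 * n_obs))
    if miss_rate > cfg.max_missing_rate:
        return None, af, n_obs, VariantStatus.SKIPPED_MISSING
    if min(af, 1 - af) < cfg.maf_min:
        return None, af, n_obs, VariantStatus.SKIPPED_MAF
    if miss.any():
        d = d.copy()
        d[miss] = 2 * af
    return d, af, n_obs, VariantStatus.OK


def build_variant_design(
    g: np.ndarray, pheno: PhenotypeTable, cfg: ScanConfig
) -> np.ndarray:
    """Stack the per-variant columns [g | g*C block | g*S block].

    Column order is fixed: genotype first, then interaction covariates,
    then tested exposures, each block in configuration order.
    """
    g = np.asarray(g, dtype=float)
    if g.shape[0] != pheno.n_samples:
        raise ValueError("dosage vector not aligned with phenotype rows")
    cols = [g]
    for names in (cfg.int_covariate_names, cfg.exposure_names):
        if names:
            idx = pheno.column_index(names)
            cols.append(g[:, None] * pheno.X[:, idx])
    return np.column_stack(cols)


def _wald(beta: np.ndarray, cov: np.ndarray) -> float:
    """Quadratic form beta' V^-1 beta; NaN when V is singular."""
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    cov = np.atleast_2d(np.asarray(cov, dtype=float))
    try:
        stat = float(beta @ np.linalg.solve(cov, beta))
    except np.linalg.LinAlgError:
        return math.nan
    return stat


def joint_statistic(beta_g_s: np.ndarray, cov_block: np.ndarray) -> float:
    """(q+1)-df quadratic form for the joint main + interaction test."""
    return _wald(beta_g_s, cov_block)


def interaction_statistic(beta_s: np.ndarray, cov_ss_block: np.ndarray) -> float:
    """q-df quadratic form for the interaction-only test."""
    return _wald(beta_s, cov_ss_block)


def test_variant(
    g: np.ndarray,
    pheno: PhenotypeTable,
    nullfit: NullModelFit,
    cfg: ScanConfig,
    meta: VariantRecord | None = None,
    af: float = math.nan,
    n_samples: int | None = None,
) -> VariantResult:
    """Run the three tests for one QC-passed dosage vector.

    The marginal test residualizes g alone (a model with no interaction
    terms); the interaction and joint tests use the full projected design.
    P-values come from the robust covariance when ``cfg.robust``, else the
    model-based one; both covariances are retained on the result.
    """
    if meta is None:
        meta = VariantRecord("g", "0", 0, "N", "N", g)
    if n_samples is None:
        n_samples = pheno.n_samples
    c, q = cfg.c, cfg.q
    base = VariantResult(
        variant_id=meta.variant_id,
        chrom=meta.chrom,
        pos=meta.pos,
        non_effect_allele=meta.non_effect_allele,
        effect_allele=meta.effect_allele,
        status=VariantStatus.SINGULAR,
        n_samples=n_samples,
        af=af,
    )
    D = build_variant_design(g, pheno, cfg)
    D_proj = project_out_covariates(D, nullfit)
    w = nullfit.weights
    r = nullfit.residuals
    try:
        A = D_proj.T @ (w[:, None] * D_proj)
        A_inv = _inv_or_raise(A)
        beta = A_inv @ (D_proj.T @ r)
        # one-step-updated residuals; exact full-model residuals for gaussian
        resid1 = r - w * (D_proj @ beta)
        cov_robust = robust_covariance(D_proj, nullfit, residuals=resid1)

        g_proj = D_proj[:, 0]
        a_m = float(g_proj @ (w * g_proj))
        if a_m <= 0 or not np.isfinite(a_m):
            raise SingularDesignError("monomorphic after projection")
        beta_m = float(g_proj @ r) / a_m
        resid_m = r - w * (g_proj * beta_m)
        var_m_robust = float(g_proj**2 @ resid_m**2) / a_m**2

        # gaussian: refresh the dispersion with the per-variant RSS (free,
        # since resid1 is already in hand); this reproduces the full-model
        # OLS covariance exactly. Binomial dispersion is fixed at 1.
        n, p = nullfit.X.shape
        k = D_proj.shape[1]
        if nullfit.family.is_gaussian:
            phi_v = float(resid1 @ resid1) / max(n - p - k, 1)
            phi_m = float(resid_m @ resid_m) / max(n - p - 1, 1)
        else:
            phi_v = phi_m = 1.0
        cov_model = phi_v * A_inv
        var_m_model = phi_m / a_m
    except SingularDesignError:
        return base

    cov = cov_robust if cfg.robust else cov_model
    var_m = var_m_robust if cfg.robust else var_m_model
    s_idx = np.arange(1 + c, 1 + c + q)
    gs_idx = np.concatenate([[0], s_idx])
    p_int = chisq_pvalue(
        interaction_statistic(beta[s_idx], cov[np.ix_(s_idx, s_idx)]), q
    )
    p_joint = chisq_pvalue(
        joint_statistic(beta[gs_idx], cov[np.ix_(gs_idx, gs_idx)]), q + 1
    )
    p_marg = chisq_pvalue(beta_m**2 / var_m, 1)

    return replace(
        base,
        status=VariantStatus.OK,
        beta_marginal=beta_m,
        se_marginal=math.sqrt(var_m_model),
        robust_se_marginal=math.sqrt(var_m_robust),
        beta_g=float(beta[0]),
        beta_c=beta[1 : 1 + c].copy(),
        beta_s=beta[s_idx].copy(),
        cov_model=cov_model,
        cov_robust=cov_robust,
        p_marginal=p_marg,
        p_interaction=p_int,
        p_joint=p_joint,
    )


def _inv_or_raise(A: np.ndarray) -> np.ndarray:
    try:
        L = np.linalg.cholesky(A)
    except np.linalg.LinAlgError as exc:
        raise SingularDesignError("singular projected cross-product") from exc
    eye = np.eye(A.shape[0])
    L_inv = np.linalg.solve(L, eye)  # A^-1 = L^-T L^-1
    if not np.all(np.isfinite(L_inv)):
        raise SingularDesignError("non-finite inverse")
    return L_inv.T @ L_inv


def _process_one(
    v: VariantRecord,
    geno_idx: np.ndarray | None,
    pheno: PhenotypeTable,
    nullfit: NullModelFit,
    cfg: ScanConfig,
) -> VariantResult:
    dos = v.dosages if geno_idx is None else v.dosages[geno_idx]
    sub = VariantRecord(
        v.variant_id, v.chrom, v.pos, v.non_effect_allele, v.effect_allele, dos,
        info_score=v.info_score,
    )
    g, af, n_obs, status = qc_variant(sub, cfg)
    if status is not VariantStatus.OK:
        return VariantResult(
            variant_id=v.variant_id,
            chrom=v.chrom,
            pos=v.pos,
            non_effect_allele=v.non_effect_allele,
            effect_allele=v.effect_allele,
            status=status,
            n_samples=n_obs,
            af=af,
        )
    return test_variant(g, pheno, nullfit, cfg, meta=sub, af=af, n_samples=n_obs)


def run_scan(
    variants: Iterable[VariantRecord],
    pheno: PhenotypeTable,
    cfg: ScanConfig,
    nullfit: NullModelFit | None = None,
    geno_index: np.ndarray | None = None,
    block_size: int = 256,
) -> Iterator[VariantResult | ScanSummary]:
    """Stream per-variant results; the final item yielded is a ScanSummary.

    ``geno_index`` maps phenotype rows into each record's dosage vector
    (from io.align_samples) when the genotype source carries a different
    sample set/order. Work is partitioned into variant blocks; with
    ``cfg.n_workers > 1`` blocks run on a thread pool, and results are
    always emitted in input order regardless of worker count.
    """
    if cfg.q < 1:
        raise ValueError("at least one tested exposure is required (q >= 1)")
    if nullfit is None:
        nullfit = fit_null_model(pheno, cfg.family)
    summary = ScanSummary(alpha_report=cfg.alpha_report)

    def work(v: VariantRecord) -> VariantResult:
        return _process_one(v, geno_index, pheno, nullfit, cfg)

    if cfg.n_workers == 1:
        for v in variants:
            res = work(v)
            summary.update(res)
            yield res
    else:
        with ThreadPoolExecutor(max_workers=cfg.n_workers) as pool:
            block: list[VariantRecord] = []
            for v in variants:
                block.append(v)
                if len(block) >= block_size:
                    for res in pool.map(work, block):
                        summary.update(res)
                        yield res
                    block = []
            for res in pool.map(work, block):
                summary.update(res)
                yield res
    yield summary
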