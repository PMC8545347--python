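"""Synthetic genotype/exposure/phenotype generation and operating-characteristic
estimation (type-I error, power) for the interaction scan.

The generative model builds a continuous liability as a sum of standardized
components with exact variance fractions:

    y = sqrt(r2_g) * Zg + sqrt(r2_e) * Ze + sqrt(r2_gxe) * Zgxe
        + sqrt(1 - r2_g - r2_e - r2_gxe) * noise

where Zg aggregates equal main effects over the causal variants, Ze the
exposure main effect(s) (optionally quadratic, the mis-specification mode),
and Zgxe equal interaction effects over causal variants x active exposures.
Each composite is standardized empirically, so "variance explained" holds
exactly by construction. Binary outcomes threshold the liability at the
quantile matching the configured case:control ratio.

Genotypes are independent Binomial(2, maf) dosages; linkage disequilibrium
is deliberately absent (it does not affect per-variant calibration or
power). Exposures are standard normal, standardized Bernoulli(0.5), or
standardized log-normal, optionally with a genetic component for
gene-environment correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .glm import PhenotypeTable, fit_null_model
from .scan import ScanConfig, test_variant

__all__ = [
    "SimConfig",
    "simulate_genotypes",
    "simulate_exposures",
    "simulate_phenotype",
    "estimate_type1_error",
    "estimate_power",
    "analytic_power",
    "binomial_acceptance_band",
    "simulate_to_files",
]

EXPOSURE_KINDS = ("continuous", "binary", "log_normal")


def _stage_rng(seed: int, stage: int) -> np.random.Generator:
    """Independent per-stage stream, so genotype, exposure and noise draws
    never overlap when the convenience functions are called separately."""
    return np.random.default_rng([stage, seed])


@dataclass
class SimConfig:
    """Generative-model settings for one simulation scenario.

    Variance fractions are of total phenotypic (liability) variance.
    ``K`` exposures (the first K) carry interaction effects, split equally;
    ``q_test`` exposures (the first q_test) enter the interaction test.
    ``n_causal`` defaults to all simulated variants.
    """

    n: int = 10_000
    m_variants: int = 100
    maf_range: tuple[float, float] = (0.05, 0.45)
    exposure_kind: str = "continuous"
    n_exposures: int = 1
    r2_g_total: float = 0.0
    r2_e_total: float = 0.10
    r2_gxe_total: float = 0.0
    K: int = 1
    q_test: int = 1
    n_causal: int | None = None
    quadratic_exposure: bool = False
    ge_corr_r2: float = 0.0
    outcome_kind: str = "continuous"
    case_control_ratio: float = 1 / 3
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi < 0.5):
            raise ValueError("maf_range must lie strictly inside (0, 0.5)")
        for name in ("r2_g_total", "r2_e_total", "r2_gxe_total"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.r2_g_total + self.r2_e_total + self.r2_gxe_total >= 1:
            raise ValueError("variance fractions must sum to < 1")
        if self.exposure_kind not in EXPOSURE_KINDS:
            raise ValueError(f"exposure_kind must be one of {EXPOSURE_KINDS}")
        if not 1 <= self.K or self.K > self.n_exposures:
            raise ValueError("K must satisfy 1 <= K <= n_exposures")
        if not 1 <= self.q_test <= self.n_exposures:
            raise ValueError("q_test must satisfy 1 <= q_test <= n_exposures")
        if self.n_causal is None:
            self.n_causal = self.m_variants
        if not 1 <= self.n_causal <= self.m_variants:
            raise ValueError("n_causal must lie in [1, m_variants]")
        if self.outcome_kind not in ("continuous", "binary"):
            raise ValueError("outcome_kind must be 'continuous' or 'binary'")

    @property
    def exposure_names(self) -> list[str]:
        return [f"e{k + 1}" for k in range(self.n_exposures)]


def _standardize(x: np.ndarray, what: str = "component") -> np.ndarray:
    sd = x.std()
    if sd == 0:
        raise ValueError(f"cannot standardize constant {what}")
    return (x - x.mean()) / sd


def simulate_genotypes(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Draw independent Binomial(2, maf) dosage columns (n x m_variants).

    MAFs are uniform over ``cfg.maf_range``. Returned dosages are int8.
    """
    rng = _stage_rng(cfg.seed, 1) if rng is None else rng
    mafs = rng.uniform(*cfg.maf_range, size=cfg.m_variants)
    G = np.empty((cfg.n, cfg.m_variants), dtype=np.int8)
    for j, p in enumerate(mafs):
        G[:, j] = rng.binomial(2, p, size=cfg.n)
    return G, mafs


def simulate_exposures(
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    genotypes: np.ndarray | None = None,
) -> np.ndarray:
    """Draw standardized exposure columns (n x n_exposures).

    Kinds: 'continuous' (standard normal), 'binary' (Bernoulli(0.5),
    standardized), 'log_normal' (exp of a standard normal, standardized).
    With ``cfg.ge_corr_r2 > 0`` each exposure receives that variance
    fraction from an equal-effects composite of the causal dosage columns
    (gene-environment correlation).
    """
    rng = _stage_rng(cfg.seed, 2) if rng is None else rng
    E = np.empty((cfg.n, cfg.n_exposures))
    for k in range(cfg.n_exposures):
        if cfg.exposure_kind == "continuous":
            e = rng.standard_normal(cfg.n)
        elif cfg.exposure_kind == "binary":
            e = rng.binomial(1, 0.5, size=cfg.n).astype(float)
        else:
            e = np.exp(rng.standard_normal(cfg.n))
        e = _standardize(e, "exposure")
        if cfg.ge_corr_r2 > 0:
            if genotypes is None:
                raise ValueError("ge_corr_r2 > 0 requires genotypes")
            zg = _standardize(
                _causal_composite(genotypes, cfg.n_causal), "genetic composite"
            )
            e = np.sqrt(cfg.ge_corr_r2) * zg + np.sqrt(1 - cfg.ge_corr_r2) * e
            e = _standardize(e, "exposure")
        E[:, k] = e
    return E


def _causal_composite(G: np.ndarray, n_causal: int) -> np.ndarray:
    """Equal-weight sum of standardized causal dosage columns."""
    out = np.zeros(G.shape[0])
    for j in range(n_causal):
        out += _standardize(G[:, j].astype(float), "dosage column")
    return out


def simulate_phenotype(
    cfg: SimConfig,
    genotypes: np.ndarray,
    exposures: np.ndarray,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, dict]:
    """Build one outcome vector from the configured variance components.

    Interaction effects are split equally across the first ``cfg.K``
    exposures and the first ``cfg.n_causal`` variants; exposure main
    effects are likewise split equally across the K active exposures.
    Returns the outcome and a truth record (component vectors, causal
    indices, active exposures, liability threshold for binary outcomes).
    """
    rng = _stage_rng(cfg.seed, 3) if rng is None else rng
    n = exposures.shape[0]
    truth: dict = {
        "causal_idx": list(range(cfg.n_causal)),
        "active_exposures": list(range(cfg.K)),
    }
    y = np.zeros(n)

    u = None
    if cfg.r2_g_total > 0 or cfg.r2_gxe_total > 0:
        u = _causal_composite(np.asarray(genotypes), cfg.n_causal)

    if cfg.r2_g_total > 0:
        zg = _standardize(u, "genetic composite")
        y += np.sqrt(cfg.r2_g_total) * zg
        truth["genetic_component"] = zg

    if cfg.r2_e_total > 0:
        e_act = exposures[:, : cfg.K]
        if cfg.quadratic_exposure:
            e_act = e_act**2
        ze = _standardize(e_act.sum(axis=1), "exposure composite")
        y += np.sqrt(cfg.r2_e_total) * ze
        truth["exposure_component"] = ze

    if cfg.r2_gxe_total > 0:
        v = exposures[:, : cfg.K].sum(axis=1)
        zgxe = _standardize(u * v, "interaction composite")
        y += np.sqrt(cfg.r2_gxe_total) * zgxe
        truth["gxe_component"] = zgxe

    resid_var = 1 - cfg.r2_g_total - cfg.r2_e_total - cfg.r2_gxe_total
    y += np.sqrt(resid_var) * rng.standard_normal(n)

    if cfg.outcome_kind == "binary":
        case_frac = cfg.case_control_ratio / (1 + cfg.case_control_ratio)
        thresh = np.quantile(y, 1 - case_frac)
        truth["liability_threshold"] = float(thresh)
        y = (y > thresh).astype(float)
    return y, truth


def _make_pheno_table(
    y: np.ndarray, exposures: np.ndarray, cfg: SimConfig, q_test: int
) -> PhenotypeTable:
    names = cfg.exposure_names
    return PhenotypeTable.from_arrays(
        y,
        {name: exposures[:, k] for k, name in enumerate(names)},
        exposure_names=names[:q_test],
    )


def _scan_variants(
    y: np.ndarray,
    exposures: np.ndarray,
    G: np.ndarray,
    cfg: SimConfig,
    robust: bool,
) -> list:
    family = "binomial" if cfg.outcome_kind == "binary" else "gaussian"
    pheno = _make_pheno_table(y, exposures, cfg, cfg.q_test)
    scan_cfg = ScanConfig(
        family=family,
        exposure_names=pheno.exposure_names,
        robust=robust,
        maf_min=0.0,
        max_missing_rate=0.0,
    )
    nullfit = fit_null_model(pheno, family)
    out = []
    for j in range(G.shape[1]):
        g = np.asarray(G[:, j], dtype=float)
        out.append(test_variant(g, pheno, nullfit, scan_cfg))
    return out


def estimate_type1_error(
    cfg: SimConfig,
    alpha_levels: Sequence[float] = (0.05, 1e-3),
    n_replicates: int = 200,
    robust: bool = True,
) -> pd.DataFrame:
    """Empirical type-I error of the interaction and joint tests.

    ``cfg`` must describe a null scenario at the tested variants
    (``r2_gxe_total = 0`` and ``r2_g_total = 0``); the phenotype still
    carries the exposure main effect (possibly quadratic). Each replicate
    draws fresh exposures and a fresh phenotype and tests all
    ``m_variants`` null variants, giving ``n_replicates * m_variants``
    null p-values per test. Rates come with exact (Clopper-Pearson) 95%
    confidence intervals; a warning is raised when the expected rejection
    count at the smallest alpha is below 5.
    """
    if cfg.r2_gxe_total != 0 or cfg.r2_g_total != 0:
        raise ValueError("type-I error scenario requires r2_gxe_total = r2_g_total = 0")
    rng = np.random.default_rng(cfg.seed)
    G, _ = simulate_genotypes(cfg, rng)
    p_int, p_joint = [], []
    for _ in range(n_replicates):
        E = simulate_exposures(cfg, rng)
        y, _truth = simulate_phenotype(cfg, G, E, rng)
        for res in _scan_variants(y, E, G, cfg, robust):
            if res.tested:
                p_int.append(res.p_interaction)
                p_joint.append(res.p_joint)
    p_int = np.array(p_int)
    p_joint = np.array(p_joint)
    n_tests = p_int.size
    if n_tests * min(alpha_levels) < 5:
        warnings.warn(
            f"expected rejection count at alpha={min(alpha_levels):g} is below 5 "
            f"({n_tests} tests); rates will be noisy",
            stacklevel=2,
        )
    rows = []
    for test_name, p in (("interaction", p_int), ("joint", p_joint)):
        for a in alpha_levels:
            k = int((p < a).sum())
            lo, hi = _clopper_pearson(k, n_tests)
            rows.append(
                {
                    "test": test_name,
                    "alpha": a,
                    "n_tests": n_tests,
                    "n_reject": k,
                    "rate": k / n_tests,
                    "ci_low": lo,
                    "ci_high": hi,
                }
            )
    return pd.DataFrame(rows)


def _clopper_pearson(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    a = (1 - conf) / 2
    lo = stats.beta.ppf(a, k, n - k + 1) if k > 0 else 0.0
    hi = stats.beta.ppf(1 - a, k + 1, n - k) if k < n else 1.0
    return float(lo), float(hi)


def binomial_acceptance_band(
    n_tests: int, alpha: float, conf: float = 0.95
) -> tuple[float, float]:
    """Central ``conf`` region of Binomial(n_tests, alpha), as rates.

    An empirical rejection rate outside this band is inconsistent (at
    level 1-conf) with a calibrated test.
    """
    tail = (1 - conf) / 2
    lo = stats.binom.ppf(tail, n_tests, alpha) / n_tests
    hi = stats.binom.ppf(1 - tail, n_tests, alpha) / n_tests
    return float(lo), float(hi)


def analytic_power(
    n: int, r2_per_test: float, resid_var: float, df: int, alpha: float
) -> float:
    """Noncentral chi-square power approximation.

    ``r2_per_test`` is the phenotypic variance captured by the tested
    effect block for one variant; the noncentrality is
    ``n * r2_per_test / resid_var``.
    """
    ncp = n * r2_per_test / resid_var
    crit = stats.chi2.isf(alpha, df)
    return float(stats.ncx2.sf(crit, df, ncp))


def estimate_power(
    cfg: SimConfig,
    alpha: float = 5e-8,
    n_replicates: int = 10,
    robust: bool = True,
    genotypes: tuple[np.ndarray, np.ndarray] | None = None,
) -> dict:
    """Empirical power of the q-df interaction test (and joint test).

    Each replicate draws fresh exposures and a phenotype over the same
    causal genotypes and tests every causal variant, giving
    ``n_replicates * n_causal`` tests. Also returns the analytic
    noncentral chi-square approximation, where the tested per-variant
    variance fraction is ``r2_gxe_total / n_causal`` scaled by the
    fraction of active exposures included in the test.
    """
    rng = np.random.default_rng(cfg.seed)
    if genotypes is None:
        G, mafs = simulate_genotypes(cfg, rng)
    else:
        G, mafs = genotypes
        if G.shape != (cfg.n, cfg.m_variants):
            raise ValueError("supplied genotypes do not match cfg dimensions")
    hits_int = hits_joint = n_tests = 0
    for _ in range(n_replicates):
        E = simulate_exposures(cfg, rng)
        y, _truth = simulate_phenotype(cfg, G, E, rng)
        for res in _scan_variants(y, E, G[:, : cfg.n_causal], cfg, robust):
            if res.tested:
                n_tests += 1
                hits_int += res.p_interaction < alpha
                hits_joint += res.p_joint < alpha

    captured = min(cfg.q_test, cfg.K) / cfg.K
    r2_per_test = cfg.r2_gxe_total / cfg.n_causal * captured
    # residual variance of the per-variant model: exposure main effects and
    # the tested variant's own contributions are removed; effects of the
    # other causal variants remain in the residual
    resid = 1 - cfg.r2_e_total - (cfg.r2_g_total + cfg.r2_gxe_total) / cfg.n_causal
    return {
        "alpha": alpha,
        "n_tests": n_tests,
        "power_interaction": hits_int / n_tests,
        "power_joint": hits_joint / n_tests,
        "analytic_interaction": analytic_power(
            cfg.n, r2_per_test, resid, cfg.q_test, alpha
        ),
    }


def simulate_to_files(cfg: SimConfig, prefix: str) -> dict:
    """Write a scenario as scan-ready fixture files.

    Produces ``<prefix>.dosages.tsv`` (dosage_tsv format),
    ``<prefix>.pheno.tsv`` (sample_id, outcome, exposures) and returns a
    manifest-ready dict (paths, truth summary).
    """
    from .io import write_dosage_tsv
    from .scan import VariantRecord

    rng = np.random.default_rng(cfg.seed)
    G, mafs = simulate_genotypes(cfg, rng)
    E = simulate_exposures(cfg, rng, genotypes=G)
    y, truth = simulate_phenotype(cfg, G, E, rng)
    sample_ids = [f"S{i + 1:06d}" for i in range(cfg.n)]

    geno_path = f"{prefix}.dosages.tsv"
    variants = [
        VariantRecord(
            variant_id=f"rs{j + 1}",
            chrom="1",
            pos=1000 * (j + 1),
            non_effect_allele="A",
            effect_allele="B",
            dosages=G[:, j].astype(float),
        )
        for j in range(cfg.m_variants)
    ]
    write_dosage_tsv(geno_path, variants, sample_ids)

    pheno_path = f"{prefix}.pheno.tsv"
    df = pd.DataFrame({"sample_id": sample_ids, "outcome": y})
    for k, name in enumerate(cfg.exposure_names):
        df[name] = E[:, k]
    df.to_csv(pheno_path, sep="\t", index=False, float_format="%.6g")

    return {
        "genotypes": geno_path,
        "phenotypes": pheno_path,
        "n": cfg.n,
        "m_variants": cfg.m_variants,
        "mafs": [float(m) for m in mafs],
        "causal_idx": truth["causal_idx"] if cfg.r2_gxe_total or cfg.r2_g_total else [],
        "active_exposures": truth["active_exposures"],
        "seed": cfg.seed,
    }
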