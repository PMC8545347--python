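import numpy as np
import pytest

from gescan import PhenotypeTable, ScanConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20250901)


def random_gaussian_dataset(rng, n, q, c, effect=0.1):
    """A random continuous-trait dataset: phenotype table plus one dosage vector.

    Covariates: two nuisance columns, q exposure columns and c
    interaction-covariate columns; the outcome carries small main and
    interaction effects so estimates are non-degenerate.
    """
    cov = {f"x{j}": rng.standard_normal(n) for j in range(2)}
    exposures = [f"e{k}" for k in range(q)]
    intcovs = [f"b{k}" for k in range(c)]
    for name in exposures + intcovs:
        cov[name] = rng.standard_normal(n)
    g = rng.binomial(2, 0.3, size=n).astype(float)
    y = rng.standard_normal(n) + effect * g
    for name in exposures:
        y = y + effect * g * cov[name] + 0.2 * cov[name]
    for name in intcovs:
        y = y + 0.5 * effect * g * cov[name]
    pheno = PhenotypeTable.from_arrays(
        y, cov, exposure_names=exposures, int_covariate_names=intcovs
    )
    cfg = ScanConfig(
        family="gaussian", exposure_names=exposures, int_covariate_names=intcovs
    )
    return pheno, g, cfg


def full_interaction_design(pheno, g, cfg):
    """Dense [X | G | G*C | G*S] design for oracle refits."""
    X = pheno.X
    cols = [X, g[:, None]]
    for names in (cfg.int_covariate_names, cfg.exposure_names):
        if names:
            idx = pheno.column_index(names)
            cols.append(g[:, None] * X[:, idx])
    return np.column_stack(cols)
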