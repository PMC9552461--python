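import numpy as np
import pytest

from pcaqtl.containers import CovariateMatrix, PhenotypeMatrix


def make_phenotypes(values) -> PhenotypeMatrix:
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    return PhenotypeMatrix(
        values, [f"s{i}" for i in range(n)], [f"f{j}" for j in range(p)]
    )


def make_covariates(values, role="known", prefix="c") -> CovariateMatrix:
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = values[:, None]
    n, k = values.shape
    return CovariateMatrix(
        values, [f"s{i}" for i in range(n)], [f"{prefix}{j}" for j in range(k)], role=role
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def gaussian_pheno(rng):
    return make_phenotypes(rng.standard_normal((40, 25)))
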