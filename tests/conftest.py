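import numpy as np
import pytest

import icacap as ic
from icacap.design import CovariateDesign


@pytest.fixture(scope="session")
def small_design():
    """20 subjects, balanced gender x alcohol cells."""
    return ic.gen_covariates(20, (5, 5, 5, 5), age_mean=29.0, age_sd=3.4, seed=11)


@pytest.fixture(scope="session")
def tiny_design():
    """Two-column design (intercept + one binary covariate), 2 subjects."""
    return CovariateDesign(
        np.array([[1.0, 0.0], [1.0, 1.0]]), ["intercept", "x"]
    )


@pytest.fixture(scope="session")
def cap_dataset():
    """One-component synthetic dataset with a known alcohol effect.

    K=4, R=1, n=60, T=250; beta has a 0.6 alcohol effect — strong enough
    that a single fit recovers the projection reliably.
    """
    beta = np.array([[0.1], [0.0], [0.0], [0.6], [0.0]])
    design = ic.gen_covariates(60, (15, 15, 15, 15), seed=5)
    model = ic.gen_true_model(K=4, R=1, beta=beta, seed=6)
    A_list = ic.gen_mixing_series(model, design, T=250, seed=7)
    covs = [ic.sample_covariance(a) for a in A_list]
    return {
        "design": design,
        "model": model,
        "beta": beta,
        "A_list": A_list,
        "covs": covs,
    }


@pytest.fixture(scope="session")
def random_psd_covs():
    """30 random PSD covariance inputs wrapped as SampleCovariance."""
    rng = np.random.default_rng(42)
    covs = []
    for i in range(30):
        W = rng.standard_normal((8, 5))
        covs.append(
            ic.sample_covariance(
                ic.SubjectSeries(id=f"s{i}", M=rng.standard_normal((40, 5)))
            )
        )
    return covs
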