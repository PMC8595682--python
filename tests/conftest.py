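import numpy as np
import pytest

from scpower.data_model import (
    CostModel,
    DispersionTrend,
    ExpressionPrior,
    ExpressionThreshold,
    GammaMixture,
    LinearCurve,
)


@pytest.fixture
def truth_mixture() -> GammaMixture:
    """Known mixture used for recovery tests (gamma1 mean 0.5, gamma2 mean 20)."""
    return GammaMixture(
        p1=0.3, p2=0.6, p3=0.1,
        shape1=1.0, rate1=2.0,
        shape2=4.0, rate2=0.2,
        censor_point=1.0 / 1000,
    )


def make_prior(n_genes: int = 21_000) -> ExpressionPrior:
    """Synthetic depth-parameterized prior with plausible 10x-like curves."""
    return ExpressionPrior(
        cell_type="synthetic",
        technology="umi-droplet-10x",
        component_curves={
            "mean1": LinearCurve(0.1, 0.0002),
            "sd1": LinearCurve(0.15, 0.0003),
            "mean2": LinearCurve(5.0, 0.005),
            "sd2": LinearCurve(4.0, 0.004),
            "p1": LinearCurve(0.5, -0.0001),
        },
        p3_const=0.05,
        dispersion_trend=DispersionTrend(a0=0.2, a1=1.0),
        read_umi_curve=LinearCurve(-20_000.0, 4_000.0),
        n_genes=n_genes,
    )


@pytest.fixture
def synthetic_prior() -> ExpressionPrior:
    return make_prior()


@pytest.fixture
def flat_prior(truth_mixture) -> ExpressionPrior:
    """Prior whose curves are constant, pinned to ``truth_mixture``."""
    return ExpressionPrior(
        cell_type="flat",
        technology="umi-droplet-10x",
        component_curves={
            "mean1": LinearCurve(truth_mixture.mean1, 0.0),
            "sd1": LinearCurve(truth_mixture.sd1, 0.0),
            "mean2": LinearCurve(truth_mixture.mean2, 0.0),
            "sd2": LinearCurve(truth_mixture.sd2, 0.0),
            "p1": LinearCurve(truth_mixture.p1, 0.0),
        },
        p3_const=truth_mixture.p3,
        dispersion_trend=DispersionTrend(a0=0.2, a1=1.0),
        read_umi_curve=LinearCurve(0.0, 1_000.0),
        n_genes=2_000,
    )


@pytest.fixture
def default_threshold() -> ExpressionThreshold:
    return ExpressionThreshold(min_count=10, individual_fraction=0.5)


@pytest.fixture
def cost_model() -> CostModel:
    return CostModel()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
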