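import pytest

from twostage import AdmissibleConstraints, DesignParams, SearchConfig, TwoStageDesign


@pytest.fixture(scope="session")
def worked_params() -> DesignParams:
    """The worked example: p0=0.25, pa=0.40, one-sided alpha=0.05, beta=0.20."""
    return DesignParams(p0=0.25, pa=0.40, alpha=0.05, beta=0.20)


@pytest.fixture(scope="session")
def default_constraints() -> AdmissibleConstraints:
    return AdmissibleConstraints()


@pytest.fixture(scope="session")
def default_config() -> SearchConfig:
    return SearchConfig()


@pytest.fixture(scope="session")
def optimized_design_worked() -> TwoStageDesign:
    """The published optimized design for the worked example."""
    return TwoStageDesign(r1=10, n1=39, r=21, n=62)


def random_design(rng, n_total_max=25):
    """Draw a random valid TwoStageDesign with n <= n_total_max."""
    n = int(rng.integers(2, n_total_max + 1))
    n1 = int(rng.integers(1, n))
    r1 = int(rng.integers(0, n1 + 1))
    r = int(rng.integers(r1, n + 1))
    return TwoStageDesign(r1=r1, n1=n1, r=r, n=n)
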