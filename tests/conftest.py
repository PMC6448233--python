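import pytest

from surv2stage import DesignProblem, HypothesisPair


@pytest.fixture(scope="session")
def pancreatic_pair() -> HypothesisPair:
    """Exponential survival, S0(1)=35%, S1(1)=50% (resectable pancreatic trial)."""
    return HypothesisPair.from_probabilities(0.35, 0.50, 1.0)


@pytest.fixture(scope="session")
def pancreatic_problem(pancreatic_pair) -> DesignProblem:
    """90% power at one-sided 10% with 24 patients/year accrual."""
    return DesignProblem(alpha=0.10, beta=0.10, pair=pancreatic_pair, theta=24.0)


@pytest.fixture(scope="session")
def exp_hr_pair() -> HypothesisPair:
    """Exponential, S0(1)=50%, constant hazard ratio 0.5."""
    return HypothesisPair.from_hazard_ratio(0.5, 0.5, 1.0)


@pytest.fixture(scope="session")
def exp_hr_problem(exp_hr_pair) -> DesignProblem:
    """90% power at one-sided 5% with 15 patients/year accrual."""
    return DesignProblem(alpha=0.05, beta=0.10, pair=exp_hr_pair, theta=15.0)


@pytest.fixture(scope="session")
def weibull_half_pair() -> HypothesisPair:
    """Weibull shape 0.5, S0(1)=10%, S1(1)=25% (refractory NSCLC trial)."""
    return HypothesisPair.from_probabilities(0.10, 0.25, 1.0, k0=0.5)
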