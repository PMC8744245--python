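import dataclasses

import pytest
from hypothesis import HealthCheck, settings

import ipfcea as m
from ipfcea.parameters import BAND_LABELS, GlobalParams, HealthState, StrategyParams, Uncertain

settings.register_profile(
    "suite",
    settings(deadline=None, derandomize=True, suppress_health_check=[HealthCheck.too_slow]),
)
settings.load_profile("suite")

BAND_BOUNDS = [(90.0, 110.0), (80.0, 89.9), (70.0, 79.9), (60.0, 69.9), (50.0, 59.9), (40.0, 49.9)]


@pytest.fixture(scope="session")
def base_inputs() -> m.ModelInputs:
    """The packaged base case with its calibrated exponential hazard."""
    return m.default_config()


def make_toy_inputs(
    *,
    utility: float = 1.0,
    decline: float = 0.0,
    exac_prob: float = 0.0,
    discount: float = 0.0,
    rate_per_year: float = 0.0,
    horizon_years: float | None = None,
    d1: float = 0.0,
    d2: float = 0.0,
    followup: float = 0.0,
    ae_cost: float = 0.0,
    start_band: str = "90-110",
    extra_strategies: tuple[StrategyParams, ...] = (),
) -> m.ModelInputs:
    """A minimal valid model with hand-settable probabilities for oracles."""
    states = tuple(
        HealthState(lbl, lo, hi, utility, 0.0, decline)
        for lbl, (lo, hi) in zip(BAND_LABELS, BAND_BOUNDS)
    ) + (HealthState("death", 0.0, 40.0, 0.0, 0.0, 0.0),)
    g = GlobalParams(
        cycle_years=0.25,
        discount_rate=discount,
        exacerbation_prob=exac_prob,
        post_ae_mortality_multiplier=Uncertain(1.40, 0.0),
        ae_episode_cost=Uncertain(ae_cost, 0.0),
        annual_followup_cost=Uncertain(followup, 0.0),
        disutility_first_cycle=Uncertain(d1, 0.0),
        disutility_subsequent=Uncertain(d2, 0.0),
        horizon_years=horizon_years,
        start_band=start_band,
    )
    strategies = (StrategyParams("symptom_management", 0.0),) + extra_strategies
    hazard = m.BaselineHazard("exponential", rate_per_year=rate_per_year)
    return m.ModelInputs(states=states, strategies=strategies, globals=g, hazard=hazard)


@pytest.fixture
def toy_factory():
    return make_toy_inputs


def zero_sd_inputs(inputs: m.ModelInputs) -> m.ModelInputs:
    """A copy of ``inputs`` with every uncertainty sd set to zero."""
    states = tuple(
        dataclasses.replace(s, utility_sd=0.0) for s in inputs.states
    )
    strategies = tuple(
        dataclasses.replace(
            s,
            or_decline=Uncertain(s.or_decline.mean, 0.0),
            or_mortality=Uncertain(s.or_mortality.mean, 0.0),
            or_exacerbation=Uncertain(s.or_exacerbation.mean, 0.0),
        )
        for s in inputs.strategies
    )
    g = inputs.globals
    g = dataclasses.replace(
        g,
        post_ae_mortality_multiplier=Uncertain(g.post_ae_mortality_multiplier.mean, 0.0),
        ae_episode_cost=Uncertain(g.ae_episode_cost.mean, 0.0),
        annual_followup_cost=Uncertain(g.annual_followup_cost.mean, 0.0),
        disutility_first_cycle=Uncertain(g.disutility_first_cycle.mean, 0.0),
        disutility_subsequent=Uncertain(g.disutility_subsequent.mean, 0.0),
    )
    return dataclasses.replace(inputs, states=states, strategies=strategies, globals=g)
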