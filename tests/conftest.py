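import numpy as np
import pytest

from slnbcost.costing import CostDistribution, PriceIndexSeries
from slnbcost.strategy import StrategyParameters

#: Institutional cohort cost summaries (mean, SD) in BRL.
SLNB_COST = (5782.49, 1767.17)
UPFRONT_COST = (11117.25, 2033.14)
DELAYED_COST = (7620.43, 1750.17)


@pytest.fixture
def flat_index():
    """An index series with no inflation between periods."""
    return PriceIndexSeries({"2020-01": 100.0, "2021-01": 100.0, "2022-01": 100.0})


@pytest.fixture
def rising_index():
    return PriceIndexSeries({"2020-01": 100.0, "2021-01": 110.0, "2022-01": 121.0})


def table_params(p_occult, q_notfound, n_per_arm=1000, **kwargs) -> StrategyParameters:
    """Strategy parameters at the institutional cost summaries."""
    upfront = CostDistribution(*UPFRONT_COST)
    return StrategyParameters(
        p_occult=p_occult,
        q_notfound=q_notfound,
        dist_slnb_base=CostDistribution(*SLNB_COST),
        dist_upfront_snd=upfront,
        dist_delayed_snd=CostDistribution(*DELAYED_COST),
        dist_conversion=upfront,
        n_per_arm=n_per_arm,
        **kwargs,
    )


def point_mass_params(p_occult, q_notfound, base=100.0, upfront=200.0,
                      delayed=50.0, conversion=200.0, n_per_arm=100) -> StrategyParameters:
    """Degenerate (zero-variance) cost model with exact analytic arm costs."""
    return StrategyParameters(
        p_occult=p_occult,
        q_notfound=q_notfound,
        dist_slnb_base=CostDistribution(base, 0.0, family="point-mass"),
        dist_upfront_snd=CostDistribution(upfront, 0.0, family="point-mass"),
        dist_delayed_snd=CostDistribution(delayed, 0.0, family="point-mass"),
        dist_conversion=CostDistribution(conversion, 0.0, family="point-mass"),
        n_per_arm=n_per_arm,
    )
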