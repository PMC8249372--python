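import pytest

from pomstat import EqsStandard, IndicatorSeries
from pomstat.monitoring_io import parse_observation


def make_series(tokens, wb="WB00000", indicator="substance", year=2017, dates=None):
    return IndicatorSeries(
        wb, indicator, year, tuple(parse_observation(t) for t in tokens), dates=dates
    )


# The three published six-observation lacustrine example series: two PAHs and
# a pesticide, all assessed good, with increasing censoring (4/6, 3/6, 6/6).

@pytest.fixture
def benzo_series():
    return make_series(
        ["< 0.00005", "0.0008", "0.00008", "< 0.00005", "< 0.00005", "< 0.00005"],
        wb="PLLW10035", indicator="benzo(a)pyrene",
    )


@pytest.fixture
def fluoranthene_series():
    return make_series(
        ["0.009", "0.003", "< 0.001", "< 0.001", "0.007", "< 0.001"],
        wb="PLLW10051", indicator="fluoranthene",
    )


@pytest.fixture
def endosulfan_series():
    return make_series(
        ["< 0.001"] * 6, wb="PLLW10015", indicator="endosulfan"
    )


@pytest.fixture
def benzo_eqs():
    return EqsStandard("benzo(a)pyrene", aa_eqs=1.7e-4, mac_eqs=0.27)


@pytest.fixture
def fluoranthene_eqs():
    return EqsStandard("fluoranthene", aa_eqs=0.006, mac_eqs=0.12)


@pytest.fixture
def endosulfan_eqs():
    return EqsStandard("endosulfan", aa_eqs=0.005, mac_eqs=0.01)
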