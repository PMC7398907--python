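import math

import pytest

from atzgem import (
    DynamicConfig,
    Media,
    build_atrazine_pathway,
    inject_pathway,
    make_mmm_media,
    make_toy_model,
)
from atzgem.synth import MMM_EXCHANGES, WATER_PROTONS


@pytest.fixture
def toy1():
    return make_toy_model("TOY-1")


@pytest.fixture
def toy2():
    return make_toy_model("TOY-2")


@pytest.fixture
def pathway_spec():
    return build_atrazine_pathway()


@pytest.fixture
def toy2_pathway(toy2, pathway_spec):
    """TOY-2 with the atrazine degradation pathway injected."""
    return inject_pathway(toy2, pathway_spec)


@pytest.fixture
def glc_nh4_media():
    return Media({"EX_glc": 10.0, "EX_nh4": 10.0}, name="glc+nh4")


@pytest.fixture
def atrazine_media():
    """MMM + water/protons + atrazine as the sole C and N source."""
    return make_mmm_media({**WATER_PROTONS, "EX_atz": 1.0})


def mineral_pools(**extra):
    """Non-depletable mineral/water pools plus finite substrate pools."""
    pools = {ex: math.inf for ex in MMM_EXCHANGES}
    pools.update({"EX_h2o": math.inf, "EX_h": math.inf})
    pools.update(extra)
    return pools


@pytest.fixture
def dynamic_caps():
    """Leave water and protons unthrottled by the per-tick uptake cap."""
    return {"EX_h2o": 1000.0, "EX_h": 1000.0}


def make_dynamic_config(caps, **pools):
    return DynamicConfig(initial_pools=mineral_pools(**pools), uptake_caps=caps)
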