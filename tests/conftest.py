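import pytest

from drivesim.model_core import (
    DepositionParams,
    FitnessTable,
    GermlineParams,
    load_params,
)


@pytest.fixture(scope="session")
def zpg():
    return load_params("zpg")


@pytest.fixture(scope="session")
def neutral(zpg):
    """Drive reduced to a neutral Mendelian marker: no cleavage anywhere,
    flat fitness."""
    return zpg.with_updates(
        germline_female=GermlineParams(0.0, 0.0, 0.0),
        germline_male=GermlineParams(0.0, 0.0, 0.0),
        deposition=DepositionParams(),
        fitness=FitnessTable.flat(),
    )


@pytest.fixture(scope="session")
def cost_free(neutral):
    """Cost-free homing: all fitness 1, no end-joining, no deposition,
    homing rate h = 0.4 in both sexes."""
    g = GermlineParams(cut_prob=0.4, hdr_frac=1.0, r1_frac=0.0)
    return neutral.with_updates(germline_female=g, germline_male=g)
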