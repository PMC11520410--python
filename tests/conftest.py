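"""Shared fixtures: small synthetic reaction sets and a hand-mapped reaction.

Expensive fixtures (generated reaction sets) are session-scoped so the
whole suite pays for them once.
"""

import numpy as np
import pytest

from retrocap.chem_io import parse_reaction
from retrocap.synthetic_data import GeneratorConfig, generate_reactions

# acetic-anhydride + fluoroaniline -> acetanilide, mapped by hand; the
# anhydride's O-acyl half is the unmapped leaving fragment.
AMIDE_LINE = (
    "[RX_2][CH3:1][C:2](=[O:3])OC(C)=O."
    "[NH2:4][c:5]1[cH:6][cH:7][cH:8][cH:9][c:10]1[F:11]"
    ">>[CH3:1][C:2](=[O:3])[NH:4][c:5]1[cH:6][cH:7][cH:8][cH:9][c:10]1[F:11]"
)


@pytest.fixture(scope="session")
def amide_reaction():
    return parse_reaction(AMIDE_LINE)


@pytest.fixture(scope="session")
def small_reaction_set():
    """50 template-generated reactions with recorded RC labels."""
    return generate_reactions(GeneratorConfig(n_reactions=50, seed=101))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
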