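import pytest

from sslinker import Peptide

#: The 29 cysteine-containing-peptide masses of the published worked
#: example (ST8Sia IV C142-C292 search), printed to integer daltons.
TABLE2_CCP_MASSES = [
    716, 728, 749, 863, 864, 891, 976, 1096, 1105, 1161, 1204, 1274,
    1359, 1367, 1418, 1480, 1593, 1733, 1754, 1846, 1863, 1864, 1976,
    2179, 2292, 2351, 2617, 2737, 2822,
]

TABLE2_PMS = 2050.5
TABLE2_EPSILON = 0.02530
TABLE2_T_IM = 1.0


@pytest.fixture
def table2_ccp():
    return [Peptide.from_mass(m, n_cys=1) for m in TABLE2_CCP_MASSES]


@pytest.fixture
def bonded_pair():
    """The worked example's bonded peptide pair, concretely assigned."""
    from sslinker import DisulfideStructure, structure_mass

    p1 = Peptide.from_sequence("KTCAVVGNSGIL")
    p2 = Peptide.from_sequence("CDEIHLY", start=100)
    return DisulfideStructure(
        peptides=(p1, p2),
        n_bonds=1,
        mass=structure_mass([p1.mass, p2.mass], 1),
        bonded_pairs=(((0, 2), (1, 0)),),
    )
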