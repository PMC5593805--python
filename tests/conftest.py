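import pytest

from ligeff.synthetic import (
    BindingGenConfig,
    PriceGenConfig,
    generate_binding_dataset,
    generate_price_catalog,
)

# formula -> element counts, for parser and descriptor checks
SMALL_MOLECULES = {
    "C6H6": {"C": 6, "H": 6},
    "H2O": {"H": 2, "O": 1},
    "C6H5Br": {"C": 6, "H": 5, "Br": 1},
    "CH4": {"C": 1, "H": 4},
    "C2H6O": {"C": 2, "H": 6, "O": 1},
    "NH3": {"N": 1, "H": 3},
    "CO2": {"C": 1, "O": 2},
    "C8H10N4O2": {"C": 8, "H": 10, "N": 4, "O": 2},
    "C9H8O4": {"C": 9, "H": 8, "O": 4},
    "CHCl3": {"C": 1, "H": 1, "Cl": 3},
    "CBr4": {"C": 1, "Br": 4},
    "C6H12O6": {"C": 6, "H": 12, "O": 6},
    "NaCl": {"Na": 1, "Cl": 1},
    "H2SO4": {"H": 2, "S": 1, "O": 4},
    "C2H5Br": {"C": 2, "H": 5, "Br": 1},
}


@pytest.fixture(scope="session")
def binding_df():
    return generate_binding_dataset(BindingGenConfig(seed=1))


@pytest.fixture(scope="session")
def catalog_df():
    return generate_price_catalog(PriceGenConfig(n_compounds=5000, seed=7))
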