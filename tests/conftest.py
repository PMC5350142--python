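import pytest

from pftyper.markers import builtin_panel


@pytest.fixture(scope="session")
def panel():
    """The shipped nine-marker panel: (markers, decision matrix)."""
    return builtin_panel()


@pytest.fixture(scope="session")
def markers(panel):
    return panel[0]


@pytest.fixture(scope="session")
def matrix(panel):
    return panel[1]


@pytest.fixture(scope="session")
def marker_by_id(markers):
    return {m.marker_id: m for m in markers}


#: Published phylogroup assignments for the model-strain PCR panel test.
MODEL_STRAIN_GROUPS = {
    "F113": "P. corrugata",
    "Q2-87": "P. corrugata",
    "Q8r1-96": "P. corrugata",
    "NFM421": "P. corrugata",
    "PCL1319": "P. chlororaphis",
    "PCL1606": "P. chlororaphis",
    "Pf-5": "P. protegens",
    "Pf0-1": "P. koreensis",
    "SBW25": "P. fluorescens",
    "KT2440": None,
    "DC3000": None,
    "PAO1": None,
    "DH5alpha": None,
}

#: Published phylogroup assignments for the 19 blind-test field isolates.
ISOLATE_GROUPS = {
    "EMC3": "P. koreensis", "EMC5": "P. koreensis", "RMT7": "P. koreensis",
    "RMC4": "P. koreensis", "RMC9": "P. koreensis", "3.2": "P. koreensis",
    "EMC11": "P. jessenii", "RMT1": "P. jessenii", "RMT2": "P. jessenii",
    "RMC8": "P. jessenii", "HFL1": "P. jessenii", "HFL4": "P. jessenii",
    "EMC7": "P. fluorescens", "EMT2": "P. fluorescens", "EMT8": "P. fluorescens",
    "RMT4": "P. fluorescens", "RMT12": "P. fluorescens",
    "RMP9": "P. corrugata", "7.3": "P. corrugata",
}

#: Published compatible-group sets for the environmental (mixed) samples.
ENVIRONMENTAL_COMPATIBLE = {
    "Soil_sample": {"P. mandelii", "P. fluorescens"},
    "Rhizosphere_1": {"P. corrugata", "P. koreensis", "P. jessenii",
                      "P. mandelii", "P. fluorescens"},
    "Rhizosphere_2": {"P. koreensis", "P. jessenii", "P. mandelii",
                      "P. fluorescens", "P. chlororaphis"},
}
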