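import numpy as np
import pytest

from hepavigil import (
    GeneratorConfig,
    MedDRADictionary,
    ReportRecord,
    load_paper_fixture,
)
from hepavigil.disproportionality import ContingencyTable

GI = "Gastrointestinal disorders"


@pytest.fixture(scope="session")
def paper():
    return load_paper_fixture()


@pytest.fixture
def toy_dictionary():
    return MedDRADictionary(
        {
            "nausea": "Gastrointestinal disorders",
            "vomiting": "Gastrointestinal disorders",
            "headache": "Nervous system disorders",
            "dizziness": "Nervous system disorders",
            "rash": "Skin and subcutaneous tissue disorders",
        }
    )


@pytest.fixture
def toy_reports():
    return [
        ReportRecord("r1", "drugX", frozenset({"nausea"})),
        ReportRecord("r2", "drugX", frozenset({"nausea", "headache"})),
        ReportRecord("r3", "drugY", frozenset({"rash"}), outcomes=frozenset({"death"})),
    ]


@pytest.fixture
def null_config():
    """Two drugs, no injected signals: every true odds ratio is 1."""
    return GeneratorConfig(
        drugs=(("drugA", 1.0), ("drugB", 1.0)),
        vocabulary=(
            ("nausea", "Gastrointestinal disorders", 0.05),
            ("vomiting", "Gastrointestinal disorders", 0.08),
            ("headache", "Nervous system disorders", 0.10),
            ("dizziness", "Nervous system disorders", 0.12),
            ("fatigue", "General disorders and administration site conditions", 0.15),
            ("rash", "Skin and subcutaneous tissue disorders", 0.20),
        ),
        n_reports=10_000,
        seed=20_260_924,
    )


@pytest.fixture
def signal_config(null_config):
    """Same vocabulary with a single 4x odds multiplier on (drugA, nausea)."""
    return GeneratorConfig(
        drugs=null_config.drugs,
        vocabulary=null_config.vocabulary,
        signals={("drugA", "nausea"): 4.0},
        n_reports=50_000,
        seed=20_260_924,
    )


def random_tables(rng: np.random.Generator, n: int, low: int = 1, high: int = 100_000):
    """n random 2x2 tables with all cells >= low."""
    cells = rng.integers(low, high, size=(n, 4))
    return [ContingencyTable(*map(int, row)) for row in cells]
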