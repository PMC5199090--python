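import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for _oracles

import ctrlregion as cr


def make_alignment(rows: dict[str, str] | list[str]) -> cr.Alignment:
    if isinstance(rows, list):
        rows = {f"s{i + 1}": r for i, r in enumerate(rows)}
    return cr.Alignment([cr.SeqRecord(i, s) for i, s in rows.items()])


@pytest.fixture
def toy_aln():
    """Three 7-column sequences with two variable columns (5 and 7)."""
    return make_alignment({"a": "ACGTACA", "b": "ACGTTCA", "c": "ACGTTCG"})


@pytest.fixture(scope="session")
def default_panel():
    """Default synthetic panel: 5 clades x 5 + 2 outgroup, one hot block."""
    return cr.generate(cr.SyntheticConfig(seed=7))


@pytest.fixture(scope="session")
def bornean_panel():
    """Bornean-style panel: three hot blocks, diagnostic deletion."""
    return cr.generate(cr.bornean_panel_config(seed=7))


@pytest.fixture(scope="session")
def sumatran_panel():
    """Sumatran-style panel: 13 sequences, two hot blocks, no deletion."""
    return cr.generate(cr.sumatran_panel_config(seed=7))
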