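from __future__ import annotations

import random

import pytest

from gbskit.enzymes import Enzyme, builtin_enzymes


@pytest.fixture(scope="session")
def enzyme_table():
    return builtin_enzymes()


@pytest.fixture(scope="session")
def apeki(enzyme_table) -> Enzyme:
    return enzyme_table.get("ApeKI")


@pytest.fixture()
def rng() -> random.Random:
    return random.Random(20240901)


def random_dna(rng: random.Random, length: int, alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(alphabet) for _ in range(length))
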