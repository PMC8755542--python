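import numpy as np
import pytest

from smquant import polymer, simulate


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def dsdna_params():
    """Standard lambda-dsDNA mechanics: Lp 50 nm, Lc 16 um, room temperature."""
    return polymer.PolymerParams(Lp=50.0, Lc=16_000.0)


def _random_reference(seed: int = 42, length: int = 201) -> str:
    gen = np.random.default_rng(seed)
    return "".join(gen.choice(list("ACGT"), length))


@pytest.fixture(scope="session")
def amplicon_reference() -> str:
    """A 201 bp random amplicon guaranteed to contain MMEJ-capable sites."""
    ref = _random_reference()
    assert simulate.find_microhomology_sites(ref), "fixture reference lacks MH sites"
    return ref


@pytest.fixture(scope="session")
def donor_substitutions(amplicon_reference):
    """Three 1 bp donor substitutions at fixed positions, never matching the reference."""
    out = []
    for pos in (50, 100, 150):
        base = "ACGT"[("ACGT".index(amplicon_reference[pos]) + 1) % 4]
        out.append((pos, base))
    return out
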