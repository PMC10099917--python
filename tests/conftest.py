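import numpy as np
import pytest

import nrcfv as nv
from nrcfv.alphabets import MISSING


def make_random_alignment(
    seed: int,
    n_taxa: int = 6,
    n_columns: int = 80,
    alphabet=nv.DNA,
    gap_fraction: float = 0.0,
    skew: float = 0.0,
) -> nv.Alignment:
    """Random alignment fixture with optional gaps and per-taxon skew.

    ``skew`` > 0 tilts each taxon's state distribution toward a
    taxon-specific random direction, creating genuine compositional
    heterogeneity.
    """
    rng = np.random.default_rng(seed)
    c = alphabet.n_states
    codes = np.empty((n_taxa, n_columns), dtype=np.uint8)
    for i in range(n_taxa):
        freqs = np.full(c, 1.0 / c)
        if skew > 0:
            freqs = rng.dirichlet(np.full(c, 1.0 / skew))
        cdf = np.cumsum(freqs)
        cdf[-1] = 1.0
        codes[i] = np.searchsorted(cdf, rng.random(n_columns), side="right")
    if gap_fraction > 0:
        mask = rng.random((n_taxa, n_columns)) < gap_fraction
        # keep at least one observed cell per taxon
        mask[:, 0] = False
        codes[mask] = MISSING
    return nv.Alignment(
        [f"tax{i:03d}" for i in range(n_taxa)], codes, alphabet
    )


@pytest.fixture
def toy_dna() -> nv.Alignment:
    return nv.Alignment.from_sequences(
        ["t1", "t2"], ["ACGT", "ACGA"], alphabet=nv.DNA
    )


@pytest.fixture
def two_state_example() -> nv.Alignment:
    """Two taxa over a binary alphabet with frequencies (0.6, 0.4) / (0.4, 0.6).

    Hand evaluation: per state the deviations are |0.6-0.5| + |0.4-0.5|,
    giving csRCFV = 0.1 per state and total RCFV = 0.2.
    """
    ry = nv.custom_alphabet("RY", name="ry")
    return nv.Alignment.from_sequences(
        ["a", "b"], ["RRRRRRYYYY", "RRRRYYYYYY"], alphabet=ry
    )


@pytest.fixture
def heterogeneous_protein() -> nv.Alignment:
    return make_random_alignment(
        seed=7, n_taxa=8, n_columns=120, alphabet=nv.PROTEIN, skew=2.0
    )
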