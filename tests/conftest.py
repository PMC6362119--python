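import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))   # for oracles.py

from refugia import Alignment, PopulationMap

BASES = "ACGT"


def random_alignment(rng: np.random.Generator, n: int, L: int,
                     missing_frac: float = 0.0, n_states: int = 4) -> Alignment:
    chars = np.array(list(BASES[:n_states] + "N-"))
    probs = np.full(n_states, (1 - missing_frac) / n_states)
    probs = np.concatenate([probs, [missing_frac / 2, missing_frac / 2]])
    mat = rng.choice(len(chars), size=(n, L), p=probs)
    seqs = ["".join(chars[row]) for row in mat]
    return Alignment([f"s{i}" for i in range(n)], seqs)


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture
def toy_alignment():
    # 8 sequences, 4 distinct strings, with one gapped site
    seqs = ["ACGTACGTAC", "ACGTACGTAC", "ACGTTCGTAC", "ACGTTCGTAC",
            "ACGTTCGAAC", "ACGTTCGAAC", "ACG-TCGAAC", "ACGTACGTAC"]
    return Alignment([f"s{i}" for i in range(8)], seqs)


@pytest.fixture
def two_group_alignment():
    # two internally identical groups with a fixed 10% difference
    a, b = "AAAAAAAAAA", "CAAAAAAAAA"
    aln = Alignment([f"x{i}" for i in range(3)] + [f"y{i}" for i in range(3)],
                    [a] * 3 + [b] * 3)
    pm = PopulationMap({f"x{i}": "P1" for i in range(3)} |
                       {f"y{i}": "P2" for i in range(3)})
    return aln, pm
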