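"""Core data containers: haploid sequence alignments and population maps.

An :class:`Alignment` is a rectangular matrix of aligned haploid sequences
(one row per individual, e.g. mtDNA haplotypes), restricted to the alphabet
``{A, C, G, T, N, -}``.  ``N`` and ``-`` are treated as missing data by the
analysis layers.  A :class:`PopulationMap` partitions the sampled individuals
into populations (lineages); population order is preserved as given, so that
downstream summary-statistic vectors have a fixed, reproducible layout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

VALID_CHARS = frozenset("ACGTN-")

# integer encoding used throughout the numeric layers
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4, "-": 5}
_DECODE = np.array(list("ACGTN-"))
MISSING_CODES = (4, 5)


@dataclass
class Alignment:
    """Equal-length haploid sequences with unique identifiers."""

    sequence_ids: list[str]
    sequences: list[str]

    def __post_init__(self) -> None:
        if len(self.sequence_ids) != len(self.sequences):
            raise ValueError("sequence_ids and sequences differ in length")
        if not self.sequences:
            raise ValueError("empty alignment")
        if len(set(self.sequence_ids)) != len(self.sequence_ids):
            raise ValueError("duplicate sequence ids")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise ValueError(f"ragged alignment: lengths {sorted(lengths)}")
        if next(iter(lengths)) < 1:
            raise ValueError("alignment length must be >= 1")
        self.sequences = [s.upper() for s in self.sequences]
        bad = set("".join(self.sequences)) - VALID_CHARS
        if bad:
            raise ValueError(f"invalid characters in alignment: {sorted(bad)}")

    @property
    def n(self) -> int:
        return len(self.sequences)

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    def to_matrix(self) -> np.ndarray:
        """Integer-coded (n, L) matrix; A,C,G,T -> 0..3, N -> 4, '-' -> 5."""
        flat = np.frombuffer("".join(self.sequences).encode(), dtype=np.uint8)
        out = np.empty(flat.shape, dtype=np.int8)
        for ch, code in _CODE.items():
            out[flat == ord(ch)] = code
        return out.reshape(self.n, self.length)

    @classmethod
    def from_matrix(cls, ids: list[str], mat: np.ndarray) -> "Alignment":
        seqs = ["".join(row) for row in _DECODE[np.asarray(mat, dtype=np.int64)]]
        return cls(list(ids), seqs)

    def missing_mask(self) -> np.ndarray:
        """Boolean (n, L) mask of N/- cells."""
        m = self.to_matrix()
        return (m == 4) | (m == 5)

    def complete_sites(self) -> np.ndarray:
        """Indices of sites with no missing data in any sequence."""
        return np.flatnonzero(~self.missing_mask().any(axis=0))


@dataclass
class PopulationMap:
    """Mapping from sample id to population label, with stable population order."""

    assignments: dict[str, str]
    _order: list[str] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not self.assignments:
            raise ValueError("empty population map")
        seen: list[str] = []
        for pop in self.assignments.values():
            if pop not in seen:
                seen.append(pop)
        self._order = seen

    @property
    def populations(self) -> list[str]:
        """Population labels in first-appearance order."""
        return list(self._order)

    def members(self, pop: str) -> list[str]:
        return [s for s, p in self.assignments.items() if p == pop]

    def sizes(self) -> dict[str, int]:
        return {p: len(self.members(p)) for p in self._order}

    def validate_against(self, aln: Alignment) -> None:
        missing = [i for i in aln.sequence_ids if i not in self.assignments]
        if missing:
            raise ValueError(f"samples not in population map: {missing[:5]}")

    def indices(self, aln: Alignment) -> dict[str, np.ndarray]:
        """Row indices in ``aln`` per population, in alignment order."""
        self.validate_against(aln)
        pos = {s: i for i, s in enumerate(aln.sequence_ids)}
        return {
            p: np.array([pos[s] for s in aln.sequence_ids if self.assignments[s] == p],
                        dtype=np.intp)
            for p in self._order
        }
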