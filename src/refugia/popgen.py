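"""Alignment-level population-genetic statistics.

Site classification, haplotype collapsing, diversity indices (nucleotide
diversity pi and Nei's unbiased haplotype diversity h), uncorrected
p-distances, barcoding-gap partitioning of pairwise distances, base
composition, and the theta -> Ne conversion for maternally inherited
haploid loci.

Missing-data policy
-------------------
Sites containing ``N`` or ``-`` in any sequence are excluded (complete
deletion) from site classification, diversity indices and haplotype
collapsing, matching the DnaSP convention.  ``p_distance_matrix`` defaults
to pairwise deletion with a complete-deletion option.  Ambiguity codes
other than ``N`` are rejected at parse time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignment import Alignment, PopulationMap


@dataclass
class SiteClassification:
    """Exhaustive partition of alignment columns.

    ``invariable + singleton + parsimony_informative + excluded == L``.
    A site is parsimony-informative iff >= 2 distinct states are each
    carried by >= 2 sequences; variable but not informative -> singleton.
    """

    invariable: int
    singleton: int
    parsimony_informative: int
    excluded: int

    @property
    def total(self) -> int:
        return self.invariable + self.singleton + self.parsimony_informative + self.excluded

    def as_dict(self) -> dict[str, int]:
        return {
            "invariable": self.invariable,
            "singleton": self.singleton,
            "parsimony_informative": self.parsimony_informative,
            "excluded": self.excluded,
            "total": self.total,
        }


@dataclass
class HaplotypeTable:
    """Distinct haplotypes with counts, frequencies and member ids."""

    haplotypes: list[str]            # representative sequences (policy-retained sites)
    counts: list[int]
    members: list[list[str]]
    sites_used: np.ndarray           # column indices retained by the policy

    @property
    def n(self) -> int:
        return int(sum(self.counts))

    @property
    def frequencies(self) -> np.ndarray:
        c = np.asarray(self.counts, dtype=float)
        return c / c.sum()


@dataclass
class DiversitySummary:
    """Per-sample diversity indices (Table-style: n, p, S, pi, h)."""

    n: int
    p: int                 # number of haplotypes
    S: int                 # segregating (polymorphic) sites
    pi: float              # nucleotide diversity per site
    h: float               # haplotype diversity, Nei's unbiased
    degenerate: bool = False   # n < 2: pi and h reported as 0

    def as_dict(self) -> dict:
        return {"n": self.n, "p": self.p, "S": self.S, "pi": self.pi,
                "h": self.h, "degenerate": self.degenerate}


@dataclass
class DistanceMatrix:
    """Symmetric matrix of uncorrected p-distances.

    Entries are proportions of differing sites among comparable sites;
    pairs with zero comparable sites are NaN.
    """

    values: np.ndarray
    ids: list[str]
    deletion: str = "pairwise"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        self.values = v


@dataclass
class ThetaEstimate:
    theta: float
    estimator: str
    mu: float
    Ne: float = field(init=False)

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise ValueError("mu must be positive")
        if self.theta < 0:
            raise ValueError("theta must be non-negative")
        self.Ne = self.theta / self.mu


def _policy_matrix(aln: Alignment) -> tuple[np.ndarray, np.ndarray]:
    """(matrix restricted to complete sites, indices of retained sites)."""
    mat = aln.to_matrix()
    keep = np.flatnonzero(~((mat == 4) | (mat == 5)).any(axis=0))
    return mat[:, keep], keep


def classify_sites(aln: Alignment) -> SiteClassification:
    """Partition sites into invariable / singleton / parsimony-informative,
    with sites removed by the missing-data policy counted as excluded."""
    mat = aln.to_matrix()
    missing = (mat == 4) | (mat == 5)
    excluded_mask = missing.any(axis=0)
    inv = sing = pinf = 0
    kept = mat[:, ~excluded_mask]
    for col in kept.T:
        _, counts = np.unique(col, return_counts=True)
        if counts.size == 1:
            inv += 1
        elif (counts >= 2).sum() >= 2:
            pinf += 1
        else:
            sing += 1
    return SiteClassification(inv, sing, pinf, int(excluded_mask.sum()))


def collapse_haplotypes(aln: Alignment) -> HaplotypeTable:
    """Group sequences identical on policy-retained sites into haplotypes.

    Haplotypes are ordered by first occurrence in the alignment.
    """
    mat, keep = _policy_matrix(aln)
    key_to_idx: dict[bytes, int] = {}
    haps: list[str] = []
    counts: list[int] = []
    members: list[list[str]] = []
    for sid, row, full in zip(aln.sequence_ids, mat, aln.sequences):
        key = row.tobytes()
        if key not in key_to_idx:
            key_to_idx[key] = len(haps)
            haps.append("".join(full[j] for j in keep))
            counts.append(0)
            members.append([])
        i = key_to_idx[key]
        counts[i] += 1
        members[i].append(sid)
    return HaplotypeTable(haps, counts, members, keep)


def diversity_summary(aln: Alignment) -> DiversitySummary:
    """n, haplotype count p, segregating sites S, per-site pi, and h.

    h uses Nei's unbiased correction ``(n/(n-1)) * (1 - sum f_i^2)``;
    pi is the mean per-site pairwise difference over all sequence pairs,
    computed on policy-retained sites.
    """
    mat, keep = _policy_matrix(aln)
    n = aln.n
    ht = collapse_haplotypes(aln)
    p = len(ht.haplotypes)
    S = int(sum(len(np.unique(col)) > 1 for col in mat.T))
    if n < 2:
        return DiversitySummary(n, p, S, 0.0, 0.0, degenerate=True)
    L = mat.shape[1]
    diffs = _pairwise_mismatch_counts(mat)
    iu = np.triu_indices(n, k=1)
    pi = float(diffs[iu].sum() / (len(iu[0]) * L)) if L > 0 else 0.0
    f = ht.frequencies
    h = float(n / (n - 1) * (1.0 - np.sum(f**2)))
    return DiversitySummary(n, p, S, pi, h)


def _pairwise_mismatch_counts(mat: np.ndarray) -> np.ndarray:
    """(n, n) counts of differing sites; assumes no missing codes in mat."""
    n, L = mat.shape
    same = np.zeros((n, n))
    for state in range(4):
        ind = (mat == state).astype(np.float64)
        same += ind @ ind.T
    return L - same


def p_distance_matrix(aln: Alignment, deletion: str = "pairwise") -> DistanceMatrix:
    """Uncorrected p-distances: mismatches / comparable sites per pair.

    deletion='pairwise' compares, for each pair, the sites where both
    sequences are unambiguous; 'complete' first drops every site with any
    missing data.  A pair with zero comparable sites gets NaN.
    """
    if deletion not in ("pairwise", "complete"):
        raise ValueError(f"unknown deletion mode {deletion!r}")
    mat = aln.to_matrix()
    if deletion == "complete":
        mat, _ = _policy_matrix(aln)
        if mat.shape[1] == 0:
            vals = np.full((aln.n, aln.n), np.nan)
            np.fill_diagonal(vals, 0.0)
            return DistanceMatrix(vals, aln.sequence_ids, deletion)
        diffs = _pairwise_mismatch_counts(mat)
        vals = diffs / mat.shape[1]
    else:
        ok = ~((mat == 4) | (mat == 5))
        okf = ok.astype(np.float64)
        comparable = okf @ okf.T
        same = np.zeros_like(comparable)
        for state in range(4):
            ind = (mat == state).astype(np.float64)
            same += ind @ ind.T
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = (comparable - same) / comparable
        vals[comparable == 0] = np.nan
    np.fill_diagonal(vals, 0.0)
    return DistanceMatrix(vals, aln.sequence_ids, deletion)


@dataclass
class DistancePartition:
    """Intra- vs inter-group pairwise distances (barcoding-gap layout)."""

    intra: dict[str, np.ndarray]
    inter: dict[tuple[str, str], np.ndarray]
    group_means: dict[tuple[str, str], float]
    bins: np.ndarray
    intra_hist: np.ndarray
    inter_hist: np.ndarray

    @property
    def all_intra(self) -> np.ndarray:
        return np.concatenate([v for v in self.intra.values()]) if self.intra else np.array([])

    @property
    def all_inter(self) -> np.ndarray:
        return np.concatenate([v for v in self.inter.values()]) if self.inter else np.array([])

    def barcoding_gap(self) -> float | None:
        """max(intra) .. min(inter) margin; None if either set is empty."""
        ai, ae = self.all_intra, self.all_inter
        if ai.size == 0 or ae.size == 0:
            return None
        return float(ae.min() - ai.max())


def distance_partition(dm: DistanceMatrix, pm: PopulationMap,
                       n_bins: int = 20) -> DistancePartition:
    """Assign every off-diagonal pair to intra or inter; tabulate means
    per group pair and histogram counts over shared bins."""
    ids = dm.ids
    pops = [pm.assignments.get(i) for i in ids]
    if any(p is None for p in pops):
        raise ValueError("distance matrix ids not all mapped to populations")
    groups = pm.populations
    vals = dm.values
    intra: dict[str, list[float]] = {g: [] for g in groups}
    inter: dict[tuple[str, str], list[float]] = {}
    n = len(ids)
    for i in range(n):
        for j in range(i + 1, n):
            d = vals[i, j]
            gi, gj = pops[i], pops[j]
            if gi == gj:
                intra[gi].append(d)
            else:
                key = tuple(sorted((gi, gj), key=groups.index))
                inter.setdefault(key, []).append(d)
    intra_a = {g: np.asarray(v, dtype=float) for g, v in intra.items()}
    inter_a = {k: np.asarray(v, dtype=float) for k, v in inter.items()}
    means: dict[tuple[str, str], float] = {}
    for g, v in intra_a.items():
        means[(g, g)] = float(np.nanmean(v)) if v.size else float("nan")
    for k, v in inter_a.items():
        means[k] = float(np.nanmean(v))
    finite = np.concatenate([v for v in list(intra_a.values()) + list(inter_a.values())
                             if v.size] or [np.array([0.0])])
    finite = finite[np.isfinite(finite)]
    hi = float(finite.max()) if finite.size else 1.0
    bins = np.linspace(0.0, max(hi, 1e-12), n_bins + 1)
    ai = np.concatenate([v for v in intra_a.values()]) if intra_a else np.array([])
    ae = np.concatenate([v for v in inter_a.values()]) if inter_a else np.array([])
    intra_hist = np.histogram(ai[np.isfinite(ai)], bins=bins)[0] if ai.size else np.zeros(n_bins, int)
    inter_hist = np.histogram(ae[np.isfinite(ae)], bins=bins)[0] if ae.size else np.zeros(n_bins, int)
    return DistancePartition(intra_a, inter_a, means, bins, intra_hist, inter_hist)


def base_composition(aln: Alignment) -> dict[str, float]:
    """Percentages of A/C/G/T over unambiguous cells (gaps and N excluded)."""
    mat = aln.to_matrix()
    counts = [(mat == s).sum() for s in range(4)]
    total = sum(counts)
    if total == 0:
        raise ValueError("alignment contains no unambiguous bases")
    return {b: 100.0 * c / total for b, c in zip("ACGT", counts)}


def harmonic_number(k: int) -> float:
    return float(np.sum(1.0 / np.arange(1, k + 1))) if k >= 1 else 0.0


def theta_and_ne(*, mu: float, estimator: str = "watterson",
                 S: int | None = None, n: int | None = None, L: int | None = None,
                 aln: Alignment | None = None) -> ThetaEstimate:
    """Per-site theta (Watterson or pi) and the Ne = theta / mu conversion
    for a maternally inherited haploid locus.

    Watterson: ``theta_W = S / (a_{n-1} * L)`` with ``a_{n-1} = sum_{i<n} 1/i``.
    """
    if mu <= 0:
        raise ValueError("mu must be positive")
    if estimator == "watterson":
        if aln is not None:
            ds = diversity_summary(aln)
            S, n = ds.S, ds.n
            L = len(aln.complete_sites())
        if S is None or n is None or L is None:
            raise ValueError("watterson estimator needs S, n and L (or aln)")
        if n < 2:
            raise ValueError("need n >= 2")
        theta = S / (harmonic_number(n - 1) * L)
    elif estimator == "pi":
        if aln is None:
            raise ValueError("pi estimator needs an alignment")
        theta = diversity_summary(aln).pi
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    return ThetaEstimate(theta=float(theta), estimator=estimator, mu=mu)


def per_generation_rate(rate_per_myr: float, generation_time_years: float) -> float:
    """Convert substitutions/site/Myr to a per-site per-generation rate."""
    return rate_per_myr * generation_time_years / 1e6
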