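"""Statistical-parsimony (TCS-style) haplotype networks.

The connection limit is the largest number of mutational steps ``j`` for
which the probability of parsimony — the probability that ``j`` observed
differences between two sequences arose from exactly ``j`` mutations with
no homoplasy — is at least the confidence level (default 95%).

The probability follows the classical coalescent derivation: for a random
pair of sequences the number of mutations ``M`` since their common ancestor
is geometric, ``P(M=k) ~ (theta/(1+theta))^k``, with theta estimated from
the observed number of differences; mutations fall independently and
uniformly over the ``m`` sites, so the chance that ``k`` mutations show up
as exactly ``j`` differing sites is a classical occupancy probability
(Stirling numbers of the second kind).  Conditioning on ``j`` observed
differences,

    P(parsimony | j) = 1 / sum_{k>=j} r^(k-j) * S2(k, j) / m^(k-j),

with ``r = theta/(1+theta)`` and ``theta = j``.  State reversions at
multiply-hit sites are ignored (any hit site is counted as differing),
which is conservative for 4-state DNA.

Haplotypes are then connected in increasing order of mutational distance;
connections whose step count exceeds the limit are forbidden, which can
leave the network in multiple components (deeply diverged lineages).
Multi-step connections insert inferred (unsampled) intermediate haplotypes.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import networkx as nx
import numpy as np

from .alignment import PopulationMap
from .popgen import HaplotypeTable


@dataclass
class ParsimonyLimit:
    max_steps: int
    alpha: float
    L: int


@lru_cache(maxsize=None)
def _stirling2_row(k: int) -> tuple[int, ...]:
    """Row k of Stirling numbers of the second kind, S2(k, 0..k)."""
    if k == 0:
        return (1,)
    prev = _stirling2_row(k - 1)
    row = [0] * (k + 1)
    for j in range(1, k + 1):
        row[j] = j * (prev[j] if j < k else 0) + prev[j - 1]
    return tuple(row)


def parsimony_probability(j: int, L: int, max_extra: int = 80) -> float:
    """Probability that j observed differences over L sites are non-homoplastic."""
    if j < 1:
        return 1.0
    theta = float(j)
    r = theta / (1.0 + theta)
    total = 0.0
    for k in range(j, j + max_extra + 1):
        s2 = _stirling2_row(k)[j]
        term = r ** (k - j) * float(s2) / float(L) ** (k - j)
        total += term
        if term < 1e-14 * total:
            break
    return 1.0 / total


def parsimony_limit(L: int, alpha: float = 0.95) -> ParsimonyLimit:
    """Largest step count justified at confidence ``alpha`` for length L.

    Always at least 1 (a single difference is connected even at alpha
    close to 1).
    """
    if L < 2:
        raise ValueError("need L >= 2")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    j = 1
    while parsimony_probability(j + 1, L) >= alpha:
        j += 1
        if j > L:      # cannot differ at more sites than there are
            break
    return ParsimonyLimit(max_steps=j, alpha=alpha, L=L)


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def build_network(ht: HaplotypeTable, limit: ParsimonyLimit,
                  pm: PopulationMap | None = None) -> nx.Graph:
    """Statistical-parsimony network over a haplotype table.

    Pairs are considered in increasing order of mutational (Hamming)
    distance; a connection is made when the two haplotypes lie in different
    components at the start of that distance level, so all equal-cost
    alternative connections are retained (loops are kept, not resolved).
    Connections longer than ``limit.max_steps`` are forbidden.  A d-step
    connection inserts d-1 inferred intermediate nodes (frequency 0).

    Nodes carry ``kind`` ('sampled'|'inferred'), ``frequency``, ``members``,
    ``sequence`` (sampled only) and, when a population map is given,
    ``populations`` (member counts per population).
    """
    if not ht.haplotypes:
        raise ValueError("empty haplotype table")
    names = [f"H{i + 1}" for i in range(len(ht.haplotypes))]
    g = nx.Graph()
    for name, seq, count, members in zip(names, ht.haplotypes, ht.counts, ht.members):
        attrs = dict(kind="sampled", frequency=int(count), members=list(members),
                     sequence=seq)
        if pm is not None:
            pops: dict[str, int] = {}
            for m in members:
                p = pm.assignments[m]
                pops[p] = pops.get(p, 0) + 1
            attrs["populations"] = pops
        g.add_node(name, **attrs)

    p = len(names)
    dist = np.zeros((p, p), dtype=int)
    for i in range(p):
        for j in range(i + 1, p):
            dist[i, j] = dist[j, i] = _hamming(ht.haplotypes[i], ht.haplotypes[j])

    by_level: dict[int, list[tuple[int, int]]] = {}
    for i in range(p):
        for j in range(i + 1, p):
            by_level.setdefault(int(dist[i, j]), []).append((i, j))

    comp = {name: k for k, name in enumerate(names)}   # union-find by relabel
    for d in sorted(by_level):
        if d == 0 or d > limit.max_steps:
            continue
        level_pairs = sorted(by_level[d], key=lambda ij: (names[ij[0]], names[ij[1]]))
        added: list[tuple[int, int]] = []
        for i, j in level_pairs:
            if comp[names[i]] != comp[names[j]]:
                added.append((i, j))
                _connect(g, names[i], names[j], d)
        for i, j in added:
            ci, cj = comp[names[i]], comp[names[j]]
            if ci != cj:
                for k, c in comp.items():
                    if c == cj:
                        comp[k] = ci
    return g


def _connect(g: nx.Graph, a: str, b: str, steps: int) -> None:
    lo, hi = sorted((a, b))
    prev = lo
    for s in range(1, steps):
        mid = f"i.{lo}.{hi}.{s}"
        if mid not in g:
            g.add_node(mid, kind="inferred", frequency=0, members=[])
        g.add_edge(prev, mid, steps=1)
        prev = mid
    g.add_edge(prev, hi, steps=1)


@dataclass
class NetworkComponents:
    """Connected components over sampled haplotypes, plus the minimum
    Hamming distances between components."""

    members: list[list[str]]                 # sampled haplotype names per component
    populations: list[dict[str, int]]        # summed member counts per population
    between_steps: np.ndarray                # min Hamming distance across each cut

    @property
    def n_components(self) -> int:
        return len(self.members)


def network_components(g: nx.Graph) -> NetworkComponents:
    comps = []
    for c in nx.connected_components(g):
        sampled = sorted(n for n in c if g.nodes[n]["kind"] == "sampled")
        if sampled:
            comps.append(sampled)
    comps.sort(key=lambda c: c[0])
    pops = []
    for c in comps:
        agg: dict[str, int] = {}
        for n in c:
            for p, k in g.nodes[n].get("populations", {}).items():
                agg[p] = agg.get(p, 0) + k
        pops.append(agg)
    m = len(comps)
    between = np.zeros((m, m), dtype=int)
    for a in range(m):
        for b in range(a + 1, m):
            dmin = min(
                _hamming(g.nodes[x]["sequence"], g.nodes[y]["sequence"])
                for x in comps[a] for y in comps[b]
            )
            between[a, b] = between[b, a] = dmin
    return NetworkComponents(comps, pops, between)
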