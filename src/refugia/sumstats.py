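"""ABC summary statistics.

Per population: number of haplotypes, segregating sites, mean pairwise
differences (counts of differing sites), private segregating sites.
Per population pair: mean between-sample pairwise differences and Hudson's
FST computed from mean pairwise differences,
``FST = 1 - Hw/Hb`` with ``Hw`` the average of the two within-population
means and ``Hb`` the between-population mean.

A segregating site is private to population k iff it is variable in the
pooled sample and every copy of every minor (non-majority) allele occurs
in k only.

The vector layout is fixed by the population order of the sample
configuration, so reference tables and observed data always align.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alignment import Alignment, PopulationMap
from .coalescent import MutatedSites
from .popgen import _pairwise_mismatch_counts, _policy_matrix


@dataclass
class SummaryStats:
    names: list[str]
    values: np.ndarray
    populations: list[str]

    def as_dict(self) -> dict[str, float]:
        return {k: float(v) for k, v in zip(self.names, self.values)}


def stat_names(populations: list[str]) -> list[str]:
    names = []
    for p in populations:
        names += [f"hap_{p}", f"segs_{p}", f"pi_{p}", f"priv_{p}"]
    for a in range(len(populations)):
        for b in range(a + 1, len(populations)):
            pa, pb = populations[a], populations[b]
            names += [f"dxy_{pa}|{pb}", f"fst_{pa}|{pb}"]
    return names


def _hap_count(X: np.ndarray) -> int:
    if X.shape[1] == 0:
        return 1
    return len(np.unique(np.ascontiguousarray(X).view(
        np.dtype((np.void, X.dtype.itemsize * X.shape[1])))))


def stats_from_matrix(X: np.ndarray, pop_indices: dict[str, np.ndarray],
                      populations: list[str]) -> np.ndarray:
    """Summary-statistic vector from an integer state matrix (n, S) with
    states 0..3 and no missing data; S may be 0."""
    X = np.ascontiguousarray(X, dtype=np.int8)
    n, S = X.shape
    D = _pairwise_mismatch_counts(X) if S else np.zeros((n, n))

    onehot = {p: np.stack([(X[idx] == s).sum(axis=0) for s in range(4)])
              for p, idx in pop_indices.items()}          # (4, S) per pop
    total = sum(onehot.values()) if S else np.zeros((4, 0))
    seg_pooled = (total > 0).sum(axis=0) > 1 if S else np.zeros(0, bool)

    if S:
        major = np.argmax(total, axis=0)
        minor_mask = (total > 0) & (np.arange(4)[:, None] != major[None, :])
    vals: list[float] = []
    for p in populations:
        idx = pop_indices[p]
        Xp = X[idx]
        vals.append(float(_hap_count(Xp)))
        if S:
            cp = onehot[p]
            vals.append(float(((cp > 0).sum(axis=0) > 1).sum()))
        else:
            vals.append(0.0)
        if len(idx) > 1:
            sub = D[np.ix_(idx, idx)]
            m = len(idx)
            vals.append(float(np.triu(sub, 1).sum() / (m * (m - 1) / 2)))
        else:
            vals.append(0.0)
        if S:
            confined = (minor_mask & (cp == total)) | ~minor_mask
            private = seg_pooled & confined.all(axis=0) & minor_mask.any(axis=0)
            vals.append(float(private.sum()))
        else:
            vals.append(0.0)

    within_mean = {}
    for p in populations:
        idx = pop_indices[p]
        if len(idx) > 1:
            m = len(idx)
            within_mean[p] = float(np.triu(D[np.ix_(idx, idx)], 1).sum() / (m * (m - 1) / 2))
    for a in range(len(populations)):
        for b in range(a + 1, len(populations)):
            pa, pb = populations[a], populations[b]
            ia, ib = pop_indices[pa], pop_indices[pb]
            hb = float(D[np.ix_(ia, ib)].mean())
            vals.append(hb)
            ws = [within_mean[p] for p in (pa, pb) if p in within_mean]
            hw = float(np.mean(ws)) if ws else 0.0
            vals.append(0.0 if hb <= 0 else 1.0 - hw / hb)
    return np.asarray(vals)


def compute_sumstats(aln: Alignment, pm: PopulationMap) -> SummaryStats:
    """Summary statistics of an observed or simulated alignment
    (missing-data policy: complete deletion)."""
    pm.validate_against(aln)
    pops = pm.populations
    mat, _ = _policy_matrix(aln)
    idx = pm.indices(aln)
    empty = [p for p in pops if len(idx[p]) == 0]
    if empty:
        raise ValueError(f"empty population(s): {empty}")
    return SummaryStats(stat_names(pops), stats_from_matrix(mat, idx, pops), pops)


def sumstats_from_mutated(ms: MutatedSites, pop_indices: dict[str, np.ndarray],
                          populations: list[str]) -> np.ndarray:
    """Fast path: statistics straight from the mutated-site matrix of a
    simulation, skipping full-alignment materialization.  Equals
    ``compute_sumstats`` on the materialized alignment."""
    return stats_from_matrix(ms.tip_states, pop_indices, populations)
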