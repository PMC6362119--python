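"""One-level analysis of molecular variance (AMOVA) with permutation tests.

Implements the Excoffier–Smouse–Quattro decomposition of squared pairwise
inter-haplotype distances into among-group and within-group variance
components, the Phi_ST fixation index, and a permutation test that shuffles
individuals among groups.  The default distance for haplotypic data is the
count of pairwise nucleotide differences (not per-site), as in Arlequin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alignment import Alignment, PopulationMap
from .popgen import DistanceMatrix, _policy_matrix, _pairwise_mismatch_counts


@dataclass
class AmovaResult:
    ss_among: float
    ss_within: float
    df_among: int
    df_within: int
    sigma2_among: float          # as estimated; may be negative
    sigma2_within: float
    phi_st: float
    pct_among: float             # uses sigma2_among clamped at 0
    p_value: float | None
    n_perm: int
    seed: int | None = None
    degenerate: bool = False     # total variance is zero

    def summary(self) -> str:
        lines = [
            "AMOVA (one level)",
            f"{'source':<16}{'df':>6}{'SS':>14}{'sigma2':>14}{'%var':>9}",
            f"{'among groups':<16}{self.df_among:>6}{self.ss_among:>14.4f}"
            f"{self.sigma2_among:>14.5f}{self.pct_among:>9.2f}",
            f"{'within groups':<16}{self.df_within:>6}{self.ss_within:>14.4f}"
            f"{self.sigma2_within:>14.5f}{100 - self.pct_among:>9.2f}",
            f"Phi_ST = {self.phi_st:.5f}"
            + ("" if self.p_value is None else f"   P = {self.p_value:.5f} ({self.n_perm} permutations)"),
        ]
        if self.degenerate:
            lines.append("note: zero total variance (all distances equal); Phi_ST reported as 0")
        return "\n".join(lines)

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "ss_among", "ss_within", "df_among", "df_within", "sigma2_among",
            "sigma2_within", "phi_st", "pct_among", "p_value", "n_perm",
            "seed", "degenerate")}


def nucleotide_difference_matrix(aln: Alignment) -> DistanceMatrix:
    """Counts of pairwise nucleotide differences on policy-retained sites."""
    mat, _ = _policy_matrix(aln)
    return DistanceMatrix(_pairwise_mismatch_counts(mat), aln.sequence_ids, "complete")


def _components(d2: np.ndarray, groups: list[np.ndarray]) -> tuple[float, float, float, float, int, int]:
    """Variance components from a squared-distance matrix and group index lists."""
    N = d2.shape[0]
    G = len(groups)
    iu = np.triu_indices(N, k=1)
    ss_total = float(d2[iu].sum() / N)
    ss_within = 0.0
    for idx in groups:
        ng = len(idx)
        if ng > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += float(np.triu(sub, k=1).sum() / ng)
    ss_among = ss_total - ss_within
    df_among = G - 1
    df_within = N - G
    ms_within = ss_within / df_within if df_within > 0 else 0.0
    ms_among = ss_among / df_among if df_among > 0 else 0.0
    sizes = np.array([len(idx) for idx in groups], dtype=float)
    n_eff = (N - np.sum(sizes**2) / N) / df_among      # average group size correction
    sigma_w = ms_within
    sigma_a = (ms_among - ms_within) / n_eff if n_eff > 0 else 0.0
    return ss_among, ss_within, sigma_a, sigma_w, df_among, df_within


def amova_one_level(dm: DistanceMatrix, pm: PopulationMap, n_perm: int = 10000,
                    seed: int | None = None) -> AmovaResult:
    """AMOVA over ``dm`` with groups from ``pm``; permutation P-value for
    Phi_ST by shuffling individuals among groups (group sizes preserved).

    ``n_perm=0`` returns the decomposition deterministically without a
    P-value.  The P-value uses the +1 correction:
    ``(1 + #{perm >= obs}) / (1 + n_perm)``.
    """
    if n_perm < 0:
        raise ValueError("n_perm must be >= 0")
    vals = np.asarray(dm.values, dtype=float)
    if np.any(vals[np.isfinite(vals)] < 0):
        raise ValueError("negative distances")
    pops = [pm.assignments.get(i) for i in dm.ids]
    if any(p is None for p in pops):
        raise ValueError("distance matrix ids not all mapped")
    labels = pm.populations
    groups = [np.flatnonzero([p == g for p in pops]) for g in labels]
    groups = [g for g in groups if len(g)]
    if len(groups) < 2:
        raise ValueError("AMOVA needs >= 2 groups")
    d2 = vals**2
    ssa, ssw, sa, sw, dfa, dfw = _components(d2, groups)
    tot = sa + sw
    degenerate = tot <= 0 and np.allclose(vals, 0)
    phi = 0.0 if tot == 0 else sa / tot
    if degenerate:
        phi = 0.0
    pct = 0.0 if tot <= 0 else 100.0 * max(sa, 0.0) / (max(sa, 0.0) + sw)
    p_value = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        N = d2.shape[0]
        sizes = [len(g) for g in groups]
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(N)
            out, pg = 0, []
            for s in sizes:
                pg.append(perm[out:out + s])
                out += s
            _, _, psa, psw, _, _ = _components(d2, pg)
            ptot = psa + psw
            pphi = 0.0 if ptot == 0 else psa / ptot
            if pphi >= phi - 1e-12:
                count += 1
        p_value = (1 + count) / (1 + n_perm)
    return AmovaResult(ssa, ssw, dfa, dfw, sa, sw, phi, pct, p_value, n_perm,
                       seed=seed, degenerate=degenerate)


def pairwise_phi_st(dm: DistanceMatrix, pm: PopulationMap, n_perm: int = 10000,
                    seed: int | None = None) -> dict[tuple[str, str], AmovaResult]:
    """Phi_ST (+ permutation P) for every population pair, each entry being
    a one-level AMOVA restricted to that pair."""
    labels = pm.populations
    if len(labels) < 2:
        raise ValueError("need >= 2 populations")
    rng = np.random.default_rng(seed)
    out: dict[tuple[str, str], AmovaResult] = {}
    id_pop = {i: pm.assignments[i] for i in dm.ids}
    for a in range(len(labels)):
        for b in range(a + 1, len(labels)):
            ga, gb = labels[a], labels[b]
            keep = [k for k, i in enumerate(dm.ids) if id_pop[i] in (ga, gb)]
            sub = DistanceMatrix(dm.values[np.ix_(keep, keep)],
                                 [dm.ids[k] for k in keep], dm.deletion)
            sub_pm = PopulationMap({i: id_pop[i] for i in sub.ids})
            sub_seed = int(rng.integers(2**31 - 1))
            out[(ga, gb)] = amova_one_level(sub, sub_pm, n_perm=n_perm, seed=sub_seed)
    return out
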