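"""Coalescent simulation of refugial-colonization demographic scenarios.

Three competing demographic hypotheses for four allopatric mountain
lineages (labelled KD-EA, CA, LarNP-CA and WA-Az) are expressed as
population trees with divergence events at generations t1 < t2 < t3 < Tt
before present:

* ``S1_fragmentation`` — all four lineages split simultaneously from a
  single ancestral refugium at Tt.
* ``S2_one_way`` — serial colonization along the northern slopes:
  WA-Az splits from CA at t1, CA from LarNP-CA at t2, LarNP-CA from
  KD-EA at t3.
* ``S3_two_way`` — colonization along both slopes: CA splits from
  LarNP-CA at t1, WA-Az splits from KD-EA at t2 (southern route),
  LarNP-CA from KD-EA at t3.

In every scenario the root population enters a distinct ancestral epoch at
Tt with its own size ``N_ANC``, so all scenarios share one rectangular
parameter vector (N_KD-EA, N_CA, N_LarNP-CA, N_WA-Az, N_ANC).

The simulator is a structured coalescent for a haploid, maternally
inherited locus: within a population of size Ne, k lineages coalesce at
rate C(k,2)/Ne per generation (so E[T2] = Ne and expected pairwise
diversity is 2*Ne*mu per site); at a divergence event the derived
population's lineages move into the source population, looking backward in
time.  Sequences evolve by Poisson mutations (rate mu per site per
generation) under Jukes-Cantor (HKY-free by design: the hypotheses are
about demography, not substitution process).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignment import Alignment, PopulationMap

POPULATIONS = ["KD-EA", "CA", "LarNP-CA", "WA-Az"]
ANCESTRAL = "ANC"

DEFAULT_TIMES = {"t1": 2.46e5, "t2": 4.30e5, "t3": 4.86e5, "Tt": 6.86e5}
DEFAULT_MU = 3.9e-8
DEFAULT_SAMPLE_SIZES = {"KD-EA": 10, "CA": 4, "LarNP-CA": 12, "WA-Az": 13}


@dataclass
class DivergenceEvent:
    """Backward in time at ``time``, lineages of ``derived`` move to ``source``."""

    time_key: str               # which prior time ('t1'..'Tt') this event uses
    derived: str
    source: str


@dataclass
class DemographicScenario:
    scenario_id: str
    populations: list[str]
    events: list[DivergenceEvent]

    def resolved_events(self, times: dict[str, float]) -> list[tuple[float, str, str]]:
        ev = [(times[e.time_key], e.derived, e.source) for e in self.events]
        if any(ev[i][0] > ev[i + 1][0] for i in range(len(ev) - 1)):
            raise ValueError("event times must be non-decreasing backward in time")
        return ev


def scenario_library() -> dict[str, DemographicScenario]:
    """The three competing colonization scenarios."""
    s1 = DemographicScenario(
        "S1_fragmentation", list(POPULATIONS),
        [DivergenceEvent("Tt", p, ANCESTRAL) for p in POPULATIONS],
    )
    s2 = DemographicScenario(
        "S2_one_way", list(POPULATIONS),
        [
            DivergenceEvent("t1", "WA-Az", "CA"),
            DivergenceEvent("t2", "CA", "LarNP-CA"),
            DivergenceEvent("t3", "LarNP-CA", "KD-EA"),
            DivergenceEvent("Tt", "KD-EA", ANCESTRAL),
        ],
    )
    s3 = DemographicScenario(
        "S3_two_way", list(POPULATIONS),
        [
            DivergenceEvent("t1", "CA", "LarNP-CA"),
            DivergenceEvent("t2", "WA-Az", "KD-EA"),
            DivergenceEvent("t3", "LarNP-CA", "KD-EA"),
            DivergenceEvent("Tt", "KD-EA", ANCESTRAL),
        ],
    )
    return {s.scenario_id: s for s in (s1, s2, s3)}


@dataclass
class PriorSpec:
    """Priors and fixed settings for the demographic parameters.

    Population sizes are uniform on (ne_low, ne_high).  Divergence times
    are fixed at ``times`` by default; with ``times_as_upper_bounds`` each
    is instead drawn uniformly on (0, stated value) and the four draws are
    sorted to preserve t1 < t2 < t3 < Tt.  ``size_change`` optionally adds,
    per sampled population, one instantaneous size change at a uniform
    random time on its branch with new size from the Ne prior.
    """

    ne_low: float = 10.0
    ne_high: float = 7e5
    times: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_TIMES))
    times_as_upper_bounds: bool = False
    size_change: bool = False

    def __post_init__(self) -> None:
        if not self.ne_low < self.ne_high:
            raise ValueError("require ne_low < ne_high")
        t = self.times
        if not (t["t1"] < t["t2"] < t["t3"] < t["Tt"]):
            raise ValueError("require t1 < t2 < t3 < Tt")

    @property
    def ne_names(self) -> list[str]:
        return [f"N_{p}" for p in POPULATIONS] + [f"N_{ANCESTRAL}"]

    @property
    def param_names(self) -> list[str]:
        return self.ne_names + list(DEFAULT_TIMES)


@dataclass
class SampleConfig:
    sample_sizes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_SAMPLE_SIZES))
    L: int = 1618
    mu: float = DEFAULT_MU
    model: str = "JC"
    generation_time: float = 3.0

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.sample_sizes.values()):
            raise ValueError("sample sizes must be >= 1")
        if self.L < 1:
            raise ValueError("L must be >= 1")
        if self.mu < 0:
            raise ValueError("mu must be >= 0")
        if self.model != "JC":
            raise ValueError("only the JC substitution model is implemented")

    @property
    def n_total(self) -> int:
        return sum(self.sample_sizes.values())


def draw_params(prior: PriorSpec, rng: np.random.Generator) -> dict[str, float]:
    """One draw from the prior: Ne per population (+ ancestral), times,
    and optional per-population size-change settings."""
    params: dict[str, float] = {}
    for name in prior.ne_names:
        params[name] = float(rng.uniform(prior.ne_low, prior.ne_high))
    if prior.times_as_upper_bounds:
        draws = np.sort([rng.uniform(0.0, prior.times[k]) for k in ("t1", "t2", "t3", "Tt")])
        for k, v in zip(("t1", "t2", "t3", "Tt"), draws):
            params[k] = float(v)
    else:
        params.update({k: float(v) for k, v in prior.times.items()})
    if prior.size_change:
        for p in POPULATIONS:
            params[f"sc_frac_{p}"] = float(rng.uniform())     # position on branch
            params[f"sc_N_{p}"] = float(rng.uniform(prior.ne_low, prior.ne_high))
    return params


@dataclass
class Genealogy:
    """Rooted binary tree over sampled lineages; times in generations."""

    parent: np.ndarray          # (2n-1,), -1 at the root
    time: np.ndarray            # (2n-1,), 0 at tips
    n_tips: int
    tip_populations: list[str]

    def __post_init__(self) -> None:
        self.parent = np.asarray(self.parent, dtype=np.int64)
        self.time = np.asarray(self.time, dtype=np.float64)

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent < 0)[0])

    def children(self) -> list[list[int]]:
        ch: list[list[int]] = [[] for _ in range(len(self.parent))]
        for i, p in enumerate(self.parent):
            if p >= 0:
                ch[p].append(i)
        return ch

    def branch_lengths(self) -> np.ndarray:
        bl = np.zeros(len(self.parent))
        has = self.parent >= 0
        bl[has] = self.time[self.parent[has]] - self.time[has]
        return bl

    @property
    def tmrca(self) -> float:
        return float(self.time[self.root])

    def total_branch_length(self) -> float:
        return float(self.branch_lengths().sum())


def _population_merge_time(scn: DemographicScenario, pop: str,
                           times: dict[str, float]) -> float:
    for ev in scn.events:
        if ev.derived == pop:
            return times[ev.time_key]
    return float("inf")


def simulate_genealogy(scn: DemographicScenario, params: dict[str, float],
                       cfg: SampleConfig, rng: np.random.Generator) -> Genealogy:
    """Structured coalescent under the scenario's divergence events.

    Coalescence rate for k co-resident lineages is C(k,2)/Ne per
    generation (haploid convention).
    """
    times = {k: params[k] for k in ("t1", "t2", "t3", "Tt")}
    events: list[tuple[float, str, str, float | None]] = [
        (t, d, s, None) for (t, d, s) in scn.resolved_events(times)
    ]
    ne = {p: params[f"N_{p}"] for p in POPULATIONS}
    ne[ANCESTRAL] = params[f"N_{ANCESTRAL}"]
    if any(v <= 0 for v in ne.values()):
        raise ValueError("non-positive Ne")
    for p in POPULATIONS:     # optional discrete size changes
        key = f"sc_frac_{p}"
        if key in params:
            t_sc = params[key] * min(_population_merge_time(scn, p, times), times["Tt"])
            events.append((t_sc, p, p, params[f"sc_N_{p}"]))
    events.sort(key=lambda e: e[0])

    n = cfg.n_total
    tip_pops: list[str] = []
    lineages: dict[str, list[int]] = {p: [] for p in POPULATIONS}
    lineages[ANCESTRAL] = []
    node = 0
    for p in POPULATIONS:
        for _ in range(cfg.sample_sizes.get(p, 0)):
            lineages[p].append(node)
            tip_pops.append(p)
            node += 1
    if node != n:
        raise ValueError("sample sizes refer to unknown populations")

    total_nodes = 2 * n - 1
    parent = np.full(total_nodes, -1, dtype=np.int64)
    ntime = np.zeros(total_nodes)
    t = 0.0
    ev_i = 0
    next_node = n
    active = n
    while active > 1:
        pops = [p for p, li in lineages.items() if len(li) >= 2]
        rates = [len(lineages[p]) * (len(lineages[p]) - 1) / 2.0 / ne[p] for p in pops]
        total_rate = sum(rates)
        t_cand = t + rng.standard_exponential() / total_rate if total_rate > 0 else float("inf")
        if ev_i < len(events) and events[ev_i][0] <= t_cand:
            t, derived, source, new_ne = events[ev_i]
            ev_i += 1
            if new_ne is not None:
                ne[derived] = new_ne
            else:
                lineages[source].extend(lineages[derived])
                lineages[derived] = []
            continue
        if total_rate <= 0:
            raise RuntimeError("coalescent stalled: unreachable population")
        t = t_cand
        if len(pops) > 1:
            u = rng.random() * total_rate
            acc = 0.0
            for pop, r in zip(pops, rates):
                acc += r
                if u <= acc:
                    break
        else:
            pop = pops[0]
        li = lineages[pop]
        m = len(li)
        i = int(rng.integers(m))
        j = int(rng.integers(m - 1))
        if j >= i:
            j += 1
        a, b = li[i], li[j]
        for x in sorted((i, j), reverse=True):
            li.pop(x)
        parent[a] = parent[b] = next_node
        ntime[next_node] = t
        li.append(next_node)
        next_node += 1
        active -= 1
    return Genealogy(parent, ntime, n, tip_pops)


@dataclass
class MutatedSites:
    """Tip states at mutated sites only — the compact product of sequence
    evolution, sufficient for summary statistics."""

    sites: np.ndarray        # (S_hit,) unique site indices, sorted
    tip_states: np.ndarray   # (n_tips, S_hit) int8 in 0..3
    ancestral: np.ndarray    # (L,) int8 full ancestral sequence


def mutate_tree(tree: Genealogy, cfg: SampleConfig,
                rng: np.random.Generator) -> MutatedSites:
    """Drop Poisson(mu * L * branch length) mutations on each branch and
    propagate Jukes-Cantor state changes to the tips.

    Only the mutated site columns are materialized; ``evolve_sequences``
    scatters them into the full-length ancestral background.
    """
    L, mu = cfg.L, cfg.mu
    anc = rng.integers(0, 4, size=L, dtype=np.int8)
    nn = len(tree.parent)
    bl = tree.branch_lengths()
    n_mut = rng.poisson(mu * L * bl)
    total_mut = int(n_mut.sum())
    all_sites = rng.integers(0, L, size=total_mut)
    bounds = np.concatenate([[0], np.cumsum(n_mut)])
    mut_sites = [all_sites[bounds[i]:bounds[i + 1]] if n_mut[i] else None
                 for i in range(nn)]
    hit = (np.unique(all_sites) if total_mut else np.empty(0, dtype=np.int64))
    col = {s: i for i, s in enumerate(hit)}
    S = len(hit)
    states = np.empty((nn, S), dtype=np.int8)
    root = tree.root
    states[root] = anc[hit]
    children = tree.children()
    stack = [root]
    order = []
    while stack:
        u = stack.pop()
        order.append(u)
        stack.extend(children[u])
    for u in order:
        if u == root:
            continue
        st = states[tree.parent[u]].copy()
        if mut_sites[u] is not None:
            jumps = rng.integers(1, 4, size=len(mut_sites[u]), dtype=np.int8)
            for s_idx, jmp in zip(mut_sites[u], jumps):
                c = col[s_idx]
                st[c] = (st[c] + jmp) % 4
        states[u] = st
    return MutatedSites(hit, states[:tree.n_tips], anc)


def evolve_sequences(tree: Genealogy, cfg: SampleConfig,
                     rng: np.random.Generator,
                     ids: list[str] | None = None) -> Alignment:
    """Full simulated alignment (one row per sampled lineage)."""
    ms = mutate_tree(tree, cfg, rng)
    if ids is None:
        ids = [f"{p}_{i}" for i, p in enumerate(tree.tip_populations)]
    mat = np.tile(ms.ancestral, (tree.n_tips, 1))
    if ms.sites.size:
        mat[:, ms.sites] = ms.tip_states
    return Alignment.from_matrix(ids, mat)


def simulate_dataset(scn: DemographicScenario, params: dict[str, float],
                     cfg: SampleConfig, rng: np.random.Generator,
                     ) -> tuple[Alignment, PopulationMap]:
    """Genealogy + sequences + population map, in one call."""
    tree = simulate_genealogy(scn, params, cfg, rng)
    ids = [f"{p}_{i}" for i, p in enumerate(tree.tip_populations)]
    aln = evolve_sequences(tree, cfg, rng, ids=ids)
    pm = PopulationMap({i: p for i, p in zip(ids, tree.tip_populations)})
    return aln, pm
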