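"""DIYABC-style approximate Bayesian computation.

Reference-table construction by prior-predictive coalescent simulation,
model choice by direct rejection (share of each scenario among the k
nearest standardized summary-statistic vectors) and by kernel-weighted
multinomial logistic regression, Beaumont-style local-linear-regression
parameter posteriors, and pseudo-observed-dataset (PODs) validation of the
model-choice procedure with type-I / type-II error estimation.

Statistics are standardized by per-statistic median and MAD computed from
the reference table itself (statistics with zero MAD carry no rejection
information and are dropped from the distance, with a warning).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coalescent import (DemographicScenario, PriorSpec, SampleConfig,
                         draw_params, mutate_tree, simulate_genealogy)
from .sumstats import SummaryStats, stat_names


def _simulate_stats(scn: DemographicScenario, prior: PriorSpec, cfg: SampleConfig,
                    rng: np.random.Generator,
                    pop_indices: dict[str, np.ndarray], pops: list[str],
                    ) -> tuple[dict[str, float], np.ndarray]:
    from .sumstats import sumstats_from_mutated

    params = draw_params(prior, rng)
    tree = simulate_genealogy(scn, params, cfg, rng)
    ms = mutate_tree(tree, cfg, rng)
    return params, sumstats_from_mutated(ms, pop_indices, pops)


def _pop_indices(cfg: SampleConfig, pops: list[str]) -> dict[str, np.ndarray]:
    idx, start = {}, 0
    for p in pops:
        n = cfg.sample_sizes[p]
        idx[p] = np.arange(start, start + n)
        start += n
    return idx


@dataclass
class ReferenceTable:
    """Rows of (scenario, parameter vector, summary statistics) plus the
    robust standardization constants computed from the table."""

    table: pd.DataFrame
    stat_names: list[str]
    param_names: list[str]
    center: np.ndarray = field(init=False)
    scale: np.ndarray = field(init=False)
    active: np.ndarray = field(init=False)       # stats with nonzero MAD
    seed: int | None = None

    def __post_init__(self) -> None:
        S = self.table[self.stat_names].to_numpy(dtype=float)
        self.center = np.median(S, axis=0)
        self.scale = np.median(np.abs(S - self.center), axis=0)
        self.active = self.scale > 0
        if not self.active.all():
            dropped = [n for n, a in zip(self.stat_names, self.active) if not a]
            warnings.warn(f"stats with zero MAD dropped from distances: {dropped}")
        self._Z = ((S - self.center) / np.where(self.active, self.scale, 1.0))[:, self.active]

    @property
    def n_rows(self) -> int:
        return len(self.table)

    @property
    def scenarios(self) -> list[str]:
        return list(dict.fromkeys(self.table["scenario"]))

    def standardize(self, stats: np.ndarray) -> np.ndarray:
        z = (np.asarray(stats, float) - self.center) / np.where(self.active, self.scale, 1.0)
        return z[self.active]

    def distances(self, stats: np.ndarray) -> np.ndarray:
        """Euclidean distances of every row to an observed stats vector."""
        z = self.standardize(stats)
        return np.sqrt(((self._Z - z) ** 2).sum(axis=1))


def build_reference_table(scenarios: dict[str, DemographicScenario], prior: PriorSpec,
                          cfg: SampleConfig, n_per_scenario: int,
                          seed: int | None = None) -> ReferenceTable:
    """Simulate ``n_per_scenario`` prior-predictive datasets per scenario
    and record (scenario, parameters, statistics).  Fully reproducible
    from the seed."""
    if n_per_scenario < 1:
        raise ValueError("n_per_scenario must be >= 1")
    rng = np.random.default_rng(seed)
    pops = [p for p in cfg.sample_sizes]
    idx = _pop_indices(cfg, pops)
    snames = stat_names(pops)
    rows = []
    for sid, scn in scenarios.items():
        for r in range(n_per_scenario):
            try:
                params, stats = _simulate_stats(scn, prior, cfg, rng, idx, pops)
            except Exception as exc:     # pragma: no cover - defensive
                raise RuntimeError(f"simulation failed at scenario {sid} row {r}") from exc
            rows.append({"scenario": sid, **params,
                         **dict(zip(snames, stats))})
    df = pd.DataFrame(rows)
    pnames = [c for c in df.columns if c not in snames and c != "scenario"]
    return ReferenceTable(df, snames, pnames, seed=seed)


@dataclass
class ModelPosterior:
    probabilities: dict[str, float]
    method: str
    acceptance: int            # rows used (k, or the 1%-window size)

    @property
    def best(self) -> str:
        return max(self.probabilities, key=self.probabilities.get)

    def as_dict(self) -> dict:
        return {"probabilities": self.probabilities, "method": self.method,
                "acceptance": self.acceptance, "best": self.best}


def model_choice_direct(rt: ReferenceTable, obs: np.ndarray | SummaryStats,
                        k: int = 500) -> ModelPosterior:
    """Direct rejection: scenario shares among the k nearest rows."""
    if k <= 0:
        raise ValueError("k must be positive")
    if k > rt.n_rows:
        raise ValueError(f"k={k} exceeds table size {rt.n_rows}")
    x = obs.values if isinstance(obs, SummaryStats) else obs
    d = rt.distances(x)
    order = np.argsort(d, kind="stable")
    if k < len(d) and d[order[k - 1]] == d[order[k]]:
        warnings.warn("tie at the k-th distance; broken by row order")
    sel = rt.table["scenario"].to_numpy()[order[:k]]
    probs = {s: float((sel == s).sum()) / k for s in rt.scenarios}
    return ModelPosterior(probs, "direct", k)


def model_choice_logistic(rt: ReferenceTable, obs: np.ndarray | SummaryStats,
                          frac: float = 0.01, weighted: bool = True) -> ModelPosterior:
    """Multinomial logistic regression of the scenario indicator on the
    (standardized) statistics over the closest ``frac`` of rows, with
    Epanechnikov distance weights; posterior = fitted probabilities at the
    observed point.  Falls back to direct rejection when the accepted set
    contains a single scenario."""
    from sklearn.linear_model import LogisticRegression

    x = obs.values if isinstance(obs, SummaryStats) else obs
    n_acc = max(int(np.ceil(frac * rt.n_rows)), 2)
    d = rt.distances(x)
    order = np.argsort(d, kind="stable")[:n_acc]
    labels = rt.table["scenario"].to_numpy()[order]
    present = list(dict.fromkeys(labels))
    if len(present) < 2:
        warnings.warn("accepted set contains one scenario; falling back to direct")
        mp = model_choice_direct(rt, x, k=n_acc)
        return ModelPosterior(mp.probabilities, "logistic(direct-fallback)", n_acc)
    Z = rt._Z[order] - rt.standardize(x)
    dmax = d[order].max()
    w = 1.0 - (d[order] / dmax) ** 2 if (weighted and dmax > 0) else np.ones(n_acc)
    w = np.clip(w, 1e-8, None)
    clf = LogisticRegression(max_iter=2000, C=100.0)
    clf.fit(Z, labels, sample_weight=w)
    p = clf.predict_proba(np.zeros((1, Z.shape[1])))[0]
    probs = {s: 0.0 for s in rt.scenarios}
    probs.update({c: float(v) for c, v in zip(clf.classes_, p)})
    return ModelPosterior(probs, "logistic", n_acc)


@dataclass
class ParameterPosterior:
    """Local-linear-regression adjusted posterior sample per parameter."""

    samples: pd.DataFrame
    weights: np.ndarray
    scenario: str

    def median(self) -> pd.Series:
        return self.samples.apply(lambda c: _weighted_quantile(c.to_numpy(), self.weights, 0.5))

    def interval(self, level: float = 0.95) -> pd.DataFrame:
        lo, hi = (1 - level) / 2, 1 - (1 - level) / 2
        return pd.DataFrame({
            "lower": self.samples.apply(lambda c: _weighted_quantile(c.to_numpy(), self.weights, lo)),
            "upper": self.samples.apply(lambda c: _weighted_quantile(c.to_numpy(), self.weights, hi)),
        })


def _weighted_quantile(x: np.ndarray, w: np.ndarray, q: float) -> float:
    order = np.argsort(x)
    cw = np.cumsum(w[order])
    return float(np.interp(q * cw[-1], cw - 0.5 * w[order], x[order]))


def _logit(u: np.ndarray) -> np.ndarray:
    return np.log(u / (1.0 - u))


def _expit(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def estimate_parameters(rt: ReferenceTable, scenario: str,
                        obs: np.ndarray | SummaryStats, prior: PriorSpec,
                        frac: float = 0.01) -> ParameterPosterior:
    """Beaumont-style adjustment ``theta* = theta - b (s - s_obs)`` with
    distance-kernel-weighted linear regression on standardized statistics,
    over the closest ``frac`` of the focal scenario's rows.

    Bounded (uniform-prior) parameters are regressed on a logit transform
    of their prior range and back-transformed, so adjusted draws stay
    inside the prior support.  Fixed parameters (zero variance in the
    table) are passed through unadjusted.
    """
    x = obs.values if isinstance(obs, SummaryStats) else obs
    sub = rt.table[rt.table["scenario"] == scenario]
    if sub.empty:
        raise ValueError(f"scenario {scenario!r} not in reference table")
    d = rt.distances(x)[sub.index.to_numpy()]
    n_acc = max(int(np.ceil(frac * len(sub))), 1)
    if n_acc < 50:
        raise ValueError(f"only {n_acc} accepted rows; need >= 50")
    keep = np.argsort(d, kind="stable")[:n_acc]
    acc = sub.iloc[keep]
    dacc = d[keep]
    dmax = dacc.max()
    w = np.clip(1.0 - (dacc / dmax) ** 2, 1e-8, None) if dmax > 0 else np.ones(n_acc)
    Z = rt._Z[acc.index.to_numpy()] - rt.standardize(x)

    adj: dict[str, np.ndarray] = {}
    lo, hi = prior.ne_low, prior.ne_high
    sw = np.sqrt(w)
    A = np.hstack([np.ones((n_acc, 1)), Z])
    for name in rt.param_names:
        theta = acc[name].to_numpy(dtype=float)
        if np.ptp(theta) == 0:
            adj[name] = theta
            continue
        if name.startswith("N_") or name.startswith("sc_N_"):
            u = np.clip((theta - lo) / (hi - lo), 1e-10, 1 - 1e-10)
            z = _logit(u)
            coef, *_ = np.linalg.lstsq(A * sw[:, None], z * sw, rcond=None)
            zstar = z - Z @ coef[1:]
            adj[name] = lo + (hi - lo) * _expit(zstar)
        else:
            coef, *_ = np.linalg.lstsq(A * sw[:, None], theta * sw, rcond=None)
            adj[name] = theta - Z @ coef[1:]
    return ParameterPosterior(pd.DataFrame(adj), w, scenario)


@dataclass
class ConfusionReport:
    """PODs validation: counts of (true scenario x selected scenario) and
    the focal scenario's type-I / type-II error rates."""

    counts: pd.DataFrame
    focal: str
    type_I: float
    type_II: float
    n_pods: int
    method: str
    seed: int | None

    def summary(self) -> str:
        lines = [f"PODs validation ({self.method}; {self.n_pods} per scenario; "
                 f"seed={self.seed})", self.counts.to_string(),
                 f"focal scenario: {self.focal}",
                 f"type I error  (focal true, not selected): {100 * self.type_I:.1f}%",
                 f"type II error (focal false, selected):    {100 * self.type_II:.1f}%"]
        return "\n".join(lines)

    def as_dict(self) -> dict:
        return {"counts": {t: dict(r) for t, r in self.counts.iterrows()},
                "focal": self.focal, "type_I": self.type_I, "type_II": self.type_II,
                "n_pods": self.n_pods, "method": self.method, "seed": self.seed}


def classify_many(rt: ReferenceTable, stats: np.ndarray, method: str = "direct",
                  k: int = 500, frac: float = 0.01) -> list[str]:
    """Selected scenario for each row of a (m, n_stats) matrix."""
    out = []
    for row in np.atleast_2d(stats):
        if method == "direct":
            mp = model_choice_direct(rt, row, k=k)
        elif method == "logistic":
            mp = model_choice_logistic(rt, row, frac=frac)
        else:
            raise ValueError(f"unknown method {method!r}")
        out.append(mp.best)
    return out


def pods_validation(scenarios: dict[str, DemographicScenario], prior: PriorSpec,
                    cfg: SampleConfig, rt: ReferenceTable, focal: str,
                    n_pods: int = 1000, method: str = "direct", k: int = 500,
                    frac: float = 0.01, seed: int | None = None,
                    pod_stats: dict[str, np.ndarray] | None = None) -> ConfusionReport:
    """Simulate ``n_pods`` prior-predictive datasets under each scenario,
    classify each with the chosen model-choice method, and report the
    confusion matrix with the focal scenario's error rates.

    ``pod_stats`` (scenario -> (n_pods, n_stats) array) allows reuse of
    pre-simulated PODs, e.g. from a generated synthetic suite.
    """
    if focal not in scenarios:
        raise ValueError(f"unknown focal scenario {focal!r}")
    if n_pods < 1:
        raise ValueError("n_pods must be >= 1")
    rng = np.random.default_rng(seed)
    pops = [p for p in cfg.sample_sizes]
    idx = _pop_indices(cfg, pops)
    sids = list(scenarios)
    counts = pd.DataFrame(0, index=sids, columns=sids, dtype=int)
    for sid, scn in scenarios.items():
        if pod_stats is not None and sid in pod_stats:
            stats = np.asarray(pod_stats[sid])[:n_pods]
        else:
            stats = np.stack([
                _simulate_stats(scn, prior, cfg, rng, idx, pops)[1]
                for _ in range(n_pods)
            ])
        for chosen in classify_many(rt, stats, method=method, k=k, frac=frac):
            counts.loc[sid, chosen] += 1
    row_tot = counts.sum(axis=1)
    type_I = 1.0 - counts.loc[focal, focal] / row_tot[focal]
    others = [s for s in sids if s != focal]
    type_II = float(np.mean([counts.loc[s, focal] / row_tot[s] for s in others]))
    return ConfusionReport(counts, focal, float(type_I), type_II,
                           n_pods, method, seed)
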