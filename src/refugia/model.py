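"""Model/Results interface for scenario choice by ABC.

`ColonizationABC` is built from observed data (an alignment plus a
population map, or a precomputed summary-statistic vector) together with
the competing demographic scenarios and priors; ``fit()`` simulates (or
reuses) a reference table and returns :class:`ABCResults` carrying the
model posteriors, the parameter posterior under the best-supported
scenario, and a ``summary()`` table.  ``ABCResults.validate_pods()`` runs
the pseudo-observed-dataset error analysis for a focal scenario.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignment import Alignment, PopulationMap
from .coalescent import DemographicScenario, PriorSpec, SampleConfig, scenario_library
from .inference import (ConfusionReport, ModelPosterior, ParameterPosterior,
                        ReferenceTable, build_reference_table,
                        estimate_parameters, model_choice_direct,
                        model_choice_logistic, pods_validation)
from .sumstats import SummaryStats, compute_sumstats


class ColonizationABC:
    """ABC model choice among refugial-colonization scenarios.

    Parameters
    ----------
    observed : SummaryStats
        Summary statistics of the observed dataset.
    scenarios : dict, optional
        Competing `DemographicScenario` objects (default: the built-in
        single-refugium / one-way / two-way library).
    prior, sample_config : optional
        Priors and sampling design; default to the study preset matching
        the observed population layout.
    """

    def __init__(self, observed: SummaryStats,
                 scenarios: dict[str, DemographicScenario] | None = None,
                 prior: PriorSpec | None = None,
                 sample_config: SampleConfig | None = None):
        from .synthetic import study_preset

        self.observed = observed
        self.scenarios = scenarios if scenarios is not None else scenario_library()
        d_cfg, d_prior = study_preset()
        self.prior = prior if prior is not None else d_prior
        self.sample_config = sample_config if sample_config is not None else d_cfg
        missing = [p for p in self.sample_config.sample_sizes if p not in observed.populations]
        if missing:
            raise ValueError(f"observed stats lack populations {missing}")

    @classmethod
    def from_alignment(cls, aln: Alignment, pm: PopulationMap, **kwargs) -> "ColonizationABC":
        obs = compute_sumstats(aln, pm)
        if "sample_config" not in kwargs:
            from .synthetic import study_preset

            cfg, _ = study_preset()
            cfg.sample_sizes = pm.sizes()
            cfg.L = aln.length
            kwargs["sample_config"] = cfg
        return cls(obs, **kwargs)

    @classmethod
    def from_files(cls, fasta_path, popmap_path, **kwargs) -> "ColonizationABC":
        from .io import read_fasta, read_popmap

        aln = read_fasta(fasta_path)
        pm = read_popmap(popmap_path)
        return cls.from_alignment(aln, pm, **kwargs)

    def fit(self, n_per_scenario: int = 20000, k: int = 500, frac: float = 0.01,
            seed: int | None = None,
            reference_table: ReferenceTable | None = None) -> "ABCResults":
        """Build (or reuse) the reference table, run both model-choice
        methods, and estimate parameters under the best direct-rejection
        scenario."""
        rt = reference_table if reference_table is not None else build_reference_table(
            self.scenarios, self.prior, self.sample_config, n_per_scenario, seed=seed)
        direct = model_choice_direct(rt, self.observed, k=k)
        logistic = model_choice_logistic(rt, self.observed, frac=frac)
        params = estimate_parameters(rt, direct.best, self.observed, self.prior, frac=frac)
        return ABCResults(self, rt, direct, logistic, params,
                          k=k, frac=frac, seed=seed)


@dataclass
class ABCResults:
    """Fitted ABC scenario choice: posteriors, parameter estimates,
    diagnostics."""

    model: ColonizationABC
    reference_table: ReferenceTable
    direct: ModelPosterior
    logistic: ModelPosterior
    parameters: ParameterPosterior
    k: int
    frac: float
    seed: int | None
    _pods: dict[str, ConfusionReport] = field(default_factory=dict)

    @property
    def best_scenario(self) -> str:
        return self.direct.best

    def validate_pods(self, focal: str | None = None, n_pods: int = 1000,
                      method: str = "direct", seed: int | None = None) -> ConfusionReport:
        """Type-I / type-II error of the model choice for a focal scenario
        (default: the best-supported one) from pseudo-observed datasets."""
        focal = focal or self.best_scenario
        rep = pods_validation(self.model.scenarios, self.model.prior,
                              self.model.sample_config, self.reference_table,
                              focal, n_pods=n_pods, method=method, k=self.k,
                              frac=self.frac, seed=seed)
        self._pods[focal] = rep
        return rep

    def replicate_posteriors(self, n_rep: int = 10, frac: float = 0.02,
                             seed: int | None = None) -> pd.DataFrame:
        """Stability report: direct-rejection posteriors over ``n_rep``
        bootstrap subsets of the closest ``frac`` window."""
        rng = np.random.default_rng(seed)
        d = self.reference_table.distances(self.model.observed.values)
        n_win = max(int(np.ceil(frac * self.reference_table.n_rows)), 2)
        window = np.argsort(d, kind="stable")[:n_win]
        labels = self.reference_table.table["scenario"].to_numpy()[window]
        rows = []
        for _ in range(n_rep):
            take = rng.choice(n_win, size=n_win, replace=True)
            sub = labels[take]
            rows.append({s: float((sub == s).mean())
                         for s in self.reference_table.scenarios})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        med = self.parameters.median()
        ci = self.parameters.interval(0.95)
        lines = [
            "ABC scenario choice",
            "=" * 55,
            f"reference table: {self.reference_table.n_rows} rows "
            f"({len(self.model.scenarios)} scenarios); seed={self.seed}",
            "",
            f"{'scenario':<22}{'P(direct)':>12}{'P(logistic)':>14}",
        ]
        for s in self.reference_table.scenarios:
            lines.append(f"{s:<22}{self.direct.probabilities[s]:>12.3f}"
                         f"{self.logistic.probabilities.get(s, 0.0):>14.3f}")
        lines += ["", f"best scenario (direct, k={self.k}): {self.best_scenario}",
                  "", "parameter posterior (best scenario; local-linear, "
                  f"{100 * self.frac:.0f}% closest):",
                  f"{'parameter':<14}{'median':>14}{'2.5%':>14}{'97.5%':>14}"]
        for name in med.index:
            if np.ptp(self.parameters.samples[name].to_numpy()) == 0:
                lines.append(f"{name:<14}{med[name]:>14.4g}{'(fixed)':>14}{'':>14}")
            else:
                lines.append(f"{name:<14}{med[name]:>14.4g}"
                             f"{ci.loc[name, 'lower']:>14.4g}{ci.loc[name, 'upper']:>14.4g}")
        for focal, rep in self._pods.items():
            lines += ["", rep.summary()]
        return "\n".join(lines)
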