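import warnings

import numpy as np
import pandas as pd
import pytest

from refugia import (PriorSpec, SampleConfig, build_reference_table,
                     estimate_parameters, model_choice_direct,
                     model_choice_logistic, pods_validation, scenario_library)
from refugia.coalescent import DemographicScenario, DivergenceEvent, POPULATIONS
from refugia.inference import ReferenceTable, _pop_indices, _simulate_stats


def small_setup(L=2000, ne_high=2000.0):
    """Deliberately well-separated scenarios: small Ne relative to the
    divergence times makes topology differences dominate the statistics."""
    cfg = SampleConfig(sample_sizes={"KD-EA": 5, "CA": 4, "LarNP-CA": 5, "WA-Az": 5},
                       L=L, mu=3.9e-8)
    prior = PriorSpec(ne_low=100.0, ne_high=ne_high)
    return cfg, prior


@pytest.fixture(scope="module")
def small_rt():
    cfg, prior = small_setup()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        rt = build_reference_table(scenario_library(), prior, cfg, 700, seed=101)
    return rt, cfg, prior


class TestReferenceTable:
    def test_shape_balance_and_determinism(self):
        cfg, prior = small_setup()
        scn = {k: v for k, v in scenario_library().items() if k != "S1_fragmentation"}
        rt1 = build_reference_table(scn, prior, cfg, 50, seed=3)
        rt2 = build_reference_table(scn, prior, cfg, 50, seed=3)
        assert rt1.n_rows == 100
        assert (rt1.table["scenario"].value_counts() == 50).all()
        pd.testing.assert_frame_equal(rt1.table, rt2.table)

    def test_scenario_separability(self, small_rt):
        rt, _, _ = small_rt
        # deep vs shallow splits shift the between-population statistics
        means = rt.table.groupby("scenario")["dxy_CA|WA-Az"].mean()
        assert means["S2_one_way"] < means["S1_fragmentation"]

    def test_invalid_size(self):
        cfg, prior = small_setup()
        with pytest.raises(ValueError):
            build_reference_table(scenario_library(), prior, cfg, 0, seed=1)


class TestDirect:
    def test_exact_row_with_k1(self, small_rt):
        rt, _, _ = small_rt
        row = rt.table.iloc[5]
        obs = row[rt.stat_names].to_numpy(dtype=float)
        mp = model_choice_direct(rt, obs, k=1)
        assert mp.probabilities[row["scenario"]] == 1.0

    def test_uninformative_stats_return_prior_proportions(self):
        snames = ["s1", "s2"]
        df = pd.DataFrame({"scenario": ["A"] * 10 + ["B"] * 30,
                           "N_x": np.arange(40.0),
                           "s1": np.r_[np.ones(40)], "s2": np.r_[np.zeros(40)]})
        df["s1"] += np.r_[np.zeros(39), 1.0]   # one off row so MAD isn't all-zero
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            rt = ReferenceTable(df, snames, ["N_x"])
            mp = model_choice_direct(rt, np.array([1.0, 0.0]), k=40)
        assert mp.probabilities["A"] == pytest.approx(0.25)
        assert mp.probabilities["B"] == pytest.approx(0.75)

    def test_posterior_sums_to_one_and_k_validation(self, small_rt):
        rt, cfg, prior = small_rt
        obs = rt.table[rt.stat_names].iloc[0].to_numpy(dtype=float)
        mp = model_choice_direct(rt, obs, k=100)
        assert sum(mp.probabilities.values()) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            model_choice_direct(rt, obs, k=rt.n_rows + 1)
        with pytest.raises(ValueError):
            model_choice_direct(rt, obs, k=0)

    def test_invariant_to_uniform_rescaling_of_standardized_stats(self, small_rt):
        rt, _, _ = small_rt
        obs = rt.table[rt.stat_names].iloc[7].to_numpy(dtype=float)
        mp1 = model_choice_direct(rt, obs, k=50)
        import copy

        rt2 = copy.copy(rt)
        rt2._Z = rt._Z * 11.0
        rt2 = copy.copy(rt2)
        # distances scale monotonically -> same neighbour set
        z = rt.standardize(obs)
        d1 = np.argsort(np.linalg.norm(rt._Z - z, axis=1))[:50]
        d2 = np.argsort(np.linalg.norm(rt2._Z - z * 11.0, axis=1))[:50]
        assert set(d1) == set(d2)
        sel = rt.table["scenario"].to_numpy()[d2]
        probs = {s: (sel == s).mean() for s in rt.scenarios}
        assert probs == pytest.approx(mp1.probabilities)

    def test_self_assignment_on_separated_scenarios(self, small_rt):
        rt, cfg, prior = small_rt
        scn = scenario_library()
        pops = list(cfg.sample_sizes)
        idx = _pop_indices(cfg, pops)
        rng = np.random.default_rng(55)
        hits = 0
        for _ in range(60):
            _, stats = _simulate_stats(scn["S3_two_way"], prior, cfg, rng, idx, pops)
            hits += model_choice_direct(rt, stats, k=50).best == "S3_two_way"
        assert hits / 60 >= 0.9


class TestLogistic:
    def test_probabilities_sum_to_one(self, small_rt):
        rt, _, _ = small_rt
        obs = rt.table[rt.stat_names].iloc[3].to_numpy(dtype=float)
        mp = model_choice_logistic(rt, obs, frac=0.05)
        assert sum(mp.probabilities.values()) == pytest.approx(1.0, abs=1e-8)

    def test_agrees_with_direct_on_separated_case(self, small_rt):
        rt, cfg, prior = small_rt
        scn = scenario_library()
        pops = list(cfg.sample_sizes)
        idx = _pop_indices(cfg, pops)
        rng = np.random.default_rng(77)
        agree = 0
        for _ in range(20):
            _, stats = _simulate_stats(scn["S1_fragmentation"], prior, cfg, rng, idx, pops)
            d = model_choice_direct(rt, stats, k=50).best
            lg = model_choice_logistic(rt, stats, frac=0.05).best
            agree += d == lg
        assert agree >= 16

    def test_single_scenario_accepted_falls_back(self):
        df = pd.DataFrame({
            "scenario": ["A"] * 30 + ["B"] * 30,
            "N_x": np.arange(60.0),
            "s1": np.r_[np.random.default_rng(0).normal(0, 1, 30),
                        np.random.default_rng(1).normal(50, 1, 30)],
            "s2": np.r_[np.random.default_rng(2).normal(size=60)],
        })
        rt = ReferenceTable(df, ["s1", "s2"], ["N_x"])
        with pytest.warns(UserWarning, match="falling back"):
            mp = model_choice_logistic(rt, np.array([0.0, 0.0]), frac=0.2)
        assert mp.probabilities["A"] == 1.0

    def test_separable_probabilities_near_certainty(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame({
            "scenario": ["A"] * 200 + ["B"] * 200,
            "N_x": np.arange(400.0),
            "s1": np.r_[rng.normal(0, 1, 200), rng.normal(30, 1, 200)],
            "s2": rng.normal(size=400),
        })
        rt = ReferenceTable(df, ["s1", "s2"], ["N_x"])
        mp = model_choice_logistic(rt, np.array([0.0, 0.0]), frac=1.0)
        assert mp.probabilities["A"] > 0.95


class TestParameterEstimation:
    def test_adjusted_draws_within_prior_support(self, small_rt):
        rt, cfg, prior = small_rt
        obs = rt.table[rt.stat_names].iloc[11].to_numpy(dtype=float)
        post = estimate_parameters(rt, "S3_two_way", obs, prior, frac=0.1)
        for p in [f"N_{x}" for x in POPULATIONS] + ["N_ANC"]:
            s = post.samples[p]
            assert (s >= prior.ne_low).all() and (s <= prior.ne_high).all()

    def test_fixed_times_pass_through(self, small_rt):
        rt, cfg, prior = small_rt
        obs = rt.table[rt.stat_names].iloc[2].to_numpy(dtype=float)
        post = estimate_parameters(rt, "S2_one_way", obs, prior, frac=0.1)
        assert np.ptp(post.samples["Tt"].to_numpy()) == 0

    def test_zero_regression_when_obs_at_centroid(self):
        # symmetric accepted cloud centred on the observation: adjustment ~ 0
        rng = np.random.default_rng(5)
        n = 400
        s1 = np.r_[rng.normal(0, 1, n), -rng.normal(0, 1, n)]   # exactly symmetric
        df = pd.DataFrame({"scenario": "A", "N_x": 350000 + 1000 * s1,
                           "s1": s1, "s2": np.tile(rng.normal(size=n), 2)})
        rt = ReferenceTable(df, ["s1", "s2"], ["N_x"])
        prior = PriorSpec()
        post = estimate_parameters(rt, "A", np.array([0.0, 0.0]), prior, frac=1.0)
        raw_med = np.median(df["N_x"])
        assert float(post.median()["N_x"]) == pytest.approx(raw_med, rel=0.02)

    def test_too_few_accepted_rows(self, small_rt):
        rt, cfg, prior = small_rt
        obs = rt.table[rt.stat_names].iloc[0].to_numpy(dtype=float)
        with pytest.raises(ValueError, match="need >= 50"):
            estimate_parameters(rt, "S1_fragmentation", obs, prior, frac=0.001)


class TestPods:
    def test_indistinguishable_scenarios_give_chance_type_I(self):
        cfg, prior = small_setup(L=200)
        s1 = scenario_library()["S1_fragmentation"]
        clones = {f"C{i}": DemographicScenario(f"C{i}", s1.populations, s1.events)
                  for i in range(3)}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            rt = build_reference_table(clones, prior, cfg, 150, seed=9)
            rep = pods_validation(clones, prior, cfg, rt, "C0", n_pods=60,
                                  method="direct", k=45, seed=10)
        assert rep.type_I == pytest.approx(2 / 3, abs=0.15)

    def test_separated_scenarios_give_low_errors(self, small_rt):
        rt, cfg, prior = small_rt
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            rep = pods_validation(scenario_library(), prior, cfg, rt, "S3_two_way",
                                  n_pods=40, method="direct", k=50, seed=21)
        assert rep.type_I <= 0.2 and rep.type_II <= 0.2

    def test_reproducible_and_counts_sum(self, small_rt):
        rt, cfg, prior = small_rt
        kw = dict(n_pods=10, method="direct", k=30, seed=33)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            a = pods_validation(scenario_library(), prior, cfg, rt, "S2_one_way", **kw)
            b = pods_validation(scenario_library(), prior, cfg, rt, "S2_one_way", **kw)
        pd.testing.assert_frame_equal(a.counts, b.counts)
        assert (a.counts.sum(axis=1) == 10).all()
        assert 0 <= a.type_I <= 1 and 0 <= a.type_II <= 1
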