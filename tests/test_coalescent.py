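import numpy as np
import pytest
from scipy import stats as sps

from refugia import (DemographicScenario, PriorSpec, SampleConfig, draw_params,
                     evolve_sequences, scenario_library, simulate_dataset,
                     simulate_genealogy)
from refugia.coalescent import DEFAULT_TIMES, POPULATIONS
from refugia.popgen import harmonic_number


def single_pop_cfg(n, L=500, mu=0.0):
    return SampleConfig(sample_sizes={"KD-EA": n}, L=L, mu=mu)


def single_pop_params(ne):
    p = {f"N_{x}": 1.0 for x in POPULATIONS}
    p.update({"N_ANC": 1.0, "N_KD-EA": float(ne),
              "t1": 1.0, "t2": 2.0, "t3": 3.0, "Tt": 4.0})
    return p


ONE_POP = DemographicScenario("single", ["KD-EA"], [])


class TestScenarioLibrary:
    def test_s1_single_epoch(self):
        s1 = scenario_library()["S1_fragmentation"]
        assert {e.time_key for e in s1.events} == {"Tt"}
        assert {e.derived for e in s1.events} == set(POPULATIONS)

    def test_s2_serial_chain(self):
        s2 = scenario_library()["S2_one_way"]
        chain = [(e.time_key, e.derived, e.source) for e in s2.events[:3]]
        assert chain == [("t1", "WA-Az", "CA"), ("t2", "CA", "LarNP-CA"),
                         ("t3", "LarNP-CA", "KD-EA")]
        times = [DEFAULT_TIMES[e.time_key] for e in s2.events]
        assert times == sorted(times)

    def test_s3_two_routes(self):
        # the western population attaches to the KD-EA branch, not to CA
        s3 = scenario_library()["S3_two_way"]
        ev = {e.derived: e.source for e in s3.events}
        assert ev["WA-Az"] == "KD-EA"
        assert ev["CA"] == "LarNP-CA"


class TestPriors:
    def test_uniform_bounds_and_mean(self):
        prior = PriorSpec()
        rng = np.random.default_rng(1)
        draws = np.array([draw_params(prior, rng)["N_CA"] for _ in range(4000)])
        assert draws.min() >= 10 and draws.max() <= 7e5
        assert np.mean(draws) == pytest.approx(3.5e5, rel=0.05)

    def test_reproducible(self):
        prior = PriorSpec()
        a = draw_params(prior, np.random.default_rng(3))
        b = draw_params(prior, np.random.default_rng(3))
        assert a == b

    def test_ks_against_uniform(self):
        prior = PriorSpec()
        nonsig = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x = np.array([draw_params(prior, rng)["N_WA-Az"] for _ in range(300)])
            p = sps.kstest(x, sps.uniform(10, 7e5 - 10).cdf).pvalue
            nonsig += p > 0.01
        assert nonsig >= 17

    def test_times_as_upper_bounds_preserve_order(self):
        prior = PriorSpec(times_as_upper_bounds=True)
        p = draw_params(prior, np.random.default_rng(0))
        assert p["t1"] <= p["t2"] <= p["t3"] <= p["Tt"] <= DEFAULT_TIMES["Tt"]

    def test_invalid_bounds(self):
        with pytest.raises(ValueError):
            PriorSpec(ne_low=100, ne_high=10)


class TestGenealogy:
    def test_pairwise_tmrca_mean(self):
        # E[T2] = Ne for a haploid pair
        rng = np.random.default_rng(7)
        cfg = single_pop_cfg(2)
        t = [simulate_genealogy(ONE_POP, single_pop_params(1000), cfg, rng).tmrca
             for _ in range(2000)]
        assert np.mean(t) == pytest.approx(1000, rel=0.05)

    def test_structure_invariants(self):
        rng = np.random.default_rng(2)
        cfg, prior = SampleConfig(), PriorSpec()
        params = draw_params(prior, rng)
        tree = simulate_genealogy(scenario_library()["S2_one_way"], params, cfg, rng)
        assert tree.n_tips == cfg.n_total
        assert np.all(tree.time[tree.n_tips:] > 0)
        bl = tree.branch_lengths()
        assert np.all(bl[np.arange(len(tree.parent)) != tree.root] >= 0)
        ch = tree.children()
        assert all(len(c) in (0, 2) for c in ch)

    def test_one_lineage_per_pop_coalesces_after_tt(self):
        rng = np.random.default_rng(9)
        cfg = SampleConfig(sample_sizes={p: 1 for p in POPULATIONS})
        prior = PriorSpec()
        scn = scenario_library()["S1_fragmentation"]
        for _ in range(20):
            params = draw_params(prior, rng)
            tree = simulate_genealogy(scn, params, cfg, rng)
            internal = tree.time[tree.n_tips:]
            assert np.all(internal >= DEFAULT_TIMES["Tt"])

    def test_tiny_ne_coalesces_before_t1_in_s2(self):
        rng = np.random.default_rng(4)
        cfg = SampleConfig()
        scn = scenario_library()["S2_one_way"]
        params = {f"N_{p}": 50.0 for p in POPULATIONS} | {
            "N_ANC": 50.0, **DEFAULT_TIMES}
        hit = 0
        for _ in range(20):
            tree = simulate_genealogy(scn, params, cfg, rng)
            # with Ne=50 every within-population MRCA is far younger than t1
            hit += tree.tmrca < DEFAULT_TIMES["Tt"] + 2000
        assert hit == 20

    def test_nonpositive_ne_rejected(self):
        params = single_pop_params(0.0)
        with pytest.raises(ValueError):
            simulate_genealogy(ONE_POP, params, single_pop_cfg(2), np.random.default_rng(0))


class TestSequences:
    def test_zero_mu_identical(self):
        rng = np.random.default_rng(5)
        tree = simulate_genealogy(ONE_POP, single_pop_params(500), single_pop_cfg(6), rng)
        aln = evolve_sequences(tree, single_pop_cfg(6, mu=0.0), rng)
        assert len(set(aln.sequences)) == 1

    def test_watterson_expected_segregating_sites(self):
        # E[S] = theta * L * a_{n-1}, theta = 2 Ne mu (haploid pairwise)
        ne, mu, L, n = 800.0, 1e-5, 300, 10
        cfg = single_pop_cfg(n, L=L, mu=mu)
        rng = np.random.default_rng(11)
        from refugia.popgen import diversity_summary

        s = []
        for _ in range(2000):
            tree = simulate_genealogy(ONE_POP, single_pop_params(ne), cfg, rng)
            aln = evolve_sequences(tree, cfg, rng)
            s.append(diversity_summary(aln).S)
        expect = 2 * ne * mu * L * harmonic_number(n - 1)
        # finite-sites simulation slightly undercounts vs infinite-sites formula
        assert np.mean(s) == pytest.approx(expect, rel=0.05)

    def test_expected_pairwise_diversity(self):
        # E[pi] = 2 Ne mu per site
        ne, mu, L = 1000.0, 1e-5, 400
        cfg = single_pop_cfg(2, L=L, mu=mu)
        rng = np.random.default_rng(13)
        from refugia.popgen import diversity_summary

        pis = []
        for _ in range(2000):
            tree = simulate_genealogy(ONE_POP, single_pop_params(ne), cfg, rng)
            pis.append(diversity_summary(evolve_sequences(tree, cfg, rng)).pi)
        assert np.mean(pis) == pytest.approx(2 * ne * mu, rel=0.05)

    def test_seed_fixes_dataset_bitwise(self):
        cfg, prior = SampleConfig(L=400), PriorSpec()
        scn = scenario_library()["S3_two_way"]
        outs = []
        for _ in range(2):
            rng = np.random.default_rng(21)
            params = draw_params(prior, rng)
            aln, pm = simulate_dataset(scn, params, cfg, rng)
            outs.append(("".join(aln.sequences), tuple(pm.assignments.items())))
        assert outs[0] == outs[1]

    def test_s1_equal_ne_symmetric_divergence(self):
        # under simultaneous fragmentation with equal Ne, mean between-pop
        # distances are exchangeable across pairs
        cfg = SampleConfig(sample_sizes={p: 6 for p in POPULATIONS}, L=400, mu=2e-7)
        scn = scenario_library()["S1_fragmentation"]
        params = {f"N_{p}": 2e4 for p in POPULATIONS} | {"N_ANC": 2e4, **DEFAULT_TIMES}
        rng = np.random.default_rng(31)
        from refugia.inference import _pop_indices
        from refugia.popgen import _pairwise_mismatch_counts

        sums = {}
        for _ in range(60):
            aln, pm = simulate_dataset(scn, params, cfg, rng)
            mat = aln.to_matrix()
            D = _pairwise_mismatch_counts(mat)
            idx = _pop_indices(cfg, POPULATIONS)
            for a in range(4):
                for b in range(a + 1, 4):
                    key = (POPULATIONS[a], POPULATIONS[b])
                    sums.setdefault(key, []).append(
                        D[np.ix_(idx[key[0]], idx[key[1]])].mean())
        means = np.array([np.mean(v) for v in sums.values()])
        assert means.std() / means.mean() < 0.1


class TestMsprimeCrossCheck:
    @pytest.mark.parametrize("ne,mu", [(500.0, 1e-5), (2000.0, 5e-6), (100.0, 2e-5)])
    def test_single_population_diversity_matches_msprime(self, ne, mu):
        msprime = pytest.importorskip("msprime")
        L, n, reps = 500, 8, 400
        rng = np.random.default_rng(17)
        cfg = single_pop_cfg(n, L=L, mu=mu)
        ours = []
        from refugia.popgen import diversity_summary

        for _ in range(reps):
            tree = simulate_genealogy(ONE_POP, single_pop_params(ne), cfg, rng)
            ours.append(diversity_summary(evolve_sequences(tree, cfg, rng)).pi)
        theirs = []
        reps_ts = msprime.sim_ancestry(samples=n, ploidy=1, population_size=ne,
                                       sequence_length=L, num_replicates=reps,
                                       random_seed=23)
        for i, ts in enumerate(reps_ts):
            mts = msprime.sim_mutations(ts, rate=mu, random_seed=29 + i,
                                        model=msprime.JC69())
            theirs.append(mts.diversity(span_normalise=True))
        assert np.mean(ours) == pytest.approx(np.mean(theirs), rel=0.08)
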