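import numpy as np
import pytest

from rhoscan.diversity import nucleotide_diversity, watterson_theta
from rhoscan.recomb_rate import min_recomb_events
from rhoscan.synthetic_data import (Hotspot, PoolAssayConfig, RecombProfile,
                                    Selection, SimConfig, pair_into_diploids,
                                    simulate_panel, simulate_panel_n_sites,
                                    simulate_pool_assay)

FLAT0 = RecombProfile(0.0, ())


class TestNeutralCoalescent:
    def test_segregating_sites_match_watterson_expectation(self):
        """E[S] = theta * a_{n-1} under the neutral coalescent."""
        theta, n, reps = 5.0, 50, 500
        S = [simulate_panel(SimConfig(n, 1000, theta, FLAT0, seed=i)).n_sites
             for i in range(reps)]
        a = np.sum(1.0 / np.arange(1, n))
        exp_S = theta * a
        se = np.std(S, ddof=1) / np.sqrt(reps)
        assert abs(np.mean(S) - exp_S) < 3 * se

    def test_no_recombination_never_violates_four_gametes(self):
        """rho = 0 with infinite sites allows at most 3 gamete types."""
        for i in range(100):
            p = simulate_panel(SimConfig(15, 1000, 4.0, FLAT0, seed=i))
            if p.n_sites >= 2:
                assert min_recomb_events(p).rm == 0

    def test_hotspot_raises_detectable_recombination(self):
        """Adding a 40x hotspot to the background map increases the
        Hudson-Kaplan bound relative to the background-only map."""
        hot = RecombProfile(0.002, (Hotspot(400, 600, 40.0),))
        flat = RecombProfile(0.002, ())
        rm_hot, rm_flat = [], []
        for i in range(200):
            rm_hot.append(min_recomb_events(
                simulate_panel(SimConfig(30, 1000, 6.0, hot,
                                         seed=i))).rm)
            rm_flat.append(min_recomb_events(
                simulate_panel(SimConfig(30, 1000, 6.0, flat,
                                         seed=i))).rm)
        assert np.mean(rm_hot) > np.mean(rm_flat)

    def test_pi_equals_theta_in_expectation(self):
        """Neutrality: E[pi] = E[theta_W]; joint 3-SE band, 300 reps."""
        pis, thetas = [], []
        for i in range(300):
            p = simulate_panel(SimConfig(20, 1000, 5.0, FLAT0, seed=i))
            if p.n_sites == 0:
                pis.append(0.0)
                thetas.append(0.0)
            else:
                pis.append(nucleotide_diversity(p))
                thetas.append(watterson_theta(p))
        diff = np.array(pis) - np.array(thetas)
        se = np.std(diff, ddof=1) / np.sqrt(len(diff))
        assert abs(np.mean(diff)) < 3 * se

    def test_seeded_determinism(self):
        cfg = SimConfig(12, 800, 4.0, RecombProfile(0.003, ()), seed=7)
        a, b = simulate_panel(cfg), simulate_panel(cfg)
        assert np.array_equal(a.matrix, b.matrix)
        assert a.snp_map == b.snp_map

    def test_nonviable_configs_rejected(self):
        with pytest.raises(ValueError):
            simulate_panel(SimConfig(1, 1000, 5.0, FLAT0, seed=0))
        with pytest.raises(ValueError):
            simulate_panel(SimConfig(10, 0, 5.0, FLAT0, seed=0))
        with pytest.raises(ValueError):
            SimConfig(10, 1000, 5.0,
                      RecombProfile(0.001, (Hotspot(900, 1200, 4.0),)),
                      seed=0).validate()

    def test_fixed_site_count_thinning(self):
        p = simulate_panel_n_sites(
            SimConfig(40, 2000, 8.0, RecombProfile(0.003, ()), seed=3), 10)
        assert p.n_sites == 10
        assert (p.matrix.min(axis=0) == 0).all()
        assert (p.matrix.max(axis=0) == 1).all()
        assert p.snp_map.labels == tuple(f"S{i}" for i in range(1, 11))


class TestSelection:
    def test_positive_selection_raises_focal_frequency(self):
        """Mean final frequency of the selected derived allele exceeds its
        initial frequency across replicates."""
        inits, finals = [], []
        for i in range(200):
            _, info = simulate_panel(
                SimConfig(20, 1000, 5.0, RecombProfile(0.002, ()),
                          selection=Selection(focal_site=1, s=0.25,
                                              n_diploids=30,
                                              n_generations=30),
                          seed=i), return_info=True)
            inits.append(info["init_freq"])
            finals.append(info["final_freq"])
        assert np.mean(finals) > np.mean(inits)

    def test_selection_panel_shape_and_polymorphism(self):
        p = simulate_panel(
            SimConfig(24, 1000, 6.0, RecombProfile(0.002, ()),
                      selection=Selection(focal_site=0, s=0.1,
                                          n_diploids=40, n_generations=20),
                      seed=11))
        assert p.n_chromosomes == 24
        assert (p.matrix.min(axis=0) == 0).all()
        assert (p.matrix.max(axis=0) == 1).all()


class TestPairing:
    def test_four_rows_make_two_individuals(self, rng):
        from conftest import make_panel
        p = make_panel(rng.integers(0, 2, (4, 3)))
        d = pair_into_diploids(p, seed=0)
        assert d.meta["individual"].nunique() == 2
        assert sorted(d.meta["chromosome"]) == [1, 1, 2, 2]

    def test_fixed_seed_reproduces_pairing(self, rng):
        from conftest import make_panel
        p = make_panel(rng.integers(0, 2, (8, 3)))
        a, b = pair_into_diploids(p, seed=5), pair_into_diploids(p, seed=5)
        assert list(a.meta["individual"]) == list(b.meta["individual"])

    def test_content_unchanged(self, rng):
        from conftest import make_panel
        p = make_panel(rng.integers(0, 2, (10, 4)))
        d = pair_into_diploids(p, seed=1)
        assert np.array_equal(d.matrix, p.matrix)

    def test_odd_row_count_rejected(self, rng):
        from conftest import make_panel
        with pytest.raises(ValueError, match="odd"):
            pair_into_diploids(make_panel(rng.integers(0, 2, (5, 3))))


class TestPoolAssay:
    def test_zero_rate_never_positive(self):
        for i in range(20):
            out = simulate_pool_assay(
                PoolAssayConfig(true_rate=0.0, seed=i))
            assert out.positives == 0

    def test_positive_run_count_matches_poisson_thinning(self):
        """Mean positives over replicates matches the closed form
        n_runs * (1 - exp(-genomes * detect * rate * bp * 1e-8))."""
        cfg_kw = dict(n_runs=77, genomes_per_run=100, true_rate=129.0,
                      interval_bp=1000, detectable_fraction=0.5)
        pos = [simulate_pool_assay(PoolAssayConfig(**cfg_kw, seed=i)).positives
               for i in range(2000)]
        lam = 100 * 0.5 * 129e-8 * 1000
        expect = 77 * (1 - np.exp(-lam))
        se = np.std(pos, ddof=1) / np.sqrt(len(pos))
        assert abs(np.mean(pos) - expect) < 3 * se

    def test_single_genome_runs_estimate_molecule_fraction(self):
        """With one genome per run, positives/runs is a direct binomial
        estimate of the detectable per-molecule recombinant fraction."""
        f = 0.5 * 2000.0 * 1e-8 * 1000  # detectable fraction per molecule
        pos = [simulate_pool_assay(
            PoolAssayConfig(n_runs=4000, genomes_per_run=1,
                            true_rate=2000.0, interval_bp=1000,
                            detectable_fraction=0.5, seed=i)).positives
               for i in range(30)]
        frac = np.array(pos) / 4000
        expect = 1 - np.exp(-f)
        se = np.std(frac, ddof=1) / np.sqrt(len(frac))
        assert abs(np.mean(frac) - expect) < 3 * se

    def test_config_validation(self):
        with pytest.raises(ValueError):
            PoolAssayConfig(detectable_fraction=0.0).validate()
        with pytest.raises(ValueError):
            PoolAssayConfig(n_runs=0).validate()
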