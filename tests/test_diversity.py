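import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra.numpy import arrays

from rhoscan.diversity import (haplotype_diversity, hd_theta_profile,
                               nucleotide_diversity, watterson_theta)
from rhoscan.synthetic_data import (Hotspot, RecombProfile, SimConfig,
                                    simulate_panel)

from conftest import make_map, make_panel, random_panel


def oracle_hd(matrix):
    """Independent counting oracle: enumerate haplotype frequencies and
    plug into Nei's unbiased formula."""
    n = len(matrix)
    counts = {}
    for row in matrix:
        counts[tuple(row)] = counts.get(tuple(row), 0) + 1
    s = sum((c / n) ** 2 for c in counts.values())
    return n * (1 - s) / (n - 1)


def oracle_theta(matrix):
    S = sum(1 for j in range(matrix.shape[1])
            if len(set(matrix[:, j])) > 1)
    return S / sum(1 / i for i in range(1, len(matrix)))


def oracle_pi(matrix):
    n = len(matrix)
    tot = sum(np.sum(matrix[i] != matrix[j])
              for i, j in itertools.combinations(range(n), 2))
    return tot / (n * (n - 1) / 2)


class TestEstimators:
    def test_identical_rows_give_zero_diversity(self, rng):
        p = make_panel(np.tile(rng.integers(0, 2, 6), (5, 1)))
        assert haplotype_diversity(p) == 0.0
        assert nucleotide_diversity(p) == 0.0

    def test_two_distinct_rows_give_unit_hd(self):
        p = make_panel([[0, 0, 1], [1, 0, 1]])
        assert haplotype_diversity(p) == pytest.approx(1.0)

    def test_watterson_hand_value(self):
        # n = 4, S = 3 -> 3 / (1 + 1/2 + 1/3)
        p = make_panel([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
        assert watterson_theta(p) == pytest.approx(3 / (1 + 0.5 + 1 / 3))

    def test_two_rows_differing_at_three_sites(self):
        p = make_panel([[0, 0, 0, 1], [1, 1, 1, 1]])
        assert nucleotide_diversity(p) == pytest.approx(3.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_estimators_match_brute_force_oracles(self, seed):
        rng = np.random.default_rng(seed)
        p = random_panel(rng, rng.integers(5, 21), rng.integers(3, 13))
        assert haplotype_diversity(p) == pytest.approx(oracle_hd(p.matrix))
        assert watterson_theta(p) == pytest.approx(oracle_theta(p.matrix))
        assert nucleotide_diversity(p) == pytest.approx(oracle_pi(p.matrix))

    def test_invariance_to_row_order_and_polarity(self, rng):
        p = random_panel(rng, 12, 8)
        vals = (haplotype_diversity(p), watterson_theta(p),
                nucleotide_diversity(p))
        perm = rng.permutation(12)
        q = make_panel(p.matrix[perm])
        flip = rng.integers(0, 2, 8).astype(bool)
        m2 = p.matrix.copy()
        m2[:, flip] = 1 - m2[:, flip]
        r = make_panel(m2)
        for other in (q, r):
            assert haplotype_diversity(other) == pytest.approx(vals[0])
            assert watterson_theta(other) == pytest.approx(vals[1])
            assert nucleotide_diversity(other) == pytest.approx(vals[2])

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(arrays(np.int8, (8, 6), elements=st.integers(0, 1)),
           st.permutations(range(8)),
           st.lists(st.booleans(), min_size=6, max_size=6))
    def test_property_row_order_and_polarity_invariance(self, matrix, perm,
                                                        flips):
        """Hd, theta_W and pi are symmetric functions of the rows and
        invariant under consistent per-column 0<->1 recoding."""
        p = make_panel(matrix)
        base = (haplotype_diversity(p), watterson_theta(p),
                nucleotide_diversity(p))
        m2 = matrix[list(perm)].copy()
        for j, f in enumerate(flips):
            if f:
                m2[:, j] = 1 - m2[:, j]
        q = make_panel(m2)
        assert (haplotype_diversity(q), watterson_theta(q),
                nucleotide_diversity(q)) == pytest.approx(base)

    def test_small_samples_rejected(self):
        p = make_panel([[0, 1, 0]])
        for fn in (haplotype_diversity, watterson_theta,
                   nucleotide_diversity):
            with pytest.raises(ValueError):
                fn(p)

    def test_missing_data_requires_drop_flag(self):
        p = make_panel([[0, 1], [1, 0], [0, 0]])
        p.matrix[0, 0] = -1
        with pytest.raises(ValueError, match="missing"):
            haplotype_diversity(p)
        assert haplotype_diversity(p, drop_incomplete=True) == \
            pytest.approx(1.0)

    def test_per_site_scaling(self, rng):
        p = random_panel(rng, 10, 6)
        L = p.snp_map.positions.max() - p.snp_map.positions.min() + 1
        assert watterson_theta(p, per_site=True) == pytest.approx(
            watterson_theta(p) / L)


class TestHdThetaProfile:
    def test_composition_identity_per_subsegment(self, rng):
        p = random_panel(rng, 20, 12)
        prof = hd_theta_profile(p).table.set_index("region")
        sites = p.snp_map.subsegment_sites("Alu")
        assert prof.loc["Alu", "Hd"] == pytest.approx(
            haplotype_diversity(p, sites))
        assert prof.loc["Alu", "hd_theta_ratio"] == pytest.approx(
            haplotype_diversity(p, sites) / watterson_theta(p, sites))

    def test_identical_subsegment_composition_gives_equal_ratios(self, rng):
        """Four sub-segments built from the same column block must score
        identical Hd/theta."""
        block = random_panel(rng, 15, 3).matrix
        matrix = np.hstack([block] * 4)
        subsegs = (["PreAlu"] * 3 + ["Alu"] * 3 + ["PostAlu"] * 3
                   + ["PostExon"] * 3)
        p = make_panel(matrix, snp_map=make_map(12, subsegments=subsegs))
        prof = hd_theta_profile(p).table
        ratios = prof[prof.region != "Segment"]["hd_theta_ratio"]
        assert ratios.nunique() == 1

    def test_monomorphic_region_reports_undefined_ratio(self, rng):
        matrix = np.zeros((8, 8), dtype=int)
        matrix[:4, 4:] = 1  # PostAlu/PostExon polymorphic, first half not
        subsegs = (["PreAlu"] * 2 + ["Alu"] * 2 + ["PostAlu"] * 2
                   + ["PostExon"] * 2)
        matrix[:, :4] = 0
        p = make_panel(matrix, snp_map=make_map(8, subsegments=subsegs))
        prof = hd_theta_profile(p).table.set_index("region")
        assert np.isnan(prof.loc["PreAlu", "hd_theta_ratio"])
        assert np.isfinite(prof.loc["PostExon", "hd_theta_ratio"])

    def test_flank_recombination_raises_flank_ratios(self):
        """Recombination confined to the flanks should rank the flank
        sub-segments above the centre by Hd/theta in most replicates."""
        wins = 0
        n_informative = 0
        # high rho on both flanks, zero across the centre
        prof_map = RecombProfile(0.02, (Hotspot(250, 800, 0.0),))
        for i in range(50):
            p = simulate_panel(SimConfig(40, 1000, 12.0, prof_map, seed=i))
            table = hd_theta_profile(p).table.set_index("region")
            try:
                pre = table.loc["PreAlu", "hd_theta_ratio"]
                post = table.loc["PostExon", "hd_theta_ratio"]
                mid = table.loc["Alu", "hd_theta_ratio"]
            except KeyError:
                continue
            if np.isnan([pre, post, mid]).any():
                continue
            n_informative += 1
            if (pre + post) / 2 > mid:
                wins += 1
        assert n_informative >= 20
        assert wins > n_informative / 2
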