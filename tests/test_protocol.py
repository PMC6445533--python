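"""Fragment-level protocol simulation: binding, extraction, PCR, sequencing."""

import itertools

import numpy as np
import pytest
from scipy.stats import chisquare, hypergeom

from chipsim.protocol import (
    _hypergeom_draw,
    allocate_to_parents,
    amplification_probability,
    amplify,
    deduplicate,
    equalize_samples,
    extract_fragments,
    pcr_distribution,
    pcr_moments,
    sequence_reads,
    simulate_binding,
)


class TestBindingAndExtraction:
    def test_degenerate_probabilities(self, rng):
        assert np.all(simulate_binding([1.0, 1.0], 500, rng) == 500)
        assert np.all(simulate_binding([0.0], 500, rng) == 0)
        fb = np.array([100, 50])
        assert np.array_equal(extract_fragments(fb, np.ones(2), rng), fb)
        assert np.all(extract_fragments(fb, np.zeros(2), rng) == 0)

    def test_binomial_moments(self, rng):
        draws = simulate_binding(np.full(1000, 0.2), 100_000, rng)
        assert draws.mean() == pytest.approx(20_000, rel=0.005)
        assert draws.var() == pytest.approx(100_000 * 0.2 * 0.8, rel=0.15)

    def test_two_stage_thinning_equals_product(self, rng):
        # extraction aggregates sub-steps: thin(p) o thin(q) == thin(pq)
        n = 10_000
        fb = np.full(n, 500)
        one = extract_fragments(fb, np.full(n, 0.4), rng)
        stage1 = extract_fragments(fb, np.full(n, 0.8), rng)
        two = extract_fragments(stage1, np.full(n, 0.5), rng)
        se = np.sqrt(500 * 0.4 * 0.6 / n)
        assert abs(one.mean() - two.mean()) < 3 * np.sqrt(2) * se
        assert two.var() == pytest.approx(500 * 0.4 * 0.6, rel=0.1)

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            extract_fragments(np.array([1, 2]), np.array([0.5]), rng)


class TestEqualize:
    def test_identity_when_balanced(self, rng):
        chip = np.full(10, 100)
        out_c, out_i = equalize_samples(chip, chip.copy(), rng)
        assert np.array_equal(out_c, chip) and np.array_equal(out_i, chip)

    @pytest.mark.parametrize("chip_tot,inp_tot", [(500, 1000), (2000, 1000)])
    def test_richer_sample_thinned(self, chip_tot, inp_tot, rng):
        reps = 400
        chip = np.full(10, chip_tot // 10)
        inp = np.full(10, inp_tot // 10)
        tot_c = tot_i = 0
        for _ in range(reps):
            c, i = equalize_samples(chip, inp, rng)
            tot_c += c.sum()
            tot_i += i.sum()
        target = min(chip_tot, inp_tot)
        assert tot_c / reps == pytest.approx(target, rel=0.02)
        assert tot_i / reps == pytest.approx(target, rel=0.02)

    def test_zero_total_rejected(self, rng):
        with pytest.raises(ValueError):
            equalize_samples(np.zeros(3, int), np.full(3, 5), rng)


class TestPCR:
    def test_single_cycle(self):
        assert pcr_distribution(0.5, 1) == pytest.approx([0.5, 0.5])

    def test_two_cycles_brute_force(self):
        # enumerate the 2-cycle branching process by hand
        assert pcr_distribution(0.5, 2) == pytest.approx([0.25, 0.375, 0.25, 0.125])

    @pytest.mark.parametrize("p_a", [0.1, 0.3, 0.58, 0.9])
    @pytest.mark.parametrize("n_cy", [1, 5, 10, 15])
    def test_moments_match_closed_form(self, p_a, n_cy):
        probs = pcr_distribution(p_a, n_cy)
        k = np.arange(1, probs.size + 1)
        m, v = pcr_moments(p_a, n_cy)
        assert probs.sum() == pytest.approx(1.0, abs=1e-9)
        assert (k * probs).sum() == pytest.approx(m, rel=1e-6)
        assert (k**2 * probs).sum() - (k * probs).sum() ** 2 == pytest.approx(
            v, rel=1e-6
        )

    def test_default_amplification_ratio(self):
        p_a = amplification_probability(1000, 15)
        probs = pcr_distribution(p_a, 15, grid=False)
        k = np.arange(1, probs.size + 1)
        assert (k * probs).sum() == pytest.approx(1000, rel=1e-6)

    def test_moment_edge_cases(self):
        assert pcr_moments(0.0, 10) == (1.0, 0.0)
        m, v = pcr_moments(1.0, 10)
        assert m == 2**10 and v == 0.0
        assert pcr_moments(0.5, 3) == pytest.approx((3.375, 2.671875))

    def test_invalid_pa_rejected(self):
        with pytest.raises(ValueError):
            pcr_distribution(0.0, 5)
        with pytest.raises(ValueError):
            pcr_distribution(1.2, 5)

    def test_grid_rounding(self):
        assert pcr_distribution(0.5849, 10, grid=True) is pcr_distribution(
            0.58, 10, grid=False
        )

    def test_amplify_monte_carlo_mean(self, rng):
        p_a = 10 ** (1 / 5) - 1
        (s,) = amplify([100_000], [p_a], 15, rng, grid=False)
        assert s.min() >= 1
        assert s.mean() == pytest.approx((1 + p_a) ** 15, rel=0.02)

    def test_amplify_edges(self, rng):
        assert amplify([0], [0.5], 15, rng)[0].size == 0
        assert np.all(amplify([7], [0.5], 0, rng)[0] == 1)


class TestSequencing:
    def test_exhaustive_draw(self, rng):
        pools = np.array([5, 3, 9])
        assert np.array_equal(sequence_reads(pools, 17, rng), pools)

    def test_two_pool_marginal_matches_hypergeom_pmf(self, rng):
        counts = np.zeros(3)
        n_draws = 30_000
        for _ in range(n_draws):
            counts[sequence_reads([2, 2], 2, rng)[0]] += 1
        expected = hypergeom.pmf([0, 1, 2], 4, 2, 2) * n_draws
        assert chisquare(counts, expected).pvalue > 0.01

    def test_equal_pools_symmetric_marginals(self, rng):
        reps, r = 400, 300
        totals = np.zeros(3)
        for _ in range(reps):
            totals += sequence_reads([1000, 1000, 1000], r, rng)
        se = np.sqrt(r * (1 / 3) * (2 / 3) / reps)
        assert np.all(np.abs(totals / reps - r / 3) < 3 * se + 0.5)

    def test_order_invariance_of_marginals(self, rng):
        # the sequential conditional scheme is exchangeable in locus order
        pools = [50, 200, 750]
        a = np.array([sequence_reads(pools, 100, rng)[0] for _ in range(4000)])
        b = np.array([sequence_reads(pools[::-1], 100, rng)[2] for _ in range(4000)])
        assert abs(a.mean() - b.mean()) < 3 * np.sqrt(a.var() / 4000 + b.var() / 4000)

    def test_oversampling_rejected(self, rng):
        with pytest.raises(ValueError):
            sequence_reads([3, 3], 7, rng)

    def test_conservation(self, rng):
        pools = rng.integers(10, 1000, size=50)
        r = sequence_reads(pools, 2000, rng)
        assert r.sum() == 2000 and np.all(r <= pools)

    def test_large_pool_fallback_matches_exact_sampler(self, rng):
        # windowed inverse-CDF draw vs numpy's sampler at identical parameters
        draws = np.array([_hypergeom_draw(10**10, 2 * 10**10, 3000, rng) for _ in range(3000)])
        mean = 3000 / 3
        var = 3000 * (1 / 3) * (2 / 3)
        assert draws.mean() == pytest.approx(mean, abs=3 * np.sqrt(var / 3000))
        assert draws.var() == pytest.approx(var, rel=0.15)


class TestDeduplication:
    def test_all_singleton_parents(self, rng):
        per_parent = allocate_to_parents(np.ones(40, dtype=np.int64), 12, rng)
        u, d = deduplicate(per_parent)
        assert (u, d) == (12, 0)

    def test_single_parent_pool(self, rng):
        per_parent = allocate_to_parents(np.array([8]), 8, rng)
        u, d = deduplicate(per_parent)
        assert (u, d) == (1, 7)

    def test_two_parent_enumeration_oracle(self, rng):
        # parents with 3 and 1 copies, 2 reads: exact E[u] by enumeration
        probs = {}
        for reads in itertools.combinations(range(4), 2):  # fragments 0-2 parent A, 3 parent B
            parents = {0 if f < 3 else 1 for f in reads}
            probs[len(parents)] = probs.get(len(parents), 0) + 1 / 6
        expected_u = sum(k * p for k, p in probs.items())
        sims = []
        for _ in range(20_000):
            per_parent = allocate_to_parents(np.array([3, 1]), 2, rng)
            sims.append(deduplicate(per_parent)[0])
        assert np.mean(sims) == pytest.approx(expected_u, rel=0.02)
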