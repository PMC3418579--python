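import numpy as np
import pytest

from ldphasekit.ld import pairwise_ld
from ldphasekit.panel_io import MISSING
from ldphasekit.simulate import (
    SimConfig,
    ascertain_and_degrade,
    evolve,
    expected_heterozygosity,
    make_crossbred,
    recombination_fractions,
    sample_panel,
    simulate_base_population,
    split_populations,
)


def small_config(**kw):
    base = dict(
        n_chromosomes=1,
        chromosome_length_bp=3_000_000,
        n_markers_per_chromosome=100,
        base_pop_size=100,
        burn_in_generations=20,
        split_generation=0,
        ne_schedule=(),
        sample_sizes=(50, 50, 0),
        missing_rate=0.0,
        seed=7,
    )
    base.update(kw)
    return SimConfig(**base)


class TestBasePopulation:
    def test_same_seed_is_bit_identical(self):
        p1 = simulate_base_population(small_config())
        p2 = simulate_base_population(small_config())
        for h1, h2 in zip(p1.haplotypes, p2.haplotypes):
            np.testing.assert_array_equal(h1, h2)
        for q1, q2 in zip(p1.positions, p2.positions):
            np.testing.assert_array_equal(q1, q2)

    def test_no_burn_in_frequencies_match_initial_draw(self):
        pop = simulate_base_population(
            small_config(base_pop_size=1000, burn_in_generations=0)
        )
        freqs = pop.haplotypes[0].mean(axis=0)
        # founder draw is Uniform(0.1, 0.9); binomial noise about p has
        # SE <= sqrt(0.25/2000), so 3 SE bounds the band
        se = np.sqrt(0.25 / 2000)
        assert freqs.min() > 0.1 - 3 * se
        assert freqs.max() < 0.9 + 3 * se
        assert abs(freqs.mean() - 0.5) < 0.05

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            small_config(base_pop_size=1)
        with pytest.raises(ValueError):
            small_config(n_markers_per_chromosome=0)
        with pytest.raises(ValueError):
            small_config(missing_rate=1.5)


class TestDrift:
    def test_heterozygosity_decay_matches_wright_fisher_expectation(self):
        # H_t / H_0 should equal (1 - 1/(2N))^t in expectation
        n, t, reps = 50, 20, 20
        ratios = []
        for seed in range(reps):
            cfg = small_config(base_pop_size=n, burn_in_generations=0, seed=seed)
            pop = simulate_base_population(cfg)
            h0 = expected_heterozygosity(pop)
            rng = np.random.default_rng(1000 + seed)
            pop_t = evolve(pop, t, n, rng)
            ratios.append(expected_heterozygosity(pop_t) / h0)
        expected = (1 - 1 / (2 * n)) ** t
        mean = np.mean(ratios)
        mc_err = 3 * np.std(ratios, ddof=1) / np.sqrt(reps)
        assert abs(mean - expected) < mc_err + 0.01

    def test_allele_frequency_martingale(self):
        # long chromosome so loci are loosely linked and replicates are
        # approximately Gaussian; drift must not bias the mean frequency
        n, t = 100, 30
        deltas = []
        for seed in range(40):
            cfg = small_config(
                base_pop_size=n,
                burn_in_generations=0,
                chromosome_length_bp=200_000_000,
                seed=seed,
            )
            pop = simulate_base_population(cfg)
            p0 = pop.haplotypes[0].mean(axis=0)
            rng = np.random.default_rng(2000 + seed)
            pt = evolve(pop, t, n, rng).haplotypes[0].mean(axis=0)
            deltas.append((pt - p0).mean())
        se = np.std(deltas, ddof=1) / np.sqrt(len(deltas))
        assert abs(np.mean(deltas)) < 3.5 * se + 1e-3


class TestRecombination:
    def test_fraction_is_linear_in_bp_and_capped(self):
        pos = np.array([1, 50_001, 100_050_001])
        frac = recombination_fractions(pos)
        assert frac[0] == pytest.approx(5e-4)
        assert frac[1] == 0.5  # one Morgan apart -> capped at free recombination

    def test_zero_recombination_gametes_are_parental(self):
        from ldphasekit.simulate import _make_gametes

        rng = np.random.default_rng(3)
        haps = rng.integers(0, 2, size=(20, 50)).astype(np.uint8)
        parents = np.arange(10)
        gametes = _make_gametes(haps, parents, np.zeros(49), rng)
        for g, p in zip(gametes, parents):
            assert (g == haps[2 * p]).all() or (g == haps[2 * p + 1]).all()


class TestSplitAndCross:
    def test_split_founders_disjoint(self):
        pop = simulate_base_population(small_config())
        rng = np.random.default_rng(11)
        a, b = split_populations(pop, 30, rng)
        assert a.n_individuals == b.n_individuals == 30
        # haplotype multisets must come from different founders: no row of a
        # equals a row of b more often than chance collisions allow
        overlap = sum(
            (a.haplotypes[0] == row).all(axis=1).any()
            for row in b.haplotypes[0][:10]
        )
        assert overlap < 10

    def test_oversized_split_resamples_with_warning(self):
        pop = simulate_base_population(small_config())
        rng = np.random.default_rng(11)
        with pytest.warns(UserWarning, match="replacement"):
            a, b = split_populations(pop, 200, rng)
        assert a.n_individuals == 200

    def test_split_without_evolution_preserves_phase(self):
        pop = simulate_base_population(
            small_config(base_pop_size=400, burn_in_generations=60)
        )
        rng = np.random.default_rng(5)
        a, b = split_populations(pop, 200, rng)
        panel_a, map_a = sample_panel(a, 200, "A", rng)
        panel_b, map_b = sample_panel(b, 200, "B", rng)
        rec_a = pairwise_ld(panel_a, map_a, max_distance_bp=200_000, min_pair_n=30)
        rec_b = pairwise_ld(panel_b, map_b, max_distance_bp=200_000, min_pair_n=30)
        merged = rec_a.merge(rec_b, on=["id_i", "id_j"], suffixes=("_a", "_b"))
        corr = np.corrcoef(merged["r_a"], merged["r_b"])[0, 1]
        assert corr > 0.9

    @pytest.mark.parametrize(
        "scheme,expected", [("F1", (0.5, 0.5)), ("backcross_A", (0.75, 0.25)),
                            ("backcross_B", (0.25, 0.75))]
    )
    def test_crossbred_composition_labels(self, scheme, expected):
        pop = simulate_base_population(small_config())
        rng = np.random.default_rng(2)
        a, b = split_populations(pop, 40, rng)
        panel, mmap, comp = make_crossbred(a, b, scheme, 25, rng)
        assert comp == expected
        assert panel.n_individuals == 25
        assert mmap.n_markers == 100

    def test_unknown_scheme_rejected(self):
        pop = simulate_base_population(small_config())
        rng = np.random.default_rng(2)
        a, b = split_populations(pop, 40, rng)
        with pytest.raises(ValueError, match="scheme"):
            make_crossbred(a, b, "F2", 10, rng)


class TestAscertainment:
    def test_identity_when_disabled(self):
        pop = simulate_base_population(small_config())
        rng = np.random.default_rng(4)
        panel, mmap = sample_panel(pop, 50, "A", rng)
        panel2, mmap2 = ascertain_and_degrade(panel, mmap, 0.0, 0.0, rng)
        np.testing.assert_array_equal(panel2.dosages, panel.dosages)
        assert mmap2.n_markers == mmap.n_markers

    def test_missing_count_within_binomial_interval(self):
        pop = simulate_base_population(small_config(n_markers_per_chromosome=200))
        rng = np.random.default_rng(4)
        panel, mmap = sample_panel(pop, 50, "A", rng)
        panel2, _ = ascertain_and_degrade(panel, mmap, 0.0, 0.1, rng)
        n_geno = panel2.dosages.size
        n_missing = int((panel2.dosages == MISSING).sum())
        # 99% binomial interval around 0.1
        sd = np.sqrt(n_geno * 0.1 * 0.9)
        assert abs(n_missing - 0.1 * n_geno) < 2.58 * sd

    def test_maf_floor_enforced(self):
        pop = simulate_base_population(small_config(burn_in_generations=80))
        rng = np.random.default_rng(4)
        panel, mmap = sample_panel(pop, 50, "A", rng)
        panel2, _ = ascertain_and_degrade(panel, mmap, 0.05, 0.0, rng)
        d = panel2.dosages
        p = d.mean(axis=0) / 2
        assert (np.minimum(p, 1 - p) >= 0.05).all()

    def test_all_markers_dropped_raises(self):
        from tests.conftest import make_map, make_panel

        panel = make_panel(np.zeros((20, 5), dtype=np.int8))  # all monomorphic
        rng = np.random.default_rng(4)
        with pytest.raises(ValueError, match="every marker"):
            ascertain_and_degrade(panel, make_map(5), 0.05, 0.0, rng)


class TestBottleneck:
    def test_bottleneck_inflates_short_range_ld(self):
        # drift in a small population raises r2 at all short distances
        wins = 0
        for seed in range(3):
            cfg = small_config(
                base_pop_size=200,
                n_markers_per_chromosome=300,
                burn_in_generations=80,
                seed=seed,
            )
            pop = simulate_base_population(cfg)
            rng = np.random.default_rng(100 + seed)
            a, b = split_populations(pop, 100, rng)
            a = evolve(a, 30, 20, rng)  # bottleneck
            b = evolve(b, 30, 200, rng)
            panel_a, map_a = sample_panel(a, 20, "A", rng)
            panel_b, map_b = sample_panel(b, 100, "B", rng)
            rec_a = pairwise_ld(panel_a, map_a, max_distance_bp=100_000, min_pair_n=15)
            rec_b = pairwise_ld(panel_b, map_b, max_distance_bp=100_000, min_pair_n=15)
            if rec_a["r2"].mean() > rec_b["r2"].mean():
                wins += 1
        assert wins >= 2
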