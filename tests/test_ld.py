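import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ldphasekit.ld import (
    PairGenotypeTable,
    _em_batch,
    haplotype_freq_em,
    ld_from_freqs,
    ld_from_phased,
    pair_table,
    pairwise_ld,
)
from ldphasekit.panel_io import MISSING
from tests.conftest import make_map, make_panel


def grid_loglik(counts: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Multinomial log-likelihood of the 3x3 table at each f_AB in grid."""
    c = counts
    n = c.sum()
    nh = 2 * n
    fa = (2 * c[2, :].sum() + c[1, :].sum()) / nh
    fb = (2 * c[:, 2].sum() + c[:, 1].sum()) / nh
    h = np.stack([grid, fa - grid, fb - grid, 1 - fa - fb + grid], axis=1)
    h = np.clip(h, 1e-300, None)
    hap_dos = np.array([[1, 1], [1, 0], [0, 1], [0, 0]])
    probs = np.zeros((len(grid), 3, 3))
    for x in range(4):
        for y in range(4):
            probs[:, hap_dos[x, 0] + hap_dos[y, 0], hap_dos[x, 1] + hap_dos[y, 1]] += (
                h[:, x] * h[:, y]
            )
    return (c[None, :, :] * np.log(np.clip(probs, 1e-300, None))).sum(axis=(1, 2))


def assert_matches_grid_search(c: np.ndarray, fab: float, step: float = 1e-5):
    """Independent oracle: f_AB must be a global maximizer of the multinomial
    likelihood, located by grid search.

    Tables that are invariant under flipping one locus's allele have two
    exactly tied maximizers (the phase sign is unidentifiable), so the EM
    answer is accepted when it matches the grid argmax within 1e-4 OR its
    own likelihood ties the grid maximum.
    """
    n = c.sum()
    nh = 2 * n
    fa = (2 * c[2, :].sum() + c[1, :].sum()) / nh
    fb = (2 * c[:, 2].sum() + c[:, 1].sum()) / nh
    lo, hi = max(0.0, fa + fb - 1.0), min(fa, fb)
    grid = np.clip(np.arange(lo, hi + step, step), lo, hi)
    ll = grid_loglik(c, grid)
    # all grid points attaining the maximum up to numerical ties
    maximizers = grid[ll >= ll.max() - 1e-9]
    assert np.min(np.abs(maximizers - fab)) <= 1e-4, (
        c.tolist(), fab, float(grid[np.argmax(ll)]))


def random_polymorphic_table(rng, max_n=12) -> np.ndarray:
    while True:
        n = rng.integers(2, max_n + 1)
        c = rng.multinomial(n, rng.dirichlet(np.ones(9))).reshape(3, 3)
        nh = 2 * n
        fa = (2 * c[2, :].sum() + c[1, :].sum()) / nh
        fb = (2 * c[:, 2].sum() + c[:, 1].sum()) / nh
        if 0 < fa < 1 and 0 < fb < 1:
            return c


class TestHaplotypeFreqEM:
    def test_phase_unambiguous_table_counts_directly(self):
        # {2x(2,2), 1x(1,2), 1x(2,1), 1x(0,0)}: no double heterozygote
        c = np.zeros((3, 3), dtype=int)
        c[2, 2], c[1, 2], c[2, 1], c[0, 0] = 2, 1, 1, 1
        fab, _, conv = haplotype_freq_em(PairGenotypeTable(c))
        assert conv
        assert fab == pytest.approx(0.6, abs=1e-9)
        d, r, r2 = ld_from_freqs(fab, 0.7, 0.7)
        assert d == pytest.approx(0.11, abs=1e-9)
        assert r2 == pytest.approx(0.0121 / 0.0441, abs=1e-6)
        assert r == pytest.approx(0.11 / 0.21, abs=1e-6)

    def test_perfect_coupling(self):
        c = np.zeros((3, 3), dtype=int)
        c[2, 2], c[0, 0] = 5, 5
        fab, _, _ = haplotype_freq_em(PairGenotypeTable(c))
        d, r, r2 = ld_from_freqs(fab, 0.5, 0.5)
        assert (fab, d, r, r2) == pytest.approx((0.5, 0.25, 1.0, 1.0))

    def test_matches_grid_search_oracle(self, rng):
        for _ in range(60):
            c = random_polymorphic_table(rng)
            fab, _, _ = haplotype_freq_em(PairGenotypeTable(c))
            assert_matches_grid_search(c, fab)

    def test_batch_agrees_with_scalar(self, rng):
        tables = np.stack([random_polymorphic_table(rng) for _ in range(80)])
        fab_b, _, _, conv = _em_batch(tables)
        for k in range(len(tables)):
            fab_s, _, _ = haplotype_freq_em(PairGenotypeTable(tables[k]))
            assert fab_b[k] == pytest.approx(fab_s, abs=1e-8)
        assert conv.all()

    def test_monomorphic_locus_rejected(self):
        c = np.zeros((3, 3), dtype=int)
        c[0, 1] = 4
        with pytest.raises(ValueError, match="monomorphic"):
            haplotype_freq_em(PairGenotypeTable(c))


class TestLDFromFreqs:
    def test_linkage_equilibrium(self):
        assert ld_from_freqs(0.35, 0.5, 0.7) == pytest.approx((0.0, 0.0, 0.0))

    def test_hand_evaluated_example(self):
        d, r, r2 = ld_from_freqs(0.4, 0.5, 0.6)
        assert d == pytest.approx(0.1)
        assert r2 == pytest.approx(0.01 / (0.25 * 0.24))
        assert r == pytest.approx(np.sqrt(0.01 / 0.06))

    def test_counted_allele_swap_negates_d_and_r(self):
        d1, r1, r2_1 = ld_from_freqs(0.4, 0.5, 0.6)
        # swap at locus B: f_Ab = f_A - f_AB, f_b = 0.4
        d2, r2_, r2_2 = ld_from_freqs(0.5 - 0.4, 0.5, 0.4)
        assert d2 == pytest.approx(-d1)
        assert r2_ == pytest.approx(-r1)
        assert r2_2 == pytest.approx(r2_1)

    def test_boundary_frequencies_rejected(self):
        with pytest.raises(ValueError):
            ld_from_freqs(0.0, 0.0, 0.5)

    @given(st.integers(0, 10**6))
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_invariants_on_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        c = random_polymorphic_table(rng, max_n=40)
        table = PairGenotypeTable(c)
        fab, _, _ = haplotype_freq_em(table)
        nh = 2 * table.n_used
        fa = (2 * c[2, :].sum() + c[1, :].sum()) / nh
        fb = (2 * c[:, 2].sum() + c[:, 1].sum()) / nh
        d, r, r2 = ld_from_freqs(fab, fa, fb)
        assert 0.0 <= r2 <= 1.0
        assert abs(d) <= 0.25 + 1e-12
        assert r == pytest.approx(np.sign(d) * np.sqrt(r2))
        assert d == pytest.approx(fab - fa * fb)


class TestLDFromPhased:
    def test_matches_unphased_on_same_configuration(self):
        d, r, r2 = ld_from_phased({"AB": 6, "Ab": 1, "aB": 1, "ab": 2})
        assert d == pytest.approx(0.11)
        assert r == pytest.approx(0.11 / 0.21, abs=1e-6)

    def test_complete_ld_and_equilibrium(self):
        assert ld_from_phased({"AB": 1, "ab": 1})[2] == pytest.approx(1.0)
        assert ld_from_phased({"AB": 1, "Ab": 1, "aB": 1, "ab": 1})[2] == pytest.approx(0.0)


def genotypes_from_phased_haplotypes(rng, n_ind, freqs2x2):
    """Diploid dosages at 2 loci from known haplotype frequencies, avoiding
    double heterozygotes so phase is never ambiguous (per-individual
    rejection of the ambiguous configuration)."""
    haps = np.array([[1, 1], [1, 0], [0, 1], [0, 0]])
    pick = rng.choice(4, size=(n_ind, 2), p=freqs2x2)
    while True:
        geno = haps[pick[:, 0]] + haps[pick[:, 1]]
        dh = (geno[:, 0] == 1) & (geno[:, 1] == 1)
        if not dh.any():
            return geno, haps[pick.ravel()]
        pick[dh] = rng.choice(4, size=(int(dh.sum()), 2), p=freqs2x2)


class TestPairwiseLD:
    def test_pair_count_single_chromosome(self, rng):
        d = rng.integers(0, 3, size=(40, 3)).astype(np.int8)
        rec = pairwise_ld(make_panel(d), make_map(3), min_pair_n=10)
        assert len(rec) == 3

    def test_no_interchromosome_pairs(self, rng):
        from ldphasekit.panel_io import MarkerMap

        d = rng.integers(0, 3, size=(40, 4)).astype(np.int8)
        mmap = MarkerMap(
            np.array(["a", "b", "c", "d"], dtype=object),
            np.array(["1", "1", "2", "2"], dtype=object),
            np.array([100, 200, 100, 200]),
            np.full(4, "A", dtype=object),
            np.full(4, "G", dtype=object),
        )
        rec = pairwise_ld(make_panel(d), mmap, min_pair_n=10)
        assert len(rec) == 2
        assert set(zip(rec["id_i"], rec["id_j"])) == {("a", "b"), ("c", "d")}

    def test_max_distance_and_min_n_respected(self, rng):
        d = rng.integers(0, 3, size=(40, 3)).astype(np.int8)
        d[:25, 2] = MISSING
        rec = pairwise_ld(make_panel(d), make_map(3), max_distance_bp=10_000,
                          min_pair_n=20)
        # distance filter keeps only adjacent pairs; missingness kills snp2 pairs
        assert list(zip(rec["id_i"], rec["id_j"])) == [("snp0", "snp1")]

    def test_equals_phased_counting_without_double_heterozygotes(self, rng):
        freqs = np.array([0.4, 0.15, 0.15, 0.3])
        geno, haps = genotypes_from_phased_haplotypes(rng, 60, freqs)
        panel = make_panel(geno)
        rec = pairwise_ld(panel, make_map(2), min_pair_n=10)
        counts = {
            "AB": int(((haps == [1, 1]).all(axis=1)).sum()),
            "Ab": int(((haps == [1, 0]).all(axis=1)).sum()),
            "aB": int(((haps == [0, 1]).all(axis=1)).sum()),
            "ab": int(((haps == [0, 0]).all(axis=1)).sum()),
        }
        d, r, r2 = ld_from_phased(counts)
        assert rec.loc[0, "r2"] == pytest.approx(r2, abs=1e-12)
        assert rec.loc[0, "r"] == pytest.approx(r, abs=1e-12)

    def test_counted_allele_flip_negates_r_across_pipeline(self, rng):
        d = rng.integers(0, 3, size=(50, 2)).astype(np.int8)
        panel = make_panel(d)
        rec1 = pairwise_ld(panel, make_map(2), min_pair_n=10)
        flipped = d.copy()
        flipped[:, 1] = 2 - flipped[:, 1]
        rec2 = pairwise_ld(make_panel(flipped), make_map(2), min_pair_n=10)
        assert rec2.loc[0, "r"] == pytest.approx(-rec1.loc[0, "r"])
        assert rec2.loc[0, "D"] == pytest.approx(-rec1.loc[0, "D"])
        assert rec2.loc[0, "r2"] == pytest.approx(rec1.loc[0, "r2"])

    def test_empty_map_rejected(self):
        panel = make_panel(np.zeros((5, 0), dtype=np.int8))
        with pytest.raises(ValueError):
            pairwise_ld(panel, make_map(0))


class TestPairTable:
    def test_counts_pairwise_complete_individuals(self):
        di = np.array([0, 1, 2, MISSING, 1], dtype=np.int8)
        dj = np.array([2, 1, 0, 1, MISSING], dtype=np.int8)
        t = pair_table(di, dj)
        assert t.n_used == 3
        assert t.counts[0, 2] == t.counts[1, 1] == t.counts[2, 0] == 1
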