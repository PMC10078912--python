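"""Windowed diversity statistics, LD and divergence against brute-force oracles."""

import numpy as np
import pytest

import oracles
from sweepcross.io_core import MISSING, GenomicInterval, GenotypeMatrix
from sweepcross.popstats import (
    WindowSpec,
    dxy,
    genotype_r2,
    iter_windows,
    ld_decay,
    nucleotide_diversity,
    site_density,
    tajimas_d,
)


def matrix_from(dosage, positions=None, chrom="chr1"):
    dosage = np.asarray(dosage, dtype=np.int8)
    s = dosage.shape[1]
    if positions is None:
        positions = np.arange(1, s + 1) * 10
    return GenotypeMatrix(
        sample_ids=[f"s{i}" for i in range(dosage.shape[0])],
        chrom=np.array([chrom] * s, dtype=object),
        pos=np.asarray(positions),
        ref=np.array(["A"] * s, dtype=object),
        alt=np.array(["T"] * s, dtype=object),
        dosage=dosage,
    )


def random_matrix(rng, n_samples, n_sites, missing_rate=0.0):
    dosage = rng.integers(0, 3, size=(n_samples, n_sites)).astype(np.int8)
    if missing_rate:
        dosage[rng.random(dosage.shape) < missing_rate] = MISSING
    return matrix_from(dosage, positions=np.sort(
        rng.choice(np.arange(1, 10_000), size=n_sites, replace=False)
    ))


class TestIterWindows:
    @pytest.mark.parametrize(
        "length,size,step,expected",
        [
            (120_000, 50_000, 50_000, [(0, 50_000), (50_000, 100_000), (100_000, 120_000)]),
            (50_000, 50_000, 50_000, [(0, 50_000)]),
            (100_000, 50_000, 25_000, [(0, 50_000), (25_000, 75_000),
                                       (50_000, 100_000), (75_000, 100_000)]),
        ],
    )
    def test_tiling(self, length, size, step, expected):
        wins = iter_windows({"chr1": length}, WindowSpec(size, step))
        assert [(w.start, w.end) for w in wins] == expected


class TestPi:
    def test_empty_window_is_zero(self):
        m = matrix_from(np.zeros((4, 2)))
        w = GenomicInterval("chr1", 5000, 6000)
        assert nucleotide_diversity(m, m.sample_ids, w) == 0.0

    def test_single_site_half_frequency(self):
        m = matrix_from([[0], [1], [1], [2]])  # p = 0.5, n = 8
        w = GenomicInterval("chr1", 0, 100)
        expect = (2 * 0.5 * 0.5 * 8 / 7) / 100
        assert nucleotide_diversity(m, m.sample_ids, w) == pytest.approx(expect)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_pairwise_mismatch_oracle(self, seed):
        rng = np.random.default_rng(seed)
        m = random_matrix(rng, n_samples=rng.integers(3, 10), n_sites=40)
        w = GenomicInterval("chr1", 0, 10_000)
        got = nucleotide_diversity(m, m.sample_ids, w)
        assert got == pytest.approx(oracles.brute_pi(m.dosage, 10_000), abs=1e-12)

    def test_empty_population_rejected(self):
        m = matrix_from([[0], [1]])
        with pytest.raises(ValueError):
            nucleotide_diversity(m, [], GenomicInterval("chr1", 0, 100))


class TestTajimasD:
    def test_no_segregating_sites_undefined(self):
        m = matrix_from(np.full((5, 4), 2))
        assert np.isnan(tajimas_d(m, m.sample_ids, GenomicInterval("chr1", 0, 100)))

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_independent_formula(self, seed):
        rng = np.random.default_rng(1000 + seed)
        n_dip = int(rng.integers(3, 12))
        s = int(rng.integers(3, 30))
        # complete-data window with at least 3 segregating sites
        dosage = rng.integers(0, 3, size=(n_dip, s)).astype(np.int8)
        m = matrix_from(dosage)
        got = tajimas_d(m, m.sample_ids, GenomicInterval("chr1", 0, 10_000))
        n = 2 * n_dip
        counts = [int(dosage[:, j].sum()) for j in range(s)
                  if 0 < dosage[:, j].sum() < n]
        if len(counts) < 3:
            assert np.isnan(got)
        else:
            assert got == pytest.approx(
                oracles.tajimas_d_reference(counts, n), abs=1e-10
            )

    def test_singleton_excess_is_negative(self):
        # n = 10 diploids, 10 sites, each a distinct singleton heterozygote
        dosage = np.zeros((10, 10), dtype=np.int8)
        np.fill_diagonal(dosage, 1)
        m = matrix_from(dosage)
        assert tajimas_d(m, m.sample_ids, GenomicInterval("chr1", 0, 1000)) < 0


class TestSiteDensity:
    def test_counts_per_kb(self):
        pos = np.array([100, 200, 300, 400, 500])
        w = GenomicInterval("chr1", 0, 50_000)
        assert site_density(pos, w) == pytest.approx(0.1)

    def test_empty_window(self):
        assert site_density(np.array([100]), GenomicInterval("chr1", 10_000, 20_000)) == 0.0

    def test_indels_counted_separately_from_snps(self):
        import pandas as pd

        from sweepcross.popstats import WindowSpec, windowed_statistics

        m = matrix_from([[0, 1], [1, 2], [2, 0]], positions=[100, 200])
        indels = pd.DataFrame({"chrom": ["chr1"] * 3, "pos": [150, 250, 350]})
        tab = windowed_statistics(
            m, m.sample_ids, {"chr1": 1000}, WindowSpec(1000, 1000),
            indel_positions=indels,
        )
        assert tab["snp_density"].iloc[0] == pytest.approx(2.0)
        assert tab["indel_density"].iloc[0] == pytest.approx(3.0)


class TestGenotypeR2:
    def test_identical_vectors(self):
        a = np.array([0, 1, 2, 0, 1])
        assert genotype_r2(a, a) == pytest.approx(1.0)

    def test_zero_covariance(self):
        assert genotype_r2([0, 0, 2, 2], [0, 2, 0, 2]) == pytest.approx(0.0)

    def test_monomorphic_undefined(self):
        assert np.isnan(genotype_r2([1, 1, 1, 1], [0, 1, 2, 0]))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_textbook_pearson(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 3, size=20)
        b = rng.integers(0, 3, size=20)
        if len(set(a)) == 1 or len(set(b)) == 1:
            return
        assert genotype_r2(a, b) == pytest.approx(oracles.brute_r2(a, b), abs=1e-12)


class TestLdDecay:
    def test_recombination_shortens_half_decay(self, ld_decay_replicates):
        low_r, high_r = ld_decay_replicates
        assert np.nanmean(low_r) > np.nanmean(high_r)

    def test_constant_curve_has_no_half_decay(self):
        # two perfectly correlated SNP pairs at every distance: r2 == 1 in
        # every occupied bin, so the half-maximum is never crossed
        dosage = np.array(
            [[0, 0, 0, 0], [1, 1, 1, 1], [2, 2, 2, 2], [2, 2, 2, 2],
             [0, 0, 0, 0], [1, 1, 1, 1]],
            dtype=np.int8,
        )
        m = matrix_from(dosage, positions=[100, 5100, 10100, 15100])
        curve = ld_decay(m, m.sample_ids, max_dist=20_000, bin_width=5_000)
        assert curve.half_decay_distance is None

    def test_single_occupied_bin_undefined(self):
        dosage = np.array([[0, 0], [1, 1], [2, 2], [0, 0], [1, 1], [2, 2]],
                          dtype=np.int8)
        m = matrix_from(dosage, positions=[100, 200])
        curve = ld_decay(m, m.sample_ids, max_dist=10_000, bin_width=10_000)
        assert curve.half_decay_distance is None
        assert curve.n_pairs.sum() == 1


class TestDxy:
    def test_fixed_difference(self):
        a = np.zeros((3, 4), dtype=np.int8)
        b = np.full((3, 4), 2, dtype=np.int8)
        m = matrix_from(np.vstack([a, b]))
        w = GenomicInterval("chr1", 0, 400)
        got = dxy(m, m.sample_ids[:3], m.sample_ids[3:], w)
        assert got == pytest.approx(4 / 400)

    def test_same_group_equals_mean_pairwise_distance(self):
        rng = np.random.default_rng(2)
        m = random_matrix(rng, 6, 30)
        w = GenomicInterval("chr1", 0, 10_000)
        got = dxy(m, m.sample_ids, m.sample_ids, w)
        # degenerate case: mean over all pairs including self-pairs
        expect = oracles.brute_dxy(m.dosage, m.dosage, 10_000)
        assert got == pytest.approx(expect, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        m = random_matrix(rng, 16, 40, missing_rate=0.1)
        w = GenomicInterval("chr1", 0, 10_000)
        got = dxy(m, m.sample_ids[:8], m.sample_ids[8:], w)
        expect = oracles.brute_dxy(m.dosage[:8], m.dosage[8:], 10_000)
        assert got == pytest.approx(expect, abs=1e-10)

    def test_non_negative(self):
        rng = np.random.default_rng(3)
        m = random_matrix(rng, 8, 25, missing_rate=0.2)
        w = GenomicInterval("chr1", 0, 10_000)
        v = dxy(m, m.sample_ids[:4], m.sample_ids[4:], w)
        assert v >= 0
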