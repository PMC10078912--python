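"""Background SFS, sweep-distorted spectra, CLR scan and omega statistic."""

import numpy as np
import pytest

import oracles
from sweepcross.io_core import GenotypeMatrix
from sweepcross.popstats import _r2_matrix
from sweepcross.sweepscan import (
    BackgroundSFS,
    background_sfs,
    clr_scan,
    default_alpha_grid,
    derived_counts,
    omega_at,
    omega_from_r2,
    omega_scan,
    projection_matrix,
    scan_grid,
    sweep_spectrum,
)


def matrix_from(dosage, positions, outgroup_rows=0, chrom="chr1"):
    dosage = np.asarray(dosage, dtype=np.int8)
    s = dosage.shape[1]
    n = dosage.shape[0]
    ids = [f"s{i}" for i in range(n - outgroup_rows)] + [
        f"og{i}" for i in range(outgroup_rows)
    ]
    return GenotypeMatrix(
        sample_ids=ids,
        chrom=np.array([chrom] * s, dtype=object),
        pos=np.asarray(positions),
        ref=np.array(["A"] * s, dtype=object),
        alt=np.array(["G"] * s, dtype=object),
        dosage=dosage,
    )


class TestBackgroundSfs:
    def test_all_singletons_give_point_mass(self):
        dosage = np.zeros((6, 8), dtype=np.int8)
        dosage[0, :4] = 1
        dosage[1, 4:] = 1
        dosage = np.vstack([dosage, np.zeros((2, 8), dtype=np.int8)])  # outgroup
        m = matrix_from(dosage, np.arange(1, 9) * 10, outgroup_rows=2)
        sfs = background_sfs(m, m.sample_ids[:6], m.sample_ids[6:])
        assert sfs.n == 12
        assert sfs.phi[1] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(4))
    def test_normalized_for_any_input(self, seed):
        rng = np.random.default_rng(seed)
        dosage = rng.integers(0, 3, size=(8, 30)).astype(np.int8)
        dosage[6:] = 0  # fixed ancestral outgroup
        m = matrix_from(dosage, np.arange(1, 31) * 10, outgroup_rows=2)
        sfs = background_sfs(m, m.sample_ids[:6], m.sample_ids[6:])
        assert sfs.phi.sum() == pytest.approx(1.0)
        assert np.all(sfs.phi >= 0)

    def test_projection_matches_exact_hypergeometric(self):
        h = projection_matrix(6, 4)
        for j in range(7):
            expect = oracles.hypergeom_projection_exact(6, j, 4)
            assert np.allclose(h[j], expect, atol=1e-12)

    def test_projected_spectrum_matches_enumeration(self):
        # sites with derived counts at n=6, projected to n=4
        counts = [1, 1, 2, 3, 5]
        acc = np.zeros(5)
        for j in counts:
            acc += oracles.hypergeom_projection_exact(6, j, 4)
        acc[0] = acc[4] = 0.0
        expect = acc / acc.sum()
        dosage = np.zeros((5, len(counts)), dtype=np.int8)
        for col, j in enumerate(counts):
            # three diploids hold the focal alleles (n_project collapses to 6)
            full = [2] * (j // 2) + [1] * (j % 2)
            full += [0] * (3 - len(full))
            dosage[:3, col] = full
        m = matrix_from(dosage, np.arange(1, len(counts) + 1) * 10,
                        outgroup_rows=2)
        sfs = background_sfs(m, m.sample_ids[:3], m.sample_ids[3:], n_project=4)
        assert np.allclose(sfs.phi[1:4], expect[1:4], atol=1e-10)

    def test_unfolded_requires_outgroup(self):
        m = matrix_from(np.array([[1, 0], [0, 1]], dtype=np.int8), [10, 20])
        with pytest.raises(ValueError, match="outgroup"):
            background_sfs(m, m.sample_ids, None, folded=False)


class TestSweepSpectrum:
    def _sfs(self, n=6, seed=0):
        rng = np.random.default_rng(seed)
        phi = np.zeros(n + 1)
        phi[1:n] = rng.dirichlet(np.ones(n - 1))
        return BackgroundSFS(n=n, phi=phi)

    def test_full_escape_returns_background(self):
        sfs = self._sfs()
        assert np.allclose(sweep_spectrum(sfs, 1.0), sfs.phi, atol=1e-14)

    def test_zero_escape_undefined(self):
        assert sweep_spectrum(self._sfs(), 0.0) is None

    @pytest.mark.parametrize("pe", [0.05, 0.3, 0.7, 0.95])
    def test_n3_matches_full_enumeration(self, pe):
        sfs = self._sfs(n=3, seed=1)
        got = sweep_spectrum(sfs, pe)
        expect = oracles.sweep_spectrum_reference(sfs.phi, 3, pe)
        assert np.allclose(got, expect, atol=1e-12)

    @pytest.mark.parametrize("pe", [1e-3, 0.2, 0.9])
    def test_normalized_when_defined(self, pe):
        got = sweep_spectrum(self._sfs(n=10, seed=2), pe)
        assert got.sum() == pytest.approx(1.0)
        assert np.all(got >= 0)

    def test_continuity_near_one(self):
        sfs = self._sfs(n=8, seed=3)
        a = sweep_spectrum(sfs, 0.999)
        b = sweep_spectrum(sfs, 0.9999)
        assert np.max(np.abs(a - b)) < 1e-2


class TestClrScan:
    def _neutral_iid_matrix(self, rng, n_dip=10, s=120, length=200_000):
        """Sites drawn iid from a neutral-ish spectrum, fixed-ancestral outgroup."""
        n = 2 * n_dip
        weights = 1.0 / np.arange(1, n)
        probs = weights / weights.sum()
        dosage = np.zeros((n_dip + 2, s), dtype=np.int8)
        positions = np.sort(rng.choice(np.arange(1, length), s, replace=False))
        for col in range(s):
            j = rng.choice(np.arange(1, n), p=probs)
            alleles = np.zeros(n, dtype=np.int8)
            alleles[rng.choice(n, size=j, replace=False)] = 1
            dosage[:n_dip, col] = alleles[0::2] + alleles[1::2]
        return matrix_from(dosage, positions, outgroup_rows=2)

    def test_neutral_iid_lambda_nonnegative_and_small(self):
        rng = np.random.default_rng(0)
        m = self._neutral_iid_matrix(rng)
        pop, og = m.sample_ids[:10], m.sample_ids[10:]
        track = clr_scan(m, pop, og, {"chr1": 200_000}, grid_spacing=5_000)
        assert np.all(track["clr"] >= -1e-9)
        # iid data carry no spatial sweep signal: Lambda stays modest
        assert track["clr"].max() < 30

    def test_window_halves_when_alpha_doubles(self):
        eps = 0.01
        d1 = -np.log(eps) / 1e-4
        d2 = -np.log(eps) / 2e-4
        assert d2 == pytest.approx(d1 / 2)

    def test_lambda_invariant_to_monomorphic_sites(self):
        rng = np.random.default_rng(1)
        m = self._neutral_iid_matrix(rng, s=60)
        pop, og = m.sample_ids[:10], m.sample_ids[10:]
        base = clr_scan(m, pop, og, {"chr1": 200_000}, grid_spacing=20_000)
        # add monomorphic columns (all hom-alt in pop, absent in outgroup)
        extra = np.zeros((12, 3), dtype=np.int8)
        extra[:10] = 2
        dosage = np.hstack([m.dosage, extra])
        pos = np.concatenate([m.pos, [190_001, 190_501, 191_001]])
        order = np.argsort(pos)
        m2 = matrix_from(dosage[:, order], pos[order], outgroup_rows=2)
        again = clr_scan(m2, pop, og, {"chr1": 200_000}, grid_spacing=20_000)
        assert np.allclose(base["clr"], again["clr"], atol=1e-9)

    def test_empty_alpha_grid_rejected(self):
        rng = np.random.default_rng(2)
        m = self._neutral_iid_matrix(rng, s=40)
        with pytest.raises(ValueError, match="alpha"):
            clr_scan(m, m.sample_ids[:10], m.sample_ids[10:], {"chr1": 200_000},
                     alpha_grid=np.array([]))

    def test_shared_grid_with_omega(self):
        g = scan_grid(100_000, 1000)
        assert g[0] == 500 and g[-1] < 100_000
        rng = np.random.default_rng(3)
        m = self._neutral_iid_matrix(rng, s=60, length=50_000)
        pop, og = m.sample_ids[:10], m.sample_ids[10:]
        track_c = clr_scan(m, pop, og, {"chr1": 50_000}, grid_spacing=2_000)
        track_o = omega_scan(m, pop, {"chr1": 50_000}, grid_spacing=2_000)
        assert np.array_equal(track_c["position"], track_o["position"])


class TestOmega:
    def test_constant_r2_gives_unity(self):
        k = 5
        r2 = np.full((2 * k, 2 * k), 0.4)
        np.fill_diagonal(r2, 1.0)
        om, nl, nr, floored = omega_from_r2(
            r2[:k, :k], r2[k:, k:], r2[:k, k:]
        )
        assert om == pytest.approx(1.0)
        assert not floored

    def test_perfect_blocks_hit_floor(self):
        k = 4
        within = np.ones((k, k))
        between = np.zeros((k, k))
        om, _, _, floored = omega_from_r2(within, within, between)
        assert floored
        assert om == pytest.approx(1.0 / 1e-6)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_split_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_snps = 8
        positions = np.sort(rng.choice(np.arange(100, 10_000), n_snps, False))
        dosage = rng.integers(0, 3, size=(12, n_snps)).astype(np.int8)
        # ensure polymorphism at every site
        for c in range(n_snps):
            if len(set(dosage[:, c])) == 1:
                dosage[0, c] = (dosage[0, c] + 1) % 3
        centre = int((positions[3] + positions[4]) // 2)
        r2 = _r2_matrix(dosage)
        got, nl, nr, _ = omega_at(centre, positions, dosage,
                                  min_snps_side=3, max_window_bp=20_000)
        expect = oracles.brute_omega(positions, r2, centre, min_side=3)
        assert got == pytest.approx(expect, abs=1e-10)

    def test_insufficient_snps_undefined(self):
        positions = np.array([100, 200, 5000])
        dosage = np.array([[0, 1, 2]] * 4, dtype=np.int8)
        om, nl, nr, fl = omega_at(1000, positions, dosage)
        assert np.isnan(om)

    def test_scan_deterministic(self):
        rng = np.random.default_rng(5)
        dosage = rng.integers(0, 3, size=(10, 40)).astype(np.int8)
        positions = np.sort(rng.choice(np.arange(1, 50_000), 40, False))
        m = matrix_from(dosage, positions)
        a = omega_scan(m, m.sample_ids, {"chr1": 50_000}, grid_spacing=5_000)
        b = omega_scan(m, m.sample_ids, {"chr1": 50_000}, grid_spacing=5_000)
        assert a.equals(b)
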