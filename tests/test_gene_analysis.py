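"""Gene overlap, orthologue inference, enrichment and fixed differences."""

import numpy as np
import pytest
from scipy import stats

import oracles
from sweepcross.gene_analysis import (
    FixedDifference,
    by_adjust,
    filter_hits,
    fixed_differences,
    genes_in_regions,
    go_enrichment,
    overlap_chisq,
    reciprocal_best_hits,
)
from sweepcross.introgression import bh_adjust
from sweepcross.io_core import (
    GeneAnnotation,
    GenomicInterval,
    GenotypeMatrix,
    SimilarityHit,
)


def hit(q, s, ident=80.0, e=1e-20, bits=100.0):
    return SimilarityHit(q, s, ident, e, bits)


class TestGenesInRegions:
    GENES = [
        GeneAnnotation("g1", "chr1", 100, 200),
        GeneAnnotation("g2", "chr1", 300, 400),
        GeneAnnotation("g3", "chr2", 100, 200),
    ]

    def test_one_bp_overlap_suffices(self):
        # region ending at 0-based 299 misses g2 (1-based start 300)...
        assert genes_in_regions(self.GENES, [GenomicInterval("chr1", 150, 299)]) == ["g1"]
        # ...while one more base catches g2's first base
        assert genes_in_regions(self.GENES, [GenomicInterval("chr1", 150, 300)]) == ["g1", "g2"]

    def test_boundary_touch_is_not_overlap(self):
        # gene 1-based [100, 200] is 0-based [99, 200); region starting at
        # 200 shares no base with it
        regions = [GenomicInterval("chr1", 200, 300)]
        assert genes_in_regions([self.GENES[0]], regions) == []
        # ...but a region starting at 199 overlaps the gene's last base
        assert genes_in_regions(
            [self.GENES[0]], [GenomicInterval("chr1", 199, 300)]
        ) == ["g1"]

    def test_empty_regions(self):
        assert genes_in_regions(self.GENES, []) == []

    def test_chromosome_must_match(self):
        assert genes_in_regions(self.GENES, [GenomicInterval("chr2", 100, 300)]) == [
            "g3"
        ]


class TestFilterHits:
    @pytest.mark.parametrize(
        "evalue,identity,kept",
        [
            (1e-5, 75.0, True),
            (1e-4, 75.0, False),  # e-value boundary is strict
            (1e-6, 60.0, False),  # identity boundary is strict
            (9.9e-5, 60.01, True),
        ],
    )
    def test_strict_boundaries(self, evalue, identity, kept):
        hits = [hit("q", "s", ident=identity, e=evalue)]
        assert (len(filter_hits(hits)) == 1) is kept


class TestReciprocalBestHits:
    def test_symmetric_unique_bests_pair(self):
        ab = [hit("a1", "b1", bits=200), hit("a1", "b2", bits=100)]
        ba = [hit("b1", "a1", bits=190)]
        pairs = reciprocal_best_hits(ab, ba)
        assert [(p.gene_a, p.gene_b) for p in pairs] == [("a1", "b1")]

    def test_non_reciprocal_rejected(self):
        ab = [hit("a1", "b1", bits=200)]
        ba = [hit("b1", "a2", bits=300), hit("b1", "a1", bits=100)]
        assert reciprocal_best_hits(ab, ba) == []

    def test_tie_resolved_by_evalue_then_subject_id(self):
        # equal bitscores: lower e-value wins; equal again: smaller id wins
        ab = [
            hit("a1", "b2", bits=100, e=1e-10),
            hit("a1", "b1", bits=100, e=1e-10),
        ]
        ba = [hit("b1", "a1", bits=100), hit("b2", "a1", bits=100)]
        pairs = reciprocal_best_hits(ab, ba)
        assert [(p.gene_a, p.gene_b) for p in pairs] == [("a1", "b1")]
        ab2 = [
            hit("a1", "b2", bits=100, e=1e-20),
            hit("a1", "b1", bits=100, e=1e-10),
        ]
        assert reciprocal_best_hits(ab2, ba)[0].gene_b == "b2"

    def test_direction_swap_gives_same_pairs(self):
        rng = np.random.default_rng(7)
        a_genes = [f"a{i}" for i in range(8)]
        b_genes = [f"b{i}" for i in range(8)]
        ab, ba = [], []
        for a in a_genes:
            for b in rng.choice(b_genes, size=4, replace=False):
                ab.append(hit(a, str(b), bits=float(rng.integers(50, 300))))
        for b in b_genes:
            for a in rng.choice(a_genes, size=4, replace=False):
                ba.append(hit(str(b), str(a), bits=float(rng.integers(50, 300))))
        fwd = {(p.gene_a, p.gene_b) for p in reciprocal_best_hits(ab, ba)}
        rev = {(p.gene_b, p.gene_a) for p in reciprocal_best_hits(ba, ab)}
        assert fwd == rev


class TestOverlapChisq:
    def test_expected_overlap_gives_zero(self):
        # k = nA * nB / N exactly
        chi2, p = overlap_chisq(100, 20, 30, 6)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_hand_computation(self):
        # N=100, nA=20, nB=30, k=12: table [[12, 8], [18, 62]]
        obs = np.array([[12, 8], [18, 62]], dtype=float)
        expected = np.outer(obs.sum(1), obs.sum(0)) / 100
        chi2_hand = ((obs - expected) ** 2 / expected).sum()
        chi2, p = overlap_chisq(100, 20, 30, 12)
        assert chi2 == pytest.approx(chi2_hand, abs=1e-12)
        assert p == pytest.approx(stats.chi2.sf(chi2_hand, 1), abs=1e-12)

    def test_chisq_grows_away_from_expectation(self):
        base = overlap_chisq(100, 20, 30, 6)[0]
        assert overlap_chisq(100, 20, 30, 9)[0] > overlap_chisq(100, 20, 30, 7)[0] > base
        assert overlap_chisq(100, 20, 30, 3)[0] > overlap_chisq(100, 20, 30, 5)[0] > base

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            overlap_chisq(100, 20, 30, 25)


def toy_matrix(dosages, positions, chrom="chr1"):
    dosages = np.asarray(dosages, dtype=np.int8)
    n = dosages.shape[0]
    return GenotypeMatrix(
        sample_ids=[f"s{i}" for i in range(n)],
        chrom=np.array([chrom] * len(positions), dtype=object),
        pos=np.asarray(positions),
        ref=np.array(["A"] * len(positions), dtype=object),
        alt=np.array(["G"] * len(positions), dtype=object),
        dosage=dosages,
    )


class TestFixedDifferences:
    GENE = [GeneAnnotation("g1", "chr1", 2000, 3000)]

    def test_engineered_sites_counted_by_the_rule(self):
        # gene body 2000-3000, flank 1000 -> window [1000, 4000]
        positions = [1500, 1600, 2500, 2600, 2700, 3500, 3600, 5000]
        #            fix   het   fix  same  miss  fix   poly  outside
        focal = [
            [2, 1, 2, 0, -1, 0, 2, 2],
            [2, 1, 2, 0, -1, 0, 2, 2],
        ]
        contrast = [
            [0, 0, 0, 0, 0, 2, 2, 0],
            [0, 0, 0, 0, 0, 2, 1, 0],
        ]
        m = toy_matrix(np.vstack([focal, contrast]), positions)
        out = fixed_differences(m, ["s0", "s1"], ["s2", "s3"], self.GENE)
        assert [f.pos for f in out] == [1500, 2500, 3500]
        assert out[0].focal_allele == "G" and out[0].contrast_allele == "A"
        assert out[2].focal_allele == "A" and out[2].contrast_allele == "G"

    def test_heterozygote_blocks_fixation(self):
        m = toy_matrix([[2, 2], [1, 2], [0, 0], [0, 0]], [2500, 2600])
        out = fixed_differences(m, ["s0", "s1"], ["s2", "s3"], self.GENE)
        assert [f.pos for f in out] == [2600]

    def test_adding_a_sample_never_adds_sites(self):
        m3 = toy_matrix([[2, 2], [2, 2], [0, 0], [0, 0]], [2500, 2600])
        base = fixed_differences(m3, ["s0", "s1"], ["s2", "s3"], self.GENE)
        m4 = toy_matrix(
            [[2, 2], [2, 2], [1, 2], [0, 0], [0, 0]], [2500, 2600]
        )
        bigger = fixed_differences(
            m4, ["s0", "s1", "s2"], ["s3", "s4"], self.GENE
        )
        assert {f.pos for f in bigger} <= {f.pos for f in base}

    def test_overlapping_groups_rejected(self):
        m = toy_matrix([[0, 0], [2, 2]], [2500, 2600])
        with pytest.raises(ValueError, match="overlap"):
            fixed_differences(m, ["s0"], ["s0", "s1"], self.GENE)

    def test_missing_tolerated_but_one_call_required(self):
        m = toy_matrix([[2], [-1], [-1], [0]], [2500])
        out = fixed_differences(m, ["s0", "s1"], ["s2", "s3"], self.GENE)
        assert len(out) == 1
        m_none = toy_matrix([[-1], [-1], [0], [0]], [2500])
        assert (
            fixed_differences(m_none, ["s0", "s1"], ["s2", "s3"], self.GENE) == []
        )


class TestGoEnrichment:
    def test_term_covering_universe_is_not_enriched(self):
        universe = {f"g{i}" for i in range(10)}
        res = go_enrichment({"g0", "g1"}, universe, {"T": set(universe)})
        assert res[0].p == pytest.approx(1.0)

    def test_p_matches_exact_hypergeometric_tail(self):
        # k = n = K = 2 in a universe of 10
        res = go_enrichment({"g0", "g1"}, {f"g{i}" for i in range(10)},
                            {"T": {"g0", "g1"}})
        expect = oracles.hypergeom_tail_exact(k=2, big_n=10, big_k=2, n=2)
        assert res[0].p == pytest.approx(expect, abs=1e-10)

    def test_adjustment_ordering_by_ge_bh_ge_p(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=25)
        bh = bh_adjust(p)
        by = by_adjust(p)
        assert np.all(by >= bh - 1e-12)
        assert np.all(bh >= p - 1e-12)

    def test_zero_count_terms_skipped(self):
        res = go_enrichment(
            {"g0"}, {"g0", "g1", "g2"}, {"T1": {"g1"}, "T2": {"g0"}}
        )
        assert [r.term for r in res] == ["T2"]

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            go_enrichment(set(), set(), {"T": {"g"}})
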