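"""Gene-level downstream analyses of selection regions.

Covers gene/region overlap, similarity-hit filtering and reciprocal best
hits, chi-square overlap enrichment between gene sets, fixed inter-group
differences near genes, and GO-term enrichment (one-sided Fisher exact with
Benjamini-Yekutieli adjustment, the conservative FDR control valid under
arbitrary dependence between terms).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import (
    MISSING,
    GeneAnnotation,
    GenomicInterval,
    GenotypeMatrix,
    SimilarityHit,
)


# ---------------------------------------------------------------------------
# gene / region overlap
# ---------------------------------------------------------------------------

def genes_in_regions(
    genes: list[GeneAnnotation], regions: list[GenomicInterval]
) -> list[str]:
    """Gene ids whose interval overlaps any region by >= 1 bp."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append(r)
    out = []
    for g in genes:
        giv = g.interval()
        for r in by_chrom.get(g.chrom, ()):
            if giv.start < r.end and r.start < giv.end:
                out.append(g.gene_id)
                break
    return out


# ---------------------------------------------------------------------------
# similarity hits and orthologues
# ---------------------------------------------------------------------------

def filter_hits(
    hits: list[SimilarityHit],
    max_evalue: float = 1e-4,
    min_identity: float = 60.0,
) -> list[SimilarityHit]:
    """Keep hits with e-value strictly below and identity strictly above cutoffs."""
    return [
        h
        for h in hits
        if h.evalue < max_evalue and h.percent_identity > min_identity
    ]


@dataclass(frozen=True)
class OrthologuePair:
    gene_a: str
    gene_b: str
    forward: SimilarityHit
    reverse: SimilarityHit


def _best_hits(hits: list[SimilarityHit]) -> dict[str, SimilarityHit]:
    """Best hit per query: highest bitscore, then lowest e-value, then
    lexicographically smallest subject id (deterministic tie rule)."""
    best: dict[str, SimilarityHit] = {}
    for h in hits:
        cur = best.get(h.query_id)
        if cur is None or (
            (-h.bitscore, h.evalue, h.subject_id)
            < (-cur.bitscore, cur.evalue, cur.subject_id)
        ):
            best[h.query_id] = h
    return best


def reciprocal_best_hits(
    hits_ab: list[SimilarityHit], hits_ba: list[SimilarityHit]
) -> list[OrthologuePair]:
    """Pairs where each gene is the other's best (filtered) hit."""
    best_ab = _best_hits(hits_ab)
    best_ba = _best_hits(hits_ba)
    pairs = []
    for a, fwd in sorted(best_ab.items()):
        rev = best_ba.get(fwd.subject_id)
        if rev is not None and rev.subject_id == a:
            pairs.append(OrthologuePair(a, fwd.subject_id, fwd, rev))
    return pairs


# ---------------------------------------------------------------------------
# overlap enrichment
# ---------------------------------------------------------------------------

def overlap_chisq(
    n_universe: int, n_set_a: int, n_set_b: int, k_overlap: int
) -> tuple[float, float]:
    """Pearson chi-square (1 df, no continuity correction) for set overlap.

    Tests whether two gene sets drawn from a universe of ``n_universe`` genes
    share more members than expected by chance.  Returns (chi2, p); (nan, nan)
    when any expected cell is zero.
    """
    if k_overlap > min(n_set_a, n_set_b) or max(n_set_a, n_set_b) > n_universe:
        raise ValueError("inconsistent overlap counts")
    obs = np.array(
        [
            [k_overlap, n_set_a - k_overlap],
            [n_set_b - k_overlap, n_universe - n_set_a - n_set_b + k_overlap],
        ],
        dtype=float,
    )
    if obs.min() < 0:
        raise ValueError("inconsistent overlap counts")
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    expected = row @ col / n_universe
    if np.any(expected == 0):
        return float("nan"), float("nan")
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    return chi2, float(stats.chi2.sf(chi2, df=1))


# ---------------------------------------------------------------------------
# fixed differences
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FixedDifference:
    chrom: str
    pos: int
    focal_allele: str
    contrast_allele: str
    gene_id: str
    offset: int  # bp from gene start (negative = upstream of the gene body)


def fixed_differences(
    matrix: GenotypeMatrix,
    focal_samples: list[str],
    contrast_samples: list[str],
    genes: list[GeneAnnotation],
    flank: int = 1000,
) -> list[FixedDifference]:
    """Sites fixed for different alleles in focal vs contrast groups near genes.

    A site is reported when every called focal sample is homozygous for one
    allele, every called contrast sample homozygous for the other, each group
    has >= 1 call, and the site lies within a gene body +/- ``flank`` bp.
    """
    if set(focal_samples) & set(contrast_samples):
        raise ValueError("focal and contrast groups overlap")
    fi = matrix.sample_indices(focal_samples)
    ci = matrix.sample_indices(contrast_samples)
    fd = matrix.dosage[fi]
    cd = matrix.dosage[ci]

    def _fixed_dosage(block: np.ndarray) -> np.ndarray:
        """Per-site 0 or 2 when all called samples share that homozygote, else -9."""
        called = block != MISSING
        any_called = called.any(axis=0)
        all0 = np.where(called, block == 0, True).all(axis=0) & any_called
        all2 = np.where(called, block == 2, True).all(axis=0) & any_called
        out = np.full(block.shape[1], -9, dtype=np.int8)
        out[all0] = 0
        out[all2] = 2
        return out

    f_fix = _fixed_dosage(fd)
    c_fix = _fixed_dosage(cd)
    candidate = (f_fix >= 0) & (c_fix >= 0) & (f_fix != c_fix)

    results: list[FixedDifference] = []
    for g in genes:
        lo = g.start - flank  # 1-based inclusive bounds
        hi = g.end + flank
        mask = (
            candidate
            & (matrix.chrom == g.chrom)
            & (matrix.pos >= lo)
            & (matrix.pos <= hi)
        )
        for j in np.nonzero(mask)[0]:
            focal_allele = matrix.ref[j] if f_fix[j] == 0 else matrix.alt[j]
            contrast_allele = matrix.ref[j] if c_fix[j] == 0 else matrix.alt[j]
            results.append(
                FixedDifference(
                    chrom=str(matrix.chrom[j]),
                    pos=int(matrix.pos[j]),
                    focal_allele=str(focal_allele),
                    contrast_allele=str(contrast_allele),
                    gene_id=g.gene_id,
                    offset=int(matrix.pos[j]) - g.start,
                )
            )
    return results


# ---------------------------------------------------------------------------
# GO enrichment
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentResult:
    term: str
    k: int            # annotated genes in the set
    n: int            # set size
    big_k: int        # annotated genes in the universe
    big_n: int        # universe size
    odds_ratio: float
    p: float
    q: float


def go_enrichment(
    gene_set: set[str] | list[str],
    universe: set[str] | list[str],
    term_map: dict[str, set[str]] | pd.DataFrame,
) -> list[EnrichmentResult]:
    """One-sided Fisher exact enrichment per term, BY-adjusted across terms.

    ``term_map`` maps term -> annotated genes (or a two-column gene/term
    DataFrame).  Terms with no annotated gene in the set are skipped.
    """
    from statsmodels.stats.multitest import multipletests

    gene_set = set(gene_set)
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    if not gene_set <= universe:
        raise ValueError("gene_set must be a subset of the universe")
    if isinstance(term_map, pd.DataFrame):
        gcol, tcol = term_map.columns[:2]
        mapping: dict[str, set[str]] = {}
        for gene, term in zip(term_map[gcol], term_map[tcol]):
            mapping.setdefault(str(term), set()).add(str(gene))
        term_map = mapping

    n = len(gene_set)
    big_n = len(universe)
    rows = []
    for term in sorted(term_map):
        annotated = term_map[term] & universe
        big_k = len(annotated)
        k = len(annotated & gene_set)
        if k == 0:
            continue
        table = [[k, n - k], [big_k - k, big_n - n - (big_k - k)]]
        odds, p = stats.fisher_exact(table, alternative="greater")
        rows.append((term, k, big_k, float(odds), float(p)))
    if not rows:
        return []
    q = multipletests([r[4] for r in rows], method="fdr_by")[1]
    return [
        EnrichmentResult(term, k, n, big_k, big_n, odds, p, float(qv))
        for (term, k, big_k, odds, p), qv in zip(rows, q)
    ]


def by_adjust(p_values) -> np.ndarray:
    """Benjamini-Yekutieli q-values, input order preserved."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_by")[1]
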