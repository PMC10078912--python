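"""Windowed diversity statistics and LD decay.

All statistics operate on unphased dosages.  Pairwise genotype distance uses
the expected allele-mismatch convention: for dosages a, b in {0,1,2} the
per-site distance is a/2 + b/2 - a*b/2, i.e. heterozygote-heterozygote pairs
count 1/2.  Per-base-pair statistics are normalized by the full window length
(accessible-site corrections are assumed to have happened upstream).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_core import MISSING, GenomicInterval, GenotypeMatrix, allele_counts


@dataclass(frozen=True)
class WindowSpec:
    size: int
    step: int

    def __post_init__(self) -> None:
        if self.size <= 0 or self.step <= 0:
            raise ValueError("window size and step must be positive")


@dataclass
class LDDecayCurve:
    bin_edges: np.ndarray     # bp, length n_bins + 1, covering (0, max_dist]
    mean_r2: np.ndarray       # nan where a bin has no pairs
    n_pairs: np.ndarray
    half_decay_distance: float | None


def iter_windows(chrom_lengths: dict[str, int], spec: WindowSpec) -> list[GenomicInterval]:
    """Tile each chromosome with windows; the last window is truncated."""
    windows = []
    for chrom, length in chrom_lengths.items():
        if length <= 0:
            raise ValueError(f"chromosome {chrom} has non-positive length")
        start = 0
        while start < length:
            windows.append(GenomicInterval(chrom, start, min(start + spec.size, length)))
            start += spec.step
    return windows


# ---------------------------------------------------------------------------
# diversity
# ---------------------------------------------------------------------------

def _pop_dosage(matrix: GenotypeMatrix, pop_samples: list[str],
                interval: GenomicInterval | None) -> np.ndarray:
    idx = matrix.sample_indices(pop_samples)
    dos = matrix.dosage[idx]
    if interval is not None:
        dos = dos[:, matrix.variant_mask(interval)]
    return dos


def nucleotide_diversity(matrix: GenotypeMatrix, pop_samples: list[str],
                         interval: GenomicInterval) -> float:
    """Per-bp nucleotide diversity (pi) in a window.

    pi = sum_sites 2*p*(1-p) * n/(n-1) / window_length, with n the
    non-missing allele count at each site; sites with n < 2 are skipped.
    """
    if not pop_samples:
        raise ValueError("empty population")
    dos = _pop_dosage(matrix, pop_samples, interval)
    alt, n = allele_counts(dos)
    ok = n >= 2
    alt, n = alt[ok], n[ok]
    if alt.size == 0:
        return 0.0
    p = alt / n
    return float(np.sum(2.0 * p * (1.0 - p) * n / (n - 1)) / len(interval))


# Tajima (1989) normalizing constants

def _tajima_constants(n: int) -> dict[str, float]:
    a1 = np.sum(1.0 / np.arange(1, n))
    a2 = np.sum(1.0 / np.arange(1, n) ** 2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "e1": e1, "e2": e2}


def tajimas_d(matrix: GenotypeMatrix, pop_samples: list[str],
              interval: GenomicInterval) -> float:
    """Tajima's D in a window; nan when S < 3 segregating sites or n < 4.

    The sample size for the normalizing constants is the window's minimum
    per-site non-missing allele count (conservative under missing data).
    """
    if not pop_samples:
        raise ValueError("empty population")
    dos = _pop_dosage(matrix, pop_samples, interval)
    alt, n = allele_counts(dos)
    called = n >= 2
    alt, n = alt[called], n[called]
    seg = (alt > 0) & (alt < n)
    s = int(seg.sum())
    if s < 3:
        return float("nan")
    n_min = int(n[seg].min())
    if n_min < 4:
        return float("nan")
    p = alt[seg] / n[seg]
    theta_pi = float(np.sum(2.0 * p * (1.0 - p) * n[seg] / (n[seg] - 1)))
    k = _tajima_constants(n_min)
    theta_w = s / k["a1"]
    var = k["e1"] * s + k["e2"] * s * (s - 1)
    return float((theta_pi - theta_w) / np.sqrt(var))


def site_density(positions: np.ndarray, interval: GenomicInterval,
                 chrom: np.ndarray | None = None) -> float:
    """Count of records in the window per kb.

    ``positions`` are 1-based; pass the matching ``chrom`` array when the
    positions span several chromosomes.
    """
    pos0 = np.asarray(positions) - 1
    mask = (pos0 >= interval.start) & (pos0 < interval.end)
    if chrom is not None:
        mask &= np.asarray(chrom, dtype=object) == interval.chrom
    return float(mask.sum() / (len(interval) / 1000.0))


# ---------------------------------------------------------------------------
# linkage disequilibrium
# ---------------------------------------------------------------------------

def genotype_r2(dosage_a: np.ndarray, dosage_b: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors.

    Computed over pairwise-complete samples; nan when fewer than 3 complete
    pairs or either site is monomorphic among them (composite genotype r2,
    the unphased convention).
    """
    a = np.asarray(dosage_a, dtype=np.float64)
    b = np.asarray(dosage_b, dtype=np.float64)
    ok = (a != MISSING) & (b != MISSING)
    if ok.sum() < 3:
        return float("nan")
    a, b = a[ok], b[ok]
    va = a - a.mean()
    vb = b - b.mean()
    den = np.sqrt((va @ va) * (vb @ vb))
    if den == 0:
        return float("nan")
    return float((va @ vb) / den) ** 2


def _r2_matrix(dos: np.ndarray) -> np.ndarray:
    """All-pairs genotype r2 for a complete-data dosage block (samples x sites)."""
    x = dos.astype(np.float64)
    if np.any(dos == MISSING):
        s = dos.shape[1]
        out = np.empty((s, s))
        for i in range(s):
            out[i, i] = 1.0
            for j in range(i + 1, s):
                out[i, j] = out[j, i] = genotype_r2(dos[:, i], dos[:, j])
        return out
    x = x - x.mean(axis=0)
    cov = x.T @ x
    sd = np.sqrt(np.diag(cov))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = cov / sd[:, None] / sd[None, :]
    out = r**2
    out[~np.isfinite(out)] = np.nan
    return out


def ld_decay(matrix: GenotypeMatrix, pop_samples: list[str],
             max_dist: int = 100_000, bin_width: int = 5_000,
             maf: float = 0.05) -> LDDecayCurve:
    """Binned mean genotype r2 against inter-SNP distance, per population.

    All intra-chromosome SNP pairs with distance <= max_dist are used, after
    a minor-allele-frequency filter (rare variants dominate r2 noise).
    half_decay_distance is the smallest bin midpoint where the mean r2 drops
    to half of the maximum bin mean, or None if never.
    """
    if max_dist <= 0:
        raise ValueError("max_dist must be positive")
    idx = matrix.sample_indices(pop_samples)
    edges = np.arange(0, max_dist + bin_width, bin_width)
    n_bins = edges.size - 1
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    for chrom in matrix.chromosomes():
        cmask = matrix.chrom == chrom
        dos = matrix.dosage[idx][:, cmask]
        pos = matrix.pos[cmask]
        alt, n = allele_counts(dos)
        with np.errstate(invalid="ignore"):
            p = np.where(n > 0, alt / np.maximum(n, 1), 0.0)
        keep = (n >= 6) & (np.minimum(p, 1 - p) >= maf)
        dos, pos = dos[:, keep], pos[keep]
        s = pos.size
        if s < 2:
            continue
        r2 = _r2_matrix(dos)
        for i in range(s - 1):
            j_hi = int(np.searchsorted(pos, pos[i] + max_dist, side="right"))
            if j_hi <= i + 1:
                continue
            d = pos[i + 1:j_hi] - pos[i]
            v = r2[i, i + 1:j_hi]
            ok = np.isfinite(v)
            if not ok.any():
                continue
            b = np.minimum((d[ok] - 1) // bin_width, n_bins - 1)
            np.add.at(sums, b, v[ok])
            np.add.at(counts, b, 1)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    half = None
    finite = np.isfinite(means)
    if finite.any() and np.nanmax(means) > 0:
        target = np.nanmax(means) / 2.0
        mids = (edges[:-1] + edges[1:]) / 2.0
        below = finite & (means <= target)
        if below.any():
            half = float(mids[np.argmax(below)])
    return LDDecayCurve(edges, means, counts, half)


# ---------------------------------------------------------------------------
# divergence
# ---------------------------------------------------------------------------

def pair_distance_sums(dos_a: np.ndarray, dos_b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Summed genotype distance and compared-site counts for all (a, b) pairs.

    Returns (D, C): D[i, j] = sum over sites compared of the per-site
    expected allele mismatch between individual i of A and j of B;
    C[i, j] = number of sites where both were called.
    """
    a = np.asarray(dos_a, dtype=np.float64)
    b = np.asarray(dos_b, dtype=np.float64)
    ma = (dos_a != MISSING).astype(np.float64)
    mb = (dos_b != MISSING).astype(np.float64)
    av = np.where(dos_a == MISSING, 0.0, a)
    bv = np.where(dos_b == MISSING, 0.0, b)
    # sum over valid sites of a/2 + b/2 - a*b/2
    d = 0.5 * (av @ mb.T + ma @ bv.T - av @ bv.T)
    c = ma @ mb.T
    return d, c


def dxy(matrix: GenotypeMatrix, pop_a: list[str], pop_b: list[str],
        interval: GenomicInterval) -> float:
    """Mean per-bp inter-population genotype divergence in a window.

    Pairs with missing data are renormalized by the fraction of window sites
    they could be compared at; nan when no pair shares a called site (or the
    window has no variants, in which case divergence is 0).
    """
    if not pop_a or not pop_b:
        raise ValueError("both populations must be non-empty")
    da = _pop_dosage(matrix, pop_a, interval)
    db = _pop_dosage(matrix, pop_b, interval)
    s = da.shape[1]
    if s == 0:
        return 0.0
    d, c = pair_distance_sums(da, db)
    ok = c > 0
    if not ok.any():
        return float("nan")
    per_bp = d[ok] / (len(interval) * c[ok] / s)
    return float(per_bp.mean())


# ---------------------------------------------------------------------------
# tabulated windowed statistics (driver convenience)
# ---------------------------------------------------------------------------

def windowed_statistics(matrix: GenotypeMatrix, pop_samples: list[str],
                        chrom_lengths: dict[str, int],
                        spec: WindowSpec = WindowSpec(50_000, 50_000),
                        indel_positions: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-window pi, Tajima's D and SNP (and optional indel) density."""
    rows = []
    for w in iter_windows(chrom_lengths, spec):
        cmask = matrix.variant_mask(w)
        row = {
            "chrom": w.chrom,
            "start": w.start,
            "end": w.end,
            "pi": nucleotide_diversity(matrix, pop_samples, w),
            "tajimas_d": tajimas_d(matrix, pop_samples, w),
            "snp_density": site_density(matrix.pos[matrix.chrom == w.chrom], w),
            "n_sites": int(cmask.sum()),
        }
        if indel_positions is not None:
            sub = indel_positions[indel_positions["chrom"] == w.chrom]
            row["indel_density"] = site_density(sub["pos"].to_numpy(), w)
        rows.append(row)
    return pd.DataFrame(rows)
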