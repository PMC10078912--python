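"""SFS-based composite likelihood ratio scan and LD-based omega scan.

CLR scan
--------
The genome-wide site frequency spectrum phi(j) (probability of derived count
j = 1..n-1, conditioned on polymorphism) is the neutral background.  A hard
sweep at position x with intensity alpha (per bp) lets each of the n sampled
lineages at a site at distance d escape the sweep independently with
probability pe = 1 - exp(-alpha * d); non-escaping lineages descend from the
single swept haplotype.  The post-sweep spectrum phi*(j; pe) follows by
summing over the number of escapees k: the pre-sweep sample has size
m = k + 1 (the k escapees plus the swept ancestor; m = n when k = n), its
derived count i is the hypergeometric projection of phi to m, the swept
lineage is a uniform member of the m, and the post-sweep derived count is
(i - d) + (n - k) * d where d indicates a derived swept lineage.  The
composite likelihood at grid position x is the product over polymorphic sites
of phi*(j; pe(site)); Lambda(x) = 2 * (max_alpha log CL_sweep - log CL_neutral).
The maximizing window around x is where pe(alpha_hat) < 1 - epsilon, i.e.
x +/- ln(1/epsilon)/alpha_hat.

omega scan
----------
At a grid position, SNPs are split into a left and a right flank; omega is
the ratio of mean r2 within flanks to mean r2 between flanks, maximized over
flank extents (>= min_snps_side SNPs each).  Recently swept regions show high
LD within each flank but little LD across the swept site.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binom, hypergeom

from numba import njit

from .io_core import GenotypeMatrix, allele_counts
from .popstats import _r2_matrix

_UNDEFINED_MASS = 1e-12


@njit(cache=True)
def _clr_kernel(pos, contrib, cum_neutral, grid, alphas, dist_edges,
                max_snps_side, out_lam, out_alpha_idx):
    """Composite-likelihood maximization over the alpha grid per position.

    ``contrib[s, k]`` is the log-likelihood of site ``s`` in pe band ``k``
    (column 0 = the neutral fallback below the first pe edge);
    ``dist_edges[a, k]`` is the distance at which pe crosses into band k+1
    for alpha index a (non-increasing in k is not assumed; they are
    ascending).  Ties in alpha resolve to the largest (last) alpha.
    """
    n_sites = pos.shape[0]
    n_alpha = alphas.shape[0]
    n_edges = dist_edges.shape[1]
    for xi in range(grid.shape[0]):
        x = grid[xi]
        centre = np.searchsorted(pos, x)
        lo = max(0, centre - max_snps_side)
        hi = min(n_sites, centre + max_snps_side)
        neutral = cum_neutral[hi] - cum_neutral[lo]
        best_ll = -np.inf
        best_ai = n_alpha - 1
        for ai in range(n_alpha):
            ll = 0.0
            # right side: ascending distance, walk the band pointer
            k = 0
            for si in range(centre, hi):
                d = pos[si] - x
                while k < n_edges and d >= dist_edges[ai, k]:
                    k += 1
                ll += contrib[si, k]
            # left side: ascending distance going outwards
            k = 0
            for si in range(centre - 1, lo - 1, -1):
                d = x - pos[si]
                while k < n_edges and d >= dist_edges[ai, k]:
                    k += 1
                ll += contrib[si, k]
            if ll >= best_ll:
                best_ll = ll
                best_ai = ai
        out_lam[xi] = 2.0 * (best_ll - neutral)
        out_alpha_idx[xi] = best_ai


# ---------------------------------------------------------------------------
# polarized site counts
# ---------------------------------------------------------------------------

def derived_counts(
    matrix: GenotypeMatrix,
    pop_samples: list[str],
    outgroup_samples: list[str] | None,
    require_fixed_outgroup: bool = False,
) -> pd.DataFrame:
    """Per-site derived-allele counts in a population.

    With an outgroup, the derived allele is the outgroup minor allele (ties
    and all-missing outgroup sites are dropped); ``require_fixed_outgroup``
    additionally drops sites where the outgroup sample is polymorphic, i.e.
    where the ancestral state is unreliable.  Without an outgroup the alt
    count is returned and only folded spectra are meaningful.  Only sites
    polymorphic within the population are kept.
    """
    dos = matrix.dosage[matrix.sample_indices(pop_samples)]
    alt, n = allele_counts(dos)
    valid = n > 0
    if outgroup_samples:
        og = matrix.dosage[matrix.sample_indices(outgroup_samples)]
        og_alt, og_n = allele_counts(og)
        valid &= og_n > 0
        if require_fixed_outgroup:
            valid &= (og_alt == 0) | (og_alt == og_n)
        with np.errstate(invalid="ignore"):
            og_freq = np.where(og_n > 0, og_alt / np.maximum(og_n, 1), np.nan)
        valid &= og_freq != 0.5
        derived = np.where(og_freq < 0.5, alt, n - alt)
    else:
        derived = alt
    valid &= (derived > 0) & (derived < n)
    return pd.DataFrame(
        {
            "chrom": matrix.chrom[valid],
            "pos": matrix.pos[valid],
            "derived": derived[valid].astype(np.int64),
            "n": n[valid],
        }
    )


# ---------------------------------------------------------------------------
# background spectrum
# ---------------------------------------------------------------------------

@dataclass
class BackgroundSFS:
    """phi[j] = P(derived count j | polymorphic), indices 0..n."""

    n: int
    phi: np.ndarray
    folded: bool = False

    def fold_index(self, j: int) -> int:
        return min(j, self.n - j)


def projection_matrix(n_from: int, n_to: int) -> np.ndarray:
    """H[j, i] = P(i derived in a subsample of n_to | j derived among n_from)."""
    j = np.arange(n_from + 1)[:, None]
    i = np.arange(n_to + 1)[None, :]
    return hypergeom.pmf(i, n_from, j, n_to)


def background_sfs(
    matrix: GenotypeMatrix,
    pop_samples: list[str],
    outgroup_samples: list[str] | None = None,
    n_project: int | None = None,
    folded: bool = False,
    require_fixed_outgroup: bool = False,
) -> BackgroundSFS:
    """Genome-wide SFS hypergeometrically projected to a common sample size.

    Sites with fewer called alleles than ``n_project`` are dropped; sites with
    more are projected down.  Defaults to the maximum per-site call count.
    """
    if not folded and not outgroup_samples:
        raise ValueError("unfolded spectrum requires an outgroup for polarization")
    counts = derived_counts(matrix, pop_samples, outgroup_samples,
                            require_fixed_outgroup)
    if len(counts) == 0:
        raise ValueError("no usable polymorphic sites")
    n_site = counts["n"].to_numpy()
    if n_project is None:
        n_project = int(n_site.max())
    if n_project > 2 * len(pop_samples):
        raise ValueError("n_project exceeds the population's allele count")
    keep = n_site >= n_project
    if not keep.any():
        raise ValueError(f"no sites with >= {n_project} called alleles")
    der = counts["derived"].to_numpy()[keep]
    n_site = n_site[keep]

    phi = np.zeros(n_project + 1)
    for nf in np.unique(n_site):
        h = projection_matrix(int(nf), n_project)
        sub = der[n_site == nf]
        cnt = np.bincount(sub, minlength=int(nf) + 1).astype(float)
        phi += cnt @ h
    phi[0] = phi[n_project] = 0.0
    if folded:
        folded_phi = np.zeros_like(phi)
        for j in range(1, n_project):
            folded_phi[min(j, n_project - j)] += phi[j]
        phi = folded_phi
    total = phi.sum()
    if total <= 0:
        raise ValueError("projected spectrum is empty")
    return BackgroundSFS(n=n_project, phi=phi / total, folded=folded)


# ---------------------------------------------------------------------------
# sweep-transformed spectrum
# ---------------------------------------------------------------------------

def _unfold(phi: np.ndarray, n: int) -> np.ndarray:
    """Symmetric unfolding of a folded spectrum (equal split of minor mass)."""
    out = np.zeros(n + 1)
    for j in range(1, n // 2 + 1):
        if j == n - j:
            out[j] = phi[j]
        else:
            out[j] += phi[j] / 2.0
            out[n - j] += phi[j] / 2.0
    return out


def _fold(phi: np.ndarray, n: int) -> np.ndarray:
    out = np.zeros(n + 1)
    for j in range(1, n):
        out[min(j, n - j)] += phi[j]
    return out


def sweep_spectrum(sfs: BackgroundSFS, pe: float) -> np.ndarray | None:
    """phi*(j; pe): the background spectrum distorted by a sweep.

    Returns None (undefined) when the probability of remaining polymorphic
    falls below 1e-12 — e.g. pe = 0, where every lineage descends from the
    single swept haplotype.  pe = 1 returns the background spectrum exactly.
    """
    if not 0.0 <= pe <= 1.0:
        raise ValueError("pe must lie in [0, 1]")
    n = sfs.n
    phi = _unfold(sfs.phi, n) if sfs.folded else sfs.phi
    out = np.zeros(n + 1)
    pk = binom.pmf(np.arange(n + 1), n, pe)
    out += pk[n] * phi  # all lineages escape: spectrum unchanged
    for k in range(n):
        m = k + 1
        psi = phi @ projection_matrix(n, m)  # derived count among the m
        i = np.arange(m + 1)
        p_swept_derived = i / m
        # swept lineage ancestral: count stays i
        np.add.at(out, i, pk[k] * psi * (1 - p_swept_derived))
        # swept lineage derived: its (n - k) descendants are all derived
        np.add.at(out, i + n - k - 1, pk[k] * psi * p_swept_derived)
    out[0] = out[n] = 0.0
    mass = out.sum()
    if mass < _UNDEFINED_MASS:
        return None
    out = out / mass
    return _fold(out, n) if sfs.folded else out


def _sweep_table(sfs: BackgroundSFS, pe_grid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """phi* for every pe in the grid -> (table (P, n+1), defined mask)."""
    table = np.zeros((pe_grid.size, sfs.n + 1))
    defined = np.zeros(pe_grid.size, dtype=bool)
    for b, pe in enumerate(pe_grid):
        res = sweep_spectrum(sfs, float(pe))
        if res is not None:
            table[b] = res
            defined[b] = True
    return table, defined


# ---------------------------------------------------------------------------
# CLR scan
# ---------------------------------------------------------------------------

def scan_grid(chrom_length: int, spacing: int) -> np.ndarray:
    """Shared scan grid: spacing/2, 3*spacing/2, ... within the chromosome."""
    return np.arange(spacing // 2, chrom_length, spacing, dtype=np.int64)


def default_alpha_grid(n_points: int = 40) -> np.ndarray:
    return np.geomspace(1e-8, 1e-2, n_points)


def clr_scan(
    matrix: GenotypeMatrix,
    pop_samples: list[str],
    outgroup_samples: list[str] | None,
    chrom_lengths: dict[str, int],
    sfs: BackgroundSFS | None = None,
    grid_spacing: int = 1000,
    alpha_grid: np.ndarray | None = None,
    window_epsilon: float = 0.01,
    max_snps_side: int = 1000,
    n_pe_bins: int = 256,
    require_fixed_outgroup: bool = False,
) -> pd.DataFrame:
    """Composite likelihood ratio scan along the shared grid.

    Returns one row per grid position: Lambda (``clr``), the maximizing sweep
    intensity ``alpha``, and the maximizing window ``win_start``/``win_end``
    (0-based half-open) where pe(alpha_hat) < 1 - window_epsilon.
    """
    if alpha_grid is None:
        alpha_grid = default_alpha_grid()
    alpha_grid = np.asarray(alpha_grid, dtype=float)
    if alpha_grid.size == 0:
        raise ValueError("alpha grid is empty")
    # append the alpha -> infinity limit, where every lineage escapes and the
    # sweep model reduces to the background: Lambda is then >= 0 exactly
    alpha_grid = np.append(alpha_grid, np.inf)
    if sfs is None:
        sfs = background_sfs(matrix, pop_samples, outgroup_samples,
                             folded=not outgroup_samples,
                             require_fixed_outgroup=require_fixed_outgroup)
    counts = derived_counts(matrix, pop_samples, outgroup_samples,
                            require_fixed_outgroup)

    # pe lookup table (geometric bins; pe below the lowest edge or at an
    # undefined phi* contributes the neutral term)
    edges = np.geomspace(1e-8, 1.0, n_pe_bins + 1)
    reps = np.sqrt(edges[:-1] * edges[1:])
    reps[-1] = 1.0  # top bin: exactly the background spectrum
    table, defined = _sweep_table(sfs, reps)

    rows = []
    for chrom, length in chrom_lengths.items():
        sub = counts[counts["chrom"] == chrom]
        pos = sub["pos"].to_numpy() - 1  # 0-based site coordinates
        der = sub["derived"].to_numpy()
        n_site = sub["n"].to_numpy()
        grid = scan_grid(length, grid_spacing)
        if pos.size == 0:
            for x in grid:
                rows.append((chrom, int(x), 0.0, np.nan, 0, length))
            continue

        # per-site weight over derived counts at the projected size
        w = np.zeros((pos.size, sfs.n + 1))
        for s_i, (c, j) in enumerate(zip(n_site, der)):
            if c == sfs.n:
                jj = sfs.fold_index(int(j)) if sfs.folded else int(j)
                w[s_i, jj] = 1.0
            elif c > sfs.n:
                row = hypergeom.pmf(np.arange(sfs.n + 1), int(c), int(j), sfs.n)
                if sfs.folded:
                    row = _fold(row, sfs.n)
                    row[0] = 0.0
                else:
                    row[0] = row[sfs.n] = 0.0
                tot = row.sum()
                if tot <= 0:
                    continue
                w[s_i] = row / tot
        usable = w.sum(axis=1) > 0
        pos, w = pos[usable], w[usable]
        if pos.size == 0:
            for x in grid:
                rows.append((chrom, int(x), 0.0, np.nan, 0, length))
            continue

        log_neutral = np.log(w @ sfs.phi)
        # contribution of a site in pe band k: log(w . phi*_k); band 0 (pe
        # below the lowest edge) and undefined bands fall back to neutral
        band = np.where(
            defined[None, :],
            np.log(np.maximum(w @ table.T, 1e-300)),
            log_neutral[:, None],
        )  # (S, P)
        contrib = np.concatenate([log_neutral[:, None], band], axis=1)
        cum_neutral = np.concatenate([[0.0], np.cumsum(log_neutral)])

        # distance at which pe = 1 - exp(-alpha d) crosses each pe edge
        with np.errstate(divide="ignore"):
            dist_edges = -np.log1p(-edges[:-1])[None, :] / alpha_grid[:, None]
        dist_edges[~np.isfinite(alpha_grid), :] = 0.0  # alpha -> inf limit

        lam = np.empty(grid.size)
        alpha_idx = np.empty(grid.size, dtype=np.int64)
        _clr_kernel(
            pos.astype(np.float64), contrib, cum_neutral,
            grid.astype(np.float64), alpha_grid, dist_edges,
            max_snps_side, lam, alpha_idx,
        )
        for gi, x in enumerate(grid):
            a_hat = float(alpha_grid[alpha_idx[gi]])
            d_w = max(-np.log(window_epsilon) / a_hat, 1.0)
            rows.append(
                (
                    chrom,
                    int(x),
                    float(lam[gi]),
                    a_hat,
                    int(max(0, np.floor(x - d_w))),
                    int(min(length, np.ceil(x + d_w))),
                )
            )
    return pd.DataFrame(
        rows, columns=["chrom", "position", "clr", "alpha", "win_start", "win_end"]
    )


# ---------------------------------------------------------------------------
# omega scan
# ---------------------------------------------------------------------------

def _cumulative_flank_sums(r2_block: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Within-flank r2 sums over the k nearest SNPs, nan-aware.

    r2_block is ordered nearest-first.  Returns (sums, counts) where
    sums[k-1] covers all pairs among the k nearest SNPs.
    """
    k = r2_block.shape[0]
    vals = np.nan_to_num(r2_block, nan=0.0)
    fin = np.isfinite(r2_block)
    sums = np.zeros(k)
    counts = np.zeros(k)
    for i in range(1, k):
        sums[i] = sums[i - 1] + vals[i, :i].sum()
        counts[i] = counts[i - 1] + fin[i, :i].sum()
    return sums, counts


def omega_from_r2(
    r2_left: np.ndarray,
    r2_right: np.ndarray,
    r2_between: np.ndarray,
    min_snps_side: int = 3,
    floor: float = 1e-6,
) -> tuple[float, int, int, bool]:
    """omega maximized over flank extents, from precomputed r2 blocks.

    ``r2_left``/``r2_right`` are within-flank matrices ordered nearest-first;
    ``r2_between[i, j]`` pairs the i-th nearest left with the j-th nearest
    right SNP.  Undefined r2 pairs are skipped with pair-count
    renormalization; the between-flank mean is floored to avoid division by
    zero (flagged).  Returns (omega, n_left, n_right, floored).
    """
    kl, kr = r2_left.shape[0], r2_right.shape[0]
    if kl < min_snps_side or kr < min_snps_side:
        return float("nan"), 0, 0, False
    sl, cl = _cumulative_flank_sums(r2_left)
    sr, cr = _cumulative_flank_sums(r2_right)
    vals = np.nan_to_num(r2_between, nan=0.0)
    fin = np.isfinite(r2_between).astype(float)
    bsum = vals.cumsum(axis=0).cumsum(axis=1)
    bcnt = fin.cumsum(axis=0).cumsum(axis=1)

    within_cnt = cl[:, None] + cr[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        within = (sl[:, None] + sr[None, :]) / within_cnt
        between = bsum / bcnt
        omega = within / np.maximum(between, floor)
    valid = (within_cnt > 0) & (bcnt > 0)
    valid[: min_snps_side - 1, :] = False
    valid[:, : min_snps_side - 1] = False
    if not valid.any():
        return float("nan"), 0, 0, False
    omega = np.where(valid, omega, -np.inf)
    il, ir = np.unravel_index(int(np.argmax(omega)), omega.shape)
    return (
        float(omega[il, ir]),
        il + 1,
        ir + 1,
        bool(between[il, ir] < floor),
    )


def omega_at(
    position: int,
    snp_positions: np.ndarray,
    dosages: np.ndarray,
    min_snps_side: int = 3,
    max_window_bp: int = 100_000,
    max_snps_side: int = 30,
    r2: np.ndarray | None = None,
) -> tuple[float, int, int, bool]:
    """omega at one position from SNP dosages (samples x sites, 0-based pos).

    Uses up to ``max_snps_side`` SNPs within ``max_window_bp`` on each side.
    Returns (omega, n_left, n_right, floored); omega is nan when either side
    has fewer than ``min_snps_side`` SNPs.
    """
    snp_positions = np.asarray(snp_positions)
    if r2 is None:
        r2 = _r2_matrix(np.asarray(dosages))
    centre = int(np.searchsorted(snp_positions, position))
    lo = int(np.searchsorted(snp_positions, position - max_window_bp))
    hi = int(np.searchsorted(snp_positions, position + max_window_bp, side="right"))
    left = np.arange(lo, centre)[::-1][:max_snps_side]   # nearest first
    right = np.arange(centre, hi)[:max_snps_side]
    if left.size < min_snps_side or right.size < min_snps_side:
        return float("nan"), 0, 0, False
    return omega_from_r2(
        r2[np.ix_(left, left)],
        r2[np.ix_(right, right)],
        r2[np.ix_(left, right)],
        min_snps_side=min_snps_side,
    )


def omega_scan(
    matrix: GenotypeMatrix,
    pop_samples: list[str],
    chrom_lengths: dict[str, int],
    grid_spacing: int = 1000,
    min_snps_side: int = 3,
    max_window_bp: int = 100_000,
    max_snps_side: int = 30,
) -> pd.DataFrame:
    """omega evaluated on the same grid as clr_scan (shared-grid contract)."""
    idx = matrix.sample_indices(pop_samples)
    rows = []
    for chrom, length in chrom_lengths.items():
        cmask = matrix.chrom == chrom
        dos = matrix.dosage[idx][:, cmask]
        pos = matrix.pos[cmask] - 1
        alt, n = allele_counts(dos)
        poly = (alt > 0) & (alt < n) & (n > 0)
        dos, pos = dos[:, poly], pos[poly]
        r2 = _r2_matrix(dos) if pos.size else None
        for x in scan_grid(length, grid_spacing):
            om, nl, nr, fl = (
                omega_at(int(x), pos, dos, min_snps_side, max_window_bp,
                         max_snps_side, r2=r2)
                if pos.size
                else (float("nan"), 0, 0, False)
            )
            rows.append((chrom, int(x), om, nl, nr, fl))
    return pd.DataFrame(
        rows, columns=["chrom", "position", "omega", "n_left", "n_right", "floored"]
    )
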