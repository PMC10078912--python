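"""Patterson's D (ABBA-BABA), block-jackknife significance, and windowed fd.

For a four-taxon arrangement {[(P1,P2),P3],O}, derived-allele frequencies
p1..p4 at each biallelic site give frequency-weighted pattern counts

    C_ABBA = (1-p1) * p2 * p3 * (1-p4)
    C_BABA = p1 * (1-p2) * p3 * (1-p4)

and D = sum(C_ABBA - C_BABA) / sum(C_ABBA + C_BABA).  Under the null of no
gene flow (and no ancestral structure) E[D] = 0; significance comes from a
delete-one block jackknife over contiguous blocks holding equal numbers of
informative sites.  fd replaces the donor frequency by p_D = max(p2, p3)
site-wise in the denominator sums, giving a bounded estimator of the fraction
of the genome affected by unidirectional P3 -> P2 introgression; it is only
defined where the window D is positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import GenotypeMatrix, allele_counts


@dataclass
class TrioResult:
    trio: tuple[str, str, str]
    d: float
    se: float
    z: float
    p: float
    q: float | None
    n_blocks: int
    abba: float
    baba: float
    n_informative: int
    degenerate: bool = False


def site_patterns(matrix: GenotypeMatrix, roles: dict[str, list[str]]) -> pd.DataFrame:
    """Per-site derived-allele frequencies and ABBA/BABA weights.

    ``roles`` maps P1, P2, P3, O to sample lists.  The derived allele is the
    allele at frequency < 0.5 in the (pooled) outgroup sample; sites where
    the outgroup is exactly at 0.5, all-missing, or where any population is
    all-missing are excluded.
    """
    for role in ("P1", "P2", "P3", "O"):
        if role not in roles or not roles[role]:
            raise ValueError(f"role {role} must bind at least one sample")
    freqs = {}
    valid = np.ones(matrix.n_variants, dtype=bool)
    for role in ("P1", "P2", "P3", "O"):
        dos = matrix.dosage[matrix.sample_indices(roles[role])]
        alt, n = allele_counts(dos)
        valid &= n > 0
        with np.errstate(invalid="ignore"):
            freqs[role] = np.where(n > 0, alt / np.maximum(n, 1), np.nan)
    out_freq = freqs["O"]
    valid &= out_freq != 0.5
    # polarize: derived allele is the minor allele in the outgroup
    derived_is_alt = out_freq < 0.5
    p = {}
    for role in ("P1", "P2", "P3", "O"):
        p[role] = np.where(derived_is_alt, freqs[role], 1.0 - freqs[role])
    if not valid.any():
        import warnings

        warnings.warn("no usable sites for site patterns")
    p1, p2, p3, p4 = (p[r][valid] for r in ("P1", "P2", "P3", "O"))
    c_abba = (1 - p1) * p2 * p3 * (1 - p4)
    c_baba = p1 * (1 - p2) * p3 * (1 - p4)
    return pd.DataFrame(
        {
            "chrom": matrix.chrom[valid],
            "pos": matrix.pos[valid],
            "p1": p1,
            "p2": p2,
            "p3": p3,
            "p4": p4,
            "c_abba": c_abba,
            "c_baba": c_baba,
        }
    )


def patterson_d(
    patterns: pd.DataFrame,
    n_blocks: int = 20,
    trio: tuple[str, str, str] = ("P1", "P2", "P3"),
    block_by: str = "span",
) -> TrioResult:
    """Genome-wide D with delete-one block-jackknife standard error.

    By default blocks are contiguous genomic intervals of equal span
    (``block_by="span"``), allotted to chromosomes in proportion to their
    extent, so a block is wider than the local LD correlation length even
    when informative sites are sparse and clustered; ``block_by="sites"``
    instead gives blocks holding equal counts of informative sites, which is
    only safe when informative sites vastly outnumber blocks.
    """
    ca_all = patterns["c_abba"].to_numpy(dtype=float)
    cb_all = patterns["c_baba"].to_numpy(dtype=float)
    informative = (ca_all + cb_all) > 0
    ca, cb = ca_all[informative], cb_all[informative]
    n_inf = int(informative.sum())
    if n_inf < n_blocks:
        raise ValueError(
            f"need >= {n_blocks} informative sites for the jackknife, got {n_inf}"
        )
    num, den = float((ca - cb).sum()), float((ca + cb).sum())
    d = num / den

    if block_by == "sites":
        blocks = np.array_split(np.arange(n_inf), n_blocks)
    elif block_by == "span":
        blocks = _span_blocks(patterns.loc[informative], n_blocks)
    else:
        raise ValueError(f"unknown block_by: {block_by!r}")
    blocks = [b for b in blocks if len(b)]
    n_blocks = len(blocks)
    if n_blocks < 2:
        raise ValueError("fewer than two non-empty jackknife blocks")
    d_del = np.empty(n_blocks)
    for b, idx in enumerate(blocks):
        bn = num - float((ca[idx] - cb[idx]).sum())
        bd = den - float((ca[idx] + cb[idx]).sum())
        d_del[b] = bn / bd if bd > 0 else 0.0
    se = float(np.sqrt((n_blocks - 1) / n_blocks * np.sum((d_del - d_del.mean()) ** 2)))
    degenerate = False
    if se == 0:
        if d == 0:
            z, pval = 0.0, 1.0
        else:
            z, pval, degenerate = np.inf, 0.0, True
    else:
        z = d / se
        # two-sided tail on t with B-1 df: the jackknife SE is itself an
        # estimate from B blocks, and the normal reference is anticonservative
        # at the block counts genome scans use
        pval = float(2 * stats.t.sf(abs(z), df=n_blocks - 1))
    return TrioResult(
        trio=trio,
        d=d,
        se=se,
        z=float(z),
        p=pval,
        q=None,
        n_blocks=n_blocks,
        abba=float(ca.sum()),
        baba=float(cb.sum()),
        n_informative=n_inf,
        degenerate=degenerate,
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _span_blocks(informative: pd.DataFrame, n_blocks: int) -> list[np.ndarray]:
    """Contiguous equal-span genomic blocks, shared out across chromosomes."""
    chroms = list(pd.unique(informative["chrom"]))
    spans = {}
    for chrom in chroms:
        pos = informative.loc[informative["chrom"] == chrom, "pos"]
        spans[chrom] = max(int(pos.max() - pos.min()), 1)
    total = sum(spans.values())
    blocks: list[np.ndarray] = []
    offset = 0
    for chrom in chroms:
        pos = informative.loc[informative["chrom"] == chrom, "pos"].to_numpy()
        k = max(1, round(n_blocks * spans[chrom] / total))
        edges = np.linspace(pos.min(), pos.max() + 1, k + 1)
        idx = np.searchsorted(edges, pos, side="right") - 1
        for b in range(k):
            blocks.append(offset + np.nonzero(idx == b)[0])
        offset += pos.size
    return blocks


def _fd_sums(p1, p2, p3, p4) -> tuple[float, float]:
    num = float(np.sum((1 - p1) * p2 * p3 * (1 - p4) - p1 * (1 - p2) * p3 * (1 - p4)))
    pd_ = np.maximum(p2, p3)
    den = float(
        np.sum((1 - p1) * pd_ * pd_ * (1 - p4) - p1 * (1 - pd_) * pd_ * (1 - p4))
    )
    return num, den


def fd_windows(patterns: pd.DataFrame, window_informative: int = 50) -> pd.DataFrame:
    """fd in consecutive blocks of ``window_informative`` informative sites.

    Windows never span chromosomes; a final partial window is flagged
    ``complete=False``.  fd is undefined (nan) where window D <= 0 or the
    dynamic-donor denominator vanishes.
    """
    inf = patterns[(patterns["c_abba"] + patterns["c_baba"]) > 0]
    rows = []
    for chrom, grp in inf.groupby("chrom", sort=False):
        grp = grp.sort_values("pos")
        for lo in range(0, len(grp), window_informative):
            w = grp.iloc[lo:lo + window_informative]
            num = float((w["c_abba"] - w["c_baba"]).sum())
            den_d = float((w["c_abba"] + w["c_baba"]).sum())
            d = num / den_d if den_d > 0 else float("nan")
            _, den = _fd_sums(
                w["p1"].to_numpy(), w["p2"].to_numpy(),
                w["p3"].to_numpy(), w["p4"].to_numpy(),
            )
            if d == d and d > 0 and den != 0:
                fd = num / den
            else:
                fd = float("nan")
            rows.append(
                {
                    "chrom": chrom,
                    "start": int(w["pos"].iloc[0]) - 1,
                    "end": int(w["pos"].iloc[-1]),
                    "n_informative": len(w),
                    "d": d,
                    "fd": fd,
                    "complete": len(w) == window_informative,
                }
            )
    return pd.DataFrame(rows)


def genome_admixture_fraction(patterns: pd.DataFrame) -> float:
    """Pooled genome-wide fd as a percentage; 0 when pooled D <= 0."""
    inf = patterns[(patterns["c_abba"] + patterns["c_baba"]) > 0]
    if len(inf) == 0:
        raise ValueError("no informative sites")
    num, den = _fd_sums(
        inf["p1"].to_numpy(), inf["p2"].to_numpy(),
        inf["p3"].to_numpy(), inf["p4"].to_numpy(),
    )
    den_d = float((inf["c_abba"] + inf["c_baba"]).sum())
    d = num / den_d
    if d <= 0 or den == 0:
        return 0.0
    return 100.0 * num / den
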