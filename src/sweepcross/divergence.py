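"""RNDmin: minimum inter-population distance relative to outgroup divergence.

RNDmin in a window is d_min / d_out where d_min is the minimum per-bp genotype
distance over all pairs (a in A, b in B) and d_out is the mean per-bp distance
of all A and B individuals to the outgroup.  Zero RNDmin flags windows that
are fully conserved or carry a recently introgressed haplotype; dividing by
outgroup divergence controls for mutation-rate variation along the genome.

The statistic was defined on haplotypes; with unphased diploids we use the
per-individual expected-mismatch genotype distance shared with dxy.
"""

from __future__ import annotations

import pandas as pd

from .io_core import GenotypeMatrix
from .popstats import WindowSpec, iter_windows, pair_distance_sums


def rndmin_windows(
    matrix: GenotypeMatrix,
    pop_a: list[str],
    pop_b: list[str],
    outgroup: list[str],
    chrom_lengths: dict[str, int],
    spec: WindowSpec = WindowSpec(50_000, 50_000),
    min_snps: int = 10,
) -> pd.DataFrame:
    """Windowed RNDmin between A and B relative to an outgroup.

    Windows with fewer than ``min_snps`` SNPs or zero outgroup divergence are
    flagged undefined (min statistics are noise-prone at tiny S).
    """
    if not pop_a or not pop_b or not outgroup:
        raise ValueError("all three groups must be non-empty")
    groups = [set(pop_a), set(pop_b), set(outgroup)]
    for i in range(3):
        for j in range(i + 1, 3):
            if groups[i] & groups[j]:
                raise ValueError(
                    f"groups overlap: {sorted(groups[i] & groups[j])}"
                )

    ia = matrix.sample_indices(pop_a)
    ib = matrix.sample_indices(pop_b)
    io = matrix.sample_indices(outgroup)

    rows = []
    for w in iter_windows(chrom_lengths, spec):
        mask = matrix.variant_mask(w)
        n_sites = int(mask.sum())
        da = matrix.dosage[ia][:, mask]
        db = matrix.dosage[ib][:, mask]
        do = matrix.dosage[io][:, mask]
        length = len(w)

        d_min = d_out = rnd = float("nan")
        defined = False
        if n_sites >= min_snps:
            dist_ab, c_ab = pair_distance_sums(da, db)
            ok = c_ab > 0
            if ok.any():
                per_bp = dist_ab[ok] / (length * c_ab[ok] / n_sites)
                d_min = float(per_bp.min())
            d_ao, c_ao = pair_distance_sums(da, do)
            d_bo, c_bo = pair_distance_sums(db, do)
            ok_a, ok_b = c_ao > 0, c_bo > 0
            total = 0.0
            n_pairs = 0
            if ok_a.any():
                total += float((d_ao[ok_a] / (length * c_ao[ok_a] / n_sites)).sum())
                n_pairs += int(ok_a.sum())
            if ok_b.any():
                total += float((d_bo[ok_b] / (length * c_bo[ok_b] / n_sites)).sum())
                n_pairs += int(ok_b.sum())
            if n_pairs:
                d_out = total / n_pairs
            if d_min == d_min and d_out == d_out and d_out > 0:
                rnd = d_min / d_out
                defined = True
        rows.append(
            {
                "chrom": w.chrom,
                "start": w.start,
                "end": w.end,
                "d_min": d_min,
                "d_out": d_out,
                "rnd_min": rnd,
                "n_sites": n_sites,
                "defined": defined,
            }
        )
    return pd.DataFrame(rows)


def count_zero_rndmin(windows: pd.DataFrame) -> int:
    """Number of defined windows with exactly zero RNDmin."""
    defined = windows[windows["defined"]]
    return int((defined["rnd_min"] == 0).sum())
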