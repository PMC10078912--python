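"""Windowed diversity statistics and LD decay on the simulated cohorts.

Computes pi, Tajima's D and SNP density in 50 kb windows for each population
of the quartet cohort, and the LD-decay curve with its half-decay distance.
Writes results/popstats/*.tsv.

Usage: python analysis/02_population_statistics.py
"""

from pathlib import Path

import pandas as pd

from sweepcross import popstats as ps
from sweepcross import synthetic_data as sd
from sweepcross.io_core import read_population_map, read_vcf

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "results" / "data" / "quartet_pulse"
OUT = ROOT / "results" / "popstats"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    matrix = read_vcf(DATA / "variants.vcf")
    popmap = read_population_map(DATA / "popmap.tsv")
    lengths = sd.read_chrom_lengths(DATA / "chrom_lengths.tsv")

    tables = []
    for pop in popmap.populations:
        tab = ps.windowed_statistics(
            matrix, popmap.samples(pop), lengths, ps.WindowSpec(50_000, 50_000)
        )
        tab.insert(0, "population", pop)
        tables.append(tab)
        mean_pi = tab["pi"].mean()
        mean_d = tab["tajimas_d"].mean()
        print(f"{pop}: mean pi = {mean_pi:.3e} /bp, mean Tajima's D = {mean_d:+.2f}")
    pd.concat(tables).to_csv(OUT / "windowed_statistics.tsv", sep="\t", index=False)

    for pop in ("P1", "P2"):
        curve = ps.ld_decay(matrix, popmap.samples(pop), max_dist=50_000,
                            bin_width=2_000)
        pd.DataFrame(
            {
                "dist_lo": curve.bin_edges[:-1],
                "dist_hi": curve.bin_edges[1:],
                "mean_r2": curve.mean_r2,
                "n_pairs": curve.n_pairs,
            }
        ).to_csv(OUT / f"ld_decay_{pop}.tsv", sep="\t", index=False)
        print(f"{pop}: LD half-decay distance = {curve.half_decay_distance} bp")


if __name__ == "__main__":
    main()
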