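"""Simulate the study cohorts and write them under results/data/.

Three forward-simulated datasets anchor the downstream analyses:

- ``quartet_pulse``: four populations {[(P1,P2),P3],OUT} with a recent
  admixture pulse P3 -> P2 (f = 0.10), for the introgression statistics;
- ``pair_pulse``: two focal populations plus outgroup with a stronger pulse
  (f = 0.20), for RNDmin;
- ``sweep``: one population carrying a conditioned hard sweep (N=500,
  s=0.1, L=1 Mb) plus an outgroup, for the selection scans.

Usage: python analysis/01_simulate_cohorts.py [--seed 1]
"""

import argparse
from pathlib import Path

from sweepcross import synthetic_data as sd

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", default=ROOT / "results" / "data")
    args = ap.parse_args()
    out = Path(args.out)

    scenarios = {
        "quartet_pulse": sd.quartet_config(seed=args.seed, pulse_fraction=0.10),
        "pair_pulse": sd.pair_config(seed=args.seed, pulse_fraction=0.20),
        "sweep": sd.sweep_config(seed=args.seed),
    }
    for name, cfg in scenarios.items():
        ds = sd.simulate(cfg)
        sd.write_dataset(ds, out / name)
        truth = ds.truth
        extra = ""
        if truth.sweep_position is not None:
            extra = (
                f" sweep@{truth.sweep_position} fixed "
                f"{truth.fixation_generation} generations before present "
                f"after {truth.n_restarts} restarts"
            )
        if truth.pulse_fraction:
            extra += (
                f" pulse {truth.pulse_source}->{truth.pulse_dest} "
                f"f={truth.pulse_fraction} at t={truth.pulse_time}"
            )
        print(
            f"{name}: {ds.genotypes.n_variants} SNPs x "
            f"{ds.genotypes.n_samples} samples{extra}"
        )


if __name__ == "__main__":
    main()
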