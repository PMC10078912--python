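"""Shared fixtures: simulated cohorts reused across test modules.

Session-scoped replicate sets keep the expensive forward simulations to a
single run each; every consumer derives its own statistics from them.
"""

import numpy as np
import pytest

from sweepcross import synthetic_data as sd


@pytest.fixture(scope="session")
def sweep_replicates():
    """Conditioned hard-sweep cohort: N=500, s=0.1, L=1 Mb."""
    return [sd.simulate(sd.sweep_config(seed=2000 + i)) for i in range(20)]


@pytest.fixture(scope="session")
def neutral_genomes():
    """Sweep-free runs of the same scenario (specificity controls)."""
    return [
        sd.simulate(sd.sweep_config(seed=3000 + i, with_sweep=False))
        for i in range(20)
    ]


def _scan_tracks(ds):
    from sweepcross import sweepscan as sw

    m, pm = ds.genotypes, ds.popmap
    foc, out = pm.samples("FOC"), pm.samples("OUT")
    sfs = sw.background_sfs(m, foc, out, n_project=20)
    clr = sw.clr_scan(m, foc, out, ds.chrom_lengths, sfs=sfs)
    om = sw.omega_scan(m, foc, ds.chrom_lengths, max_window_bp=50_000)
    return clr, om


@pytest.fixture(scope="session")
def sweep_scans(sweep_replicates):
    """(dataset, clr track, omega track) per sweep replicate, computed once."""
    return [(ds, *_scan_tracks(ds)) for ds in sweep_replicates]


@pytest.fixture(scope="session")
def neutral_scans(neutral_genomes):
    return [(ds, *_scan_tracks(ds)) for ds in neutral_genomes]


@pytest.fixture(scope="session")
def small_dataset():
    """A quick multi-population dataset for I/O round-trip style tests."""
    return sd.simulate(sd.pair_config(seed=42, length=150_000))


@pytest.fixture(scope="session")
def ld_decay_replicates():
    """Half-decay distances for low vs high recombination, 10 replicates each.

    Returns (low_r_half_decays, high_r_half_decays) with r = 1e-7 vs 1e-6 at
    equal theta.
    """
    from sweepcross.popstats import ld_decay

    halves = {1e-7: [], 1e-6: []}
    for rec, out in halves.items():
        for i in range(10):
            ds = sd.simulate(
                sd.neutral_config(
                    seed=4000 + i, n=100, length=200_000, mu=2e-7, rec=rec,
                    sample_size=20,
                )
            )
            m = ds.genotypes
            curve = ld_decay(m, m.sample_ids, max_dist=100_000, bin_width=5_000)
            out.append(
                curve.half_decay_distance
                if curve.half_decay_distance is not None
                else 100_000.0
            )
    return np.asarray(halves[1e-7]), np.asarray(halves[1e-6])
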