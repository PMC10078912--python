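"""Discrete-generation Wright-Fisher forward simulator with ground truth.

Produces multi-population diploid SNP data with (a) neutral background
diversity, (b) an optional hard selective sweep in one population,
(c) an optional one-generation admixture pulse, and (d) a diverged outgroup
used for polarization.  Everything downstream of the simulator (windowed
statistics, D/fd, RNDmin, CLR and omega scans) can therefore be checked
against known truth.

Model
-----
Non-overlapping generations of N diploids per population.  Each offspring
draws two parents (selfing allowed) with probability proportional to fitness
1, 1+s, 1+2s at the sweep site (additive selection).  Each transmitted gamete
is a recombinant of the parent's two haplotypes with a Poisson(L*r) number of
crossovers at uniform positions.  Mutation is infinite-sites on integer
positions: Poisson(2*N*L*mu) new mutations per population per generation,
position collisions resampled.  Populations split by copying founders from
the parent population; an admixture pulse at generation t replaces each
destination parent draw by a source-population parent with probability f.
A burn-in of ``burn_in_factor * N`` generations precedes the first recorded
event so the root population is near mutation-drift equilibrium.

The output VCF convention is ref = outgroup-sample consensus allele (the
ancestral-state estimate used by all polarized statistics); sites where the
outgroup sample is polymorphic are emitted but flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .io_core import MISSING, GenotypeMatrix, PopulationMap

_LETTERS = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class PopulationSpec:
    name: str
    size: int            # diploid N
    sample_size: int     # diploids sampled at present


@dataclass
class SplitEvent:
    child: str
    parent: str
    time: int            # generations before present


@dataclass
class AdmixturePulse:
    time: int
    source: str
    dest: str
    fraction: float


@dataclass
class SweepConfig:
    population: str
    position: int
    s: float
    onset_time: int
    condition_on_fixation: bool = True


@dataclass
class SimulationConfig:
    populations: list[PopulationSpec]
    sequence_length: int
    mutation_rate: float
    recombination_rate: float
    splits: list[SplitEvent] = field(default_factory=list)
    outgroup: str | None = None
    pulse: AdmixturePulse | None = None
    sweep: SweepConfig | None = None
    seed: int = 0
    chrom_name: str = "chr1"
    burn_in_factor: int = 10
    max_restarts: int = 10_000
    # test hooks: optionally freeze mutation after burn-in, pad the recorded
    # timeline, and record an expected-heterozygosity trace
    mutation_stops_after_burn_in: bool = False
    trace_interval: int | None = None
    extra_generations: int = 0

    def validate(self) -> None:
        names = [p.name for p in self.populations]
        if len(set(names)) != len(names):
            raise ValueError("duplicate population names")
        children = [s.child for s in self.splits]
        if len(set(children)) != len(children):
            raise ValueError("a population may split from its parent only once")
        root = names[0]
        if root in children:
            raise ValueError("the first (root) population may not have a split event")
        for name in names[1:]:
            if name not in children:
                raise ValueError(f"population {name!r} has no split event")
        birth = {root: np.inf}
        for s in sorted(self.splits, key=lambda s: -s.time):
            if s.parent not in birth:
                raise ValueError(f"split parent {s.parent!r} undefined or born later")
            if s.time >= birth[s.parent]:
                raise ValueError(
                    f"{s.child!r} splits at {s.time}, before parent {s.parent!r} exists"
                )
            if s.time < 1:
                raise ValueError("split times must be >= 1 generation before present")
            birth[s.child] = s.time
        if self.outgroup is not None and self.outgroup not in names:
            raise ValueError(f"outgroup {self.outgroup!r} is not a population")
        if self.pulse is not None:
            p = self.pulse
            if not 0.0 <= p.fraction <= 1.0:
                raise ValueError("pulse fraction must be in [0, 1]")
            for pop in (p.source, p.dest):
                if pop not in birth:
                    raise ValueError(f"pulse population {pop!r} undefined")
                if p.time >= birth[pop]:
                    raise ValueError(f"pulse predates population {pop!r}")
        if self.sweep is not None:
            w = self.sweep
            if w.population not in birth:
                raise ValueError(f"sweep population {w.population!r} undefined")
            if not 0 <= w.position < self.sequence_length:
                raise ValueError("sweep position outside [0, L)")
            if w.s < 0:
                raise ValueError("selection coefficient must be >= 0")
            if w.onset_time >= birth[w.population]:
                raise ValueError("sweep onset predates its population")
        for p in self.populations:
            if p.size < 2 or p.sample_size < 1 or p.sample_size > p.size:
                raise ValueError(f"bad sizes for population {p.name!r}")
        # desk-scale guard on expected segregating sites
        n_max = max(p.size for p in self.populations)
        theta = 4 * n_max * self.mutation_rate * self.sequence_length
        expected_s = theta * (np.log(2 * n_max) + 1) * len(self.populations)
        if expected_s > 1e6:
            raise ValueError(
                f"expected segregating sites ~{expected_s:.2g} exceeds 1e6 guard"
            )


@dataclass
class SimulationTruth:
    seed: int
    sample_sizes: dict[str, int]
    sweep_position: int | None = None
    selection_coefficient: float | None = None
    fixation_generation: int | None = None  # generations before present
    sweep_lost: bool = False
    n_restarts: int = 0
    pulse_time: int | None = None
    pulse_source: str | None = None
    pulse_dest: str | None = None
    pulse_fraction: float | None = None


@dataclass
class SimulatedDataset:
    genotypes: GenotypeMatrix
    popmap: PopulationMap
    ancestral: np.ndarray            # per-site ancestral-by-convention allele
    outgroup_polymorphic: np.ndarray  # per-site flag
    truth: SimulationTruth
    chrom_lengths: dict[str, int]
    diversity_trace: list[tuple[int, float]] | None = None


# ---------------------------------------------------------------------------
# engine internals
# ---------------------------------------------------------------------------

#: generations between fixed/lost-site compactions (output-invariant)
_PRUNE_INTERVAL = 8


class _State:
    """Mutable simulator state: a shared site table + per-population haplotypes."""

    def __init__(self, sequence_length: int):
        self.L = sequence_length
        self.positions = np.empty(0, dtype=np.int64)
        self.pos_set: set[int] = set()
        self.haps: dict[str, np.ndarray] = {}
        self.sweep_pos: int | None = None

    def clone(self) -> "_State":
        st = _State(self.L)
        st.positions = self.positions.copy()
        st.pos_set = set(self.pos_set)
        st.haps = {k: v.copy() for k, v in self.haps.items()}
        st.sweep_pos = self.sweep_pos
        return st

    @property
    def n_sites(self) -> int:
        return int(self.positions.size)

    def sweep_col(self) -> int | None:
        if self.sweep_pos is None:
            return None
        idx = np.nonzero(self.positions == self.sweep_pos)[0]
        return int(idx[0]) if idx.size else None

    def add_columns(self, new_positions: np.ndarray, carriers: dict[str, np.ndarray]):
        """Insert new mutation columns keeping positions sorted.

        ``carriers[pop]`` gives (haplotype rows, block column indices) of the
        single carriers, indexed into the order of ``new_positions``.
        """
        m = new_positions.size
        if m == 0:
            return
        order = np.argsort(new_positions, kind="stable")
        new_sorted = new_positions[order]
        rank = np.empty(m, dtype=np.intp)
        rank[order] = np.arange(m)
        idx = np.searchsorted(self.positions, new_sorted)
        s_old = self.positions.size
        old_target = np.arange(s_old) + np.searchsorted(idx, np.arange(s_old), "right")
        new_target = idx + np.arange(m)
        pos = np.empty(s_old + m, dtype=np.int64)
        pos[old_target] = self.positions
        pos[new_target] = new_sorted
        self.positions = pos
        self.pos_set.update(int(p) for p in new_positions)
        for pop, h in self.haps.items():
            out = np.zeros((h.shape[0], s_old + m), dtype=np.uint8)
            out[:, old_target] = h
            if pop in carriers:
                rows, cols = carriers[pop]
                out[rows, new_target[rank[cols]]] = 1
            self.haps[pop] = out

    def prune(self) -> None:
        """Drop sites lost everywhere or fixed everywhere."""
        if self.n_sites == 0:
            return
        tot = np.zeros(self.n_sites, dtype=np.int64)
        n_haps = 0
        for h in self.haps.values():
            tot += h.sum(axis=0, dtype=np.int64)
            n_haps += h.shape[0]
        keep = (tot > 0) & (tot < n_haps)
        if keep.all():
            return
        dropped = self.positions[~keep]
        self.pos_set.difference_update(int(p) for p in dropped)
        self.positions = self.positions[keep]
        for pop in self.haps:
            self.haps[pop] = np.ascontiguousarray(self.haps[pop][:, keep])
        if self.sweep_pos is not None and self.sweep_pos not in self.pos_set:
            self.sweep_pos = None


from numba import njit


@njit(cache=True)
def _gamete_kernel(pool_a, pool_b, from_b, parents, starts, cut_offsets, cuts,
                   ins_idx, out):
    """Assemble gametes by copying haplotype segments between crossover cuts.

    ``cuts`` holds, per gamete (ranges given by ``cut_offsets``), sorted OLD
    column indices where the copied haplotype switches.  ``ins_idx`` gives
    sorted OLD column indices before which a fresh (all-zero) mutation column
    is spliced in, so ``out`` has ``pool.shape[1] + len(ins_idx)`` columns.
    ``from_b`` selects the migrant pool (admixture pulse).
    """
    n_gam = out.shape[0]
    s_old = pool_a.shape[1]
    m = ins_idx.size
    for g in range(n_gam):
        pool = pool_b if from_b[g] else pool_a
        h0 = pool[2 * parents[g] + starts[g]]
        h1 = pool[2 * parents[g] + 1 - starts[g]]
        use0 = True
        ci = cut_offsets[g]
        ci_end = cut_offsets[g + 1]
        ii = 0
        src = 0
        dst = 0
        while src < s_old:
            next_cut = cuts[ci] if ci < ci_end else s_old
            next_ins = ins_idx[ii] if ii < m else s_old
            stop = min(next_cut, next_ins)
            if stop > src:
                h = h0 if use0 else h1
                shift = dst - src
                for j in range(src, stop):
                    out[g, j + shift] = h[j]
                dst += stop - src
                src = stop
            while ci < ci_end and cuts[ci] == src:
                use0 = not use0
                ci += 1
            while ii < m and ins_idx[ii] == src:
                out[g, dst] = 0
                dst += 1
                ii += 1
        while ii < m:
            out[g, dst] = 0
            dst += 1
            ii += 1


def _meiosis_rows(
    pool: np.ndarray,
    parents: np.ndarray,
    starts: np.ndarray,
    n_cross: np.ndarray,
    positions: np.ndarray,
    L: int,
    rng: np.random.Generator,
    out: np.ndarray,
    ins_idx: np.ndarray,
    migrant_pool: np.ndarray | None = None,
    from_migrant: np.ndarray | None = None,
) -> None:
    """Fill ``out`` with gametes; ``positions`` must be sorted ascending."""
    n_gam = out.shape[0]
    total = int(n_cross.sum())
    breaks = rng.integers(0, L, size=total)
    offsets = np.zeros(n_gam + 1, dtype=np.int64)
    np.cumsum(n_cross, out=offsets[1:])
    # convert breakpoints to column cut indices, sorted within each gamete
    cuts = np.searchsorted(positions, breaks, side="left").astype(np.int64)
    for g in np.nonzero(n_cross > 1)[0]:
        cuts[offsets[g]:offsets[g + 1]].sort()
    if migrant_pool is None:
        migrant_pool = pool
        from_migrant = np.zeros(n_gam, dtype=np.bool_)
    _gamete_kernel(
        pool, migrant_pool, from_migrant,
        parents.astype(np.int64), starts.astype(np.int64),
        offsets, cuts, ins_idx, out,
    )


def _reproduce(
    state: _State,
    pop: str,
    n_offspring: int,
    rng: np.random.Generator,
    rec_rate: float,
    s: float,
    sweep_here: bool,
    pulse_from: str | None,
    pulse_f: float,
    ins_idx: np.ndarray,
) -> np.ndarray:
    haps = state.haps[pop]
    n_dip = haps.shape[0] // 2
    n_gam = 2 * n_offspring
    weights = None
    if sweep_here and s > 0:
        col = state.sweep_col()
        if col is not None:
            dos = haps[0::2, col].astype(np.float64) + haps[1::2, col]
            weights = 1.0 + s * dos
            if np.all(weights == weights[0]):
                weights = None
    if weights is None:
        parents = rng.integers(0, n_dip, size=n_gam)
    else:
        parents = rng.choice(n_dip, size=n_gam, p=weights / weights.sum())
    starts = rng.integers(0, 2, size=n_gam)
    n_cross = rng.poisson(state.L * rec_rate, size=n_gam)

    child = np.empty((n_gam, haps.shape[1] + ins_idx.size), dtype=haps.dtype)
    migrant_pool = None
    from_migrant = None
    if pulse_from is not None and pulse_f > 0:
        from_migrant = rng.random(n_gam) < pulse_f
        migrant_pool = state.haps[pulse_from]
        n_src = migrant_pool.shape[0] // 2
        n_mig = int(from_migrant.sum())
        parents = parents.copy()
        parents[from_migrant] = rng.integers(0, n_src, size=n_mig)
    _meiosis_rows(
        haps, parents, starts, n_cross, state.positions, state.L, rng,
        child, ins_idx, migrant_pool, from_migrant,
    )
    return child


def _draw_positions(state: _State, m: int, rng: np.random.Generator) -> np.ndarray:
    """Draw m fresh infinite-sites positions (collisions resampled)."""
    out = np.empty(m, dtype=np.int64)
    taken = state.pos_set
    filled = 0
    while filled < m:
        cand = rng.integers(0, state.L, size=m - filled)
        for c in cand:
            c = int(c)
            if c not in taken:
                out[filled] = c
                taken.add(c)
                filled += 1
    return out


class _Engine:
    def __init__(self, config: SimulationConfig):
        config.validate()
        self.cfg = config
        self.ss = np.random.SeedSequence(config.seed)
        self.rng = np.random.default_rng(self.ss.spawn(1)[0])
        self.sizes = {p.name: p.size for p in config.populations}
        self.root = config.populations[0].name
        self.birth: dict[int, list[SplitEvent]] = {}
        for s in config.splits:
            self.birth.setdefault(s.time, []).append(s)
        self.t_max = max((s.time for s in config.splits), default=0)
        if config.sweep is not None:
            self.t_max = max(self.t_max, config.sweep.onset_time)
        if config.pulse is not None:
            self.t_max = max(self.t_max, config.pulse.time)
        self.t_max = max(self.t_max, config.extra_generations)
        self.truth = SimulationTruth(
            seed=config.seed,
            sample_sizes={p.name: p.sample_size for p in config.populations},
        )
        if config.pulse is not None:
            pu = config.pulse
            self.truth.pulse_time = pu.time
            self.truth.pulse_source = pu.source
            self.truth.pulse_dest = pu.dest
            self.truth.pulse_fraction = pu.fraction
        if config.sweep is not None:
            self.truth.sweep_position = config.sweep.position
            self.truth.selection_coefficient = config.sweep.s
        self.trace: list[tuple[int, float]] = []

    # -- generation bookkeeping ------------------------------------------

    def _mu_at(self, burn_in_done: bool) -> float:
        if burn_in_done and self.cfg.mutation_stops_after_burn_in:
            return 0.0
        return self.cfg.mutation_rate

    def _step(self, state: _State, t: int, rng: np.random.Generator,
              sweep_fixed: bool, burn_in_done: bool = True) -> None:
        """Advance every population one generation (events at time t applied)."""
        cfg = self.cfg
        for ev in self.birth.get(t, []):
            # the child's first generation is drawn from the parent pool by
            # ordinary reproduction below — no extra founding drift
            state.haps[ev.child] = state.haps[ev.parent].copy()
        pulse = cfg.pulse if (cfg.pulse is not None and cfg.pulse.time == t) else None

        # draw this generation's mutations up front so the gamete kernel can
        # splice the new (all-zero) columns in a single pass
        mu = self._mu_at(burn_in_done)
        new_pos_parts: list[np.ndarray] = []
        carrier_parts: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        offset = 0
        if mu > 0:
            for pop in state.haps:
                n_haps = 2 * self.sizes[pop]
                m = int(rng.poisson(n_haps * state.L * mu))
                if m == 0:
                    continue
                new_pos_parts.append(_draw_positions(state, m, rng))
                carrier_parts[pop] = (
                    rng.integers(0, n_haps, size=m).astype(np.intp),
                    np.arange(offset, offset + m, dtype=np.intp),
                )
                offset += m
        m_total = offset
        if m_total:
            new_all = np.concatenate(new_pos_parts)
            order = np.argsort(new_all, kind="stable")
            new_sorted = new_all[order]
            rank = np.empty(m_total, dtype=np.intp)
            rank[order] = np.arange(m_total)
            ins_idx = np.searchsorted(state.positions, new_sorted).astype(np.int64)
            new_target = ins_idx + np.arange(m_total)
        else:
            ins_idx = np.empty(0, dtype=np.int64)

        children = {}
        for pop in state.haps:
            sweep_here = (
                cfg.sweep is not None
                and pop == cfg.sweep.population
                and not sweep_fixed
            )
            children[pop] = _reproduce(
                state, pop, self.sizes[pop], rng,
                rec_rate=cfg.recombination_rate,
                s=cfg.sweep.s if cfg.sweep is not None else 0.0,
                sweep_here=sweep_here,
                pulse_from=pulse.source if (pulse and pulse.dest == pop) else None,
                pulse_f=pulse.fraction if pulse else 0.0,
                ins_idx=ins_idx,
            )
        for pop, child in children.items():
            if pop in carrier_parts:
                rows, cols = carrier_parts[pop]
                child[rows, new_target[rank[cols]]] = 1
            state.haps[pop] = child
        if m_total:
            s_old = state.positions.size
            old_target = np.arange(s_old) + np.searchsorted(
                ins_idx, np.arange(s_old), "right"
            )
            pos = np.empty(s_old + m_total, dtype=np.int64)
            pos[old_target] = state.positions
            pos[new_target] = new_sorted
            state.positions = pos

    def _sweep_status(self, state: _State) -> str:
        """'absent' | 'segregating' | 'fixed' | 'lost' in the sweep population."""
        cfg = self.cfg
        if cfg.sweep is None:
            return "absent"
        col = state.sweep_col()
        if col is None:
            # status is checked before pruning, so a vanished column means loss
            return "lost"
        h = state.haps[cfg.sweep.population]
        c = int(h[:, col].sum())
        if c == 0:
            return "lost"
        if c == h.shape[0]:
            return "fixed"
        return "segregating"

    # -- phases -----------------------------------------------------------

    def run(self) -> SimulatedDataset:
        cfg = self.cfg
        state = _State(cfg.sequence_length)
        n_root = self.sizes[self.root]
        state.haps[self.root] = np.zeros((2 * n_root, 0), dtype=np.uint8)

        burn_in = cfg.burn_in_factor * n_root
        for g in range(burn_in):
            self._step(state, t=self.t_max + 1, rng=self.rng,
                       sweep_fixed=True, burn_in_done=False)
            if g % _PRUNE_INTERVAL == 0:
                state.prune()
        state.prune()

        onset = cfg.sweep.onset_time if cfg.sweep is not None else 0
        self._run_span(state, self.t_max, onset, self.rng, sweep_fixed=True)

        if cfg.sweep is not None:
            state = self._sweep_phase(state, onset)

        return self._sample(state)

    def _run_span(self, state: _State, t_from: int, t_to: int,
                  rng: np.random.Generator, sweep_fixed: bool,
                  record_fixation: bool = False,
                  stop_on_loss: bool = False) -> bool:
        """Simulate generations t_from down to t_to (exclusive).

        Returns False when the sweep allele was lost and ``stop_on_loss`` is
        set; otherwise runs to completion.  Sets ``self._record_fixed`` /
        ``self._record_lost`` for the caller.
        """
        fixed = sweep_fixed
        lost = False
        for t in range(t_from, t_to, -1):
            self._step(state, t, rng, sweep_fixed=fixed or lost)
            if record_fixation and not fixed and not lost:
                status = self._sweep_status(state)
                if status == "lost":
                    lost = True
                    if stop_on_loss:
                        return False
                elif status == "fixed":
                    fixed = True
                    if self.truth.fixation_generation is None:
                        self.truth.fixation_generation = t - 1
            if t % _PRUNE_INTERVAL == 0:
                state.prune()
            if self.cfg.trace_interval and t % self.cfg.trace_interval == 0:
                self.trace.append((t, self._expected_heterozygosity(state)))
        state.prune()
        self._record_fixed = fixed
        self._record_lost = lost
        return True

    def _expected_heterozygosity(self, state: _State) -> float:
        h = state.haps[self.root]
        if state.n_sites == 0:
            return 0.0
        p = h.mean(axis=0)
        return float(np.sum(2 * p * (1 - p)) / state.L)

    def _introduce_sweep(self, state: _State, rng: np.random.Generator) -> None:
        cfg = self.cfg
        pos = int(cfg.sweep.position)
        while pos in state.pos_set:
            pos = (pos + 1) % state.L
        pop = cfg.sweep.population
        carrier = int(rng.integers(0, state.haps[pop].shape[0]))
        state.add_columns(
            np.asarray([pos], dtype=np.int64),
            {pop: (np.asarray([carrier], dtype=np.intp),
                   np.asarray([0], dtype=np.intp))},
        )
        state.sweep_pos = pos
        self.truth.sweep_position = pos

    def _sweep_phase(self, base: _State, onset: int) -> _State:
        cfg = self.cfg
        attempts = self.ss.spawn(cfg.max_restarts)
        for attempt, child_ss in enumerate(attempts):
            rng = np.random.default_rng(child_ss)
            conditioned = cfg.sweep.condition_on_fixation
            state = base.clone() if conditioned else base
            self.truth.fixation_generation = None
            self._introduce_sweep(state, rng)
            ok = self._run_span(
                state, onset, 0, rng, sweep_fixed=False,
                record_fixation=True, stop_on_loss=conditioned,
            )
            if not conditioned:
                self.truth.sweep_lost = self._record_lost
                self.truth.n_restarts = 0
                return state
            if ok and self._record_fixed:
                self.truth.n_restarts = attempt
                return state
        raise RuntimeError(
            f"sweep failed to fix in {cfg.max_restarts} restarts"
        )

    # -- output ------------------------------------------------------------

    def _sample(self, state: _State) -> SimulatedDataset:
        cfg = self.cfg
        rng = self.rng
        order = np.argsort(state.positions, kind="stable")
        positions = state.positions[order]

        sample_ids: list[str] = []
        assignments: dict[str, str] = {}
        blocks: list[np.ndarray] = []
        og_block = None
        for p in cfg.populations:
            h = state.haps[p.name][:, order] if state.n_sites else state.haps[p.name]
            chosen = rng.choice(h.shape[0] // 2, size=p.sample_size, replace=False)
            chosen.sort()
            dos = (h[2 * chosen] + h[2 * chosen + 1]).astype(np.int16)
            blocks.append(dos)
            if cfg.outgroup == p.name:
                og_block = h[np.concatenate([2 * chosen, 2 * chosen + 1])]
            for i in range(p.sample_size):
                sid = f"{p.name}_{i}"
                sample_ids.append(sid)
                assignments[sid] = p.name
        derived = np.concatenate(blocks, axis=0)

        n_hap_total = 2 * derived.shape[0]
        tot = derived.sum(axis=0, dtype=np.int64)
        keep = (tot > 0) & (tot < n_hap_total)
        positions = positions[keep]
        derived = derived[:, keep]

        n_sites = positions.size
        if cfg.outgroup is not None and og_block is not None:
            og = og_block[:, keep].sum(axis=0, dtype=np.int64)
            og_n = og_block.shape[0]
            og_poly = (og > 0) & (og < og_n)
            consensus_derived = og > og_n / 2  # tie -> ancestral consensus
        else:
            og_poly = np.zeros(n_sites, dtype=bool)
            consensus_derived = np.zeros(n_sites, dtype=bool)

        anc_idx = rng.integers(0, 4, size=n_sites)
        der_off = rng.integers(1, 4, size=n_sites)
        der_idx = (anc_idx + der_off) % 4
        anc_letter = _LETTERS[anc_idx]
        der_letter = _LETTERS[der_idx]
        ref = np.where(consensus_derived, der_letter, anc_letter)
        alt = np.where(consensus_derived, anc_letter, der_letter)
        dosage = np.where(consensus_derived[None, :], 2 - derived, derived).astype(
            np.int8
        )

        matrix = GenotypeMatrix(
            sample_ids=sample_ids,
            chrom=np.asarray([cfg.chrom_name] * n_sites, dtype=object),
            pos=positions + 1,  # 1-based VCF coordinates
            ref=np.asarray(ref, dtype=object),
            alt=np.asarray(alt, dtype=object),
            dosage=dosage,
        )
        return SimulatedDataset(
            genotypes=matrix,
            popmap=PopulationMap(assignments),
            ancestral=np.asarray(ref, dtype=object),
            outgroup_polymorphic=og_poly,
            truth=self.truth,
            chrom_lengths={cfg.chrom_name: cfg.sequence_length},
            diversity_trace=self.trace if cfg.trace_interval else None,
        )


def simulate(config: SimulationConfig) -> SimulatedDataset:
    """Run one forward simulation; same seed gives bit-identical output."""
    return _Engine(config).run()


# ---------------------------------------------------------------------------
# canned scenarios (the study conditions used by tests and drivers)
# ---------------------------------------------------------------------------

def quartet_config(
    seed: int,
    pulse_fraction: float = 0.0,
    pulse_time: int = 20,
    n: int = 100,
    length: int = 500_000,
    mu: float = 4e-7,
    rec: float = 1e-6,
    samples: tuple[int, int, int, int] = (8, 8, 8, 4),
) -> SimulationConfig:
    """Four-taxon scenario {[(P1,P2),P3],OUT} with an optional P3->P2 pulse.

    Split times are fractions of 2N generations (0.3, 0.75 and 2.0) so that
    incomplete lineage sorting leaves plenty of informative ABBA/BABA sites,
    as in closely related crop/wild-relative groups.  Mutation and
    recombination are scaled up so a 500 kb pseudo-chromosome carries many
    quasi-independent gene trees — the regime the block jackknife assumes.
    """
    pulse = (
        AdmixturePulse(time=pulse_time, source="P3", dest="P2", fraction=pulse_fraction)
        if pulse_fraction > 0
        else None
    )
    return SimulationConfig(
        populations=[
            PopulationSpec("P1", n, samples[0]),
            PopulationSpec("P2", n, samples[1]),
            PopulationSpec("P3", n, samples[2]),
            PopulationSpec("OUT", n, samples[3]),
        ],
        splits=[
            SplitEvent("OUT", "P1", 400),
            SplitEvent("P3", "P1", 150),
            SplitEvent("P2", "P1", 60),
        ],
        outgroup="OUT",
        sequence_length=length,
        mutation_rate=mu,
        recombination_rate=rec,
        pulse=pulse,
        seed=seed,
    )


def sweep_config(
    seed: int,
    s: float = 0.1,
    n: int = 500,
    length: int = 1_000_000,
    mu: float = 5e-8,
    rec: float = 1e-6,
    with_sweep: bool = True,
    position: int | None = None,
    onset: int = 200,
    outgroup_split: int = 1500,
    n_out: int = 100,
    samples: tuple[int, int] = (40, 6),
) -> SimulationConfig:
    """Single focal population plus outgroup, optional conditioned hard sweep."""
    sweep = (
        SweepConfig(
            population="FOC",
            position=position if position is not None else length // 2,
            s=s,
            onset_time=onset,
            condition_on_fixation=True,
        )
        if with_sweep
        else None
    )
    return SimulationConfig(
        populations=[
            PopulationSpec("FOC", n, samples[0]),
            PopulationSpec("OUT", n_out, samples[1]),
        ],
        splits=[SplitEvent("OUT", "FOC", outgroup_split)],
        outgroup="OUT",
        sequence_length=length,
        mutation_rate=mu,
        recombination_rate=rec,
        sweep=sweep,
        seed=seed,
    )


def pair_config(
    seed: int,
    pulse_fraction: float = 0.0,
    pulse_time: int = 30,
    n: int = 100,
    length: int = 400_000,
    mu: float = 4e-7,
    rec: float = 1e-6,
    samples: tuple[int, int, int] = (8, 8, 6),
) -> SimulationConfig:
    """Two focal populations plus outgroup, optional recent B->A pulse."""
    pulse = (
        AdmixturePulse(time=pulse_time, source="B", dest="A", fraction=pulse_fraction)
        if pulse_fraction > 0
        else None
    )
    return SimulationConfig(
        populations=[
            PopulationSpec("A", n, samples[0]),
            PopulationSpec("B", n, samples[1]),
            PopulationSpec("OUT", n, samples[2]),
        ],
        splits=[
            SplitEvent("OUT", "A", 1200),
            SplitEvent("B", "A", 600),
        ],
        outgroup="OUT",
        sequence_length=length,
        mutation_rate=mu,
        recombination_rate=rec,
        pulse=pulse,
        seed=seed,
    )


def neutral_config(
    seed: int,
    n: int = 200,
    length: int = 200_000,
    mu: float = 1e-8,
    rec: float = 1e-8,
    sample_size: int = 20,
    **kwargs,
) -> SimulationConfig:
    """Single neutral population, no outgroup."""
    return SimulationConfig(
        populations=[PopulationSpec("POP", n, sample_size)],
        splits=[],
        outgroup=None,
        sequence_length=length,
        mutation_rate=mu,
        recombination_rate=rec,
        seed=seed,
        **kwargs,
    )


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def write_dataset(dataset: SimulatedDataset, directory) -> None:
    """Write VCF, population map TSV, truth (key-value) and chrom lengths."""
    from pathlib import Path

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    m = dataset.genotypes

    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(d / "variants.vcf", "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, length in dataset.chrom_lengths.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write(
            '##INFO=<ID=OGP,Number=0,Type=Flag,'
            'Description="Outgroup sample polymorphic at this site">\n'
        )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(m.sample_ids)
            + "\n"
        )
        for j in range(m.n_variants):
            info = "OGP" if dataset.outgroup_polymorphic[j] else "."
            gts = "\t".join(gt_str[int(m.dosage[i, j])] for i in range(m.n_samples))
            fh.write(
                f"{m.chrom[j]}\t{m.pos[j]}\t.\t{m.ref[j]}\t{m.alt[j]}\t.\tPASS\t"
                f"{info}\tGT\t{gts}\n"
            )

    with open(d / "popmap.tsv", "w") as fh:
        for sample, pop in dataset.popmap.assignments.items():
            fh.write(f"{sample}\t{pop}\n")

    with open(d / "truth.txt", "w") as fh:
        yaml.safe_dump(asdict(dataset.truth), fh, sort_keys=False)

    with open(d / "chrom_lengths.tsv", "w") as fh:
        for chrom, length in dataset.chrom_lengths.items():
            fh.write(f"{chrom}\t{length}\n")


def read_truth(path) -> SimulationTruth:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return SimulationTruth(**data)


def read_chrom_lengths(path) -> dict[str, int]:
    out: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if line.strip():
                chrom, length = line.split("\t")
                out[chrom] = int(length)
    return out


def load_config(path) -> SimulationConfig:
    """Load a simulation config from a plain-text key-value (YAML) file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    raw["populations"] = [PopulationSpec(**p) for p in raw["populations"]]
    raw["splits"] = [SplitEvent(**s) for s in raw.get("splits", [])]
    if raw.get("pulse"):
        raw["pulse"] = AdmixturePulse(**raw["pulse"])
    if raw.get("sweep"):
        raw["sweep"] = SweepConfig(**raw["sweep"])
    return SimulationConfig(**raw)
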