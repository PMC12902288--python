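"""Structured-coalescent simulator with admixture pulses.

Generates multi-deme SNP datasets with the statistical structure the
downstream analyses assume: population splits, epoch-wise continuous
migration, instantaneous unidirectional admixture pulses, and
infinite-sites mutation on independent non-recombining loci.  The same
engine drives the demographic-inference module (via branch-length SFS
accumulation) and the synthetic test data for the whole pipeline.

Model of time: generations, measured backwards from the present (time 0).
Deme sizes are diploid effective sizes; a pair of lineages in a deme of
size ``Ne`` coalesces at rate ``1/(2*Ne)`` per generation.  Migration
rates are *backward* lineage rates: ``m[(a, b)]`` is the per-generation
probability that a lineage currently traced in deme ``a`` originated in
deme ``b`` (i.e. forward-time migration b -> a).  A forward-time pulse
``source -> dest`` with proportion ``phi`` relocates each lineage in
``dest`` to ``source`` with probability ``phi`` at the event time.

Seed policy: one root seed; locus ``i`` uses two child RNG streams
derived as ``SeedSequence(root_seed, spawn_key=(i, k))`` with ``k=0`` for
the genealogy/mutation stream and ``k=1`` for pulse relocation draws.
Pulse decisions never touch the genealogy stream, so a ``phi = 0`` pulse
moves no lineages and leaves the genealogy distribution unchanged (the
event still truncates waiting-time draws at its time point, which is
distribution-neutral by the memorylessness of the exponential clock).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Callable, Iterator, Sequence

import numpy as np

__all__ = [
    "Split",
    "Pulse",
    "MigrationChange",
    "SizeChange",
    "DemographicModel",
    "SimulatedDataset",
    "simulate",
    "simulate_trees",
    "scenario_preset",
    "degrade",
    "write_vcf",
    "PRESET_NAMES",
]

ANCESTRAL_ALLELE = "A"
DERIVED_ALLELE = "T"


# ---------------------------------------------------------------------------
# demographic events and model


@dataclass(frozen=True)
class Split:
    """Backwards in time, all lineages in ``child`` move into ``parent``."""

    time: float
    child: str
    parent: str


@dataclass(frozen=True)
class Pulse:
    """Forward-time admixture pulse ``source -> dest`` of proportion phi."""

    time: float
    source: str
    dest: str
    proportion: float


@dataclass(frozen=True)
class MigrationChange:
    """Replace the backward migration-rate matrix at ``time``."""

    time: float
    rates: tuple  # tuple of ((from, to), rate) pairs, hashable

    @staticmethod
    def of(time: float, rates: dict) -> "MigrationChange":
        return MigrationChange(time, tuple(sorted(rates.items())))

    def rate_dict(self) -> dict:
        return dict(self.rates)


@dataclass(frozen=True)
class SizeChange:
    time: float
    deme: str
    ne: float


Event = Split | Pulse | MigrationChange | SizeChange


class ModelError(ValueError):
    """Structural problem with a demographic model."""


@dataclass
class DemographicModel:
    """Deme sizes, time-ordered events, migration and mutation parameters.

    Parameters
    ----------
    demes
        Mapping deme name -> diploid effective size at time 0.
    events
        Events ordered by strictly increasing backwards time.
    mutation_rate
        Per site per generation.
    migration
        Initial backward migration rates ``(from, to) -> rate``; may be
        replaced later (pastwards) by :class:`MigrationChange` events.
    generation_time
        Years per generation, used only when scaling to absolute units.
    """

    demes: dict[str, float]
    events: list[Event] = field(default_factory=list)
    mutation_rate: float = 6.675e-8
    migration: dict[tuple[str, str], float] = field(default_factory=dict)
    generation_time: float = 10.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.demes:
            raise ModelError("model needs at least one deme")
        for name, ne in self.demes.items():
            if not ne > 0:
                raise ModelError(f"deme {name!r} has non-positive Ne {ne}")
        if self.mutation_rate < 0:
            raise ModelError("mutation rate must be >= 0")
        times = [e.time for e in self.events]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ModelError("event times must be strictly increasing backwards in time")
        if times and times[0] <= 0:
            raise ModelError("event times must be positive")
        alive = set(self.demes)
        for ev in self.events:
            if isinstance(ev, Split):
                if ev.child not in alive:
                    raise ModelError(f"split child {ev.child!r} not alive at t={ev.time}")
                if ev.parent not in alive:
                    raise ModelError(f"split parent {ev.parent!r} not alive at t={ev.time}")
                alive.remove(ev.child)
            elif isinstance(ev, Pulse):
                if not 0.0 <= ev.proportion <= 1.0:
                    raise ModelError(f"pulse proportion {ev.proportion} outside [0, 1]")
                for d in (ev.source, ev.dest):
                    if d not in alive:
                        raise ModelError(f"pulse deme {d!r} not alive at t={ev.time}")
            elif isinstance(ev, MigrationChange):
                for (a, b), r in ev.rate_dict().items():
                    if r < 0:
                        raise ModelError(f"negative migration rate {a}->{b}")
            elif isinstance(ev, SizeChange):
                if ev.deme not in alive:
                    raise ModelError(f"size change for dead deme {ev.deme!r}")
                if not ev.ne > 0:
                    raise ModelError("size change to non-positive Ne")
        for (a, b), r in self.migration.items():
            if r < 0:
                raise ModelError(f"negative migration rate {a}->{b}")
        if len(alive) != 1:
            raise ModelError(
                f"exactly one root deme must remain after all splits; got {sorted(alive)}"
            )

    def to_dict(self) -> dict:
        return {
            "demes": dict(self.demes),
            "events": [
                {"kind": type(e).__name__, **dataclasses.asdict(e)} for e in self.events
            ],
            "mutation_rate": self.mutation_rate,
            "migration": {f"{a}>{b}": r for (a, b), r in self.migration.items()},
            "generation_time": self.generation_time,
        }


# ---------------------------------------------------------------------------
# dataset container


@dataclass
class SimulatedDataset:
    """Genotypes plus site metadata and a ground-truth record.

    ``haplotypes`` is a (2*n_diploids, n_sites) 0/1 derived-allele matrix;
    consecutive haplotype rows 2k, 2k+1 form diploid sample k.  ``missing``
    masks diploid genotype calls (samples x sites).  Positions are 0-based
    and strictly increasing within each contig.
    """

    samples: list[str]
    sample_pops: list[str]
    contigs: dict[str, int]
    site_contig: np.ndarray  # contig name per site
    positions: np.ndarray  # 0-based per-contig positions
    haplotypes: np.ndarray  # uint8 (2n, S)
    qual: np.ndarray  # float per site, NaN when unset
    missing: np.ndarray  # bool (n, S)
    truth: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[1]

    def genotypes(self) -> np.ndarray:
        """Diploid derived-allele dosage, -1 where masked missing."""
        g = (self.haplotypes[0::2] + self.haplotypes[1::2]).astype(np.int8)
        g[self.missing] = -1
        return g

    def mean_pairwise_diversity(self) -> float:
        """Mean pairwise differences per simulated base (ignores masking)."""
        h = self.haplotypes
        n = h.shape[0]
        d = h.sum(axis=0).astype(float)
        pair_diff = (d * (n - d)).sum() / (n * (n - 1) / 2)
        return pair_diff / sum(self.contigs.values())


# ---------------------------------------------------------------------------
# core per-locus genealogy simulation


def _locus_rngs(seed: int, locus: int) -> tuple[np.random.Generator, np.random.Generator]:
    main = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed, spawn_key=(locus, 0))))
    pulse = np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed, spawn_key=(locus, 1))))
    return main, pulse


def _sim_genealogy(
    model: DemographicModel,
    leaf_demes: np.ndarray,
    deme_index: dict[str, int],
    rng: np.random.Generator,
    pulse_rng: np.random.Generator,
    pulse_log: list | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate one genealogy; returns (parent, node_time).

    Nodes 0..n-1 are leaves; internal nodes are appended in coalescence
    order, so every parent index exceeds its children's indices.  The
    root's parent is -1.
    """
    n = len(leaf_demes)
    n_demes = len(deme_index)
    names = {v: k for k, v in deme_index.items()}
    parent = np.full(2 * n - 1, -1, dtype=np.int64)
    node_time = np.zeros(2 * n - 1)
    # lineage bookkeeping: per-deme python lists of active node ids
    by_deme: list[list[int]] = [[] for _ in range(n_demes)]
    for node, d in enumerate(leaf_demes):
        by_deme[d].append(node)
    ne = np.zeros(n_demes)
    for name, i in deme_index.items():
        ne[i] = model.demes[name]
    mig = np.zeros((n_demes, n_demes))
    for (a, b), r in model.migration.items():
        mig[deme_index[a], deme_index[b]] = r
    events = list(model.events)
    ei = 0
    t = 0.0
    next_node = n
    n_active = n
    # scalar python state in the hot loop; numpy overhead dominates otherwise
    ne_l = ne.tolist()
    mig_rows = [mig[i].tolist() for i in range(n_demes)]
    mig_row_sum = [sum(r) for r in mig_rows]
    exponential = rng.exponential
    uniform = rng.random
    while n_active > 1:
        coal_rate = [len(g) * (len(g) - 1) / (4.0 * ne_l[i])
                     for i, g in enumerate(by_deme)]
        mig_rate = [len(g) * mig_row_sum[i] for i, g in enumerate(by_deme)]
        total = sum(coal_rate) + sum(mig_rate)
        ev_time = events[ei].time if ei < len(events) else np.inf
        dt = exponential(1.0 / total) if total > 0 else np.inf
        if t + dt >= ev_time:
            if not np.isfinite(ev_time):
                occupied = sorted(names[i] for i in range(n_demes) if by_deme[i])
                raise ModelError(
                    "lineages cannot reach a common ancestor; demes "
                    f"{occupied} are isolated with no further events"
                )
            t = ev_time
            ev = events[ei]
            ei += 1
            if isinstance(ev, Split):
                c, p = deme_index[ev.child], deme_index[ev.parent]
                by_deme[p].extend(by_deme[c])
                by_deme[c] = []
                mig_rows[c] = [0.0] * n_demes
                for i in range(n_demes):
                    mig_rows[i][c] = 0.0
                mig_row_sum = [sum(r) for r in mig_rows]
            elif isinstance(ev, Pulse):
                s, d = deme_index[ev.source], deme_index[ev.dest]
                moved, stay = [], []
                n_dest = len(by_deme[d])
                draws = pulse_rng.random(n_dest) if n_dest else []
                for node, u in zip(by_deme[d], draws):
                    (moved if u < ev.proportion else stay).append(node)
                by_deme[d] = stay
                by_deme[s].extend(moved)
                if pulse_log is not None:
                    pulse_log.append(
                        {"time": ev.time, "source": ev.source, "dest": ev.dest,
                         "n_in_dest": n_dest, "n_moved": len(moved)}
                    )
            elif isinstance(ev, MigrationChange):
                mig_rows = [[0.0] * n_demes for _ in range(n_demes)]
                for (a, b), r in ev.rate_dict().items():
                    mig_rows[deme_index[a]][deme_index[b]] = r
                mig_row_sum = [sum(r) for r in mig_rows]
            elif isinstance(ev, SizeChange):
                ne_l[deme_index[ev.deme]] = ev.ne
            continue
        t += dt
        u = uniform() * total
        acc = 0.0
        done = False
        for i in range(n_demes):
            acc += coal_rate[i]
            if u < acc:
                g = by_deme[i]
                m_g = len(g)
                a = int(uniform() * m_g)
                b = int(uniform() * (m_g - 1))
                if b >= a:
                    b += 1
                if a > b:
                    a, b = b, a
                nb = g.pop(b)
                na = g.pop(a)
                parent[na] = next_node
                parent[nb] = next_node
                node_time[next_node] = t
                g.append(next_node)
                next_node += 1
                n_active -= 1
                done = True
                break
        if done:
            continue
        for i in range(n_demes):
            acc += mig_rate[i]
            if u < acc:
                g = by_deme[i]
                node = g.pop(int(uniform() * len(g)))
                row = mig_rows[i]
                v = uniform() * mig_row_sum[i]
                acc2 = 0.0
                dest = n_demes - 1
                for j in range(n_demes):
                    acc2 += row[j]
                    if v < acc2:
                        dest = j
                        break
                by_deme[dest].append(node)
                break
    return parent, node_time


def _leaf_layout(
    model: DemographicModel, sampling: dict[str, int]
) -> tuple[np.ndarray, dict[str, int], list[str], list[str]]:
    unknown = set(sampling) - set(model.demes)
    if unknown:
        raise ModelError(f"sampling demes not in model: {sorted(unknown)}")
    deme_index = {name: i for i, name in enumerate(model.demes)}
    leaf_demes = []
    samples, sample_pops = [], []
    for deme, n_dip in sampling.items():
        if n_dip < 0:
            raise ModelError("negative sample count")
        for i in range(n_dip):
            samples.append(f"{deme}_{i}")
            sample_pops.append(deme)
            leaf_demes.extend([deme_index[deme]] * 2)
    return np.array(leaf_demes), deme_index, samples, sample_pops


def simulate_trees(
    model: DemographicModel,
    sampling: dict[str, int],
    n_loci: int,
    seed: int,
) -> Iterator[tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Yield (parent, node_time, leaf_deme_index) for independent loci.

    Lightweight entry point for consumers that need genealogies rather
    than mutations (e.g. branch-length SFS accumulation).
    """
    leaf_demes, deme_index, _, _ = _leaf_layout(model, sampling)
    for locus in range(n_loci):
        rng, pulse_rng = _locus_rngs(seed, locus)
        parent, node_time = _sim_genealogy(model, leaf_demes, deme_index, rng, pulse_rng)
        yield parent, node_time, leaf_demes


def _drop_mutations(
    parent: np.ndarray,
    node_time: np.ndarray,
    mu: float,
    locus_length: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Poisson infinite-sites mutations; returns (positions, carrier node per mutation)."""
    n_nodes = len(parent)
    has_parent = parent >= 0
    blen = np.zeros(n_nodes)
    blen[has_parent] = node_time[parent[has_parent]] - node_time[np.nonzero(has_parent)[0]]
    total = blen.sum()
    n_mut = rng.poisson(mu * locus_length * total) if total > 0 else 0
    n_mut = min(n_mut, locus_length)  # infinite-sites cap at one mutation per bp
    if n_mut == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    branches = rng.choice(n_nodes, size=n_mut, p=blen / total)
    positions = rng.choice(locus_length, size=n_mut, replace=False)
    order = np.argsort(positions)
    return positions[order], branches[order]


def _descendant_matrix(parent: np.ndarray, n_leaves: int) -> np.ndarray:
    """Boolean (n_nodes, n_leaves) leaf-descendancy matrix (index order is topological)."""
    n_nodes = len(parent)
    desc = np.zeros((n_nodes, n_leaves), dtype=bool)
    desc[np.arange(n_leaves), np.arange(n_leaves)] = True
    for v in range(n_nodes - 1):
        if parent[v] >= 0:
            desc[parent[v]] |= desc[v]
    return desc


def simulate(
    model: DemographicModel,
    sampling: dict[str, int],
    n_loci: int = 100,
    locus_length: int = 1000,
    seed: int = 0,
    n_contigs: int = 1,
) -> SimulatedDataset:
    """Simulate independent non-recombining loci and drop infinite-sites mutations.

    Loci are laid out consecutively on ``n_contigs`` contigs (round-robin
    blocks), so positions within a contig are strictly increasing.
    Monomorphic sites never arise (mutations always fall on branches with
    a proper leaf subset below them).
    """
    if n_loci <= 0 or locus_length <= 0:
        raise ModelError("n_loci and locus_length must be positive")
    leaf_demes, deme_index, samples, sample_pops = _leaf_layout(model, sampling)
    n_hap = len(leaf_demes)
    if n_hap < 2:
        raise ModelError("need at least two haplotypes (one diploid sample)")
    loci_per_contig = [n_loci // n_contigs + (1 if i < n_loci % n_contigs else 0)
                       for i in range(n_contigs)]
    contigs = {f"contig{i + 1}": loci_per_contig[i] * locus_length for i in range(n_contigs)}
    hap_cols, pos_all, contig_all = [], [], []
    pulse_log: list = []
    locus = 0
    for ci, n_in_contig in enumerate(loci_per_contig):
        cname = f"contig{ci + 1}"
        for li in range(n_in_contig):
            rng, pulse_rng = _locus_rngs(seed, locus)
            parent, node_time = _sim_genealogy(
                model, leaf_demes, deme_index, rng, pulse_rng, pulse_log
            )
            positions, branches = _drop_mutations(
                parent, node_time, model.mutation_rate, locus_length, rng
            )
            if len(positions):
                desc = _descendant_matrix(parent, n_hap)
                hap_cols.append(desc[branches].T.astype(np.uint8))
                pos_all.append(positions + li * locus_length)
                contig_all.append(np.repeat(cname, len(positions)))
            locus += 1
    if hap_cols:
        haplotypes = np.concatenate(hap_cols, axis=1)
        positions_arr = np.concatenate(pos_all)
        site_contig = np.concatenate(contig_all)
    else:
        haplotypes = np.zeros((n_hap, 0), dtype=np.uint8)
        positions_arr = np.empty(0, dtype=np.int64)
        site_contig = np.empty(0, dtype=object)
    n_dip = n_hap // 2
    truth = {
        "model": model.to_dict(),
        "seed": seed,
        "n_loci": n_loci,
        "locus_length": locus_length,
        "pulses": pulse_log,
    }
    return SimulatedDataset(
        samples=samples,
        sample_pops=sample_pops,
        contigs=contigs,
        site_contig=site_contig,
        positions=positions_arr,
        haplotypes=haplotypes,
        qual=np.full(haplotypes.shape[1], np.nan),
        missing=np.zeros((n_dip, haplotypes.shape[1]), dtype=bool),
        truth=truth,
    )


# ---------------------------------------------------------------------------
# presets

PRESET_NAMES = (
    "study_null",
    "study_pulse",
    "pair_IM_early",
    "pair_IM_different",
    "pair_IM_constant",
    "pair_IM_recent",
)

# Study-system calibration: deepest ingroup/outgroup structure anchored at a
# 6.4 My species split (640 000 generations at 10 y/generation), ecotype
# splits at ~3.56 kya and ~36.93 kya, and a recent HS -> TP_E pulse.
STUDY_SPLITS = {
    "tp_em": 356.0,      # TP_E/TP_M divergence, ~3.56 kya
    "tp_w": 3_693.0,     # TP_W vs (TP_E, TP_M), ~36.93 kya
    "species": 640_000.0,  # HS vs D. catenatum ancestor, 6.4 Mya
    "outgroup": 1_280_000.0,  # outgroup J join (chosen, not data-derived)
}
# Diploid Ne large enough that ancestral polymorphism straddles the species
# split (2Ne of the same order as the split depth), as the ABBA-BABA framework
# assumes; widespread outcrossing plants commonly reach this range.
STUDY_NE = 200_000.0
STUDY_PULSE_TIME = 100.0  # generations (~1 kya), more recent than any split
MUTATION_RATE = 6.675e-8
GENERATION_TIME = 10.0

# Two-deme isolation-with-migration template defaults.
PAIR_NE = 10_000.0
PAIR_SPLIT = 20_000.0  # generations
PAIR_M = 2.5e-5  # backward per-lineage migration rate per generation
PAIR_EPOCH_FRACTION = 0.5  # boundary between "recent" and "early" epochs


def _study_model(phi: float) -> DemographicModel:
    demes = {"HS": STUDY_NE, "TP_E": STUDY_NE, "TP_M": STUDY_NE,
             "TP_W": STUDY_NE, "J": STUDY_NE}
    events: list[Event] = []
    if phi > 0:
        events.append(Pulse(STUDY_PULSE_TIME, source="HS", dest="TP_E", proportion=phi))
    events += [
        Split(STUDY_SPLITS["tp_em"], child="TP_M", parent="TP_E"),
        Split(STUDY_SPLITS["tp_w"], child="TP_W", parent="TP_E"),
        Split(STUDY_SPLITS["species"], child="TP_E", parent="HS"),
        Split(STUDY_SPLITS["outgroup"], child="HS", parent="J"),
    ]
    return DemographicModel(
        demes=demes, events=events, mutation_rate=MUTATION_RATE,
        generation_time=GENERATION_TIME,
    )


def _pair_model(
    ne: float = PAIR_NE,
    t_split: float = PAIR_SPLIT,
    m: float = PAIR_M,
    m_old: float | None = None,
    epoch: str = "constant",
    epoch_fraction: float = PAIR_EPOCH_FRACTION,
    pulse: tuple[str, str, float, float] | None = None,
) -> DemographicModel:
    """Two-deme IM template; ``epoch`` selects the migration-epoch structure.

    constant: symmetric migration on [0, t_split)
    recent:   migration only on [0, f*t_split)
    early:    migration only on [f*t_split, t_split)
    different: rate m on [0, f*t_split), rate m_old on [f*t_split, t_split)
    """
    demes = {"A": ne, "B": ne}
    t_epoch = epoch_fraction * t_split
    sym = lambda r: {("A", "B"): r, ("B", "A"): r}
    events: list[Event] = []
    if epoch == "constant":
        migration = sym(m)
    elif epoch == "recent":
        migration = sym(m)
        events.append(MigrationChange.of(t_epoch, {}))
    elif epoch == "early":
        migration = {}
        events.append(MigrationChange.of(t_epoch, sym(m)))
    elif epoch == "different":
        migration = sym(m)
        events.append(MigrationChange.of(t_epoch, sym(m_old if m_old is not None else m)))
    else:
        raise ModelError(f"unknown epoch structure {epoch!r}")
    if pulse is not None:
        src, dst, tp, phi = pulse
        if phi > 0:
            events.insert(0, Pulse(tp, source=src, dest=dst, proportion=phi))
            events.sort(key=lambda e: e.time)
    events.append(Split(t_split, child="B", parent="A"))
    return DemographicModel(
        demes=demes, events=events, mutation_rate=MUTATION_RATE,
        migration=migration, generation_time=GENERATION_TIME,
    )


def scenario_preset(name: str, phi: float = 0.1, **kwargs) -> DemographicModel:
    """Fully parameterized demographic model for a named scenario.

    ``study_pulse``/``study_null`` are the five-deme study system (HS,
    TP_E, TP_M, TP_W, outgroup J) with/without a single HS -> TP_E pulse.
    The four ``pair_IM_*`` presets are two-deme isolation-with-migration
    templates differing only in migration-epoch structure: early, recent,
    constant, or two different epoch rates.
    """
    if name == "study_null":
        return _study_model(0.0)
    if name == "study_pulse":
        return _study_model(phi)
    if name == "pair_IM_constant":
        return _pair_model(epoch="constant", **kwargs)
    if name == "pair_IM_recent":
        return _pair_model(epoch="recent", **kwargs)
    if name == "pair_IM_early":
        return _pair_model(epoch="early", **kwargs)
    if name == "pair_IM_different":
        return _pair_model(epoch="different", **kwargs)
    raise ValueError(f"unknown preset {name!r}; valid presets: {', '.join(PRESET_NAMES)}")


# ---------------------------------------------------------------------------
# degradation and VCF export


def degrade(
    data: SimulatedDataset,
    missing_rate: float,
    qual_distribution,
    seed: int = 0,
) -> SimulatedDataset:
    """RAD-seq-style degradation: independent genotype masking + per-site QUAL.

    ``qual_distribution`` is either a number (constant QUAL) or an object
    with an ``rvs(size, random_state)`` method (e.g. a frozen scipy.stats
    distribution).
    """
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError("missing_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    n, s = data.n_samples, data.n_sites
    missing = data.missing.copy()
    if missing_rate > 0:
        missing |= rng.random((n, s)) < missing_rate
    if np.isscalar(qual_distribution):
        qual = np.full(s, float(qual_distribution))
    else:
        qual = np.asarray(qual_distribution.rvs(size=s, random_state=rng), dtype=float)
    truth = dict(data.truth)
    truth["degrade"] = {"missing_rate": missing_rate, "seed": seed}
    return dataclasses.replace(data, missing=missing, qual=qual, truth=truth)


_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}


def write_vcf(data: SimulatedDataset, path, popmap_path, truth_path=None) -> None:
    """Write a VCFv4.2 (GT + QUAL) plus a sample->population TSV.

    Round-trips losslessly through :func:`introflow.genotypes.read_vcf`
    (derived dosage, positions, QUAL and missingness are preserved).
    """
    if data.n_sites == 0:
        raise ValueError("refusing to write an empty dataset")
    g = data.genotypes()
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=introflow.coalsim\n")
        for cname, clen in data.contigs.items():
            fh.write(f"##contig=<ID={cname},length={clen}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(data.samples) + "\n")
        for j in range(data.n_sites):
            q = data.qual[j]
            qs = "." if np.isnan(q) else f"{q:g}"
            row = [
                str(data.site_contig[j]),
                str(int(data.positions[j]) + 1),  # VCF is 1-based
                ".",
                ANCESTRAL_ALLELE,
                DERIVED_ALLELE,
                qs,
                "PASS",
                ".",
                "GT",
            ] + [_GT_STR[int(x)] for x in g[:, j]]
            fh.write("\t".join(row) + "\n")
    with open(popmap_path, "w") as fh:
        for s, p in zip(data.samples, data.sample_pops):
            fh.write(f"{s}\t{p}\n")
    if truth_path is not None:
        with open(truth_path, "w") as fh:
            json.dump(data.truth, fh, indent=1, sort_keys=True)
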