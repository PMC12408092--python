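"""Forward-in-time Wright-Fisher dynamics with interleaved clonal and
sexual generations.

The population holds N diploid individuals.  In a clonal generation each
of the N offspring copies both haplotypes of a single fitness-weighted
parent; in a sexual generation each offspring is the union of two
gametes from two independently drawn fitness-weighted parents (drawn
with replacement, so self-pairing occurs with probability 1/N).

The neutral genome is discretized: each chromosome is represented by its
tracked neutral loci (one per diversity window), plus the selected site.
Gametes are formed by a no-interference switch process: the starting
homolog is chosen with probability 1/2 per chromosome and the active
homolog switches between consecutive sites with the Haldane recombination
fraction for the gap.

Genealogy recording: at every reproduction event the parent haplotype
slot of each offspring haplotype at each tracked locus is appended to
``Population.history``.  Sample genealogies are later obtained by
backward lineage tracing (:mod:`meiosweep.genealogy_diversity`), which is
equivalent to tree-sequence recording followed by simplification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from meiosweep.lifecycle_core import (
    ConfigurationError,
    GenomeMap,
    LifeCycleConfig,
    MeiosisSchedule,
    SelectionParams,
    build_schedule,
    fitness_array,
)
from meiosweep.sweep_theory import haldane_r

__all__ = [
    "Population",
    "SweepReplicateResult",
    "adjacent_recombination_fractions",
    "make_gamete",
    "reproduce_clonal",
    "reproduce_sexual",
    "run_selected_locus_only",
    "conditional_fixation_times",
    "full_sim_fixation_time",
    "run_sweep_replicate",
    "run_neutral",
]


def adjacent_recombination_fractions(gmap: GenomeMap) -> list:
    """Per-meiosis recombination fractions between consecutive tracked loci.

    For each chromosome, returns the array of r values between adjacent
    tracked neutral loci, r_i = (1 - exp(-2 d_i))/2 with
    d_i = gap_bp * rho_alpha.  Loci on different chromosomes assort
    independently (r = 1/2).
    """
    out = []
    for _, pos in gmap.chromosomes:
        gaps = np.diff(np.asarray(pos, dtype=float))
        out.append(haldane_r(gaps * gmap.rho_alpha))
    return out


class _TransmissionPlan:
    """Merged per-chromosome site lists (neutral loci + selected site)
    with adjacent recombination fractions, used for gamete formation."""

    def __init__(self, gmap: GenomeMap):
        self.gmap = gmap
        self.chrom_sites: list = []        # per chromosome: sorted bp positions
        self.chrom_fracs: list = []        # per chromosome: r between adjacent sites
        self.chrom_locus_cols: list = []   # per chromosome: (site index, global locus index)
        self.sel_chrom, sel_bp = gmap.selected_position
        self.sel_col: int = -1
        locus_id = 0
        for ci, (_, pos) in enumerate(gmap.chromosomes):
            sites = list(pos)
            locus_cols = [(i, locus_id + i) for i in range(len(pos))]
            if ci == self.sel_chrom:
                sites = sorted(set(sites) | {sel_bp})
                idx = {p: i for i, p in enumerate(sites)}
                locus_cols = [(idx[p], locus_id + j) for j, p in enumerate(pos)]
                self.sel_col = idx[sel_bp]
            sites_arr = np.asarray(sites, dtype=float)
            self.chrom_sites.append(sites_arr)
            self.chrom_fracs.append(haldane_r(np.diff(sites_arr) * gmap.rho_alpha))
            self.chrom_locus_cols.append(locus_cols)
            locus_id += len(pos)
        self.n_loci = locus_id


@dataclass
class Population:
    """State of the diploid population.

    Haplotype slot ``2*i`` and ``2*i + 1`` belong to individual ``i``.
    ``sel_allele[slot]`` is 0/1 for the beneficial allele on that
    haplotype; the individual genotype is the sum over its two slots.
    ``history[g]`` is the (2N, n_loci) array of parent haplotype slots
    for the reproduction event that produced generation ``g + 1``.
    """

    N: int
    plan: _TransmissionPlan
    sel_allele: np.ndarray = field(default=None)
    generation: int = 0
    n_sexual: int = 0
    history: list = field(default_factory=list)
    record: bool = True

    def __post_init__(self) -> None:
        if self.sel_allele is None:
            self.sel_allele = np.zeros(2 * self.N, dtype=np.int8)

    @classmethod
    def initial(cls, N: int, gmap: GenomeMap, record: bool = True) -> "Population":
        return cls(N=N, plan=_TransmissionPlan(gmap), record=record)

    @property
    def sel_genotype(self) -> np.ndarray:
        return self.sel_allele[0::2] + self.sel_allele[1::2]

    def snapshot(self) -> dict:
        return {
            "sel_allele": self.sel_allele.copy(),
            "generation": self.generation,
            "n_sexual": self.n_sexual,
            "history_len": len(self.history),
        }

    def restore(self, snap: dict) -> None:
        self.sel_allele = snap["sel_allele"].copy()
        self.generation = snap["generation"]
        self.n_sexual = snap["n_sexual"]
        del self.history[snap["history_len"]:]


def _parent_weights(pop: Population, sel: Optional[SelectionParams]) -> np.ndarray:
    if sel is None or sel.s == 0:
        return np.full(pop.N, 1.0 / pop.N)
    w = fitness_array(sel)[pop.sel_genotype]
    tot = w.sum()
    if tot <= 0:
        raise RuntimeError("all parental fitnesses are zero")
    return w / tot


def _gametes(pop: Population, parents: np.ndarray, rng: np.random.Generator):
    """Vectorized gamete formation for ``len(parents)`` gametes.

    Returns (slot matrix over tracked loci, beneficial allele vector).
    """
    plan = pop.plan
    n = len(parents)
    slots = np.empty((n, plan.n_loci), dtype=np.int32)
    sel_allele = None
    for ci, sites in enumerate(plan.chrom_sites):
        m = len(sites)
        bits = np.empty((n, m), dtype=bool)
        bits[:, 0] = rng.random(n) < 0.5
        if m > 1:
            bits[:, 1:] = rng.random((n, m - 1)) < plan.chrom_fracs[ci]
        homolog = np.bitwise_xor.accumulate(bits, axis=1)
        chrom_slots = 2 * parents[:, None] + homolog
        for site_i, locus_j in plan.chrom_locus_cols[ci]:
            slots[:, locus_j] = chrom_slots[:, site_i]
        if ci == plan.sel_chrom:
            sel_allele = pop.sel_allele[chrom_slots[:, plan.sel_col]]
    return slots, sel_allele


def make_gamete(pop: Population, parent: int, rng: np.random.Generator):
    """Form one gamete from ``parent``: (parent slot per tracked locus,
    beneficial allele carried).  Thin wrapper over the vectorized path."""
    slots, allele = _gametes(pop, np.array([parent]), rng)
    return slots[0], int(allele[0])


def reproduce_clonal(pop: Population, sel: Optional[SelectionParams],
                     rng: np.random.Generator) -> Population:
    """One clonal (mitotic) generation, in place.

    Each of N offspring copies both haplotypes of one fitness-weighted
    parent.  Within-individual haplotype pairs can never coalesce along
    a clonal chain.
    """
    parents = rng.choice(pop.N, size=pop.N, p=_parent_weights(pop, sel))
    if pop.record:
        rec = np.empty((2 * pop.N, pop.plan.n_loci), dtype=np.int32)
        rec[0::2] = (2 * parents)[:, None]
        rec[1::2] = (2 * parents + 1)[:, None]
        pop.history.append(rec)
    new_allele = np.empty_like(pop.sel_allele)
    new_allele[0::2] = pop.sel_allele[2 * parents]
    new_allele[1::2] = pop.sel_allele[2 * parents + 1]
    pop.sel_allele = new_allele
    pop.generation += 1
    return pop


def reproduce_sexual(pop: Population, sel: Optional[SelectionParams],
                     rng: np.random.Generator) -> Population:
    """One sexual (meiotic) generation, in place.

    Each offspring unites gametes from two independently drawn
    fitness-weighted parents (with replacement)."""
    p = _parent_weights(pop, sel)
    parents1 = rng.choice(pop.N, size=pop.N, p=p)
    parents2 = rng.choice(pop.N, size=pop.N, p=p)
    slots1, allele1 = _gametes(pop, parents1, rng)
    slots2, allele2 = _gametes(pop, parents2, rng)
    if pop.record:
        rec = np.empty((2 * pop.N, pop.plan.n_loci), dtype=np.int32)
        rec[0::2] = slots1
        rec[1::2] = slots2
        pop.history.append(rec)
    new_allele = np.empty_like(pop.sel_allele)
    new_allele[0::2] = allele1
    new_allele[1::2] = allele2
    pop.sel_allele = new_allele
    pop.generation += 1
    pop.n_sexual += 1
    return pop


def _step(pop: Population, sexual: bool, sel: Optional[SelectionParams],
          rng: np.random.Generator) -> Population:
    return (reproduce_sexual if sexual else reproduce_clonal)(pop, sel, rng)


# ---------------------------------------------------------------------------
# Selected-locus-only simulation (genotype counts; the full model
# marginalized to the selected site).

def run_selected_locus_only(cfg: LifeCycleConfig, sel: SelectionParams,
                            schedule: MeiosisSchedule, rng: np.random.Generator):
    """Evolve genotype counts from a single heterozygote to fixation or loss.

    Clonal generations draw offspring genotype counts from a
    fitness-weighted multinomial over the three genotypes; sexual
    generations draw them from the Hardy-Weinberg probabilities implied
    by the fitness-weighted parental gamete frequency.  Returns the
    number of generations to all-homozygote fixation, or ``None`` on
    loss or when the schedule horizon is exhausted.
    """
    N = cfg.N
    w = fitness_array(sel)
    counts = np.array([N - 1, 1, 0], dtype=np.int64)
    for g, sexual in enumerate(schedule.flags):
        wc = w * counts
        tot = wc.sum()
        if sexual:
            q = (0.5 * wc[1] + wc[2]) / tot
            probs = np.array([(1 - q) ** 2, 2 * q * (1 - q), q * q])
        else:
            probs = wc / tot
        counts = rng.multinomial(N, probs)
        if counts[2] == N:
            return g + 1
        if counts[1] == 0 and counts[2] == 0:
            return None
    return None


def conditional_fixation_times(cfg: LifeCycleConfig, sel: SelectionParams,
                               n_fixing: int, rng: np.random.Generator,
                               max_attempts: int = 2_000_000) -> np.ndarray:
    """Fixation times of ``n_fixing`` replicates that fix, rerunning on loss.

    The beneficial mutation is introduced immediately after a sexual
    generation: each attempt starts a fresh schedule, whose first sexual
    generation falls one full interval later.
    """
    times = []
    horizon = cfg.max_sweep_generations
    fixed_schedule = None
    if cfg.schedule_mode == "fixed":
        fixed_schedule = build_schedule(cfg, horizon, rng)
    for _ in range(max_attempts):
        schedule = fixed_schedule or build_schedule(cfg, horizon, rng)
        t = run_selected_locus_only(cfg, sel, schedule, rng)
        if t is not None:
            times.append(t)
            if len(times) == n_fixing:
                return np.array(times)
    raise RuntimeError(f"only {len(times)} fixations in {max_attempts} attempts")


def full_sim_fixation_time(cfg: LifeCycleConfig, gmap: GenomeMap, sel: SelectionParams,
                           rng: np.random.Generator):
    """Fixation time of one sweep attempt in the full simulator, without
    genealogy recording (None on loss/timeout).  Starts from one
    heterozygote in an otherwise wild-type population; the schedule is
    anchored at the introduction, as in the genotype-count simulator."""
    schedule = build_schedule(cfg, cfg.max_sweep_generations, rng)
    pop = Population.initial(cfg.N, gmap, record=False)
    pop.sel_allele[int(rng.integers(2 * cfg.N))] = 1
    for g in range(cfg.max_sweep_generations):
        _step(pop, bool(schedule.flags[g]), sel, rng)
        tot = int(pop.sel_allele.sum())
        if tot == 0:
            return None
        if tot == 2 * cfg.N:
            return g + 1
    return None


# ---------------------------------------------------------------------------
# Full replicates.

@dataclass
class SweepReplicateResult:
    """Outcome of one conditioned sweep replicate."""

    fixation_time: int
    n_meioses_during_sweep: int
    attempts: int
    population: Population
    sample_individuals: np.ndarray
    sample_slots: np.ndarray
    schedule: MeiosisSchedule


def _neutral_phase(cfg: LifeCycleConfig, gmap: GenomeMap, rng: np.random.Generator,
                   generations: int, schedule: MeiosisSchedule,
                   record: bool = True) -> Population:
    pop = Population.initial(cfg.N, gmap, record=record)
    for g in range(generations):
        _step(pop, bool(schedule.flags[g]), None, rng)
    return pop


def run_neutral(cfg: LifeCycleConfig, gmap: GenomeMap, rng: np.random.Generator,
                generations: int = 10_000, record: bool = True) -> tuple:
    """Neutral forward evolution under the alpha schedule.

    Returns ``(population, schedule)``; genealogies are extracted from
    ``population.history`` by :mod:`meiosweep.genealogy_diversity`.
    """
    schedule = build_schedule(cfg, generations, rng)
    pop = _neutral_phase(cfg, gmap, rng, generations, schedule, record=record)
    return pop, schedule


def sample_individuals(pop: Population, sample_size: int, rng: np.random.Generator):
    """Draw individuals without replacement (all of them if N < sample_size);
    returns (individual ids, haplotype slots)."""
    n = min(sample_size, pop.N)
    ind = np.sort(rng.choice(pop.N, size=n, replace=False))
    slots = np.empty(2 * n, dtype=np.int64)
    slots[0::2] = 2 * ind
    slots[1::2] = 2 * ind + 1
    return ind, slots


def run_sweep_replicate(cfg: LifeCycleConfig, gmap: GenomeMap, sel: SelectionParams,
                        rng: np.random.Generator, sample_size: int = 100,
                        attempts_cap: int = 500,
                        strict_rerun: bool = False) -> SweepReplicateResult:
    """Burn in neutrally, introduce one beneficial copy, condition on fixation.

    The mutation enters a random haplotype of a random individual at the
    configured position immediately after the burn-in (which, in fixed
    mode, ends on a sexual generation whenever ``burn_in`` is a multiple
    of the interval).  On loss, or if fixation has not occurred within
    ``max_sweep_generations``, the sweep phase restarts from the
    post-burn-in state with fresh randomness (``strict_rerun=True``
    instead reruns the burn-in as well).  Raises after ``attempts_cap``
    failed attempts.
    """
    horizon = cfg.burn_in + cfg.max_sweep_generations
    schedule = build_schedule(cfg, horizon, rng)
    pop = _neutral_phase(cfg, gmap, rng, cfg.burn_in, schedule, record=True)

    attempts = 0
    while True:
        attempts += 1
        if attempts > attempts_cap:
            raise RuntimeError(
                f"sweep failed to fix in {attempts_cap} attempts "
                f"(N={cfg.N}, s={sel.s}, h={sel.h}, alpha={cfg.alpha})"
            )
        snap = pop.snapshot()
        mutant_slot = int(rng.integers(2 * cfg.N))
        pop.sel_allele[mutant_slot] = 1
        meioses = 0
        fixed_at = None
        for g in range(cfg.burn_in, horizon):
            sexual = bool(schedule.flags[g])
            _step(pop, sexual, sel, rng)
            if sexual:
                meioses += 1
            tot = int(pop.sel_allele.sum())
            if tot == 0:
                break
            if tot == 2 * cfg.N:
                fixed_at = pop.generation
                break
        if fixed_at is not None:
            break
        # loss or timeout: rerun
        if strict_rerun:
            schedule = build_schedule(cfg, horizon, rng)
            pop = _neutral_phase(cfg, gmap, rng, cfg.burn_in, schedule, record=True)
        else:
            pop.restore(snap)

    ind, slots = sample_individuals(pop, sample_size, rng)
    return SweepReplicateResult(
        fixation_time=fixed_at - cfg.burn_in,
        n_meioses_during_sweep=meioses,
        attempts=attempts,
        population=pop,
        sample_individuals=ind,
        sample_slots=slots,
        schedule=schedule,
    )
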