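"""Genealogy extraction, simplification, root grafting, mutation overlay
and windowed nucleotide diversity.

The forward simulator records, for every reproduction event, the parent
haplotype slot of each offspring haplotype at each tracked neutral locus.
Backward lineage tracing through that record yields the simplified
genealogy of any sample directly (every internal node is a coalescence;
pairwise TMRCAs are exact).  Non-coalesced roots are completed with a
neutral Kingman coalescent (pairwise rate 1/(2N) per generation) before
neutral mutations are overlaid as a Poisson process on branches
(infinite sites within a window).

Node times are *forward* birth generations (grafted nodes may be
negative); branch lengths are time differences child minus parent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "GenealogyTables",
    "VariantTable",
    "WindowDiversity",
    "tables_from_history",
    "full_tables_from_history",
    "simplify",
    "graft_roots",
    "overlay_mutations",
    "window_pi",
    "branch_pi",
    "summarize_windows",
    "pairwise_tmrca",
    "diversity_from_population",
]


@dataclass
class GenealogyTables:
    """Per-locus genealogy: birth time and parent id per node.

    ``samples`` are the node ids of the sampled haplotypes (leaves).
    Roots have parent -1.  Birth times strictly decrease child -> parent.
    """

    times: np.ndarray
    parent: np.ndarray
    samples: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.parent = np.asarray(self.parent, dtype=np.int64)
        self.samples = np.asarray(self.samples, dtype=np.int64)

    @property
    def n_nodes(self) -> int:
        return len(self.times)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def roots(self) -> np.ndarray:
        return np.flatnonzero(self.parent == -1)

    def branch_lengths(self) -> np.ndarray:
        """Length of the branch above each node (0 for roots)."""
        out = np.zeros(self.n_nodes)
        has = self.parent >= 0
        out[has] = self.times[has] - self.times[self.parent[has]]
        return out

    def sample_descendants(self) -> np.ndarray:
        """Number of sampled leaves below (or at) each node."""
        ndesc = np.zeros(self.n_nodes, dtype=np.int64)
        ndesc[self.samples] = 1
        for i in np.argsort(-self.times, kind="stable"):
            p = self.parent[i]
            if p >= 0:
                ndesc[p] += ndesc[i]
        return ndesc

    def total_branch_length(self) -> float:
        return float(self.branch_lengths().sum())

    def to_records(self):
        """(node, parent, birth_generation) rows for TSV export."""
        return [(i, int(self.parent[i]), float(self.times[i])) for i in range(self.n_nodes)]

    def to_tsv(self, path: str, locus: int = 0) -> None:
        """Write node records as TSV (node, parent, birth_generation, locus)."""
        with open(path, "w") as fh:
            fh.write("node\tparent\tbirth_generation\tlocus\n")
            for node, parent, birth in self.to_records():
                fh.write(f"{node}\t{parent}\t{birth:g}\t{locus}\n")


def tables_from_history(history: Sequence[np.ndarray], locus: int,
                        sample_slots: Sequence[int]) -> GenealogyTables:
    """Backward-trace the genealogy of ``sample_slots`` at one locus.

    ``history[g]`` maps haplotype slots of generation ``g + 1`` to parent
    slots in generation ``g``; the sample lives in generation
    ``len(history)``.  The output contains only sample leaves and their
    coalescences (it is born simplified).
    """
    T = len(history)
    k = len(sample_slots)
    times = [float(T)] * k
    parent = [-1] * k
    active_nodes = np.arange(k, dtype=np.int64)
    active_slots = np.asarray(sample_slots, dtype=np.int64)
    for t in range(T - 1, -1, -1):
        if len(active_nodes) == 1:
            break
        new_slots = history[t][active_slots, locus]
        uniq, inv, counts = np.unique(new_slots, return_inverse=True, return_counts=True)
        if len(uniq) == len(new_slots):
            active_slots = new_slots
            continue
        nodes_out = np.empty(len(uniq), dtype=np.int64)
        for u in range(len(uniq)):
            members = active_nodes[inv == u]
            if len(members) == 1:
                nodes_out[u] = members[0]
            else:
                new_id = len(times)
                times.append(float(t))
                parent.append(-1)
                for m in members:
                    parent[m] = new_id
                nodes_out[u] = new_id
        active_nodes = nodes_out
        active_slots = uniq
    return GenealogyTables(np.array(times), np.array(parent), np.arange(k))


def full_tables_from_history(history: Sequence[np.ndarray], locus: int,
                             n_haplotypes: int) -> GenealogyTables:
    """Unsimplified tables with one node per haplotype per generation.

    Node id of slot ``s`` in generation ``g`` is ``g * n_haplotypes + s``;
    the final generation's haplotypes are the samples.  Intended for
    small populations (tests, oracles)."""
    T = len(history)
    n_nodes = (T + 1) * n_haplotypes
    times = np.repeat(np.arange(T + 1, dtype=float), n_haplotypes)
    parent = np.full(n_nodes, -1, dtype=np.int64)
    for g in range(1, T + 1):
        base = g * n_haplotypes
        parent[base:base + n_haplotypes] = (g - 1) * n_haplotypes + history[g - 1][:, locus]
    samples = np.arange(T * n_haplotypes, n_nodes)
    return GenealogyTables(times, parent, samples)


def simplify(tables: GenealogyTables, samples: Sequence[int]) -> GenealogyTables:
    """Reduce ``tables`` to the ancestry of ``samples``.

    Unary chains are collapsed into single edges; pairwise coalescence
    times of all sample pairs are preserved exactly.  Sample ids come
    first in the output, in the order given.
    """
    samples = np.asarray(samples, dtype=np.int64)
    if np.any(samples < 0) or np.any(samples >= tables.n_nodes):
        raise ValueError("unknown sample id")
    ndesc = np.zeros(tables.n_nodes, dtype=np.int64)
    ndesc[samples] += 1
    order = np.argsort(-tables.times, kind="stable")
    n_active_children = np.zeros(tables.n_nodes, dtype=np.int64)
    for i in order:
        p = tables.parent[i]
        if p >= 0 and ndesc[i] > 0:
            ndesc[p] += ndesc[i]
            n_active_children[p] += 1
    keep = np.zeros(tables.n_nodes, dtype=bool)
    keep[samples] = True
    keep |= n_active_children >= 2
    keep &= ndesc > 0

    new_id = np.full(tables.n_nodes, -1, dtype=np.int64)
    for j, s in enumerate(samples):
        new_id[s] = j
    internal = [i for i in np.flatnonzero(keep) if new_id[i] < 0]
    internal.sort(key=lambda i: -tables.times[i])
    for j, i in enumerate(internal, start=len(samples)):
        new_id[i] = j

    n_new = len(samples) + len(internal)
    new_times = np.empty(n_new)
    new_parent = np.full(n_new, -1, dtype=np.int64)
    for i in np.flatnonzero(keep):
        j = new_id[i]
        new_times[j] = tables.times[i]
        p = tables.parent[i]
        while p >= 0 and not keep[p]:
            p = tables.parent[p]
        new_parent[j] = new_id[p] if p >= 0 else -1
    return GenealogyTables(new_times, new_parent, np.arange(len(samples)))


def graft_roots(tables: GenealogyTables, N: int, rng: np.random.Generator,
                start_time: float | None = None) -> GenealogyTables:
    """Join remaining roots under a neutral Kingman coalescent.

    Pairs of root lineages coalesce at rate 1/(2N) per generation,
    extending the genealogy backward (negative times allowed) until a
    single root remains.  The paper's pipeline does the same with a
    standard coalescent ("recapitation"); the alpha-dependent excess of
    within-individual coalescence times is generated by the forward
    burn-in, not here.
    """
    roots = list(tables.roots())
    if len(roots) <= 1:
        return tables
    times = list(tables.times)
    parent = list(tables.parent)
    t = float(np.min(tables.times[tables.roots()])) if start_time is None else float(start_time)
    while len(roots) > 1:
        k = len(roots)
        rate = k * (k - 1) / 2.0 / (2.0 * N)
        t -= rng.exponential(1.0 / rate)
        i, j = rng.choice(k, size=2, replace=False)
        a, b = roots[i], roots[j]
        new_id = len(times)
        times.append(t)
        parent.append(-1)
        parent[a] = new_id
        parent[b] = new_id
        roots = [r for r in roots if r not in (a, b)] + [new_id]
    return GenealogyTables(np.array(times), np.array(parent), tables.samples.copy())


@dataclass
class VariantTable:
    """Segregating variants in one window: derived count per mutation."""

    derived_counts: np.ndarray
    n_haplotypes: int

    def __post_init__(self) -> None:
        self.derived_counts = np.asarray(self.derived_counts, dtype=np.int64)

    @property
    def records(self):
        return [(i, int(x)) for i, x in enumerate(self.derived_counts)]


def overlay_mutations(tables: GenealogyTables, mu_per_site: float,
                      window_length: int, rng: np.random.Generator) -> VariantTable:
    """Poisson mutation overlay (infinite sites within the window).

    Each branch receives Poisson(mu * window_length * branch_length)
    mutations; each mutation assigns the derived allele to every sampled
    descendant of the branch.  Fixed or absent variants are dropped.
    """
    if mu_per_site < 0:
        raise ValueError("mutation rate must be >= 0")
    n = tables.n_samples
    if mu_per_site == 0:
        return VariantTable(np.array([], dtype=np.int64), n)
    lens = tables.branch_lengths()
    ndesc = tables.sample_descendants()
    nmut = rng.poisson(mu_per_site * window_length * lens)
    counts = np.repeat(ndesc, nmut)
    counts = counts[(counts > 0) & (counts < n)]
    return VariantTable(counts, n)


def window_pi(variants: VariantTable, n_haplotypes: int, window_length: int) -> float:
    """Nucleotide diversity: mean pairwise differences per site.

    pi = sum_v x (2n - x) / (C(2n, 2) * L) over segregating variants.
    Matches tskit's site-mode diversity for the same sample.
    """
    if window_length <= 0:
        raise ValueError("window_length must be > 0")
    if n_haplotypes < 2:
        raise ValueError("need at least two haplotypes")
    x = variants.derived_counts
    npairs = n_haplotypes * (n_haplotypes - 1) / 2.0
    return float(np.sum(x * (n_haplotypes - x)) / (npairs * window_length))


def branch_pi(tables: GenealogyTables, mu_per_site: float) -> float:
    """Branch-mode diversity 2*mu*(mean pairwise TMRCA), a variance-reduced
    alternative to the mutation overlay (no Poisson noise)."""
    n = tables.n_samples
    lens = tables.branch_lengths()
    ndesc = tables.sample_descendants()
    npairs = n * (n - 1) / 2.0
    return float(mu_per_site * np.sum(lens * ndesc * (n - ndesc)) / npairs)


@dataclass
class WindowDiversity:
    """Across-replicate summary of per-window diversity."""

    window_mean: np.ndarray
    window_sd: np.ndarray
    ratio: np.ndarray
    pi0: float
    n_replicates: int
    sd_defined: bool = True


def summarize_windows(pi_by_replicate: np.ndarray, pi0: float) -> WindowDiversity:
    """Mean and SD of pi per window across replicates, and pi/pi0.

    ``pi_by_replicate`` has shape (replicates, windows).  With a single
    replicate the SD is reported as 0 and flagged undefined.
    """
    if pi0 <= 0:
        raise ValueError("pi0 must be > 0")
    arr = np.atleast_2d(np.asarray(pi_by_replicate, dtype=float))
    if arr.shape[0] < 1:
        raise ValueError("need at least one replicate")
    mean = arr.mean(axis=0)
    if arr.shape[0] == 1:
        sd = np.zeros(arr.shape[1])
        defined = False
    else:
        sd = arr.std(axis=0, ddof=1)
        defined = True
    return WindowDiversity(mean, sd, mean / pi0, pi0, arr.shape[0], defined)


def pairwise_tmrca(tables: GenealogyTables, a: int, b: int) -> float:
    """Birth time of the most recent common ancestor of nodes a and b
    (parent-chain walk; -inf when they never coalesce)."""
    anc = {}
    i = a
    while i >= 0:
        anc[i] = tables.times[i]
        i = tables.parent[i]
    j = b
    while j >= 0:
        if j in anc:
            return float(tables.times[j])
        j = tables.parent[j]
    return float("-inf")


def diversity_from_population(pop, sample_slots, mu_per_site: float,
                              rng: np.random.Generator,
                              loci: Sequence[int] | None = None,
                              mode: str = "site") -> np.ndarray:
    """Per-locus window diversity for a sampled set of haplotypes.

    Runs the full pipeline per tracked locus: backward trace, Kingman
    root grafting at the recorded population size, mutation overlay
    (``mode="site"``) or branch-mode expectation (``mode="branch"``).
    """
    gmap = pop.plan.gmap
    loci = range(gmap.n_loci) if loci is None else loci
    out = np.empty(len(list(loci)) if not hasattr(loci, "__len__") else len(loci))
    loci = list(loci)
    for k, locus in enumerate(loci):
        tables = tables_from_history(pop.history, locus, sample_slots)
        tables = graft_roots(tables, pop.N, rng, start_time=0.0)
        if mode == "branch":
            out[k] = branch_pi(tables, mu_per_site)
        else:
            var = overlay_mutations(tables, mu_per_site, gmap.window_length, rng)
            out[k] = window_pi(var, tables.n_samples, gmap.window_length)
    return out
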