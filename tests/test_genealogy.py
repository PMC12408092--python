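"""Genealogy tracing, simplification, root grafting, mutation overlay
and window diversity."""

import numpy as np
import pytest

from meiosweep.forward_simulator import Population, reproduce_clonal, run_neutral, sample_individuals
from meiosweep.genealogy_diversity import (
    GenealogyTables,
    VariantTable,
    branch_pi,
    diversity_from_population,
    full_tables_from_history,
    graft_roots,
    overlay_mutations,
    pairwise_tmrca,
    simplify,
    summarize_windows,
    tables_from_history,
    window_pi,
)
from meiosweep.lifecycle_core import GenomeMap, LifeCycleConfig


def tiny_map(n_loci=1):
    pos = tuple(100 + 100 * i for i in range(n_loci))
    return GenomeMap(chromosomes=((1000, pos),), rho_alpha=1e-4, alpha=1.0)


def small_run(N=10, gens=15, seed=0, alpha=1.0, n_loci=1):
    rng = np.random.default_rng(seed)
    cfg = LifeCycleConfig(N=N, alpha=alpha)
    pop, _ = run_neutral(cfg, tiny_map(n_loci), rng, generations=gens)
    return pop, rng


class TestSimplify:
    def test_tmrca_preserved_against_parent_chain_oracle(self):
        """All pairwise TMRCAs of the simplified tree equal those obtained
        by brute-force parent-chain tracing in the unsimplified tables."""
        for seed in range(5):
            pop, rng = small_run(N=10, gens=15, seed=seed, alpha=0.3)
            full = full_tables_from_history(pop.history, 0, 2 * pop.N)
            samples = rng.choice(full.samples, size=8, replace=False)
            simp = simplify(full, samples)
            for i in range(8):
                for j in range(i + 1, 8):
                    assert pairwise_tmrca(simp, i, j) == pairwise_tmrca(
                        full, samples[i], samples[j]
                    )

    def test_trace_equals_simplify_of_full_tables(self):
        """Backward lineage tracing and generic simplification agree on
        every pairwise coalescence time."""
        pop, rng = small_run(N=8, gens=20, seed=3, alpha=0.5)
        slots = np.arange(2 * pop.N)
        traced = tables_from_history(pop.history, 0, slots)
        full = full_tables_from_history(pop.history, 0, 2 * pop.N)
        simp = simplify(full, full.samples)
        for i in range(0, 16, 3):
            for j in range(i + 1, 16, 3):
                assert pairwise_tmrca(traced, i, j) == pairwise_tmrca(simp, i, j)

    def test_idempotent(self):
        pop, _ = small_run(N=6, gens=12, seed=1)
        full = full_tables_from_history(pop.history, 0, 12)
        once = simplify(full, full.samples)
        twice = simplify(once, once.samples)
        assert np.array_equal(once.times, twice.times)
        assert np.array_equal(once.parent, twice.parent)

    def test_unknown_sample_rejected(self):
        tab = GenealogyTables(np.array([1.0, 1.0, 0.0]), np.array([2, 2, -1]),
                              np.array([0, 1]))
        with pytest.raises(ValueError):
            simplify(tab, [5])

    def test_unary_chains_collapsed(self):
        # 0 -> 2 -> 3 -> root 4, 1 -> 4: node 2, 3 are unary and must vanish
        times = np.array([5.0, 5.0, 4.0, 3.0, 1.0])
        parent = np.array([2, 4, 3, 4, -1])
        simp = simplify(GenealogyTables(times, parent, np.array([0, 1])), [0, 1])
        assert simp.n_nodes == 3
        assert pairwise_tmrca(simp, 0, 1) == 1.0


class TestClonalLineages:
    def test_within_individual_lineages_never_coalesce_clonally(self, rng):
        """Clonal reproduction copies both homologs: the two lineages of an
        individual stay distinct for the whole clonal epoch."""
        pop = Population.initial(2, tiny_map())
        for _ in range(60):
            reproduce_clonal(pop, None, rng)
        tables = tables_from_history(pop.history, 0, [0, 1])
        assert len(tables.roots()) == 2


class TestGraftRoots:
    @staticmethod
    def two_root_tables():
        return GenealogyTables(np.array([0.0, 0.0]), np.array([-1, -1]),
                               np.array([0, 1]))

    def test_single_root_unchanged(self, rng):
        tab = GenealogyTables(np.array([2.0, 2.0, 0.0]), np.array([2, 2, -1]),
                              np.array([0, 1]))
        out = graft_roots(tab, 100, rng)
        assert out.n_nodes == 3

    def test_two_roots_exponential_joint_time(self, rng):
        """The grafted coalescence time of two roots is Exp(mean 2N)."""
        N = 100
        times = []
        for _ in range(10_000):
            out = graft_roots(self.two_root_tables(), N, rng)
            times.append(-out.times[-1])
        mean = np.mean(times)
        se = np.std(times, ddof=1) / np.sqrt(len(times))
        assert abs(mean - 2 * N) < 3 * se

    def test_k_root_total_length_identity(self, rng):
        """E[total grafted branch length] for k equal-time roots is
        4N * sum_{j=1}^{k-1} 1/j (Kingman, pairwise rate 1/(2N))."""
        N, k = 50, 5
        tab = GenealogyTables(np.zeros(k), np.full(k, -1), np.arange(k))
        totals = []
        for _ in range(3000):
            out = graft_roots(tab, N, rng)
            totals.append(out.total_branch_length())
        expected = 4 * N * sum(1.0 / j for j in range(1, k))
        se = np.std(totals, ddof=1) / np.sqrt(len(totals))
        assert abs(np.mean(totals) - expected) < 3 * se


class TestOverlayAndPi:
    @staticmethod
    def cherry(depth=10.0, n=2):
        # n sample leaves at time `depth`, one root at 0
        times = np.concatenate([np.full(n, depth), [0.0]])
        parent = np.concatenate([np.full(n, n, dtype=int), [-1]])
        return GenealogyTables(times, parent, np.arange(n))

    def test_zero_mutation_rate(self, rng):
        var = overlay_mutations(self.cherry(), 0.0, 100, rng)
        assert len(var.derived_counts) == 0
        assert window_pi(var, 4, 10) == 0.0

    def test_poisson_mean(self, rng):
        """E[#mutations] = mu * L * total branch length."""
        tab = self.cherry(depth=10.0)
        mu, L = 1e-3, 100
        counts = [len(overlay_mutations(tab, mu, L, rng).derived_counts)
                  for _ in range(3000)]
        expected = mu * L * 20.0
        se = np.std(counts, ddof=1) / np.sqrt(len(counts))
        assert abs(np.mean(counts) - expected) < 3 * se

    def test_window_pi_single_variant(self):
        # 2n=4, one variant at count 2, L=10: 4 of 6 pairs differ
        var = VariantTable(np.array([2]), 4)
        assert window_pi(var, 4, 10) == pytest.approx(4 / (6 * 10))

    def test_window_pi_matches_haplotype_matrix_oracle(self, rng):
        """pi from derived counts equals brute-force mean pairwise Hamming
        distance over explicit haplotype strings."""
        n, sites, L = 12, 30, 1000
        H = (rng.random((n, sites)) < rng.uniform(0.05, 0.6, size=sites)).astype(int)
        x = H.sum(axis=0)
        keep = (x > 0) & (x < n)
        var = VariantTable(x[keep], n)
        diffs = [np.sum(H[i] != H[j]) for i in range(n) for j in range(i + 1, n)]
        oracle = np.mean(diffs) / L
        assert window_pi(var, n, L) == pytest.approx(oracle)

    def test_site_mode_matches_branch_mode(self, rng):
        """Overlay (site) diversity averages to the branch-mode expectation
        2*mu*(mean pairwise TMRCA) on the same tables."""
        pop, rng2 = small_run(N=20, gens=300, seed=9)
        tables = tables_from_history(pop.history, 0, np.arange(40))
        tables = graft_roots(tables, 20, rng2, start_time=0.0)
        mu, L = 5e-6, 20_000
        b = branch_pi(tables, mu)
        sites = [window_pi(overlay_mutations(tables, mu, L, rng), 40, L)
                 for _ in range(200)]
        se = np.std(sites, ddof=1) / np.sqrt(len(sites))
        assert abs(np.mean(sites) - b) < 3 * se

    def test_site_diversity_matches_tskit(self, rng):
        """Cross-check the pi estimator against tskit's site-mode diversity
        on an identical constructed genealogy."""
        tskit = pytest.importorskip("tskit")
        pop, rng2 = small_run(N=10, gens=120, seed=4)
        tables = tables_from_history(pop.history, 0, np.arange(20))
        tables = graft_roots(tables, 10, rng2, start_time=0.0)
        L = 1000.0
        tc = tskit.TableCollection(sequence_length=L)
        t_max = tables.times.max()
        ids = []
        for i in range(tables.n_nodes):
            flags = tskit.NODE_IS_SAMPLE if i < tables.n_samples else 0
            ids.append(tc.nodes.add_row(flags=flags, time=t_max - tables.times[i]))
        for i in range(tables.n_nodes):
            if tables.parent[i] >= 0:
                tc.edges.add_row(0, L, parent=ids[tables.parent[i]], child=ids[i])
        tc.sort()
        ts = tc.tree_sequence()
        # place one mutation on every node with a parent, at distinct sites
        var_counts = []
        ndesc = tables.sample_descendants()
        for i in range(tables.n_nodes):
            if tables.parent[i] >= 0 and 0 < ndesc[i] < tables.n_samples:
                var_counts.append(ndesc[i])
        ours = window_pi(VariantTable(np.array(var_counts), tables.n_samples),
                         tables.n_samples, int(L))
        pos = 0.5
        for i in range(tables.n_nodes):
            if tables.parent[i] >= 0 and 0 < ndesc[i] < tables.n_samples:
                site = tc.sites.add_row(position=pos, ancestral_state="A")
                tc.mutations.add_row(site=site, node=ids[i], derived_state="T")
                pos += 1
        tc.sort()
        ts = tc.tree_sequence()
        assert ours == pytest.approx(float(ts.diversity(mode="site")), rel=1e-9)


class TestSummaries:
    def test_single_replicate_sd_flagged(self):
        out = summarize_windows(np.array([[1e-5, 2e-5]]), pi0=1e-5)
        assert not out.sd_defined
        assert np.all(out.window_sd == 0)

    def test_self_normalized_ratio_is_one(self):
        arr = np.array([[1e-5], [3e-5]])
        out = summarize_windows(arr, pi0=2e-5)
        assert out.ratio[0] == pytest.approx(1.0)

    def test_known_mean_and_sd(self):
        arr = np.array([[1.0, 2.0], [3.0, 6.0], [5.0, 10.0]])
        out = summarize_windows(arr, pi0=1.0)
        assert out.window_mean.tolist() == [3.0, 6.0]
        assert out.window_sd[0] == pytest.approx(2.0)
        assert out.window_sd[1] == pytest.approx(4.0)

    def test_rejects_bad_pi0(self):
        with pytest.raises(ValueError):
            summarize_windows(np.ones((2, 2)), pi0=0.0)


class TestNeutralExpectations:
    def test_pairwise_coalescence_time_near_2n(self):
        """Obligate sex: sampled pairs coalesce on average ~2N generations ago."""
        N = 30
        per_rep = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            cfg = LifeCycleConfig(N=N, alpha=1.0)
            pop, _ = run_neutral(cfg, tiny_map(), rng, generations=12 * N)
            _, slots = sample_individuals(pop, 10, rng)
            tables = tables_from_history(pop.history, 0, slots)
            tables = graft_roots(tables, N, rng, start_time=0.0)
            T = 12 * N
            times = [T - pairwise_tmrca(tables, i, j)
                     for i in range(10) for j in range(i + 1, 10)]
            per_rep.append(np.mean(times))
        mean = np.mean(per_rep)
        se = np.std(per_rep, ddof=1) / np.sqrt(len(per_rep))
        assert abs(mean - 2 * N) < 3.5 * se

    def test_equilibrium_diversity_near_4nmu(self):
        """Mean pi over windows approaches theta = 4*N*mu at alpha=1."""
        N, mu = 40, 2.5e-7
        pis = []
        for seed in range(25):
            rng = np.random.default_rng(100 + seed)
            cfg = LifeCycleConfig(N=N, alpha=1.0)
            pop, _ = run_neutral(cfg, tiny_map(n_loci=4), rng, generations=10 * N)
            _, slots = sample_individuals(pop, 40, rng)
            pis.append(diversity_from_population(pop, slots, mu, rng).mean())
        mean = np.mean(pis)
        se = np.std(pis, ddof=1) / np.sqrt(len(pis))
        assert abs(mean - 4 * N * mu) < 3 * se
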