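"""Scenario presets, replicate orchestration and group comparisons.

Presets reproduce the study configurations (two 1 Mb chromosomes,
N = 1000, rho = 5e-8 per bp per generation, mu = 1e-8, 20 kb windows,
500 replicates) and carry a scale knob: scaling by a factor ``f < 1``
multiplies N, burn-in and run length by f and divides s, mu and alpha by
f (rho_alpha unchanged), preserving the dimensionless quantities
4*N*mu, 2*N*s, 2*N*alpha*r and alpha*t_s1 that control the sweep
footprint.  When alpha would exceed 1 the remainder of the alpha
rescaling is moved onto rho_alpha, preserving 2*N*alpha*r exactly.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from meiosweep.forward_simulator import (
    run_neutral,
    run_sweep_replicate,
    sample_individuals,
)
from meiosweep.genealogy_diversity import diversity_from_population
from meiosweep.lifecycle_core import (
    ConfigurationError,
    GenomeMap,
    LifeCycleConfig,
    SelectionParams,
)
from meiosweep.sweep_theory import het_sweep_duration

__all__ = [
    "Scenario",
    "ScenarioResult",
    "ComparisonReport",
    "make_presets",
    "scale_scenario",
    "run_scenario",
    "compare_groups",
    "dunn_posthoc",
]


@dataclass(frozen=True)
class Scenario:
    """A complete, runnable experiment configuration."""

    name: str
    lifecycle: LifeCycleConfig
    genome: GenomeMap
    selection: Optional[SelectionParams] = None
    replicates: int = 500
    sample_size: int = 100
    neutral: bool = False
    neutral_generations: int = 10_000
    scale: float = 1.0
    outdir: Optional[str] = None

    def metadata(self) -> dict:
        meta = {
            "name": self.name,
            "lifecycle": dataclasses.asdict(self.lifecycle),
            "genome": dataclasses.asdict(self.genome),
            "selection": dataclasses.asdict(self.selection) if self.selection else None,
            "replicates": self.replicates,
            "sample_size": self.sample_size,
            "neutral": self.neutral,
            "neutral_generations": self.neutral_generations,
            "scale": self.scale,
            "rho": self.genome.rho,
            "theta_4Nmu": None,
        }
        if self.selection is not None:
            ts1 = het_sweep_duration(self.lifecycle.N, self.selection.s, self.selection.h)
            meta["t_s1"] = ts1
            meta["alpha_t_s1"] = self.lifecycle.alpha * ts1
        return meta


def _windows(length: int, window: int) -> tuple:
    """Window-centre positions covering [0, length)."""
    return tuple(range(window // 2, length, window))


def _default_genome(alpha: float, rho: float = 5e-8, chr1_mb: float = 1.0,
                    n_chr2_loci: int = 10, selected_bp: int = 500_000,
                    window: int = 20_000) -> GenomeMap:
    chr1_len = int(chr1_mb * 1_000_000)
    chr2_len = 1_000_000
    chr2_step = chr2_len // n_chr2_loci
    return GenomeMap(
        chromosomes=(
            (chr1_len, _windows(chr1_len, window)),
            (chr2_len, tuple(range(chr2_step // 2, chr2_len, chr2_step))),
        ),
        rho_alpha=rho / alpha,
        alpha=alpha,
        selected_position=(0, selected_bp),
        window_length=window,
    )


MU_DEFAULT = 1e-8


def make_presets(alpha: float = 0.01, s: float = 0.05) -> dict:
    """Scenario library mirroring the study's experiments (full scale).

    ``alpha`` and ``s`` parametrize the presets that vary them;
    fig2_grid ignores both and returns its full grid.
    """
    presets: dict = {}
    presets["fig1_neutral"] = Scenario(
        name=f"fig1_neutral_a{alpha}",
        lifecycle=LifeCycleConfig(N=1000, alpha=alpha, schedule_mode="fixed"),
        genome=_default_genome(alpha),
        neutral=True,
        neutral_generations=10_000,
    )
    presets["fig1_sweep"] = Scenario(
        name=f"fig1_sweep_a{alpha}",
        lifecycle=LifeCycleConfig(N=1000, alpha=alpha, schedule_mode="fixed",
                                  burn_in=2000),
        genome=_default_genome(alpha),
        selection=SelectionParams(s=0.05, h=0.5),
    )
    presets["fig2_grid"] = {
        (a, sv): Scenario(
            name=f"fig2_a{a}_s{sv}",
            lifecycle=LifeCycleConfig(N=1000, alpha=a, schedule_mode="gaussian",
                                      burn_in=2000),
            genome=_default_genome(a),
            selection=SelectionParams(s=sv, h=0.5),
        )
        for a in (0.01, 0.02, 0.1, 1.0)
        for sv in (0.02, 0.05, 0.1)
    }
    presets["fig3_theory_compare"] = Scenario(
        name=f"fig3_a{alpha}_s{s}",
        lifecycle=LifeCycleConfig(N=1000, alpha=alpha, schedule_mode="gaussian",
                                  burn_in=2000),
        genome=_default_genome(alpha, chr1_mb=0.5, selected_bp=500_000),
        selection=SelectionParams(s=s, h=0.5),
    )
    presets["fig4_single_meiosis"] = Scenario(
        name="fig4_a0.004_s0.1",
        lifecycle=LifeCycleConfig(N=1000, alpha=0.004, schedule_mode="gaussian",
                                  burn_in=2000),
        genome=_default_genome(0.004, chr1_mb=0.5, selected_bp=0),
        selection=SelectionParams(s=0.1, h=0.5),
    )
    return presets


def scale_scenario(scn: Scenario, scale: float) -> Scenario:
    """Rescale a scenario to population size ``scale * N``.

    N, burn-in and neutral run length are multiplied by ``scale``; s, mu
    (via the caller) and alpha are divided by it; rho_alpha is adjusted
    only if alpha saturates at 1.  Burn-in is snapped to a multiple of
    the meiosis interval so the sweep still starts right after a sexual
    generation.
    """
    if scale <= 0 or scale > 1:
        raise ConfigurationError("scale must be in (0, 1]")
    if scale == 1.0:
        return scn
    lc, gm = scn.lifecycle, scn.genome
    new_alpha_raw = lc.alpha / scale
    new_alpha = min(1.0, new_alpha_raw)
    rho_alpha = gm.rho_alpha * new_alpha_raw / new_alpha
    interval = max(1, round(1.0 / new_alpha))
    burn_in = max(interval, round(lc.burn_in * scale / interval) * interval) if lc.burn_in else 0
    new_lc = replace(lc, N=max(2, round(lc.N * scale)), alpha=new_alpha, burn_in=burn_in)
    new_gm = replace(gm, rho_alpha=rho_alpha, alpha=new_alpha)
    new_sel = None
    if scn.selection is not None:
        new_s = scn.selection.s / scale
        if new_s >= 1:
            raise ConfigurationError(f"scaled s = {new_s} >= 1; use a milder scale")
        new_sel = replace(scn.selection, s=new_s)
    return replace(
        scn,
        name=f"{scn.name}_scale{scale}",
        lifecycle=new_lc,
        genome=new_gm,
        selection=new_sel,
        neutral_generations=max(1, round(scn.neutral_generations * scale)),
        scale=scn.scale * scale,
    )


def scaled_mu(mu: float, scale: float) -> float:
    """Mutation rate compensating a population rescaling (preserves 4*N*mu)."""
    return mu / scale


@dataclass
class ScenarioResult:
    """Bundle of per-replicate outputs of one scenario."""

    scenario: Scenario
    pi: pd.DataFrame                      # replicate x window
    fixation_times: np.ndarray
    n_meioses: np.ndarray
    attempts: np.ndarray
    mu: float
    master_seed: int

    def chr_columns(self, chrom: int) -> list:
        """Window columns of a chromosome (0-based index)."""
        return [c for c in self.pi.columns if c.startswith(f"chr{chrom + 1}_")]

    def mean_pi(self, chrom: int | None = None) -> float:
        cols = self.pi.columns if chrom is None else self.chr_columns(chrom)
        return float(self.pi[cols].mean(axis=1).mean())


def replicate_rng(master_seed: int, replicate_id: int) -> np.random.Generator:
    """Counter-based per-replicate RNG: independent and re-runnable."""
    return np.random.default_rng(np.random.SeedSequence((master_seed, replicate_id)))


def _pi_columns(gmap: GenomeMap) -> list:
    return [f"chr{ci + 1}_{bp}" for ci, bp in gmap.locus_positions()]


def run_scenario(scn: Scenario, master_seed: int = 0,
                 mu: float = MU_DEFAULT, resume: bool = True) -> ScenarioResult:
    """Run all replicates of a scenario and collect window diversity.

    Each replicate derives its RNG from (master_seed, replicate_id), so
    identical inputs give bitwise-identical outputs and individual
    replicates can be re-run.  With ``outdir`` set, per-replicate rows
    are written to TSV and completed replicates are skipped on resume.
    """
    cols = _pi_columns(scn.genome)
    rows: dict = {}
    fix: dict = {}
    pi_path = meta_path = None
    if scn.outdir:
        os.makedirs(scn.outdir, exist_ok=True)
        pi_path = os.path.join(scn.outdir, f"{scn.name}_pi.tsv")
        meta_path = os.path.join(scn.outdir, f"{scn.name}_meta.json")
        if resume and os.path.exists(pi_path):
            prev = pd.read_csv(pi_path, sep="\t", index_col="replicate")
            for rid, row in prev.iterrows():
                rows[int(rid)] = row[cols].to_numpy()
                fix[int(rid)] = (row.get("fixation_time", np.nan),
                                 row.get("n_meioses", np.nan), row.get("attempts", np.nan))

    for rid in range(scn.replicates):
        if rid in rows:
            continue
        rng = replicate_rng(master_seed, rid)
        if scn.neutral:
            pop, _ = run_neutral(scn.lifecycle, scn.genome, rng,
                                 generations=scn.neutral_generations)
            _, slots = sample_individuals(pop, scn.sample_size, rng)
            pi = diversity_from_population(pop, slots, mu, rng)
            fix[rid] = (np.nan, np.nan, np.nan)
        else:
            res = run_sweep_replicate(scn.lifecycle, scn.genome, scn.selection, rng,
                                      sample_size=scn.sample_size)
            pi = diversity_from_population(res.population, res.sample_slots, mu, rng)
            fix[rid] = (res.fixation_time, res.n_meioses_during_sweep, res.attempts)
        rows[rid] = pi
        if pi_path:
            _write_rows(pi_path, cols, rows, fix)

    pi_df = pd.DataFrame([rows[r] for r in sorted(rows)], columns=cols,
                         index=sorted(rows))
    fixation = np.array([fix[r][0] for r in sorted(rows)], dtype=float)
    meioses = np.array([fix[r][1] for r in sorted(rows)], dtype=float)
    attempts = np.array([fix[r][2] for r in sorted(rows)], dtype=float)
    if meta_path:
        meta = scn.metadata()
        meta.update({"mu": mu, "master_seed": master_seed,
                     "theta_4Nmu": 4 * scn.lifecycle.N * mu})
        with open(meta_path, "w") as fh:
            json.dump(meta, fh, indent=2, default=str)
    return ScenarioResult(scn, pi_df, fixation, meioses, attempts, mu, master_seed)


def _write_rows(path: str, cols: list, rows: dict, fix: dict) -> None:
    df = pd.DataFrame([rows[r] for r in sorted(rows)], columns=cols, index=sorted(rows))
    df.index.name = "replicate"
    df["fixation_time"] = [fix[r][0] for r in sorted(rows)]
    df["n_meioses"] = [fix[r][1] for r in sorted(rows)]
    df["attempts"] = [fix[r][2] for r in sorted(rows)]
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Group comparisons (normality pre-check, then t / Mann-Whitney /
# Kruskal-Wallis + Dunn, as in the study's statistical protocol).

@dataclass
class ComparisonReport:
    groups: list
    means: dict
    sds: dict
    normal: dict
    test: str
    pvalue: float
    posthoc: Optional[pd.DataFrame] = None


def dunn_posthoc(values_by_group: dict, adjust: str = "holm") -> pd.DataFrame:
    """Dunn's rank-based post hoc test with tie correction.

    z_ij = (Rbar_i - Rbar_j) / sqrt((M(M+1)/12 - T)(1/n_i + 1/n_j)),
    with M the pooled size and T = sum(t^3 - t)/(12(M-1)) over tie
    groups; two-sided normal p-values, Holm-adjusted by default.
    """
    labels = list(values_by_group)
    pooled = np.concatenate([np.asarray(values_by_group[g], float) for g in labels])
    sizes = {g: len(values_by_group[g]) for g in labels}
    ranks = stats.rankdata(pooled)
    M = len(pooled)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts ** 3 - tie_counts) / (12.0 * (M - 1))
    mean_rank = {}
    start = 0
    for g in labels:
        mean_rank[g] = ranks[start:start + sizes[g]].mean()
        start += sizes[g]
    recs = []
    for i, gi in enumerate(labels):
        for gj in labels[i + 1:]:
            se = np.sqrt((M * (M + 1) / 12.0 - tie_term)
                         * (1.0 / sizes[gi] + 1.0 / sizes[gj]))
            z = (mean_rank[gi] - mean_rank[gj]) / se
            p = 2 * stats.norm.sf(abs(z))
            recs.append({"group1": gi, "group2": gj, "z": z, "p": p})
    df = pd.DataFrame(recs)
    if adjust == "holm":
        p = df["p"].to_numpy()
        m = len(p)
        idx = np.argsort(p)
        adj = np.empty(m)
        running = 0.0
        for rank_i, i in enumerate(idx):
            running = max(running, (m - rank_i) * p[i])
            adj[i] = min(1.0, running)
        df["p_adjusted"] = adj
    else:
        df["p_adjusted"] = np.minimum(1.0, df["p"] * len(df))
    return df


def compare_groups(values_by_group: dict, normality_alpha: float = 0.05) -> ComparisonReport:
    """Compare group means following the study's decision rule.

    Shapiro normality check per group; two groups -> Student's t-test if
    both Gaussian else Mann-Whitney U; more than two -> Kruskal-Wallis
    followed by Dunn's post hoc.
    """
    labels = list(values_by_group)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    arrays = {g: np.asarray(values_by_group[g], dtype=float) for g in labels}
    for g, a in arrays.items():
        if len(a) < 3:
            raise ValueError(f"group {g!r} has fewer than 3 values")
    normal = {g: bool(stats.shapiro(a).pvalue >= normality_alpha) for g, a in arrays.items()}
    means = {g: float(a.mean()) for g, a in arrays.items()}
    sds = {g: float(a.std(ddof=1)) for g, a in arrays.items()}
    posthoc = None
    if len(labels) == 2:
        a, b = arrays[labels[0]], arrays[labels[1]]
        if all(normal.values()):
            test = "t-test"
            p = float(stats.ttest_ind(a, b).pvalue)
        else:
            test = "mann-whitney"
            p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    else:
        test = "kruskal-dunn"
        p = float(stats.kruskal(*arrays.values()).pvalue)
        posthoc = dunn_posthoc(arrays)
    return ComparisonReport(labels, means, sds, normal, test, p, posthoc)
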