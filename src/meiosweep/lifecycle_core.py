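"""Configuration types, meiosis scheduling, and fitness primitives.

The life cycle alternates clonal (mitotic) generations with sexual
(meiotic) generations.  The meiotic frequency ``alpha`` is the long-run
fraction of generations that are sexual; ``1/alpha`` is the mean interval
between sexual generations.  Two schedules are supported:

``fixed``
    sexual generations occur every ``round(1/alpha)`` generations,
    anchored one full interval after schedule start;
``gaussian``
    each interval is drawn from Normal(1/alpha, (1/(10*alpha))**2),
    rounded to the nearest integer and floored at 1.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = [
    "LifeCycleConfig",
    "GenomeMap",
    "SelectionParams",
    "MeiosisSchedule",
    "build_schedule",
    "genotype_fitness",
    "fitness_array",
    "config_from_file",
    "config_metadata",
]


class ConfigurationError(ValueError):
    """Raised when a configuration violates a model invariant."""


@dataclass(frozen=True)
class LifeCycleConfig:
    """Population size, meiotic frequency and run-length configuration.

    Parameters
    ----------
    N : int
        Diploid population size (constant, Wright-Fisher).
    alpha : float
        Meiotic frequency, in (0, 1].  ``alpha = 1`` is obligate sex.
    schedule_mode : {"fixed", "gaussian"}
        How the interval between sexual generations is generated.
    burn_in : int
        Generations of neutral forward evolution before the beneficial
        mutation is introduced.
    max_sweep_generations : int
        Cap on the sweep phase before the replicate is restarted.
    seed : int
        Base RNG seed for the replicate.
    replicate_id : int
        Identifier mixed into derived per-replicate seeds.
    """

    N: int
    alpha: float = 1.0
    schedule_mode: str = "fixed"
    burn_in: int = 0
    max_sweep_generations: int = 10_000
    seed: int = 0
    replicate_id: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha <= 1.0):
            raise ConfigurationError(f"alpha must be in (0, 1], got {self.alpha}")
        if self.N < 2:
            raise ConfigurationError(f"N must be >= 2, got {self.N}")
        if self.burn_in < 0:
            raise ConfigurationError("burn_in must be >= 0")
        if self.max_sweep_generations <= 0:
            raise ConfigurationError("max_sweep_generations must be > 0")
        if self.schedule_mode not in ("fixed", "gaussian"):
            raise ConfigurationError(
                f"schedule_mode must be 'fixed' or 'gaussian', got {self.schedule_mode!r}"
            )


@dataclass(frozen=True)
class GenomeMap:
    """Chromosome layout and tracked neutral loci.

    Each chromosome is a ``(length_bp, positions)`` pair where
    ``positions`` are the basepair coordinates of the tracked neutral
    loci (window centres), strictly increasing.  ``rho_alpha`` is the
    recombination rate per basepair per *meiosis*; the net per-generation
    rate is ``rho = alpha * rho_alpha``.

    ``selected_position`` is ``(chromosome_index, bp)``.
    """

    chromosomes: tuple
    rho_alpha: float
    alpha: float
    selected_position: tuple = (0, 0)
    window_length: int = 20_000

    def __post_init__(self) -> None:
        chroms = tuple((int(L), tuple(int(p) for p in pos)) for L, pos in self.chromosomes)
        object.__setattr__(self, "chromosomes", chroms)
        if self.rho_alpha < 0:
            raise ConfigurationError("rho_alpha must be >= 0")
        if self.window_length <= 0:
            raise ConfigurationError("window_length must be > 0")
        for L, pos in chroms:
            if any(b <= a for a, b in zip(pos, pos[1:])):
                raise ConfigurationError("tracked locus positions must be strictly increasing")
            if any(p < 0 or p > L for p in pos):
                raise ConfigurationError("tracked locus outside chromosome")
        ci, bp = self.selected_position
        if not (0 <= ci < len(chroms)):
            raise ConfigurationError("selected_position chromosome index out of range")
        if not (0 <= bp <= chroms[ci][0]):
            raise ConfigurationError("selected_position outside its chromosome")

    @property
    def rho(self) -> float:
        """Net recombination rate per basepair per generation, alpha * rho_alpha."""
        return self.alpha * self.rho_alpha

    @property
    def n_loci(self) -> int:
        return sum(len(pos) for _, pos in self.chromosomes)

    def locus_positions(self) -> list:
        """Flat list of (chromosome index, bp) for every tracked neutral locus."""
        return [(ci, p) for ci, (_, pos) in enumerate(self.chromosomes) for p in pos]


@dataclass(frozen=True)
class SelectionParams:
    """Single-locus selection: fitnesses 1 : 1+hs : 1+s for 0/1/2 copies."""

    s: float
    h: float = 0.5

    def __post_init__(self) -> None:
        if self.s <= -1:
            raise ConfigurationError("s must be > -1 (fitnesses must stay positive)")
        if 1 + self.h * self.s <= 0:
            raise ConfigurationError("heterozygote fitness 1+hs must be positive")


@dataclass
class MeiosisSchedule:
    """Realized schedule of sexual generations over a horizon.

    ``flags[g]`` is True when generation ``g`` (0-based, the first
    generation produced after schedule start) is sexual.
    """

    flags: np.ndarray
    intervals: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __len__(self) -> int:
        return len(self.flags)

    @property
    def n_sexual(self) -> int:
        return int(np.count_nonzero(self.flags))


def build_schedule(cfg: LifeCycleConfig, horizon: int, rng: np.random.Generator) -> MeiosisSchedule:
    """Generate the sexual/clonal schedule for ``horizon`` generations.

    With ``alpha = 1`` every generation is sexual.  Fixed mode places a
    sexual generation every ``round(1/alpha)`` generations, the first one
    a full interval after schedule start.  Gaussian mode draws each
    interval from Normal(1/alpha, (1/(10*alpha))**2), rounds it, and
    floors it at 1.
    """
    if horizon < 1:
        raise ConfigurationError("horizon must be >= 1")
    flags = np.zeros(horizon, dtype=bool)
    if cfg.alpha == 1.0:
        flags[:] = True
        return MeiosisSchedule(flags, np.ones(horizon, dtype=int))
    mean_interval = 1.0 / cfg.alpha
    intervals = []
    t = 0
    while True:
        if cfg.schedule_mode == "fixed":
            step = max(1, round(mean_interval))
        else:
            step = max(1, round(float(rng.normal(mean_interval, mean_interval / 10.0))))
        t += step
        if t > horizon:
            break
        intervals.append(step)
        flags[t - 1] = True
    return MeiosisSchedule(flags, np.array(intervals, dtype=int))


def genotype_fitness(genotype: int, sel: SelectionParams) -> float:
    """Relative fitness of a genotype carrying 0, 1 or 2 beneficial copies."""
    if genotype not in (0, 1, 2):
        raise ValueError(f"genotype must be 0, 1 or 2, got {genotype}")
    return (1.0, 1.0 + sel.h * sel.s, 1.0 + sel.s)[genotype]


def fitness_array(sel: SelectionParams) -> np.ndarray:
    """Fitnesses of the three genotypes as an array indexed by copy number."""
    return np.array([1.0, 1.0 + sel.h * sel.s, 1.0 + sel.s])


# ---------------------------------------------------------------------------
# Config file ingestion (canonical dialect: YAML; JSON is a YAML subset).

_LIFECYCLE_FIELDS = {f.name for f in dataclasses.fields(LifeCycleConfig)}


def config_from_file(path: str) -> dict:
    """Read a YAML config file into ``{"lifecycle", "genome", "selection"}``.

    The three sections map one-to-one onto :class:`LifeCycleConfig`,
    :class:`GenomeMap` and :class:`SelectionParams` constructor fields.
    ``genome.alpha`` defaults to ``lifecycle.alpha``.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    lc = LifeCycleConfig(**{k: v for k, v in raw.get("lifecycle", {}).items() if k in _LIFECYCLE_FIELDS})
    graw = dict(raw.get("genome", {}))
    graw.setdefault("alpha", lc.alpha)
    graw["chromosomes"] = tuple((c["length"], tuple(c["loci"])) for c in graw["chromosomes"])
    if "selected_position" in graw:
        graw["selected_position"] = tuple(graw["selected_position"])
    gm = GenomeMap(**graw)
    sel = SelectionParams(**raw.get("selection", {"s": 0.0}))
    return {"lifecycle": lc, "genome": gm, "selection": sel}


def config_metadata(cfg: LifeCycleConfig, gmap: GenomeMap | None = None,
                    sel: SelectionParams | None = None, **extra) -> str:
    """Echo every configuration field into a JSON run-metadata record."""
    rec: dict = dataclasses.asdict(cfg)
    if gmap is not None:
        rec["genome"] = dataclasses.asdict(gmap)
        rec["genome"]["rho"] = gmap.rho
    if sel is not None:
        rec["selection"] = dataclasses.asdict(sel)
    rec.update(extra)
    return json.dumps(rec, default=str, indent=2)
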