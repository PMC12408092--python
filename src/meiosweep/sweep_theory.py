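"""Analytical sweep predictions under facultative sex.

All functions are pure.  Notation: ``s`` and ``h`` are the homozygous
selection and dominance coefficients of the beneficial allele, ``alpha``
the meiotic frequency, ``r`` the recombination fraction per meiosis
between a neutral site and the target of selection, ``d`` the map
distance in Morgans, and ``Ne`` the effective population size of the
obligately sexual reference population.

Two regimes are covered:

* ``alpha * t_s1 >> 1`` (several meioses per sweep): standard hard-sweep
  theory applies, with the per-generation recombination rate ``r*alpha``
  and the alpha-modified selection recursion.
* ``alpha * t_s1 <= 1`` (at most one meiosis during the heterozygote
  sweep): diversity is governed deterministically by the probability
  ``2r(1-r)`` that the single meiosis creates beneficial homozygotes that
  are non-identical-by-descent at the neutral site, plus mutational
  recovery during the two sweep phases.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "TheoryInputs",
    "EULER_GAMMA",
    "haldane_r",
    "inverse_haldane",
    "fixation_time_semidominant",
    "het_sweep_duration",
    "hom_sweep_duration",
    "expected_meioses_per_sweep",
    "delta_q_facultative",
    "deterministic_trajectory",
    "conditioned_q0",
    "standard_sweep_pi_ratio",
    "single_meiosis_pi_ratio",
    "rescale_parameters",
]

EULER_GAMMA = 0.5772  # truncated Euler-Mascheroni constant, as used in Eq-1-style formulae


@dataclass(frozen=True)
class TheoryInputs:
    """Bundle of inputs for the sweep-diversity predictions."""

    Ne: float
    s: float
    h: float = 0.5
    alpha: float = 1.0
    r: float | None = None
    d: float | None = None
    mu: float = 1e-8
    window_length: int = 20_000

    def __post_init__(self) -> None:
        r, d = self.r, self.d
        if r is None and d is None:
            raise ValueError("supply r or d")
        if r is None:
            object.__setattr__(self, "r", haldane_r(d))
        elif d is None:
            if r < 0.5:
                object.__setattr__(self, "d", inverse_haldane(r))
            else:
                object.__setattr__(self, "d", math.inf)
        else:
            if not math.isclose(r, haldane_r(d), rel_tol=1e-9, abs_tol=1e-12):
                raise ValueError("inconsistent r and d: r must equal (1 - exp(-2d))/2")
        if not (0.0 <= self.r <= 0.5):
            raise ValueError("r must lie in [0, 1/2]")


def haldane_r(d):
    """Recombination fraction from map distance (Morgans), no interference.

    r = (1 - exp(-2 d)) / 2.  Strictly increasing, concave, bounded by 1/2.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be >= 0")
    out = 0.5 * -np.expm1(-2.0 * d)
    return float(out) if out.ndim == 0 else out


def inverse_haldane(r):
    """Map distance (Morgans) from recombination fraction; exact inverse."""
    r = np.asarray(r, dtype=float)
    if np.any((r < 0) | (r >= 0.5)):
        raise ValueError("r must lie in [0, 1/2); r = 1/2 is infinite map distance")
    out = -0.5 * np.log1p(-2.0 * r)
    return float(out) if out.ndim == 0 else out


def fixation_time_semidominant(Ne: float, s: float) -> float:
    """Expected fixation time of a semidominant (h=1/2) beneficial mutation.

    t_s = (4/s) [ln(2 Ne s) + 0.5772], valid for 2 Ne s >> 1
    (Hermisson-Pennings establishment-plus-logistic approximation).
    """
    if s <= 0:
        raise ValueError("s must be > 0")
    if 2 * Ne * s < 10:
        warnings.warn("fixation_time_semidominant assumes 2*Ne*s >> 1", stacklevel=2)
    return 4.0 / s * (math.log(2.0 * Ne * s) + EULER_GAMMA)


def het_sweep_duration(Ne: float, s: float, h: float = 0.5) -> float:
    """Duration t_s1 of the initial clonal sweep of heterozygotes.

    Before the first meiosis the beneficial allele exists only in
    heterozygotes, which compete clonally against wild-type with a
    haploid-like advantage hs:  t_s1 = (2/hs) [ln(2 Ne hs) + 0.5772].
    """
    hs = h * s
    if hs <= 0:
        raise ValueError("hs must be > 0")
    return 2.0 / hs * (math.log(2.0 * Ne * hs) + EULER_GAMMA)


def hom_sweep_duration(Ne: float, s: float, h: float = 0.5) -> float:
    """Duration of the second, homozygote phase of a single-meiosis sweep.

    Beneficial homozygotes out-compete heterozygotes clonally with
    advantage approximately (1-h)s; same haploid-like form as t_s1.
    """
    adv = (1.0 - h) * s
    if adv <= 0:
        raise ValueError("(1-h)s must be > 0")
    return 2.0 / adv * (math.log(2.0 * Ne * adv) + EULER_GAMMA)


def expected_meioses_per_sweep(alpha: float, t_s1: float) -> float:
    """Expected number of sexual generations during the heterozygote sweep."""
    return alpha * t_s1


def delta_q_facultative(q, s: float, h: float, alpha: float):
    """One-generation change in beneficial-allele frequency.

    Delta q = s q (1-q) [ alpha (h + (1-2h) q) + (1-alpha) 2h ].

    At ``alpha = 1`` this is the standard diploid recursion
    s q (1-q) [h + (1-2h) q]; at ``alpha = 0`` clonal diploids behave like
    haploids with selection coefficient 2hs, giving 2hs q (1-q).  The
    bracket interpolates linearly in alpha between the two.
    """
    q = np.asarray(q, dtype=float)
    if np.any((q < 0) | (q > 1)):
        raise ValueError("q must lie in [0, 1]")
    out = s * q * (1.0 - q) * (alpha * (h + (1.0 - 2.0 * h) * q) + (1.0 - alpha) * 2.0 * h)
    return float(out) if out.ndim == 0 else out


def conditioned_q0(Ne: float, s: float, h: float = 0.5) -> float:
    """Effective starting frequency of a sweep conditioned on fixation.

    A mutation destined to fix escapes drift faster than the neutral
    expectation; the deterministic trajectory started from
    q0 = 1/(4 Ne h s e^gamma) has the same duration as the conditioned
    stochastic sweep (it reproduces the Eq-1 fixation time at h = 1/2
    when combined with :func:`conditioned_q_end`).
    """
    denom = 4.0 * Ne * h * s * math.exp(EULER_GAMMA)
    if denom <= 1:
        raise ValueError("requires 4*Ne*h*s*e^gamma > 1")
    return 1.0 / denom


def conditioned_q_end(Ne: float, s: float, h: float = 0.5) -> float:
    """Effective end frequency of a conditioned sweep.

    The final wild-type copy is lost under an advantage (1-h)s of the
    beneficial homozygote, mirrored from :func:`conditioned_q0`:
    q_end = 1 - 1/(4 Ne (1-h) s e^gamma).
    """
    denom = 4.0 * Ne * (1.0 - h) * s * math.exp(EULER_GAMMA)
    if denom <= 1:
        raise ValueError("requires 4*Ne*(1-h)*s*e^gamma > 1")
    return 1.0 - 1.0 / denom


def deterministic_trajectory(s: float, h: float, alpha: float, Ne: float,
                             q0: float | None = None, q_end: float | None = None,
                             max_steps: int = 10_000_000):
    """Iterate the facultative-sex recursion from q0 to q_end.

    Returns ``(q, duration)`` where ``q`` is the discrete path (one entry
    per generation, starting at q0) and ``duration`` its length in
    generations.  Defaults ``q0 = 1/(2Ne)`` (a single new copy) and
    ``q_end = 1 - q0``; pass :func:`conditioned_q0` /
    :func:`conditioned_q_end` to emulate a sweep conditioned on fixation.
    """
    if q0 is None:
        q0 = 1.0 / (2.0 * Ne)
    if q_end is None:
        q_end = 1.0 - q0
    path = [q0]
    q = q0
    for _ in range(max_steps):
        if q >= q_end:
            break
        q = min(1.0, q + delta_q_facultative(q, s, h, alpha))
        path.append(q)
    else:
        raise RuntimeError("trajectory failed to reach fixation threshold")
    return np.asarray(path), len(path) - 1


def standard_sweep_pi_ratio(inputs: TheoryInputs) -> float:
    """Post-sweep pi/pi0 from standard hard-sweep theory with r -> r*alpha.

    Trajectory-integral structured-coalescent approximation: a sampled
    lineage linked to the beneficial background escapes by recombination
    at rate ``r*alpha*(1-q(t))`` per generation along the deterministic
    (conditioned) trajectory.  Writing P for the probability of *no*
    escape over the whole sweep, a pair of lineages coalesces at the
    sweep origin iff neither escapes, so

        pi/pi0 = 1 - P^2 (1 - t_fix / (2 Ne)),

    the last factor being the mutational recovery over the sweep
    duration (pairs forced to coalesce at the origin still carry
    mutations accumulated since then; pi0 = 4 Ne mu).

    Accurate for ``alpha = 1``; for small alpha it systematically
    underestimates diversity because the discreteness of rare meioses is
    ignored.
    """
    q, t_fix = deterministic_trajectory(
        inputs.s, inputs.h, inputs.alpha, inputs.Ne,
        q0=conditioned_q0(inputs.Ne, inputs.s, inputs.h),
        q_end=conditioned_q_end(inputs.Ne, inputs.s, inputs.h),
    )
    r_net = inputs.r * inputs.alpha
    p_no_escape = math.exp(-r_net * float(np.sum(1.0 - q)))
    ratio = 1.0 - p_no_escape ** 2 * (1.0 - t_fix / (2.0 * inputs.Ne))
    return float(min(max(ratio, 0.0), 1.0))


def single_meiosis_pi_ratio(inputs: TheoryInputs) -> float:
    """Post-sweep pi/pi0 when at most one meiosis occurs during the sweep.

    The lone meiosis turns heterozygote carriers into beneficial
    homozygotes.  Every heterozygote is a clonal copy of the original
    mutant, carrying neutral allele ``a`` on the beneficial haplotype and
    allele ``b`` on the homolog; a gamete transmits ``b`` with
    probability ``r``.  The homozygotes founded by the meiosis therefore
    carry ``a`` with frequency 1-r and ``b`` with frequency r, and after
    they replace all other genotypes the heterozygosity at the neutral
    site is ``2 r (1-r)`` relative to baseline.  Mutational recovery adds
    diversity accumulated over the two clonal sweep phases (durations
    t_s1 and t_s2) for the identical-by-descent pair fraction
    ``(1-r)^2 + r^2``:

        pi/pi0 = 2 r (1-r) + [(1-r)^2 + r^2] (t_s1 + t_s2) / (2 Ne).

    With ``mu = 0`` the recovery term is dropped (mutation-free limit),
    giving exactly 2 r (1-r), i.e. 0.5 at r = 1/2.
    """
    t_s1 = het_sweep_duration(inputs.Ne, inputs.s, inputs.h)
    n_meioses = expected_meioses_per_sweep(inputs.alpha, t_s1)
    if n_meioses > 1.5:
        warnings.warn(
            f"single-meiosis model outside its regime: alpha*t_s1 = {n_meioses:.3g} > 1",
            stacklevel=2,
        )
    r = inputs.r
    core = 2.0 * r * (1.0 - r)
    if inputs.mu == 0:
        return core
    t_s2 = hom_sweep_duration(inputs.Ne, inputs.s, inputs.h)
    recovery = ((1.0 - r) ** 2 + r ** 2) * (t_s1 + t_s2) / (2.0 * inputs.Ne)
    return float(min(core + recovery, 1.0))


def rescale_parameters(Ns: float, Nn: float, s: float, r: float, alpha: float,
                       regime: str = "standard") -> dict:
    """Map simulation parameters (size Ns) onto a natural population (size Nn).

    standard regime (alpha*t_s1 >> 1): the sweep is controlled by 2*Ne*s
    and 2*Ne*alpha*r, so s' = s*Ns/Nn and r' = r*Ns/Nn with alpha
    unchanged (fixation times scale by Nn/Ns).

    rare-meiosis regime (alpha*t_s1 <= 1): diversity depends on r itself
    through 2r(1-r), so r is NOT rescaled, while alpha' = alpha*Ns/Nn.
    """
    k = Ns / Nn
    if regime == "standard":
        return {"s": s * k, "r": r * k, "alpha": alpha,
                "rule": "s,r multiplied by Ns/Nn; alpha unchanged (2Ne*s, 2Ne*alpha*r preserved)"}
    if regime == "rare-meiosis":
        return {"s": s, "r": r, "alpha": alpha * k,
                "rule": "alpha multiplied by Ns/Nn; r unchanged (2r(1-r) is scale-free)"}
    raise ValueError("regime must be 'standard' or 'rare-meiosis'")
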