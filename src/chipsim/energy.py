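"""Binding-energy distributions and statistical-mechanics occupancy models.

A transcription factor (TF) binding site is described by a mismatch binding
energy eps >= 0 (in units of kBT, with kBT = 1 throughout): the highest
affinity sequence has energy 0 and every mutation away from it adds energy.
A locus is a two-state system (bound / unbound) whose bound-state Boltzmann
weight is exp(-(eps - mu)) and unbound weight exp(-eps_u), where mu is the
TF's chemical potential (proportional to log concentration).  The occupancy
probability is therefore a logistic function of eps - eps_u - mu.

Genome-wide energies are drawn from a power law truncated to [0, E_max],
density f(eps) = (1 - alpha) / E_max^(1-alpha) * (E_max - eps)^(-alpha),
which concentrates mass at weak (high-energy) sites.

The module also covers the occupancy models for cooperative binding (a
four-state partition function with interaction energy delta), indirect
binding (occupancy tracks a second TF's energy), antibody false positives
(a derived power law with scaled mean and preserved variance), and
chromatin-accessibility masking (a sigmoid in DNase read density).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate, optimize

__all__ = [
    "BindingConfig",
    "TruncatedPowerLaw",
    "CooperativeParams",
    "FalsePositiveLaw",
    "F_FALSE_POSITIVE_DEFAULT",
    "occupancy_probability",
    "sample_energies",
    "cooperative_occupancy",
    "indirect_occupancy",
    "false_positive_params",
    "solve_fp_scaling",
    "mean_occupancy",
    "mean_occupancy_ratio",
    "accessibility_probability",
]

#: Mean-scaling factor f that maps the true-positive law (alpha=0.5,
#: E_max=6) onto the false-positive law (alpha=0.76, E_max=6.78) used for
#: the antibody-specificity-2 scenario: f = (6.78 / (2 - 0.76)) / 4.
F_FALSE_POSITIVE_DEFAULT = 1.367


@dataclass(frozen=True)
class BindingConfig:
    """Chemical potential and unbound-state energy, both in kBT.

    The default ``eps_u = 1.59`` pins the occupancy of a consensus site
    (eps = 0) at 0.99 when ``mu = 3``.
    """

    mu: float = 3.0
    eps_u: float = 1.59

    def __post_init__(self) -> None:
        if not (math.isfinite(self.mu) and math.isfinite(self.eps_u)):
            raise ValueError("mu and eps_u must be finite")


@dataclass(frozen=True)
class TruncatedPowerLaw:
    """Power law on [0, e_max] with density ~ (e_max - eps)^(-alpha).

    ``alpha`` must be < 1 for the density to be normalisable; sampling uses
    the exact inverse CDF.  Laws derived for false-positive scenarios may
    have alpha outside (0, 1) (including negative values) and remain valid.
    """

    alpha: float
    e_max: float

    def __post_init__(self) -> None:
        if not self.e_max > 0:
            raise ValueError(f"e_max must be > 0, got {self.e_max}")
        if not self.alpha < 1:
            raise ValueError(f"alpha must be < 1, got {self.alpha}")

    def pdf(self, eps):
        eps = np.asarray(eps, dtype=float)
        out = np.zeros_like(eps)
        inside = (eps >= 0) & (eps < self.e_max)
        x = self.e_max - eps[inside]
        out[inside] = (1 - self.alpha) / self.e_max ** (1 - self.alpha) * x ** (-self.alpha)
        return out

    def cdf(self, eps):
        eps = np.clip(np.asarray(eps, dtype=float), 0.0, self.e_max)
        return 1.0 - ((self.e_max - eps) / self.e_max) ** (1 - self.alpha)

    def mean(self) -> float:
        return self.e_max / (2 - self.alpha)

    def var(self) -> float:
        a = self.alpha
        return self.e_max**2 * ((1 - a) / (3 - a) - ((1 - a) / (2 - a)) ** 2)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        # inverse CDF: eps = e_max * (1 - (1 - u)^(1/(1-alpha)))
        u = rng.random(n)
        return self.e_max * (1.0 - (1.0 - u) ** (1.0 / (1.0 - self.alpha)))


@dataclass(frozen=True)
class CooperativeParams:
    """Site energies, chemical potentials, and interaction energy (kBT).

    ``delta < 0`` is cooperative, 0 independent, > 0 competitive;
    ``delta = +inf`` is the strict-competition limit (no double binding).
    """

    eps_a: float
    eps_b: float
    mu_a: float
    mu_b: float
    delta: float = 0.0


@dataclass(frozen=True)
class FalsePositiveLaw:
    """Energy law of antibody false-positive loci, derived from the TP law.

    The derived law has mean ``f * m`` and the same variance as the
    true-positive law (m = TP mean).
    """

    alpha_fp: float
    e_max_fp: float
    f: float
    alpha_tp: float
    e_max_tp: float

    @property
    def law(self) -> TruncatedPowerLaw:
        return TruncatedPowerLaw(self.alpha_fp, self.e_max_fp)


def occupancy_probability(eps, cfg: BindingConfig = BindingConfig()):
    """Boltzmann two-state occupancy 1 / (1 + exp(eps - eps_u - mu)).

    Strictly decreasing in ``eps``, increasing in ``mu``; vectorised.
    """
    eps = np.asarray(eps, dtype=float)
    with np.errstate(over="ignore"):
        p = 1.0 / (1.0 + np.exp(eps - cfg.eps_u - cfg.mu))
    return p if p.ndim else float(p)


def sample_energies(law: TruncatedPowerLaw, n: int, rng) -> np.ndarray:
    """Draw ``n`` site energies from a truncated power law.

    ``rng`` may be a Generator or an integer seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    return law.sample(n, rng)


def cooperative_occupancy(p: CooperativeParams, cfg: BindingConfig = BindingConfig()):
    """Probability that TF A occupies its site, given a co-binding TF B.

    Four states: unbound, A only, B only, A+B, with Boltzmann weights
    exp(-eps_u), exp(-eps_A + mu_A), exp(-eps_B + mu_B) and
    exp(-eps_A - eps_B - delta + mu_A + mu_B).  A is bound in the two
    states involving A, so the ChIP of A sees w_A + w_AB over the total.
    """
    eps_a = np.asarray(p.eps_a, dtype=float)
    eps_b = np.asarray(p.eps_b, dtype=float)
    w_u = np.exp(-cfg.eps_u)
    w_a = np.exp(-eps_a + p.mu_a)
    w_b = np.exp(-eps_b + p.mu_b)
    if np.isposinf(p.delta):
        w_ab = np.zeros_like(w_a)
    else:
        w_ab = np.exp(-eps_a - eps_b - p.delta + p.mu_a + p.mu_b)
    out = (w_a + w_ab) / (w_u + w_a + w_b + w_ab)
    return out if out.ndim else float(out)


def indirect_occupancy(eps_b, mu_b: float, cfg: BindingConfig = BindingConfig()):
    """Occupancy of an indirectly bound locus: tracks TF B's energy.

    Same logistic form as :func:`occupancy_probability` with B's energy and
    chemical potential; independent of A's energy by construction.
    """
    return occupancy_probability(eps_b, BindingConfig(mu=mu_b, eps_u=cfg.eps_u))


def false_positive_params(alpha_tp: float, e_max_tp: float, f: float) -> FalsePositiveLaw:
    """Derive the false-positive energy law from the true-positive law.

    Given the TP law's mean m and variance v, the FP law's exponent and
    truncation are chosen so its mean is ``f * m`` while the variance stays
    at v:

        r = v / (f^2 m^2) + 1
        alpha_fp = 3 + 2 / (r - 2)
        E_max_fp = f * m * (2 - alpha_fp)
    """
    if f <= 0:
        raise ValueError("f must be > 0")
    tp = TruncatedPowerLaw(alpha_tp, e_max_tp)
    m, v = tp.mean(), tp.var()
    r = v / (f**2 * m**2) + 1.0
    if r == 2.0:
        raise ValueError("degenerate scaling: r = 2 (division by zero)")
    alpha_fp = 3.0 + 2.0 / (r - 2.0)
    if alpha_fp >= 1.0:
        raise ValueError(f"derived alpha_fp={alpha_fp:.3f} >= 1 is not a valid law")
    e_max_fp = f * m * (2.0 - alpha_fp)
    return FalsePositiveLaw(alpha_fp, e_max_fp, f, alpha_tp, e_max_tp)


def mean_occupancy(law: TruncatedPowerLaw, cfg: BindingConfig = BindingConfig()) -> float:
    """Expected occupancy under an energy law, by adaptive quadrature.

    Integrates the logistic occupancy against the law's density after the
    substitution x = e_max - eps, which removes the integrable singularity
    at the upper truncation.
    """
    a, emax = law.alpha, law.e_max

    def integrand(x):
        dens = (1 - a) / emax ** (1 - a) * x ** (-a)
        return occupancy_probability(emax - x, cfg) * dens

    val, _ = integrate.quad(integrand, 0.0, emax, points=[0.0], limit=200)
    return val


def solve_fp_scaling(
    target_ratio: float,
    tp_law: TruncatedPowerLaw,
    cfg: BindingConfig = BindingConfig(),
    bracket: tuple[float, float] = (1.0, 30.0),
) -> FalsePositiveLaw:
    """Find the mean-scaling factor f whose FP law yields a given
    mean-occupancy ratio (TP over FP), by Brent root-finding on quadrature.
    """
    mo_tp = mean_occupancy(tp_law, cfg)

    def gap(f):
        fp = false_positive_params(tp_law.alpha, tp_law.e_max, f)
        return mo_tp / mean_occupancy(fp.law, cfg) - target_ratio

    f_star = optimize.brentq(gap, *bracket)
    return false_positive_params(tp_law.alpha, tp_law.e_max, f_star)


def mean_occupancy_ratio(tp_occupancies, fp_occupancies) -> float:
    """Ratio of mean occupancy at true-positive vs false-positive loci.

    A proxy for antibody specificity: with equal extraction efficiencies the
    fragment-yield ratio between the two classes reduces to this quantity.
    """
    tp = np.asarray(tp_occupancies, dtype=float)
    fp = np.asarray(fp_occupancies, dtype=float)
    if tp.size == 0 or fp.size == 0:
        raise ValueError("occupancy lists must be nonempty")
    fp_mean = fp.mean()
    if fp_mean <= 0:
        raise ValueError("false-positive mean occupancy is zero")
    return float(tp.mean() / fp_mean)


def accessibility_probability(density, beta: float):
    """Sigmoid accessibility prior p_acc = 1 / (1 + exp(-beta * d)).

    ``density`` is per-base DNase read density (>= 0); the effective
    occupancy used downstream is p_b * p_acc.
    """
    if beta < 0:
        raise ValueError("beta must be >= 0")
    density = np.asarray(density, dtype=float)
    if np.any(density < 0):
        raise ValueError("density must be >= 0")
    p = 1.0 / (1.0 + np.exp(-beta * density))
    return p if p.ndim else float(p)
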