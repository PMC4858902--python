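"""Efficacy, cost, survival and fitness of hosts and parasites.

Defence efficacy weighs each effector's equilibrium activity by its killing
coefficient against the encountered parasite, E = xi_S*y_ES + xi_N*y_EN,
while the physiological cost is genotype-blind, C = kappa*(y_ES + y_EN).
Both are evaluated twice: at the resting (constitutive) equilibrium,
giving E0/C0, and at the infected equilibrium, giving E*/C*.

An infection has two phases.  For a fraction ``delta`` of its duration the
induced response is not yet mounted and only constitutive defence acts;
afterwards the induced equilibrium applies.  Infected survival multiplies
the two phase-wise survival factors,

    s* = [(1-C0)(1 - nu*exp(-E0))]^delta * [(1-C*)(1 - nu*exp(-E*))]^(1-delta),

where ``nu`` is the maximum virulence (0.99 by default: an undefended host
loses 99 % of its fitness) and exp(-E) is the probability the parasite
establishes.  Every host pays the constitutive cost up front, s0 = 1 - C0;
overall host fitness is s0 for unchallenged hosts and s0*s* for challenged
ones.  Parasite fitness is its phase-weighted establishment probability,
W_parasite = exp(-(delta*E0 + (1-delta)*E*)).

With kappa up to 0.8 and both effectors saturated, C can exceed 1; each
survival bracket is floored at 0 before exponentiation so fitness bottoms
out at 0 instead of turning complex.  Evolution never visits that corner;
the clamp only defines the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamics import ActivityState

__all__ = [
    "NU_DEFAULT",
    "FitnessComponents",
    "DefenceParams",
    "efficacy_and_cost",
    "survival_infected",
    "host_fitness",
    "parasite_fitness",
    "evaluate_pair",
]

NU_DEFAULT = 0.99


@dataclass(frozen=True)
class DefenceParams:
    """Tunable defence economics: marginal effector cost ``kappa``, relative
    induction delay ``delta`` in [0, 1], maximum virulence ``nu`` in [0, 1)."""

    kappa: float
    delta: float
    nu: float = NU_DEFAULT

    def __post_init__(self):
        if self.kappa < 0:
            raise ValueError("kappa must be non-negative")
        if not 0.0 <= self.delta <= 1.0:
            raise ValueError("delta must lie in [0, 1]")
        if not 0.0 <= self.nu < 1.0:
            raise ValueError("nu must lie in [0, 1)")


@dataclass(frozen=True)
class FitnessComponents:
    """All fitness ingredients of one host-parasite evaluation."""

    E0: float
    C0: float
    Estar: float
    Cstar: float
    s0: float
    sstar: float
    W_host: float
    W_parasite: float


def efficacy_and_cost(
    y: ActivityState, xi_s: float, xi_n: float, kappa: float
) -> tuple[float, float]:
    """Defence efficacy and expression cost at one effector equilibrium."""
    if kappa < 0:
        raise ValueError("kappa must be non-negative")
    E = xi_s * y.y_es + xi_n * y.y_en
    C = kappa * (y.y_es + y.y_en)
    return E, C


def survival_infected(E0, C0, Estar, Cstar, nu: float = NU_DEFAULT, delta: float = 0.5):
    """Probability an infected host survives both phases of the infection.

    Each bracket (1-C)(1 - nu*exp(-E)) is floored at 0 before taking the
    fractional power, so high-cost genotypes hit zero fitness rather than
    an undefined value.
    """
    if not 0.0 <= delta <= 1.0:
        raise ValueError("delta must lie in [0, 1]")
    if not 0.0 <= nu < 1.0:
        raise ValueError("nu must lie in [0, 1)")
    pre = np.clip((1.0 - np.asarray(C0)) * (1.0 - nu * np.exp(-np.asarray(E0))), 0.0, None)
    post = np.clip((1.0 - np.asarray(Cstar)) * (1.0 - nu * np.exp(-np.asarray(Estar))), 0.0, None)
    return pre**delta * post ** (1.0 - delta)


def host_fitness(C0, sstar=None):
    """Overall host fitness: pre-infection survival s0 = max(1-C0, 0), times
    infected survival when the host was challenged."""
    s0 = np.clip(1.0 - np.asarray(C0), 0.0, None)
    if sstar is None:
        return s0
    return s0 * np.asarray(sstar)


def parasite_fitness(E0, Estar, delta: float):
    """Phase-weighted establishment probability exp(-(delta*E0+(1-delta)*E*)),
    in (0, 1] and decreasing in both efficacies."""
    if not 0.0 <= delta <= 1.0:
        raise ValueError("delta must lie in [0, 1]")
    return np.exp(-(delta * np.asarray(E0) + (1.0 - delta) * np.asarray(Estar)))


def evaluate_pair(
    y0: ActivityState,
    ystar: ActivityState,
    xi_s: float,
    xi_n: float,
    params: DefenceParams,
) -> FitnessComponents:
    """Full fitness bookkeeping for one challenged host-parasite pair."""
    E0, C0 = efficacy_and_cost(y0, xi_s, xi_n, params.kappa)
    Estar, Cstar = efficacy_and_cost(ystar, xi_s, xi_n, params.kappa)
    sstar = float(survival_infected(E0, C0, Estar, Cstar, params.nu, params.delta))
    s0 = float(host_fitness(C0))
    return FitnessComponents(
        E0=E0,
        C0=C0,
        Estar=Estar,
        Cstar=Cstar,
        s0=s0,
        sstar=sstar,
        W_host=s0 * sstar,
        W_parasite=float(parasite_fitness(E0, Estar, params.delta)),
    )
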