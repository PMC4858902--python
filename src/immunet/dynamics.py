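"""Protein-activity dynamics on the fixed immune-network topology.

Each protein exists in an active and inactive form; the state variable
``y_i`` is the active fraction.  On the fixed wiring (receptor R and the
constitutive protein C both feed the two effectors E_S and E_N, the
effectors cross-regulate each other, and during an infection the parasite
protein P drives R) the activities obey

    dy_i/dt = -phi * y_i + sum_j c_ij * mu_ij * y_j * { 1 - y_i  if mu_ij > 0
                                                      { y_i      if mu_ij < 0

with spontaneous deactivation at rate ``phi``.  C is constitutively active
(y_C = 1) and the parasite protein is a static inducer (y_P = 1): both are
sources, never integrated.  The piecewise factor makes [0, 1] forward
invariant: activation saturates as y -> 1 and inhibition vanishes as
y -> 0.

Two solvers are provided.  ``solve_equilibrium`` is a damped fixed-point
iteration on the per-node balance y = A / (phi + A + B) (A = summed
activating input, B = summed inhibiting input); each step moves every
activity in the direction of its time derivative, so from a given initial
state the iteration settles on the same attractor the flow would reach.
Fixed-step RK4 forward integration (``integrate_rk4``) is the reference
semantics and is used to cross-check the fixed point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import genome as gn
from .genome import HostGenome, ParasiteGenome

__all__ = [
    "PHI_DEFAULT",
    "TOL_DEFAULT",
    "T_MAX_DEFAULT",
    "EDGES",
    "EDGE_NAMES",
    "InteractionMatrix",
    "ActivityState",
    "EquilibriumError",
    "build_interactions",
    "host_edge_coefficients",
    "derivative",
    "integrate_rk4",
    "solve_equilibrium",
    "constitutive_state",
    "induced_state",
    "effector_equilibria",
    "receptor_equilibrium",
]

PHI_DEFAULT = 0.3
TOL_DEFAULT = 1e-8
T_MAX_DEFAULT = 1e3
RK4_STEP = 0.05

# the six evolvable host edges, target <- source, in canonical order
EDGES = (
    ("E_S", "R"),
    ("E_N", "R"),
    ("E_S", "C"),
    ("E_N", "C"),
    ("E_S", "E_N"),
    ("E_N", "E_S"),
)
EDGE_NAMES = tuple(f"mu_{i.lower().replace('_', '')}_{j.lower().replace('_', '')}" for i, j in EDGES)

_PIDX = {name: k for k, name in enumerate(gn.HOST_PROTEINS)}
# (target, source) protein indices per edge
_EDGE_IDX = tuple((_PIDX[i], _PIDX[j]) for i, j in EDGES)


class EquilibriumError(RuntimeError):
    """Raised when a solver fails to reach the requested residual."""


@dataclass(frozen=True)
class InteractionMatrix:
    """Signed interaction strengths on the evolvable edges.

    ``mu`` holds the six host-edge coefficients in `EDGES` order; ``mu_rp``
    is the parasite->receptor coefficient, or None when no parasite is
    attached.  Source activities are fixed: y_C = 1 always, y_P = 1 during
    infection.
    """

    mu: np.ndarray
    mu_rp: float | None = None

    def __post_init__(self):
        object.__setattr__(self, "mu", np.asarray(self.mu, dtype=float))
        if self.mu.shape != (6,):
            raise ValueError("expected six host-edge coefficients")


@dataclass(frozen=True)
class ActivityState:
    """Activities of the dynamic proteins (receptor and the two effectors)."""

    y_r: float
    y_es: float
    y_en: float

    def as_array(self) -> np.ndarray:
        return np.array([self.y_r, self.y_es, self.y_en])


def build_interactions(
    host: HostGenome,
    parasite: ParasiteGenome | None = None,
    receptor_mode: str = "nonspecific",
) -> InteractionMatrix:
    """Assemble the interaction matrix of one host (and optional parasite).

    Host-edge coefficients follow the linear Hamming rule on the stored
    bitstrings; the parasite edge follows the specificity rule of the
    configured receptor mode.
    """
    block = host.array
    mu = np.empty(6)
    for k, (i, j) in enumerate(_EDGE_IDX):
        mu[k] = gn.interaction_coefficient(block[i, gn.S_I], block[j, gn.S_O])
    mu_rp = None
    if parasite is not None:
        mu_rp = gn.receptor_parasite_coefficient(host.r, parasite, receptor_mode)
    return InteractionMatrix(mu, mu_rp)


def host_edge_coefficients(host_pop: np.ndarray) -> np.ndarray:
    """(N, 6) evolvable-edge coefficients for a (N, 4, 3, L) host population."""
    L = host_pop.shape[-1]
    out = np.empty((host_pop.shape[0], 6))
    for k, (i, j) in enumerate(_EDGE_IDX):
        h = np.count_nonzero(host_pop[:, i, gn.S_I] != host_pop[:, j, gn.S_O], axis=-1)
        out[:, k] = 1.0 - 2.0 * h / L
    return out


# ---------------------------------------------------------------------------
# derivative
# ---------------------------------------------------------------------------

def _split(term: np.ndarray):
    """Split signed input terms mu*y_j into activating (A) and inhibiting (B)
    magnitudes; valid because source activities are non-negative."""
    return np.clip(term, 0.0, None), np.clip(-term, 0.0, None)


def _rates(y: np.ndarray, mu: np.ndarray, mu_rp, phi: float, parasite_present: bool):
    """Vectorised dy/dt for state array y of shape (..., 3) = (y_r, y_es, y_en).

    ``mu`` broadcasts as (..., 6); ``mu_rp`` as (...,) or scalar.
    """
    y_r, y_es, y_en = y[..., 0], y[..., 1], y[..., 2]
    mu = np.asarray(mu, dtype=float)

    if parasite_present:
        a_r, b_r = _split(np.asarray(mu_rp, dtype=float) * 1.0)
    else:
        a_r = b_r = np.zeros(np.shape(y_r))
    d_r = a_r * (1.0 - y_r) - b_r * y_r - phi * y_r

    # inputs to E_S: R, C (source y=1), E_N
    t_es = np.stack(
        [mu[..., 0] * y_r, mu[..., 2] * 1.0 * np.ones_like(y_r), mu[..., 4] * y_en], axis=-1
    )
    a_es, b_es = _split(t_es)
    a_es, b_es = a_es.sum(axis=-1), b_es.sum(axis=-1)
    d_es = a_es * (1.0 - y_es) - b_es * y_es - phi * y_es

    t_en = np.stack(
        [mu[..., 1] * y_r, mu[..., 3] * 1.0 * np.ones_like(y_r), mu[..., 5] * y_es], axis=-1
    )
    a_en, b_en = _split(t_en)
    a_en, b_en = a_en.sum(axis=-1), b_en.sum(axis=-1)
    d_en = a_en * (1.0 - y_en) - b_en * y_en - phi * y_en

    return np.stack([d_r, d_es, d_en], axis=-1)


def derivative(
    y: ActivityState,
    m: InteractionMatrix,
    phi: float = PHI_DEFAULT,
    parasite_present: bool = False,
) -> np.ndarray:
    """Time derivative (dy_R, dy_ES, dy_EN) at one state."""
    if phi <= 0:
        raise ValueError("deactivation rate phi must be positive")
    arr = y.as_array()
    if np.any(arr < -1e-12) or np.any(arr > 1 + 1e-12):
        raise ValueError("activities must lie in [0, 1]")
    if parasite_present and m.mu_rp is None:
        raise ValueError("parasite_present=True requires an interaction matrix with mu_rp")
    return _rates(arr, m.mu, m.mu_rp if parasite_present else 0.0, phi, parasite_present)


# ---------------------------------------------------------------------------
# solvers
# ---------------------------------------------------------------------------

def _rk4_batch(
    mu: np.ndarray,
    mu_rp,
    phi: float,
    init: np.ndarray,
    parasite_present: bool,
    tol: float,
    t_max: float,
    step: float = RK4_STEP,
) -> np.ndarray:
    """Fixed-step RK4 on (N, 3) states until max |dy/dt| < tol everywhere."""
    y = np.array(init, dtype=float)
    t = 0.0
    while True:
        k1 = _rates(y, mu, mu_rp, phi, parasite_present)
        if np.max(np.abs(k1)) < tol:
            return np.clip(y, 0.0, 1.0)
        if t >= t_max:
            raise EquilibriumError(
                f"RK4 integration did not reach residual {tol:g} by t={t_max:g} "
                f"(worst residual {np.max(np.abs(k1)):.3e})"
            )
        k2 = _rates(y + 0.5 * step * k1, mu, mu_rp, phi, parasite_present)
        k3 = _rates(y + 0.5 * step * k2, mu, mu_rp, phi, parasite_present)
        k4 = _rates(y + step * k3, mu, mu_rp, phi, parasite_present)
        y = y + (step / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        np.clip(y, 0.0, 1.0, out=y)
        t += step


def receptor_equilibrium(mu_rp, phi: float = PHI_DEFAULT):
    """Closed-form receptor steady state: a single-input node driven by the
    static parasite source satisfies y_R = mu/(phi + mu) for mu > 0, else 0."""
    mu_rp = np.asarray(mu_rp, dtype=float)
    return np.where(mu_rp > 0, mu_rp / (phi + mu_rp), 0.0)


def effector_equilibria(
    mu: np.ndarray,
    y_r,
    phi: float = PHI_DEFAULT,
    init: np.ndarray | None = None,
    tol: float = TOL_DEFAULT,
    max_iter: int = 200_000,
    damping: float = 0.5,
):
    """Damped fixed-point solve of the coupled effector pair.

    ``mu`` is (N, 6), ``y_r`` (N,) the (already equilibrated) receptor
    activity.  Returns ((N, 2) effector activities, iteration count).
    Each sweep updates y <- y + damping * (A/(phi+A+B) - y); the update has
    the sign of dy/dt, so trajectories follow the flow from ``init``
    (all-zero when omitted).
    """
    mu = np.atleast_2d(np.asarray(mu, dtype=float))
    n = mu.shape[0]
    y_r = np.broadcast_to(np.asarray(y_r, dtype=float), (n,))
    y = np.zeros((n, 2)) if init is None else np.array(init, dtype=float).reshape(n, 2)

    for it in range(1, max_iter + 1):
        y_es, y_en = y[:, 0], y[:, 1]
        t_es = np.stack([mu[:, 0] * y_r, mu[:, 2], mu[:, 4] * y_en], axis=-1)
        t_en = np.stack([mu[:, 1] * y_r, mu[:, 3], mu[:, 5] * y_es], axis=-1)
        a_es, b_es = _split(t_es)
        a_en, b_en = _split(t_en)
        a_es, b_es = a_es.sum(-1), b_es.sum(-1)
        a_en, b_en = a_en.sum(-1), b_en.sum(-1)
        d_es = a_es * (1 - y_es) - b_es * y_es - phi * y_es
        d_en = a_en * (1 - y_en) - b_en * y_en - phi * y_en
        resid = max(np.max(np.abs(d_es)), np.max(np.abs(d_en)))
        if resid < tol:
            return np.clip(y, 0.0, 1.0), it
        f_es = a_es / (phi + a_es + b_es)
        f_en = a_en / (phi + a_en + b_en)
        y = y + damping * (np.stack([f_es, f_en], axis=-1) - y)
    raise EquilibriumError(
        f"fixed-point iteration did not reach residual {tol:g} in {max_iter} sweeps"
    )


def integrate_rk4(
    m: InteractionMatrix,
    phi: float = PHI_DEFAULT,
    parasite_present: bool = False,
    init: ActivityState | None = None,
    tol: float = TOL_DEFAULT,
    t_max: float = T_MAX_DEFAULT,
) -> ActivityState:
    """Reference solver: forward RK4 integration until max |dy/dt| < tol."""
    y0 = np.zeros(3) if init is None else init.as_array()
    mu_rp = m.mu_rp if parasite_present else 0.0
    if parasite_present and m.mu_rp is None:
        raise ValueError("parasite_present=True requires mu_rp")
    y = _rk4_batch(m.mu[None, :], mu_rp, phi, y0[None, :], parasite_present, tol, t_max)[0]
    return ActivityState(*y)


def solve_equilibrium(
    m: InteractionMatrix,
    phi: float = PHI_DEFAULT,
    parasite_present: bool = False,
    init: ActivityState | None = None,
    tol: float = TOL_DEFAULT,
    t_max: float = T_MAX_DEFAULT,
    method: str = "fixed_point",
    full_output: bool = False,
):
    """Steady state of the network from a given initial state.

    ``method='fixed_point'`` (default) uses the damped accelerator;
    ``method='rk4'`` integrates the flow directly.  With ``full_output``
    the residual and iteration count are returned for logging.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    if phi <= 0:
        raise ValueError("deactivation rate phi must be positive")
    if parasite_present and m.mu_rp is None:
        raise ValueError("parasite_present=True requires mu_rp")

    if method == "rk4":
        state = integrate_rk4(m, phi, parasite_present, init, tol, t_max)
        iters = -1
    elif method == "fixed_point":
        y_r = float(receptor_equilibrium(m.mu_rp, phi)) if parasite_present else 0.0
        y0 = None if init is None else np.array([[init.y_es, init.y_en]])
        eff, iters = effector_equilibria(m.mu[None, :], np.array([y_r]), phi, y0, tol)
        state = ActivityState(y_r, eff[0, 0], eff[0, 1])
    else:
        raise ValueError(f"unknown method {method!r}")

    resid = float(np.max(np.abs(_rates(
        state.as_array(), m.mu, m.mu_rp if parasite_present else 0.0, phi, parasite_present
    ))))
    if full_output:
        return state, {"residual": resid, "iterations": iters}
    return state


def constitutive_state(
    host: HostGenome,
    phi: float = PHI_DEFAULT,
    tol: float = TOL_DEFAULT,
    method: str = "fixed_point",
) -> ActivityState:
    """Resting equilibrium without a parasite, reached from all-zero
    activities; the receptor, lacking inputs, stays at zero."""
    m = build_interactions(host)
    return solve_equilibrium(m, phi=phi, parasite_present=False, tol=tol, method=method)


def induced_state(
    host: HostGenome,
    parasite: ParasiteGenome,
    receptor_mode: str = "nonspecific",
    phi: float = PHI_DEFAULT,
    tol: float = TOL_DEFAULT,
    method: str = "fixed_point",
) -> ActivityState:
    """Infected equilibrium with the parasite source y_P = 1, initialised
    from the constitutive resting state (induction perturbs a maintained
    system, it does not restart it)."""
    m = build_interactions(host, parasite, receptor_mode)
    rest = constitutive_state(host, phi=phi, tol=tol, method=method)
    return solve_equilibrium(
        m, phi=phi, parasite_present=True, init=rest, tol=tol, method=method
    )
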