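"""The individual-based coevolutionary loop.

Host and parasite populations of fixed size evolve in discrete,
non-overlapping generations.  Each generation: every host is challenged
with probability ``p_encounter`` by a single parasite drawn uniformly with
replacement; resting and (for challenged hosts) infected network
equilibria are solved; fitnesses follow the two-phase survival model.
Hosts then reproduce sexually — both parents drawn by a fitness-weighted
lottery with replacement, free recombination between (never within)
proteins — while parasites reproduce clonally by the same lottery.  Both
populations finally receive point mutations at a fixed per-individual
event rate.

Parasite fitness is the mean establishment probability over the
encounters a parasite actually realised; parasites that were never drawn
receive the mean fitness of the drawn ones, keeping sampling noise
selectively neutral.  A burn-in window (flagged per row in the output,
default the first half of the run) lets genetic variation build up before
summary statistics are interpreted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields, replace

import numpy as np
import pandas as pd

from . import genome as gn
from . import metrics as mt
from .dynamics import EDGE_NAMES, effector_equilibria, host_edge_coefficients, receptor_equilibrium
from .fitness import host_fitness, parasite_fitness, survival_infected

__all__ = [
    "SimulationConfig",
    "Population",
    "GenerationEvaluation",
    "assign_encounters",
    "evaluate_generation",
    "reproduce_hosts",
    "reproduce_parasites",
    "run_replicate",
    "run_simulation",
    "SUMMARY_COLUMNS",
]

logger = logging.getLogger(__name__)

RECEPTOR_MODES = ("specific", "nonspecific")

SUMMARY_COLUMNS = (
    ("replicate", "generation", "post_burn_in", "n_challenged")
    + ("y0_es", "y0_en", "ind_es", "ind_en", "receptor_activity", "parasite_diversity")
    + EDGE_NAMES
    + ("host_fitness", "parasite_fitness")
    + mt.DIVERGENCE_COLUMNS
)


@dataclass(frozen=True)
class SimulationConfig:
    """One simulation setting.  Defaults are the study conditions of the
    headline experiment: populations of 2000 haploid hosts and parasites,
    bitstrings of length 10, deactivation rate 0.3, mutation rate 1 % per
    individual per generation, maximum virulence 0.99, 10000 generations
    with a 5000-generation burn-in, 20 replicates; cost and delay at the
    low end (0.2) of the explored [0.2, 0.8] range."""

    receptor_mode: str = "nonspecific"
    p_encounter: float = 1.0
    kappa: float = 0.2
    delta: float = 0.2
    nu: float = 0.99
    phi: float = 0.3
    L: int = 10
    n_host: int = 2000
    n_parasite: int = 2000
    mutation_rate: float = 0.01
    generations: int = 10000
    burn_in: int = 5000
    replicates: int = 20
    seed: int = 1
    record_every: int = 1
    selection: bool = True
    diversity_pairs: int = 10000
    tol: float = 1e-8

    def __post_init__(self):
        if self.receptor_mode not in RECEPTOR_MODES:
            raise ValueError(
                f"receptor_mode must be one of {RECEPTOR_MODES}, got {self.receptor_mode!r}"
            )
        for name, lo, hi in (
            ("p_encounter", 0.0, 1.0),
            ("delta", 0.0, 1.0),
            ("mutation_rate", 0.0, 1.0),
        ):
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name} must lie in [{lo}, {hi}], got {v}")
        if self.kappa < 0:
            raise ValueError("kappa must be non-negative")
        if not 0.0 <= self.nu < 1.0:
            raise ValueError("nu must lie in [0, 1)")
        if self.phi <= 0:
            raise ValueError("phi must be positive")
        if self.L < 1:
            raise ValueError("sequence length L must be at least 1")
        for name in ("n_host", "n_parasite", "replicates", "record_every"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be at least 1")
        if self.generations < 0:
            raise ValueError("generations must be non-negative")
        if not 0 <= self.burn_in <= max(self.generations, 1):
            raise ValueError("burn_in must lie within the simulated generations")
        if self.tol <= 0:
            raise ValueError("tol must be positive")

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass
class Population:
    """Host and parasite genomes of one generation, as stacked bit arrays."""

    hosts: np.ndarray  # (n_host, 4, 3, L)
    parasites: np.ndarray  # (n_parasite, 3, L)
    generation: int = 0

    @classmethod
    def random(cls, config: SimulationConfig, rng: np.random.Generator) -> "Population":
        return cls(
            hosts=gn.random_host_population(config.n_host, config.L, rng),
            parasites=gn.random_parasite_population(config.n_parasite, config.L, rng),
            generation=0,
        )


@dataclass
class GenerationEvaluation:
    """Everything computed when one generation meets its parasites."""

    mu6: np.ndarray  # (n_host, 6) evolvable edge coefficients
    y0: np.ndarray  # (n_host, 2) resting effector equilibria
    s0: np.ndarray  # (n_host,) pre-infection survival
    challenged_idx: np.ndarray  # (M,) indices of challenged hosts
    parasite_idx: np.ndarray  # (M,) matched parasite index per challenge
    y_r_star: np.ndarray  # (M,) infected receptor activity
    ystar: np.ndarray  # (M, 2) infected effector equilibria
    xi_s: np.ndarray  # (M,) specific-effector efficacy per pair
    E0: np.ndarray
    Estar: np.ndarray
    sstar: np.ndarray
    w_host: np.ndarray  # (n_host,)
    w_parasite: np.ndarray  # (n_parasite,)
    w_pair: np.ndarray  # (M,) per-encounter parasite fitness


def assign_encounters(
    n_host: int, n_parasite: int, p_encounter: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Challenge each host independently with probability ``p_encounter``
    and pair every challenged host with one parasite drawn uniformly with
    replacement.  Returns (challenged host indices, parasite indices)."""
    if not 0.0 <= p_encounter <= 1.0:
        raise ValueError("p_encounter must lie in [0, 1]")
    challenged = np.nonzero(rng.random(n_host) < p_encounter)[0]
    parasite_idx = rng.integers(n_parasite, size=challenged.size)
    return challenged, parasite_idx


def evaluate_generation(
    pop: Population, config: SimulationConfig, rng: np.random.Generator
) -> GenerationEvaluation:
    """Solve all equilibria and score every individual's fitness."""
    hosts, parasites = pop.hosts, pop.parasites
    n_host, n_parasite = hosts.shape[0], parasites.shape[0]
    phi, kappa, delta = config.phi, config.kappa, config.delta

    mu6 = host_edge_coefficients(hosts)
    # one constitutive solve per host per generation, from rest
    y0, _ = effector_equilibria(mu6, np.zeros(n_host), phi, None, config.tol)
    c0_all = kappa * y0.sum(axis=1)
    s0 = host_fitness(c0_all)

    cidx, pidx = assign_encounters(n_host, n_parasite, config.p_encounter, rng)
    m = cidx.size
    h_pair = hosts[cidx]
    p_pair = parasites[pidx]

    xi_s = gn.match_active(p_pair[:, gn.S_I], h_pair[:, gn.E_S, gn.S_O])
    if config.receptor_mode == "nonspecific":
        mu_rp = np.full(m, gn.NONSPECIFIC_COEFF)
    else:
        mu_rp = gn.match_active(h_pair[:, gn.R, gn.S_I], p_pair[:, gn.S_O])
    y_r_star = receptor_equilibrium(mu_rp, phi)

    if m:
        ystar, _ = effector_equilibria(mu6[cidx], y_r_star, phi, y0[cidx], config.tol)
    else:
        ystar = np.zeros((0, 2))

    xi_n = gn.NONSPECIFIC_COEFF
    E0 = xi_s * y0[cidx, 0] + xi_n * y0[cidx, 1]
    Estar = xi_s * ystar[:, 0] + xi_n * ystar[:, 1]
    C0 = c0_all[cidx]
    Cstar = kappa * ystar.sum(axis=1)
    sstar = survival_infected(E0, C0, Estar, Cstar, config.nu, delta)

    w_host = s0.copy()
    w_host[cidx] *= sstar

    w_pair = parasite_fitness(E0, Estar, delta)
    counts = np.bincount(pidx, minlength=n_parasite)
    totals = np.bincount(pidx, weights=w_pair, minlength=n_parasite)
    w_parasite = np.empty(n_parasite)
    if m:
        fill = w_pair.mean()  # unencountered parasites are selectively neutral
    else:
        fill = 1.0
    hit = counts > 0
    w_parasite[hit] = totals[hit] / counts[hit]
    w_parasite[~hit] = fill

    if not config.selection:
        w_host = np.ones(n_host)
        w_parasite = np.ones(n_parasite)

    return GenerationEvaluation(
        mu6=mu6, y0=y0, s0=s0, challenged_idx=cidx, parasite_idx=pidx,
        y_r_star=y_r_star, ystar=ystar, xi_s=xi_s, E0=E0, Estar=Estar,
        sstar=sstar, w_host=w_host, w_parasite=w_parasite, w_pair=w_pair,
    )


def _lottery_p(w: np.ndarray, what: str) -> np.ndarray | None:
    total = w.sum()
    if total <= 0 or not np.isfinite(total):
        logger.warning("all %s fitnesses are zero; falling back to uniform sampling", what)
        return None
    return w / total


def reproduce_hosts(
    hosts: np.ndarray, w: np.ndarray, rng: np.random.Generator, mutation_rate: float
) -> np.ndarray:
    """Sexual reproduction: two parents per offspring by fitness-weighted
    lottery with replacement (parents may coincide), protein-wise
    recombination, then mutation.  Population size is preserved."""
    n = hosts.shape[0]
    p = _lottery_p(w, "host")
    parents = rng.choice(n, size=2 * n, replace=True, p=p).reshape(n, 2)
    offspring = gn.recombine_population(hosts, parents[:, 0], parents[:, 1], rng)
    return gn.mutate_population(offspring, mutation_rate, rng)


def reproduce_parasites(
    parasites: np.ndarray, w: np.ndarray, rng: np.random.Generator, mutation_rate: float
) -> np.ndarray:
    """Clonal reproduction by fitness-weighted lottery, then mutation."""
    n = parasites.shape[0]
    p = _lottery_p(w, "parasite")
    idx = rng.choice(n, size=n, replace=True, p=p)
    return gn.mutate_population(parasites[idx], mutation_rate, rng)


def _summary_row(
    replicate: int,
    gen: int,
    config: SimulationConfig,
    pop: Population,
    ev: GenerationEvaluation,
    rng_metrics: np.random.Generator,
    ref_host: np.ndarray,
    ref_par: np.ndarray,
    ref_gen: int,
) -> dict:
    row = {
        "replicate": replicate,
        "generation": gen,
        "post_burn_in": gen >= config.burn_in,
        "n_challenged": int(ev.challenged_idx.size),
    }
    row.update(mt.activity_decomposition(ev.y0, ev.ystar, ev.challenged_idx))
    row["receptor_activity"] = (
        float(ev.y_r_star.mean()) if ev.challenged_idx.size else np.nan
    )
    row["parasite_diversity"] = mt.parasite_pairwise_diversity(
        pop.parasites, rng_metrics, max_pairs=config.diversity_pairs
    )
    row.update(dict(zip(EDGE_NAMES, ev.mu6.mean(axis=0))))
    row["host_fitness"] = float(ev.w_host.mean())
    row["parasite_fitness"] = float(ev.w_parasite.mean())

    elapsed = gen - ref_gen
    host_rate = mt.consensus_divergence(ref_host, mt.consensus(pop.hosts), elapsed)
    par_rate = mt.consensus_divergence(ref_par, mt.consensus(pop.parasites), elapsed)
    for pi, plabel in enumerate(mt.HOST_LABELS):
        for ci, clabel in enumerate(("sn", "si", "so")):
            row[f"div_host_{plabel}_{clabel}"] = float(host_rate[pi, ci])
    for ci, clabel in enumerate(("sn", "si", "so")):
        row[f"div_par_{clabel}"] = float(par_rate[ci])
    return row


def run_replicate(
    config: SimulationConfig,
    seed: int | np.random.SeedSequence,
    replicate: int = 0,
) -> pd.DataFrame:
    """One replicate: initialise random populations, iterate the
    evaluate/record/reproduce cycle, and return the generation table.

    Rows are recorded every ``record_every`` generations (fitness and
    equilibria refer to the parental generation before selection).  The
    divergence reference consensus is re-anchored at the burn-in
    generation so post-burn-in rates are unpolluted by initial transients.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    evo_ss, metrics_ss = ss.spawn(2)
    rng = np.random.default_rng(evo_ss)
    rng_metrics = np.random.default_rng(metrics_ss)

    pop = Population.random(config, rng)
    ref_host, ref_par = mt.consensus(pop.hosts), mt.consensus(pop.parasites)
    ref_gen = 0
    rows = []

    def record(gen: int, ev: GenerationEvaluation):
        rows.append(
            _summary_row(replicate, gen, config, pop, ev, rng_metrics, ref_host, ref_par, ref_gen)
        )

    if config.generations == 0:
        record(0, evaluate_generation(pop, config, rng))
        return pd.DataFrame(rows, columns=list(SUMMARY_COLUMNS))

    for gen in range(config.generations):
        if gen == config.burn_in and gen > 0:
            ref_host, ref_par = mt.consensus(pop.hosts), mt.consensus(pop.parasites)
            ref_gen = gen
        ev = evaluate_generation(pop, config, rng)
        if gen % config.record_every == 0 or gen == config.generations - 1:
            record(gen, ev)
        pop = Population(
            hosts=reproduce_hosts(pop.hosts, ev.w_host, rng, config.mutation_rate),
            parasites=reproduce_parasites(pop.parasites, ev.w_parasite, rng, config.mutation_rate),
            generation=gen + 1,
        )
    return pd.DataFrame(rows, columns=list(SUMMARY_COLUMNS))


def replicate_seeds(config: SimulationConfig) -> list[np.random.SeedSequence]:
    """Fixed derivation rule: the master seed spawns one child seed
    sequence per replicate, so replicates are independent and individually
    re-runnable."""
    return np.random.SeedSequence(config.seed).spawn(config.replicates)


def run_simulation(config: SimulationConfig) -> pd.DataFrame:
    """All replicates of one configuration, concatenated into a single
    generation table keyed by (replicate, generation).  Deterministic
    given ``config.seed``."""
    tables = []
    for r, child in enumerate(replicate_seeds(config)):
        logger.info("replicate %d/%d starting", r + 1, config.replicates)
        tables.append(run_replicate(config, child, replicate=r))
    return pd.concat(tables, ignore_index=True)
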