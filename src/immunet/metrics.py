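"""Per-generation population summaries.

The quantities tracked here are the observables of the coevolutionary
experiment: the split of effector activity into its constitutive part
(resting equilibrium, averaged over all hosts) and its induced part
(infected minus resting equilibrium, averaged over challenged hosts);
receptor activity among challenged hosts, which doubles as the parasite
detection rate; parasite genetic diversity as the mean pairwise Hamming
distance of the functional domains; the population-mean interaction
strength of each evolvable network edge; and per-sequence-class divergence
rates that contrast functional (input/output-domain) against neutral
sequence evolution.

Divergence is measured on the population consensus (majority bit per
position) relative to a reference generation's consensus, divided by the
generations elapsed — a deliberate approximation that avoids lineage
tracing; the neutral reference sequence S_N provides the molecular-clock
baseline against which adaptive evolution in S_I/S_O shows up as excess
divergence.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import genome as gn
from .dynamics import EDGE_NAMES, host_edge_coefficients

__all__ = [
    "HOST_LABELS",
    "DIVERGENCE_COLUMNS",
    "parasite_pairwise_diversity",
    "activity_decomposition",
    "edge_strengths",
    "consensus",
    "consensus_divergence",
    "divergence_rates",
    "summarise_replicates",
]

HOST_LABELS = ("r", "c", "es", "en")
_CLASS_LABELS = ("sn", "si", "so")

DIVERGENCE_COLUMNS = tuple(
    f"div_host_{p}_{c}" for p in HOST_LABELS for c in _CLASS_LABELS
) + tuple(f"div_par_{c}" for c in _CLASS_LABELS)

EXACT_PAIR_THRESHOLD = 200


def _functional_bits(parasites: np.ndarray, include_neutral: bool) -> np.ndarray:
    """Flatten each parasite to the bit set entering the distance."""
    parasites = np.asarray(parasites, dtype=np.uint8)
    if include_neutral:
        picked = parasites
    else:
        picked = parasites[:, (gn.S_I, gn.S_O), :]
    return picked.reshape(parasites.shape[0], -1)


def parasite_pairwise_diversity(
    parasites: np.ndarray,
    rng: np.random.Generator | None = None,
    max_pairs: int = 10_000,
    include_neutral: bool = False,
) -> float:
    """Mean Hamming distance over unordered pairs of parasites.

    By default the distance is computed on the concatenated input+output
    domains (2L bits), where selection acts; the neutral sequence can be
    folded in with ``include_neutral``.  All pairs are enumerated up to
    ``EXACT_PAIR_THRESHOLD`` individuals, beyond which ``max_pairs``
    uniformly sampled pairs estimate the mean.
    """
    bits = _functional_bits(parasites, include_neutral)
    n = bits.shape[0]
    if n == 0:
        raise ValueError("empty parasite population")
    if n == 1:
        return 0.0
    if n <= EXACT_PAIR_THRESHOLD:
        x = bits.astype(np.int32)
        ones = x.sum(axis=1)
        dot = x @ x.T
        d = ones[:, None] + ones[None, :] - 2 * dot
        iu = np.triu_indices(n, k=1)
        return float(d[iu].mean())
    rng = np.random.default_rng() if rng is None else rng
    i = rng.integers(n, size=max_pairs)
    j = rng.integers(n, size=max_pairs)
    keep = i != j
    d = np.count_nonzero(bits[i[keep]] != bits[j[keep]], axis=1)
    return float(d.mean())


def activity_decomposition(
    y0: np.ndarray, ystar: np.ndarray | None, challenged_idx: np.ndarray | None = None
) -> dict:
    """Population means of the constitutive and induced activity components.

    ``y0`` is (N, 2) resting effector activities for every host; ``ystar``
    is (M, 2) infected activities for the challenged subset (indexed by
    ``challenged_idx``).  With no challenged hosts the induced components
    are reported as NaN (missing), not zero.
    """
    y0 = np.atleast_2d(y0)
    out = {"y0_es": float(y0[:, 0].mean()), "y0_en": float(y0[:, 1].mean())}
    if ystar is None or len(ystar) == 0:
        out["ind_es"] = np.nan
        out["ind_en"] = np.nan
    else:
        ystar = np.atleast_2d(ystar)
        base = y0 if challenged_idx is None else y0[challenged_idx]
        delta = ystar - base
        out["ind_es"] = float(delta[:, 0].mean())
        out["ind_en"] = float(delta[:, 1].mean())
    return out


def edge_strengths(hosts: np.ndarray) -> dict:
    """Population-mean interaction coefficient for each evolvable edge."""
    mu = host_edge_coefficients(np.asarray(hosts, dtype=np.uint8))
    return dict(zip(EDGE_NAMES, mu.mean(axis=0)))


def consensus(pop: np.ndarray) -> np.ndarray:
    """Majority bit per position (ties break to 0)."""
    pop = np.asarray(pop, dtype=np.uint8)
    return (pop.mean(axis=0) > 0.5).astype(np.uint8)


def consensus_divergence(ref: np.ndarray, cur: np.ndarray, elapsed: int) -> np.ndarray:
    """Per-sequence Hamming distance between two consensus blocks, per
    generation elapsed.  Shapes (..., n_seq, L) -> (..., n_seq); zero when
    no time has elapsed."""
    d = np.count_nonzero(np.asarray(ref) != np.asarray(cur), axis=-1).astype(float)
    if elapsed <= 0:
        return np.zeros_like(d)
    return d / elapsed


def divergence_rates(
    snapshots: dict[int, tuple[np.ndarray, np.ndarray]], reference_generation: int
) -> pd.DataFrame:
    """Tidy table of consensus divergence rates from a snapshot series.

    ``snapshots`` maps generation -> (host consensus (4, 3, L), parasite
    consensus (3, L)).  Rates are Hamming distance from the reference
    generation's consensus divided by generations elapsed, one row per
    (generation, species, protein, sequence class).
    """
    if reference_generation not in snapshots:
        raise KeyError(f"no snapshot at reference generation {reference_generation}")
    ref_host, ref_par = snapshots[reference_generation]
    rows = []
    for gen in sorted(snapshots):
        host_c, par_c = snapshots[gen]
        elapsed = gen - reference_generation
        host_rate = consensus_divergence(ref_host, host_c, elapsed)
        par_rate = consensus_divergence(ref_par, par_c, elapsed)
        for pi, protein in enumerate(HOST_LABELS):
            for ci, cls in enumerate(_CLASS_LABELS):
                rows.append(
                    {"generation": gen, "species": "host", "protein": protein,
                     "seq_class": cls, "rate": float(host_rate[pi, ci])}
                )
        for ci, cls in enumerate(_CLASS_LABELS):
            rows.append(
                {"generation": gen, "species": "parasite", "protein": "p",
                 "seq_class": cls, "rate": float(par_rate[ci])}
            )
    return pd.DataFrame(rows)


def summarise_replicates(table: pd.DataFrame) -> pd.DataFrame:
    """Aggregate a multi-replicate generation table to mean and standard
    error per generation (columns suffixed _mean / _se)."""
    value_cols = [
        c for c in table.columns
        if c not in ("replicate", "generation") and np.issubdtype(table[c].dtype, np.number)
    ]
    g = table.groupby("generation")[value_cols]
    mean = g.mean().add_suffix("_mean")
    se = (g.std(ddof=1) / np.sqrt(g.count())).add_suffix("_se")
    return pd.concat([mean, se], axis=1).reset_index()
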