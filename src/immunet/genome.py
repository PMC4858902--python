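"""Bitstring genomes and the sequence-matching rules that turn them into
protein-interaction strengths.

Every protein carries three bitstrings of length ``L``: a neutral reference
sequence ``S_N`` (no phenotypic effect, a molecular clock), an input domain
``S_I`` and an output domain ``S_O``.  The interaction strength between two
proteins is a linear function of the Hamming distance between the input
domain of the downstream protein and the output domain of the upstream one,

    mu = 1 - 2 H(S_I, S_O) / L,

so a bitwise match above 50 % activates and one below 50 % inhibits.
Host-parasite interfaces follow an all-or-nothing matching-allele rule for
specific components (coefficient 1 when the sequence match reaches 60 %,
0 otherwise) and a low constant for non-specific ones (0.2 regardless of
genotype).

Genomes are stored as small ``uint8`` numpy arrays: a host is a
``(4, 3, L)`` block (proteins R, C, E_S, E_N x sequences S_N, S_I, S_O),
a parasite a single ``(3, L)`` protein.  Population-scale helpers operate
on stacked arrays with a leading individual axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "L_DEFAULT",
    "HOST_PROTEINS",
    "SEQUENCE_CLASSES",
    "NONSPECIFIC_COEFF",
    "MATCH_THRESHOLD",
    "ProteinSequences",
    "HostGenome",
    "ParasiteGenome",
    "random_genome",
    "random_host_population",
    "random_parasite_population",
    "hamming",
    "sequence_match",
    "interaction_coefficient",
    "specific_coefficient",
    "receptor_parasite_coefficient",
    "effector_parasite_efficacy",
    "mutate",
    "mutate_population",
    "recombine",
    "recombine_population",
    "genome_to_text",
    "genome_from_text",
]

L_DEFAULT = 10

HOST_PROTEINS = ("R", "C", "E_S", "E_N")
SEQUENCE_CLASSES = ("S_N", "S_I", "S_O")

# index constants for the protein and sequence axes
R, C, E_S, E_N = 0, 1, 2, 3
S_N, S_I, S_O = 0, 1, 2

NONSPECIFIC_COEFF = 0.2
MATCH_THRESHOLD = 0.6


def _as_bits(seq) -> np.ndarray:
    """Coerce a bitstring ('0101...', list, or array) to a uint8 array."""
    if isinstance(seq, str):
        arr = np.frombuffer(seq.encode(), dtype=np.uint8) - ord("0")
    else:
        arr = np.asarray(seq, dtype=np.uint8)
    if arr.ndim != 1:
        raise ValueError("a bitstring must be one-dimensional")
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("bitstring symbols must be 0 or 1")
    return arr.astype(np.uint8)


def _bits_to_str(bits: np.ndarray) -> str:
    return "".join("1" if b else "0" for b in np.asarray(bits).ravel())


@dataclass(frozen=True)
class ProteinSequences:
    """The three bitstrings (neutral, input domain, output domain) of one protein."""

    s_n: np.ndarray
    s_i: np.ndarray
    s_o: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "s_n", _as_bits(self.s_n))
        object.__setattr__(self, "s_i", _as_bits(self.s_i))
        object.__setattr__(self, "s_o", _as_bits(self.s_o))
        if not (len(self.s_n) == len(self.s_i) == len(self.s_o)):
            raise ValueError("all three sequences of a protein must share length L")

    @property
    def length(self) -> int:
        return len(self.s_n)

    @property
    def array(self) -> np.ndarray:
        """(3, L) block in S_N, S_I, S_O order."""
        return np.stack([self.s_n, self.s_i, self.s_o])

    @classmethod
    def from_array(cls, block: np.ndarray) -> "ProteinSequences":
        block = np.asarray(block, dtype=np.uint8)
        if block.shape[0] != 3:
            raise ValueError("expected a (3, L) sequence block")
        return cls(block[S_N], block[S_I], block[S_O])


@dataclass(frozen=True)
class HostGenome:
    """Four proteins with fixed roles: receptor R, constitutive protein C,
    specific effector E_S and non-specific effector E_N."""

    r: ProteinSequences
    c: ProteinSequences
    e_s: ProteinSequences
    e_n: ProteinSequences

    def __post_init__(self):
        lengths = {p.length for p in (self.r, self.c, self.e_s, self.e_n)}
        if len(lengths) != 1:
            raise ValueError("all proteins of a host must share sequence length L")

    @property
    def length(self) -> int:
        return self.r.length

    @property
    def array(self) -> np.ndarray:
        """(4, 3, L) block in R, C, E_S, E_N order."""
        return np.stack([p.array for p in (self.r, self.c, self.e_s, self.e_n)])

    @classmethod
    def from_array(cls, block: np.ndarray) -> "HostGenome":
        block = np.asarray(block, dtype=np.uint8)
        if block.shape[:2] != (4, 3):
            raise ValueError("expected a (4, 3, L) host genome block")
        return cls(*(ProteinSequences.from_array(block[i]) for i in range(4)))


@dataclass(frozen=True)
class ParasiteGenome:
    """A single parasite protein.  Its output domain faces the host receptor,
    its input domain faces the host effectors; S_N is the neutral clock."""

    p: ProteinSequences

    @property
    def length(self) -> int:
        return self.p.length

    @property
    def array(self) -> np.ndarray:
        """(3, L) block in S_N, S_I, S_O order."""
        return self.p.array

    @classmethod
    def from_array(cls, block: np.ndarray) -> "ParasiteGenome":
        return cls(ProteinSequences.from_array(block))


# ---------------------------------------------------------------------------
# random initialisation
# ---------------------------------------------------------------------------

def _check_length(L: int) -> None:
    if not (isinstance(L, (int, np.integer)) and L >= 1):
        raise ValueError(f"sequence length L must be a positive integer, got {L!r}")


def random_genome(kind: str, L: int = L_DEFAULT, rng: np.random.Generator | None = None):
    """Draw a genome with every bit independently 0 or 1 with probability 1/2."""
    _check_length(L)
    rng = np.random.default_rng() if rng is None else rng
    if kind == "host":
        return HostGenome.from_array(rng.integers(0, 2, size=(4, 3, L), dtype=np.uint8))
    if kind == "parasite":
        return ParasiteGenome.from_array(rng.integers(0, 2, size=(3, L), dtype=np.uint8))
    raise ValueError(f"kind must be 'host' or 'parasite', got {kind!r}")


def random_host_population(n: int, L: int, rng: np.random.Generator) -> np.ndarray:
    """(n, 4, 3, L) array of independent random host genomes."""
    _check_length(L)
    return rng.integers(0, 2, size=(n, 4, 3, L), dtype=np.uint8)


def random_parasite_population(n: int, L: int, rng: np.random.Generator) -> np.ndarray:
    """(n, 3, L) array of independent random parasite genomes."""
    _check_length(L)
    return rng.integers(0, 2, size=(n, 3, L), dtype=np.uint8)


# ---------------------------------------------------------------------------
# sequence matching
# ---------------------------------------------------------------------------

def hamming(a, b) -> int:
    """Number of differing positions between two equal-length bitstrings."""
    a, b = _as_bits(a), _as_bits(b)
    if a.shape != b.shape:
        raise ValueError("Hamming distance requires equal-length bitstrings")
    return int(np.count_nonzero(a != b))


def sequence_match(a, b) -> float:
    """Fraction of matching bits, 1 - H/L."""
    a = _as_bits(a)
    return 1.0 - hamming(a, b) / len(a)


def interaction_coefficient(s_i, s_o) -> float:
    """Evolvable interaction strength mu = 1 - 2H/L in [-1, 1].

    Positive (activating) iff the bitwise match exceeds 50 %.
    """
    s_i = _as_bits(s_i)
    return 1.0 - 2.0 * hamming(s_i, s_o) / len(s_i)


def specific_coefficient(s_i, s_o) -> float:
    """All-or-nothing matching-allele coefficient: 1 when the sequence match
    1 - H/L reaches the 60 % threshold, else 0.  The boundary (match exactly
    0.6, i.e. H = 0.4 L) activates."""
    s_i = _as_bits(s_i)
    L = len(s_i)
    # integer comparison: match >= 0.6  <=>  5 * (L - H) >= 3 * L
    return 1.0 if 5 * (L - hamming(s_i, s_o)) >= 3 * L else 0.0


def receptor_parasite_coefficient(
    receptor: ProteinSequences, parasite: ParasiteGenome, mode: str
) -> float:
    """Coefficient mu_RxP of the parasite->receptor edge.

    Non-specific recognition is a genotype-blind constant 0.2; specific
    recognition matches the receptor input domain against the parasite
    output domain with the 60 % threshold.
    """
    if mode == "nonspecific":
        return NONSPECIFIC_COEFF
    if mode == "specific":
        return specific_coefficient(receptor.s_i, parasite.p.s_o)
    raise ValueError(f"receptor mode must be 'specific' or 'nonspecific', got {mode!r}")


def effector_parasite_efficacy(
    effector: ProteinSequences, parasite: ParasiteGenome, which: str
) -> float:
    """Killing efficacy xi_PxE of one effector against one parasite.

    The non-specific effector acts at constant 0.2; the specific effector's
    output domain must match the parasite input domain to the 60 % threshold.
    """
    if which == "E_N":
        return NONSPECIFIC_COEFF
    if which == "E_S":
        return specific_coefficient(parasite.p.s_i, effector.s_o)
    raise ValueError(f"effector label must be 'E_S' or 'E_N', got {which!r}")


def match_active(s_i: np.ndarray, s_o: np.ndarray) -> np.ndarray:
    """Vectorised 60 %-threshold rule on (..., L) bit arrays -> float 0/1."""
    L = s_i.shape[-1]
    h = np.count_nonzero(s_i != s_o, axis=-1)
    return (5 * (L - h) >= 3 * L).astype(float)


# ---------------------------------------------------------------------------
# mutation and recombination
# ---------------------------------------------------------------------------

def mutate(genome, rate: float, rng: np.random.Generator):
    """Point mutation at the stated per-individual event rate.

    With probability ``rate`` the individual receives exactly one bit flip
    at a position uniform over all of its bitstrings (host: 4x3xL bits,
    parasite: 3xL); otherwise the genome is returned unchanged.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("mutation rate must lie in [0, 1]")
    if rng.random() >= rate:
        return genome
    block = genome.array.copy()
    pos = rng.integers(block.size)
    block.ravel()[pos] ^= 1
    return type(genome).from_array(block)


def mutate_population(pop: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Apply `mutate` independently to every row of a population array."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError("mutation rate must lie in [0, 1]")
    n = pop.shape[0]
    nbits = pop[0].size
    hit = rng.random(n) < rate
    pos = rng.integers(nbits, size=n)
    out = pop.copy()
    flat = out.reshape(n, nbits)
    idx = np.nonzero(hit)[0]
    flat[idx, pos[idx]] ^= 1
    return out


def recombine(parent_a: HostGenome, parent_b: HostGenome, rng: np.random.Generator) -> HostGenome:
    """Free recombination between, but never within, proteins: each of the
    four proteins is inherited intact (all three sequences together) from
    either parent with probability 1/2."""
    pick = rng.integers(0, 2, size=4)
    a, b = parent_a.array, parent_b.array
    child = np.where(pick[:, None, None] == 0, a, b)
    return HostGenome.from_array(child)


def recombine_population(
    pop: np.ndarray,
    parents_a: np.ndarray,
    parents_b: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorised `recombine` producing one offspring per (parent_a, parent_b) row."""
    a = pop[parents_a]
    b = pop[parents_b]
    pick = rng.integers(0, 2, size=(len(parents_a), 4))
    return np.where(pick[:, :, None, None] == 0, a, b)


# ---------------------------------------------------------------------------
# plain-text serialization
# ---------------------------------------------------------------------------

def genome_to_text(genome) -> str:
    """One line per sequence: '<protein> <class> <bits>'."""
    lines = []
    if isinstance(genome, HostGenome):
        labels = HOST_PROTEINS
        blocks = genome.array
    elif isinstance(genome, ParasiteGenome):
        labels = ("P",)
        blocks = genome.array[None]
    else:
        raise TypeError(f"cannot serialise {type(genome).__name__}")
    for label, block in zip(labels, blocks):
        for cls_name, seq in zip(SEQUENCE_CLASSES, block):
            lines.append(f"{label} {cls_name} {_bits_to_str(seq)}")
    return "\n".join(lines) + "\n"


def genome_from_text(text: str):
    """Inverse of `genome_to_text`; infers host vs parasite from the labels."""
    rows: dict[tuple[str, str], np.ndarray] = {}
    for line in text.strip().splitlines():
        protein, cls_name, bits = line.split()
        rows[(protein, cls_name)] = _as_bits(bits)
    proteins = {p for p, _ in rows}
    def block(p):
        return np.stack([rows[(p, c)] for c in SEQUENCE_CLASSES])
    if proteins == {"P"}:
        return ParasiteGenome.from_array(block("P"))
    if proteins == set(HOST_PROTEINS):
        return HostGenome.from_array(np.stack([block(p) for p in HOST_PROTEINS]))
    raise ValueError(f"unrecognised protein labels: {sorted(proteins)}")
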