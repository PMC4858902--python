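"""Configuration files, output tables, run manifests and test fixtures.

Configs are TOML key-value files mirroring `SimulationConfig`; unspecified
keys fall back to the defaults of the headline experiment and unknown or
out-of-range keys raise descriptive errors.  Generation tables are written
as TSV with a stable column order and fixed float precision so identical
runs produce byte-identical files.
"""

from __future__ import annotations

import json
import tomllib
from dataclasses import fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import genome as gn
from .evolution import SimulationConfig, replicate_seeds

__all__ = [
    "ConfigError",
    "load_config",
    "config_to_toml",
    "write_generation_table",
    "read_generation_table",
    "write_manifest",
    "make_fixture",
]

FLOAT_FORMAT = "%.10g"


class ConfigError(ValueError):
    """A configuration file failed validation."""


_FIELDS = {f.name: f.type for f in fields(SimulationConfig)}
_INT_KEYS = {"L", "n_host", "n_parasite", "generations", "burn_in",
             "replicates", "seed", "record_every", "diversity_pairs"}
_BOOL_KEYS = {"selection"}
_STR_KEYS = {"receptor_mode"}


def load_config(path: str | Path) -> SimulationConfig:
    """Parse and validate a TOML config; missing keys take the defaults."""
    raw = tomllib.loads(Path(path).read_text())
    unknown = set(raw) - set(_FIELDS)
    if unknown:
        raise ConfigError(
            f"unknown configuration keys: {sorted(unknown)}; "
            f"valid keys are {sorted(_FIELDS)}"
        )
    coerced = {}
    for key, value in raw.items():
        if key in _BOOL_KEYS:
            if not isinstance(value, bool):
                raise ConfigError(f"{key} must be a boolean, got {value!r}")
        elif key in _STR_KEYS:
            if not isinstance(value, str):
                raise ConfigError(f"{key} must be a string, got {value!r}")
        elif key in _INT_KEYS:
            if isinstance(value, bool) or not isinstance(value, int):
                raise ConfigError(f"{key} must be an integer, got {value!r}")
        else:
            if isinstance(value, bool) or not isinstance(value, (int, float)):
                raise ConfigError(f"{key} must be a number, got {value!r}")
            value = float(value)
        coerced[key] = value
    try:
        return SimulationConfig(**coerced)
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc


def config_to_toml(config: SimulationConfig) -> str:
    lines = []
    for key, value in config.to_dict().items():
        if isinstance(value, bool):
            lines.append(f"{key} = {'true' if value else 'false'}")
        elif isinstance(value, str):
            lines.append(f'{key} = "{value}"')
        else:
            lines.append(f"{key} = {value}")
    return "\n".join(lines) + "\n"


def write_generation_table(table: pd.DataFrame, path: str | Path) -> None:
    """Deterministic TSV: rows sorted by (replicate, generation), header
    always present, floats at fixed precision."""
    table = table.sort_values(["replicate", "generation"], kind="mergesort")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_generation_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_manifest(
    config: SimulationConfig, out_dir: str | Path, outputs: list[str]
) -> Path:
    """Record what produced the files in ``out_dir``: the full config, the
    software version, and the per-replicate seed entropy (spawned from the
    master seed by the fixed SeedSequence rule)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "software": {"name": "immunet", "version": __version__},
        "config": config.to_dict(),
        "replicate_seed_entropy": [
            list(map(int, np.atleast_1d(ss.entropy))) + [r]
            for r, ss in enumerate(replicate_seeds(config))
        ],
        "generations": {"start": 0, "end": config.generations},
        "outputs": sorted(outputs),
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

def _all_matching_host(L: int) -> gn.HostGenome:
    """Every input domain identical to every output domain: all six
    evolvable coefficients equal 1."""
    block = np.zeros((4, 3, L), dtype=np.uint8)
    return gn.HostGenome.from_array(block)


def make_fixture(kind: str, seed: int = 0, L: int = gn.L_DEFAULT, n: int = 10, k: int = 4):
    """Small deterministic populations for tests and examples.

    kinds:
      perfect_match_host   - monomorphic hosts whose domains all match
                             (all six edge coefficients 1; a parasite of
                             all-zero bits is detected and killed
                             specifically)
      escaped_parasite     - (host, parasite) pair whose receptor match is
                             below the 60 % threshold (specific mu_RxP = 0)
      two_genotype_parasites - n parasites, half at each of two genotypes
                             a functional-domain distance k apart
      random_host / random_parasite - seeded random single genome
    """
    rng = np.random.default_rng(seed)
    if kind == "perfect_match_host":
        host = _all_matching_host(L)
        return [host] * n
    if kind == "escaped_parasite":
        host = _all_matching_host(L)
        par_block = np.zeros((3, L), dtype=np.uint8)
        # mismatch the parasite output domain beyond the 60 % threshold
        flips = int(np.floor(0.4 * L)) + 1
        par_block[gn.S_O, :flips] = 1
        return host, gn.ParasiteGenome.from_array(par_block)
    if kind == "two_genotype_parasites":
        if not 0 <= k <= 2 * L:
            raise ValueError("k must lie in [0, 2L] (functional domains only)")
        a = np.zeros((3, L), dtype=np.uint8)
        b = a.copy()
        flat = b[(gn.S_I, gn.S_O), :].reshape(-1)
        flat[:k] = 1
        b[(gn.S_I, gn.S_O), :] = flat.reshape(2, L)
        pop = [gn.ParasiteGenome.from_array(a)] * (n // 2)
        pop += [gn.ParasiteGenome.from_array(b)] * (n - n // 2)
        return pop
    if kind == "random_host":
        return gn.random_genome("host", L, rng)
    if kind == "random_parasite":
        return gn.random_genome("parasite", L, rng)
    raise ValueError(f"unknown fixture kind {kind!r}")
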