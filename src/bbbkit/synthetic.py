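"""Seeded generator of two-class descriptor tables with known structure.

Produces tables with planted informative descriptors (class-conditional
distributions shifted by a configurable separation), pure-noise descriptors,
correlated (redundant) descriptor pairs, and structural-key descriptors
realised as class-dependent missing-value patterns — everything the
selection/encoding/splitting/modeling pipeline assumes, with a ground-truth
manifest so tests can assert recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .data_model import DescriptorTable
from .exceptions import InputError

__all__ = ["SyntheticSpec", "generate", "generate_bit_dataset"]


@dataclass(frozen=True)
class SyntheticSpec:
    n_active: int = 300
    n_inactive: int = 100
    n_informative: int = 10
    n_noise: int = 10
    n_correlated_pairs: int = 2
    n_structural_keys: int = 4
    separation: float = 3.0  # standardized mean difference for informative cols
    absence_rates: Tuple[float, float] = (0.7, 0.1)  # (active, inactive)
    bimodal_inactive: bool = False
    seed: int = 0

    def __post_init__(self):
        counts = (self.n_active, self.n_inactive, self.n_informative,
                  self.n_noise, self.n_correlated_pairs, self.n_structural_keys)
        if any(c < 0 for c in counts):
            raise InputError("all counts must be >= 0")
        if self.n_active + self.n_inactive < 2:
            raise InputError("need at least 2 samples")
        if not all(0.0 <= r <= 1.0 for r in self.absence_rates):
            raise InputError("absence rates must be in [0, 1]")


def _informative_column(rng, n_act, n_ina, separation, bimodal):
    a = rng.normal(loc=separation, scale=1.0, size=n_act)
    if bimodal:
        comp = rng.integers(0, 2, size=n_ina)
        b = rng.normal(loc=np.where(comp == 0, -2.0, 2.0), scale=1.0, size=n_ina)
    else:
        b = rng.normal(loc=0.0, scale=1.0, size=n_ina)
    return np.concatenate([a, b])


def generate(spec: SyntheticSpec) -> Tuple[DescriptorTable, np.ndarray, Dict]:
    """Build (table, labels, manifest); the seed fully determines the output.

    Manifest keys: ``informative``, ``noise``, ``correlated_base``,
    ``correlated_redundant``, ``structural_keys`` — each a list of
    descriptor names.
    """
    rng = np.random.default_rng(spec.seed)
    n_act, n_ina = spec.n_active, spec.n_inactive
    n = n_act + n_ina
    labels = np.concatenate([np.ones(n_act, dtype=int),
                             np.zeros(n_ina, dtype=int)])

    cols: Dict[str, np.ndarray] = {}
    manifest: Dict[str, List[str]] = {
        "informative": [], "noise": [],
        "correlated_base": [], "correlated_redundant": [],
        "structural_keys": [],
    }

    for i in range(spec.n_informative):
        name = f"inf_{i:03d}"
        cols[name] = _informative_column(rng, n_act, n_ina, spec.separation,
                                         spec.bimodal_inactive)
        manifest["informative"].append(name)

    for i in range(spec.n_noise):
        name = f"noise_{i:03d}"
        cols[name] = rng.normal(size=n)
        manifest["noise"].append(name)

    for i in range(spec.n_correlated_pairs):
        base_name = f"corrbase_{i:03d}"
        red_name = f"corrred_{i:03d}"
        base = _informative_column(rng, n_act, n_ina, spec.separation,
                                   spec.bimodal_inactive)
        # small independent jitter keeps population correlation >= 0.9
        redundant = base + rng.normal(scale=0.3, size=n)
        cols[base_name] = base
        cols[red_name] = redundant
        manifest["correlated_base"].append(base_name)
        manifest["correlated_redundant"].append(red_name)

    rate_act, rate_ina = spec.absence_rates
    for i in range(spec.n_structural_keys):
        name = f"key_{i:03d}"
        vals = rng.normal(size=n)
        absent = np.concatenate([
            rng.random(n_act) < rate_act,
            rng.random(n_ina) < rate_ina,
        ])
        vals[absent] = np.nan
        cols[name] = vals
        manifest["structural_keys"].append(name)

    ids = [f"cmpd_{i:05d}" for i in range(n)]
    frame = pd.DataFrame(cols, index=ids)
    table = DescriptorTable(frame=frame, set_tag="2D")
    return table, labels, manifest


def generate_bit_dataset(n: int, length: int, seed: int = 0) -> np.ndarray:
    """Seeded random 0/1 matrix guaranteed to contain two distinct rows."""
    if n <= 0 or length <= 0:
        raise InputError("n and length must be positive")
    rng = np.random.default_rng(seed)
    X = rng.integers(0, 2, size=(n, length)).astype(np.uint8)
    if n >= 2 and all((X[i] == X[0]).all() for i in range(1, n)):
        X[1, 0] ^= 1  # force at least two distinct rows
    return X
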