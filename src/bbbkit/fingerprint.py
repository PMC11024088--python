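"""Property-based bit-fingerprint codec plus a circular-fingerprint adapter.

A fingerprint starts with one presence/absence bit per structural key
(1 = the substructure is present, i.e. the descriptor value is non-missing),
followed by one thermometer-coded field per selected continuous descriptor.

Field widths are 1, 4 or 8 bits.  For widths 4 and 8 the training-set value
range of the descriptor is divided by ``bits`` boundaries

    bound_i = val_min + i * val_range / bits,   i = 0 .. bits-1

into ``bits + 1`` bins; a value is assigned to bin 0 if it is <= the first
boundary, to the top bin if it is greater than the last boundary, and to bin
i+1 when bound_i < value <= bound_{i+1}.  The bin index j is written as j
leading set bits.  For width 1 the single bit is set iff the value is >= the
training median.  Boundaries and medians are fitted on training data only
and reused unchanged for any later compound.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .exceptions import ConfigurationError, InputError

__all__ = [
    "DescriptorEncoding",
    "FingerprintSchema",
    "Fingerprint",
    "fit_schema",
    "assign_bin",
    "encode",
    "encode_table",
    "morgan_adapter",
]

_VALID_BITS = (1, 4, 8)


@dataclass(frozen=True)
class DescriptorEncoding:
    """Fitted encoding parameters for one continuous descriptor."""

    descriptor_name: str
    bits: int
    val_min: float
    val_range: float
    boundaries: Optional[Tuple[float, ...]] = None  # bits in {4, 8}
    median: Optional[float] = None  # bits == 1
    degenerate: bool = False  # zero training range

    def __post_init__(self):
        if self.bits not in _VALID_BITS:
            raise ConfigurationError(f"bits must be one of {_VALID_BITS}")
        if self.bits == 1 and self.median is None:
            raise ConfigurationError("1-bit encoding requires a median")
        if self.bits > 1 and self.boundaries is None:
            raise ConfigurationError("multi-bit encoding requires boundaries")


@dataclass
class FingerprintSchema:
    """Ordered structural keys + per-descriptor encodings, fitted on training data."""

    structural_keys: List[str]
    encodings: List[DescriptorEncoding]

    @property
    def total_length(self) -> int:
        return len(self.structural_keys) + sum(e.bits for e in self.encodings)

    def to_json(self) -> str:
        return json.dumps(
            {
                "structural_keys": self.structural_keys,
                "encodings": [
                    {
                        "descriptor_name": e.descriptor_name,
                        "bits": e.bits,
                        "val_min": e.val_min,
                        "val_range": e.val_range,
                        "boundaries": (list(e.boundaries)
                                       if e.boundaries is not None else None),
                        "median": e.median,
                        "degenerate": e.degenerate,
                    }
                    for e in self.encodings
                ],
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "FingerprintSchema":
        d = json.loads(text)
        encs = [
            DescriptorEncoding(
                descriptor_name=e["descriptor_name"],
                bits=e["bits"],
                val_min=e["val_min"],
                val_range=e["val_range"],
                boundaries=(tuple(e["boundaries"])
                            if e["boundaries"] is not None else None),
                median=e["median"],
                degenerate=e["degenerate"],
            )
            for e in d["encodings"]
        ]
        return cls(structural_keys=list(d["structural_keys"]), encodings=encs)


@dataclass
class Fingerprint:
    bits: np.ndarray  # uint8 0/1 vector
    compound_id: str = ""
    missing_descriptors: Tuple[str, ...] = field(default_factory=tuple)

    def __len__(self) -> int:
        return int(self.bits.size)

    def to_hex(self) -> str:
        return np.packbits(self.bits).tobytes().hex()


def make_encoding(name: str, train_values: Sequence[float],
                  bits: int) -> DescriptorEncoding:
    """Fit one descriptor's encoding from its non-missing training values."""
    vals = np.asarray(train_values, dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ConfigurationError(f"descriptor {name}: no training values")
    vmin = float(vals.min())
    vrange = float(vals.max() - vals.min())
    degenerate = vrange == 0.0
    if bits == 1:
        return DescriptorEncoding(
            descriptor_name=name, bits=1, val_min=vmin, val_range=vrange,
            median=float(np.median(vals)), degenerate=degenerate,
        )
    bounds = tuple(vmin + i * vrange / bits for i in range(bits))
    return DescriptorEncoding(
        descriptor_name=name, bits=bits, val_min=vmin, val_range=vrange,
        boundaries=bounds, degenerate=degenerate,
    )


def fit_schema(train_table, selection, bits: int = 8) -> FingerprintSchema:
    """Fit the full schema from a training DescriptorTable and a FeatureSelection.

    Boundaries/medians come exclusively from the training table; any later
    encoding of unseen compounds reuses them unchanged.
    """
    if bits not in _VALID_BITS:
        raise ConfigurationError(f"bits must be one of {_VALID_BITS}")
    frame = train_table.frame
    missing = [n for n in selection.descriptor_names if n not in frame.columns]
    if missing:
        raise ConfigurationError(
            f"selected descriptors absent from training table: {missing}")
    encodings = [
        make_encoding(name, frame[name].to_numpy(dtype=float), bits)
        for name in selection.descriptor_names
    ]
    return FingerprintSchema(
        structural_keys=list(selection.structural_key_names),
        encodings=encodings,
    )


def assign_bin(value: float, enc: DescriptorEncoding) -> int:
    """Map a value to its bin index in [0, bits] for a 4- or 8-bit encoding."""
    if enc.bits == 1:
        raise InputError("assign_bin applies to 4- or 8-bit encodings")
    b = enc.boundaries
    if value <= b[0]:
        return 0
    if value > b[-1]:
        return enc.bits
    # unique i with b[i] < value <= b[i+1]
    idx = int(np.searchsorted(np.asarray(b), value, side="left"))
    return idx


def _field_bits(value: float, enc: DescriptorEncoding) -> np.ndarray:
    out = np.zeros(enc.bits, dtype=np.uint8)
    if not np.isfinite(value):
        return out  # "no information" thermometer state
    if enc.bits == 1:
        out[0] = 1 if value >= enc.median else 0
        return out
    j = assign_bin(value, enc)
    out[:j] = 1
    return out


def encode(compound_descriptors: Mapping[str, float],
           schema: FingerprintSchema,
           compound_id: str = "") -> Fingerprint:
    """Encode one compound's descriptor values against a fitted schema.

    Missing structural-key values give a 0 prefix bit; missing continuous
    values give an all-zero field and are reported in the fingerprint's
    ``missing_descriptors``.
    """
    parts: List[np.ndarray] = []
    missing: List[str] = []

    prefix = np.zeros(len(schema.structural_keys), dtype=np.uint8)
    for i, key in enumerate(schema.structural_keys):
        v = compound_descriptors.get(key, np.nan)
        prefix[i] = 1 if np.isfinite(v) else 0
    parts.append(prefix)

    for enc in schema.encodings:
        v = compound_descriptors.get(enc.descriptor_name, np.nan)
        v = float(v) if v is not None else np.nan
        if not np.isfinite(v):
            missing.append(enc.descriptor_name)
        parts.append(_field_bits(v, enc))

    bits = np.concatenate(parts) if parts else np.zeros(0, dtype=np.uint8)
    assert bits.size == schema.total_length
    return Fingerprint(bits=bits, compound_id=compound_id,
                       missing_descriptors=tuple(missing))


def encode_table(table, schema: FingerprintSchema) -> np.ndarray:
    """Encode every row of a DescriptorTable; returns an (n, total_length) matrix."""
    frame = table.frame
    fps = []
    for cid, row in frame.iterrows():
        fp = encode(row.to_dict(), schema, compound_id=str(cid))
        fps.append(fp.bits)
    return np.vstack(fps) if fps else np.zeros((0, schema.total_length), np.uint8)


def fingerprints_to_frame(table, schema: FingerprintSchema):
    import pandas as pd

    mat = encode_table(table, schema)
    cols = [f"bit_{i}" for i in range(mat.shape[1])]
    return pd.DataFrame(mat, index=table.frame.index, columns=cols)


def morgan_adapter(record, radius: int = 2, n_bits: int = 2048) -> Fingerprint:
    """Standard circular bit fingerprint of a compound, for baseline comparison."""
    from rdkit import Chem
    from rdkit.Chem import rdFingerprintGenerator

    mol = Chem.MolFromSmiles(record.smiles)
    if mol is None:
        raise InputError(f"compound {record.id}: invalid SMILES {record.smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    bv = gen.GetFingerprint(mol)
    arr = np.zeros(n_bits, dtype=np.uint8)
    for idx in bv.GetOnBits():
        arr[idx] = 1
    return Fingerprint(bits=arr, compound_id=record.id)
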