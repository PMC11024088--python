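"""Compound and descriptor-table I/O, label derivation, dataset standardization.

File formats are plain delimited text: compounds as CSV with columns
``id, smiles, logbb, label``; descriptor tables as CSV with the compound id
in the first column and descriptor names in the header.  Missing values are
spelled ``NaN`` or left empty.

Missing-value semantics differ by descriptor dimensionality: in a 2D
structure-based descriptor a missing value means the encoded substructure is
absent from the molecule; in a 3D descriptor it means the computation
failed, and the compound is dropped from the 3D table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, InputError

logger = logging.getLogger(__name__)

__all__ = [
    "LOGBB_ACTIVE_THRESHOLD",
    "CompoundRecord",
    "DescriptorTable",
    "RemovalLogEntry",
    "load_compounds",
    "write_compounds",
    "standardize_dataset",
    "load_descriptor_table",
    "descriptor_adapter",
]

#: Compounds with logBB at or above this are labelled active (BBB+).
LOGBB_ACTIVE_THRESHOLD = -1.0

# Atoms considered "organic subset"; anything else flags the compound.
_ORGANIC = {"H", "B", "C", "N", "O", "F", "P", "S", "Cl", "Br", "I"}


@dataclass
class CompoundRecord:
    """One molecule with its structure string and activity information."""

    id: str
    smiles: str
    logbb: Optional[float] = None
    label: Optional[int] = None
    mw: Optional[float] = None
    flagged: bool = False
    flag_reason: str = ""

    def __post_init__(self):
        if self.logbb is None and self.label is None:
            raise InputError(
                f"compound {self.id}: at least one of logbb/label required"
            )
        if self.label is None and self.logbb is not None:
            self.label = int(self.logbb >= LOGBB_ACTIVE_THRESHOLD)
        elif self.logbb is not None and self.label is not None:
            derived = int(self.logbb >= LOGBB_ACTIVE_THRESHOLD)
            if derived != self.label:
                # explicit label wins; note the disagreement
                logger.warning(
                    "compound %s: explicit label %d disagrees with "
                    "logbb-derived label %d", self.id, self.label, derived,
                )


@dataclass
class RemovalLogEntry:
    compound_id: str
    reason: str


@dataclass
class DescriptorTable:
    """Compounds x named descriptors with per-descriptor dimension tags."""

    frame: pd.DataFrame  # index = compound ids, columns = descriptor names
    dimension_tags: Dict[str, str] = field(default_factory=dict)
    set_tag: str = "2D"

    def __post_init__(self):
        if self.frame.columns.duplicated().any():
            raise InputError("descriptor names must be unique")
        if self.frame.index.duplicated().any():
            raise InputError("compound ids must be unique")
        for name in self.frame.columns:
            self.dimension_tags.setdefault(name, self.set_tag)

    @property
    def compound_ids(self) -> List[str]:
        return [str(i) for i in self.frame.index]

    @property
    def descriptor_names(self) -> List[str]:
        return list(self.frame.columns)

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    def subset_rows(self, ids: Sequence[str]) -> "DescriptorTable":
        return DescriptorTable(
            frame=self.frame.loc[list(ids)].copy(),
            dimension_tags=dict(self.dimension_tags),
            set_tag=self.set_tag,
        )

    def write(self, path) -> None:
        self.frame.to_csv(path, index_label="id", na_rep="NaN")


def _parse_optional_float(v) -> Optional[float]:
    if v is None or (isinstance(v, float) and np.isnan(v)) or v == "":
        return None
    return float(v)


def load_compounds(
    path,
    logbb_column: str = "logbb",
    label_column: str = "label",
    id_column: str = "id",
    smiles_column: str = "smiles",
) -> List[CompoundRecord]:
    """Read a compound CSV; labels are derived from logBB when absent.

    A row whose SMILES cannot be parsed by the toolkit is kept but flagged.
    """
    df = pd.read_csv(path)
    if logbb_column not in df.columns and label_column not in df.columns:
        raise InputError(
            f"{path}: need at least one of columns "
            f"{logbb_column!r}/{label_column!r}"
        )
    from rdkit import Chem  # deferred: keep import cost off the module path

    records: List[CompoundRecord] = []
    for _, row in df.iterrows():
        logbb = (_parse_optional_float(row[logbb_column])
                 if logbb_column in df.columns else None)
        label = (_parse_optional_float(row[label_column])
                 if label_column in df.columns else None)
        rec = CompoundRecord(
            id=str(row[id_column]),
            smiles=str(row[smiles_column]),
            logbb=logbb,
            label=None if label is None else int(label),
        )
        mol = Chem.MolFromSmiles(rec.smiles)
        if mol is None:
            logger.warning("compound %s: unparseable SMILES %r",
                           rec.id, rec.smiles)
            rec.flagged = True
            rec.flag_reason = "unparseable SMILES"
        records.append(rec)
    return records


def write_compounds(records: Sequence[CompoundRecord], path) -> None:
    pd.DataFrame(
        {
            "id": [r.id for r in records],
            "smiles": [r.smiles for r in records],
            "logbb": [r.logbb for r in records],
            "label": [r.label for r in records],
        }
    ).to_csv(path, index=False, na_rep="")


def standardize_dataset(
    records: Sequence[CompoundRecord],
    mw_max: float = 1000.0,
) -> Tuple[List[CompoundRecord], List[RemovalLogEntry]]:
    """Filter a compound list down to clean, unique, consistently labelled records.

    Removes, in order: unparseable structures; multi-fragment structures
    (salts/mixtures); structures containing atoms outside the organic subset;
    compounds heavier than ``mw_max`` daltons (strict >, average MW); exact
    duplicates by canonical SMILES (first occurrence kept); and every copy of
    a structure whose duplicates disagree on the label.  Each removal is
    logged, so ``len(records) == len(kept) + len(log)``.
    """
    from rdkit import Chem
    from rdkit.Chem import Descriptors

    log: List[RemovalLogEntry] = []
    parsed: List[Tuple[CompoundRecord, str]] = []  # (record, canonical smiles)

    for rec in records:
        mol = Chem.MolFromSmiles(rec.smiles)
        if mol is None:
            log.append(RemovalLogEntry(rec.id, "unparseable SMILES"))
            continue
        if len(Chem.GetMolFrags(mol)) > 1:
            log.append(RemovalLogEntry(rec.id, "multi-fragment (salt/mixture)"))
            continue
        symbols = {a.GetSymbol() for a in mol.GetAtoms()}
        bad = symbols - _ORGANIC
        if bad:
            log.append(RemovalLogEntry(
                rec.id, f"non-organic atoms: {','.join(sorted(bad))}"))
            continue
        mw = Descriptors.MolWt(mol)
        rec.mw = mw
        if mw > mw_max:
            log.append(RemovalLogEntry(rec.id, f"MW {mw:.1f} > {mw_max:g}"))
            continue
        parsed.append((rec, Chem.MolToSmiles(mol)))

    # group by canonical structure
    groups: Dict[str, List[CompoundRecord]] = {}
    order: List[str] = []
    for rec, canon in parsed:
        if canon not in groups:
            groups[canon] = []
            order.append(canon)
        groups[canon].append(rec)

    kept: List[CompoundRecord] = []
    for canon in order:
        grp = groups[canon]
        labels = {r.label for r in grp}
        if len(labels) > 1:
            for r in grp:
                log.append(RemovalLogEntry(r.id, "contradictory duplicate labels"))
            continue
        kept.append(grp[0])
        for r in grp[1:]:
            log.append(RemovalLogEntry(r.id, "duplicate structure"))

    if not kept:
        logger.warning("standardize_dataset removed every compound")
    return kept, log


def load_descriptor_table(path, set_tag: str = "2D",
                          dimension_tags: Optional[Dict[str, str]] = None
                          ) -> DescriptorTable:
    """Read a precomputed descriptor CSV (first column = compound id)."""
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.map(str)
    return DescriptorTable(frame=df.astype(float),
                           dimension_tags=dict(dimension_tags or {}),
                           set_tag=set_tag)


def _rdkit_2d_calculator(records: Sequence[CompoundRecord]) -> pd.DataFrame:
    """Small built-in 2D descriptor set (fallback when no external calculator)."""
    from rdkit import Chem
    from rdkit.Chem import Crippen, Descriptors, rdMolDescriptors

    fns = {
        "MolWt": Descriptors.MolWt,
        "TopoPSA": rdMolDescriptors.CalcTPSA,
        "MolLogP": Crippen.MolLogP,
        "NumHAcceptors": rdMolDescriptors.CalcNumHBA,
        "NumHDonors": rdMolDescriptors.CalcNumHBD,
        "NumRotatableBonds": rdMolDescriptors.CalcNumRotatableBonds,
        "NumAromaticRings": rdMolDescriptors.CalcNumAromaticRings,
        "FractionCSP3": rdMolDescriptors.CalcFractionCSP3,
        "HeavyAtomCount": lambda m: m.GetNumHeavyAtoms(),
        "RingCount": rdMolDescriptors.CalcNumRings,
    }
    rows = {}
    for rec in records:
        mol = Chem.MolFromSmiles(rec.smiles)
        if mol is None:
            rows[rec.id] = {k: np.nan for k in fns}
            continue
        rows[rec.id] = {k: float(f(mol)) for k, f in fns.items()}
    return pd.DataFrame.from_dict(rows, orient="index")[list(fns)]


def descriptor_adapter(
    records: Sequence[CompoundRecord],
    dimension: str = "2D",
    precomputed: Optional[DescriptorTable] = None,
    calculator: str = "auto",
) -> DescriptorTable:
    """Produce a DescriptorTable for ``records`` in the requested dimension.

    Precedence: an explicitly supplied precomputed table; an external
    calculator (``mordred``) when importable; for 2D only, a small built-in
    toolkit descriptor set.  Compounds whose 3D computation fails (all-NaN
    row in a 3D table) are dropped and logged.
    """
    if dimension not in {"2D", "3D"}:
        raise InputError(f"dimension must be 2D or 3D, got {dimension!r}")

    if precomputed is not None:
        table = precomputed
    else:
        if calculator in ("auto", "mordred"):
            try:
                table = _mordred_calculator(records, dimension)
            except ImportError:
                if calculator == "mordred":
                    raise ConfigurationError(
                        "mordred calculator requested but not importable")
                table = None
        else:
            table = None
        if table is None:
            if dimension == "3D":
                raise ConfigurationError(
                    "no 3D descriptor calculator available and no "
                    "precomputed table supplied"
                )
            table = DescriptorTable(frame=_rdkit_2d_calculator(records),
                                    set_tag="2D")

    if dimension == "3D":
        vals = table.frame
        failed = vals.index[vals.isna().all(axis=1)]
        for cid in failed:
            logger.warning("compound %s: 3D computation failed, dropped", cid)
        table = DescriptorTable(
            frame=vals.drop(index=failed),
            dimension_tags={n: "3D" for n in vals.columns},
            set_tag="3D",
        )
    return table


def _mordred_calculator(records: Sequence[CompoundRecord],
                        dimension: str) -> DescriptorTable:
    from mordred import Calculator, descriptors  # noqa: F401

    from rdkit import Chem

    calc = Calculator(descriptors, ignore_3D=(dimension == "2D"))
    mols, ids = [], []
    for rec in records:
        mol = Chem.MolFromSmiles(rec.smiles)
        if mol is None:
            continue
        mols.append(mol)
        ids.append(rec.id)
    df = calc.pandas(mols, quiet=True)
    df.index = ids
    df = df.apply(pd.to_numeric, errors="coerce")
    return DescriptorTable(frame=df, set_tag=dimension)
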