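"""Reaction and descriptor data model, plus readers/writers for the table
formats the pipeline touches.

Two containers carry all data through the pipeline:

* :class:`ReactionSet` — the bipartite enzyme <-> substrate relation, as a
  deduplicated set of ``(enzyme_id, substrate_id)`` pairs with identifier
  registries.  Identifiers are opaque strings (UniProt accessions, EC
  numbers, database-native ids); no cross-database resolution is attempted.
* :class:`DescriptorMatrix` — molecules x named numeric descriptors, a thin
  wrapper over a :class:`pandas.DataFrame` that additionally records
  whether (and with which parameters) the matrix has been z-scored.

Readers accept CSV/TSV with a header row (RFC 4180 quoting, UTF-8); the
descriptor reader follows the PaDEL-Descriptor output dialect where the
first column is the molecule name and every other column is numeric.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, TYPE_CHECKING

import numpy as np
import pandas as pd

from .errors import EmptyInputError, FormatError

if TYPE_CHECKING:  # pragma: no cover - import cycle guard for type hints
    from .pair_features import NormalizationParams

logger = logging.getLogger(__name__)

__all__ = [
    "ReactionSet",
    "DescriptorMatrix",
    "read_reaction_table",
    "write_reaction_table",
    "merge_reaction_sets",
    "read_descriptor_table",
    "write_descriptor_table",
    "compute_descriptors",
    "read_smiles_file",
]


@dataclass(frozen=True)
class ReactionSet:
    """A deduplicated set of enzyme-substrate reactions.

    Parameters
    ----------
    reactions
        Set of ``(enzyme_id, substrate_id)`` pairs.
    provenance
        Optional free-text source label per reaction.
    """

    reactions: frozenset[tuple[str, str]]
    provenance: Mapping[tuple[str, str], str] = field(default_factory=dict)

    @classmethod
    def from_pairs(
        cls,
        pairs: Iterable[tuple[str, str]],
        provenance: Mapping[tuple[str, str], str] | None = None,
    ) -> "ReactionSet":
        return cls(frozenset(pairs), dict(provenance or {}))

    @property
    def enzymes(self) -> frozenset[str]:
        return frozenset(e for e, _ in self.reactions)

    @property
    def substrates(self) -> frozenset[str]:
        return frozenset(s for _, s in self.reactions)

    def substrates_of(self, enzyme_id: str) -> frozenset[str]:
        return frozenset(s for e, s in self.reactions if e == enzyme_id)

    def enzymes_of(self, substrate_id: str) -> frozenset[str]:
        return frozenset(e for e, s in self.reactions if s == substrate_id)

    def substrate_to_enzymes(self) -> dict[str, frozenset[str]]:
        """Map every substrate to the set of enzymes that catalyze it."""
        out: dict[str, set[str]] = {}
        for e, s in self.reactions:
            out.setdefault(s, set()).add(e)
        return {s: frozenset(es) for s, es in out.items()}

    def enzyme_to_substrates(self) -> dict[str, frozenset[str]]:
        out: dict[str, set[str]] = {}
        for e, s in self.reactions:
            out.setdefault(e, set()).add(s)
        return {e: frozenset(ss) for e, ss in out.items()}

    def restrict(
        self,
        enzymes: Iterable[str] | None = None,
        substrates: Iterable[str] | None = None,
    ) -> "ReactionSet":
        """Keep only reactions whose enzyme/substrate is in the given sets."""
        es = None if enzymes is None else set(enzymes)
        ss = None if substrates is None else set(substrates)
        kept = frozenset(
            (e, s)
            for e, s in self.reactions
            if (es is None or e in es) and (ss is None or s in ss)
        )
        prov = {k: v for k, v in self.provenance.items() if k in kept}
        return ReactionSet(kept, prov)

    def __len__(self) -> int:
        return len(self.reactions)


@dataclass
class DescriptorMatrix:
    """Molecules x descriptors, with optional normalization state.

    ``data`` is indexed by molecule id with one column per descriptor.
    ``normalization`` is ``None`` for raw matrices and holds the fitted
    per-column parameters once :func:`~enzypred.pair_features.apply_normalization`
    has been applied.
    """

    data: pd.DataFrame
    normalization: "NormalizationParams | None" = None

    def __post_init__(self) -> None:
        idx = self.data.index
        if idx.has_duplicates:
            dups = sorted(idx[idx.duplicated()].unique())
            raise FormatError(f"duplicate molecule names: {dups}")
        cols = self.data.columns
        if cols.has_duplicates:
            dups = sorted(cols[cols.duplicated()].unique())
            raise FormatError(f"duplicate descriptor names: {dups}")

    @property
    def molecule_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def descriptor_names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def missing_mask(self) -> np.ndarray:
        return self.data.isna().to_numpy()

    def subset(self, molecule_ids: Sequence[str]) -> "DescriptorMatrix":
        missing = [m for m in molecule_ids if m not in self.data.index]
        if missing:
            raise KeyError(f"molecules without descriptor rows: {sorted(missing)}")
        return dataclasses.replace(self, data=self.data.loc[list(molecule_ids)])

    def row(self, molecule_id: str) -> pd.Series:
        return self.data.loc[molecule_id]

    def __len__(self) -> int:
        return len(self.data)


def read_reaction_table(
    path,
    enzyme_col: str = "enzyme_id",
    substrate_col: str = "substrate_id",
    source_col: str | None = "source",
    sep: str | None = None,
) -> ReactionSet:
    """Read an enzyme-substrate reaction table from CSV/TSV.

    Duplicate ``(enzyme, substrate)`` rows collapse to a single reaction;
    row order never affects the result.  ``sep=None`` sniffs comma vs tab.
    """
    import csv as _csv

    try:
        df = pd.read_csv(path, sep=sep, engine="python", dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise EmptyInputError(f"empty reaction table: {path}") from exc
    except _csv.Error:
        # the sniffer cannot tell comma from tab on trivial content;
        # fall back to comma, mapping an empty file to the empty-input error
        try:
            df = pd.read_csv(path, sep=",", dtype=str)
        except pd.errors.EmptyDataError as exc:
            raise EmptyInputError(f"empty reaction table: {path}") from exc
    if df.empty and df.columns.empty:
        raise EmptyInputError(f"empty reaction table: {path}")
    for col in (enzyme_col, substrate_col):
        if col not in df.columns:
            raise FormatError(
                f"reaction table {path} is missing required column {col!r} "
                f"(found {list(df.columns)})"
            )
    pairs: list[tuple[str, str]] = []
    provenance: dict[tuple[str, str], str] = {}
    has_source = source_col is not None and source_col in df.columns
    for _, row in df.iterrows():
        key = (str(row[enzyme_col]), str(row[substrate_col]))
        pairs.append(key)
        if has_source and pd.notna(row[source_col]):
            provenance[key] = str(row[source_col])
    return ReactionSet.from_pairs(pairs, provenance)


def write_reaction_table(rs: ReactionSet, path) -> None:
    """Write a ReactionSet as CSV (columns enzyme_id, substrate_id, source)."""
    rows = sorted(rs.reactions)
    df = pd.DataFrame(rows, columns=["enzyme_id", "substrate_id"])
    df["source"] = [rs.provenance.get(r, "") for r in rows]
    df.to_csv(path, index=False)


def merge_reaction_sets(a: ReactionSet, b: ReactionSet) -> ReactionSet:
    """Union of two reaction sets; redundant reactions collapse.

    Identifiers must already share a namespace — no mapping is attempted.
    Provenance from ``a`` wins on conflicts.
    """
    provenance = dict(b.provenance)
    provenance.update(a.provenance)
    return ReactionSet(a.reactions | b.reactions, provenance)


def read_descriptor_table(path, name_col: str | None = None) -> DescriptorMatrix:
    """Read a PaDEL-style descriptor CSV (first column = molecule name).

    Empty cells and non-numeric tokens become missing values; column order
    is preserved.
    """
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise EmptyInputError(f"empty descriptor table: {path}") from exc
    if name_col is None:
        name_col = df.columns[0]
    elif name_col not in df.columns:
        raise FormatError(f"descriptor table {path} has no column {name_col!r}")
    if df.shape[1] < 2:
        raise FormatError(f"descriptor table {path} has zero descriptor columns")
    names = df[name_col].astype(str)
    if names.duplicated().any():
        dups = sorted(names[names.duplicated()].unique())
        raise FormatError(f"duplicate molecule names in {path}: {dups}")
    body = df.drop(columns=[name_col]).apply(pd.to_numeric, errors="coerce")
    body.index = pd.Index(names, name="Name")
    return DescriptorMatrix(body)


def write_descriptor_table(dm: DescriptorMatrix, path) -> None:
    """Write a DescriptorMatrix in the PaDEL CSV dialect (Name first column)."""
    out = dm.data.copy()
    out.index.name = "Name"
    out.to_csv(path)


def read_smiles_file(path) -> dict[str, str]:
    """Read a SMILES list: one molecule per line, optional tab-separated id.

    Returns an ordered mapping id -> SMILES; lines without an explicit id
    get the SMILES string itself as id.
    """
    out: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            smiles = parts[0].strip()
            ident = parts[1].strip() if len(parts) > 1 else smiles
            out[ident] = smiles
    if not out:
        raise EmptyInputError(f"no SMILES found in {path}")
    return out


def compute_descriptors(
    smiles_list: Sequence[str],
    ids: Sequence[str] | None = None,
) -> tuple[DescriptorMatrix, dict[str, str]]:
    """Compute the RDKit 1-D/2-D descriptor set for a list of SMILES.

    The descriptor set is whatever the installed RDKit exposes through
    ``Descriptors.CalcMolDescriptors`` (about 210 physico-chemical and
    topological descriptors); identical SMILES give identical rows.

    Returns
    -------
    (matrix, failures)
        ``failures`` maps the id of every unparsable SMILES to an error
        message.  Raises :class:`EmptyInputError` when nothing parses.
    """
    from rdkit import Chem
    from rdkit.Chem import Descriptors
    from rdkit import RDLogger

    RDLogger.DisableLog("rdApp.error")
    if ids is None:
        # default ids are the SMILES themselves; repeats get a #k suffix so
        # every input molecule keeps its own row
        seen: dict[str, int] = {}
        ids = []
        for smi in smiles_list:
            k = seen.get(smi, 0)
            seen[smi] = k + 1
            ids.append(smi if k == 0 else f"{smi}#{k}")
    if len(ids) != len(smiles_list):
        raise FormatError("ids and smiles_list must have equal length")
    rows: dict[str, dict[str, float]] = {}
    failures: dict[str, str] = {}
    for ident, smi in zip(ids, smiles_list):
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            failures[ident] = f"unparsable SMILES: {smi!r}"
            continue
        rows[ident] = Descriptors.CalcMolDescriptors(mol)
    if not rows:
        raise EmptyInputError("no valid SMILES in input")
    if failures:
        logger.warning("%d of %d SMILES failed to parse", len(failures), len(smiles_list))
    df = pd.DataFrame.from_dict(rows, orient="index").astype(float)
    return DescriptorMatrix(df), failures
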