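"""Small-molecule parsing and the annotated-graph container.

Molecules are held as hydrogen-suppressed RDKit graphs wrapped in a light
:class:`Molecule` record that remembers where each structure came from
(file, line/record index, raw SMILES).  All downstream descriptor and
pharmacophore code works on this container.

Parsing policy: standard organic-subset SMILES with lowercase aromatic
notation; kekulization failures are hard errors.  SDF input is restricted
to V2000 connection tables.  Multi-fragment records (salts) are reduced to
the largest connected fragment with a warning, because the topological
descriptors downstream are defined on connected graphs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

from rdkit import Chem
from rdkit import RDLogger

logger = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.*")  # rdkit reports errors via None returns; we raise

#: Elements accepted by the reader.  Anything else is a parse-time error,
#: never a silent drop.
SUPPORTED_ELEMENTS = frozenset(
    {"H", "B", "C", "N", "O", "F", "Si", "P", "S", "Cl", "Br", "I"}
)


class MoleculeParseError(ValueError):
    """Raised when a structure record cannot be turned into a valid graph."""


@dataclass(frozen=True)
class Atom:
    """One heavy atom of the hydrogen-suppressed graph."""

    symbol: str
    formal_charge: int
    aromatic: bool
    n_hydrogens: int


@dataclass(frozen=True)
class Bond:
    i: int
    j: int
    order: float  # 1, 2, 3, or 1.5 for aromatic


@dataclass
class Molecule:
    """A parsed small molecule.

    ``rdmol`` is the hydrogen-suppressed RDKit graph (implicit hydrogens
    resolved); ``atoms``/``bonds`` expose it as plain records for code that
    wants the bare graph.
    """

    id: str
    rdmol: Chem.Mol
    source: str = ""
    record_index: int = 0

    @property
    def atoms(self) -> list[Atom]:
        return [
            Atom(
                symbol=a.GetSymbol(),
                formal_charge=a.GetFormalCharge(),
                aromatic=a.GetIsAromatic(),
                n_hydrogens=a.GetTotalNumHs(),
            )
            for a in self.rdmol.GetAtoms()
        ]

    @property
    def bonds(self) -> list[Bond]:
        out = []
        for b in self.rdmol.GetBonds():
            order = 1.5 if b.GetIsAromatic() else b.GetBondTypeAsDouble()
            out.append(Bond(b.GetBeginAtomIdx(), b.GetEndAtomIdx(), order))
        return out

    def to_smiles(self) -> str:
        return Chem.MolToSmiles(self.rdmol)

    def __repr__(self) -> str:  # keep test failure output readable
        return f"Molecule({self.id!r}, {self.to_smiles()!r})"


def _check_elements(rdmol: Chem.Mol, context: str) -> None:
    bad = sorted(
        {a.GetSymbol() for a in rdmol.GetAtoms() if a.GetSymbol() not in SUPPORTED_ELEMENTS}
    )
    if bad:
        raise MoleculeParseError(f"{context}: unsupported element(s) {', '.join(bad)}")


def _largest_fragment(rdmol: Chem.Mol, context: str) -> Chem.Mol:
    frags = Chem.GetMolFrags(rdmol, asMols=True, sanitizeFrags=False)
    if len(frags) > 1:
        logger.warning("%s: multi-fragment record, keeping largest fragment", context)
        warnings.warn(f"{context}: keeping largest of {len(frags)} fragments")
        rdmol = max(frags, key=lambda m: m.GetNumAtoms())
    return rdmol


def mol_from_smiles(smiles: str, mol_id: str = "", record_index: int = 0) -> Molecule:
    """Parse one SMILES string into a :class:`Molecule`.

    Raises :class:`MoleculeParseError` on syntax, valence, kekulization or
    unsupported-element problems.
    """
    context = f"record {record_index} ({mol_id or smiles})"
    rdmol = Chem.MolFromSmiles(smiles, sanitize=True)
    if rdmol is None:
        raise MoleculeParseError(f"{context}: unparsable SMILES {smiles!r}")
    _check_elements(rdmol, context)
    rdmol = _largest_fragment(rdmol, context)
    Chem.SanitizeMol(rdmol)
    return Molecule(id=mol_id or smiles, rdmol=rdmol, source=smiles, record_index=record_index)


def _iter_smiles_file(path: Path) -> Iterator[tuple[int, str, str]]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            parts = stripped.split(None, 1)
            smiles = parts[0]
            name = parts[1].strip() if len(parts) > 1 else ""
            yield lineno, smiles, name


def read_molecules(path: str | Path, fmt: str | None = None) -> list[Molecule]:
    """Read a SMILES (.smi) or SDF (V2000) file into a list of molecules.

    ``fmt`` is ``"smiles"`` or ``"sdf"``; inferred from the suffix when
    omitted.  Order follows the file; an unparsable record raises an error
    naming its line/record number; an empty file returns an empty list with
    a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = {"smi": "smiles", "smiles": "smiles", "sdf": "sdf"}.get(
            path.suffix.lstrip(".").lower(), ""
        )
    if fmt not in ("smiles", "sdf"):
        raise ValueError(f"unsupported format {fmt!r} for {path}")

    molecules: list[Molecule] = []
    if fmt == "smiles":
        for lineno, smiles, name in _iter_smiles_file(path):
            try:
                mol = mol_from_smiles(smiles, mol_id=name or f"mol{lineno}", record_index=lineno)
            except MoleculeParseError as exc:
                raise MoleculeParseError(f"{path} line {lineno}: {exc}") from exc
            molecules.append(mol)
    else:
        supplier = Chem.SDMolSupplier(str(path), sanitize=True, removeHs=True)
        for idx, rdmol in enumerate(supplier, start=1):
            if rdmol is None:
                raise MoleculeParseError(f"{path} record {idx}: unparsable SDF record")
            context = f"{path} record {idx}"
            _check_elements(rdmol, context)
            rdmol = _largest_fragment(rdmol, context)
            name = rdmol.GetProp("_Name") if rdmol.HasProp("_Name") else ""
            molecules.append(
                Molecule(
                    id=name.strip() or f"mol{idx}",
                    rdmol=rdmol,
                    source=f"{path.name}#{idx}",
                    record_index=idx,
                )
            )
    if not molecules:
        warnings.warn(f"{path}: no molecule records found")
    return molecules


def heavy_atom_count(mol: Molecule) -> int:
    """Number of non-hydrogen atoms (the HA of ligand-efficiency metrics)."""
    return mol.rdmol.GetNumHeavyAtoms()
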