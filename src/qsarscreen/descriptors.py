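"""2D molecular descriptors for the pIC50 regression and drug-likeness filters.

The regression uses five descriptors — molar polarizability, clogP, TPSA,
hydrogen-bond-acceptor count and the Balaban connectivity index J — and the
filters additionally need HBD, heavy-atom count and molecular weight.

Provenance of each scheme:

* TPSA: Ertl fragment contributions (N/O-centred polar fragments), via RDKit.
* clogP: Wildman-Crippen atomic contributions, via RDKit.
* molar polarizability: element-additive table shipped with the package
  (``data/polarizability.yaml``), summed over all atoms including hydrogens.
* Balaban J: the classic distance-sum form on the hydrogen-suppressed graph
  with unit bond lengths, J = M/(mu+1) * sum over bonds (s_i * s_j)^(-1/2),
  implemented here (no bond-order weighting).
* HBA: Lipinski-style N+O count excluding positively charged atoms;
  HBD: N/O atoms bearing at least one hydrogen, each counted once.

The original study retrieved descriptors from proprietary web tools whose
algorithms are unpublished, so every pipeline stage that consumes a
:class:`DescriptorVector` also accepts externally supplied values that
override the computed ones (see :func:`descriptor_vector`'s ``overrides``).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, fields
from importlib import resources

import yaml
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, rdmolops

from .molecules import Molecule

logger = logging.getLogger(__name__)


class DescriptorError(ValueError):
    """Raised when a descriptor is undefined for the given graph."""


def _load_polarizability_table() -> dict[str, float]:
    text = resources.files("qsarscreen.data").joinpath("polarizability.yaml").read_text()
    return {str(k): float(v) for k, v in yaml.safe_load(text).items()}


POLARIZABILITY_TABLE: dict[str, float] = _load_polarizability_table()

#: Names of the five regression descriptors, in model order.
MODEL_DESCRIPTORS = ("mol_polarizability", "logp", "tpsa", "hba", "balaban_j")


@dataclass(frozen=True)
class DescriptorVector:
    """Complete descriptor record for one molecule.

    Units: ``mol_polarizability`` A^3, ``tpsa`` A^2, ``mw`` g/mol; the rest
    are unitless or counts.
    """

    id: str
    mol_polarizability: float
    logp: float
    tpsa: float
    hba: int
    balaban_j: float
    ha: int
    hbd: int
    mw: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def model_values(self) -> tuple[float, ...]:
        """The five regression descriptors in model order."""
        return tuple(getattr(self, name) for name in MODEL_DESCRIPTORS)


def balaban_index(mol: Molecule) -> float:
    """Balaban connectivity index J of the hydrogen-suppressed graph.

    J = M/(mu+1) * sum over bonds (i,j) of (s_i s_j)^(-1/2), where M is the
    number of heavy-atom bonds, mu = M - N + 1 the cyclomatic number and
    s_i the sum of topological distances from atom i to every heavy atom
    (all bonds counted as length 1).  Undefined for single-atom or
    disconnected graphs.
    """
    rdmol = mol.rdmol
    n = rdmol.GetNumHeavyAtoms()
    if n < 2:
        raise DescriptorError(f"{mol.id}: Balaban J undefined for < 2 heavy atoms")
    if len(Chem.GetMolFrags(rdmol)) > 1:
        raise DescriptorError(f"{mol.id}: Balaban J undefined for disconnected graphs")
    dist = rdmolops.GetDistanceMatrix(rdmol)  # topological, unit bond lengths
    s = dist.sum(axis=1)
    m = rdmol.GetNumBonds()
    mu = m - n + 1
    total = 0.0
    for bond in rdmol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        total += 1.0 / math.sqrt(s[i] * s[j])
    return m / (mu + 1) * total


def tpsa(mol: Molecule) -> float:
    """Topological polar surface area (Ertl fragment contributions), A^2."""
    return Descriptors.TPSA(mol.rdmol)


def clogp(mol: Molecule) -> float:
    """Calculated octanol-water logP (Wildman-Crippen atomic contributions)."""
    return Crippen.MolLogP(mol.rdmol)


def hba_count(mol: Molecule) -> int:
    """Hydrogen-bond acceptors: N and O atoms without positive formal charge."""
    return sum(
        1
        for a in mol.rdmol.GetAtoms()
        if a.GetSymbol() in ("N", "O") and a.GetFormalCharge() <= 0
    )


def hbd_count(mol: Molecule) -> int:
    """Hydrogen-bond donors: N/O atoms bearing >= 1 H, each counted once."""
    return sum(
        1
        for a in mol.rdmol.GetAtoms()
        if a.GetSymbol() in ("N", "O") and a.GetTotalNumHs() >= 1
    )


def molar_polarizability(mol: Molecule) -> float:
    """Element-additive molecular polarizability (A^3), hydrogens included."""
    total = 0.0
    for atom in mol.rdmol.GetAtoms():
        symbol = atom.GetSymbol()
        if symbol not in POLARIZABILITY_TABLE:
            raise DescriptorError(f"{mol.id}: no polarizability entry for element {symbol}")
        total += POLARIZABILITY_TABLE[symbol]
        total += atom.GetTotalNumHs() * POLARIZABILITY_TABLE["H"]
    return total


def molecular_weight(mol: Molecule) -> float:
    return Descriptors.MolWt(mol.rdmol)


def descriptor_vector(mol: Molecule, overrides: dict[str, float] | None = None) -> DescriptorVector:
    """Assemble the full descriptor vector for one molecule.

    ``overrides`` replaces any computed field by an externally supplied
    value (e.g. a printed clogP), preserving exact reproduction of published
    numbers where they exist.
    """
    try:
        values = {
            "mol_polarizability": molar_polarizability(mol),
            "logp": clogp(mol),
            "tpsa": tpsa(mol),
            "hba": hba_count(mol),
            "balaban_j": balaban_index(mol),
            "ha": mol.rdmol.GetNumHeavyAtoms(),
            "hbd": hbd_count(mol),
            "mw": molecular_weight(mol),
        }
    except DescriptorError as exc:
        raise DescriptorError(f"descriptor failure for compound {mol.id}: {exc}") from exc
    if overrides:
        unknown = set(overrides) - set(values)
        if unknown:
            raise ValueError(f"unknown descriptor override(s): {sorted(unknown)}")
        values.update(overrides)
    for name, value in values.items():
        logger.debug("%s %s = %s", mol.id, name, value)
    return DescriptorVector(id=mol.id, **values)


#: Fixed column order of the descriptor CSV interface.
CSV_COLUMNS = ("id", "mol_polarizability", "logp", "tpsa", "hba", "hbd", "balaban_j", "ha", "mw")


def descriptors_to_csv(vectors: list[DescriptorVector], path, round_2dp: bool = False) -> None:
    """Write descriptor vectors as CSV in the fixed column order."""
    import pandas as pd

    rows = []
    for v in vectors:
        d = v.as_dict()
        if round_2dp:
            d = {k: (round(x, 2) if isinstance(x, float) else x) for k, x in d.items()}
        rows.append({"id": v.id, **{c: d[c] for c in CSV_COLUMNS if c != "id"}})
    pd.DataFrame(rows, columns=list(CSV_COLUMNS)).to_csv(path, index=False)
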