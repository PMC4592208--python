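"""2D topological pharmacophore surrogate.

A ligand-based pharmacophore is the arrangement of chemical features —
hydrogen-bond donors/acceptors, aromatic rings, hydrophobic regions,
ionizable groups — shared by known actives.  Full 3D pharmacophore engines
align features in space; this module implements a deliberately 2D
surrogate that preserves the pipeline role (build a shared-feature model
from training actives, score and rank a library, threshold into hits):

* feature perception is rule-based on the molecular graph (HBD/HBA by
  atom environment, aromatic rings from ring perception, hydrophobic
  patches as maximal carbon-only connected subgraphs of >= 3 atoms with no
  charged neighbour, ionizable groups by versioned SMARTS patterns in
  ``data/pharmacophore_features.yaml``);
* the merged model keeps, per feature kind, the largest count present in
  at least a consensus fraction ``f`` of the training actives (f = 1 is
  the per-kind minimum, i.e. the strict intersection);
* query fit of a library molecule is the fraction of required feature
  counts it satisfies, in [0, 1].
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from importlib import resources

import yaml
from rdkit import Chem

from .molecules import Molecule

FEATURE_KINDS = (
    "HBD",
    "HBA",
    "aromatic_ring",
    "hydrophobic",
    "pos_ionizable",
    "neg_ionizable",
)


@dataclass(frozen=True)
class PharmacophoreFeature:
    kind: str
    atom_indices: frozenset[int]


def _load_smarts_patterns() -> dict[str, list[Chem.Mol]]:
    text = resources.files("qsarscreen.data").joinpath("pharmacophore_features.yaml").read_text()
    raw = yaml.safe_load(text)
    patterns: dict[str, list[Chem.Mol]] = {}
    for kind, smarts_list in raw.items():
        patterns[kind] = []
        for smarts in smarts_list:
            patt = Chem.MolFromSmarts(smarts)
            if patt is None:
                raise ValueError(f"invalid SMARTS for {kind}: {smarts!r}")
            patterns[kind].append(patt)
    return patterns


_SMARTS_PATTERNS = _load_smarts_patterns()


def _hydrophobic_patches(rdmol: Chem.Mol) -> list[frozenset[int]]:
    """Maximal connected carbon-only subgraphs of >= 3 atoms, excluding
    carbons adjacent to formally charged atoms."""
    eligible = set()
    for atom in rdmol.GetAtoms():
        if atom.GetSymbol() != "C" or atom.GetFormalCharge() != 0:
            continue
        if any(nb.GetFormalCharge() != 0 for nb in atom.GetNeighbors()):
            continue
        eligible.add(atom.GetIdx())
    patches = []
    seen: set[int] = set()
    for start in sorted(eligible):
        if start in seen:
            continue
        component = {start}
        stack = [start]
        while stack:
            idx = stack.pop()
            for nb in rdmol.GetAtomWithIdx(idx).GetNeighbors():
                j = nb.GetIdx()
                if j in eligible and j not in component:
                    component.add(j)
                    stack.append(j)
        seen |= component
        if len(component) >= 3:
            patches.append(frozenset(component))
    return patches


def perceive_features(mol: Molecule) -> list[PharmacophoreFeature]:
    """Perceive all pharmacophore features of one molecule."""
    rdmol = mol.rdmol
    features: list[PharmacophoreFeature] = []

    for atom in rdmol.GetAtoms():
        if atom.GetSymbol() not in ("N", "O"):
            continue
        idx = frozenset({atom.GetIdx()})
        if atom.GetTotalNumHs() >= 1:
            features.append(PharmacophoreFeature("HBD", idx))
        if atom.GetFormalCharge() <= 0:
            features.append(PharmacophoreFeature("HBA", idx))

    for ring in rdmol.GetRingInfo().AtomRings():
        if all(rdmol.GetAtomWithIdx(i).GetIsAromatic() for i in ring):
            features.append(PharmacophoreFeature("aromatic_ring", frozenset(ring)))

    for patch in _hydrophobic_patches(rdmol):
        features.append(PharmacophoreFeature("hydrophobic", patch))

    for kind, patterns in _SMARTS_PATTERNS.items():
        matched: set[frozenset[int]] = set()
        for patt in patterns:
            for match in rdmol.GetSubstructMatches(patt):
                matched.add(frozenset(match))
        # collapse overlapping matches of the same group (e.g. acid + its anion)
        kept: list[frozenset[int]] = []
        for m in sorted(matched, key=lambda s: (-len(s), sorted(s))):
            if not any(m & k for k in kept):
                kept.append(m)
        for m in sorted(kept, key=sorted):
            features.append(PharmacophoreFeature(kind, m))

    return features


def feature_counts(mol: Molecule) -> Counter:
    return Counter(f.kind for f in perceive_features(mol))


@dataclass(frozen=True)
class PharmacophoreModel:
    """Shared-feature model: required count per feature kind."""

    required: dict[str, int]
    consensus_fraction: float
    provenance: tuple[str, ...] = field(default_factory=tuple)

    @property
    def total_required(self) -> int:
        return sum(self.required.values())


def merge_feature_model(training: list[Molecule], f: float = 1.0) -> PharmacophoreModel:
    """Merge the features of training actives into a consensus model.

    For each kind the required count is the largest c such that at least a
    fraction ``f`` of training molecules carry >= c features of that kind
    (f = 1 reduces to the per-kind minimum).  An all-zero consensus is an
    error — lower f or revisit the training set.
    """
    if len(training) < 2:
        raise ValueError("need >= 2 training molecules to merge")
    if not 0 < f <= 1:
        raise ValueError(f"consensus fraction must be in (0, 1], got {f}")
    counts = [feature_counts(m) for m in training]
    needed = -(-f * len(training) // 1)  # ceil(f * n)
    needed = int(needed)
    required: dict[str, int] = {}
    for kind in FEATURE_KINDS:
        per_mol = sorted((c.get(kind, 0) for c in counts), reverse=True)
        # largest c with at least `needed` molecules having count >= c
        req = per_mol[needed - 1] if needed <= len(per_mol) else 0
        if req > 0:
            required[kind] = req
    if not required:
        raise ValueError("empty consensus (all feature counts 0); lower the consensus fraction f")
    return PharmacophoreModel(
        required=required,
        consensus_fraction=f,
        provenance=tuple(m.id for m in training),
    )


def query_fit(model: PharmacophoreModel, mol: Molecule) -> float:
    """Fraction of the model's required feature counts met by a molecule.

    score = sum_k min(count_k, required_k) / sum_k required_k, in [0, 1];
    1 exactly when every requirement is met.
    """
    counts = feature_counts(mol)
    total = model.total_required
    if total == 0:
        raise ValueError("model requires no features")
    met = sum(min(counts.get(kind, 0), req) for kind, req in model.required.items())
    return met / total


def screen_library(
    model: PharmacophoreModel,
    library: list[Molecule],
    min_fit: float = 0.0,
) -> list[tuple[str, float]]:
    """Score a library against the model and return (id, query_fit) pairs
    sorted by descending fit (ties keep input order), dropping entries
    below ``min_fit``."""
    if not library:
        raise ValueError("library is empty")
    scored = [(mol.id, query_fit(model, mol)) for mol in library]
    retained = [(cid, s) for cid, s in scored if s >= min_fit]
    retained.sort(key=lambda t: -t[1])  # stable: ties keep input order
    return retained


def save_pharmacophore(model: PharmacophoreModel, path) -> None:
    lines = [f"consensus_fraction\t{model.consensus_fraction!r}"]
    lines += [f"require\t{kind}\t{count}" for kind, count in sorted(model.required.items())]
    lines.append("provenance\t" + ",".join(model.provenance))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def load_pharmacophore(path) -> PharmacophoreModel:
    required: dict[str, int] = {}
    f = 1.0
    provenance: tuple[str, ...] = ()
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if parts[0] == "consensus_fraction":
                f = float(parts[1])
            elif parts[0] == "require":
                required[parts[1]] = int(parts[2])
            elif parts[0] == "provenance":
                provenance = tuple(p for p in parts[1].split(",") if p)
    return PharmacophoreModel(required=required, consensus_fraction=f, provenance=provenance)
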