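"""Synthetic compound libraries and activities for pipeline testing.

Real HDAC-inhibitor screening data cannot be redistributed here, so every
stage of the pipeline is exercised on generated data with the same
statistical structure: molecules assembled from a cap-linker-zinc-binding
fragment grammar (the canonical architecture of this inhibitor class), and
activities drawn from the linear five-descriptor pIC50 model with Gaussian
noise, then thresholded into actives (IC50 < 2500 nM) and decoys.

Defaults mirror the study conditions: the true coefficients are the
published model's, the noise standard deviation is its reported standard
error of estimate (0.24 pIC50 units), and the active/decoy threshold is
2500 nM.  All generators are pure functions of their configuration; the
RNG is NumPy's PCG64 (``numpy.random.default_rng``), so a given seed gives
bit-identical output across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import descriptors as desc
from . import qsar
from .molecules import Molecule, mol_from_smiles


def _load_fragments() -> dict[str, list[str]]:
    text = resources.files("qsarscreen.data").joinpath("fragments.yaml").read_text()
    return {k: list(v) for k, v in yaml.safe_load(text).items()}


FRAGMENTS: dict[str, list[str]] = _load_fragments()


@dataclass(frozen=True)
class SimulationConfig:
    """Configuration of one synthetic dataset."""

    n_compounds: int = 100
    seed: int = 0
    intercept: float = 14.48
    coefficients: dict[str, float] = field(
        default_factory=lambda: dict(qsar.published_model().coefficients)
    )
    noise_sd: float = 0.24  # pIC50 units, the published model's SEE
    active_threshold_nM: float = qsar.ACTIVE_THRESHOLD_NM
    fragment_set: str = "default"

    def __post_init__(self):
        if self.n_compounds < 1:
            raise ValueError("n_compounds must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def model(self) -> qsar.QSARModel:
        return qsar.QSARModel(intercept=self.intercept, coefficients=dict(self.coefficients))


def generate_library(cfg: SimulationConfig) -> list[Molecule]:
    """Assemble ``n_compounds`` molecules by seeded uniform choice of one
    cap, one linker and one zinc-binding fragment each."""
    rng = np.random.default_rng(cfg.seed)
    caps, linkers, zbgs = FRAGMENTS["cap"], FRAGMENTS["linker"], FRAGMENTS["zbg"]
    molecules = []
    width = len(str(cfg.n_compounds))
    for k in range(cfg.n_compounds):
        smiles = (
            caps[int(rng.integers(len(caps)))]
            + linkers[int(rng.integers(len(linkers)))]
            + zbgs[int(rng.integers(len(zbgs)))]
        )
        molecules.append(mol_from_smiles(smiles, mol_id=f"S{k + 1:0{width}d}", record_index=k + 1))
    return molecules


def simulate_activities(library: list[Molecule], cfg: SimulationConfig) -> pd.DataFrame:
    """Draw activities for a library from the configured linear model.

    pIC50 = model(computed descriptors) + Normal(0, noise_sd); IC50/nM =
    10^(9 - pIC50).  Compounds whose descriptors fail are skipped with a
    warning.  Columns: compound_id, smiles, pic50, ic50_nM, label.
    """
    rng = np.random.default_rng([cfg.seed, 1])
    model = cfg.model()
    rows = []
    for mol in library:
        try:
            vec = desc.descriptor_vector(mol)
        except desc.DescriptorError as exc:
            import warnings

            warnings.warn(f"skipping {mol.id}: {exc}")
            continue
        pic50 = qsar.predict_pic50(model, vec) + rng.normal(0.0, cfg.noise_sd)
        rows.append(
            {
                "compound_id": mol.id,
                "smiles": mol.to_smiles(),
                "pic50": pic50,
                "ic50_nM": qsar.ic50_nM_from_pic50(pic50),
                "label": "active" if qsar.ic50_nM_from_pic50(pic50) < cfg.active_threshold_nM else "decoy",
            }
        )
    return pd.DataFrame(rows)


def descriptor_table(library: list[Molecule]) -> pd.DataFrame:
    """Computed five-descriptor design matrix for a library (model order),
    indexed by compound id."""
    rows = {}
    for mol in library:
        vec = desc.descriptor_vector(mol)
        rows[mol.id] = {name: getattr(vec, name) for name in desc.MODEL_DESCRIPTORS}
    return pd.DataFrame.from_dict(rows, orient="index")


def generate_screen_scenario(
    A: int,
    n_decoys: int,
    planted_sensitivity: float,
    seed: int,
    n_decoy_hits: int | None = None,
) -> tuple[dict[str, str], set[str]]:
    """Construct a labelled dataset and a hit set with known counts.

    Exactly ``round(planted_sensitivity * A)`` actives are placed in the
    hit set (seeded choice), plus ``n_decoy_hits`` decoys (a seeded
    binomial draw at rate 0.2 when not given), so the expected screen
    metrics follow in closed form from the counts.
    """
    if not 0 <= planted_sensitivity <= 1:
        raise ValueError("planted_sensitivity must be in [0, 1]")
    rng = np.random.default_rng(seed)
    labels = {f"A{i + 1}": "active" for i in range(A)}
    labels.update({f"D{i + 1}": "decoy" for i in range(n_decoys)})
    n_active_hits = round(planted_sensitivity * A)
    if n_decoy_hits is None:
        n_decoy_hits = int(rng.binomial(n_decoys, 0.2))
    if n_decoy_hits > n_decoys:
        raise ValueError("n_decoy_hits exceeds n_decoys")
    active_ids = [f"A{i + 1}" for i in range(A)]
    decoy_ids = [f"D{i + 1}" for i in range(n_decoys)]
    hits = set(rng.choice(active_ids, size=n_active_hits, replace=False)) if n_active_hits else set()
    if n_decoy_hits:
        hits |= set(rng.choice(decoy_ids, size=n_decoy_hits, replace=False))
    return labels, hits


def write_library(library: list[Molecule], path: str | Path, cfg: SimulationConfig | None = None) -> None:
    """Write a library as a .smi file, echoing the config as header comments."""
    path = Path(path)
    with open(path, "w") as fh:
        if cfg is not None:
            fh.write(f"# generator: qsarscreen.synthetic (numpy PCG64)\n")
            fh.write(f"# n_compounds: {cfg.n_compounds}  seed: {cfg.seed}\n")
            fh.write(f"# noise_sd: {cfg.noise_sd}  active_threshold_nM: {cfg.active_threshold_nM}\n")
        for mol in library:
            fh.write(f"{mol.source} {mol.id}\n")
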