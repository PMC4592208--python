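# Methods

## Scope and model

The package implements a ligand-based (2D) QSAR screening pipeline for
class I HDAC inhibitors. The statistical core is an ordinary-least-squares
linear model of potency,

    pIC50 = β0 + β1·Polarizability + β2·logP + β3·TPSA + β4·HBA + β5·BalabanJ + ε,

with pIC50 = 9 − log10(IC50/nM) (molar convention: 1 nM ↔ 9.0). A frozen
literature parameterization is shipped (`qsar.published_model()`):
β = (14.48, −0.13, +0.06, +0.17, −2.54, −2.57), n = 10, R² = 0.93,
adjusted R² = 0.84, SEE = 0.24, overall-F p = 0.02. The positive TPSA
coefficient is chemically unusual for a potency model; it is retained
exactly as published, not reinterpreted. Structure-based stages of a full
discovery campaign (docking, molecular dynamics, 3D pharmacophore
alignment, ADMET web services) are out of scope by design.

## Descriptor conventions

* **Balaban J** uses unit bond lengths on the hydrogen-suppressed graph —
  the classic distance-sum definition, with no bond-order weighting
  (RDKit's built-in `BalabanJ` weights the distance matrix by bond order,
  so the index is implemented here directly). Undefined for single-atom or
  disconnected graphs; multi-fragment input records are reduced to their
  largest fragment at parse time with a warning.
* **TPSA** is Ertl's N/O fragment-contribution scheme and **clogP** the
  Wildman–Crippen atomic-contribution scheme, both via RDKit — these are
  the open, published contribution tables; tests verify them atom-by-atom
  against RDKit's per-atom contribution API as an independent sum oracle.
* **Molar polarizability** is an element-additive sum over all atoms
  including hydrogens, from the versioned table in
  `data/polarizability.yaml` (free-atom static polarizabilities, Å³). The
  tools used for the original model are proprietary and unpublished, so
  predictions with repo-computed polarizability can shift relative to the
  original; every consumer of a descriptor vector therefore accepts
  externally supplied values as overrides (`descriptor_vector(...,
  overrides=...)`), which is also how printed per-compound inputs are fed
  through the pipeline unchanged.
* **HBA** counts N and O atoms without positive formal charge (the common
  2D Lipinski convention — consequential here, at −2.54 pIC50 units per
  acceptor). **HBD** counts N/O atoms bearing ≥ 1 hydrogen, each heteroatom
  once regardless of hydrogen multiplicity.

Descriptors are kept at full precision internally; reports round to two
decimals.

## Activity handling

IC50 values are converted to pIC50 before averaging across isoforms
(HDAC1/2/3/8), i.e. the per-compound summary is the geometric mean on the
IC50 scale. The active/decoy split is at 2500 nM with the boundary value
assigned to the decoy class (the published rule leaves exactly 2500 nM
open; strict-active is the conservative choice). Descriptor selection
(forward, backward, stepwise) uses p-value thresholds 0.05 to enter and
0.10 to remove — standard statistical-package defaults — with ties broken
by column order for determinism.

## Efficiency metrics and rounding

LE = (1.37/HA)·pIC50, LEScale = 0.104 + 0.65·e^(−0.037·HA),
LipE = pIC50 − clogP, FQ = LE/LEScale. In the default *reproduction mode*,
FQ divides the two-decimal-rounded LE and LEScale and rounds the ratio —
the convention that reproduces tables computed from printed intermediates
(e.g. 0.44/0.36 = 1.22 where the unrounded ratio gives 1.21). A
full-precision mode is available by flag; the two differ by < 0.025 across
the shipped ten-hit table. The optimality flags are clogP < 3, LipE > 5
and |FQ − 1| ≤ 0.25 (the "close to 1" radius is a package choice, exposed
as a parameter). Rule-of-five passes require zero violations by default
(configurable) with boundary values passing (≤ convention).

The packaged ten-hit table carries two cells that contradict the defining
equations: C5's LEScale (printed 0.29 = 0.65·e^(−0.037·22) with the 0.104
offset dropped; the formula gives 0.39) and C1's FQ (printed 0.95; both
rounding conventions give 0.94). `check_published_consistency()` re-derives
every cell and reports exactly these mismatches; `efficiency_table`
accepts per-compound LEScale overrides so either reading can be
reproduced.

## Screen validation

With D compounds, A actives, Ht hits and Ha active hits: sensitivity
Ha/A, specificity TN/(D−A), %Y = 100·Ha/Ht, EF = (Ha/Ht)/(A/D), and
GH = [Ha(3A+Ht)/(4·Ht·A)]·[1 − (Ht−Ha)/(D−A)]. These are the standard
Güner–Henry forms; GH is 1 for a perfect screen and 0 when everything is
retrieved. Undefined ratios (no actives, no hits, no decoys) are explicit
`None` markers rather than NaN. "Retrieval of active compounds" is read as
sensitivity throughout.

## Pharmacophore surrogate

The original workflow used a proprietary 3D engine building pharmacophores
from docked poses. Since neither the engine nor model coordinates are
available, the package implements a deliberately 2D surrogate that keeps
the pipeline role (build from actives → score → threshold → validate):
feature perception is rule-based on the graph (HBD/HBA by atom
environment; aromatic rings from ring perception; hydrophobic patches as
maximal carbon-only connected subgraphs of ≥ 3 atoms with no charged
neighbour; ionizable groups via versioned SMARTS in
`data/pharmacophore_features.yaml`). The merged model requires, per
feature kind, the largest count present in at least a consensus fraction
*f* of training actives (f = 1 → per-kind minimum), and query fit is the
satisfied fraction of required counts, in [0, 1]. Published per-model
retrieval bars and hit counts from the 3D engine are consequently not
reproduction targets; the surrogate is validated by exact recovery of
planted actives in synthetic libraries.

## Synthetic data

The generator emulates what the analysis assumes about real data, not
real chemical space. Molecules are assembled by seeded uniform choice of
one capping, one linker and one zinc-binding fragment from curated
~10-per-slot SMILES lists (`data/fragments.yaml`) reflecting the
cap–linker–ZBG architecture of this inhibitor class (hydroxamate,
carboxylate, carboxamide, o-aminoanilide, sulfonamide, thiol warheads).
Activities are drawn as pIC50 = model(computed descriptors) + N(0, σ) with
σ = 0.24 by default (the published model's standard error of estimate) and
thresholded at 2500 nM. The RNG is NumPy's PCG64 (`default_rng`), so a
given seed yields bit-identical libraries across platforms. What passing
tests on this data do **not** show: robustness to assay noise structure,
activity cliffs, property-matched decoys, or descriptor error in real
compound collections — the generator's activities are, by construction,
linear in the very descriptors the model fits.

## Numerical choices and problem sizes

OLS goes through statsmodels; rank-deficient designs are rejected with the
offending columns named. Model serialization uses hexadecimal floats for
bit-exact round trips. Ranking ties (query fit; pipeline ranks) are broken
by input order; pipeline ranking is by predicted pIC50, then LipE, then
input order. Test problem sizes are desk-scale by design: exhaustive
screen-metric enumeration to D ≤ 30, pseudo-inverse cross-checks on 100
small random designs, parameter recovery at n = 200 and σ = 0.24, and a
100-seed distributional check that n = 10 refits land in the high-R²
regime observed for the published fit. The full suite runs in a few
seconds on one CPU.

## Known limitations

* Eq-level reproduction of published per-compound *predicted* pIC50 values
  requires the original (unpublished) descriptor values; with repo-computed
  descriptors the frozen coefficients extrapolate and can produce values
  far outside [0, 14] for polar molecules — the pipeline reports them as
  computed.
* The pharmacophore surrogate is topological; molecules with the right
  feature counts in the wrong geometry still score 1.
* clogP/TPSA/polarizability schemes here need not equal the proprietary
  tools' outputs; printed per-compound values, where they exist, are the
  authoritative inputs (supplied as overrides).
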