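# qsarscreen

2D QSAR virtual screening and ligand-efficiency lead prioritization for
class I histone-deacetylase (HDAC) inhibitor discovery.

HDAC1/2/3/8 are zinc-dependent epigenetic targets; their inhibitors share a
cap–linker–zinc-binding-group architecture (hydroxamates, benzamides,
sulfonamides, …). This package implements, as a tested and reusable
pipeline, the ligand-based workflow used to find and rank such inhibitors:

1. **Descriptors** — five 2D descriptors on the hydrogen-suppressed
   molecular graph: molar polarizability (element-additive, Å³),
   Wildman–Crippen clogP, Ertl TPSA (Å²), hydrogen-bond-acceptor count
   (Lipinski N+O convention), and the Balaban connectivity index
   *J* = *M*/(*μ*+1) · Σ<sub>bonds (i,j)</sub> (*s<sub>i</sub>s<sub>j</sub>*)<sup>−1/2</sup>.
2. **QSAR** — activities converted as pIC50 = 9 − log₁₀(IC50/nM), averaged
   per compound over isoforms, split at 2500 nM into actives and decoys,
   and fitted by ordinary least squares:
   pIC50 = β₀ + Σ β<sub>k</sub> x<sub>k</sub> + ε,
   with forward/backward/stepwise descriptor selection, ANOVA, external
   validation, and the frozen literature model
   `pIC50 = 14.48 − 0.13·Polarizability + 0.06·logP + 0.17·TPSA − 2.54·HBA − 2.57·BalabanJ`
   (n = 10, R² = 0.93, adj. R² = 0.84, SEE = 0.24).
3. **Pharmacophore surrogate** — 2D feature perception (HBD, HBA, aromatic
   ring, hydrophobic patch, ± ionizable), merged shared-feature models from
   training actives, and query-fit ranking of libraries.
4. **Screen validation** — sensitivity, specificity, percent yield of
   actives, enrichment factor EF = (Ha/Ht)/(A/D), and the Güner–Henry score
   GH = [Ha(3A+Ht)/(4·Ht·A)]·[1 − (Ht−Ha)/(D−A)].
5. **Efficiency prioritization** — LE = (1.37/HA)·pIC50,
   LEScale = 0.104 + 0.65·e^(−0.037·HA), LipE = pIC50 − clogP,
   FQ = LE/LEScale, with optimality flags (clogP < 3, LipE > 5, FQ ≈ 1) and
   the rule-of-five filter.
6. **Synthetic data** — seeded generation of cap–linker–ZBG libraries with
   activities drawn from the linear descriptor model plus Gaussian noise,
   so every stage is testable without proprietary compound collections.

## Worked example

Rank the ten prioritized hits (C1–C10, shipped with the package) by their
efficiency profile:

```python
from qsarscreen import efficiency as eff

rows = [(cid, *vals) for cid, vals in eff.PUBLISHED_HIT_INPUTS.items()]
table = eff.efficiency_frame(eff.efficiency_table(rows))
print(table[["id", "pic50", "ha", "clogp", "le", "le_scale", "lipe", "fq", "lipe_gt_5"]])
```

```
 id  pic50  ha  clogp   le  le_scale  lipe   fq  lipe_gt_5
 C1    6.2  25   2.94 0.34      0.36  3.26 0.94      False
 C2    8.1  25   0.81 0.44      0.36  7.29 1.22       True
 C3    8.0  19   0.27 0.58      0.43  7.73 1.35       True
 C4    5.2  27   1.49 0.26      0.34  3.71 0.76      False
 C5    6.0  22   4.11 0.37      0.39  1.89 0.95      False
 C6    8.0  19   3.38 0.58      0.43  4.62 1.35      False
 C7   12.5  26   2.23 0.66      0.35 10.27 1.89       True
 C8    8.0  25   1.70 0.44      0.36  6.30 1.22       True
 C9    6.4  25  -0.20 0.35      0.36  6.60 0.97       True
C10    7.2  23   2.50 0.43      0.38  4.70 1.13      False
```

C7 is the stand-out lead: highest ligand efficiency (0.66 pIC50 units per
heavy atom against a size-expectation of 0.35) and a lipophilic efficiency
of 10.27, well above the LipE > 5 optimality bar that exactly half the
hits clear. `eff.check_published_consistency()` re-derives every cell and
flags the two literature cells that disagree with the defining equations
(C5's LEScale and C1's FQ).

A command-line interface mirrors the library
(`qsarscreen descriptors|fit|predict|screen|validate|efficiency|simulate|pipeline`);
for example, a fully synthetic end-to-end run:

```sh
qsarscreen simulate --n 100 --seed 7 --library-out lib.smi --activity-out act.csv
qsarscreen descriptors lib.smi --out desc.csv
qsarscreen fit desc.csv act.csv --out model.txt
```

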