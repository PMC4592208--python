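# Substructure patterns for 2D pharmacophore feature perception. version: 1
# SMARTS-based kinds match whole functional groups; HBD/HBA/aromatic_ring/
# hydrophobic are perceived by atom/graph rules in code (see pharmacophore.py).
neg_ionizable:
  - "[CX3](=O)[OX2H1]"        # carboxylic acid
  - "[CX3](=O)[O-]"           # carboxylate
  - "[SX4](=O)(=O)[OX2H1,OX1-]"  # sulfonic acid / sulfonate
  - "[SX4](=O)(=O)[NX3;H1,H2]"   # acidic sulfonamide N-H
  - "[CX3](=O)[NX3][OX2H1]"   # hydroxamic acid (zinc-binding warhead)
pos_ionizable:
  - "[NX3;H2,H1,H0;+0;!$(NC=[O,S]);!$(NS(=O)=O);!$(N=*);!$([N]a);!a]"  # basic amine
  - "[NX3+,NX4+]"             # protonated / quaternary nitrogen
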