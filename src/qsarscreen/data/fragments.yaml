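# Fragment library for the synthetic compound generator. version: 1
# Molecules follow the canonical HDAC-inhibitor architecture: an aromatic
# capping group, a linker, and a zinc-binding group (hydroxamate,
# carboxylate, carboxamide, o-aminoanilide, sulfonamide, thiol).  The three
# slots use disjoint SMILES ring-closure digits (1/2, 4, 3) so plain
# string concatenation cap+linker+zbg is a valid SMILES.
cap:
  - "c1ccc(cc1)"        # phenyl
  - "Cc1ccc(cc1)"       # p-tolyl
  - "COc1ccc(cc1)"      # p-methoxyphenyl
  - "Fc1ccc(cc1)"       # p-fluorophenyl
  - "Clc1ccc(cc1)"      # p-chlorophenyl
  - "c1ccc(nc1)"        # pyridinyl
  - "c1csc(c1)"         # thiophenyl
  - "c1cc(oc1)"         # furanyl
  - "c1ccc2ccc(cc2c1)"  # naphthalenyl
  - "CN(C)c1ccc(cc1)"   # p-(dimethylamino)phenyl
linker:
  - "C"
  - "CC"
  - "CCC"
  - "CCCC"
  - "C=C"               # cinnamoyl-style vinylene
  - "OC"                # ether-methylene
  - "C(=O)NC"           # amide-methylene
  - "CNC(=O)"           # reversed amide
  - "c4ccc(cc4)"        # phenylene (biaryl)
  - "Cc4ccc(cc4)"       # methylene-phenylene
zbg:
  - "C(=O)NO"           # hydroxamic acid
  - "C(=O)O"            # carboxylic acid
  - "C(=O)N"            # primary carboxamide
  - "C(=O)Nc3ccccc3N"   # ortho-aminoanilide (benzamide class)
  - "S(=O)(=O)N"        # primary sulfonamide
  - "CS"                # methylene-thiol
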