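# Protein-binding alert library for the five mechanistic domains of skin
# sensitization. Each domain maps to SMARTS patterns for electrophilic
# substructures capable of haptenating skin proteins. The bit order of the
# 5-bit alert fingerprint follows the order of this file. Patterns are
# configuration, not code: edit or extend per domain as needed.
domains:
  - name: michael_addition
    smarts:
      - "[CX3]=[CX3][CX3]=[OX1]"            # alpha,beta-unsaturated ketone/aldehyde
      - "[CX3]=[CX3][CX3](=[OX1])[OX2]"     # acrylate ester / acrylic acid
      - "[CX3]=[CX3][CX2]#[NX1]"            # acrylonitrile
      - "[CX3]=[CX3][SX4](=[OX1])=[OX1]"    # vinyl sulfone
      - "[CX3]=[CX3][NX3+](=[OX1])[OX1-]"   # nitroalkene
  - name: sn2_reaction
    smarts:
      - "[CX4;H2,H3][Cl,Br,I]"              # primary/methyl alkyl halide
      - "[CX4][OX2][SX4](=[OX1])(=[OX1])"   # alkyl sulfonate ester
      - "[#6]1[#6][OX2]1"                   # epoxide
      - "[#6]1[#6][NX3]1"                   # aziridine
  - name: schiff_base_formation
    smarts:
      - "[CX3H1](=[OX1])[#6]"               # aldehyde
      - "[CX3H2]=[OX1]"                     # formaldehyde
      - "[CX3](=[OX1])[CX3](=[OX1])"        # 1,2-dicarbonyl
      - "[CX3](=[OX1])[CX4][CX3](=[OX1])"   # 1,3-dicarbonyl
  - name: acylation
    smarts:
      - "[CX3](=[OX1])[F,Cl,Br,I]"                  # acyl halide
      - "[CX3](=[OX1])[OX2][CX3](=[OX1])"           # carboxylic anhydride
      - "[NX2]=[CX2]=[OX1]"                         # isocyanate
      - "[NX2]=[CX2]=[SX1]"                         # isothiocyanate
      - "[SX4](=[OX1])(=[OX1])[F,Cl,Br,I]"          # sulfonyl halide
  - name: nucleophilic_addition
    smarts:
      - "[OX1]=[#6]1[#6]=[#6][#6](=[OX1])[#6]=[#6]1"   # para-quinone
      - "[OX1]=[#6]1[#6](=[OX1])[#6]=[#6][#6]=[#6]1"   # ortho-quinone
      - "[NX2]=[CX2]=[NX2]"                            # carbodiimide
      - "[#6][NX2]=[OX1]"                              # C-nitroso
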