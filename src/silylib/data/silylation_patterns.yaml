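# Silylation-amenable functional groups: SMARTS pattern table, version 1.
# A site is a heteroatom carrying an active hydrogen; each heteroatom counts
# once even when it bears two hydrogens (-NH2 is one site).
# `site_atom` is the index, within the SMARTS match, of the heteroatom that
# accepts the silyl group.
version: 1
patterns:
  - kind: carboxyl
    smarts: "[CX3](=O)[OX2H1]"
    site_atom: 2
  - kind: hydroxyl
    smarts: "[OX2H1][#6;!$([CX3]=O)]"
    site_atom: 0
  - kind: thiol
    smarts: "[SX2H1]"
    site_atom: 0
  - kind: amine
    # N-H not adjacent to a carboxamide carbonyl (urea/carbamoyl N-H, whose
    # carbonyl carbon bears no carbon substituent, still counts), not a
    # sulfonamide (separate pattern), not charged, not imine-type
    smarts: "[NX3;H1,H2;!$(N[CX3](=O)[#6]);!$(N[SX4](=O)(=O));!$(N=*);!$([N+])]"
    site_atom: 0
  - kind: sulfonamide_NH
    smarts: "[NX3;H1,H2][SX4](=O)(=O)"
    site_atom: 0
# optional patterns, disabled by default; enable via include_optional
optional_patterns:
  - kind: amide_NH
    smarts: "[NX3;H1,H2;$(N[CX3](=O)[#6])]"
    site_atom: 0
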