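# Physicochemical property truth table used by the Zvelebil-style conservation
# score: for each canonical residue, the truth value of the ten properties
# small, polar, hydrophobic, tiny, charged, negative, positive, aromatic,
# aliphatic, proline. Membership follows the Taylor Venn-diagram sets as adopted
# by the AMAS/Jalview conservation implementations. The table ships as data so
# the (rarely varying) membership choices are auditable and editable.
properties: [small, polar, hydrophobic, tiny, charged, negative, positive, aromatic, aliphatic, proline]
residues:
  A: [small, hydrophobic, tiny]
  R: [polar, charged, positive]
  N: [small, polar]
  D: [small, polar, charged, negative]
  C: [small, polar, hydrophobic]
  Q: [polar]
  E: [polar, charged, negative]
  G: [small, hydrophobic, tiny]
  H: [polar, hydrophobic, charged, positive, aromatic]
  I: [hydrophobic, aliphatic]
  L: [hydrophobic, aliphatic]
  K: [polar, hydrophobic, charged, positive]
  M: [hydrophobic]
  F: [hydrophobic, aromatic]
  P: [small, proline]
  S: [small, polar, tiny]
  T: [small, polar, hydrophobic]
  W: [polar, hydrophobic, aromatic]
  Y: [polar, hydrophobic, aromatic]
  V: [small, hydrophobic, aliphatic]
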