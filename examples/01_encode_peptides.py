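"""Encode peptides as composition vectors.

The g-gap dipeptide composition counts ordered residue pairs separated
by g intervening residues, so unlike the plain amino-acid composition it
retains part of the sequence order.
"""

from acpred import ALPHABET, Peptide, aac_composition, ggap_composition

magainin = Peptide("magainin-2", "GIGKFLHSAKKFGKAFVGEIMNS")

aac = aac_composition(magainin)
print(f"AAC of {magainin.id}: {aac.omega} components, "
      f"f(K) = {aac.values[ALPHABET.index('K')]:.3f}")

for g in range(3):
    v = ggap_composition(magainin, g)
    top = v.values.argsort()[::-1][:3]
    from acpred import DIPEPTIDE_NAMES
    names = ", ".join(f"{DIPEPTIDE_NAMES[u]}={v.values[u]:.3f}" for u in top)
    print(f"g={g}: {magainin.length - g - 1} counted pairs; most frequent: {names}")

# A permuted sequence keeps its AAC but changes its g-gap composition:
shuffled = Peptide("shuffled", magainin.sequence[::-1])
same_aac = (aac_composition(shuffled).values == aac.values).all()
same_ggap = (ggap_composition(shuffled, 1).values == ggap_composition(magainin, 1).values).all()
print(f"reversed sequence: AAC identical={same_aac}, 1-gap identical={same_ggap}")
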