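"""ORP/Osh-family sequence curation and lid-charge analysis.

Family membership is gated by the literal signature motif EQTSHHPP; the
PS-transporting subfamily additionally carries the lid pattern LPTFILE.
The lid of such transporters holds a D/E-rich motif whose negative charge
can be neutralized by alanine/glycine substitutions; the net-charge change
of each preset quantifies how much less anionic the mutant lid is.
"""

import lipswitch as lw
from lipswitch.motifs import MUTATION_PRESETS, PS_MOTIF, SIGNATURE_MOTIF

# a synthetic family: half the records carry the PS-recognizing lid motif
records, planted = lw.generate_sequences(
    20, motif=PS_MOTIF, plant_fraction=0.5, length=120, seed=5
)
retained, report = lw.filter_by_motifs(records, require=[PS_MOTIF])
print(f"{len(retained)} of {len(records)} sequences carry {PS_MOTIF} "
      f"({len(planted)} were planted)")
print(report["status"].value_counts().to_string())

# signature gating: a record without the family signature is rejected first
odd = lw.SequenceRecord("no_sig", "A" * 50)
_, rep = lw.filter_by_motifs([odd], require=[PS_MOTIF],
                             reject_if_missing=[SIGNATURE_MOTIF])
print(f"\n{odd.id}: {rep.loc[0, 'status']}")

# lid-charge presets on a synthetic carrier with the D/E-rich motif at 38-45
lid_seq = lw.SequenceRecord("lid", "A" * 37 + "DDADEDDE" + "A" * 23 + "L" + "A" * 51)
print(f"\nlid 36-69 net charge before mutation: "
      f"{lw.net_charge(lid_seq, residue_range=(36, 69))}")
for name in ("L69D", "4A", "5A2G"):
    mutated, delta = lw.apply_mutations(lid_seq, MUTATION_PRESETS[name])
    print(f"preset {name:5s}: delta charge = {delta:+d} "
          f"(lid now {lw.net_charge(mutated, residue_range=(36, 69))})")
# 4A neutralizes four acidic residues (+4); 5A2G neutralizes seven (+7);
# L69D instead adds an acidic residue to the lid (-1).
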