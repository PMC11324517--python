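"""Rigid superposition and helix displacement/reorientation.

Builds a synthetic orthologue pair: a small helical fold plus a copy in
which one helix (the TM1b stand-in) has been displaced by 1.9 Å and
reoriented by 3.1°, hidden behind a random global rigid motion.  The
analysis aligns the shared TM3/TM8 core with a Cα Kabsch fit (using the
packaged cross-species residue mapping) and then measures how far the
helix moved in the aligned frame.
"""

from bindsight import geometry, presets, synthetic

ref, target = synthetic.make_helix_shift_pair(
    displacement=1.9, reorientation=3.1, seed=0
)
mapping = presets.load_residue_mapping("hdat-hsert", ["TM3", "TM8"])
_, lo, hi = presets.load_helix_ranges()["TM1b"]

cmp = geometry.compare_helix(
    ref, target, mapping, ("A", (lo, hi)), ("A", (lo + 19, hi + 19))
)
print(f"alignment rmsd : {cmp.alignment_rmsd:.3f} A")
print(f"displacement   : {cmp.displacement:.2f} A")
print(f"reorientation  : {cmp.reorientation:.1f} deg")
# The displacement is the distance between helix Ca centroids after the
# core alignment; the planted 1.9 A / 3.1 deg are recovered exactly.

ref2, target2, mapping2 = synthetic.make_fold_pair(1.05, seed=1)
sup = geometry.superpose_structures(ref2, target2, mapping2)
print(f"fold pair rmsd : {sup.rmsd:.2f} A over {sup.n_pairs} Ca pairs")
# A whole-fold comparison with a planted 1.05 A Ca RMSD, the magnitude
# typical of closely related transporter structures.
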