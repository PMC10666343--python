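"""Positional information-entropy analysis of an anchored peptide set.

Positives carry a leucine anchor at position 9; that position's residue
distribution is concentrated, so its Shannon entropy PP drops well below
the other positions, while the negative set stays near the uniform maximum
log2(20) = 4.32 bits everywhere.  The per-residue profile AP shows the same
signal from the other margin: the anchor position contributes almost no
entropy to any residue (the anchor residue because its probability is near
1 there, the others because theirs is near 0), so every AP value in the
positive set sits below its negative-set counterpart.
"""

import numpy as np

import ncbind as nb

dataset = nb.generate(nb.SyntheticConfig(
    n_pos=1000, n_neg=1000, motif=((9, "L", 0.9),), seed=0))
positives = [r for r, y in zip(dataset.records, dataset.labels) if y == 1]
negatives = [r for r, y in zip(dataset.records, dataset.labels) if y == 0]

profiles = nb.entropy_report(positives, negatives, n_max=15)

print("positional entropy PP (bits), positions 1-15:")
for group in ("POS", "NEG"):
    pp = profiles[group].pp
    print(f"  {group}: " + " ".join(f"{v:5.2f}" for v in pp))
print(f"  uniform maximum log2(20) = {np.log2(20):.2f} bits")
print("the POS dip at position 9 is the anchor; "
      "NEG stays near the maximum everywhere.")

mean_pos = profiles["POS"].ap.mean()
mean_neg = profiles["NEG"].ap.mean()
print(f"\nmean per-residue entropy AP: POS {mean_pos:.2f} bits, "
      f"NEG {mean_neg:.2f} bits")
print("binders carry less entropy: the anchored position is nearly "
      "deterministic for every residue's distribution.")
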