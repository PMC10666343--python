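"""Encode a peptide with the three per-residue channels and print them.

The six-mer CEFSQC maps to an EIIP vector (physicochemical constants), an
INM vector (integer residue codes 1-20) and an AAAF vector (prefix
frequency of the residue at each position).  Stacked and zero-padded to 15
positions these form the 15 x 3 matrix the classifier consumes.
"""

import numpy as np

import ncbind as nb

peptide = nb.PeptideRecord(id="example", sequence="CEFSQC")

print(f"peptide {peptide.sequence} (n={peptide.n})")
print("EIIP:", nb.encode_eiip(peptide))
print("INM: ", nb.encode_inm(peptide))
print("AAAF:", np.round(nb.encode_aaaf(peptide), 5))

matrix = nb.encode_stack(peptide, l_max=15)
print(f"\nstacked input matrix: shape {matrix.data.shape}, "
      f"true length {matrix.mask_length}, channels {matrix.channels}")
print(matrix.to_frame().head(8).to_string())
print("rows beyond position 6 are padding (all zeros).")
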