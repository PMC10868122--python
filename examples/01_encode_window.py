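"""Encode one 41-nt RNA window into the 522-value feature vector.

The window must have adenosine at its center (the m1A candidate).  The
printed numbers are the first coefficients of each feature group: moments
of the position-relative incidence matrices (PRIM/RPRIM) and of the
sequence matrix, raw k-mer counts (FV) and position sums (AAPIV/RAAPIV).
"""

from m1apred import assemble, validate_window
from m1apred.features import GROUP_SLICES

seq = "GUUCAAUUGGUUAGAGCACCAUCUUGAGGUAAUGGUUAGGA"  # 41 nt, A at position 21
window = validate_window(seq, 41, id="example")
fv = assemble(window)

print(f"window {window.id}: {window.bases}")
print(f"feature vector length: {len(fv.values)}")
for group, sl in GROUP_SLICES.items():
    block = fv.group(group)
    print(f"  {group:7s} [{sl.start:3d}:{sl.stop:3d}]  first values: "
          + ", ".join(f"{v:.3g}" for v in block[:4]))

# The FV block holds plain k-mer counts: its first four cells are the
# A/C/G/U composition of the window and must sum to 41.
fv_block = fv.group("FV")
print(f"mono-nucleotide counts (A,C,G,U): {fv_block[:4].astype(int).tolist()}"
      f"  -> sum {int(fv_block[:4].sum())}")
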