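"""Encode an sgRNA-target interface as the 6x23 binary matrix.

Rows 0-3 are the OR of the two one-hot sequences (channel order A,T,G,C);
rows 4-5 mark mismatch direction.  A matched column has one set bit and no
direction; a mismatched column has two set bits and one direction bit.
"""

import guidepost as gp

sgrna = "GGGTGGGGGGAGTTTGCTCCTGG"
target = "GGATGGAGGGAGTTTGCTCCTGG"  # two mismatches vs the guide

pair = gp.SgRNATargetPair(sgrna, target)
enc = gp.encode_pair(pair)

print(f"sgRNA : {sgrna}")
print(f"target: {target}")
print(f"mismatches: {gp.mismatch_count(pair)}")
print("interface matrix (rows A,T,G,C, dir10, dir01):")
for row, label in zip(enc.matrix.astype(int), ["A", "T", "G", "C", ">", "<"]):
    print(label, "".join(map(str, row)))

# The two mismatch columns carry exactly one direction bit each; e.g. the
# published convention encodes G->C as 0011-10 and C->G as 0011-01.
print("G->C column:", gp.encode_base_pair("G", "C").astype(int))
print("C->G column:", gp.encode_base_pair("C", "G").astype(int))
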