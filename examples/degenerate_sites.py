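"""Classify shared degenerate sites between two aligned coding sequences.

Third positions of fourfold boxes (e.g. CTx = Leu) tolerate any base;
twofold boxes (e.g. AAx = Lys/Asn) tolerate only the transition partner.
Only codons with identical context in both sequences enter the mask.
"""

from mitosweep import count_synonymous_differences, shared_degenerate_sites

ingroup = "CTAAAAGGATGA"
outgroup = "CTGAAGGGCTGG"

mask = shared_degenerate_sites(ingroup, outgroup, frame_offset=0, code_table=5)
print("fourfold third positions (0-based):", mask.fourfold_sites)
print("twofold third positions (0-based): ", mask.twofold_sites)

counts = count_synonymous_differences(ingroup, outgroup, mask)
print(f"d4 = {counts.d4}/{counts.l} fourfold, d2 = {counts.d2}/{counts.m} twofold")
print("each d counts a synonymous difference usable for rate calibration")
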