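"""Myopic MCES distance between two molecules given as SMILES.

Caffeine vs. theobromine differ by one methyl group: the exact ILP runs
(the lower bound is below the threshold T=10) and reports the weighted
edge-edit distance.  Caffeine vs. octane share almost no structure, so the
matching lower bound already reaches T and the ILP is skipped — the value
is a censored "at least this dissimilar" distance.
"""

from mcesdist import from_smiles, myopic_distance

caffeine = from_smiles("Cn1cnc2c1c(=O)n(C)c(=O)n2C", id="caffeine")
theobromine = from_smiles("Cn1cnc2c1c(=O)[nH]c(=O)n2C", id="theobromine")
octane = from_smiles("CCCCCCCC", id="octane")

for other in (theobromine, octane):
    res = myopic_distance(caffeine, other, T=10)
    print(f"caffeine vs {other.id}: d = {res.value}  "
          f"(provenance: {res.provenance}, T = {res.threshold})")

print("\nA 'bound' provenance means no exact computation was needed: the")
print("pair is provably at least T apart, which is all the double-")
print("thresholded metric requires.")
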