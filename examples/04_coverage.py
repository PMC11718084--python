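"""Chemical-space coverage: how far is each dataset structure from its
nearest background structure?

A training set covers a region of structure space only if every structure
of interest has a close neighbor in it.  Large or censored distances flag
coverage gaps.  Here the "dataset" is a few small molecules and the
"background" a small alkane/arene collection.
"""

from mcesdist import coverage_profile, from_smiles

dataset = [from_smiles(s, id=i) for s, i in [
    ("CC(=O)Oc1ccccc1C(=O)O", "aspirin"),
    ("c1ccccc1", "benzene"),
    ("CCO", "ethanol"),
]]
background = [from_smiles(s, id=i) for s, i in [
    ("c1ccccc1C", "toluene"),
    ("CCCCCC", "hexane"),
    ("CCOC", "ether"),
]]

prof = coverage_profile(dataset, background, T=10)
print(prof.to_string(index=False))
print("\nbenzene and ethanol sit one edit from the background (well")
print("covered); aspirin is 8 edits from its closest neighbor, close to")
print("the censoring threshold T = 10 -- a poorly covered structure.")
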