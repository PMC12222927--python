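"""ORF detection: the model's coverage feature and an NCBI-style audit scan.

ORF coverage — length of the longest forward open reading frame divided by
transcript length — is the classifier's strongest single feature: mRNAs
cluster near 0.7, lncRNAs near 0.2. The both-strand scan with a 75 nt
minimum mirrors NCBI ORF Finder defaults for auditing single transcripts.
"""

import numpy as np

import lncspect as L

rng = np.random.default_rng(3)
utr5 = "".join(rng.choice(list("ACGT"), size=60))
utr3 = "".join(rng.choice(list("ACGT"), size=120))
orf = "ATG" + "".join(rng.choice(["GGA", "CTT", "ACA", "GAG"], size=150)) + "TGA"
mrna_like = L.SequenceRecord("mrna_like", utr5 + orf + utr3)

feats = L.orf_features(mrna_like)
print(f"{mrna_like.id}: length {mrna_like.length} nt")
print(f"  longest ORF {feats.orf_length_nt} nt -> coverage {feats.orf_coverage:.3f}, "
      f"peptide {feats.longest_orf_aa} aa")

print("\nNCBI-style scan (both strands, >= 75 nt):")
for o in L.ncbi_style_scan(mrna_like):
    print(f"  {o.strand} strand frame {o.frame}: [{o.start}, {o.end})  {o.length_nt} nt")
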