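"""Fourier power spectra of numerically mapped transcripts.

Coding sequences carry a three-base periodicity from their codon
structure; in the power spectrum of a numerically mapped sequence this
shows up as an elevated bin at frequency N/3. The example contrasts a
codon-structured sequence with a shuffled copy of itself.
"""

import numpy as np

import lncspect as L

rng = np.random.default_rng(0)
codons = rng.choice(["GCT", "GAA", "AAG", "GAT", "TCT"], size=200)
coding = L.SequenceRecord("coding_like", "ATG" + "".join(codons) + "TAA")
shuffled = L.SequenceRecord("shuffled", "".join(rng.permutation(list(coding.seq))))

for rec in (coding, shuffled):
    spec = L.power_spectrum(L.map_sequence(rec, "complex"))
    d = L.spectral_descriptors(spec)
    cavg, aamp = L.key_fourier_features(rec)
    print(f"{rec.id:>12}: period-3 bin / spectrum mean = {d['peak'] / d['average']:6.2f}   "
          f"complex Fourier average = {cavg:9.1f}   atomic Fourier amplitude = {aamp:12.1f}")

print("\nthe codon-structured sequence concentrates spectral power at N/3;")
print("shuffling the same bases destroys the periodicity, not the composition.")
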