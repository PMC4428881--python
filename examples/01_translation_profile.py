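"""Translation profile of an ORF under the E. coli tRNAome.

Builds a small coding sequence that is mostly fast-translated but carries a
patch of codons read by rare tRNAs, then computes the per-codon rate
profile and its 19-codon smoothed average.
"""

from ribodesign import Orf, ecoli_rates, raw_profile, smooth

rates = ecoli_rates()

# 120 codons: fast Glu/Gly/Val background with a slow patch at codons 55-65
codons = ["ATG"] + ["GAA", "GGC", "GTT"] * 40
for i in range(54, 65):
    codons[i] = ["CTA", "AGG", "CGG"][i % 3]  # codons of rare tRNAs
orf = Orf(id="demo", dna="".join(codons[:121]))

prof = smooth(raw_profile(orf, rates), window=19)

print(f"ORF length: {prof.length} codons")
print(f"mean per-codon rate : {prof.raw.mean():.3f}   (1.0 = fastest codon, CTG)")
print(f"smoothed minimum    : {prof.smoothed.min():.3f} at codon "
      f"{prof.smoothed.argmin() + prof.smoothed_start}")
print("\ncodon_pos  raw    smoothed   (around the slow patch)")
for pos in range(50, 71, 2):
    print(f"{pos:9d}  {prof.raw[pos - 1]:.3f}  {prof.smoothed_at(pos):.3f}")
print("\nThe smoothed dip marks a putative translational attenuation site:")
print("a stretch the ribosome is predicted to transit slowly.")
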