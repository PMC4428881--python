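"""Insert a translational pause downstream of a protein domain boundary.

A smooth, fast-translated ORF (the typical situation for a heterologous
gene) gets one attenuation site ~30 aa downstream of a stated domain
boundary, so the finished domain can fold once it has cleared the
ribosomal exit tunnel.  If a leucine is available in the 20-70 aa window,
a single Leu -> CTA exchange suffices: CTA is read by the rarest
Leu-decoding tRNA in E. coli.
"""

from ribodesign import Orf, ecoli_rates, insert_pause, raw_profile, smooth, verify_synonymy

rates = ecoli_rates()

# 200-codon ORF, uniformly fast; a Leu (CTG) sits at codon 130
codons = ["ATG"] + ["GGC", "GAA", "CGT"] * 70
codons[129] = "CTG"
orf = Orf(id="target", dna="".join(codons[:200]))
domain_end_aa = 100

plan = insert_pause(orf, domain_end_aa, rates)

print(f"domain boundary at aa {domain_end_aa}; eligible window: aa 120-170")
for e in plan.edits:
    print(f"edit: codon {e.codon_pos}  {e.old_codon} -> {e.new_codon}  ({e.reason})")
print(f"protein unchanged: {verify_synonymy(orf, plan)}")

before = smooth(raw_profile(orf, rates), 19)
after = smooth(raw_profile(Orf(id="redesigned", dna=plan.result_dna), rates), 19)
print(f"smoothed minimum in window: {min(before.smoothed_at(p) for p in range(120, 171)):.3f}"
      f" -> {min(after.smoothed_at(p) for p in range(120, 171)):.3f}")
print("One synonymous codon swap carves a pause into the translation profile.")
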