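"""Weaken mRNA secondary structure in the initial 5'-coding region.

Stable structure around the start codon hinders ribosome loading and can
throttle expression.  Setting the third base of codons 3-7 to A wherever
that is synonymous disrupts such structure without touching the protein.
The input here is the start region of an epoxide-hydrolase gene whose
expression was limited by exactly this effect; folding energies are
computed with the ViennaRNA thermodynamic model over 39-nt windows in a
synthetic 5' vector context.
"""

import numpy as np

from ribodesign import Orf, ViennaFoldingEngine, dg_profile, optimize_five_prime

wild_type = "ATGAAACCCCGCACGGTGCCG"  # codons 1-7: M K P R T V P

plan = optimize_five_prime(Orf(id="m9", dna=wild_type), mode="force_preferred")
print(f"wild type : {wild_type}")
print(f"optimized : {plan.result_dna}")
print(f"{len(plan.edits)} third-base edits in codons "
      f"{min(e.codon_pos for e in plan.edits)}-{max(e.codon_pos for e in plan.edits)}; "
      "protein MKPRTVP unchanged")

# windowed folding energies over the edited span, shared synthetic context
rng = np.random.default_rng(26)
upstream = "".join(rng.choice(list("ACGT"), 69))   # synthetic stand-in for vector 5' UTR
tail = "GGCAGCGGTAGCGGTTCTGGCAGC"                  # synthetic ORF continuation
engine = ViennaFoldingEngine()
for name, head in (("wild type", wild_type), ("optimized", plan.result_dna)):
    prof = dg_profile(Orf(id=name, dna=head + tail, upstream=upstream), engine, range=(6, 20))
    print(f"{name}: min window dG over codons 3-7 = {prof.dG.min():+.2f} kcal/mol")
print("A less negative dG means weaker 5' structure, hence easier initiation.")
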