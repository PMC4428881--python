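# ribodesign

Translation-profile-guided synonymous redesign of coding sequences.

## The problem

Heterologous proteins expressed in *E. coli* frequently misfold into
inclusion bodies, and genes with stable mRNA structure around the start
codon express poorly.  Both failure modes are encoded in the *silent*
layer of the coding sequence: which synonymous codons it uses.  mRNAs are
translated at non-uniform speed — codons read by scarce tRNAs are decoded
slowly — and in well-behaved multidomain proteins slow-translated
stretches sit characteristically 20–70 aa (typically ~30 aa) downstream of
structural domain boundaries: the ribosome pauses once a finished domain
has cleared the exit tunnel, giving it time to fold co-translationally.

`ribodesign` makes this design space programmable, for protein engineers
and expression labs:

* **profile** — compute per-codon relative translation rates from a host
  tRNA abundance table and smooth them along the ORF;
* **detect** — call translational attenuation sites (smoothed-profile
  minima below a genome-wide threshold) and relate them to domain
  boundaries;
* **redesign** — insert a pause downstream of a domain boundary (slow-down)
  or erase existing pauses (speed-up), by strictly synonymous edits;
* **initiate** — weaken 5′-coding-region mRNA secondary structure by
  synonymous third-base substitutions, raising the windowed folding energy
  around the start codon.

## The model

The relative decoding rate of sense codon *c* is the summed concentration
of the tRNA species able to read it,

    rate(c) = Σ_{a ∈ wobble(c)} [tRNA_a]  /  max_c′ Σ_{a ∈ wobble(c′)} [tRNA_a]

so the fastest codon has rate 1 and rates are invariant to the overall
scale of the abundance measurements.  A built-in *E. coli* abundance table
(classic measurements, molecules/cell) and a curated codon→anticodon
wobble map ship as editable package data.  Profiles are smoothed with a
centered 19-codon running mean; attenuation sites are maximal runs of
smoothed values below a threshold taken, by default, as the 10th
percentile of pooled smoothed rates over a reference ORF set.

For pause insertion the tool prefers the single exchange Leu → CUA: CUA is
read by the rarest Leu-decoding tRNA in *E. coli*, and one such codon is
enough to dent the smoothed profile.  Leu-free target windows fall back to
a greedy slowest-synonym substitution capped at a few codons.  Every edit
is synonymous by construction and can be annotated with the local mRNA
folding-energy change (ΔΔG over the 39-nt window centered on the edit,
ViennaRNA); edits whose |ΔΔG| exceeds a guard (default 2 kcal/mol) are
flagged.

5′ folding-energy profiles are minimum free energies of a 39-nt sliding
window, centers −50…+50 nt relative to the first nucleotide of ATG
(upstream vector/UTR context supplied by the caller, never fabricated).

## Worked example

```python
from ribodesign import Orf, optimize_five_prime

plan = optimize_five_prime(Orf(id="m9", dna="ATGAAACCCCGCACGGTGCCG"),
                           mode="force_preferred")
print(plan.result_dna, len(plan.edits))
```

prints

```
ATGAAACCACGAACAGTACCA 5
```

— the third base of codons 3–7 set to A (five synonymous edits; codon 2 is
AAA already), leaving the protein MKPRTVP untouched.  Running
`examples/04_five_prime_optimization.py` additionally folds both variants
in a shared synthetic 5′ context:

```
wild type: min window dG over codons 3-7 = -12.80 kcal/mol
optimized: min window dG over codons 3-7 = -10.00 kcal/mol
```

The optimized start region forms weaker secondary structure, which favors
ribosome loading.  The other scripts in `examples/` walk through profile
computation, pause insertion (a single CTG→CTA edit at a stated domain
offset), pause removal, and planted-site recovery on synthetic fixtures —
each prints the numbers it computes and says what they mean.

## Command line

A thin CLI mirrors the library:

```
ribodesign profile    --orf genes.fasta                      # rate profile TSV
ribodesign threshold  --reference genome_sample.fasta        # genome-wide threshold
ribodesign sites      --orf genes.fasta --reference ... --domains domains.tsv
ribodesign attenuate  --orf genes.fasta --domains domains.tsv --out-fasta slow.fasta
ribodesign smooth-out --orf genes.fasta --reference ...      # erase all pauses
ribodesign optimize5p --orf genes.fasta --mode force
ribodesign rarecodons --usage usage.tsv -k 10
ribodesign fixture    --seed 1 --out fixture_dir/
ribodesign report     --orf genes.fasta --reference ... --out report.json
```

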