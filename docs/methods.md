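# Methods

## Per-codon translation rates

The package models elongation speed as a static property of each sense
codon in a given host: the more abundant the tRNA species that can read a
codon, the faster it is decoded.  Concretely,

    rate(c) = Σ_{a ∈ wobble(c)} [tRNA_a],

normalized by the maximum over the codons of the wobble map (mode `max`,
default; the fastest codon has rate 1.0 and rates are invariant to
rescaling all abundances) or by the sum (mode `sum`).  The summed-cognate
form is the minimal model in which per-codon speed is driven by tRNA
concentration; possible refinements — near-cognate competition, codon–
anticodon binding strengths, modification-state kinetics — are deliberately
out of scope, and nothing downstream depends on more than the rate
*ordering* within each synonymous family.

Two data files ship with the package and are both plain, editable TSV:

* `data/ecoli_trna_dong1996.tsv` — *E. coli* tRNA abundances
  (molecules/cell at 0.4 doublings/h, classic measurements).  Isoacceptors
  sharing an anticodon are merged by summing (Thr GGU, Tyr GUA, Val GAC);
  initiator Met and Sec are excluded.  The lysidine-modified Ile2
  anticodon (chemically CAU but functionally reading AUA only) is stored
  under its functional reading equivalent UAU so it cannot collide with
  elongator Met CAU — the table is keyed by what an anticodon *reads*, not
  its chemistry.
* `data/ecoli_wobble.tsv` — a curated codon→anticodon decoding map
  (Watson–Crick plus G34 C/U reading, modified-U34 A/G reading extended to
  U in cmo5U-served four-codon boxes, C34 G-only, inosine U/C/A).  It is
  shipped as data rather than derived algorithmically because base-34
  modifications make rule-based derivation unreliable; users expressing in
  another host supply their own two files.

Under this table the CUA codon gets the lowest rate of all Leu codons
(its only decoder is the rarest Leu isoacceptor), which is the property
the pause-insertion design relies on.  When tRNA abundances are unknown
for a species, `rare_codons(usage, k=10)` provides the usual fallback:
the ten least-used codons of a codon-usage table (ties broken
lexicographically for determinism).

## Profiles, threshold, attenuation sites

A translation profile is the per-codon rate sequence of an ORF (codon 1 =
ATG, 1-based), smoothed with a centered arithmetic-mean window of 19
codons.  Smoothed values exist only where the full window fits; edges are
neither padded nor shrunk, so no speed is fabricated for the initiation
region.  The window statistic is the mean (a median or weighted window
would also be defensible; the mean is the simplest linear choice and makes
the profile an affine-linear function of the rates).

Attenuation sites are maximal runs of smoothed values strictly below a
genome-wide threshold.  No analytic definition of that threshold exists in
this modelling tradition, so it is an explicit, configurable object:

* `percentile` (default, parameter 10): linear-interpolation percentile of
  the pooled smoothed values of a user-supplied reference ORF set —
  scale-free and reproducible;
* `mean_minus_sd` (parameter = number of SDs);
* `fixed` (parameter passed through).

Runs separated by fewer than `min_gap` codons (default 5) are merged so a
single biological pause does not fragment into several calls; each site
reports its smoothed minimum (`argmin`, ties to the smaller position) and
depth.  `site_domain_offsets` pairs each site with the nearest upstream
domain end; the offset is in amino acids (codon-index difference).

## Redesign operations

All redesigns are sets of codon-level synonymous edits; every plan is
checked by `verify_synonymy` (standard-genetic-code translation equality),
and this is property-tested over randomized calls.

**insert_pause** targets the window `[domain_end+20, domain_end+70]` aa —
the span of nascent chain the ribosomal exit tunnel can cover — with a
preference for `domain_end+30`.  If the window already contains the
preferred slow codon (CTA) the site is considered slow and the plan is
empty.  If it contains a Leu, exactly one edit is made: the Leu nearest
the preferred offset (ties to the smaller position) becomes CTA.  A
Leu-free window falls back to greedy slowest-synonym substitution, largest
rate drop first, capped at `max_codons_per_site` (default 3) and stopping
early if a supplied threshold is undercut by the window's smoothed
minimum.  For windows no wider than half a smoothing window the greedy
choice is provably optimal (every edit lowers every window position's
smoothed value by drop/19), which the tests exploit by comparing against
exhaustive enumeration on 10-codon windows.  A window of only Met/Trp
admits no synonymous slow-down and errors.

**remove_pause** replaces every codon in a site whose raw rate is below
the site-call threshold with its fastest synonym (ties lexicographic);
the smoothed profile over the site can only rise.  **remove_all_pauses**
composes detection and removal into one merged plan.  Note that removal
cannot always push a site above the threshold: amino acids whose fastest
synonym is still slow (His, Ser in *E. coli*) leave a shallow residual dip
— the biologically expected behaviour for His/Ser-rich pause regions.

Each edit may carry a local ΔΔG: the folding-energy change of the 39-nt
window centered on the edited codon, computed before/after with the
folding engine.  |ΔΔG| above `ddG_guard_kcal` (default 2.0 kcal/mol — an
order of magnitude below typical 39-nt window energies, chosen so only
structure-reshaping edits trigger it) produces a warning on the plan; the
edit is *not* silently dropped, since the trade-off between pausing and
mRNA stability is the caller's to make.

## 5′ folding energy and optimization

`dg_profile` slides a 39-nt window over centers −50…+50 nt relative to the
first nt of ATG, assigning each window's minimum free energy to its center
position.  Negative coordinates draw on the caller-supplied upstream
(vector/UTR) context — 69 nt are required for the default range, and the
tool refuses to fabricate context; centers lacking full context are
omitted, never extrapolated.  Folding is delegated through the
`FoldingEngine` contract (RNA string → MFE, kcal/mol).  The default
adapter binds ViennaRNA at default parameters (37 °C); tests mostly use a
deterministic stub engine so the oracles are exact, with the thermodynamic
engine exercised where the claim is thermodynamic.

`optimize_five_prime` edits only third codon positions within
`codon_range` (default codons 3–7; codons 1–2 are never touched — the
start codon is fixed and position 2 belongs to the initiation context).
`force_preferred` sets third bases to A wherever synonymous (ATG/TGG and
stop-creating swaps are skipped automatically by the synonymy rule).
`search` exhaustively enumerates synonymous third-base combinations and
maximizes the minimum windowed dG over centers spanned by the edited
codons, breaking ties by fewest edits, then most preferred bases, then
lexicographically smallest sequence — fully deterministic.

## Synthetic fixtures

`generate_fixture(seed, ...)` fabricates a self-contained input bundle:
a toy tRNAome (log-uniform concentrations, 100–5000, over the shipped
wobble map's anticodons), `n_orfs` background ORFs, planted attenuation
sites, a reference ORF set, and — when `out_dir` is given — byte-stable
FASTA/TSV files.  Design choices:

* the background encodes a random protein by each residue's *fastest*
  synonym, emulating the smooth fast profile of a codon-"optimized"
  heterologous gene; residues are drawn from amino acids whose fastest
  synonym has rate ≥ 0.5 under the toy tRNAome, since an amino acid with
  no fast codon would dent the profile no matter the codon choice;
* planted sites are 19-codon runs (one full smoothing window, so the
  smoothed minimum sits at the planted center) of slow synonyms with rate
  ≤ the requested depth, centered `offset_aa` downstream of a generated
  domain boundary;
* the reference set is uniform random sense-codon "soup" — a stand-in for
  a genome-wide sample mixing fast and slow stretches — from which the
  10th-percentile threshold is drawn.

What passing recovery tests shows: the detection pipeline finds exactly
the planted below-threshold runs, localizes their minima to within half a
window, and calls nothing on clean fixtures.  What it does not show: real
genes have correlated codon usage, amino-acid composition far from
uniform, and pause regions shaped by selection rather than planted as
clean runs — fixture results bound algorithmic correctness, not biological
sensitivity/specificity.

## Problem sizes and numerical choices

The shipped verification runs use 200 randomized instances per oracle
comparison, 10 fixture seeds × 3 ORFs × 2 planted sites (plus equal-size
clean controls), and 1,000 randomized design calls for synonymy — sizes at
which every check is exact (agreement rates are 1.0, not approximately 1).
Floating-point comparisons in tests use absolute tolerances ≤ 1e-9; the
smoothing convolution and the loop-based oracle agree to ~1e-15.
Tie-breaks are deterministic everywhere (smallest position / lexicographic
smallest codon), so all outputs are byte-reproducible for a fixed seed.

## Known limitations

* Rates are static per codon: no ribosome-flow/traffic simulation, no
  initiation-rate coupling, no starvation-dependent reading.
* The rate model ignores near-cognate competition and modification-state
  kinetics; only within-family orderings are load-bearing.
* Solubility and expression outcomes are wet-lab quantities; the package
  predicts profiles and designs sequences but cannot score folding success.
* Domain boundaries are inputs (from structure alignment of a solved
  homolog); no secondary/tertiary structure prediction is performed.
* The 5′ optimizer explores third-base substitutions only; full codon
  shuffles could reach weaker structures at the cost of perturbing the
  translation profile.
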