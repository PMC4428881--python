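# Curated E. coli codon -> anticodon decoding map (sense codons only).
# Watson-Crick pairs plus wobble-position reading: G34 reads codon-3rd C/U;
# modified U34 (mnm5U, cmo5U) reads A/G, extended to U in four-codon boxes
# served by a cmo5U isoacceptor; C34 reads G; inosine (Arg2 ICG) reads U/C/A;
# lysidine Ile2 is written as its functional anticodon UAU (reads AUA only).
# Editable package data: one codon<TAB>anticodon pair per line.
# codon	anticodon
TTT	GAA
TTC	GAA
TTA	UAA
TTG	CAA
TTG	UAA
CTT	GAG
CTC	GAG
CTA	UAG
CTG	CAG
CTG	UAG
ATT	GAU
ATC	GAU
ATA	UAU
ATG	CAU
GTT	UAC
GTT	GAC
GTC	GAC
GTA	UAC
GTG	UAC
TCT	GGA
TCT	UGA
TCC	GGA
TCA	UGA
TCG	CGA
TCG	UGA
AGT	GCU
AGC	GCU
CCT	GGG
CCT	UGG
CCC	GGG
CCA	UGG
CCG	CGG
CCG	UGG
ACT	GGU
ACT	UGU
ACC	GGU
ACA	UGU
ACG	CGU
ACG	UGU
GCT	GGC
GCT	UGC
GCC	GGC
GCA	UGC
GCG	UGC
TAT	GUA
TAC	GUA
CAT	GUG
CAC	GUG
CAA	UUG
CAG	CUG
CAG	UUG
AAT	GUU
AAC	GUU
AAA	UUU
AAG	UUU
GAT	GUC
GAC	GUC
GAA	UUC
GAG	UUC
TGT	GCA
TGC	GCA
TGG	CCA
CGT	ACG
CGC	ACG
CGA	ACG
CGG	CCG
AGA	UCU
AGG	CCU
GGT	GCC
GGC	GCC
GGA	UCC
GGG	CCC
GGG	UCC
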