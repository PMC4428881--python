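# E. coli tRNA abundances (molecules per cell, growth rate 0.4 doublings/h),
# transcribed from the classic Dong/Nilsson/Kurland measurements.
# One row per distinct anticodon; isoacceptors sharing an anticodon are merged
# (concentrations summed; see note column). Initiator Met and Sec excluded.
# The lysidine-modified Ile2 anticodon (chemically CAU, functionally reading
# AUA only) is encoded by its functional reading equivalent UAU so that it
# does not collide with elongator Met CAU.
# anticodon	concentration	note
UGC	3250	Ala1B/Ala1C
GGC	617	Ala2
ACG	4752	Arg2 (I34: reads CGU/CGC/CGA)
CCG	639	Arg3
UCU	867	Arg4
CCU	420	Arg5
GUU	1193	Asn
GUC	2396	Asp1
GCA	1587	Cys
UUG	764	Gln1
CUG	881	Gln2
UUC	4717	Glu2
CCC	1068	Gly1
UCC	1068	Gly2
GCC	4359	Gly3
GUG	639	His
GAU	1737	Ile1
UAU	1737	Ile2 (lysidine-modified CAU; reads AUA)
CAG	4470	Leu1
GAG	943	Leu2
UAG	666	Leu3
CAA	1913	Leu4
UAA	1031	Leu5
UUU	1924	Lys
CAU	706	Met-m (elongator)
GAA	1037	Phe
CGG	900	Pro1
GGG	720	Pro2
UGG	581	Pro3
UGA	1296	Ser1
CGA	344	Ser2
GCU	1408	Ser3
GGA	764	Ser5
CGU	541	Thr2
GGU	1199	Thr1+Thr3 (104+1095)
UGU	916	Thr4
CCA	943	Trp
GUA	2030	Tyr1+Tyr2 (769+1261)
UAC	3840	Val1
GAC	1265	Val2A+Val2B (630+635)
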