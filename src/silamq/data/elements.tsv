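# Isotope masses (Da) and natural abundances for the elements of unmodified
# and carbamidomethylated peptides (C, H, N, O, S).
# Values: IUPAC/CIAAW 2013 atomic masses and representative isotopic
# abundances. The 15N-14N mass difference implied by this table is
# 15.0001089 - 14.0030740 = 0.9970349 Da, the per-nitrogen spacing between
# the light and heavy channels of a metabolically labeled peptide.
# Columns: element, nominal mass number, exact mass (Da), natural abundance.
element	nominal	mass	abundance
H	1	1.0078250319	0.999885
H	2	2.0141017778	0.000115
C	12	12.0	0.9893
C	13	13.0033548378	0.0107
N	14	14.0030740	0.99636
N	15	15.0001089	0.00364
O	16	15.9949146196	0.99757
O	17	16.9991317	0.00038
O	18	17.9991610	0.00205
S	32	31.9720710	0.9499
S	33	32.9714588	0.0075
S	34	33.9678669	0.0425
S	36	35.9670808	0.0001
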