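feature	kmer	value
propeller_twist	AA	-18.66
propeller_twist	AC	-13.1
propeller_twist	AG	-14.0
propeller_twist	AT	-15.01
propeller_twist	CA	-9.45
propeller_twist	CC	-8.11
propeller_twist	CG	-10.03
propeller_twist	CT	-14.0
propeller_twist	GA	-13.48
propeller_twist	GC	-11.08
propeller_twist	GG	-8.11
propeller_twist	GT	-13.1
propeller_twist	TA	-11.85
propeller_twist	TC	-13.48
propeller_twist	TG	-9.45
propeller_twist	TT	-18.66
dna_denaturation	AA	54.5
dna_denaturation	AC	97.73
dna_denaturation	AG	58.42
dna_denaturation	AT	57.02
dna_denaturation	CA	54.71
dna_denaturation	CC	85.97
dna_denaturation	CG	72.55
dna_denaturation	CT	58.42
dna_denaturation	GA	86.44
dna_denaturation	GC	136.12
dna_denaturation	GG	85.97
dna_denaturation	GT	97.73
dna_denaturation	TA	36.73
dna_denaturation	TC	86.44
dna_denaturation	TG	54.71
dna_denaturation	TT	54.5
bending_stiffness	AA	35.0
bending_stiffness	AC	60.0
bending_stiffness	AG	60.0
bending_stiffness	AT	20.0
bending_stiffness	CA	60.0
bending_stiffness	CC	130.0
bending_stiffness	CG	85.0
bending_stiffness	CT	60.0
bending_stiffness	GA	60.0
bending_stiffness	GC	85.0
bending_stiffness	GG	130.0
bending_stiffness	GT	60.0
bending_stiffness	TA	20.0
bending_stiffness	TC	60.0
bending_stiffness	TG	60.0
bending_stiffness	TT	35.0
bendability	AAA	-0.274
bendability	AAC	-0.205
bendability	AAG	-0.081
bendability	AAT	-0.28
bendability	ACA	-0.006
bendability	ACC	-0.032
bendability	ACG	-0.033
bendability	ACT	-0.183
bendability	AGA	0.027
bendability	AGC	0.017
bendability	AGG	-0.057
bendability	AGT	-0.183
bendability	ATA	0.182
bendability	ATC	-0.11
bendability	ATG	0.134
bendability	ATT	-0.28
bendability	CAA	0.015
bendability	CAC	0.04
bendability	CAG	0.175
bendability	CAT	0.134
bendability	CCA	-0.246
bendability	CCC	-0.012
bendability	CCG	-0.136
bendability	CCT	-0.057
bendability	CGA	-0.003
bendability	CGC	-0.077
bendability	CGG	-0.136
bendability	CGT	-0.033
bendability	CTA	0.09
bendability	CTC	0.031
bendability	CTG	0.175
bendability	CTT	-0.081
bendability	GAA	-0.037
bendability	GAC	-0.013
bendability	GAG	0.031
bendability	GAT	-0.11
bendability	GCA	0.076
bendability	GCC	0.107
bendability	GCG	-0.077
bendability	GCT	0.017
bendability	GGA	0.013
bendability	GGC	0.107
bendability	GGG	-0.012
bendability	GGT	-0.032
bendability	GTA	0.025
bendability	GTC	-0.013
bendability	GTG	0.04
bendability	GTT	-0.205
bendability	TAA	0.068
bendability	TAC	0.025
bendability	TAG	0.09
bendability	TAT	0.182
bendability	TCA	0.194
bendability	TCC	0.013
bendability	TCG	-0.003
bendability	TCT	0.027
bendability	TGA	0.194
bendability	TGC	0.076
bendability	TGG	-0.246
bendability	TGT	-0.006
bendability	TTA	0.068
bendability	TTC	-0.037
bendability	TTG	0.015
bendability	TTT	-0.274
duplex_disrupt_energy	AA	1.9
duplex_disrupt_energy	AC	1.3
duplex_disrupt_energy	AG	1.6
duplex_disrupt_energy	AT	1.5
duplex_disrupt_energy	CA	1.9
duplex_disrupt_energy	CC	3.1
duplex_disrupt_energy	CG	3.6
duplex_disrupt_energy	CT	1.6
duplex_disrupt_energy	GA	1.6
duplex_disrupt_energy	GC	3.1
duplex_disrupt_energy	GG	3.1
duplex_disrupt_energy	GT	1.3
duplex_disrupt_energy	TA	0.9
duplex_disrupt_energy	TC	1.6
duplex_disrupt_energy	TG	1.9
duplex_disrupt_energy	TT	1.9
stacking_energy	AA	-5.37
stacking_energy	AC	-10.51
stacking_energy	AG	-6.78
stacking_energy	AT	-6.57
stacking_energy	CA	-6.57
stacking_energy	CC	-8.26
stacking_energy	CG	-9.69
stacking_energy	CT	-6.78
stacking_energy	GA	-9.81
stacking_energy	GC	-14.59
stacking_energy	GG	-8.26
stacking_energy	GT	-10.51
stacking_energy	TA	-3.82
stacking_energy	TC	-9.81
stacking_energy	TG	-6.57
stacking_energy	TT	-5.37
z_dna	AA	3.9
z_dna	AC	4.6
z_dna	AG	3.4
z_dna	AT	5.9
z_dna	CA	1.3
z_dna	CC	2.4
z_dna	CG	0.7
z_dna	CT	3.4
z_dna	GA	3.4
z_dna	GC	4.0
z_dna	GG	2.4
z_dna	GT	4.6
z_dna	TA	2.5
z_dna	TC	3.4
z_dna	TG	1.3
z_dna	TT	3.9
duplex_free_energy	AA	-1.0
duplex_free_energy	AC	-1.44
duplex_free_energy	AG	-1.28
duplex_free_energy	AT	-0.88
duplex_free_energy	CA	-1.45
duplex_free_energy	CC	-1.84
duplex_free_energy	CG	-2.17
duplex_free_energy	CT	-1.28
duplex_free_energy	GA	-1.3
duplex_free_energy	GC	-2.24
duplex_free_energy	GG	-1.84
duplex_free_energy	GT	-1.44
duplex_free_energy	TA	-0.58
duplex_free_energy	TC	-1.3
duplex_free_energy	TG	-1.45
duplex_free_energy	TT	-1.0
a_philicity	AA	1.04
a_philicity	AC	0.38
a_philicity	AG	0.56
a_philicity	AT	1.18
a_philicity	CA	0.63
a_philicity	CC	0.17
a_philicity	CG	0.11
a_philicity	CT	0.56
a_philicity	GA	0.43
a_philicity	GC	0.08
a_philicity	GG	0.17
a_philicity	GT	0.38
a_philicity	TA	1.27
a_philicity	TC	0.43
a_philicity	TG	0.63
a_philicity	TT	1.04
protein_dna_twist	AA	35.1
protein_dna_twist	AC	31.5
protein_dna_twist	AG	31.9
protein_dna_twist	AT	29.3
protein_dna_twist	CA	37.3
protein_dna_twist	CC	32.9
protein_dna_twist	CG	36.1
protein_dna_twist	CT	31.9
protein_dna_twist	GA	36.3
protein_dna_twist	GC	33.6
protein_dna_twist	GG	32.9
protein_dna_twist	GT	31.5
protein_dna_twist	TA	37.8
protein_dna_twist	TC	36.3
protein_dna_twist	TG	37.3
protein_dna_twist	TT	35.1
b_dna_twist	AA	35.62
b_dna_twist	AC	34.4
b_dna_twist	AG	27.7
b_dna_twist	AT	31.5
b_dna_twist	CA	34.5
b_dna_twist	CC	33.67
b_dna_twist	CG	29.8
b_dna_twist	CT	27.7
b_dna_twist	GA	36.9
b_dna_twist	GC	40.0
b_dna_twist	GG	33.67
b_dna_twist	GT	34.4
b_dna_twist	TA	36.0
b_dna_twist	TC	36.9
b_dna_twist	TG	34.5
b_dna_twist	TT	35.62
protein_deformation	AA	2.9
protein_deformation	AC	2.3
protein_deformation	AG	2.1
protein_deformation	AT	1.6
protein_deformation	CA	9.8
protein_deformation	CC	6.1
protein_deformation	CG	12.1
protein_deformation	CT	2.1
protein_deformation	GA	4.5
protein_deformation	GC	4.0
protein_deformation	GG	6.1
protein_deformation	GT	2.3
protein_deformation	TA	6.3
protein_deformation	TC	4.5
protein_deformation	TG	9.8
protein_deformation	TT	2.9
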