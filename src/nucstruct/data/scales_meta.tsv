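feature	k	sign_class	units
propeller_twist	2	positive	degrees
dna_denaturation	2	positive	degC
bending_stiffness	2	positive	nm
bendability	3	positive	arbitrary
duplex_disrupt_energy	2	positive	kcal/mol
stacking_energy	2	negative	kcal/mol
z_dna	2	negative	kcal/mol
duplex_free_energy	2	negative	kcal/mol
a_philicity	2	negative	kcal/mol
protein_dna_twist	2	negative	degrees
b_dna_twist	2	negative	degrees
protein_deformation	2	negative	arbitrary
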