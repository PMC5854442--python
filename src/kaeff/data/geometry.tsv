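name	V_um3	A_um2	v_over_a_um	provenance
human_cell	1200	767	1.5645	cytoplasmic volume and plasma-membrane area, human CME conditions
yeast_cell	37.2	75.8	0.4908	cytoplasmic volume and plasma-membrane area, yeast CME conditions
yeast_plasma_membrane_ratio	0.5	1.0	0.5	reference V/A ratio for the yeast plasma membrane (ratio only)
ode_reference	50	65.63	0.7618	reference geometry used for kinetics baselines
clathrin_invitro	9.46	1.0	9.46	V/A extracted from the in vitro clathrin/AP-2 assay (ratio only)
calmodulin_assay	6.7	1.0	6.7	V/A of the 2D calmodulin-peptide binding measurement (ratio only)
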