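protein1	protein2	kd_pp_um	notes
AP-2	EPN1	FILL_ME	per-pair Kd^PP not machine-readable here; supply a measured value
AP-2	DAB2	FILL_ME	per-pair Kd^PP not machine-readable here; supply a measured value
AP-2	SNAP91/AP180	FILL_ME	per-pair Kd^PP not machine-readable here; supply a measured value
AP-2	AMPH	FILL_ME	per-pair Kd^PP not machine-readable here; supply a measured value
AP-2	HIP1	FILL_ME	per-pair Kd^PP not machine-readable here; supply a measured value
AP-2	FCHO1	FILL_ME	per-pair Kd^PP not machine-readable here; supply a measured value
SH3GL2/Endophilin	SH3GL2/Endophilin	FILL_ME	homodimer; supply a measured value
FCHO1	FCHO2	FILL_ME	heterodimer; supply a measured value
SLA2	YAP1802	FILL_ME	yeast pair; supply a measured value
ENT1	ENT2	FILL_ME	yeast pair; supply a measured value
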