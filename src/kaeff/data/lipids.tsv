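name	membrane	density_per_um2	provenance
PIP2	plasma membrane	25000	PI(4,5)P2 average density in mouse fibroblast plasma membrane (~1 percent of lipids)
PIP2_invitro_clathrin	liposome	54668	lipid density extracted from the in vitro clathrin/AP-2 assay
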