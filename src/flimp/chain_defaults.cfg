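# Oligomer chain model calibration, version 1
# Ligand separations grow linearly from the tetramer anchor; the dye
# contribution converts ligand-ligand to fluorophore-fluorophore distance.
config_version = 1
tetramer_anchor_nm = 18.5
per_dimer_increment_nm = 7.5
dye_contribution_nm = 1.1
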