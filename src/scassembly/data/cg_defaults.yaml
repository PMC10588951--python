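# Frozen calibration of the coarse-grained dissociation assay.
# Chosen once so that, at the middle steering force (0.05 kJ/mol/nm per atom,
# default run length), wild-type assemblies remain intact while the core
# (L106E) and double (L102E/L106E) mutants dissociate, the double mutant
# earlier than the single. Do not edit without bumping the version.
version: 1
interface_well_depth: 4.0   # kT per tip-bead pair, wild type
genotype_scales:
  WT: 1.0
  L102E: 0.7
  L106E: 0.3
  L102E/L106E: 0.15
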