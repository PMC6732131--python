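# Example pipeline configuration (all sections optional; defaults apply).

seed = 1
out_dir = "results"
n_boot = 200            # bootstrap replicates for rarefaction bands
n_subsamples = 20       # effort-standardization subsamples
min_occurrences = 5     # occurrence filter for relative densities
n_permutations = 999    # PermANOVA permutations
max_managed_age = 100   # drop managed stands older than this (years)
exclude_clearcuts = false

[simulation]
seed = 1
affinity_concentration = 0.5   # < 1: specialists, > 1: generalists

[simulation.n_stands_by_type]
clearcut = 12
young = 12
old = 12
unmanaged = 12

[simulation.n_species_by_taxon]
fungi = 104
lichens = 20
beetles = 80

[simulation.landscape_area_by_type]  # ha, weighting basis
clearcut = 2100.0
young = 7100.0
old = 8400.0
unmanaged = 2650.0

# Override a single intensity cell: "standtype/dwtype/treespecies"
[simulation.deadwood_intensity]
"unmanaged/snag/pine" = 30.0
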