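# Example run configuration for the trendsvar CLI.
#
# Each construct maps to the CSV column (search-term) names used for its
# composite; an empty list means "use every column in <label>.csv".
constructs:
  VA: []        # e.g. [Shooting, Shootings, Gun Violence, Massacre, Terrorist Attack]
  GC: []        # e.g. [Gun Control, Gun Laws, Gun Rights, Gun Safety, Gun Regulations]
  GP: []        # e.g. [Gun Purchase, Buy Gun, Buy Weapon, Concealed Weapon, Concealed Carry]
ordering: [VA, GC, GP]   # Wold causal order; earlier variables act contemporaneously on later ones
horizons: [1, 2, 3, 6, 12]   # FEVD horizons, months
irf_horizon: 12              # impulse-response horizon, months
n_boot: 1000                 # residual-bootstrap replicates
seed: 0
log_offset: 1.0              # panel is ln(index + log_offset)
out_dir: results
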