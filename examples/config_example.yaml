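# Analysis configuration for `dlptp detect --config config_example.yaml`.
# Column names map published spreadsheets onto the canonical schema
# without code changes.
column_map:
  gene_name: protein_id
  temp: temperature
  concentration: conc
  rel_value: log2_value
  qupm: n_peptides
# Declared design grids (optional; imports fail loudly on stray values)
# temperature_grid: [42.0, 44.1, 46.2, 48.1, 50.4, 51.9, 54.0, 56.1, 58.2, 60.1, 62.4, 63.9]
# conc_grid: [0.0, 4.0e-8, 2.9e-7, 2.0e-6, 1.0e-5]
# MS-run assignment; omit to pair consecutive temperatures automatically
# runs:
#   run1: [42.0, 44.1]
#   run2: [46.2, 48.1]
# Generic per-run QC exclusion (e.g. a run with anomalous noise)
exclude_runs: []
conc_offset: 2.0        # decades below the lowest dose for the vehicle
min_obs: 20             # minimum non-missing measurements per protein
mode: moderated
alpha: 0.10
B: 100
seed: 0
model:
  kappa_max: 500.0
  a_max: 1.0
  zeta_margin: 2.0
  tol: 1.0e-9
  max_iter: 300
  n_restarts: 3
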