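# Small demo world: a 6x6 road lattice (5 km cells), 12 census units,
# 300,000 adults, benchmark-style true prevalence and band detection.
seed: 42
grid_rows: 6
grid_cols: 6
cell_length_m: 5000.0
n_census_units: 12
total_population: 300000
n_clinics: 2
survey:
  n_respondents: 400
  n_contacts: 1200
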