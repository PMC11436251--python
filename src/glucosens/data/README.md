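# Bundled spectral tables

Representative NIR optical properties on a 10-nm grid over 1000–1700 nm,
regenerable with `scripts/make_tables.py`. Values between grid nodes are
linearly interpolated; lookups outside the span raise.

## skin_three_layer.csv / intralipid_2pct.csv

Columns: `wavelength_nm, layer, mu_a_mm-1, mu_s_mm-1, g, n`

- `layer`: `epidermis` | `dermis` | `subcutis` (skin) or `intralipid_2pct`
- `mu_a_mm-1`, `mu_s_mm-1`: absorption / scattering coefficients
- `g`: scattering anisotropy; `n`: refractive index

The skin table's dermis row at 1314 nm is pinned to mu_a = 2.05 mm^-1
and mu_s = 13 mm^-1; every other entry is representative (water-shaped
absorption plus flat background; 1/lambda scattering power law; g = 0.9,
n = 1.4). Runs can substitute an alternative CSV with the same schema
via the pipeline config.

## glucose_absorption.csv

Columns: `wavelength_nm, dmua_dCg_mm-1_per_mmolL` — representative
glucose-induced absorption change per mmol/L.
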