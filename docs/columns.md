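# CSV column dictionary

## Trait table (one row per harvested plant)

| column | unit | description |
|---|---|---|
| `species_id` | — | taxon label; must match a tree tip |
| `status` | — | `crop` or `progenitor` |
| `family` | — | `grass` or `legume` |
| `accession_id` | — | seed-bank accession label |
| `experiment_id` | — | yield experiment `1` or `2` |
| `block_id` | — | randomized block label |
| `seed_mass_sown_mg` | mg | mean individual seed mass at sowing |
| `biomass_total_g` | g | final above-ground dry mass (Md) |
| `mass_vegetative_g` | g | vegetative compartment |
| `mass_reproductive_g` | g | reproductive compartment incl. culm + chaff |
| `mass_chaff_g` | g | chaff (incl. culm by convention) |
| `mass_grain_g` | g | grain = total seed yield Y |
| `seed_mass_harvest_mg` | mg | mean individual seed mass at harvest |
| `n_seeds_total` | count (mean) | total seeds per plant |
| `n_seeds_per_infructescence` | count (mean) | cereals only; empty for pulses |
| `n_infructescences` | count (mean) | cereals only; empty for pulses |
| `duration_days` | days | germination to flowering |
| `height_cm` | cm | maximum plant height; optional |

Invariants enforced at read time: masses ≥ 0;
`mass_chaff_g + mass_grain_g ≤ mass_reproductive_g ≤ biomass_total_g`;
`duration_days > 0`; packaging counts both present or both absent.

## Growth table (one row per harvested seedling)

| column | unit | description |
|---|---|---|
| `species_id` | — | taxon label |
| `accession_id` | — | accession label (or `pooled`) |
| `block_id` | — | growth-experiment block |
| `day` | days | days since germination |
| `mass_g` | g | whole-plant dry mass |

## Tree

Newick with branch lengths; rooted; ultrametric within 1e-6 relative
tolerance; tip labels must equal the trait table's `species_id` set.
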