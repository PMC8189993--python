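# Packaged data dictionary

All tables are comma-separated UTF-8 with a mandatory header row and "."
decimal point; the readers accept user files in the same dialect.

## `reference_summaries.csv` (48 rows: 47 species + Typical)

| column | type | meaning |
|---|---|---|
| `species_code` | str | primary key (culture short-code, e.g. `A10b`); binomials are display metadata only |
| `binomial` | str | species name as identified on collection |
| `n` | int | individuals summarised (20 throughout) |
| `IL_mean`, `IL_sd` | µm | idiosomal index (body-size surrogate) |
| `CLI_mean`, `CLI_sd` | µm | cheliceral length (reach) |
| `L2M_mean`, `L2M_sd` | µm | moveable-digit length (gape) |
| `VR_mean`, `VR_sd` | – | velocity ratio `L1U/L2M`, mean of per-individual values |
| `F2AV_mean`, `F2AV_sd` | µm² | consensus crunch force, mean of per-individual values |
| `CHI_mean`, `CHI_sd` | µm | cheliceral height |
| `L1U_mean`, `L1U_sd` | µm | chelal input lever |

## `species_metadata.csv` (47 rows)

| column | meaning |
|---|---|
| `superfamily`, `family`, `subfamily` | taxonomic placement (subfamily empty where none is given) |
| `pest` | bool; one of the nine recognised stored-product pest species |
| `published_group` | `omnivore` / `fragmentary` — the published 21/26 binary split used in hypothesis tests (not rule-derivable for specialists; never recomputed) |
| `published_habit` | `surface` / `interstitial` — the published 20/27 split |
| `fig23_group` | published four-way functional group (`omnivore_type1`, `fragmentary_type2`, `small_omnivore`, `specialist`) |
| `specialist_sublabel` | free text for specialist sub-designs |
| `habitat_flags` | free text, empty by default (no machine-readable habitat data is published) |

## `comparative_records.csv` (41 rows)

Cross-suborder records (oribatids plus two mesostigmatids) carried verbatim
from their source studies: `taxon`, `leverage_or_VR` (–), `PHI_squared`
(µm², squared cheliceral height), `product` (µm², ≈ crunch-force
surrogate), `gape` (µm), `reach` (µm), `designation` (source study's
trophic label), `source`.  Some radio-isotope-study rows have
`product ≠ leverage_or_VR × PHI_squared`; they are not reconciled.

## `published_verbal_codes.csv` (48 rows)

The transcribed 8-slot verbal trophic coding (`size`, `reach`, `rel_reach`,
`hardness`, `grip`, `food_size`, `grab`, `stuffing`) for every species and
the Typical row — verification data for the descriptor coder.

## `published_summaries.csv` (47 rows)

The published per-species narrative (`summary`), display data; the
classifier's token-level output is tested against it.

## `constants.yaml`

Versioned numeric constants: the condyle inflation factor and adductor
shaft fraction; the typical reference moments; the nomogram weights and
normalisers; the cross-suborder band thresholds and the pest-range
toughness constant.
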