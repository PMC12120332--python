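# CSV column schemas

All tables are comma-separated with a header row. Timestamps are ISO-8601
and interpreted as UTC; distances are river-kilometres downstream of the
release site (0 at release). A column-name mapping can be passed to every
reader to absorb local dialects (`read_*(path, rename={...})`).

## detections.csv (also marine_detections.csv)

| column      | type      | notes                                   |
|-------------|-----------|-----------------------------------------|
| tag_code    | string    | acoustic transmitter code               |
| receiver_id | string    | receiver that heard the transmission    |
| timestamp   | datetime  | ISO-8601, UTC                           |

## fish.csv

| column           | type     | notes                                    |
|------------------|----------|------------------------------------------|
| fish_id          | string   | unique fish identifier                   |
| tag_code         | string   | unique within a year's active window     |
| river            | string   |                                          |
| year             | integer  |                                          |
| release_datetime | datetime | ISO-8601, UTC                            |
| fork_length_mm   | float    | may be missing                           |
| mass_g           | float    | may be missing                           |
| tag_mass_g       | float    | mass of the implanted tag in air         |
| release_site_km  | float    | 0 by convention                          |

## receivers.csv

| column      | type    | notes                                          |
|-------------|---------|------------------------------------------------|
| river       | string  |                                                |
| year        | integer |                                                |
| role        | string  | "first" (below release) or "last" (river mouth); exactly one of each per river-year |
| receiver_id | string  |                                                |
| river_km    | float   | last must be strictly downstream of first      |
| elevation_m | float   | used for the river gradient                    |

## discharge.csv

| column        | type     | notes                    |
|---------------|----------|--------------------------|
| river         | string   |                          |
| year          | integer  |                          |
| date          | datetime | daily resolution         |
| discharge_m3s | float    | daily mean discharge     |

## catchments.csv

| column       | type    | notes                                            |
|--------------|---------|--------------------------------------------------|
| river        | string  |                                                  |
| grassland    | float   | proportion of catchment cover, in [0, 1]         |
| woodland     | float   | proportion                                       |
| wetland      | float   | proportion                                       |
| urban        | float   | proportion                                       |
| agricultural | float   | proportion (five covers sum to at most 1)        |
| peat         | float   | proportion of superficial geology, in [0, 1]     |
| bedrock      | string  | dominant class: igneous, metamorphic, sedimentary |
| area_km2     | float   | catchment area                                   |
| gradient     | float   | elevation drop / river distance (m m^-1)         |
| barriers     | integer | artificial barriers between the two receivers    |

## Filter report (JSON)

`FilterReport.to_json()` writes `n_input`, `duplicates`, `out_of_window`,
`unknown_tag`, `retained`, `removed`; the three defect-class counts sum to
`removed = n_input - retained`.
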