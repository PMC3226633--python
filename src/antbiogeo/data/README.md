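# Packaged printed-table fixtures

Verbatim transcriptions of the three summary tables printed in the published
2005–2009 All Taxa Biodiversity Inventory of ants in the Boston Harbor Islands
National Recreation Area (Boston, MA, USA). The full event-level field dataset
is not distributed with these tables; these fixtures support inventory
arithmetic and regression tests only.

- `island_occurrences.tsv` — island-by-island occurrence counts for the 51
  collected species ("occurrence" = appearance in any single collecting event
  at an island). Total across all cells is 3,311.
- `island_geography.tsv` — per-island sampling statistics: terrestrial area
  above the high-tide line (km²), distance to nearest mainland (km), number of
  sampling events, observed species, and individuals collected.
- `diversity_summary.tsv` — per-island observed species, rarefaction-based
  asymptotic estimates of active species (mean ± 1 SD, annual and average
  week), mean species per sampling event, spatial turnover, and weekly
  Bray-Curtis temporal turnover, plus the park-wide totals row.

Island names are normalized to a single canonical spelling per island
("Worlds End", "Great Brewster"); the printed tables vary ("Word's End",
"Words End", "Gr. Brewster").

Known internal inconsistencies of the printed tables are preserved, not
reconciled: the geography table's observed-species column disagrees with the
summary table for Grape (37 vs 36), Langlee (32 vs 30), Ragged (27 vs 25),
Snake (22 vs 21), Spectacle (22 vs 21), Thompson (40 vs 38) and Worlds End
(40 vs 39). The summary table is consistent with the nonzero cell counts of
the occurrence table and is the reference for tests.
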