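# Methods

## Model

The package estimates above-ground living-biomass carbon by the
volume-expansion route used in national inventories.  For each forest type a
single representative stem of dimensions (DBH, H) — the type's database mean —
is evaluated through the species' stem-volume equation for the ecozone at
hand, scaled by stand density `N` to a per-hectare growing stock `V_stand`,
and converted to carbon density with the species-weighted product
`EF · D · CF`.  A grid cell's carbon is the density times the allocated area;
a landscape total is the sum over cells.

Assumptions worth stating explicitly:

- **One representative stem per type.** `V_stand = N · V_stem(DBH̄, H̄)`,
  not an average over a stem list.  With convex (log-log) volume equations
  this underestimates the stand mean volume for a given DBH spread; the
  Monte Carlo module quantifies exactly this sensitivity.
- **Above-ground only.** The general inventory form with a combined
  biomass conversion/expansion factor and a below-ground ratio
  (`C = A·V·BCEF·(1+R)·CF`) is implemented (`carbon_storage_bcef`) but
  disabled by default: the data this model targets support only the
  `EF·D·CF` above-ground route.
- **One ecozone per cell.**  A cell straddling a zone boundary is assigned
  wholly to one zone; sub-cell ecozone mixing is not represented.
- **No disturbance over the sequestration year.**  The one-year update
  `C_next = C·(1+G)(1−M)` assumes stable land use and no harvest, fire or
  pest losses.  This is a documented model assumption, not a checked
  condition.

The sequestration formulas are implemented in the form consistent with the
definition ΔC = C_next − C, i.e. ΔC = C[(1+G)(1−M) − 1] and ΔC_A = ΔC/A.
Printed renderings of these relations elsewhere sometimes carry a stray
(1+G)(1−M) factor; the forms here are the dimensionally consistent ones, and
the bundled summary tables corroborate them (the largest natural broadleaved
type's ΔC/C and ΔC_A/C_A agree to rounding).

## Units

Internal carbon unit is tonnes C everywhere; megatonnes (Mt C) appear only at
report formatting.  Areas are kept as integer m² inside grid cells (the land
use database's stated 1-m² precision) and converted to hectares once per
computation.  Rates G and M are fractions per year internally; the stand
parameter CSV may declare percent units with a `# rate_units: percent`
header line.

## Monte Carlo design

- One (DBH, H) draw per varied forest type per iteration — stand-level, not
  per-stem, variability.  Per-stem draws would shrink the interval by
  ~1/√(N·A) and could not produce the survey-scale type-level intervals of
  tens of percent.
- Draws are independent normals truncated at zero by resampling; resampling
  preserves unimodality and avoids sign pathologies near zero means.
- By default the 26 state-owned forest types vary; newly added, private,
  bamboo and bamboo-mixed types are held at their point estimates.
- Percentiles use linear interpolation between order statistics
  (`numpy.percentile` default), stated so results are reproducible across
  implementations.
- Labeling: survey convention labels the numerically *lower* carbon bound
  with the 97.5th percentile of the error distribution.  The API exposes
  unambiguous `c_lower`/`c_upper`; the fixtures keep the printed sign
  convention for relative bounds.
- Identical seed and configuration give bit-identical results; draws are
  made in the fixed order of the configured varied-type list, so the result
  does not depend on which types happen to occur in the landscape.

## Synthetic world

The generator replaces the unavailable survey databases.  What it emulates:

- A rectangular grid of 1-km² cells with five ecozones in latitudinal
  bands (or Voronoi blobs), ~10% no-data cells, and ~40% non-forest area
  per cell (island forest cover is a little under 60%).
- One to four forest types per cell with a skewed type-area distribution
  (the widespread natural mixed-broadleaved, private broadleaved and
  conifer–broadleaf mixed types get higher sampling weight), allocations in
  integer m² summing to at most 10⁶ per cell.
- Log-log (Schumacher–Hall form) stem-volume equations per species and
  ecozone.  The intercept is anchored to a plausible reference-stem volume
  (e.g. 0.4–0.8 m³ for a 30 cm/20 m conifer, 0.015–0.04 m³ for an
  8 cm/12 m bamboo culm) so that exponent draws cannot push predictions out
  of the realistic envelope; ±15% per-ecozone jitter stands in for climatic
  morphology differences.
- Conversion parameters per taxonomic group: EF 1.1–2.0, D 0.35–0.8,
  CF 0.45–0.52.  The "mixed conifer"/"mixed broadleaf" pseudo-species get
  the mean EF/D/CF of their group's concrete species, mirroring how
  composite types are parameterized in practice.
- Stand density with a self-thinning correction (stands of
  larger-than-typical stems carry proportionally fewer of them), G in
  1–6%/yr, M in 0.2–2%/yr, DBH/H standard deviations at 20% of the mean —
  the magnitude required to reproduce type-level 95% intervals of roughly
  −35%/+50%, as published surveys show.

Realized carbon densities span ≈7–280 t C ha⁻¹ across seeds (median ≈80),
matching the magnitude of the published 7–222 t C ha⁻¹ span.  The generator
makes no attempt to reproduce the published *totals*: that would require the
actual parameter databases.  A green pipeline test therefore establishes
internal consistency (grid/aggregation equivalence, algebraic identities,
statistical calibration of the Monte Carlo machinery) — not agreement with
the published landscape numbers, which are checked separately through the
bundled printed-table fixtures.

Printed cells below table resolution ("<0.005", "<0.05") are loaded as an
explicit `BelowThreshold` sentinel; aggregate checks that would touch them
use the printed subtotal rows instead.

## Numerical choices

- Landscape totals accumulate per-(cell, type) contributions with
  `math.fsum`, so types-then-cells and cells-then-types marginalization
  give the same grand total bit for bit.
- Effective species parameters are weight-summed in sorted species order
  with exact summation — reordering a weight list cannot change any value.
- Class maps use left-open/right-closed intervals (a value equal to a break
  falls in the lower class), the common choropleth-legend convention; the
  boundary convention is asserted in tests.
- ESRI ASCII rasters serialize floats with `repr`, making write/read
  round-trips bit-exact.
- Nonpositive DBH/H reaching the carbon chain is a hard error; only the
  Monte Carlo sampler, which truncates by resampling, may generate and
  handle such draws.

## Known limitations

- Soil, dead wood, litter and below-ground pools are out of scope.
- Only DBH and H carry uncertainty; EF, D, CF, N, G, M, areas and equation
  coefficients are treated as exact.
- Multi-year projection with land-use change is not supported; the
  sequestration update is a single no-disturbance year.
- No geodetic reprojection; the grid is a plain row-major raster with a
  1,000 m cell size from a northwest origin.
- The published "Average" rows mix inconsistent conventions; summary tables
  therefore emit both the area-weighted mean (total mass / total area) and
  the unweighted mean of per-type densities rather than guessing.
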