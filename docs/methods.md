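# Methods

## Scope and units of analysis

`swrisk` assesses risk to raw drinking water at the sub-watershed level.
Sub-watershed delineation is *not* performed here: the package consumes a
sub-watershed label raster (or pre-tabulated areas) produced by standard
DEM tooling. The two assessments are independent and joined only at the
reporting stage: the hazard-quotient screen describes measured, current
water quality at monitoring stations; the S × P × E matrix ranks potential
sources by likelihood-and-consequence reasoning, without requiring
source-specific monitoring.

## Hazard quotients

HQ = exposure / threshold, with HQ > 1 flagging an exceedance. Two
exposures are screened per station × parameter: the record mean (chronic)
and the record maximum (acute). Quotients are carried unrounded; only the
reporting layer rounds, half-up to two decimals, because rounding inside
the pipeline would compound (half-up rather than banker's rounding matches
how compliance tables are conventionally printed). Exceedance flags use the
strict comparison HQ > 1.0 on the unrounded value, so HQ = 1.00 exactly is
not an exceedance.

Parameters whose standard is a lower limit (dissolved oxygen) or a range
(pH) are never converted into a reciprocal quotient; they are reported with
absent HQs plus the fraction of samples inside the safe range. When only a
summary (min/max envelope) is available that fraction is 1.0 if the
envelope is inside the range and *indeterminate* (None) otherwise — a
deliberate refusal to guess a compliance rate a summary cannot support;
supplying raw values yields the exact fraction.

### Standards

The built-in registry holds the Taiwan EPA Class A surface-water criteria
and the drinking-water quality standards. Cells the regulation leaves
unspecified are absent and produce a distinguishable not-found error rather
than a silent zero. Three naming decisions:

* parameter labels are normalised through an alias table
  ("total phosphorus" ↔ "TP", "ammonia nitrogen" ↔ "NH3-N", …), since
  monitoring files and regulation tables rarely agree on labels;
* total coliform counts screen against the Class A *E. coli* row
  (50 CFU/100 mL). The regulatory intent is arguable (coliforms are an
  indicator group, not *E. coli* per se), but this is the convention the
  TSWA screening tables themselves use, so the package follows it;
* suspended solids (Class A) and total dissolved solids (drinking) are
  distinct parameters and never cross-compared.

## Censoring policy

Non-detects are first-class records carrying their detection limit.
`summarize` computes n, n-detected, mean, min and max over the value set a
named policy selects: `detected_only` (default) or substitution by 0, DL/2
or DL. The default is `detected_only` because published screening summaries
report ranges starting at detected minima, which only that policy
reproduces; the choice is a flag everywhere it matters. For fully detected
data all four policies agree exactly, and means are non-decreasing in the
order zero ≤ half-DL ≤ DL. Statistics pool the full record span per station
(no monthly weighting). Means use compensated summation (`math.fsum`) so
summaries are invariant to record order.

## Buffer zones and the spatial engine

Distance to stream is the Euclidean distance between cell centers to the
nearest stream-mask cell (scipy's exact distance transform with
`sampling=cell_size`), not a flow-path distance. Whether the mask includes
reservoir cells is the user's call — "proximity to water" can reasonably
mean either.

Zone bins are closed on the upper edge: [0, 50], (50, 250], (250, 1000],
(1000, ∞) metres. Published zone labels ("0–50 / 50–250") overlap at shared
endpoints; upper-inclusive is fixed arbitrarily and documented, and no
reference area in the shipped fixtures sits on a boundary, so any
consistent convention reproduces them. The same style of decision applies
to the extent bins (lower-inclusive, top-clamped: <0.01% → 1, [0.01, 0.1)
→ 2, [0.1, 1) → 3, ≥1% → 4); this convention reproduces all four reference
E assignments.

Area tabulation counts cells, so per-(sub-watershed, class) zone areas sum
exactly to the class total — conservation is an integer identity, with only
the final float multiplication by cell-area subject to rounding. NODATA
cells are excluded from all tabulations. Areas are carried in m²
internally; land-use basin tables use km² at I/O.

Rasters travel as ESRI ASCII grids — a line-oriented text format read and
written directly (numpy-backed), losslessly for integer layers. A bypass
accepts pre-tabulated zone-area CSVs so the qualitative model runs without
any geometry, which is also how the shipped case-study fixture enters.

## The S × P × E matrix

S is derived from two booleans (pathogen source?, major source?) mapping to
4/3/2/1 as pathogen∧major / pathogen / major / neither. P maps the four
zones to 4..1 inward-out. E comes from the activity's percent of its *own
sub-watershed's* total area (not basin or zone area). R = S × P × E per
zone, in [1, 64]; the aggregate is the unweighted arithmetic mean of R over
zones where the activity is actually present. Zones with zero activity area
are excluded by default — averaging in vacuous zones would dilute risk —
with `include_empty_zones` restoring strict four-zone averaging (the
reference assessment has all four zones occupied, so both conventions
reproduce it). Bands: low ≤ 6 < medium ≤ 9 < high ≤ 16 < very high. The
scale is comparative, built to rank activities for further investigation;
R = 64 is not "four times the risk" of R = 16.

Point-like sources (recreation spots, outfalls) have no meaningful areal
percent; declared P/E overrides on the source characterization take
precedence over computed levels. Multiple sources in one sub-watershed are
assessed independently; `rollup_sources` (unweighted mean of their
aggregates, then banded) is provided as an explicitly interpretive roll-up.

## Synthetic generator

`gen_monitoring` emulates a monthly grab-sampling campaign: concentrations
are lognormal — strictly positive, right-skewed, consistent with summaries
whose mean sits far below the maximum — with an optional multiplicative
sinusoidal seasonal factor `1 + A·sin(2π(month − phase)/12)` (emulating
summer peaks in suspended solids). Draws below the detection limit become
non-detects. Default parameter models (e.g. coliforms LN(ln 800, 1.5²)
CFU/100 mL, TP LN(ln 0.03, 0.8²) mg/L with DL 0.013) were chosen once to
give raw-water orders of magnitude typical of a forested source-water area.
`gen_watershed` rasterizes a stream polyline, a background land-use class
with rectangular activity patches, and an axis-aligned sub-watershed
partition. Both generators are deterministic under their seed.

What the generator does *not* emulate: rainfall–runoff dynamics,
autocorrelation between months, inter-parameter correlation, laboratory
error structure, or irregular sampling. Tests passing on synthetic data
therefore demonstrate correctness of the pipeline arithmetic and its
statistical conventions, not calibration to any real watershed.

The `tswa_*` fixtures embed the printed summary tables of the Taipei
Source Water Area case study (station screening summaries, the A002
tea-growing zone areas and total, basin land-use areas, sub-watershed
attributes) verbatim — printed numbers only, nothing interpolated from
figures. One internal inconsistency in that source material is preserved
rather than repaired: the A008 total-phosphorus average quotient is
tabulated as 1.42, which traces to an unrounded mean near 0.0284, while
the mean itself is printed to three decimals as 0.028 (giving 1.40); the
corresponding test documents and exposes the discrepancy. The basin
land-use table likewise carries its published basin totals (Bei-Shih
classes sum to 316.99 km² against a printed total of 316.9), and those
published totals are used as percentage denominators.

## Reporting

Pollutant ranking keys on the max-over-stations chronic quotient
(`hq_avg`), with `hq_max` then parameter name as tie-breaks — the chronic
screen is the sustained-concern signal; the acute maximum breaks ties.
Range/lower-limit parameters cannot rank by HQ and are listed in a trailing
block rather than dropped. Land-use percentages round half-up to one
decimal. Report CSVs are written deterministically (fixed column order,
fixed line terminator): identical inputs give identical bytes.

## Problem sizes

The shipped tests run the spatial oracle comparison on 100 random grids up
to 50 × 50, and statistical recovery checks on 10,000-sample synthetic
series at 3-standard-error tolerances; the whole suite completes in a few
seconds on one CPU.

## Known limitations

* Buffer zones are straight-line distance bands; no flow routing, slope
  interaction or attenuation modelling.
* The qualitative scale is ordinal and comparative; aggregate scores of
  different sources are averaged un-weighted, which is one defensible
  reading among several.
* Only the A002 pathway of the reference qualitative assessment is
  reproducible end-to-end; per-zone geometry for the other sub-watersheds
  was never published, so they are covered by property tests only.
* Raw sample-level records behind the reference summaries are unpublished;
  the summary → HQ step is verified exactly, the raw → summary step only
  on synthetic data.
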