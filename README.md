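# swrisk

Integrated risk screening for drinking-water source watersheds.

Watersheds supplying surface drinking water need two complementary views of
risk. Current condition: are monitored concentrations already exceeding the
water-quality criteria for a raw-water source? Potential risk: which land
uses and activities, in which sub-watersheds, are most likely to degrade
water quality next? `swrisk` implements both and joins them into ranked,
per-sub-watershed reports. It is written for watershed managers and
environmental-health analysts working from routine monitoring CSVs, a
standards table, and either GIS rasters or pre-tabulated buffer-zone areas.

## The model

**Quantitative screen — hazard quotients.** For each station × parameter,

&nbsp;&nbsp;&nbsp;&nbsp;HQ = exposure / threshold

where the exposure is the station mean (chronic screen, `hq_avg`) or
maximum (acute screen, `hq_max`) of the monitoring record, and the
threshold is the parameter's standard — by default the Taiwan EPA Class A
surface-water criteria (e.g. TP ≤ 0.02 mg/L, coliforms ≤ 50 CFU/100 mL).
HQ > 1 means exposure exceeds the allowable limit. Dissolved oxygen
(lower-limit standard) and pH (two-sided range) have no meaningful upper
ratio; they are reported as the fraction of samples inside the safe range.
Non-detects in the monitoring record are handled by an explicit censoring
policy (`detected_only` by default; zero / half-DL / DL substitution
available).

**Qualitative screen — the S × P × E matrix.** Each potential pollution
source in a sub-watershed is scored 1–4 on three factors: source
characteristics **S** (pathogen vs non-pathogenic, major vs minor),
proximity to water **P** (riparian buffer zone: 0–50 m → 4, 50–250 m → 3,
250–1,000 m → 2, >1,000 m → 1), and spatial extent **E** (percent of the
sub-watershed occupied: ≥1% → 4 down to <0.01% → 1). The per-zone product
R = S × P × E is averaged over occupied zones and classified into four
bands: low (≤6), medium (≤9), high (≤16), very high (>16). Buffer zones
come either from a raster distance-to-stream transform (ESRI ASCII grids)
or from a pre-tabulated zone-area CSV.

## Worked example

Screening the three treatment-plant intake stations of the Taipei Source
Water Area (summaries shipped as fixtures) against the Class A standards,
then scoring tea-growing in sub-watershed A002:

```python
from swrisk import default_registry, hq_table, assess, SourceCharacterization
from swrisk.synthetic import tswa_summaries, tswa_zone_areas
from swrisk.report import rank_pollutants

results = hq_table(tswa_summaries(), default_registry(), "class_a")
print(rank_pollutants(results).head(3).to_string(index=False))

risk = assess(
    tswa_zone_areas(),
    SourceCharacterization("tea-growing", pathogen_source=False, major_source=True),
)
for z in risk.zones:
    print(f"{z.zone.label:>10}  {z.percent:5.1f}%  P={z.p_level} E={z.e_level}  R={z.r}")
print(f"aggregate R = {risk.aggregate_r}  band = {risk.band.value}")
```

prints

```
 rank        parameter  hq_avg  hq_max station
    1  Total coliforms   60.96   740.0    B006
    2 Total phosphorus    4.65    29.0    C003
    3 Ammonia nitrogen    1.35    17.0    C003

    0-50 m    0.6%  P=4 E=3  R=24
  50-250 m    3.1%  P=3 E=4  R=24
250-1000 m    6.8%  P=2 E=4  R=16
   >1000 m    3.8%  P=1 E=4  R=8
aggregate R = 18.0  band = very_high
```

Total coliforms are the top parameter of concern (worst station mean 61×
the Class A limit), followed by total phosphorus. Tea-growing occupies
0.6–6.8% of A002's area across the four buffer zones; the aggregate score
18 classifies it as a very-high-risk source.

## Command line

Every stage is also a `swrisk` subcommand over the same library:

```sh
swrisk standards dump                          # built-in standard sets as YAML
swrisk synth monitoring --seed 3 --out m.csv   # synthetic monthly monitoring
swrisk monitoring summarize m.csv --out s.csv  # censored summaries
swrisk hq s.csv --standard-set class_a         # hazard-quotient table
swrisk synth watershed --seed 1 --out-dir g/   # synthetic rasters (.asc)
swrisk spatial zones --landuse g/landuse.asc --stream g/stream.asc \
       --activity-class 1 --out zones.csv      # buffer-zone areas
swrisk qualrisk zones.csv --no-pathogen --major  # S x P x E assessment
swrisk report --summaries s.csv --zones zones.csv --out-dir report/
```

Monitoring CSV schema: columns `station, date, parameter, value, detected
(0/1), detection_limit`; non-detects may also be written `<0.013` in the
value column. Zone-area CSV schema: `subwatershed, class, zone,
activity_area_m2, subwatershed_area_m2`.

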