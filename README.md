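# vulnindex

District-level health-equity analysis built around a composite
vulnerability index. The package is written for health-systems and
epidemiology researchers who need to ask, for a state-run hospital
insurance scheme: *are the services the scheme pays for actually
available where the most vulnerable people live?*

It implements, end to end, the analysis design used to study
geographical inequity in Chhattisgarh state's universal hospital
insurance scheme (RSBY/MSBY, financial year 2015–16, 27 districts),
ships the published district data, and provides a synthetic state
generator so every stage can be tested without any external data.

## The method

1. **Composite vulnerability index (VI).** Each of k district-level
   socio-economic indicators X_i (by default five: SC/ST population
   share, un-irrigated net sown area, female illiteracy, rural
   population share, and year of district formation) is min-max
   normalized across districts,

       Y_i = (X_i − X_min) / (X_max − X_min),

   oriented so Y_i = 1 always marks the most vulnerable extreme, and the
   VI is the unweighted sum Σ_i Y_i ∈ [0, k] (the HDI recipe with equal
   weights; the mean is available as an option and changes no ranking).

2. **Tertiles.** Districts are ranked on the VI (rank 1 = most
   vulnerable) and split into highest / middle / lowest vulnerability
   groups (HVD / MVD / LVD) of as-equal-as-possible size.

3. **Scheme indicators.** Availability and utilization are expressed
   per 100,000 *enrolled* persons — empanelled hospitals, claim counts
   and claim amounts (INR lakh), each split by public/private sector —
   with group-level rates pooled (Σ numerators / Σ enrolled).

4. **Inequality.** Between-group inequality is summarized by the rate
   ratio (LVD/HVD and MVD/HVD) and the rate difference.

5. **Association.** Pearson's r between the VI and each indicator
   across districts, with two-sided p-values from
   t = r√(n−2)/√(1−r²) (df = n−2) and 95% confidence intervals from the
   Fisher z-transform, tanh(atanh r ± z₀.₉₇₅/√(n−3)).

6. **Mapping.** Tertile labels and rates are joined onto district
   boundary polygons and exported as GeoJSON for any downstream viewer.

## Worked example

Correlate the packaged published vulnerability index with hospital
availability across the 27 Chhattisgarh districts:

```python
from vulnindex import load_chhattisgarh, correlation_table
from vulnindex.association import correlations_to_frame

df = load_chhattisgarh("district_table")
res = correlation_table(df, vi="vi", indicators=[
    "hospitals_per_100k", "public_hospitals_per_100k",
    "private_hospitals_per_100k",
])
print(correlations_to_frame(res).round(3).to_string(index=False))
```

prints

```
                 indicator      r  n  p_value  ci_lower  ci_upper significant
        hospitals_per_100k -0.583 27    0.001    -0.788    -0.261           *
 public_hospitals_per_100k  0.414 27    0.032     0.041     0.686           *
private_hospitals_per_100k -0.750 27    0.000    -0.879    -0.518           *
```

Overall hospital availability falls significantly as vulnerability
rises (r = −0.583), driven entirely by the private sector
(r = −0.750); public hospital availability actually rises with
vulnerability (r = 0.414). This is the Inverse Care Law in the data:
availability varies inversely with need.

The same analysis is available from the shell, along with the other
stages:

```sh
vulnindex reproduce --outdir reproduction    # published tables from packaged data
vulnindex simulate --seed 9 --outdir sim     # synthetic state panel + boundaries
vulnindex pipeline --input sim/state_table.csv --outdir out
vulnindex map --input sim/state_table.csv --boundaries sim/boundaries.geojson
```

`reproduce` writes the re-ranked tertiles (9/9/9 districts, VI ranges
4.9–3.7 / 3.6–2.9 / 2.9–0.2), the full correlation table, and the
recomputed MVD:HVD and LVD:HVD ratio columns (e.g. total hospitals
per 100,000 enrolled: 8.2 in LVDs vs 3.4 in HVDs, ratio 2.4; private
hospitals 10).

## Layout

- `vulnindex.data_model` — district records, state tables, CSV I/O
- `vulnindex.datasets` — packaged published district/tertile data
- `vulnindex.index` — normalization, composite index, ranking, tertiles
- `vulnindex.rates` — per-100,000-enrolled indicators, pooled aggregates
- `vulnindex.inequality` — rate ratios and differences
- `vulnindex.association` — Pearson r, p-values, Fisher-z intervals
- `vulnindex.geo` — choropleth GeoJSON export
- `vulnindex.synthetic` — synthetic state generator, recovery experiment
- `vulnindex.pipeline`, `vulnindex.cli` — orchestration and CLI

See `docs/methods.md` for modelling assumptions, parameter defaults and
known limitations.
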