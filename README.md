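# pharmpec

Convert national pharmaceutical **wholesale records** — packages sold per
product per year — into annual **sales masses per active pharmaceutical
ingredient (API)** and worst-case **surface-water predicted environmental
concentrations (PEC_SW)**, with the evaluation toolkit such screening work
needs (Bland–Altman agreement analysis, DDD-based prescription comparison,
per-capita normalisation, extreme-change flagging).

It is written for environmental chemists and risk assessors who have access
to product-level sales data (or want to prototype against realistic
synthetic data) and need substance-level mass and exposure estimates.

## The computation

Three tables describe the source: a product catalogue (ATC code, medium,
package quantity), a product–API strength table, and a sales table. The
pipeline computes

    grams(api, year) = Σ_products  strength × package_quantity × packages_sold

after standardising strengths (mg/pill, mg/mL, mg/g, percent, …) and
package quantities (pills, litres, grams) through an editable unit
dictionary, splitting combination products into one entry per constituent
API, and applying an exclusion cascade: exempt classes (vaccines, vitamins,
antibodies) → non-mass units (international units) → negative sales
(returns) → gas APIs → low-volume products (< 1000 packages over the
window, except antibiotics and sex hormones) → zero/unit-less records.
Every stage reports its removal counts, split human vs veterinary.

Annual masses then feed the standard worst-case exposure screen

    PEC_SW = M × (1 − f_removal) / (365 × Q_ww × P × D)

with M the grams sold in a year, f_removal the WWTP removal fraction
(default 0), Q_ww per-capita wastewater (L person⁻¹ day⁻¹), P the
population and D the dilution factor (default 10).

Because real wholesale databases are confidential, the package includes a
synthetic-database generator with exactly known ground truth (`synthgen`),
so the whole pipeline is verifiable end to end without any external data.

## Worked example

```python
from pharmpec import synthgen, filters, pec

config = synthgen.GeneratorConfig(n_products=200, seed=7)
products, product_apis, sales, truth = synthgen.generate(config)

frame, report = filters.run_cascade(products, product_apis, sales)
annual = filters.aggregate_annual(frame)
filters.stage_counts(report, annual)
print(report.to_frame().to_string(index=False))
print("unique APIs per year:", report.unique_apis_per_year)

w = max(annual, key=lambda w: w.grams)
r = pec.compute_pec(w, pec.PECParameters(population=5.3e6))
print(f"largest mass: {w.api_name} {w.year}: {w.grams:.4g} g -> PEC {r.pec_ng_per_L:.4g} ng/L")
```

prints

```
         stage  records_in  records_removed  records_out  products_human_removed  products_vet_removed
        exempt        1173              100         1073                      13                     1
      non_mass        1073               76          997                      11                     1
negative_sales         997               28          969                      24                     3
           gas         969               18          951                       3                     0
    low_volume         951               58          893                      13                     0
 zero_unitless         893                0          893                       0                     0
unique APIs per year: {2016: 155, 2017: 156, 2018: 158, 2019: 160}
largest mass: paracetine 2016: 3.369e+05 g -> PEC 87.07 ng/L
```

Reading it: 1173 joined (product, API, sales-row) records enter the
cascade; each stage removes its share (in − removed = out, and the counts
reconcile exactly), leaving 893 records that aggregate to between 155 and
160 distinct APIs per year. The largest single annual mass, 3.4 × 10⁵ g of
a synthetic high-volume analgesic, corresponds under worst-case default
parameters (no treatment removal, 200 L person⁻¹ day⁻¹ wastewater, 5.3
million people, dilution 10) to a screening concentration of 87 ng L⁻¹ in
receiving surface waters.

The same pipeline is available from the shell:

```sh
pharmpec generate --n-products 200 --seed 7 --out synth
pharmpec weights --products synth/products.csv \
  --product-apis synth/product_apis.csv --sales synth/sales.csv --out results
pharmpec pec --weights results/annual_api_weights.csv --out results/pec.csv
pharmpec evaluate --weights results/annual_api_weights.csv --out results
```

Real exports in the same column layout (see `docs/methods.md`) can be fed
to `weights`/`pec`/`evaluate` directly.

## Layout

- `src/pharmpec/synthgen.py` — synthetic database generator + ground truth
- `src/pharmpec/ingest.py` — table readers, ATC parsing, integrity checks
- `src/pharmpec/decompose.py` — unit standardisation, per-package masses,
  combination splitting, ATC↔API map
- `src/pharmpec/filters.py` — exclusion cascade, stage accounting, annual
  aggregation
- `src/pharmpec/pec.py` — exposure equation and per-capita normalisation
- `src/pharmpec/evaluate.py` — Bland–Altman, DDD comparison, extreme-change
  flagging and categorisation
- `src/pharmpec/cli.py` — `pharmpec` command-line interface
- `docs/methods.md` — model, conventions, and design notes
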