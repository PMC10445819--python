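# Methods

## The problem

National drug wholesale registries record, per product and year, how many
*packages* were sold. Environmental exposure screening needs something
different: the *mass* of each active pharmaceutical ingredient (API) that
entered circulation, because ecotoxicological thresholds are defined per
substance, not per product or per ATC code. `pharmpec` performs that
conversion and the downstream worst-case exposure estimate, and provides the
evaluation tools used to sanity-check such a dataset.

## From packages to grams

The mass of an API sold in a year is

    grams(api, year) = Σ_products strength × package_quantity × packages_sold

where the strength is the API concentration in the product (per item, per
volume, or per mass of medium) and the package quantity is the amount of
medium per package (pills, litres, grams). The two factors arrive in
heterogeneous units; the unit dictionary (an editable CSV resource,
`pharmpec/data/units.csv`) normalises strengths to g/item, g/L or g/g and
package quantities to counts, litres or grams, and the product of the two is
the grams-per-package figure. Records that cannot be converted are never
silently dropped: they carry a status (`non_mass` for international units,
`missing` with a reason for unknown symbols or dimensional mismatches) and
are removed at a named stage of the cascade with their counts reported.

Conventions worth stating explicitly:

* **Bare mass units** ("500 mg") are read as mass per item, the labelling
  convention for solid dose forms.
* **Percent strengths** are w/v (1% = 10 g/L) for liquid media and w/w
  (1% = 0.01 g/g) for semi-solid media, selected by the product's medium
  type; a bare `%` with no usable medium is treated as unconvertible rather
  than guessed.
* **Micro-sign variants** (µg, μg, ug, mcg) normalise to one symbol. The
  dictionary is deliberately explicit and every conversion is reconstructable,
  because unit-prefix mistakes (mg read as µg) are a documented failure mode
  of this kind of data work.
* **Salt forms**: the full stated strength mass is attributed to the API.
  No free-base molecular-weight correction is applied; a salt-factor hook
  exists but ships empty. This overestimates the active moiety's mass for
  heavy counter-ions and is the conservative choice for screening.
* **Precedence**: when a record carries both a raw strength and a directly
  supplied per-package amount in a mass unit, the direct value wins — it
  represents upstream manual curation.

Combination products (one ATC code, several APIs) are split into one
per-package mass per constituent, so splitting conserves mass by
construction. The observed (ATC, API) pairs also yield the many-to-many
ATC↔API map, maintained in both directions.

## The exclusion cascade

Six stages, each a predicate on attributes fixed before the cascade runs
(hence the final kept set is order-invariant, which the tests assert by
permuting stages):

1. **exempt** — classes exempt from environmental risk assessment on
   non-toxicity grounds (vaccines, vitamins, antibodies), identified by ATC
   ranges (J07/A11/J06 and veterinary counterparts) and by class keywords
   on the product record;
2. **non-mass** — strengths in international units and other dose-undefined
   units, for which no mass can be computed;
3. **negative sales** — return/disposal rows. Default policy is *drop* (the
   returned packages do not reduce the sold mass); a *netting* mode
   (returns offset the same product-year's sales, floored at zero) exists
   for sensitivity analysis;
4. **gas** — gas APIs (anaesthetic gases), identified by medium type;
5. **low-volume** — products with fewer than 1000 packages summed over the
   study window. "Below 1000" is strict: exactly 1000 is kept. Antibiotic
   (J01/QJ01) and sex-hormone (G03/QG03) ranges are exempt from this
   removal as categories of special interest. The predicate uses raw
   positive package counts, so it commutes with the returns stage;
6. **zero/unit-less** — zero-gram, zero-package and unconvertible records.

Each stage reports records in / removed / out (an exact accounting
identity) and unique products removed, split human vs veterinary by the ATC
Q prefix. Surviving records aggregate to grams per API per year; zero-gram
annual rows are not emitted.

## Exposure model

    PEC_SW = M × (1 − f_removal) / (365 × Q_ww × P × D)

with M grams sold per year, f_removal the WWTP removal fraction (default 0),
Q_ww per-capita wastewater in L person⁻¹ day⁻¹ (default 200, the standard
screening default; real runs should supply national per-year statistics),
P the population, and D the dilution factor (default 10). The defaults are
worst-case on purpose: zero removal, zero metabolism, and a dilution far
below the 50–75 reported for deep coastal outfalls, so the output is an
upper screening bound, not a fate prediction. PEC is linear in M and in
(1 − f_removal) and inversely proportional to each denominator term; the
test suite asserts these scaling laws to machine precision. Output is in
g L⁻¹ with a ng L⁻¹ convenience column. Per-capita normalised masses
(g person⁻¹ yr⁻¹) support trend comparison across years and studies.

## Evaluation toolkit

**Bland–Altman (Tukey mean-difference)** on log10 masses: per-pair
difference vs per-pair mean, mean difference, and limits of agreement at
mean ± 1.96·sd (sample sd). The limits bound *individual* differences;
a CI-of-mean mode (±1.96·sd/√n) is available behind a flag for users who
want the confidence interval of the bias instead. Pairs with a zero or
missing value on either side are excluded and counted — the log transform
is undefined for them, and known-erroneous pairs are handled the same way.

**DDD comparison**: prescription registries report consumption in defined
daily doses; count × grams-per-DDD gives a mass comparable with the
wholesale figure. Where one ATC code carries several DDD values (routes of
administration), the highest is used, since DDD-denominated data does not
distinguish routes — this biases the prescription-derived mass upward,
which is the right direction for a completeness check of wholesale data.
A panel of common drugs ships as a packaged CSV fixture.

**Extreme-change flagging**: an API is shortlisted when some year's mass is
more than a factor (default 10) above or below its mean over the window.
An algebraic note: with n strictly positive years, max/mean < n, so for a
4-year window the mean-based rule can *only* fire on the small side. The
two-sided mean rule is therefore the default (it matches how such
shortlists are drawn in practice), and a leave-one-out variant — each year
against the mean of the remaining years — is offered for genuine
single-year spikes; both are reported when they disagree. Shortlisted APIs
are categorised from an annotation table (marketing-authorisation events,
supply shortages, unexplained; unannotated APIs are `unclassified`), with
counts and computed percentages. The annotation table for the 2016–2019
national screening shortlist ships as a packaged fixture.

## Synthetic data generator

The real wholesale source is confidential, so the generator produces a
stand-in with *exactly known* ground truth. It emulates the features that
drive pipeline behaviour: combination products; human and Q-prefixed
veterinary ATC codes built level-by-level (always syntactically valid);
strengths across per-item, per-volume, per-mass, percent, and
international-unit conventions; exempt classes marked both by ATC range and
by keyword; gas products; sub-threshold low-volume products, including
antibiotic/sex-hormone ones that the threshold spares; negative return
rows; and step changes from mid-window (de)registration. Defaults describe
a four-year national window (2016–2019), ~10% veterinary share, mean sales
of 5000 packages per product-year, and small minority fractions for the
special classes — plausible magnitudes for a small national market, chosen
once and fixed.

Category membership is drawn per product as independent Bernoulli trials,
so realised fractions carry binomial sampling error (tested with a 3σ
bound). Products with any removal-relevant trait get API names unique to
them, so each API's removal flags are unambiguous; a shared-API pool among
plain products exercises aggregation across products. All randomness flows
from one seed; identical config + seed gives byte-identical CSVs. The
low-volume intent is derived from a per-product sub-seed so the catalogue
and sales stages agree without sharing a stream.

The ground-truth oracle recomputes grams by straight-line per-record
enumeration — deliberately independent of the pipeline's unit machinery and
pandas path — and flags each API with its expected removal reasons. The
headline test: on a 500-product, 4-year database the full pipeline
(including a CSV write/read round-trip) reproduces ground-truth grams for
every eligible API to better than 1e-9 relative (measured: ~3e-16), and no
exempt or gas API leaks into the final aggregate.

What the generator does **not** emulate: real market composition, brand
names, price data, manual strength curation against product-information
sites, and genuinely malformed exports beyond simple type errors. Passing
tests therefore demonstrate the correctness of the computation and the
cascade semantics, not robustness to every artefact of a real registry
export.

## Numerical and degenerate-input choices

* Aggregation and recovery comparisons use relative tolerance 1e-9;
  unit round-trips 1e-12. All arithmetic is double precision.
* Duplicate (year, product) sales rows are summed — the schema permits
  them and the source's uniqueness guarantee is unknown.
* Empty sales tables yield empty outputs and zero-count reports, not
  errors; a product with no strength rows yields an all-missing record
  flagged for manual sourcing.
* Boundary: exactly 1000 packages is kept; a PEC of 0 arises exactly for
  zero mass or complete removal.
* Problem sizes in the tests and acceptance script (500 products, 4 years,
  10,000 random series for the flagging bound) are small enough to run in
  seconds while leaving every code path exercised.

## Known limitations

* No salt/free-base correction (deliberate, see above), no metabolite
  fractions, no WWTP-removal database, no marine/fjord compartment, no
  spatial routing.
* The shipped unit dictionary is a practical superset of the units named in
  national exports; any real export should be reviewed against it (unknown
  symbols surface in the removal counts rather than failing).
* Identification of exempt classes by ATC range and keyword is a heuristic
  stand-in for a curated exemption registry.
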