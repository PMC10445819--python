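"""Synthetic wholesale database generator with exactly known ground truth.

The confidential national wholesale source cannot be redistributed, so this
module generates a statistically similar stand-in: a product catalogue, a
product–API strength table, and a multi-year sales table, together with the
exact annual grams of every API computed by direct enumeration.  Every
downstream stage — ingestion, unit standardisation, the exclusion cascade,
aggregation — can then be verified against a known answer.

The generator emulates the features of the real database that drive the
pipeline's behaviour: single and combination products; human and veterinary
(Q-prefixed) ATC codes; strengths in mass-per-item, mass-per-volume,
mass-per-mass, and percent conventions; non-mass (international-unit)
strengths; exempt product classes (vaccines, vitamins, antibodies); gas
APIs; low-volume products below the 1000-package threshold, including
antibiotic and sex-hormone products that the threshold spares; negative
sales records (returns); and step changes in multi-year series from
product (de)registration.  It makes no attempt to match any real market's
brand names, prices, or product mix.

All randomness flows from a single seed: identical configuration and seed
give byte-identical output tables.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, fields as dataclass_fields
from pathlib import Path
from typing import Sequence

import numpy as np

from .ingest import (
    ProductAPIRecord,
    ProductRecord,
    ReferentialIntegrityError,
    SalesRecord,
    write_product_apis,
    write_products,
    write_sales,
)

__all__ = [
    "GeneratorConfig",
    "ApiFlags",
    "GroundTruth",
    "generate_catalogue",
    "generate_sales",
    "generate",
    "ground_truth_weights",
    "write_tables",
]

#: base lexicon for API names; per-product names get a numeric suffix so an
#: API's removal flags are unambiguous, while a small shared pool exercises
#: aggregation across products
_LEXICON = (
    "paracetine", "ibuprofanil", "amoxirol", "metoprene", "atorvin",
    "sertralon", "omeprazil", "simvastol", "losartil", "diclofast",
    "cetirizan", "ramiprol", "warfaxin", "tramadene", "gabapentol",
    "fluoxamin", "prednisol", "azithrin", "ciprofloxil", "doxycyclan",
    "estradiol", "levothyrin", "metformol", "salbutol",
)
_SHARED_POOL = ("paracetine", "ibuprofanil", "omeprazil", "cetirizan")

_ORDINARY_ANATOMICAL = "ABCDHLMNPRS"  # avoids V (allergen range) and special J/G handled separately


def _intended_low_volume(config: "GeneratorConfig", product_code: int) -> bool:
    """Per-product low-volume intent, derived deterministically from the seed
    and product code so the catalogue and sales stages agree without sharing
    generator state."""
    sub = np.random.default_rng([config.seed, product_code, 0xB10B])
    return bool(sub.random() < config.low_volume_frac)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic wholesale database.

    Defaults mirror a national four-year study window: a market where
    roughly one product in ten is veterinary, combination products are a
    modest minority, a few percent of products sit in risk-assessment-exempt
    classes or use international units, and mean sales are in the thousands
    of packages per product-year so only a deliberate low-volume subset
    falls under the 1000-package threshold.
    """

    n_products: int = 500
    years: tuple[int, ...] = (2016, 2017, 2018, 2019)
    seed: int = 0
    frac_combination: float = 0.15
    frac_exempt: float = 0.05
    frac_veterinary: float = 0.10
    frac_nonmass_units: float = 0.05
    frac_gas: float = 0.02
    neg_sale_rate: float = 0.05
    low_volume_frac: float = 0.10
    sales_scale: float = 5000.0
    frac_special_interest: float = 0.08  # antibiotic / sex-hormone ATC ranges
    frac_shared_api: float = 0.20        # ordinary products reusing a pool API
    step_change_rate: float = 0.10       # products (de)registered mid-window
    negative_policy: str = "drop"        # ground-truth treatment of returns

    def __post_init__(self) -> None:
        if self.n_products < 1:
            raise ValueError("n_products must be >= 1")
        if not self.years:
            raise ValueError("years must be non-empty")
        if any(b <= a for a, b in zip(self.years, self.years[1:])):
            raise ValueError("years must be strictly increasing")
        if not self.sales_scale > 0:
            raise ValueError("sales_scale must be > 0")
        if self.negative_policy not in {"drop", "net"}:
            raise ValueError("negative_policy must be 'drop' or 'net'")
        for f in dataclass_fields(self):
            if f.name.startswith("frac_") or f.name in {"neg_sale_rate", "low_volume_frac"}:
                v = getattr(self, f.name)
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"{f.name} must be within [0, 1], got {v}")


@dataclass(frozen=True)
class ApiFlags:
    """Why (if at all) an API leaves the pipeline before the final aggregate."""

    exempt: bool = False
    gas: bool = False
    non_mass: bool = False
    low_volume: bool = False

    @property
    def eligible(self) -> bool:
        return not (self.exempt or self.gas or self.non_mass or self.low_volume)


@dataclass
class GroundTruth:
    """Exact annual grams per API, by direct per-record enumeration.

    ``entries`` maps (api_name, year) → grams; ``flags`` records, per API,
    whether it belongs to an exempt class, is a gas, is sold in non-mass
    units, or is carried only by sub-threshold (low-volume) products.
    """

    entries: dict[tuple[str, int], float] = field(default_factory=dict)
    flags: dict[str, ApiFlags] = field(default_factory=dict)

    def eligible_entries(self) -> dict[tuple[str, int], float]:
        return {
            (api, year): grams
            for (api, year), grams in self.entries.items()
            if self.flags[api].eligible
        }


# --------------------------------------------------------------------------
# internal per-product plan (not exported; regenerated from the tables by
# ground_truth_weights so the oracle works on the tables alone)
# --------------------------------------------------------------------------


def _draw_atc(rng: np.random.Generator, *, veterinary: bool, exempt_class: str | None,
              gas: bool, special: str | None) -> str:
    """Build a syntactically valid ATC code level-by-level."""
    letters = "ABCDEFGHJKLMNPRSTVWX"
    if exempt_class is not None:
        prefix = {"vaccine": "J07", "vitamin": "A11", "antibody": "J06"}[exempt_class]
        body = prefix + "".join(rng.choice(list(letters), 2)) + f"{rng.integers(1, 100):02d}"
    elif gas:
        body = "N01AB" + f"{rng.integers(1, 100):02d}"
    elif special is not None:
        prefix = {"antibiotic": "J01", "sex_hormone": "G03"}[special]
        body = prefix + "".join(rng.choice(list(letters), 2)) + f"{rng.integers(1, 100):02d}"
    else:
        while True:
            body = (
                str(rng.choice(list(_ORDINARY_ANATOMICAL)))
                + f"{rng.integers(1, 100):02d}"
                + "".join(rng.choice(list(letters), 2))
                + f"{rng.integers(1, 100):02d}"
            )
            # keep clear of the reserved exempt/special/gas ranges
            if not body.startswith(("J07", "J06", "A11", "J01", "G03", "N01AB", "V01")):
                break
    return ("Q" + body) if veterinary else body


def generate_catalogue(
    config: GeneratorConfig,
) -> tuple[list[ProductRecord], list[ProductAPIRecord]]:
    """Generate the product catalogue and strength table.

    Category membership (combination, exempt, veterinary, non-mass, gas,
    low-volume, special-interest) is drawn per product as independent
    Bernoulli trials at the configured fractions, so realised counts follow
    binomial sampling error around them.
    """
    rng = np.random.default_rng(config.seed)
    products: list[ProductRecord] = []
    product_apis: list[ProductAPIRecord] = []

    for i in range(config.n_products):
        code = 1000 + i
        veterinary = rng.random() < config.frac_veterinary
        exempt = rng.random() < config.frac_exempt
        exempt_class = (
            str(rng.choice(["vaccine", "vitamin", "antibody"])) if exempt else None
        )
        gas = (not exempt) and rng.random() < config.frac_gas
        special = None
        if not exempt and not gas and rng.random() < config.frac_special_interest:
            special = str(rng.choice(["antibiotic", "sex_hormone"]))
        combination = rng.random() < config.frac_combination
        n_apis = int(rng.integers(2, 4)) if combination else 1
        non_mass = rng.random() < config.frac_nonmass_units
        low_volume = _intended_low_volume(config, code)

        atc = _draw_atc(
            rng, veterinary=veterinary, exempt_class=exempt_class, gas=gas, special=special
        )
        if gas:
            product_type, qty, qty_unit = "gas", float(rng.integers(1, 20)), "l"
        else:
            product_type = str(rng.choice(["pill", "fluid", "cream"], p=[0.7, 0.2, 0.1]))
            if product_type == "pill":
                qty, qty_unit = float(rng.integers(10, 101)), "pills"
            elif product_type == "fluid":
                qty, qty_unit = float(rng.choice([50, 100, 250, 500])), "ml"
            else:
                qty, qty_unit = float(rng.choice([30, 50, 100])), "g"

        # an API name may be shared across plain products; any product with a
        # removal-relevant trait gets its own suffixed names so its flags are
        # unambiguous
        plain = not (exempt or gas or non_mass or low_volume or special)
        api_names: list[str] = []
        for j in range(n_apis):
            if (
                plain
                and j == 0
                and n_apis == 1
                and rng.random() < config.frac_shared_api
            ):
                api_names.append(str(rng.choice(list(_SHARED_POOL))))
            else:
                base = str(rng.choice(list(_LEXICON)))
                api_names.append(f"{base}-{code}" if n_apis == 1 else f"{base}-{code}.{j + 1}")

        details = exempt_class or ""
        products.append(
            ProductRecord(
                product_code=code,
                product_name=f"Synthprod {code}",
                atc_code=atc,
                product_details=details,
                product_type=product_type,
                product_group=1,
                package_quantity_value=qty,
                package_quantity_unit=qty_unit,
                n_api_per_product=n_apis,
            )
        )

        for api in api_names:
            if non_mass:
                value = float(rng.integers(100, 1001))
                unit = "IU"
            elif gas:
                # gases carry a nominal mass-per-volume strength; they are
                # removed by the gas stage regardless
                value, unit = float(rng.integers(1, 10)), "mg/ml"
            elif product_type == "pill":
                value = float(rng.choice([5, 10, 20, 25, 50, 100, 200, 250, 500]))
                unit = str(rng.choice(["mg", "mg/tablet"]))
            elif product_type == "fluid":
                value, unit = float(rng.integers(1, 51)), "mg/ml"
            else:  # cream
                if rng.random() < 0.2:
                    value, unit = float(rng.choice([1, 2, 5])), "%"
                else:
                    value, unit = float(rng.integers(1, 51)), "mg/g"
            rec = ProductAPIRecord(
                product_code=code,
                api_name=api,
                strength_value=value,
                strength_unit=unit,
            )
            # a minority of rows also carry the pre-computed per-package
            # amount, exercising the direct-value precedence path
            if not non_mass and not gas and rng.random() < 0.1:
                grams = _strength_to_grams(value, unit, product_type, qty, qty_unit)
                if grams is not None:
                    rec.amount_per_package_value = grams
                    rec.amount_per_package_unit = "g"
            product_apis.append(rec)
    return products, product_apis


def generate_sales(
    catalogue: tuple[list[ProductRecord], list[ProductAPIRecord]] | list[ProductRecord],
    config: GeneratorConfig,
) -> list[SalesRecord]:
    """Generate multi-year sales with returns, step changes, and low-volume
    products guaranteed below the 1000-package threshold.

    Sales draws are seeded independently of the catalogue (seed + 1) so the
    two stages can be regenerated separately yet reproducibly.
    """
    products = catalogue[0] if isinstance(catalogue, tuple) else catalogue
    if not products:
        raise ValueError("catalogue must be non-empty")
    rng = np.random.default_rng(config.seed + 1)
    years = list(config.years)
    sales: list[SalesRecord] = []
    for p in products:
        low_volume = _intended_low_volume(config, p.product_code)
        active = list(years)
        if len(years) > 1 and rng.random() < config.step_change_rate:
            k = int(rng.integers(1, len(years)))
            active = years[k:] if rng.random() < 0.5 else years[:k]
        if low_volume:
            # spread a sub-threshold total across the active years
            total = int(rng.integers(0, 1000))
            shares = rng.multinomial(total, [1 / len(active)] * len(active))
            per_year = {y: int(s) for y, s in zip(active, shares)}
        else:
            # floor guarantees the multi-year total stays above threshold
            floor = int(np.ceil(1000 / len(active)))
            per_year = {
                y: int(rng.poisson(config.sales_scale)) + floor for y in active
            }
        for y in years:
            packages = per_year.get(y, None)
            if packages is None:
                continue  # not registered that year: no record at all
            if packages > 10 and rng.random() < 0.3:
                split = int(rng.integers(1, packages))
                sales.append(SalesRecord(year=y, product_code=p.product_code,
                                         packages_sold=float(split)))
                sales.append(SalesRecord(year=y, product_code=p.product_code,
                                         packages_sold=float(packages - split)))
            else:
                sales.append(SalesRecord(year=y, product_code=p.product_code,
                                         packages_sold=float(packages)))
            if rng.random() < config.neg_sale_rate:
                returned = int(rng.integers(1, max(2, packages // 20 + 2)))
                sales.append(SalesRecord(year=y, product_code=p.product_code,
                                         packages_sold=float(-returned)))
    return sales


def generate(
    config: GeneratorConfig,
) -> tuple[list[ProductRecord], list[ProductAPIRecord], list[SalesRecord], GroundTruth]:
    """Full generation: catalogue, sales, and the ground-truth oracle."""
    products, product_apis = generate_catalogue(config)
    sales = generate_sales((products, product_apis), config)
    truth = ground_truth_weights((products, product_apis), sales, config=config)
    return products, product_apis, sales, truth


# --------------------------------------------------------------------------
# Ground truth by direct enumeration
# --------------------------------------------------------------------------

_MASS_G = {"g": 1.0, "mg": 1e-3, "ug": 1e-6, "kg": 1e3}


def _strength_to_grams(
    value: float, unit: str, product_type: str, qty: float, qty_unit: str
) -> float | None:
    """Direct grams-per-package conversion for the generator's unit set.

    Deliberately written as straight-line arithmetic, independent of the
    pipeline's unit machinery, so it can serve as an oracle for it.
    """
    u = unit.strip().lower()
    q = qty_unit.strip().lower()
    if u in {"iu", "ie"}:
        return None
    if u in _MASS_G and q in {"pills", "pill", "tablets", "tablet", "capsules", "doses"}:
        return value * _MASS_G[u] * qty
    if "/" in u:
        num, _, den = u.partition("/")
        if num in _MASS_G:
            if den == "ml" and q == "ml":
                return value * _MASS_G[num] * qty
            if den == "l" and q == "l":
                return value * _MASS_G[num] * qty
            if den == "ml" and q == "l":
                # mass/mL equals mass g/L numerically: scale by litres sold
                return value * _MASS_G[num] * 1000.0 * qty
            if den in _MASS_G and q in _MASS_G:
                return value * _MASS_G[num] / _MASS_G[den] * qty * _MASS_G[q]
            if den in {"tablet", "pill", "dose"} and q in {"pills", "tablets", "doses"}:
                return value * _MASS_G[num] * qty
    if u == "%" and product_type == "cream" and q in _MASS_G:
        return value / 100.0 * qty * _MASS_G[q]
    return None


def _product_traits(
    products: Sequence[ProductRecord], config: GeneratorConfig
) -> dict[int, dict[str, bool]]:
    """Re-derive category traits from the tables themselves (not from the
    generator's private draws), so the oracle needs only the tables."""
    special_prefixes = ("J01", "QJ01", "G03", "QG03")
    exempt_prefixes = ("J07", "QJ07", "A11", "QA11", "J06", "QJ06")
    traits: dict[int, dict[str, bool]] = {}
    for p in products:
        traits[p.product_code] = {
            "exempt": p.atc_code.startswith(exempt_prefixes) or bool(p.product_details),
            "gas": p.product_type == "gas",
            "special": p.atc_code.startswith(special_prefixes),
            "low_volume": False,  # filled in once sales are known
        }
    return traits


def ground_truth_weights(
    catalogue: tuple[Sequence[ProductRecord], Sequence[ProductAPIRecord]],
    sales: Sequence[SalesRecord],
    *,
    config: GeneratorConfig | None = None,
    low_sales_threshold: int = 1000,
) -> GroundTruth:
    """Exact per-API annual grams by brute-force enumeration of the tables.

    Returns and negative rows follow the configured policy (``drop``
    ignores them, matching the pipeline's default; ``net`` offsets them
    within each product-year, floored at zero).  The low-volume flag marks
    APIs carried only by products whose summed positive packages over all
    years fall below the threshold and whose ATC is not in the
    special-interest antibiotic/sex-hormone ranges.

    Raises
    ------
    ReferentialIntegrityError
        If a sales or strength row references an unknown product code.
    """
    products, product_apis = catalogue
    policy = config.negative_policy if config is not None else "drop"
    by_code = {p.product_code: p for p in products}
    for s in sales:
        if s.product_code not in by_code:
            raise ReferentialIntegrityError(f"sales row references unknown product {s.product_code}")
    strengths: dict[int, list[ProductAPIRecord]] = {}
    for pa in product_apis:
        if pa.product_code not in by_code:
            raise ReferentialIntegrityError(
                f"strength row references unknown product {pa.product_code}"
            )
        strengths.setdefault(pa.product_code, []).append(pa)

    # net packages per (product, year) under the chosen returns policy
    packages: dict[tuple[int, int], float] = {}
    pos_totals: dict[int, float] = {}
    for s in sales:
        key = (s.product_code, s.year)
        if policy == "drop":
            if s.packages_sold > 0:
                packages[key] = packages.get(key, 0.0) + s.packages_sold
        else:
            packages[key] = packages.get(key, 0.0) + s.packages_sold
        if s.packages_sold > 0:
            pos_totals[s.product_code] = pos_totals.get(s.product_code, 0.0) + s.packages_sold
    if policy == "net":
        packages = {k: max(v, 0.0) for k, v in packages.items()}
    years_by_product: dict[int, set[int]] = {}
    for code, year in packages:
        years_by_product.setdefault(code, set()).add(year)

    traits = _product_traits(products, GeneratorConfig() if config is None else config)
    for code, t in traits.items():
        t["low_volume"] = (
            not t["special"] and pos_totals.get(code, 0.0) < low_sales_threshold
        )

    truth = GroundTruth()
    for p in products:
        t = traits[p.product_code]
        for pa in strengths.get(p.product_code, []):
            if pa.amount_per_package_value is not None and pa.amount_per_package_unit:
                grams_pkg = pa.amount_per_package_value * _MASS_G.get(
                    pa.amount_per_package_unit.strip().lower(), float("nan")
                )
            elif pa.strength_value is not None:
                grams_pkg = _strength_to_grams(
                    pa.strength_value, pa.strength_unit, p.product_type,
                    p.package_quantity_value or 0.0, p.package_quantity_unit,
                )
            else:
                grams_pkg = None
            non_mass = grams_pkg is None
            prev = truth.flags.get(pa.api_name, ApiFlags())
            truth.flags[pa.api_name] = ApiFlags(
                exempt=prev.exempt or t["exempt"],
                gas=prev.gas or t["gas"],
                non_mass=prev.non_mass or non_mass,
                low_volume=prev.low_volume or t["low_volume"],
            )
            if grams_pkg is None:
                continue
            for year in years_by_product.get(p.product_code, {}):
                n = packages[(p.product_code, year)]
                if n <= 0:
                    continue
                key = (pa.api_name, year)
                truth.entries[key] = truth.entries.get(key, 0.0) + grams_pkg * n
    truth.entries = {k: v for k, v in truth.entries.items() if v > 0}
    return truth


# --------------------------------------------------------------------------
# Output
# --------------------------------------------------------------------------


def write_tables(
    out_dir: str | Path,
    products: Sequence[ProductRecord],
    product_apis: Sequence[ProductAPIRecord],
    sales: Sequence[SalesRecord],
    truth: GroundTruth | None = None,
) -> dict[str, Path]:
    """Write the three tables (and optionally the ground truth) as CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "products": out / "products.csv",
        "product_apis": out / "product_apis.csv",
        "sales": out / "sales.csv",
    }
    write_products(paths["products"], products)
    write_product_apis(paths["product_apis"], product_apis)
    write_sales(paths["sales"], sales)
    if truth is not None:
        paths["ground_truth"] = out / "ground_truth.csv"
        with paths["ground_truth"].open("w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(["api_name", "year", "grams", "exempt", "gas", "non_mass", "low_volume"])
            for (api, year), grams in sorted(truth.entries.items()):
                f = truth.flags[api]
                w.writerow([api, year, repr(grams), int(f.exempt), int(f.gas),
                            int(f.non_mass), int(f.low_volume)])
    return paths
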