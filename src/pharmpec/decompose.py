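"""Strength standardisation, per-package API masses, and combination splitting.

The per-package mass of an API is the product of two factors recorded in
different units across the source: the *strength* (API concentration per
item, per volume, or per mass of medium) and the *package quantity* (number
of items, litres, or grams of medium per package).  This module normalises
both to SI-consistent standards — grams per item, grams per litre, grams
per gram — and multiplies them, recording a status instead of failing when
a record cannot be converted (non-mass units such as international units,
unknown symbols, dimensional mismatches).

Combination products carry one strength row per constituent API and are
split into one per-package mass per API, so no substance is lost when a
single ATC code covers a cocktail.

Salt forms: the full stated strength mass is attributed to the API — no
free-base molecular-weight correction is applied.  A hook for an optional
salt-factor table exists but ships empty.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .ingest import ProductAPIRecord, ProductRecord

__all__ = [
    "UnitDictionary",
    "UnknownUnitError",
    "PackageAmount",
    "AtcApiMap",
    "load_default_units",
    "standardise_concentration",
    "grams_per_package",
    "split_combination",
    "compute_package_amounts",
    "build_atc_api_map",
]

CONVERTED = "converted"
NON_MASS = "non_mass"
MISSING = "missing"

#: media treated as liquids (percent strengths read as w/v, g per 100 mL)
LIQUID_MEDIA = {"fluid", "liquid", "solution", "suspension", "syrup", "drops"}
#: media treated as semi-solid or solid (percent strengths read as w/w)
SEMISOLID_MEDIA = {"cream", "ointment", "gel", "paste", "powder", "semisolid"}


class UnknownUnitError(ValueError):
    """A strength or package unit symbol is not in the unit dictionary."""


def _normalise_symbol(symbol: str) -> str:
    """Canonicalise a unit symbol: case, micro-sign variants, whitespace."""
    s = symbol.strip().lower()
    s = s.replace("µ", "u").replace("μ", "u")  # µ, μ -> u
    s = s.replace("mcg", "ug")
    s = re.sub(r"\s+", " ", s)
    s = s.replace(" / ", "/").replace(" /", "/").replace("/ ", "/")
    return s


@dataclass
class UnitDictionary:
    """Unit symbol → conversion tables, loaded from an editable CSV resource.

    ``mass_units`` map to grams; ``per_volume_units`` to grams per litre;
    ``per_mass_units`` to grams per gram of medium; ``package_count_units``
    and ``package_volume_units`` classify package-quantity units (counts and
    litres).  ``non_mass_units`` (international units and kin) are
    recognised but not convertible to mass.
    """

    mass_units: dict[str, float] = field(default_factory=dict)
    per_volume_units: dict[str, float] = field(default_factory=dict)
    per_mass_units: dict[str, float] = field(default_factory=dict)
    non_mass_units: set[str] = field(default_factory=set)
    package_count_units: set[str] = field(default_factory=set)
    package_volume_units: dict[str, float] = field(default_factory=dict)
    percent_wv_multiplier: float = 10.0  # 1% w/v = 10 g/L
    percent_ww_multiplier: float = 0.01  # 1% w/w = 0.01 g/g

    def __post_init__(self) -> None:
        strength_cats = [
            set(self.mass_units),
            set(self.per_volume_units),
            set(self.per_mass_units),
            self.non_mass_units,
        ]
        seen: set[str] = set()
        for cat in strength_cats:
            dup = seen & cat
            if dup:
                raise ValueError(f"unit symbol(s) in two categories: {sorted(dup)}")
            seen |= cat
        for table in (self.mass_units, self.per_volume_units, self.per_mass_units,
                      self.package_volume_units):
            for sym, mult in table.items():
                if not mult > 0:
                    raise ValueError(f"unit {sym!r}: multiplier must be > 0")

    @classmethod
    def from_csv(cls, path: str | Path) -> "UnitDictionary":
        d = cls()
        with Path(path).open(newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                sym = _normalise_symbol(row["symbol"])
                cat = row["category"].strip()
                mult = float(row["multiplier"]) if row["multiplier"].strip() else None
                if cat == "mass":
                    d.mass_units[sym] = mult
                elif cat == "per_volume":
                    d.per_volume_units[sym] = mult
                elif cat == "per_mass":
                    d.per_mass_units[sym] = mult
                elif cat == "percent_wv":
                    d.percent_wv_multiplier = mult
                elif cat == "percent_ww":
                    d.percent_ww_multiplier = mult
                elif cat == "percent":
                    pass  # context-dependent; handled in standardise_concentration
                elif cat == "non_mass":
                    d.non_mass_units.add(sym)
                elif cat == "package_count":
                    d.package_count_units.add(sym)
                elif cat == "package_volume":
                    d.package_volume_units[sym] = mult
                else:
                    raise ValueError(f"unknown unit category {cat!r} for {sym!r}")
        d.__post_init__()
        return d


def load_default_units() -> UnitDictionary:
    """Load the unit dictionary shipped with the package."""
    with resources.as_file(
        resources.files("pharmpec.data").joinpath("units.csv")
    ) as path:
        return UnitDictionary.from_csv(path)


@dataclass
class PackageAmount:
    """Grams of one API in one package of one product, with conversion status."""

    product_code: int
    api_name: str
    grams_per_package: float | None
    status: str  # converted | non_mass | missing
    reason: str = ""

    def __post_init__(self) -> None:
        if self.status == CONVERTED:
            if self.grams_per_package is None or not self.grams_per_package >= 0:
                raise ValueError(
                    f"product {self.product_code}/{self.api_name}: converted amount "
                    "must be finite and >= 0"
                )


def standardise_concentration(
    strength_value: float,
    strength_unit: str,
    unit_dict: UnitDictionary,
    *,
    medium: str | None = None,
) -> tuple[str, float | None]:
    """Classify a strength and convert it to its standard unit.

    Returns ``(kind, value)`` with kind one of ``per_item`` (grams per
    item), ``per_volume`` (grams per litre), ``per_mass`` (grams per gram of
    medium) or ``non_mass`` (value ``None``).  Bare mass units (``500 mg``)
    are read as mass per item, the labelling convention for solid forms.
    Percent strengths are w/v for liquid media and w/w for semi-solid ones.

    Raises
    ------
    UnknownUnitError
        For symbols absent from the dictionary (these feed the unit-less
        removal stage downstream), and for a bare ``%`` with no medium to
        disambiguate it.
    """
    sym = _normalise_symbol(strength_unit)
    if not sym:
        raise UnknownUnitError("empty strength unit")
    if sym in unit_dict.non_mass_units:
        return NON_MASS, None
    if sym in unit_dict.mass_units:
        return "per_item", strength_value * unit_dict.mass_units[sym]
    if sym in unit_dict.per_volume_units:
        return "per_volume", strength_value * unit_dict.per_volume_units[sym]
    if sym in unit_dict.per_mass_units:
        return "per_mass", strength_value * unit_dict.per_mass_units[sym]
    if sym in {"%w/v", "% w/v"}:
        return "per_volume", strength_value * unit_dict.percent_wv_multiplier
    if sym in {"%w/w", "% w/w"}:
        return "per_mass", strength_value * unit_dict.percent_ww_multiplier
    if sym == "%":
        if medium in LIQUID_MEDIA:
            return "per_volume", strength_value * unit_dict.percent_wv_multiplier
        if medium in SEMISOLID_MEDIA:
            return "per_mass", strength_value * unit_dict.percent_ww_multiplier
        raise UnknownUnitError(
            f"percent strength needs a liquid or semi-solid medium, got {medium!r}"
        )
    # compositional fallback: "<mass>/<denominator>"
    if "/" in sym:
        num, _, den = sym.partition("/")
        if num in unit_dict.mass_units:
            grams = unit_dict.mass_units[num]
            if den in unit_dict.package_volume_units:
                return "per_volume", strength_value * grams / unit_dict.package_volume_units[den]
            if den in unit_dict.mass_units:
                return "per_mass", strength_value * grams / unit_dict.mass_units[den]
            if den in unit_dict.package_count_units:
                return "per_item", strength_value * grams
    raise UnknownUnitError(f"unknown strength unit symbol {strength_unit!r}")


def grams_per_package(
    kind: str,
    value: float | None,
    package_quantity_value: float | None,
    package_quantity_unit: str,
    unit_dict: UnitDictionary,
    *,
    product_code: int = 0,
    api_name: str = "",
) -> PackageAmount:
    """Combine a standardised concentration with the package quantity.

    grams per package = concentration × quantity, with the quantity
    interpreted per the concentration kind: item counts for per-item,
    litres for per-volume, grams of medium for per-mass.  A dimensional
    mismatch (e.g. a per-volume strength on a pill-count package) yields
    ``status='missing'`` with the reason recorded — nothing is fatal here.
    """

    def missing(reason: str) -> PackageAmount:
        return PackageAmount(product_code, api_name, None, MISSING, reason)

    if kind == NON_MASS:
        return PackageAmount(product_code, api_name, None, NON_MASS, "non-mass strength unit")
    if value is None or not value >= 0:
        return missing(f"invalid standardised concentration {value!r}")
    if package_quantity_value is None or not package_quantity_value > 0:
        return missing("missing or non-positive package quantity")

    qsym = _normalise_symbol(package_quantity_unit)
    if kind == "per_item":
        if qsym not in unit_dict.package_count_units:
            return missing(f"per-item strength with non-count package unit {package_quantity_unit!r}")
        grams = value * package_quantity_value
    elif kind == "per_volume":
        if qsym not in unit_dict.package_volume_units:
            return missing(f"per-volume strength with non-volume package unit {package_quantity_unit!r}")
        litres = package_quantity_value * unit_dict.package_volume_units[qsym]
        grams = value * litres
    elif kind == "per_mass":
        if qsym not in unit_dict.mass_units:
            return missing(f"per-mass strength with non-mass package unit {package_quantity_unit!r}")
        medium_grams = package_quantity_value * unit_dict.mass_units[qsym]
        grams = value * medium_grams
    else:
        return missing(f"unknown concentration kind {kind!r}")
    return PackageAmount(product_code, api_name, grams, CONVERTED)


def split_combination(
    product: ProductRecord,
    strengths: Sequence[ProductAPIRecord],
    unit_dict: UnitDictionary,
) -> list[PackageAmount]:
    """Per-package mass for every constituent API of one product.

    Single-API products pass through unchanged; combination products yield
    one :class:`PackageAmount` per strength row, so the total package mass
    is the sum over constituents.  A product with no strength rows at all
    returns a single all-missing amount flagged for manual sourcing.  When a
    strength row carries a directly supplied per-package amount in a mass
    unit, that value wins over re-deriving from the raw strength.
    """
    if not strengths:
        return [
            PackageAmount(
                product.product_code, "", None, MISSING,
                "no strength rows; manual sourcing required",
            )
        ]
    out: list[PackageAmount] = []
    for s in strengths:
        if s.product_code != product.product_code:
            raise ValueError(
                f"strength row for product {s.product_code} passed with product "
                f"{product.product_code}"
            )
        if s.exclude:
            out.append(
                PackageAmount(product.product_code, s.api_name, None, MISSING,
                              "excluded by source Exclude flag")
            )
            continue
        # direct per-package amount takes precedence
        if s.amount_per_package_value is not None and s.amount_per_package_unit:
            asym = _normalise_symbol(s.amount_per_package_unit)
            if asym in unit_dict.mass_units:
                grams = s.amount_per_package_value * unit_dict.mass_units[asym]
                out.append(
                    PackageAmount(product.product_code, s.api_name, grams, CONVERTED)
                )
                continue
        # otherwise standardise the strength (preferring the standardised
        # per-item concentration column when filled)
        value, unit = s.strength_value, s.strength_unit
        if s.conc_per_item_value is not None and s.conc_per_item_unit:
            value, unit = s.conc_per_item_value, s.conc_per_item_unit
        if value is None or not unit:
            out.append(
                PackageAmount(product.product_code, s.api_name, None, MISSING,
                              "no usable strength value/unit")
            )
            continue
        try:
            kind, std = standardise_concentration(
                value, unit, unit_dict, medium=product.product_type
            )
        except UnknownUnitError as exc:
            out.append(
                PackageAmount(product.product_code, s.api_name, None, MISSING, str(exc))
            )
            continue
        out.append(
            grams_per_package(
                kind, std, product.package_quantity_value,
                product.package_quantity_unit, unit_dict,
                product_code=product.product_code, api_name=s.api_name,
            )
        )
    return out


def compute_package_amounts(
    products: Iterable[ProductRecord],
    product_apis: Iterable[ProductAPIRecord],
    unit_dict: UnitDictionary | None = None,
) -> list[PackageAmount]:
    """Split every product in the catalogue into per-API package masses."""
    unit_dict = unit_dict or load_default_units()
    by_product: dict[int, list[ProductAPIRecord]] = {}
    for pa in product_apis:
        by_product.setdefault(pa.product_code, []).append(pa)
    out: list[PackageAmount] = []
    for p in products:
        out.extend(split_combination(p, by_product.get(p.product_code, []), unit_dict))
    return out


@dataclass
class AtcApiMap:
    """The many-to-many mapping between ATC codes and API names.

    One ATC code can cover several APIs (combination products) and one API
    can sit under several ATC codes (different indications and forms), so
    both directions are one-to-many; the two mappings are mutual inverses.
    """

    atc_to_apis: dict[str, set[str]] = field(default_factory=dict)
    api_to_atcs: dict[str, set[str]] = field(default_factory=dict)

    def check_inverse(self) -> bool:
        fwd = {(a, api) for a, apis in self.atc_to_apis.items() for api in apis}
        rev = {(a, api) for api, atcs in self.api_to_atcs.items() for a in atcs}
        return fwd == rev


def build_atc_api_map(
    product_apis: Iterable[ProductAPIRecord],
    products: Iterable[ProductRecord],
) -> AtcApiMap:
    """Assemble the ATC↔API map from observed (atc_code, api_name) pairs."""
    atc_by_product = {p.product_code: p.atc_code for p in products}
    m = AtcApiMap()
    for pa in product_apis:
        atc = atc_by_product.get(pa.product_code)
        if atc is None:
            continue
        m.atc_to_apis.setdefault(atc, set()).add(pa.api_name)
        m.api_to_atcs.setdefault(pa.api_name, set()).add(atc)
    return m
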