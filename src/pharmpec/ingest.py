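"""Reading and validation of the three wholesale tables, and ATC code parsing.

The wholesale source consists of three delimited tables:

* a **product catalogue** — one row per sold product, carrying its ATC code,
  medium type (pill, fluid, gas, ...), and the quantity of medium per package;
* a **product–API strength table** — one row per (product, API) pair with the
  original strength figure and, when available, a standardised per-item
  concentration and per-package amount;
* a **sales table** — packages sold of each product in each calendar year
  (negative rows record returns and disposals).

Readers are strict about schemas (a missing mandatory column is an error
naming the column) but forgiving about rows: a malformed row becomes an
entry in a rejects report rather than being silently dropped.  Unused
columns from real exports (registration dates, conversion factors, item
helpers) are accepted and ignored.
"""

from __future__ import annotations

import csv
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "ATCCode",
    "ATCParseError",
    "ProductRecord",
    "ProductAPIRecord",
    "SalesRecord",
    "RejectedRow",
    "SchemaError",
    "ReferentialIntegrityError",
    "ValidationReport",
    "parse_atc",
    "read_products",
    "read_product_apis",
    "read_sales",
    "write_products",
    "write_product_apis",
    "write_sales",
    "validate_referential_integrity",
]


class SchemaError(ValueError):
    """A mandatory column is absent from an input table."""


class ATCParseError(ValueError):
    """An ATC code string violates the tiered code scheme.

    The message names the level (length, anatomical, therapeutic,
    pharmacological/chemical, substance) at which parsing failed.
    """


class ReferentialIntegrityError(ValueError):
    """A cross-table reference points at a product code that does not exist."""


# --------------------------------------------------------------------------
# ATC codes
# --------------------------------------------------------------------------

_ATC_RE = re.compile(
    r"^(?P<vet>Q?)"
    r"(?P<anatomical>[A-Z])"
    r"(?P<therapeutic>\d{2})"
    r"(?P<pharm>[A-Z])(?P<chem>[A-Z])"
    r"(?P<substance>\d{2})$"
)


@dataclass(frozen=True)
class ATCCode:
    """A parsed Anatomical Therapeutic Chemical classification code.

    The code is a tiered 7-character alphanumeric identifier (8 with the
    leading ``Q`` that marks veterinary use): one letter for the anatomical
    main group, two digits for the therapeutic subgroup, two letters for the
    pharmacological and chemical subgroups, and two digits identifying the
    substance.  ``N02BE01`` is paracetamol sold as an analgesic;
    ``QJ01CA04`` is veterinary amoxicillin.
    """

    raw: str
    anatomical: str
    therapeutic: str
    pharmacological: str
    chemical_subgroup: str
    substance: str
    veterinary: bool

    def serialise(self) -> str:
        """Re-assemble the levels; the identity of :func:`parse_atc`."""
        prefix = "Q" if self.veterinary else ""
        return (
            prefix
            + self.anatomical
            + self.therapeutic
            + self.pharmacological
            + self.chemical_subgroup
            + self.substance
        )

    def startswith(self, prefix: str) -> bool:
        return self.raw.startswith(prefix)


def parse_atc(code: str) -> ATCCode:
    """Parse an ATC code into its hierarchical levels.

    Parameters
    ----------
    code:
        A 7-character ATC code, optionally prefixed with ``Q`` (veterinary).

    Raises
    ------
    ATCParseError
        If the string has the wrong length or a wrong character class at any
        level; the message identifies the offending level.
    """
    if not code:
        raise ATCParseError("empty ATC code")
    text = code.strip()
    expected = 8 if text[:1] == "Q" else 7
    if len(text) != expected:
        raise ATCParseError(
            f"ATC code {text!r}: wrong length {len(text)} (expected {expected})"
        )
    m = _ATC_RE.match(text)
    if m is None:
        # locate the level that broke, for a useful message
        body = text[1:] if text[:1] == "Q" else text
        checks = [
            ("anatomical", body[0:1], r"[A-Z]"),
            ("therapeutic", body[1:3], r"\d{2}"),
            ("pharmacological/chemical", body[3:5], r"[A-Z]{2}"),
            ("substance", body[5:7], r"\d{2}"),
        ]
        for level, chunk, pattern in checks:
            if re.fullmatch(pattern, chunk) is None:
                raise ATCParseError(
                    f"ATC code {text!r}: invalid {level} level {chunk!r}"
                )
        raise ATCParseError(f"ATC code {text!r} is not a valid tiered code")
    return ATCCode(
        raw=text,
        anatomical=m["anatomical"],
        therapeutic=m["therapeutic"],
        pharmacological=m["pharm"],
        chemical_subgroup=m["chem"],
        substance=m["substance"],
        veterinary=bool(m["vet"]),
    )


# --------------------------------------------------------------------------
# Record types
# --------------------------------------------------------------------------


@dataclass
class ProductRecord:
    """One sold pharmaceutical product (a catalogue row).

    ``package_quantity_value``/``unit`` describe the amount of medium per
    package — number of pills, litres of fluid, grams of ointment — which is
    the second factor of the per-package API mass.  ``product_group`` is 1
    for industrially manufactured products and 2 for compounding-pharmacy
    preparations.
    """

    product_code: int
    product_name: str
    atc_code: str
    product_details: str = ""
    product_type: str = "pill"
    product_group: int = 1
    package_quantity_value: float | None = None
    package_quantity_unit: str = ""
    n_api_per_product: int = 1

    def __post_init__(self) -> None:
        if self.package_quantity_value is not None and not (
            self.package_quantity_value > 0
        ):
            raise ValueError(
                f"product {self.product_code}: package_quantity_value must be > 0"
            )
        if self.n_api_per_product < 1:
            raise ValueError(
                f"product {self.product_code}: n_api_per_product must be >= 1"
            )

    @property
    def veterinary(self) -> bool:
        return self.atc_code.startswith("Q")


@dataclass
class ProductAPIRecord:
    """Strength of one API within one product (a strength-table row).

    The original (non-standardised) strength is kept verbatim; the
    standardised per-item concentration and the derived grams-per-package
    amount are optional and, when present, take precedence over re-deriving
    them from the raw strength.
    """

    product_code: int
    api_name: str
    strength_value: float | None = None
    strength_unit: str = ""
    conc_per_item_value: float | None = None
    conc_per_item_unit: str = ""
    amount_per_package_value: float | None = None
    amount_per_package_unit: str = ""
    exclude: bool = False


@dataclass
class SalesRecord:
    """Packages of one product sold in one year; negative counts are returns."""

    year: int
    product_code: int
    packages_sold: float


@dataclass
class RejectedRow:
    """A malformed input row, kept for the rejects report."""

    row_number: int  # 1-based data row number (header excluded)
    reason: str


@dataclass
class ValidationReport:
    """Findings of the cross-table referential-integrity check."""

    orphan_sales: list[SalesRecord] = field(default_factory=list)
    products_without_api: list[int] = field(default_factory=list)
    api_count_mismatches: list[tuple[int, int, int]] = field(default_factory=list)
    # (product_code, declared n_api, observed strength rows)

    @property
    def ok(self) -> bool:
        return not (
            self.orphan_sales or self.products_without_api or self.api_count_mismatches
        )


# --------------------------------------------------------------------------
# Delimited-text readers
# --------------------------------------------------------------------------

PRODUCT_COLUMNS = {
    "productcode": "product_code",
    "productname": "product_name",
    "atc_code": "atc_code",
    "productdetails": "product_details",
    "producttype": "product_type",
    "productgroup": "product_group",
    "packagequantityvalue": "package_quantity_value",
    "packagequantityunit": "package_quantity_unit",
    "noofapi_perproduct": "n_api_per_product",
}
PRODUCT_MANDATORY = {
    "productcode",
    "productname",
    "atc_code",
    "producttype",
    "packagequantityvalue",
    "packagequantityunit",
    "noofapi_perproduct",
}

PRODUCT_API_COLUMNS = {
    "productcode": "product_code",
    "api_name": "api_name",
    "strengthvalue": "strength_value",
    "strengthunit": "strength_unit",
    "api_concentrationperitemvalue": "conc_per_item_value",
    "api_concentrationperitemunit": "conc_per_item_unit",
    "api_amountperpackagevalue": "amount_per_package_value",
    "api_amountperpackageunit": "amount_per_package_unit",
    "exclude": "exclude",
}
PRODUCT_API_MANDATORY = {"productcode", "api_name", "strengthvalue", "strengthunit"}

SALES_COLUMNS = {
    "syear": "year",
    "productcode": "product_code",
    "packageamountsoldvalue": "packages_sold",
}
SALES_MANDATORY = {"syear", "productcode", "packageamountsoldvalue"}


def _open_table(
    path: str | Path, mandatory: set[str], known: dict[str, str]
) -> tuple[list[dict[str, str]], dict[str, str]]:
    """Read a delimited table, check mandatory headers case-insensitively.

    Returns the rows (as raw string dicts keyed by lower-cased header) and
    the header map actually present.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file, no header row")
        headers = {h.strip().lower(): h for h in reader.fieldnames}
        missing = sorted(mandatory - set(headers))
        if missing:
            raise SchemaError(f"{path}: missing mandatory column(s): {', '.join(missing)}")
        rows = [
            {h.strip().lower(): (v if v is not None else "") for h, v in row.items() if h}
            for row in reader
        ]
    return rows, headers


def _to_float(text: str, *, decimal_comma: bool = False) -> float | None:
    text = text.strip()
    if not text:
        return None
    if decimal_comma:
        text = text.replace(",", ".")
    value = float(text)  # may raise ValueError
    if not math.isfinite(value):
        raise ValueError(f"non-finite number {text!r}")
    return value


def read_products(
    path: str | Path, *, decimal_comma: bool = False
) -> tuple[list[ProductRecord], list[RejectedRow]]:
    """Read the product catalogue; malformed rows go to the rejects list."""
    rows, _ = _open_table(path, PRODUCT_MANDATORY, PRODUCT_COLUMNS)
    records: list[ProductRecord] = []
    rejects: list[RejectedRow] = []
    seen: set[int] = set()
    for i, row in enumerate(rows, start=1):
        try:
            code = int(row["productcode"])
            if code in seen:
                raise ValueError(f"duplicate ProductCode {code}")
            qty = _to_float(row.get("packagequantityvalue", ""), decimal_comma=decimal_comma)
            rec = ProductRecord(
                product_code=code,
                product_name=row.get("productname", ""),
                atc_code=row.get("atc_code", "").strip(),
                product_details=row.get("productdetails", ""),
                product_type=row.get("producttype", "").strip().lower(),
                product_group=int(row.get("productgroup", "1") or 1),
                package_quantity_value=qty,
                package_quantity_unit=row.get("packagequantityunit", "").strip(),
                n_api_per_product=int(row.get("noofapi_perproduct", "1") or 1),
            )
            parse_atc(rec.atc_code)  # reject syntactically invalid codes
        except (ValueError, ATCParseError) as exc:
            rejects.append(RejectedRow(i, str(exc)))
            continue
        seen.add(code)
        records.append(rec)
    return records, rejects


def read_product_apis(
    path: str | Path, *, decimal_comma: bool = False
) -> tuple[list[ProductAPIRecord], list[RejectedRow]]:
    """Read the product–API strength table."""
    rows, _ = _open_table(path, PRODUCT_API_MANDATORY, PRODUCT_API_COLUMNS)
    records: list[ProductAPIRecord] = []
    rejects: list[RejectedRow] = []
    seen: set[tuple[int, str]] = set()
    for i, row in enumerate(rows, start=1):
        try:
            code = int(row["productcode"])
            api = row.get("api_name", "").strip()
            if not api:
                raise ValueError("empty API_name")
            key = (code, api)
            if key in seen:
                raise ValueError(f"duplicate (ProductCode, API_name) {key}")
            rec = ProductAPIRecord(
                product_code=code,
                api_name=api,
                strength_value=_to_float(row.get("strengthvalue", ""), decimal_comma=decimal_comma),
                strength_unit=row.get("strengthunit", "").strip(),
                conc_per_item_value=_to_float(
                    row.get("api_concentrationperitemvalue", ""), decimal_comma=decimal_comma
                ),
                conc_per_item_unit=row.get("api_concentrationperitemunit", "").strip(),
                amount_per_package_value=_to_float(
                    row.get("api_amountperpackagevalue", ""), decimal_comma=decimal_comma
                ),
                amount_per_package_unit=row.get("api_amountperpackageunit", "").strip(),
                exclude=row.get("exclude", "").strip().lower() in {"yes", "true", "1"},
            )
        except ValueError as exc:
            rejects.append(RejectedRow(i, str(exc)))
            continue
        seen.add(key)
        records.append(rec)
    return records, rejects


def read_sales(
    path: str | Path, *, decimal_comma: bool = False
) -> tuple[list[SalesRecord], list[RejectedRow]]:
    """Read the sales table; (year, product) rows may legitimately repeat."""
    rows, _ = _open_table(path, SALES_MANDATORY, SALES_COLUMNS)
    records: list[SalesRecord] = []
    rejects: list[RejectedRow] = []
    for i, row in enumerate(rows, start=1):
        try:
            packages = _to_float(row["packageamountsoldvalue"], decimal_comma=decimal_comma)
            if packages is None:
                raise ValueError("empty PackageAmountSoldValue")
            rec = SalesRecord(
                year=int(row["syear"]),
                product_code=int(row["productcode"]),
                packages_sold=packages,
            )
        except ValueError as exc:
            rejects.append(RejectedRow(i, str(exc)))
            continue
        records.append(rec)
    return records, rejects


# --------------------------------------------------------------------------
# Writers (round-trip partners of the readers; also used by synthgen)
# --------------------------------------------------------------------------


def _fmt(value: float | int | None) -> str:
    if value is None:
        return ""
    if isinstance(value, float) and value == int(value) and abs(value) < 1e15:
        return str(int(value))
    return repr(value)


def write_products(path: str | Path, records: Sequence[ProductRecord]) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(
            [
                "ProductCode", "ProductName", "ATC_code", "ProductDetails",
                "ProductType", "ProductGroup", "PackageQuantityValue",
                "PackageQuantityUnit", "NoOfAPI_PerProduct",
            ]
        )
        for r in records:
            w.writerow(
                [
                    r.product_code, r.product_name, r.atc_code, r.product_details,
                    r.product_type, r.product_group, _fmt(r.package_quantity_value),
                    r.package_quantity_unit, r.n_api_per_product,
                ]
            )


def write_product_apis(path: str | Path, records: Sequence[ProductAPIRecord]) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(
            [
                "ProductCode", "API_name", "StrengthValue", "StrengthUnit",
                "API_ConcentrationPerItemValue", "API_ConcentrationPerItemUnit",
                "API_AmountPerPackageValue", "API_AmountPerPackageUnit", "Exclude",
            ]
        )
        for r in records:
            w.writerow(
                [
                    r.product_code, r.api_name, _fmt(r.strength_value), r.strength_unit,
                    _fmt(r.conc_per_item_value), r.conc_per_item_unit,
                    _fmt(r.amount_per_package_value), r.amount_per_package_unit,
                    "Yes" if r.exclude else "",
                ]
            )


def write_sales(path: str | Path, records: Sequence[SalesRecord]) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["sYear", "ProductCode", "PackageAmountSoldValue"])
        for r in records:
            w.writerow([r.year, r.product_code, _fmt(r.packages_sold)])


def write_rejects(path: str | Path, rejects: Sequence[RejectedRow]) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["RowNumber", "Reason"])
        for r in rejects:
            w.writerow([r.row_number, r.reason])


# --------------------------------------------------------------------------
# Referential integrity
# --------------------------------------------------------------------------


def validate_referential_integrity(
    products: Iterable[ProductRecord],
    product_apis: Iterable[ProductAPIRecord],
    sales: Iterable[SalesRecord],
    *,
    strict: bool = False,
) -> ValidationReport:
    """Cross-check the three tables.

    The report lists sales rows referencing unknown products, products with
    no strength row at all, and products whose declared API count disagrees
    with the number of strength rows observed.  With ``strict=True`` any
    finding raises :class:`ReferentialIntegrityError`.
    """
    product_codes = {p.product_code for p in products}
    api_counts: dict[int, int] = {}
    for pa in product_apis:
        api_counts[pa.product_code] = api_counts.get(pa.product_code, 0) + 1

    report = ValidationReport()
    for s in sales:
        if s.product_code not in product_codes:
            report.orphan_sales.append(s)
    for p in products:
        observed = api_counts.get(p.product_code, 0)
        if observed == 0:
            report.products_without_api.append(p.product_code)
        elif observed != p.n_api_per_product:
            report.api_count_mismatches.append(
                (p.product_code, p.n_api_per_product, observed)
            )
    if strict and not report.ok:
        raise ReferentialIntegrityError(
            f"{len(report.orphan_sales)} orphan sales row(s), "
            f"{len(report.products_without_api)} product(s) without strengths, "
            f"{len(report.api_count_mismatches)} API-count mismatch(es)"
        )
    return report
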