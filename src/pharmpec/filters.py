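"""Exclusion cascade and aggregation to annual per-API masses.

The screening pipeline removes, in order: products in classes exempt from
environmental risk assessment on grounds of non-toxicity (vaccines,
vitamins, antibodies, ...); records whose strength is in non-mass units
(international units) or could not be converted; negative sales rows
(returns and disposals of product); gas APIs (anaesthetic gases); products
selling fewer than 1000 packages over the study window — except the
special-interest antibiotic and sex-hormone classes, which are kept
regardless; and finally zero-mass or unit-less records.  Each stage reports
how many records it removed, split into human and veterinary products, so
the whole cascade reconciles like an accounting statement.

Surviving records are aggregated to the pipeline's central output: grams of
each API sold per calendar year.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from . import decompose
from .decompose import PackageAmount, UnitDictionary, compute_package_amounts
from .ingest import ProductAPIRecord, ProductRecord, SalesRecord

__all__ = [
    "FilterConfig",
    "StageCount",
    "StageReport",
    "AnnualAPIWeight",
    "DEFAULT_STAGE_ORDER",
    "EXEMPT_ATC_PREFIXES",
    "build_sales_frame",
    "apply_exemption_filter",
    "apply_low_sales_filter",
    "drop_invalid_and_negative",
    "aggregate_annual",
    "run_cascade",
    "stage_counts",
    "write_weights",
]

#: ATC prefixes identifying the exempt classes named in risk-assessment
#: guidance; the product-details text is scanned for the class keyword as a
#: second route (source data marks exempt classes both ways).
EXEMPT_ATC_PREFIXES: dict[str, tuple[str, ...]] = {
    "vaccine": ("J07", "QJ07", "QI"),
    "vitamin": ("A11", "QA11"),
    "antibody": ("J06", "QJ06"),
    "allergen": ("V01",),
}

#: ATC prefixes for categories of special interest kept despite low sales.
SPECIAL_INTEREST_ATC_PREFIXES: dict[str, tuple[str, ...]] = {
    "antibiotics": ("J01", "QJ01"),
    "sex hormones": ("G03", "QG03"),
}

DEFAULT_STAGE_ORDER = (
    "exempt",
    "non_mass",
    "negative_sales",
    "gas",
    "low_volume",
    "zero_unitless",
)


@dataclass
class FilterConfig:
    """Tunable knobs of the exclusion cascade.

    ``low_sales_threshold`` is strict: a product is removed when its summed
    packages over the window are **below** the threshold, so exactly 1000
    packages is kept.  ``negative_policy`` is ``"drop"`` (remove return rows,
    the default, matching the accounting of the source pipeline) or
    ``"net"`` (offset returns against sales; for sensitivity analysis).
    """

    exemption_list: frozenset[str] = frozenset(EXEMPT_ATC_PREFIXES)
    low_sales_threshold: int = 1000
    low_sales_window: frozenset[int] | None = None  # None = all years present
    low_sales_exempt_categories: frozenset[str] = frozenset(SPECIAL_INTEREST_ATC_PREFIXES)
    extra_special_interest_prefixes: tuple[str, ...] = ()
    drop_negative_sales: bool = True
    negative_policy: str = "drop"
    drop_gas: bool = True

    def __post_init__(self) -> None:
        if self.low_sales_threshold < 0:
            raise ValueError("low_sales_threshold must be >= 0")
        if self.negative_policy not in {"drop", "net"}:
            raise ValueError("negative_policy must be 'drop' or 'net'")

    def special_interest_prefixes(self) -> tuple[str, ...]:
        out: list[str] = list(self.extra_special_interest_prefixes)
        for cat in self.low_sales_exempt_categories:
            out.extend(SPECIAL_INTEREST_ATC_PREFIXES.get(cat, ()))
        return tuple(out)

    def exempt_prefixes(self) -> tuple[str, ...]:
        out: list[str] = []
        for cat in self.exemption_list:
            out.extend(EXEMPT_ATC_PREFIXES.get(cat, ()))
        return tuple(out)


@dataclass
class StageCount:
    """Record bookkeeping for one cascade stage (in − removed = out)."""

    stage: str
    n_in: int
    n_removed: int
    n_out: int
    products_human_removed: int = 0
    products_vet_removed: int = 0

    def __post_init__(self) -> None:
        if self.n_in - self.n_removed != self.n_out:
            raise ValueError(f"stage {self.stage}: in - removed != out")


@dataclass
class StageReport:
    """Per-stage counts for the whole cascade, plus final unique-API counts."""

    stages: list[StageCount] = field(default_factory=list)
    unique_apis_per_year: dict[int, int] = field(default_factory=dict)
    products_in_human: int = 0
    products_in_vet: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "stage": s.stage,
                    "records_in": s.n_in,
                    "records_removed": s.n_removed,
                    "records_out": s.n_out,
                    "products_human_removed": s.products_human_removed,
                    "products_vet_removed": s.products_vet_removed,
                }
                for s in self.stages
            ]
        )

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class AnnualAPIWeight:
    """Grams of one API sold in one year — the pipeline's central output."""

    api_name: str
    year: int
    grams: float
    n_products_contributing: int = 0

    def __post_init__(self) -> None:
        if not self.grams >= 0:
            raise ValueError(f"{self.api_name}/{self.year}: grams must be >= 0")


# --------------------------------------------------------------------------
# Joined working frame
# --------------------------------------------------------------------------


def build_sales_frame(
    products: Sequence[ProductRecord],
    product_apis: Sequence[ProductAPIRecord],
    sales: Sequence[SalesRecord],
    unit_dict: UnitDictionary | None = None,
) -> pd.DataFrame:
    """Join catalogue, per-package masses, and sales into one long frame.

    One row per (product, API, sales record); the cascade's stages are
    boolean predicates on this frame's columns.
    """
    amounts = compute_package_amounts(products, product_apis, unit_dict)
    prod_meta = {
        p.product_code: (p.atc_code, p.veterinary, p.product_type, p.product_details)
        for p in products
    }
    amount_rows = [
        {
            "product_code": a.product_code,
            "api_name": a.api_name,
            "grams_per_package": a.grams_per_package,
            "status": a.status,
            "reason": a.reason,
        }
        for a in amounts
        if a.product_code in prod_meta
    ]
    adf = pd.DataFrame(
        amount_rows,
        columns=["product_code", "api_name", "grams_per_package", "status", "reason"],
    )
    meta = pd.DataFrame(
        [
            {
                "product_code": code,
                "atc_code": atc,
                "veterinary": vet,
                "product_type": ptype,
                "product_details": details,
            }
            for code, (atc, vet, ptype, details) in prod_meta.items()
        ],
        columns=["product_code", "atc_code", "veterinary", "product_type", "product_details"],
    )
    sdf = pd.DataFrame(
        [
            {"year": s.year, "product_code": s.product_code, "packages_sold": s.packages_sold}
            for s in sales
        ],
        columns=["year", "product_code", "packages_sold"],
    )
    frame = adf.merge(meta, on="product_code").merge(sdf, on="product_code")
    return frame


# --------------------------------------------------------------------------
# Stage predicates — each returns a boolean "remove" mask
# --------------------------------------------------------------------------


def _is_exempt(frame: pd.DataFrame, config: FilterConfig) -> pd.Series:
    prefixes = config.exempt_prefixes()
    mask = pd.Series(False, index=frame.index)
    if prefixes:
        mask |= frame["atc_code"].str.startswith(prefixes)
    keywords = {c.lower() for c in config.exemption_list}
    if keywords:
        details = frame["product_details"].fillna("").str.lower()
        for kw in keywords:
            mask |= details.str.contains(kw, regex=False)
        mask |= frame["api_name"].str.lower().isin(keywords)
    return mask


def _is_non_mass(frame: pd.DataFrame) -> pd.Series:
    return frame["status"].eq(decompose.NON_MASS)


def _is_negative_sale(frame: pd.DataFrame, config: FilterConfig) -> pd.Series:
    if not config.drop_negative_sales or config.negative_policy == "net":
        return pd.Series(False, index=frame.index)
    return frame["packages_sold"].lt(0)


def _is_gas(frame: pd.DataFrame, config: FilterConfig) -> pd.Series:
    if not config.drop_gas:
        return pd.Series(False, index=frame.index)
    return frame["product_type"].eq("gas")


def _low_volume_products(
    sales: Sequence[SalesRecord],
    products: Sequence[ProductRecord],
    config: FilterConfig,
) -> set[int]:
    """Product codes failing the packages-sold threshold.

    The predicate depends only on raw positive package counts over the
    window (returns are accounted for at their own stage), so it commutes
    with the other stages.  Special-interest ATC prefixes are never removed.
    """
    window = config.low_sales_window
    totals: dict[int, float] = {}
    for s in sales:
        if window is not None and s.year not in window:
            continue
        if s.packages_sold > 0:
            totals[s.product_code] = totals.get(s.product_code, 0.0) + s.packages_sold
    special = config.special_interest_prefixes()
    low: set[int] = set()
    for p in products:
        if special and p.atc_code.startswith(special):
            continue
        if totals.get(p.product_code, 0.0) < config.low_sales_threshold:
            low.add(p.product_code)
    return low


def _is_zero_or_unitless(frame: pd.DataFrame, config: FilterConfig) -> pd.Series:
    mask = frame["status"].eq(decompose.MISSING)
    mask |= frame["grams_per_package"].fillna(0).eq(0)
    if config.negative_policy == "drop":
        # packages of exactly 0 contribute nothing; "remove any zero values"
        mask |= frame["packages_sold"].eq(0)
    return mask


# --------------------------------------------------------------------------
# Public stage operations (kept, removed) on record lists
# --------------------------------------------------------------------------


def apply_exemption_filter(
    frame: pd.DataFrame, config: FilterConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove records in exempt classes (by ATC range, keyword, or API name)."""
    mask = _is_exempt(frame, config)
    return frame[~mask], frame[mask]


def apply_low_sales_filter(
    frame: pd.DataFrame,
    sales: Sequence[SalesRecord],
    products: Sequence[ProductRecord],
    config: FilterConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove products selling below the threshold over the window,
    keeping antibiotic and sex-hormone ranges regardless."""
    low = _low_volume_products(sales, products, config)
    mask = frame["product_code"].isin(low)
    return frame[~mask], frame[mask]


def drop_invalid_and_negative(
    frame: pd.DataFrame, config: FilterConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove non-mass records, unconvertible/zero records, and returns."""
    mask = _is_non_mass(frame) | _is_negative_sale(frame, config)
    mask |= _is_zero_or_unitless(frame, config)
    return frame[~mask], frame[mask]


# --------------------------------------------------------------------------
# Cascade
# --------------------------------------------------------------------------


def run_cascade(
    products: Sequence[ProductRecord],
    product_apis: Sequence[ProductAPIRecord],
    sales: Sequence[SalesRecord],
    config: FilterConfig | None = None,
    unit_dict: UnitDictionary | None = None,
    stage_order: Sequence[str] = DEFAULT_STAGE_ORDER,
) -> tuple[pd.DataFrame, StageReport]:
    """Apply the full exclusion cascade; return the surviving frame and report.

    Every stage is a predicate on attributes fixed before the cascade runs,
    so the final kept set does not depend on ``stage_order`` — only the
    per-stage removal counts do.
    """
    config = config or FilterConfig()
    if set(stage_order) != set(DEFAULT_STAGE_ORDER):
        raise ValueError(f"stage_order must be a permutation of {DEFAULT_STAGE_ORDER}")
    frame = build_sales_frame(products, product_apis, sales, unit_dict)
    low = _low_volume_products(sales, products, config)

    predicates = {
        "exempt": lambda f: _is_exempt(f, config),
        "non_mass": _is_non_mass,
        "negative_sales": lambda f: _is_negative_sale(f, config),
        "gas": lambda f: _is_gas(f, config),
        "low_volume": lambda f: f["product_code"].isin(low),
        "zero_unitless": lambda f: _is_zero_or_unitless(f, config),
    }

    report = StageReport(
        products_in_human=sum(1 for p in products if not p.veterinary),
        products_in_vet=sum(1 for p in products if p.veterinary),
    )
    for stage in stage_order:
        mask = predicates[stage](frame)
        removed = frame[mask]
        kept = frame[~mask]
        report.stages.append(
            StageCount(
                stage=stage,
                n_in=len(frame),
                n_removed=len(removed),
                n_out=len(kept),
                products_human_removed=removed.loc[~removed["veterinary"], "product_code"].nunique(),
                products_vet_removed=removed.loc[removed["veterinary"], "product_code"].nunique(),
            )
        )
        frame = kept
    return frame, report


def aggregate_annual(frame: pd.DataFrame) -> list[AnnualAPIWeight]:
    """Sum surviving records to grams per API per year.

    grams(api, year) = Σ grams_per_package × packages_sold over surviving
    product records; zero-gram annual rows are not emitted.  Under the
    netting policy a product-year whose returns exceed its sales is floored
    at zero before summation across products.
    """
    if frame.empty:
        return []
    work = frame.copy()
    work["grams"] = work["grams_per_package"] * work["packages_sold"]
    # net within product-year first so returns can only offset that product's
    # own sales (a no-op under the drop policy, where negatives are gone)
    per_product = (
        work.groupby(["api_name", "year", "product_code"], sort=True)["grams"]
        .sum()
        .clip(lower=0.0)
        .reset_index()
    )
    grouped = per_product.groupby(["api_name", "year"], sort=True)
    out: list[AnnualAPIWeight] = []
    for (api, year), g in grouped:
        grams = float(g["grams"].sum())
        if grams == 0.0:
            continue
        out.append(
            AnnualAPIWeight(
                api_name=api,
                year=int(year),
                grams=grams,
                n_products_contributing=int(g.loc[g["grams"] > 0, "product_code"].nunique()),
            )
        )
    return out


def stage_counts(
    report: StageReport, weights: Sequence[AnnualAPIWeight]
) -> StageReport:
    """Attach final unique-API-per-year counts to a cascade report."""
    per_year: dict[int, set[str]] = {}
    for w in weights:
        per_year.setdefault(w.year, set()).add(w.api_name)
    report.unique_apis_per_year = {y: len(apis) for y, apis in sorted(per_year.items())}
    return report


def weights_to_frame(weights: Sequence[AnnualAPIWeight]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "api_name": w.api_name,
                "year": w.year,
                "grams": w.grams,
                "n_products_contributing": w.n_products_contributing,
            }
            for w in weights
        ],
        columns=["api_name", "year", "grams", "n_products_contributing"],
    )


def write_weights(path: str | Path, weights: Sequence[AnnualAPIWeight]) -> None:
    """Write the final dataset as comma-separated text (api, year, grams)."""
    weights_to_frame(weights).to_csv(path, index=False)
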