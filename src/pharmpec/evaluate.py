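"""Evaluation toolkit: agreement analysis, DDD comparison, extreme-change flags.

Three independent checks of a sales-mass dataset:

* **Bland–Altman (Tukey mean-difference) analysis** of two estimates of the
  same per-API annual masses, on log10-transformed weights: per-pair
  difference vs per-pair mean, the mean difference, and limits of agreement
  at mean ± 1.96·sd of the differences.
* **DDD-based comparison** against prescription registries that report
  consumption in defined daily doses: a DDD count times the grams-per-DDD
  value for the ATC code gives a mass comparable with the wholesale figure
  (where several DDD values exist for one code, the highest is used).
* **Extreme-change flagging**: an API whose sales mass in some year is more
  than a factor (default 10) above or below its mean across the study
  window is shortlisted for manual review, and the shortlist is categorised
  by explanation (marketing-authorisation events, supply shortages,
  unexplained).

Note an algebraic property of the mean-based rule: with n strictly positive
years, max(w)/mean(w) < n always, so for a 4-year window the factor-10 rule
can only ever fire on the small side.  A leave-one-out variant (each year
compared with the mean of the remaining years) is offered for the large
side.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .filters import AnnualAPIWeight

__all__ = [
    "PairedWeights",
    "BlandAltmanSummary",
    "DDDEntry",
    "DDDRegistry",
    "ExtremeChangeFlag",
    "CategorySummary",
    "InsufficientDataError",
    "UndefinedDDDError",
    "bland_altman",
    "ddd_to_grams",
    "compare_sources",
    "flag_extreme_changes",
    "categorise_flags",
    "load_ddd_panel",
    "load_extreme_change_annotations",
]

CATEGORIES = ("authorisation_change", "supply_shortage", "unexplained", "unclassified")


class InsufficientDataError(ValueError):
    """Fewer than two usable pairs; agreement statistics are undefined."""


class UndefinedDDDError(KeyError):
    """No defined daily dose exists for the requested ATC code."""


# --------------------------------------------------------------------------
# Bland–Altman agreement
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PairedWeights:
    """Two independent estimates of the same API's mass for one period."""

    api_name: str
    weight_a: float
    weight_b: float

    @property
    def usable(self) -> bool:
        return self.weight_a > 0 and self.weight_b > 0


@dataclass
class BlandAltmanSummary:
    """Mean-difference statistics of paired log10 masses.

    ``points`` holds (mean of logs, difference of logs, api_name) per pair;
    the limits bound individual differences at mean ± 1.96·sd (sample sd,
    n−1 denominator); ``outliers`` are pairs strictly outside the limits.
    """

    n_pairs: int
    n_excluded: int
    mean_difference: float
    sd_difference: float
    lower_limit: float
    upper_limit: float
    points: list[tuple[float, float, str]] = field(default_factory=list)
    outliers: list[str] = field(default_factory=list)


def bland_altman(
    pairs: Sequence[PairedWeights],
    *,
    limit_multiplier: float = 1.96,
    ci_of_mean: bool = False,
) -> BlandAltmanSummary:
    """Agreement between two mass datasets on the log10 scale.

    Pairs with a zero, negative, or missing value on either side are
    excluded (the log transform is undefined for them) and counted in
    ``n_excluded``.  With ``ci_of_mean=True`` the red lines are the 95%
    confidence interval of the mean difference (±1.96·sd/√n) instead of the
    limits of agreement that bound individual points.

    Raises
    ------
    InsufficientDataError
        If fewer than two usable pairs remain.
    """
    usable = [p for p in pairs if p.usable]
    n_excluded = len(pairs) - len(usable)
    if len(usable) < 2:
        raise InsufficientDataError(
            f"need >= 2 positive pairs, got {len(usable)} ({n_excluded} excluded)"
        )
    la = np.log10([p.weight_a for p in usable])
    lb = np.log10([p.weight_b for p in usable])
    diffs = la - lb
    means = 0.5 * (la + lb)
    mean_d = float(np.mean(diffs))
    sd_d = float(np.std(diffs, ddof=1))
    half_width = limit_multiplier * sd_d
    if ci_of_mean:
        half_width /= math.sqrt(len(usable))
    lower, upper = mean_d - half_width, mean_d + half_width
    points = [(float(m), float(d), p.api_name) for m, d, p in zip(means, diffs, usable)]
    outliers = [p.api_name for _, d, p in zip(means, diffs, usable) if d < lower or d > upper]
    return BlandAltmanSummary(
        n_pairs=len(usable),
        n_excluded=n_excluded,
        mean_difference=mean_d,
        sd_difference=sd_d,
        lower_limit=lower,
        upper_limit=upper,
        points=points,
        outliers=outliers,
    )


def bland_altman_plot(summary: BlandAltmanSummary, path: str | Path) -> None:
    """Render the mean-difference plot to a static image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 5))
    xs = [p[0] for p in summary.points]
    ys = [p[1] for p in summary.points]
    ax.scatter(xs, ys, s=14, alpha=0.7)
    ax.axhline(summary.mean_difference, color="blue", label="mean difference")
    ax.axhline(summary.lower_limit, color="red", linestyle="--", label="limits of agreement")
    ax.axhline(summary.upper_limit, color="red", linestyle="--")
    ax.set_xlabel("mean of log10 masses")
    ax.set_ylabel("difference of log10 masses")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


# --------------------------------------------------------------------------
# DDD comparison
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class DDDEntry:
    """A defined daily dose for one ATC code and administration route."""

    atc_code: str
    ddd_value: float  # grams per DDD
    route: str = ""

    def __post_init__(self) -> None:
        if not self.ddd_value > 0:
            raise ValueError(f"{self.atc_code}: ddd_value must be > 0")


class DDDRegistry:
    """Lookup of DDD values by ATC code; several (value, route) pairs may
    exist per code, and by convention the highest value is selected when a
    consumption figure does not distinguish routes."""

    def __init__(self, entries: Iterable[DDDEntry] = ()) -> None:
        self._by_code: dict[str, list[DDDEntry]] = {}
        for e in entries:
            self._by_code.setdefault(e.atc_code, []).append(e)

    def add(self, entry: DDDEntry) -> None:
        self._by_code.setdefault(entry.atc_code, []).append(entry)

    def entries(self, atc_code: str) -> list[DDDEntry]:
        return list(self._by_code.get(atc_code, []))

    def highest(self, atc_code: str) -> DDDEntry:
        entries = self._by_code.get(atc_code)
        if not entries:
            raise UndefinedDDDError(f"no DDD defined for ATC code {atc_code}")
        return max(entries, key=lambda e: e.ddd_value)

    @classmethod
    def from_csv(cls, path: str | Path) -> "DDDRegistry":
        reg = cls()
        with Path(path).open(newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                value = row.get("ddd_value_g", "").strip()
                if not value:  # codes with no assigned DDD
                    continue
                reg.add(
                    DDDEntry(
                        atc_code=row["atc_code"].strip(),
                        ddd_value=float(value),
                        route=row.get("route", "").strip(),
                    )
                )
        return reg


def load_ddd_panel() -> DDDRegistry:
    """DDD registry for the packaged comparison panel of common human and
    veterinary drugs (painkillers, a decongestant, antibacterials, hormones,
    a statin, a beta blocker)."""
    with resources.as_file(
        resources.files("pharmpec.data").joinpath("ddd_panel.csv")
    ) as path:
        return DDDRegistry.from_csv(path)


def ddd_to_grams(ddd_count: float, entry: DDDEntry) -> float:
    """Convert a DDD consumption count to grams: count × grams-per-DDD."""
    if ddd_count < 0:
        raise ValueError("ddd_count must be >= 0")
    return ddd_count * entry.ddd_value


def compare_sources(
    wholesale: AnnualAPIWeight, prescription_grams: float
) -> tuple[float, float]:
    """Ratio and log10 difference of wholesale vs prescription mass.

    Returns ``(wholesale/prescription, log10(wholesale) − log10(prescription))``;
    the log differences across a panel feed :func:`bland_altman`.
    """
    if prescription_grams <= 0:
        raise ZeroDivisionError("prescription mass must be > 0 for a defined ratio")
    if wholesale.grams <= 0:
        raise ValueError("wholesale mass must be > 0 for a defined log ratio")
    ratio = wholesale.grams / prescription_grams
    return ratio, math.log10(ratio)


# --------------------------------------------------------------------------
# Extreme-change flagging
# --------------------------------------------------------------------------


@dataclass
class ExtremeChangeFlag:
    """One API's year-on-mean ratios and shortlist decision."""

    api_name: str
    yearly_grams: dict[int, float]
    mean_grams: float
    max_ratio: float
    min_ratio: float
    flagged: bool
    rule: str
    category: str = "unclassified"
    note: str = ""


def flag_extreme_changes(
    weights: Sequence[AnnualAPIWeight],
    *,
    factor: float = 10.0,
    rule: str = "overall_mean",
) -> tuple[list[ExtremeChangeFlag], list[tuple[str, str]]]:
    """Shortlist APIs whose sales mass swings by more than ``factor``.

    Under ``overall_mean`` each year is compared with the mean over all
    years with records: flag if max/mean > factor or min/mean < 1/factor.
    Under ``leave_one_out`` each year is compared with the mean of the
    remaining years, which can detect single-year spikes the overall mean
    absorbs.  APIs with fewer than two recorded years are excluded and
    returned with a reason.  The decision is invariant to jointly rescaling
    all years (ratios are scale-free) and to input ordering.
    """
    if not factor > 1:
        raise ValueError("factor must be > 1")
    if rule not in {"overall_mean", "leave_one_out"}:
        raise ValueError("rule must be 'overall_mean' or 'leave_one_out'")
    series: dict[str, dict[int, float]] = {}
    for w in weights:
        series.setdefault(w.api_name, {})[w.year] = w.grams
    flags: list[ExtremeChangeFlag] = []
    excluded: list[tuple[str, str]] = []
    for api in sorted(series):
        yearly = dict(sorted(series[api].items()))
        values = np.array(list(yearly.values()), dtype=float)
        if len(values) < 2:
            excluded.append((api, "fewer than two years of records; mean undefined"))
            continue
        mean = float(values.mean())
        if rule == "overall_mean":
            if mean <= 0:
                excluded.append((api, "non-positive mean mass"))
                continue
            max_ratio = float(values.max() / mean)
            min_ratio = float(values.min() / mean)
        else:  # leave_one_out
            n = len(values)
            total = values.sum()
            rest_means = (total - values) / (n - 1)
            if np.any(rest_means <= 0):
                excluded.append((api, "non-positive leave-one-out mean"))
                continue
            ratios = values / rest_means
            max_ratio = float(ratios.max())
            min_ratio = float(ratios.min())
        flagged = max_ratio > factor or min_ratio < 1.0 / factor
        flags.append(
            ExtremeChangeFlag(
                api_name=api,
                yearly_grams=yearly,
                mean_grams=mean,
                max_ratio=max_ratio,
                min_ratio=min_ratio,
                flagged=flagged,
                rule=rule,
            )
        )
    return flags, excluded


@dataclass
class CategorySummary:
    """Counts and percentages of shortlist explanations."""

    counts: dict[str, int]
    percentages: dict[str, float]
    total: int


def load_extreme_change_annotations() -> dict[str, tuple[str, str]]:
    """Packaged annotation table for the 2016–2019 national screening
    shortlist: API name → (explanation category, free-text note)."""
    out: dict[str, tuple[str, str]] = {}
    with resources.as_file(
        resources.files("pharmpec.data").joinpath("extreme_change_annotations.csv")
    ) as path:
        with path.open(newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                out[row["api_name"].strip()] = (
                    row["category"].strip(),
                    row.get("note", "").strip(),
                )
    return out


def categorise_flags(
    flags: Sequence[ExtremeChangeFlag],
    annotations: Mapping[str, tuple[str, str]] | Mapping[str, str],
) -> tuple[list[ExtremeChangeFlag], CategorySummary]:
    """Attach explanation categories to flagged APIs and summarise.

    Unannotated APIs become ``unclassified``; percentages are computed over
    the flagged shortlist.
    """
    shortlist = [f for f in flags if f.flagged]
    for f in shortlist:
        ann = annotations.get(f.api_name)
        if ann is None:
            f.category = "unclassified"
        elif isinstance(ann, tuple):
            f.category, f.note = ann
        else:
            f.category = ann
        if f.category not in CATEGORIES:
            raise ValueError(f"{f.api_name}: unknown category {f.category!r}")
    counts = {c: 0 for c in CATEGORIES}
    for f in shortlist:
        counts[f.category] += 1
    total = len(shortlist)
    percentages = {
        c: (100.0 * n / total if total else 0.0) for c, n in counts.items()
    }
    return shortlist, CategorySummary(counts=counts, percentages=percentages, total=total)
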