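"""Index of Pathology (IPa) aggregation.

Each taxon's elements are scored 1-4 in seven osteopathology categories. The
per-category IPa is the count-weighted mean rank; the overall IPa is the sum
of the seven category means, bounded in [7, 28] (7 = every category all
normal bone, 28 = every category uniformly severe).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from decimal import ROUND_HALF_EVEN, Decimal
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .records import (
    CATEGORIES,
    PathologyCategory,
    SpecimenRecord,
    ValidationError,
    classify_element,
    packaged_path,
)

__all__ = [
    "CategoryFrequencyTable",
    "IpaProfile",
    "tabulate_frequencies",
    "category_ipa",
    "overall_ipa",
    "ipa_profile",
    "percent_pathologic",
    "round_for_report",
    "load_frequency_fixture",
    "frequency_report",
]


@dataclass(frozen=True)
class CategoryFrequencyTable:
    """Per-taxon counts of elements at ranks 1..4 in each category."""

    taxon: str
    counts: dict[PathologyCategory, tuple[int, int, int, int]]

    def total(self, category: PathologyCategory) -> int:
        return sum(self.counts.get(category, (0, 0, 0, 0)))


@dataclass(frozen=True)
class IpaProfile:
    """Category mean ranks and their sum (the overall IPa) for one taxon.

    ``overall`` is None when fewer than seven categories were scored; the
    profile is then flagged ``partial`` rather than silently summing.
    """

    taxon: str
    category_means: dict[PathologyCategory, float]
    overall: float | None
    partial: bool


def tabulate_frequencies(
    records: Iterable[SpecimenRecord], taxon: str
) -> CategoryFrequencyTable:
    """Tally rank frequencies for one taxon, weighting rows by their count."""
    records = list(records)
    known = sorted({r.taxon for r in records})
    if taxon not in known:
        raise ValidationError(f"unknown taxon {taxon!r}; known taxa: {known}")
    counts = {cat: [0, 0, 0, 0] for cat in CATEGORIES}
    for rec in records:
        if rec.taxon != taxon:
            continue
        for cat, rank in rec.ranks.items():
            counts[cat][rank - 1] += rec.count
    return CategoryFrequencyTable(
        taxon=taxon, counts={c: tuple(v) for c, v in counts.items()}
    )


def category_ipa(counts: Sequence[int]) -> float:
    """Mean rank of a (n1, n2, n3, n4) frequency vector, unrounded."""
    if len(counts) != 4 or any(c < 0 for c in counts):
        raise ValidationError("counts must be four nonnegative integers")
    n = sum(counts)
    if n == 0:
        raise ValidationError("category unscored (all-zero counts)")
    return sum(r * c for r, c in zip((1, 2, 3, 4), counts)) / n


def overall_ipa(category_means: Sequence[float]) -> float:
    """Sum of the seven category mean ranks; lies in [7, 28]."""
    means = list(category_means)
    if len(means) != 7:
        raise ValidationError(
            f"partial profile: expected 7 category means, got {len(means)}"
        )
    for m in means:
        if not 1.0 <= m <= 4.0:
            raise ValidationError(f"category mean {m} outside [1, 4]")
    return float(sum(means))


def ipa_profile(freq: CategoryFrequencyTable) -> IpaProfile:
    """Category means and overall IPa from a frequency table.

    Categories with no scored elements are omitted and the profile flagged
    partial (overall is then None).
    """
    means = {
        cat: category_ipa(freq.counts[cat])
        for cat in CATEGORIES
        if freq.total(cat) > 0
    }
    partial = len(means) < 7
    overall = None if partial else overall_ipa([means[c] for c in CATEGORIES])
    return IpaProfile(freq.taxon, means, overall, partial)


def percent_pathologic(
    records: Iterable[SpecimenRecord],
    group_by: str = "taxon",
    *,
    threshold: int = 2,
) -> pd.DataFrame:
    """Percent of elements showing any osteopathology, per group.

    An element counts as pathologic iff any scored category has rank >=
    ``threshold`` (default 2, i.e. any departure from normal bone).
    ``group_by`` is one of ``taxon``, ``functional``, ``developmental``;
    anatomical groupings classify each record's element name. Percentages are
    weighted by each row's element count. Groups with no scored elements are
    absent from the output rather than reported as 0%.
    """
    if group_by not in ("taxon", "functional", "developmental"):
        raise ValidationError(f"unknown grouping {group_by!r}")
    tallies: dict[str, list[float]] = {}
    for rec in records:
        if not rec.ranks:
            continue
        if group_by == "taxon":
            key = rec.taxon
        else:
            cls = classify_element(rec.element)
            key = getattr(cls, group_by)
        tot, path = tallies.setdefault(key, [0.0, 0.0])
        tallies[key][0] = tot + rec.count
        if rec.max_rank is not None and rec.max_rank >= threshold:
            tallies[key][1] = path + rec.count
    rows = [
        {
            "group": key,
            "n_elements": int(tot),
            "n_pathologic": int(path),
            "percent_pathologic": 100.0 * path / tot,
        }
        for key, (tot, path) in sorted(tallies.items())
    ]
    return pd.DataFrame(rows, columns=["group", "n_elements", "n_pathologic", "percent_pathologic"])


def round_for_report(value: float, places: int = 2) -> float:
    """Round half-even at `places` decimals; used only at reporting time."""
    if places < 0:
        raise ValidationError("places must be >= 0")
    q = Decimal(1).scaleb(-places)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_EVEN))


# ---------------------------------------------------------------------------
# fixtures and report writer


def load_frequency_fixture(
    path: str | Path | None = None,
) -> tuple[dict[str, CategoryFrequencyTable], pd.DataFrame]:
    """Load a rank-frequency table (packaged study fixture by default).

    Returns the frequency tables keyed by taxon plus the raw tidy DataFrame
    (which for the packaged fixture also carries the printed per-category and
    overall index values, preserved verbatim).
    """
    path = packaged_path("table3_frequencies.csv") if path is None else Path(path)
    df = pd.read_csv(path)
    tables: dict[str, CategoryFrequencyTable] = {}
    for taxon, sub in df.groupby("taxon", sort=False):
        counts = {}
        for _, row in sub.iterrows():
            counts[PathologyCategory(row["category"])] = (
                int(row["n1"]), int(row["n2"]), int(row["n3"]), int(row["n4"]),
            )
        tables[taxon] = CategoryFrequencyTable(taxon=taxon, counts=counts)
    return tables, df


def frequency_report(
    tables: Iterable[CategoryFrequencyTable], path: str | Path | None = None
) -> pd.DataFrame:
    """Tidy report: taxon, category, n, counts_1..4, mean, overall.

    Means and overalls are unrounded; apply :func:`round_for_report` at the
    display boundary. Optionally written to CSV.
    """
    rows = []
    for freq in tables:
        prof = ipa_profile(freq)
        for cat in CATEGORIES:
            n1, n2, n3, n4 = freq.counts.get(cat, (0, 0, 0, 0))
            rows.append(
                {
                    "taxon": freq.taxon,
                    "category": cat.value,
                    "n": freq.total(cat),
                    "counts_1": n1,
                    "counts_2": n2,
                    "counts_3": n3,
                    "counts_4": n4,
                    "mean": prof.category_means.get(cat),
                    "overall": prof.overall,
                }
            )
    df = pd.DataFrame(rows)
    if path is not None:
        df.to_csv(path, index=False)
    return df
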