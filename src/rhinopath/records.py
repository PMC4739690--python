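"""Specimen-level pathology records, anatomical classification, and taxon metadata.

The unit of observation is a skeletal element (or an aggregated lot of
identical elements) scored on seven ordinal osteopathology categories, each
ranked 1 (normal bone) to 4 (severe). Taxon metadata carry body mass and
stratigraphic first/last appearance data (FAD/LAD) used downstream for
time-calibration and mass regressions.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "PathologyCategory",
    "CATEGORIES",
    "SpecimenRecord",
    "ElementClass",
    "TaxonProfile",
    "ValidationError",
    "read_specimen_table",
    "write_specimen_table",
    "classify_element",
    "load_element_dictionary",
    "load_taxon_profiles",
    "estimate_mass_allometric",
    "packaged_path",
]


class ValidationError(ValueError):
    """Raised when an input table violates the data contract."""


class PathologyCategory(str, Enum):
    """The seven scored osteopathology categories, in fixed reporting order."""

    exostoses = "exostoses"
    lipping = "lipping"
    texture = "texture"
    cavitation = "cavitation"
    foramen_shape = "foramen_shape"
    foramen_size = "foramen_size"
    articular_surface = "articular_surface"


#: Fixed reporting order of the seven categories.
CATEGORIES: tuple[PathologyCategory, ...] = tuple(PathologyCategory)

_CATEGORY_NAMES = tuple(c.value for c in CATEGORIES)

VALID_RANKS = frozenset({1, 2, 3, 4})

FUNCTIONAL_CLASSES = ("forelimb", "hindlimb", "axial", "indeterminate")
DEVELOPMENTAL_CLASSES = (
    "girdle",
    "stylopod",
    "zeugopod",
    "autopod",
    "other",
    "indeterminate",
)


@dataclass(frozen=True)
class ElementClass:
    """Functional (fore/hindlimb/axial) and developmental (limb-segment) bin."""

    functional: str
    developmental: str

    def __post_init__(self) -> None:
        if self.functional not in FUNCTIONAL_CLASSES:
            raise ValidationError(f"unknown functional class {self.functional!r}")
        if self.developmental not in DEVELOPMENTAL_CLASSES:
            raise ValidationError(
                f"unknown developmental class {self.developmental!r}"
            )
        if self.functional == "axial" and self.developmental not in (
            "other",
            "indeterminate",
        ):
            raise ValidationError(
                "axial elements must have developmental class 'other' or "
                "'indeterminate'"
            )


INDETERMINATE = ElementClass("indeterminate", "indeterminate")


@dataclass
class SpecimenRecord:
    """One scored skeletal element (or an aggregated lot of `count` alike).

    ``ranks`` maps each scored category to an ordinal severity in {1,2,3,4};
    categories absent from the mapping were not scorable for this element and
    are excluded from all aggregation (never imputed).
    """

    specimen_id: str
    taxon: str
    element: str
    count: int = 1
    ranks: dict[PathologyCategory, int] = field(default_factory=dict)
    row: int | None = None  # source row for error reporting

    def __post_init__(self) -> None:
        if not self.taxon:
            raise ValidationError("taxon must be nonempty")
        if self.count < 1:
            raise ValidationError(f"count must be >= 1, got {self.count}")
        for cat, rank in self.ranks.items():
            if rank not in VALID_RANKS:
                raise ValidationError(
                    f"rank {rank!r} for category {cat.value!r} outside 1-4"
                )

    @property
    def max_rank(self) -> int | None:
        """Highest scored rank across categories, or None if nothing scored."""
        return max(self.ranks.values()) if self.ranks else None


@dataclass(frozen=True)
class TaxonProfile:
    """Body mass and stratigraphic range metadata for one taxon.

    Ages are in Ma before present (larger = older); FAD >= LAD. An extant
    taxon has LAD = 0.
    """

    taxon: str
    mass_kg: float
    fad_ma: float
    lad_ma: float
    nisp: int
    mni: int
    extant: bool = False

    def __post_init__(self) -> None:
        if not self.taxon:
            raise ValidationError("taxon must be nonempty")
        if self.mass_kg <= 0:
            raise ValidationError(f"{self.taxon}: mass must be positive")
        if self.fad_ma < 0 or self.lad_ma < 0:
            raise ValidationError(f"{self.taxon}: ages must be >= 0")
        if self.fad_ma < self.lad_ma:
            raise ValidationError(
                f"{self.taxon}: FAD ({self.fad_ma}) < LAD ({self.lad_ma})"
            )
        if self.extant and self.lad_ma != 0:
            raise ValidationError(
                f"{self.taxon}: extant taxon must have LAD = 0, got {self.lad_ma}"
            )
        if self.nisp < 1 or self.mni < 1:
            raise ValidationError(f"{self.taxon}: NISP and MNI must be positive")


def packaged_path(name: str) -> Path:
    """Filesystem path of a packaged data fixture (CSV or Newick)."""
    return Path(str(resources.files("rhinopath").joinpath("data", name)))


# ---------------------------------------------------------------------------
# specimen table I/O

_META_COLUMNS = ("specimen_id", "taxon", "element", "count")


def read_specimen_table(
    path: str | Path, *, delimiter: str = ","
) -> list[SpecimenRecord]:
    """Read a specimen score table (CSV with header) into records.

    The header must name ``specimen_id, taxon, element, count`` plus the seven
    category columns. Blank rank cells are preserved as missing. A rank
    outside 1-4 raises :class:`ValidationError` naming the row and column.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        if reader.fieldnames is None:
            raise ValidationError(f"{path}: empty file")
        missing = [c for c in _META_COLUMNS if c not in reader.fieldnames]
        unknown = [
            c
            for c in reader.fieldnames
            if c not in _META_COLUMNS and c not in _CATEGORY_NAMES
        ]
        if missing or unknown:
            raise ValidationError(
                f"{path}: bad header; missing {missing or 'none'}, "
                f"unexpected {unknown or 'none'}; expected "
                f"{list(_META_COLUMNS) + list(_CATEGORY_NAMES)}"
            )
        records = []
        for i, row in enumerate(reader, start=2):  # header is line 1
            ranks: dict[PathologyCategory, int] = {}
            for cat in CATEGORIES:
                cell = (row.get(cat.value) or "").strip()
                if not cell:
                    continue
                try:
                    rank = int(cell)
                except ValueError:
                    raise ValidationError(
                        f"{path} row {i}, column {cat.value!r}: "
                        f"non-integer rank {cell!r}"
                    ) from None
                if rank not in VALID_RANKS:
                    raise ValidationError(
                        f"{path} row {i}, column {cat.value!r}: "
                        f"rank {rank} outside 1-4"
                    )
                ranks[cat] = rank
            try:
                records.append(
                    SpecimenRecord(
                        specimen_id=row["specimen_id"].strip(),
                        taxon=row["taxon"].strip(),
                        element=row["element"].strip(),
                        count=int(row["count"] or 1),
                        ranks=ranks,
                        row=i,
                    )
                )
            except ValidationError as err:
                raise ValidationError(f"{path} row {i}: {err}") from None
    if not records:
        raise ValidationError(f"{path}: no data rows")
    return records


def write_specimen_table(
    records: Iterable[SpecimenRecord], path: str | Path, *, delimiter: str = ","
) -> None:
    """Write records in the same CSV layout :func:`read_specimen_table` reads."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(list(_META_COLUMNS) + list(_CATEGORY_NAMES))
        for rec in records:
            writer.writerow(
                [rec.specimen_id, rec.taxon, rec.element, rec.count]
                + [rec.ranks.get(c, "") for c in CATEGORIES]
            )


# ---------------------------------------------------------------------------
# anatomical classification

_QUALIFIERS = frozenset(
    {
        "left", "right", "distal", "proximal", "partial", "dist", "prox",
        "end", "of", "and", "upper", "lower", "middle", "medial", "lateral",
        "frag", "fragment", "fragments", "juvenile", "fetal", "articulated",
        "broken", "into", "two", "parts", "head", "general", "na",
    }
)

_cached_dictionary: dict[str, ElementClass] | None = None


def load_element_dictionary(path: str | Path | None = None) -> dict[str, ElementClass]:
    """Load the element-name -> anatomical-class lookup table.

    The dictionary is packaged data (``element_classes.csv``) so users can
    extend it with their own table.
    """
    path = packaged_path("element_classes.csv") if path is None else Path(path)
    table: dict[str, ElementClass] = {}
    with Path(path).open(newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            table[row["element"].strip().lower()] = ElementClass(
                row["functional"].strip(), row["developmental"].strip()
            )
    return table


def _default_dictionary() -> dict[str, ElementClass]:
    global _cached_dictionary
    if _cached_dictionary is None:
        _cached_dictionary = load_element_dictionary()
    return _cached_dictionary


def _tokens(element: str) -> list[str]:
    name = re.sub(r"\(.*?\)", " ", element.lower())
    name = re.sub(r"[^a-z\- ]", " ", name)
    name = name.replace("- ", " ").replace(" -", " ")
    return [t for t in name.split() if t and t not in _QUALIFIERS]


def classify_element(
    element: str, dictionary: Mapping[str, ElementClass] | None = None
) -> ElementClass:
    """Classify an element name into functional and developmental bins.

    Matching is case-insensitive, strips side/position qualifiers
    ("left", "distal", "(juvenile)"), depluralizes, and for compound names
    ("astragalus and partial calcaneum") uses the first recognized element.
    Unknown names classify as (indeterminate, indeterminate); this function
    never raises.
    """
    table = _default_dictionary() if dictionary is None else dictionary
    toks = _tokens(element)
    # try the full cleaned phrase, then bigrams/single tokens left to right
    phrase = " ".join(toks)
    if phrase in table:
        return table[phrase]
    for i, tok in enumerate(toks):
        for cand in (f"{tok} {toks[i + 1]}" if i + 1 < len(toks) else None, tok):
            if cand is None:
                continue
            if cand in table:
                return table[cand]
            if cand.endswith("s") and cand[:-1] in table:  # plural
                return table[cand[:-1]]
    return INDETERMINATE


# ---------------------------------------------------------------------------
# taxon metadata

_BOOL = {"true": True, "1": True, "yes": True, "false": False, "0": False, "": False}


def load_taxon_profiles(path: str | Path | None = None) -> dict[str, TaxonProfile]:
    """Load taxon metadata (mass, FAD/LAD, NISP, MNI) keyed by taxon name.

    With no argument, loads the packaged seven-taxon study table.
    """
    path = packaged_path("table1_taxa.csv") if path is None else Path(path)
    profiles: dict[str, TaxonProfile] = {}
    with Path(path).open(newline="", encoding="utf-8") as fh:
        for i, row in enumerate(csv.DictReader(fh), start=2):
            try:
                prof = TaxonProfile(
                    taxon=row["taxon"].strip(),
                    mass_kg=float(row["mass_kg"]),
                    fad_ma=float(row["fad_ma"]),
                    lad_ma=float(row["lad_ma"]),
                    nisp=int(row["nisp"]),
                    mni=int(row["mni"]),
                    extant=_BOOL.get(
                        (row.get("extant") or "").strip().lower(), False
                    ),
                )
            except (KeyError, ValueError, ValidationError) as err:
                raise ValidationError(f"{path} row {i}: {err}") from None
            profiles[prof.taxon] = prof
    if not profiles:
        raise ValidationError(f"{path}: no taxa")
    return profiles


def estimate_mass_allometric(
    m13_length_mm: float, coeff_a: float | None = None, coeff_b: float | None = None
) -> float:
    """Power-law mass estimate a * length**b from total molar row length.

    The coefficients are configuration supplied by the user; the study
    pipeline uses tabulated masses directly and never calls this by default.
    """
    if coeff_a is None or coeff_b is None:
        raise ValidationError(
            "no mass estimator configured: supply coeff_a and coeff_b"
        )
    if m13_length_mm <= 0:
        raise ValidationError("molar length must be positive")
    return coeff_a * m13_length_mm**coeff_b
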