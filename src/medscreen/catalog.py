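"""Drug catalog and contraindication-table loading.

A drug catalog (the matching dictionary) is a deduplicated set of product
names with dosage suffixes stripped; a contraindication table is a symmetric
set of product-name pairs that must not be co-administered.  Dosage removal
creates duplicates — e.g. ``Acer cap.(0.1g)`` and ``Acer cap.(0.2g)`` both
normalize to ``Acer cap.`` — which collapse to a single entry, since
contraindications are a property of the active ingredient, not the dose.

Name comparison throughout the package is case-insensitive on NFC-normalized
text; stored display forms preserve the source case of the first occurrence.
"""

from __future__ import annotations

import csv
import logging
import re
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "DrugCatalog",
    "ContraindicationTable",
    "PreprocessReport",
    "InvalidInputError",
    "normalize_name",
    "casefold_key",
    "load_catalog",
    "load_contraindications",
    "read_catalog_csv",
    "read_contraindications_csv",
    "write_catalog_csv",
]


class InvalidInputError(ValueError):
    """Raised when an operation receives input it cannot meaningfully process."""


# Dose units accepted after a number inside a parenthesized group.  Longer
# alternatives must precede their prefixes (mcg before g, mL before L).
_DOSE_UNITS = r"(?:mcg|mg|μg|µg|m[lL]|g|[lL]|IU|iu|%)"
_NUMBER = r"\d+(?:[.,]\d+)?"
# A parenthesized group is dosage-like when its content contains a number
# immediately followed by a dose unit, or consists solely of a bare number
# (optionally repeated with separators, e.g. "(0.1g/2mL)" or "(500)").
_DOSE_TOKEN = re.compile(rf"{_NUMBER}\s*{_DOSE_UNITS}")
_BARE_NUMBER = re.compile(rf"^\s*{_NUMBER}\s*$")
_PAREN_GROUP = re.compile(r"\(([^()]*)\)")
_WS = re.compile(r"\s+")


def _is_dosage_content(content: str) -> bool:
    return bool(_DOSE_TOKEN.search(content)) or bool(_BARE_NUMBER.match(content))


def normalize_name(raw: str) -> str:
    """Normalize a product name: strip dosage parentheticals, tidy whitespace.

    The input is NFC-normalized (so a Korean syllable block is one character),
    every parenthesized group whose content is dosage-like — a number followed
    by a unit (g, mg, mcg, μg, mL, L, IU, %) or a bare number — is removed,
    runs of whitespace collapse to single spaces, and the result is stripped.
    Idempotent.  Only dosage-like groups are removed; parentheticals carrying
    words (e.g. a manufacturer) are preserved.

    Raises
    ------
    InvalidInputError
        If ``raw`` is empty or whitespace-only.
    """
    if not isinstance(raw, str) or not raw.strip():
        raise InvalidInputError("product name must be non-empty text")
    text = unicodedata.normalize("NFC", raw)

    def _drop_dosage(m: re.Match[str]) -> str:
        if _is_dosage_content(m.group(1)):
            logger.debug("dosage group %r stripped from %r", m.group(0), raw)
            return " "
        return m.group(0)

    text = _PAREN_GROUP.sub(_drop_dosage, text)
    return _WS.sub(" ", text).strip()


def casefold_key(name: str) -> str:
    """Case-insensitive comparison key for a (normalized) name."""
    return unicodedata.normalize("NFC", name).casefold()


@dataclass(frozen=True)
class PreprocessReport:
    """Accounting of a load: raw rows in, distinct entries out."""

    raw_count: int
    normalized_count: int
    duplicates_removed: int
    skipped_rows: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if min(self.raw_count, self.normalized_count, self.duplicates_removed) < 0:
            raise InvalidInputError("report counts must be non-negative")
        if self.raw_count - len(self.skipped_rows) != (
            self.normalized_count + self.duplicates_removed
        ):
            raise InvalidInputError(
                "raw_count must equal normalized_count + duplicates_removed "
                "(+ skipped rows)"
            )


@dataclass
class DrugCatalog:
    """Deduplicated dictionary of normalized drug names.

    ``entries`` holds display forms (first-seen case); ``provenance`` maps each
    entry back to the raw names that produced it.  Membership and lookup are
    case-insensitive.
    """

    entries: list[str] = field(default_factory=list)
    provenance: dict[str, list[str]] = field(default_factory=dict)
    _by_key: dict[str, str] = field(default_factory=dict, repr=False)

    def add(self, raw: str) -> bool:
        """Normalize and insert one raw name; return True if it was new."""
        norm = normalize_name(raw)
        key = casefold_key(norm)
        if key in self._by_key:
            self.provenance[self._by_key[key]].append(raw)
            return False
        self._by_key[key] = norm
        self.entries.append(norm)
        self.provenance[norm] = [raw]
        return True

    def __contains__(self, name: str) -> bool:
        return casefold_key(name) in self._by_key

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def canonical(self, name: str) -> str | None:
        """Return the stored display form for ``name``, or None."""
        return self._by_key.get(casefold_key(name))


@dataclass
class ContraindicationTable:
    """Symmetric set of normalized name pairs that must not be combined."""

    pairs: set[frozenset[str]] = field(default_factory=set)
    display: dict[frozenset[str], tuple[str, str]] = field(default_factory=dict)

    def add(self, name_a: str, name_b: str) -> bool:
        """Insert an unordered pair of *already normalized* names."""
        key = frozenset((casefold_key(name_a), casefold_key(name_b)))
        if len(key) == 1:
            logger.warning("self-pair in contraindication source: %r", name_a)
        if key in self.pairs:
            return False
        self.pairs.add(key)
        self.display[key] = (name_a, name_b)
        return True

    def contains(self, name_a: str, name_b: str) -> bool:
        return frozenset((casefold_key(name_a), casefold_key(name_b))) in self.pairs

    def __len__(self) -> int:
        return len(self.pairs)


def load_catalog(records: Sequence[str]) -> tuple[DrugCatalog, PreprocessReport]:
    """Build a :class:`DrugCatalog` from raw product names.

    Every record is normalized via :func:`normalize_name`; names agreeing
    after normalization (case-insensitively) collapse to one entry.

    Raises
    ------
    InvalidInputError
        If ``records`` is empty.
    """
    records = list(records)
    if not records:
        raise InvalidInputError("catalog source contains no records")
    catalog = DrugCatalog()
    dupes = 0
    for raw in records:
        if not catalog.add(raw):
            dupes += 1
    report = PreprocessReport(
        raw_count=len(records),
        normalized_count=len(catalog),
        duplicates_removed=dupes,
    )
    logger.info(
        "catalog loaded: %d raw -> %d entries (%d duplicates removed)",
        report.raw_count, report.normalized_count, report.duplicates_removed,
    )
    return catalog, report


def load_contraindications(
    records: Iterable[tuple[str, str]],
) -> tuple[ContraindicationTable, PreprocessReport]:
    """Build a :class:`ContraindicationTable` from raw (name A, name B) rows.

    Both names are normalized; pairs are unordered, so ``(X, Y)`` and
    ``(Y, X)`` dedup to one pair.  A row with a missing or empty name is
    skipped with its index recorded in the report.
    """
    table = ContraindicationTable()
    dupes = 0
    skipped: list[int] = []
    raw_count = 0
    for idx, record in enumerate(records):
        raw_count += 1
        try:
            raw_a, raw_b = record
            pair = (normalize_name(raw_a), normalize_name(raw_b))
        except (InvalidInputError, TypeError, ValueError) as exc:
            logger.warning("contraindication row %d skipped: %s", idx, exc)
            skipped.append(idx)
            continue
        if not table.add(*pair):
            dupes += 1
    report = PreprocessReport(
        raw_count=raw_count,
        normalized_count=len(table),
        duplicates_removed=dupes,
        skipped_rows=tuple(skipped),
    )
    return table, report


# ---------------------------------------------------------------------------
# CSV interfaces


def _read_rows(path: str | Path) -> tuple[list[str], list[dict[str, str]]]:
    path = Path(path)
    if not path.exists():
        raise InvalidInputError(f"input file not found: {path}")
    delimiter = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        if reader.fieldnames is None:
            raise InvalidInputError(f"no header row in {path}")
        return list(reader.fieldnames), list(reader)


def read_catalog_csv(
    path: str | Path, name_column: str = "product_name"
) -> tuple[DrugCatalog, PreprocessReport]:
    """Load a catalog from a CSV/TSV file with a header row."""
    fields, rows = _read_rows(path)
    if name_column not in fields:
        raise InvalidInputError(
            f"column {name_column!r} not found in {path} (has {fields})"
        )
    return load_catalog([row[name_column] for row in rows])


def read_contraindications_csv(
    path: str | Path,
    column_a: str = "product_name_a",
    column_b: str = "product_name_b",
) -> tuple[ContraindicationTable, PreprocessReport]:
    """Load a contraindication table from CSV/TSV; ingredient-code columns
    present in the source are ignored for matching."""
    fields, rows = _read_rows(path)
    for col in (column_a, column_b):
        if col not in fields:
            raise InvalidInputError(f"column {col!r} not found in {path}")
    return load_contraindications(
        [(row.get(column_a) or "", row.get(column_b) or "") for row in rows]
    )


def write_catalog_csv(catalog: DrugCatalog, path: str | Path) -> None:
    """Write normalized entries with a ``raw_names`` provenance column."""
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["product_name", "raw_names"])
        for entry in catalog.entries:
            writer.writerow([entry, "|".join(catalog.provenance[entry])])
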