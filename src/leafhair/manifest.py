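"""Core domain types: the 9-level ordinal hairiness scale and the dataset manifest.

The manifest is a plain CSV, one row per image, carrying the leaf-level
metadata (leaf id, genotype colorname, score, leaf number, year, environment,
site) plus the per-image position on the leaf (vein index, position index,
is-first flag) and the image path. All downstream stages (splitting, training,
scoring) consume this structure.
"""

from __future__ import annotations

import csv
import functools
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping

__all__ = [
    "SCORE_LABELS",
    "SCORE_ALIASES",
    "ScoreClass",
    "ImageRecord",
    "Manifest",
    "ManifestError",
    "parse_score_label",
    "read_manifest",
    "write_manifest",
]

#: Canonical label order of the ordinal hairiness scale, glabrous to pilose.
SCORE_LABELS: tuple[str, ...] = ("1", "2", "3", "3/4", "4", "4/4+", "4+", "5", "5+")

#: Print variants accepted on input and normalized to a canonical label.
SCORE_ALIASES: Mapping[str, str] = {"4/4": "4/4+"}

MANIFEST_COLUMNS = (
    "image_id",
    "leaf_id",
    "genotype",
    "score",
    "leaf_number",
    "year",
    "environment",
    "site",
    "vein_index",
    "position_index",
    "is_first",
    "image_path",
)

_LEAF_LEVEL_FIELDS = ("genotype", "score", "leaf_number", "year", "environment", "site")

YEARS = ("Y1", "Y2")
ENVIRONMENTS = ("GH", "FD")
SITES = ("N", "C")
LEAF_NUMBERS = (3, 4)


class ManifestError(ValueError):
    """Raised when a manifest violates its structural invariants."""


@functools.total_ordering
@dataclass(frozen=True)
class ScoreClass:
    """One of the 9 ordered hairiness labels; ``rank`` is its position on the scale."""

    label: str
    rank: int

    def __post_init__(self) -> None:
        if self.label not in SCORE_LABELS:
            raise ValueError(f"unknown score label {self.label!r}")
        if SCORE_LABELS.index(self.label) != self.rank:
            raise ValueError(f"rank {self.rank} inconsistent with label {self.label!r}")

    @classmethod
    def from_label(cls, label: str) -> "ScoreClass":
        return parse_score_label(label)

    @classmethod
    def from_rank(cls, rank: int) -> "ScoreClass":
        if not 0 <= rank < len(SCORE_LABELS):
            raise ValueError(f"rank must be in [0, {len(SCORE_LABELS) - 1}], got {rank}")
        return cls(SCORE_LABELS[rank], rank)

    def __lt__(self, other: object) -> bool:
        if not isinstance(other, ScoreClass):
            return NotImplemented
        return self.rank < other.rank

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


def parse_score_label(text: str) -> ScoreClass:
    """Parse a score token into a :class:`ScoreClass`.

    The print variant ``"4/4"`` is accepted as an alias of ``"4/4+"``.
    Raises :class:`ValueError` for tokens not on the scale.
    """
    token = text.strip()
    token = SCORE_ALIASES.get(token, token)
    if token not in SCORE_LABELS:
        raise ValueError(
            f"unknown score label {text!r}; valid labels are "
            f"{', '.join(SCORE_LABELS)} (alias: 4/4 -> 4/4+)"
        )
    return ScoreClass(token, SCORE_LABELS.index(token))


@dataclass(frozen=True)
class ImageRecord:
    """Per-image metadata row. ``extras`` holds any non-schema columns found on read."""

    image_id: str
    leaf_id: str
    genotype: str
    score: ScoreClass
    leaf_number: int
    year: str
    environment: str
    site: str
    vein_index: int
    position_index: int
    is_first: bool
    image_path: str
    extras: tuple[tuple[str, str], ...] = field(default=(), compare=True)

    def __post_init__(self) -> None:
        if self.leaf_number not in LEAF_NUMBERS:
            raise ValueError(f"leaf_number must be one of {LEAF_NUMBERS}, got {self.leaf_number}")
        if self.year not in YEARS:
            raise ValueError(f"year must be one of {YEARS}, got {self.year!r}")
        if self.environment not in ENVIRONMENTS:
            raise ValueError(
                f"environment must be one of {ENVIRONMENTS}, got {self.environment!r}"
            )
        if self.site not in SITES:
            raise ValueError(f"site must be one of {SITES}, got {self.site!r}")
        if not 1 <= self.vein_index <= 3:
            raise ValueError(f"vein_index must be in [1, 3], got {self.vein_index}")
        if self.position_index < 1:
            raise ValueError(f"position_index must be >= 1, got {self.position_index}")


@dataclass(frozen=True)
class Manifest:
    """Ordered collection of :class:`ImageRecord` with validated leaf grouping."""

    records: tuple[ImageRecord, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        validate_records(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ImageRecord]:
        return iter(self.records)

    @property
    def image_ids(self) -> tuple[str, ...]:
        return tuple(r.image_id for r in self.records)

    def by_image_id(self) -> dict[str, ImageRecord]:
        return {r.image_id: r for r in self.records}

    def leaf_groups(self) -> dict[str, list[ImageRecord]]:
        """Partition of records by leaf_id, preserving row order."""
        groups: dict[str, list[ImageRecord]] = {}
        for r in self.records:
            groups.setdefault(r.leaf_id, []).append(r)
        return groups

    def score_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for r in self.records:
            counts[r.score.label] = counts.get(r.score.label, 0) + 1
        return counts

    def subset(self, image_ids: Iterable[str]) -> "Manifest":
        """Row-order-preserving restriction to the given image ids."""
        wanted = set(image_ids)
        return Manifest(tuple(r for r in self.records if r.image_id in wanted))


def validate_records(records: Iterable[ImageRecord]) -> None:
    """Check manifest invariants; raise :class:`ManifestError` citing row numbers.

    Row numbers are 1-based over the record sequence (header excluded).
    """
    seen: dict[str, int] = {}
    leaf_meta: dict[str, tuple] = {}
    leaf_meta_row: dict[str, int] = {}
    first_rows: dict[str, list[int]] = {}
    leaf_rows: dict[str, list[int]] = {}
    for i, r in enumerate(records, start=1):
        if r.image_id in seen:
            raise ManifestError(
                f"duplicate image_id {r.image_id!r} at rows {seen[r.image_id]} and {i}"
            )
        seen[r.image_id] = i
        meta = tuple(getattr(r, f) for f in _LEAF_LEVEL_FIELDS)
        if r.leaf_id in leaf_meta:
            if leaf_meta[r.leaf_id] != meta:
                raise ManifestError(
                    f"inconsistent leaf-level metadata for leaf {r.leaf_id!r}: "
                    f"row {i} disagrees with row {leaf_meta_row[r.leaf_id]}"
                )
        else:
            leaf_meta[r.leaf_id] = meta
            leaf_meta_row[r.leaf_id] = i
        leaf_rows.setdefault(r.leaf_id, []).append(i)
        if r.is_first:
            first_rows.setdefault(r.leaf_id, []).append(i)
    for leaf_id, rows in leaf_rows.items():
        firsts = first_rows.get(leaf_id, [])
        if len(firsts) == 0:
            raise ManifestError(f"leaf {leaf_id!r} has no is_first record (rows {rows})")
        if len(firsts) > 1:
            raise ManifestError(f"leaf {leaf_id!r} has multiple is_first records at rows {firsts}")


def _record_to_row(r: ImageRecord) -> dict[str, str]:
    return {
        "image_id": r.image_id,
        "leaf_id": r.leaf_id,
        "genotype": r.genotype,
        "score": r.score.label,
        "leaf_number": str(r.leaf_number),
        "year": r.year,
        "environment": r.environment,
        "site": r.site,
        "vein_index": str(r.vein_index),
        "position_index": str(r.position_index),
        "is_first": "true" if r.is_first else "false",
        "image_path": r.image_path,
    }


def _row_to_record(row: Mapping[str, str], rownum: int, extra_cols: tuple[str, ...]) -> ImageRecord:
    try:
        is_first_raw = row["is_first"].strip().lower()
        if is_first_raw not in ("true", "false"):
            raise ManifestError(f"row {rownum}: is_first must be true/false, got {row['is_first']!r}")
        return ImageRecord(
            image_id=row["image_id"],
            leaf_id=row["leaf_id"],
            genotype=row["genotype"],
            score=parse_score_label(row["score"]),
            leaf_number=int(row["leaf_number"]),
            year=row["year"],
            environment=row["environment"],
            site=row["site"],
            vein_index=int(row["vein_index"]),
            position_index=int(row["position_index"]),
            is_first=is_first_raw == "true",
            image_path=row["image_path"],
            extras=tuple((c, row[c]) for c in extra_cols),
        )
    except (ValueError, KeyError) as exc:
        if isinstance(exc, ManifestError):
            raise
        raise ManifestError(f"row {rownum}: {exc}") from exc


def read_manifest(path: str) -> Manifest:
    """Read a manifest CSV. Extra columns are preserved in ``record.extras``."""
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in MANIFEST_COLUMNS if c not in header]
        if missing:
            raise ManifestError(f"manifest {path} missing columns: {', '.join(missing)}")
        extra_cols = tuple(c for c in header if c not in MANIFEST_COLUMNS)
        records = [_row_to_record(row, i, extra_cols) for i, row in enumerate(reader, start=1)]
    return Manifest(tuple(records))


def write_manifest(manifest: Manifest, path: str) -> None:
    """Write the manifest as UTF-8 CSV; ``read_manifest`` round-trips exactly."""
    extra_cols: list[str] = []
    for r in manifest.records:
        for c, _ in r.extras:
            if c not in extra_cols:
                extra_cols.append(c)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(MANIFEST_COLUMNS) + extra_cols)
        writer.writeheader()
        for r in manifest.records:
            row = _record_to_row(r)
            row.update(dict(r.extras))
            writer.writerow(row)


def strip_extras(manifest: Manifest) -> Manifest:
    """Drop all non-schema columns from every record."""
    return Manifest(tuple(replace(r, extras=()) for r in manifest.records))
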