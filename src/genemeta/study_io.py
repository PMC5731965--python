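"""Study-level data model and CSV I/O for case-control genotype counts.

A *study* is one published case-control comparison carrying genotype
counts (GG / GA / AA for a biallelic G>A variant) in each arm plus the
grouping metadata used in subgroup analyses (country, control source).
A *collapsed* record carries only an exposed/reference split per arm
(GA+AA vs GG), the form in which stratified counts (by sex, smoking or
drinking status) are typically reported.

CSV schemas
-----------
studies CSV::

    study_id,first_author,year,country,control_source,
    case_gg,case_ga,case_aa,control_gg,control_ga,control_aa,nos_score

``nos_score`` (Newcastle-Ottawa quality score, 0-9) is optional and
carried as metadata only.

collapsed CSV::

    study_id,stratum_label,case_exposed,case_ref,control_exposed,control_ref
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator, Sequence

__all__ = [
    "ValidationError",
    "GenotypeCounts",
    "StudyRecord",
    "CollapsedStudyRecord",
    "StudyCollection",
    "read_studies_csv",
    "write_studies_csv",
    "read_collapsed_csv",
    "write_collapsed_csv",
    "load_bundled_table2",
    "BUNDLED_TABLE2_NOTES",
]

STUDY_COLUMNS = (
    "study_id", "first_author", "year", "country", "control_source",
    "case_gg", "case_ga", "case_aa",
    "control_gg", "control_ga", "control_aa",
)
COLLAPSED_COLUMNS = (
    "study_id", "stratum_label",
    "case_exposed", "case_ref", "control_exposed", "control_ref",
)

CONTROL_SOURCES = ("HB", "PB")  # hospital-based / population-based

#: Provenance notes for the packaged 12-study gastric-cancer fixture.
#: The source publication prints the Matsuo case total as 697 in its
#: characteristics table but 696 in its genotype table (310+323+63).
#: The fixture treats the genotype counts as ground truth, so total
#: cases sum to 6420 rather than the headline 6421; control totals sum
#: to 8832 either way.  Yuan's controls violate Hardy-Weinberg
#: equilibrium (p ~ 0.03) and are retained, as in the source analysis.
BUNDLED_TABLE2_NOTES = (
    "Matsuo case total taken from genotype counts (696, not 697); "
    "Yuan's HWE-violating controls retained."
)


class ValidationError(ValueError):
    """An input record or file violates the documented schema."""


@dataclass(frozen=True)
class GenotypeCounts:
    """Genotype counts for one study arm of a biallelic G>A variant."""

    gg: int
    ga: int
    aa: int

    def __post_init__(self) -> None:
        for name in ("gg", "ga", "aa"):
            v = getattr(self, name)
            if not isinstance(v, int) or isinstance(v, bool):
                raise ValidationError(f"genotype count {name!r} must be an integer, got {v!r}")
            if v < 0:
                raise ValidationError(f"genotype count {name!r} must be non-negative, got {v}")

    def total(self) -> int:
        return self.gg + self.ga + self.aa

    @property
    def g_alleles(self) -> int:
        """Count of major (G) alleles: 2*gg + ga."""
        return 2 * self.gg + self.ga

    @property
    def a_alleles(self) -> int:
        """Count of minor (A) alleles: ga + 2*aa."""
        return self.ga + 2 * self.aa

    def maf(self) -> float:
        """Frequency of the A allele in this arm."""
        n = self.total()
        if n == 0:
            raise ValidationError("cannot compute allele frequency of an empty arm")
        return self.a_alleles / (2 * n)


@dataclass(frozen=True)
class StudyRecord:
    """One case-control study: genotype counts plus grouping metadata."""

    study_id: str
    first_author: str
    year: int
    country: str
    control_source: str
    cases: GenotypeCounts
    controls: GenotypeCounts
    nos_score: int | None = None

    def __post_init__(self) -> None:
        if not self.study_id:
            raise ValidationError("study_id must be non-empty")
        if self.cases.total() <= 0:
            raise ValidationError(f"study {self.study_id!r}: case arm is empty")
        if self.controls.total() <= 0:
            raise ValidationError(f"study {self.study_id!r}: control arm is empty")
        if not self.country:
            raise ValidationError(f"study {self.study_id!r}: country must be non-empty")
        if self.control_source not in CONTROL_SOURCES:
            raise ValidationError(
                f"study {self.study_id!r}: control_source must be one of "
                f"{CONTROL_SOURCES}, got {self.control_source!r}"
            )
        if self.nos_score is not None and not 0 <= self.nos_score <= 9:
            raise ValidationError(
                f"study {self.study_id!r}: nos_score must be in 0..9, got {self.nos_score}"
            )


@dataclass(frozen=True)
class CollapsedStudyRecord:
    """Dominant-model counts for one study within a labelled stratum.

    Carries only the exposed (GA+AA) / reference (GG) split per arm,
    the form in which sex-, smoking- and drinking-stratified counts
    are usually published.
    """

    study_id: str
    stratum_label: str
    case_exposed: int
    case_ref: int
    control_exposed: int
    control_ref: int

    def __post_init__(self) -> None:
        for name in ("case_exposed", "case_ref", "control_exposed", "control_ref"):
            v = getattr(self, name)
            if not isinstance(v, int) or isinstance(v, bool) or v < 0:
                raise ValidationError(
                    f"record {self.study_id!r}: {name!r} must be a non-negative integer, got {v!r}"
                )
        if self.case_exposed + self.case_ref <= 0:
            raise ValidationError(f"record {self.study_id!r}: case arm is empty")
        if self.control_exposed + self.control_ref <= 0:
            raise ValidationError(f"record {self.study_id!r}: control arm is empty")


@dataclass
class StudyCollection:
    """Ordered collection of studies with unique identifiers."""

    studies: list[StudyRecord] = field(default_factory=list)
    label: str = ""

    def __post_init__(self) -> None:
        ids = [s.study_id for s in self.studies]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValidationError(f"duplicate study_id values: {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.studies)

    def __iter__(self) -> Iterator[StudyRecord]:
        return iter(self.studies)

    def __getitem__(self, study_id: str) -> StudyRecord:
        for s in self.studies:
            if s.study_id == study_id:
                return s
        raise KeyError(study_id)

    def study_ids(self) -> list[str]:
        return [s.study_id for s in self.studies]

    def subset(self, predicate, label: str | None = None) -> "StudyCollection":
        """New collection with the studies satisfying ``predicate``."""
        kept = [s for s in self.studies if predicate(s)]
        return StudyCollection(kept, label if label is not None else self.label)

    def drop(self, study_id: str) -> "StudyCollection":
        """New collection with one study removed."""
        if study_id not in self.study_ids():
            raise KeyError(study_id)
        return StudyCollection(
            [s for s in self.studies if s.study_id != study_id], self.label
        )

    def group_by(self, attr: str) -> dict[str, "StudyCollection"]:
        """Partition into sub-collections keyed by a metadata attribute."""
        groups: dict[str, StudyCollection] = {}
        for s in self.studies:
            key = getattr(s, attr)
            groups.setdefault(key, StudyCollection([], label=key)).studies.append(s)
        return groups

    def total_cases(self) -> int:
        return sum(s.cases.total() for s in self.studies)

    def total_controls(self) -> int:
        return sum(s.controls.total() for s in self.studies)


def _parse_int(value: str, row: int, column: str) -> int:
    try:
        return int(value)
    except (TypeError, ValueError):
        raise ValidationError(
            f"row {row}: column {column!r} must be an integer, got {value!r}"
        ) from None


def _check_header(header: Sequence[str] | None, required: Sequence[str], path) -> None:
    if header is None:
        raise ValidationError(f"{path}: file is empty (no header row)")
    missing = [c for c in required if c not in header]
    if missing:
        raise ValidationError(f"{path}: missing required column(s) {missing}")


def read_studies_csv(path: str | Path, label: str | None = None) -> StudyCollection:
    """Read a studies CSV into a :class:`StudyCollection`.

    Rows are kept in file order.  Raises :class:`ValidationError` naming
    the offending row and field for any schema violation (missing
    column, non-integer or negative count, duplicate study_id).
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        _check_header(reader.fieldnames, STUDY_COLUMNS, path)
        studies: list[StudyRecord] = []
        for i, row in enumerate(reader, start=2):  # header is line 1
            counts = {c: _parse_int(row[c], i, c) for c in STUDY_COLUMNS[5:]}
            for c, v in counts.items():
                if v < 0:
                    raise ValidationError(f"row {i}: column {c!r} is negative ({v})")
            nos_raw = (row.get("nos_score") or "").strip()
            try:
                studies.append(StudyRecord(
                    study_id=row["study_id"],
                    first_author=row["first_author"],
                    year=_parse_int(row["year"], i, "year"),
                    country=row["country"],
                    control_source=row["control_source"],
                    cases=GenotypeCounts(counts["case_gg"], counts["case_ga"], counts["case_aa"]),
                    controls=GenotypeCounts(
                        counts["control_gg"], counts["control_ga"], counts["control_aa"]
                    ),
                    nos_score=_parse_int(nos_raw, i, "nos_score") if nos_raw else None,
                ))
            except ValidationError as err:
                raise ValidationError(f"row {i}: {err}") from None
    return StudyCollection(studies, label if label is not None else path.stem)


def write_studies_csv(collection: StudyCollection, path: str | Path) -> None:
    """Write a collection in the studies CSV schema (lossless round-trip)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(STUDY_COLUMNS + ("nos_score",))
        for s in collection:
            writer.writerow([
                s.study_id, s.first_author, s.year, s.country, s.control_source,
                s.cases.gg, s.cases.ga, s.cases.aa,
                s.controls.gg, s.controls.ga, s.controls.aa,
                "" if s.nos_score is None else s.nos_score,
            ])


def read_collapsed_csv(path: str | Path) -> list[CollapsedStudyRecord]:
    """Read a collapsed (dominant-model-only) CSV into records."""
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        _check_header(reader.fieldnames, COLLAPSED_COLUMNS, path)
        records: list[CollapsedStudyRecord] = []
        for i, row in enumerate(reader, start=2):
            counts = {c: _parse_int(row[c], i, c) for c in COLLAPSED_COLUMNS[2:]}
            try:
                records.append(CollapsedStudyRecord(
                    study_id=row["study_id"],
                    stratum_label=row["stratum_label"],
                    **counts,
                ))
            except ValidationError as err:
                raise ValidationError(f"row {i}: {err}") from None
    return records


def write_collapsed_csv(records: Sequence[CollapsedStudyRecord], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(COLLAPSED_COLUMNS)
        for r in records:
            writer.writerow([
                r.study_id, r.stratum_label,
                r.case_exposed, r.case_ref, r.control_exposed, r.control_ref,
            ])


def load_bundled_table2() -> StudyCollection:
    """Load the packaged 12-study ALDH2 rs671 / gastric-cancer fixture.

    Twelve East-Asian case-control studies (8 China, 2 Japan, 2 Korea;
    6 hospital-based, 6 population-based controls) with per-arm
    genotype counts; see :data:`BUNDLED_TABLE2_NOTES` for provenance
    caveats.
    """
    src = resources.files("genemeta.data").joinpath("table2_studies.csv")
    with resources.as_file(src) as p:
        return read_studies_csv(p, label="aldh2_rs671_gastric_cancer")
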