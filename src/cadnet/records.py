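"""EMR record data model, term normalization, and cohort I/O.

The unit of analysis is one hospitalization record carrying two sets of
canonical clinical terms: *diagnoses* (index-disease diagnoses such as
"Unstable Angina" or severity classes like "KILLIP Class I") and
*comorbidities* (accompanying conditions such as "Hypertension").
Raw free-text terms are mapped onto canonical vocabulary entries through a
deterministic lookup table (:class:`TermMap`); no fuzzy matching or NLP is
attempted here — the mapping table is the normalization.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "Sex",
    "Category",
    "MedicalRecord",
    "TermMap",
    "Cohort",
    "CohortParseError",
    "UnmappedTermError",
    "load_cohort",
    "write_cohort",
    "apply_term_map",
    "load_term_map",
    "vocab_summary",
]

AGE_RANGE = (18, 120)
YEAR_RANGE = (1990, 2100)

CSV_COLUMNS = [
    "record_id",
    "sex",
    "age",
    "admission_year",
    "city",
    "diagnoses",
    "comorbidities",
]
LIST_SEP = ";"


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"


class Category(str, Enum):
    DIAGNOSIS = "diagnosis"
    COMORBIDITY = "comorbidity"


class CohortParseError(ValueError):
    """Structured parse failure naming the offending row and field."""

    def __init__(self, row: int | None, field_name: str | None, message: str):
        self.row = row
        self.field = field_name
        loc = []
        if row is not None:
            loc.append(f"row {row}")
        if field_name is not None:
            loc.append(f"field '{field_name}'")
        prefix = " ".join(loc)
        super().__init__(f"{prefix}: {message}" if prefix else message)


class UnmappedTermError(ValueError):
    """Raised in strict normalization when raw terms have no mapping."""

    def __init__(self, terms: Sequence[str]):
        self.terms = sorted(set(terms))
        super().__init__(
            "unmapped terms (strict mode): " + ", ".join(repr(t) for t in self.terms)
        )


def _clean_terms(terms: Iterable[str]) -> frozenset[str]:
    out = {t.strip() for t in terms}
    out.discard("")
    return frozenset(out)


@dataclass(frozen=True)
class MedicalRecord:
    """One hospitalization with canonical diagnosis/comorbidity term sets."""

    record_id: str
    sex: Sex
    age: int
    admission_year: int
    diagnoses: frozenset[str] = frozenset()
    comorbidities: frozenset[str] = frozenset()
    city: str | None = None

    def __post_init__(self):
        object.__setattr__(self, "sex", Sex(self.sex))
        object.__setattr__(self, "diagnoses", _clean_terms(self.diagnoses))
        object.__setattr__(self, "comorbidities", _clean_terms(self.comorbidities))
        if not str(self.record_id).strip():
            raise ValueError("record_id must be non-empty")
        if not AGE_RANGE[0] <= self.age <= AGE_RANGE[1]:
            raise ValueError(f"age {self.age} outside {AGE_RANGE}")
        if not YEAR_RANGE[0] <= self.admission_year <= YEAR_RANGE[1]:
            raise ValueError(f"admission_year {self.admission_year} outside {YEAR_RANGE}")

    def terms(self, category: Category | str) -> frozenset[str]:
        category = Category(category)
        return self.diagnoses if category is Category.DIAGNOSIS else self.comorbidities


@dataclass(frozen=True)
class Cohort:
    """Ordered collection of records plus the canonical vocabularies."""

    records: tuple[MedicalRecord, ...]

    def __post_init__(self):
        object.__setattr__(self, "records", tuple(self.records))
        ids = [r.record_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate record_ids: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def diagnosis_vocabulary(self) -> frozenset[str]:
        return frozenset().union(*(r.diagnoses for r in self.records)) if self.records else frozenset()

    @property
    def comorbidity_vocabulary(self) -> frozenset[str]:
        return frozenset().union(*(r.comorbidities for r in self.records)) if self.records else frozenset()

    def vocabulary(self, category: Category | str) -> frozenset[str]:
        category = Category(category)
        if category is Category.DIAGNOSIS:
            return self.diagnosis_vocabulary
        return self.comorbidity_vocabulary

    def n_by_sex(self) -> dict[Sex, int]:
        out = {Sex.MALE: 0, Sex.FEMALE: 0}
        for r in self.records:
            out[r.sex] += 1
        return out


@dataclass(frozen=True)
class TermMap:
    """Deterministic raw-term → (canonical term, category) lookup.

    Matching is case-insensitive after whitespace trimming; the canonical
    output preserves the mapping table's casing.
    """

    entries: Mapping[str, tuple[str, Category]]
    _index: dict[str, tuple[str, Category]] = field(init=False, repr=False)

    def __post_init__(self):
        index: dict[str, tuple[str, Category]] = {}
        for raw, (canon, cat) in dict(self.entries).items():
            key = raw.strip().lower()
            canon = canon.strip()
            if not key or not canon:
                raise ValueError("raw and canonical terms must be non-empty")
            cat = Category(cat)
            if key in index and index[key] != (canon, cat):
                raise ValueError(f"conflicting mappings for raw term {raw!r}")
            index[key] = (canon, cat)
        object.__setattr__(self, "_index", index)

    def __len__(self) -> int:
        return len(self._index)

    def lookup(self, raw: str) -> tuple[str, Category] | None:
        return self._index.get(raw.strip().lower())


def load_term_map(path: str | Path) -> TermMap:
    """Read a raw_term,canonical_term,category CSV into a :class:`TermMap`."""
    entries: dict[str, tuple[str, Category]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {"raw_term", "canonical_term", "category"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise CohortParseError(None, None, f"term map needs columns {sorted(required)}")
        for i, row in enumerate(reader, start=2):
            entries[row["raw_term"]] = (row["canonical_term"], Category(row["category"]))
    return TermMap(entries)


# ---------------------------------------------------------------------------
# cohort I/O


def _record_from_mapping(obj: Mapping, row: int, fmt: str) -> MedicalRecord:
    for name in ("record_id", "sex", "age", "admission_year"):
        if name not in obj or obj[name] in (None, ""):
            raise CohortParseError(row, name, "missing required field")
    sex_token = str(obj["sex"]).strip().lower()
    try:
        sex = Sex(sex_token)
    except ValueError:
        raise CohortParseError(row, "sex", f"unknown sex token {obj['sex']!r}") from None
    try:
        age = int(obj["age"])
        year = int(obj["admission_year"])
    except (TypeError, ValueError) as exc:
        raise CohortParseError(row, "age/admission_year", str(exc)) from None

    def listify(value) -> list[str]:
        if value is None:
            return []
        if isinstance(value, str):
            return value.split(LIST_SEP) if fmt == "csv" else [value]
        return list(value)

    dia = listify(obj.get("diagnoses"))
    com = listify(obj.get("comorbidities"))
    if fmt == "csv":  # JSONL carries real lists; CSV packs them with ';'
        dia = obj.get("diagnoses", "").split(LIST_SEP) if obj.get("diagnoses") else []
        com = obj.get("comorbidities", "").split(LIST_SEP) if obj.get("comorbidities") else []
    city = obj.get("city") or None
    try:
        return MedicalRecord(
            record_id=str(obj["record_id"]),
            sex=sex,
            age=age,
            admission_year=year,
            diagnoses=dia,
            comorbidities=com,
            city=city,
        )
    except ValueError as exc:
        raise CohortParseError(row, None, str(exc)) from None


def load_cohort(path: str | Path, format: str | None = None) -> Cohort:
    """Load a cohort from JSON Lines or CSV.

    The format is inferred from the suffix when not given. Term list fields
    are JSON arrays in JSONL and ";"-separated strings in CSV. Row order is
    preserved; duplicate record ids are an error.
    """
    path = Path(path)
    fmt = format or ("csv" if path.suffix.lower() == ".csv" else "jsonl")
    if fmt not in ("jsonl", "csv"):
        raise ValueError(f"unknown format {fmt!r}")
    records: list[MedicalRecord] = []
    if fmt == "jsonl":
        with open(path, encoding="utf-8") as fh:
            for i, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    obj = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise CohortParseError(i, None, f"invalid JSON: {exc}") from None
                records.append(_record_from_mapping(obj, i, "jsonl"))
    else:
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            for i, row in enumerate(reader, start=2):
                records.append(_record_from_mapping(row, i, "csv"))
    try:
        return Cohort(records)
    except ValueError as exc:
        raise CohortParseError(None, "record_id", str(exc)) from None


def write_cohort(cohort: Cohort, path: str | Path, format: str | None = None) -> None:
    """Write a cohort as JSONL or CSV (the `load_cohort` round-trip partner)."""
    path = Path(path)
    fmt = format or ("csv" if path.suffix.lower() == ".csv" else "jsonl")
    if fmt == "jsonl":
        with open(path, "w", encoding="utf-8") as fh:
            for r in cohort:
                obj = {
                    "record_id": r.record_id,
                    "sex": r.sex.value,
                    "age": r.age,
                    "admission_year": r.admission_year,
                    "city": r.city,
                    "diagnoses": sorted(r.diagnoses),
                    "comorbidities": sorted(r.comorbidities),
                }
                fh.write(json.dumps(obj, ensure_ascii=False) + "\n")
    elif fmt == "csv":
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.DictWriter(fh, fieldnames=CSV_COLUMNS)
            writer.writeheader()
            for r in cohort:
                writer.writerow(
                    {
                        "record_id": r.record_id,
                        "sex": r.sex.value,
                        "age": r.age,
                        "admission_year": r.admission_year,
                        "city": r.city or "",
                        "diagnoses": LIST_SEP.join(sorted(r.diagnoses)),
                        "comorbidities": LIST_SEP.join(sorted(r.comorbidities)),
                    }
                )
    else:
        raise ValueError(f"unknown format {fmt!r}")


# ---------------------------------------------------------------------------
# normalization


def apply_term_map(cohort: Cohort, term_map: TermMap, strict: bool = False) -> Cohort:
    """Replace every raw term by its canonical form.

    Terms collapsing onto the same canonical form deduplicate within a
    record (sets). Unmapped terms pass through unchanged unless ``strict``,
    in which case all unmapped terms are collected into one error. A term
    whose mapping assigns the other category is moved to that category's
    set, so a raw "diagnosis" string that the table classifies as a
    comorbidity ends up among the comorbidities.
    """
    if len(term_map) == 0:
        raise ValueError("term map is empty")
    unmapped: list[str] = []
    new_records = []
    for r in cohort:
        new_sets = {Category.DIAGNOSIS: set(), Category.COMORBIDITY: set()}
        for category in Category:
            for term in r.terms(category):
                hit = term_map.lookup(term)
                if hit is None:
                    unmapped.append(term)
                    new_sets[category].add(term)
                else:
                    canon, canon_cat = hit
                    new_sets[canon_cat].add(canon)
        new_records.append(
            replace(
                r,
                diagnoses=frozenset(new_sets[Category.DIAGNOSIS]),
                comorbidities=frozenset(new_sets[Category.COMORBIDITY]),
            )
        )
    if strict and unmapped:
        raise UnmappedTermError(unmapped)
    return Cohort(new_records)


def vocab_summary(before: Cohort, after: Cohort) -> dict:
    """Distinct term counts per category before and after normalization."""
    return {
        "diagnosis": {
            "before": len(before.diagnosis_vocabulary),
            "after": len(after.diagnosis_vocabulary),
        },
        "comorbidity": {
            "before": len(before.comorbidity_vocabulary),
            "after": len(after.comorbidity_vocabulary),
        },
    }
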