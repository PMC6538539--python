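"""Reading, validating, cleaning and writing entity-pair feature records.

A feature record is one extracted instance of a relation between two
biomedical entities in a sentence, as produced by rule-based entity/relation
extraction over PubMed abstracts: the two entity mentions with their semantic
types and local contexts, the relation verb linking them, negation and tense
flags, a reference relation word, the verb phrase and the raw sentence.
Records travel as UTF-8 tab-separated files with a header; the literal string
``"NA"`` is the single missing-value sentinel (trailing semicolons, an
artifact of the upstream extractor, are stripped on read).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, fields as dc_fields, replace
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

NA = "NA"

NEGATION_VALUES = ("POSITIVE", "NEGATIVE")
TENSE_VALUES = ("ACTIVE", "PASSIVE")

#: Binary relation classes: a direct cause-effect link via the relation verb,
#: versus an indirect association with no cause-effect.
BINARY_CLASSES = ("DirectedLink", "UndirectedLink")

#: Fine-grained relation classes.  Cause/Correlation split on directedness,
#: Increase/Decrease subtypes are distinguished by an effect trigger word,
#: and the two coarse classes remain as fallbacks when no finer type applies.
MULTICLASS_CLASSES = (
    "PositiveCause",
    "NegativeCause",
    "PositiveIncrease",
    "PositiveDecrease",
    "NegativeIncrease",
    "NegativeDecrease",
    "PositiveCorrelation",
    "NegativeCorrelation",
    "DirectedLink",
    "UndirectedLink",
)


class SchemaError(ValueError):
    """A record file does not match the expected column schema."""


class LabelError(ValueError):
    """A label value is not part of the active label scheme."""


@dataclass(frozen=True)
class LabelScheme:
    """A named, ordered set of relation classes.

    Parameters
    ----------
    name : {"binary", "multiclass"} or free text for custom schemes
    classes : ordered class names, unique; the binary scheme has exactly two.
    """

    name: str
    classes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.classes)) != len(self.classes):
            raise ValueError("class names must be unique")
        if self.name == "binary" and len(self.classes) != 2:
            raise ValueError("binary scheme must have exactly 2 classes")

    @classmethod
    def binary(cls) -> "LabelScheme":
        return cls("binary", BINARY_CLASSES)

    @classmethod
    def multiclass(cls) -> "LabelScheme":
        return cls("multiclass", MULTICLASS_CLASSES)

    @property
    def label_field(self) -> str:
        return "binary_label" if self.name == "binary" else "multiclass_label"

    def validate(self, label: str, row: int | None = None) -> str:
        if label not in self.classes:
            where = "" if row is None else f" (row {row})"
            raise LabelError(
                f"label {label!r} not in scheme {self.name!r} classes{where}"
            )
        return label


@dataclass
class FeatureRecord:
    """One extracted entity-pair instance with its 15 features and labels.

    Optional label fields are ``None`` when unlabeled; every other absent
    value is stored as the sentinel ``"NA"``.
    """

    doc_id: str
    sent_id: int
    entity_left: str
    type_left: str = NA
    context_left: str = NA
    entity_right: str = NA
    type_right: str = NA
    context_right: str = NA
    negation: str = "POSITIVE"
    tense: str = "ACTIVE"
    verb: str = NA
    relation: str = NA
    context_level: str = NA
    verb_phrase: str = NA
    sentence: str = NA
    binary_label: str | None = None
    multiclass_label: str | None = None

    def __post_init__(self) -> None:
        if self.sent_id < 0:
            raise ValueError(f"sent_id must be >= 0, got {self.sent_id}")
        if self.negation not in NEGATION_VALUES:
            raise ValueError(f"negation must be one of {NEGATION_VALUES}")
        if self.tense not in TENSE_VALUES:
            raise ValueError(f"tense must be one of {TENSE_VALUES}")

    def label(self, scheme: LabelScheme) -> str | None:
        return getattr(self, scheme.label_field)


#: TSV column name -> FeatureRecord attribute, in file column order.
COLUMN_MAP = {
    "id": "doc_id",
    "sent_id": "sent_id",
    "entity_l": "entity_left",
    "type_l": "type_left",
    "context_l": "context_left",
    "entity_r": "entity_right",
    "type_r": "type_right",
    "context_r": "context_right",
    "negation": "negation",
    "tense": "tense",
    "verb": "verb",
    "relation": "relation",
    "context_level": "context_level",
    "verb_phrase": "verb_phrase",
    "sentence": "sentence",
}
FEATURE_COLUMNS = tuple(COLUMN_MAP)
LABEL_COLUMNS = ("binary_label", "multiclass_label")


def _clean_cell(value: str) -> str:
    value = value.strip()
    # upstream extractor emits "NA;" style cells
    if value.endswith(";"):
        value = value[:-1]
    return value if value else NA


def read_records(
    path: str | Path, scheme: LabelScheme | None = None
) -> list[FeatureRecord]:
    """Read feature records from a tab-separated file with a header.

    The header must name all 15 feature columns (see ``FEATURE_COLUMNS``);
    the two label columns are optional.  When `scheme` is given, labels in
    its label column are validated against ``scheme.classes`` (the sentinel
    ``"NA"`` reads back as an absent label).

    Raises
    ------
    SchemaError
        if a mandatory column is missing or a row has the wrong width.
    LabelError
        if a label is outside the scheme, reporting the 1-based data row.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise SchemaError(f"{path}: empty file, expected a header row")
        header = [h.strip() for h in header]
        for col in FEATURE_COLUMNS:
            if col not in header:
                raise SchemaError(f"{path}: missing mandatory column {col!r}")
        positions = {col: header.index(col) for col in header}

        records: list[FeatureRecord] = []
        for row_no, row in enumerate(reader, start=1):
            if not row:
                continue
            if len(row) != len(header):
                raise SchemaError(
                    f"{path}: row {row_no} has {len(row)} columns, "
                    f"expected {len(header)}"
                )
            kwargs: dict[str, object] = {}
            for col, attr in COLUMN_MAP.items():
                cell = _clean_cell(row[positions[col]])
                kwargs[attr] = int(cell) if attr == "sent_id" else cell
            for col in LABEL_COLUMNS:
                if col in positions:
                    cell = _clean_cell(row[positions[col]])
                    kwargs[col] = None if cell == NA else cell
            record = FeatureRecord(**kwargs)
            if scheme is not None:
                label = record.label(scheme)
                if label is not None:
                    scheme.validate(label, row=row_no)
            records.append(record)
    return records


@dataclass(frozen=True)
class CleaningRules:
    """Which fields must be present for a record to survive cleaning."""

    required_fields: tuple[str, ...] = ("entity_left", "entity_right", "verb")
    require_sentence: bool = True

    def keeps(self, record: FeatureRecord) -> bool:
        for name in self.required_fields:
            value = getattr(record, name)
            if not value or value == NA:
                return False
        if self.require_sentence and not record.sentence:
            return False
        return True


def clean_records(
    records: Iterable[FeatureRecord], rules: CleaningRules | None = None
) -> list[FeatureRecord]:
    """Drop records with irregular core fields; an order-preserving filter.

    A record is dropped when either entity, or the relation verb, is empty or
    the ``"NA"`` sentinel, or when the sentence is empty.  Idempotent; the
    number of dropped records is logged.
    """
    rules = rules or CleaningRules()
    records = list(records)
    kept = [r for r in records if rules.keeps(r)]
    dropped = len(records) - len(kept)
    if dropped:
        logger.info("clean_records: dropped %d of %d records", dropped, len(records))
    return kept


def write_records(
    records: Sequence[FeatureRecord], path: str | Path
) -> Path:
    """Write records as UTF-8 TSV; inverse of :func:`read_records`.

    Label columns are always written, with ``"NA"`` for absent labels, so
    a write/read round trip preserves every field exactly.
    """
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(list(FEATURE_COLUMNS) + list(LABEL_COLUMNS))
        for rec in records:
            row = [str(getattr(rec, attr)) for attr in COLUMN_MAP.values()]
            row += [rec.binary_label or NA, rec.multiclass_label or NA]
            writer.writerow(row)
    return path
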