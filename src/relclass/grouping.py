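"""Feature groups: turning a record's fields into a single classifier text.

Five fixed orderings of record fields are concatenated into one plain-text
string per record — from a minimal triple (both entities and the relation
verb) up to every extracted feature plus the raw sentence, or the raw
sentence alone.  Fields are joined by single spaces in the group's order,
``"NA"`` sentinels are skipped, and the result is truncated to a character
limit (default 256).
"""

from __future__ import annotations

from dataclasses import dataclass

from .records_io import NA, FeatureRecord, LabelScheme

DEFAULT_MAX_CHARS = 256

_GROUP3_FIELDS = (
    "entity_left",
    "type_left",
    "context_left",
    "entity_right",
    "type_right",
    "context_right",
    "negation",
    "tense",
    "verb",
    "relation",
    "context_level",
    "verb_phrase",
)

#: Field order per group: 1 = entities + verb; 2 = the most relevant
#: features; 3 = all extracted features; 4 = group 3 plus the sentence;
#: 5 = the raw sentence alone.
GROUP_FIELDS: dict[int, tuple[str, ...]] = {
    1: ("entity_left", "entity_right", "verb"),
    2: ("entity_left", "entity_right", "negation", "tense", "verb", "relation"),
    3: _GROUP3_FIELDS,
    4: _GROUP3_FIELDS + ("sentence",),
    5: ("sentence",),
}


class GroupConfigError(ValueError):
    """Unknown group number or invalid group specification."""


class LabelingError(ValueError):
    """A record lacks the label required to build a labeled dataset."""


@dataclass(frozen=True)
class GroupSpec:
    """A feature group: which fields, in which order, with which length cap."""

    group_no: int
    feature_order: tuple[str, ...]
    max_chars: int = DEFAULT_MAX_CHARS

    def __post_init__(self) -> None:
        if self.max_chars < 1:
            raise GroupConfigError("max_chars must be positive")

    @classmethod
    def for_group(cls, group_no: int, max_chars: int = DEFAULT_MAX_CHARS) -> "GroupSpec":
        try:
            order = GROUP_FIELDS[group_no]
        except KeyError:
            raise GroupConfigError(
                f"unknown group number {group_no!r}; expected 1..5"
            ) from None
        return cls(group_no=group_no, feature_order=order, max_chars=max_chars)


@dataclass(frozen=True)
class GroupText:
    """The concatenated, length-limited input text for one record."""

    text: str
    group_no: int
    record: FeatureRecord | None = None

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.text


def build_group_text(record: FeatureRecord, spec: GroupSpec) -> GroupText:
    """Concatenate the spec's fields of `record` into one group text.

    Fields are joined in order by single spaces; ``"NA"`` fields are skipped
    so sentinel tokens never reach the embedding vocabulary; the joined
    string is truncated to ``spec.max_chars`` characters and stripped.
    """
    parts = []
    for name in spec.feature_order:
        value = getattr(record, name)
        if value and value != NA:
            parts.append(value)
    text = " ".join(parts)[: spec.max_chars].strip()
    return GroupText(text=text, group_no=spec.group_no, record=record)


def build_dataset(
    records,
    spec: GroupSpec,
    scheme: LabelScheme,
) -> list[tuple[GroupText, str]]:
    """Build (group text, label) pairs for every record, order preserved.

    Raises :class:`LabelingError` naming the record if one lacks the label
    for `scheme`.
    """
    pairs: list[tuple[GroupText, str]] = []
    for rec in records:
        label = rec.label(scheme)
        if label is None:
            raise LabelingError(
                f"record {rec.doc_id!r}/{rec.sent_id} has no "
                f"{scheme.label_field} for scheme {scheme.name!r}"
            )
        pairs.append((build_group_text(rec, spec), label))
    return pairs
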