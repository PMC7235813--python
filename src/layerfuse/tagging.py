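"""BIO tag scheme for character-level clinical entity recognition.

Six clinical entity types — disease (Dis), symptom (Sym), test (Test),
treatment (Tre), medicine (Med) and abnormal inspection result (Abn) —
are encoded over a character sequence with the BIO scheme: ``B-t`` opens
an entity of type ``t``, ``I-t`` continues it, ``O`` marks a non-entity
character.  That gives a 13-label vocabulary (6 types x {B, I} + O).

Spans use 0-based half-open offsets ``[start, end)``.  Nested or
overlapping entities are not representable in a single BIO layer and are
rejected.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Sequence

ENTITY_TYPES: tuple = ("Dis", "Sym", "Test", "Tre", "Med", "Abn")

_TAGS: List[str] = [f"{p}-{t}" for t in ENTITY_TYPES for p in ("B", "I")] + ["O"]
_TAG_INDEX = {t: i for i, t in enumerate(_TAGS)}

O_TAG = "O"
REPAIR_POLICIES = ("start-new", "strict")


class TagVocabularyError(ValueError):
    """A label outside the 13-tag vocabulary was encountered."""


class SpanValidationError(ValueError):
    """Entity spans violate the non-overlap / bounds contract."""


def tag_vocabulary() -> List[str]:
    """Return the 13 BIO labels in stable order, ``O`` last.

    Order: B-Dis, I-Dis, B-Sym, I-Sym, B-Test, I-Test, B-Tre, I-Tre,
    B-Med, I-Med, B-Abn, I-Abn, O.
    """
    return list(_TAGS)


def tag_index(tag: str) -> int:
    try:
        return _TAG_INDEX[tag]
    except KeyError:
        raise TagVocabularyError(f"unknown tag {tag!r}; expected one of {_TAGS}")


@dataclass(frozen=True, order=True)
class EntitySpan:
    """A typed entity occupying characters ``[start, end)`` of a sentence."""

    start: int
    end: int
    entity_type: str

    def __post_init__(self):
        if self.entity_type not in ENTITY_TYPES:
            raise SpanValidationError(
                f"unknown entity type {self.entity_type!r}; "
                f"expected one of {ENTITY_TYPES}"
            )
        if not (0 <= self.start < self.end):
            raise SpanValidationError(
                f"need 0 <= start < end, got [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


def _check_spans(spans: Sequence[EntitySpan], length: int) -> List[EntitySpan]:
    ordered = sorted(spans)
    for s in ordered:
        if s.end > length:
            raise SpanValidationError(
                f"span {s} exceeds sentence length {length}"
            )
    for a, b in zip(ordered, ordered[1:]):
        if b.start < a.end:
            raise SpanValidationError(f"overlapping spans: {a} and {b}")
    return ordered


def spans_to_tags(spans: Iterable[EntitySpan], length: int) -> List[str]:
    """Encode non-overlapping spans as a BIO tag sequence of ``length``.

    Position ``start`` gets ``B-t``, positions ``start+1 .. end-1`` get
    ``I-t``, everything else ``O``.
    """
    tags = [O_TAG] * length
    for s in _check_spans(list(spans), length):
        tags[s.start] = f"B-{s.entity_type}"
        for i in range(s.start + 1, s.end):
            tags[i] = f"I-{s.entity_type}"
    return tags


def tags_to_spans(tags: Sequence[str], repair: str = "start-new") -> List[EntitySpan]:
    """Decode a BIO tag sequence into typed spans.

    A span closes at ``O``, at any ``B-``, or at an ``I-`` of a different
    type.  An ``I-t`` with no valid predecessor is handled by *repair*:

    - ``"start-new"`` (default): it opens a new span of type ``t``;
    - ``"strict"``: it raises :class:`SpanValidationError` with the position.

    Output spans never overlap and are sorted by start, for any input
    drawn from the tag vocabulary.
    """
    if repair not in REPAIR_POLICIES:
        raise ValueError(f"repair must be one of {REPAIR_POLICIES}, got {repair!r}")
    spans: List[EntitySpan] = []
    cur_type = None
    cur_start = 0
    for i, tag in enumerate(tags):
        if tag not in _TAG_INDEX:
            raise TagVocabularyError(f"unknown tag {tag!r} at position {i}")
        if tag == O_TAG:
            prefix, etype = "O", None
        else:
            prefix, etype = tag.split("-", 1)
        if prefix == "I" and etype == cur_type:
            continue  # extend current span
        if cur_type is not None:
            spans.append(EntitySpan(cur_start, i, cur_type))
            cur_type = None
        if prefix == "B":
            cur_type, cur_start = etype, i
        elif prefix == "I":
            if repair == "strict":
                raise SpanValidationError(
                    f"orphan {tag!r} at position {i} under strict decoding"
                )
            cur_type, cur_start = etype, i
    if cur_type is not None:
        spans.append(EntitySpan(cur_start, len(tags), cur_type))
    return spans
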