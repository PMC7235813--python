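"""Synthetic clinical-style annotated corpora and column-file I/O.

Real annotated electronic-medical-record text cannot be redistributed,
so this module generates a synthetic stand-in: character sentences built
from templates, with entity mentions drawn from small per-type lexicons
embedded in non-entity context.  The per-type lexicons are disjoint (by
construction the default lexicons even use disjoint character pools), so
entity identity is learnable from characters alone and an end-to-end
tagger can be exercised without private data.

Sentences are exchanged in the CoNLL-2003-style column format: one
``character<TAB>tag`` pair per line, UTF-8, blank line between sentences.
"""

from __future__ import annotations

import re
import string
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .tagging import (
    ENTITY_TYPES,
    EntitySpan,
    SpanValidationError,
    TagVocabularyError,
    spans_to_tags,
    tag_vocabulary,
    tags_to_spans,
)

__all__ = [
    "CorpusSpec",
    "AnnotatedSentence",
    "CorpusConfigError",
    "ColumnFormatError",
    "default_corpus_spec",
    "generate_corpus",
    "read_column_file",
    "write_column_file",
    "split_corpus",
]


class CorpusConfigError(ValueError):
    """A corpus specification violates its invariants."""


class ColumnFormatError(ValueError):
    """A column file is malformed; the message carries the line number."""


_SLOT_RE = re.compile(r"\{(" + "|".join(ENTITY_TYPES) + r")\}")


@dataclass(frozen=True)
class AnnotatedSentence:
    """One character-tokenized sentence with its gold entity spans."""

    tokens: Tuple[str, ...]
    entities: Tuple[EntitySpan, ...]

    def __post_init__(self):
        if len(self.tokens) == 0:
            raise CorpusConfigError("sentence must contain at least one token")
        ordered = sorted(self.entities)
        for s in ordered:
            if s.end > len(self.tokens):
                raise SpanValidationError(
                    f"span {s} exceeds sentence length {len(self.tokens)}"
                )
        for a, b in zip(ordered, ordered[1:]):
            if b.start < a.end:
                raise SpanValidationError(f"overlapping spans: {a} and {b}")
        object.__setattr__(self, "entities", tuple(ordered))

    @property
    def text(self) -> str:
        return "".join(self.tokens)

    def tags(self) -> List[str]:
        return spans_to_tags(self.entities, len(self.tokens))


@dataclass(frozen=True)
class CorpusSpec:
    """Recipe for a synthetic annotated corpus.

    ``templates`` are strings in which ``{Dis}``, ``{Sym}``, ``{Test}``,
    ``{Tre}``, ``{Med}`` and ``{Abn}`` mark entity slots; every other
    character is emitted literally as non-entity context.
    """

    entity_lexicons: Dict[str, Tuple[str, ...]]
    context_alphabet: Tuple[str, ...]
    templates: Tuple[str, ...]
    n_sentences: int
    max_entities_per_sentence: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.n_sentences < 1:
            raise CorpusConfigError(
                f"n_sentences must be >= 1, got {self.n_sentences}"
            )
        if self.max_entities_per_sentence < 0:
            raise CorpusConfigError("max_entities_per_sentence must be >= 0")
        if not self.templates:
            raise CorpusConfigError("at least one template is required")
        for etype in self.entity_lexicons:
            if etype not in ENTITY_TYPES:
                raise CorpusConfigError(f"unknown entity type {etype!r}")
        seen: Dict[str, str] = {}
        for etype, entries in self.entity_lexicons.items():
            for e in entries:
                if not (1 <= len(e) <= 8):
                    raise CorpusConfigError(
                        f"lexicon entry {e!r} for {etype} must have 1-8 characters"
                    )
                if "\t" in e or "\n" in e:
                    raise CorpusConfigError(
                        f"lexicon entry {e!r} for {etype} contains a reserved separator"
                    )
                if e in seen and seen[e] != etype:
                    raise CorpusConfigError(
                        f"entry {e!r} appears in lexicons for both "
                        f"{seen[e]} and {etype}; lexicons must be disjoint"
                    )
                seen[e] = etype
        for ch in self.context_alphabet:
            if ch in ("\t", "\n"):
                raise CorpusConfigError("context alphabet contains a reserved separator")
        for tpl in self.templates:
            n_slots = len(_SLOT_RE.findall(tpl))
            if n_slots > self.max_entities_per_sentence:
                raise CorpusConfigError(
                    f"template {tpl!r} has {n_slots} slots, exceeding "
                    f"max_entities_per_sentence={self.max_entities_per_sentence}"
                )
            for etype in _SLOT_RE.findall(tpl):
                if not self.entity_lexicons.get(etype):
                    raise CorpusConfigError(
                        f"template {tpl!r} requests type {etype} "
                        f"but its lexicon is empty"
                    )


# Default study conditions: six disjoint per-type character pools, so
# entity type is decidable from any of its characters, with the first
# two characters of each pool reserved for entity-initial positions
# only.  Every BIO tag is then a function of the character itself — the
# corpus is separable by construction, and the end-to-end sanity floor
# exercises the pipeline rather than the capacity of a small encoder.
# Entity lengths 2-4 characters; context drawn from a disjoint pool.
_TYPE_POOLS = {
    "Dis": "abcde",
    "Sym": "fghij",
    "Test": "klmno",
    "Tre": "pqrst",
    "Med": "uvwxy",
    "Abn": "zABCD",
}
_CONTEXT_POOL = tuple("EFGHJKLMNP" + string.digits + ".,;:()")


def _default_lexicons(entries_per_type: int = 12) -> Dict[str, Tuple[str, ...]]:
    rng = np.random.default_rng(20260921)  # fixed: lexicons are part of the spec
    lex: Dict[str, Tuple[str, ...]] = {}
    for etype, pool in _TYPE_POOLS.items():
        initial, interior = list(pool[:2]), list(pool[2:])
        entries: List[str] = []
        while len(entries) < entries_per_type:
            n = int(rng.integers(2, 5))
            w = rng.choice(initial) + "".join(rng.choice(interior, size=n - 1))
            if w not in entries:
                entries.append(w)
        lex[etype] = tuple(entries)
    return lex


def _default_templates() -> Tuple[str, ...]:
    rng = np.random.default_rng(20260922)  # fixed: templates are part of the spec
    templates: List[str] = []
    types = list(ENTITY_TYPES)
    for _ in range(24):
        n_slots = int(rng.integers(1, 4))
        parts: List[str] = []
        for k in range(n_slots):
            ctx = "".join(rng.choice(_CONTEXT_POOL, size=int(rng.integers(2, 6))))
            parts.append(ctx)
            parts.append("{" + types[int(rng.integers(len(types)))] + "}")
        parts.append("".join(rng.choice(_CONTEXT_POOL, size=int(rng.integers(1, 4)))))
        templates.append("".join(parts))
    # a few entity-free sentences keep the O class represented on its own
    for _ in range(4):
        templates.append("".join(rng.choice(_CONTEXT_POOL, size=int(rng.integers(4, 10)))))
    return tuple(templates)


def default_corpus_spec(n_sentences: int = 2000, seed: int = 0) -> CorpusSpec:
    """The default synthetic-corpus recipe used throughout the package."""
    return CorpusSpec(
        entity_lexicons=_default_lexicons(),
        context_alphabet=_CONTEXT_POOL,
        templates=_default_templates(),
        n_sentences=n_sentences,
        max_entities_per_sentence=4,
        seed=seed,
    )


def _instantiate(template: str, spec: CorpusSpec, rng: np.random.Generator) -> AnnotatedSentence:
    chars: List[str] = []
    spans: List[EntitySpan] = []
    pos = 0
    last = 0
    for m in _SLOT_RE.finditer(template):
        literal = template[last : m.start()]
        chars.extend(literal)
        pos += len(literal)
        etype = m.group(1)
        entries = spec.entity_lexicons.get(etype)
        if not entries:
            raise CorpusConfigError(f"empty lexicon for requested type {etype}")
        entry = entries[int(rng.integers(len(entries)))]
        chars.extend(entry)
        spans.append(EntitySpan(pos, pos + len(entry), etype))
        pos += len(entry)
        last = m.end()
    tail = template[last:]
    chars.extend(tail)
    return AnnotatedSentence(tuple(chars), tuple(spans))


def generate_corpus(spec: CorpusSpec) -> List[AnnotatedSentence]:
    """Generate ``spec.n_sentences`` annotated sentences.

    A pure function of ``spec.seed``: the same spec yields byte-identical
    corpora on every call.  Every embedded lexicon entry is recorded as an
    :class:`~layerfuse.tagging.EntitySpan` with exact character offsets.
    """
    rng = np.random.default_rng(spec.seed)
    out: List[AnnotatedSentence] = []
    for _ in range(spec.n_sentences):
        tpl = spec.templates[int(rng.integers(len(spec.templates)))]
        out.append(_instantiate(tpl, spec, rng))
    return out


def write_column_file(sentences: Sequence[AnnotatedSentence], path) -> None:
    """Write sentences in the two-column format (``char<TAB>tag``)."""
    with open(path, "w", encoding="utf-8") as fh:
        for i, sent in enumerate(sentences):
            if i:
                fh.write("\n")
            for ch, tag in zip(sent.tokens, sent.tags()):
                fh.write(f"{ch}\t{tag}\n")


def read_column_file(path) -> List[AnnotatedSentence]:
    """Parse a two-column file back into annotated sentences.

    Raises :class:`ColumnFormatError` (with the 1-based line number) for a
    line with the wrong column count and
    :class:`~layerfuse.tagging.TagVocabularyError` for a tag outside the
    13-label set.
    """
    vocab = set(tag_vocabulary())
    sentences: List[AnnotatedSentence] = []
    tokens: List[str] = []
    tags: List[str] = []

    def flush():
        if tokens:
            spans = tags_to_spans(tags, repair="start-new")
            sentences.append(AnnotatedSentence(tuple(tokens), tuple(spans)))
            tokens.clear()
            tags.clear()

    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if line == "":
                flush()
                continue
            cols = line.split("\t")
            if len(cols) != 2 or len(cols[0]) != 1:
                raise ColumnFormatError(
                    f"{path}:{lineno}: expected 'character<TAB>tag', got {line!r}"
                )
            ch, tag = cols
            if tag not in vocab:
                raise TagVocabularyError(
                    f"{path}:{lineno}: unknown tag {tag!r}"
                )
            tokens.append(ch)
            tags.append(tag)
    flush()
    return sentences


def _largest_remainder_sizes(n: int, fractions: Sequence[float]) -> List[int]:
    exact = [n * f for f in fractions]
    sizes = [int(np.floor(x)) for x in exact]
    short = n - sum(sizes)
    # distribute leftovers by descending remainder; ties go to earlier splits
    order = sorted(range(len(fractions)), key=lambda i: (-(exact[i] - sizes[i]), i))
    for i in order[:short]:
        sizes[i] += 1
    return sizes


def split_corpus(
    sentences: Sequence[AnnotatedSentence],
    fractions: Sequence[float] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> Tuple[List[AnnotatedSentence], ...]:
    """Shuffle and partition a corpus, e.g. 60/20/20 train/validation/test.

    Sizes follow largest-remainder rounding (ties broken by split order),
    so 4000 sentences at (0.6, 0.2, 0.2) give (2400, 800, 800).  The
    shuffle is a pure function of ``seed``.
    """
    fractions = list(fractions)
    if any(f <= 0 for f in fractions):
        raise CorpusConfigError(f"fractions must be positive, got {fractions}")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise CorpusConfigError(f"fractions must sum to 1, got {fractions}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(sentences))
    shuffled = [sentences[i] for i in order]
    sizes = _largest_remainder_sizes(len(sentences), fractions)
    parts: List[List[AnnotatedSentence]] = []
    at = 0
    for sz in sizes:
        parts.append(shuffled[at : at + sz])
        at += sz
    return tuple(parts)
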