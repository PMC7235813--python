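"""Synthetic corpus generation, column-file I/O and splitting."""

import numpy as np
import pytest

import layerfuse as lf
from layerfuse.corpus import (
    CorpusConfigError,
    ColumnFormatError,
    _largest_remainder_sizes,
)
from layerfuse.tagging import TagVocabularyError


def _one_entry_spec(**kw):
    defaults = dict(
        entity_lexicons={"Dis": ("xq",)},
        context_alphabet=tuple("ABC"),
        templates=("ABC{Dis}",),
        n_sentences=3,
        seed=0,
    )
    defaults.update(kw)
    return lf.CorpusSpec(**defaults)


class TestSpecValidation:
    def test_zero_sentences_rejected(self):
        with pytest.raises(CorpusConfigError, match="n_sentences"):
            _one_entry_spec(n_sentences=0)

    def test_overlapping_lexicons_rejected(self):
        with pytest.raises(CorpusConfigError, match="disjoint"):
            _one_entry_spec(entity_lexicons={"Dis": ("xq",), "Med": ("xq",)})

    def test_reserved_separator_rejected(self):
        with pytest.raises(CorpusConfigError, match="separator"):
            _one_entry_spec(entity_lexicons={"Dis": ("x\tq",)})

    def test_template_requesting_empty_lexicon_rejected(self):
        with pytest.raises(CorpusConfigError, match="Med"):
            _one_entry_spec(templates=("A{Med}",))

    def test_too_long_entry_rejected(self):
        with pytest.raises(CorpusConfigError, match="1-8"):
            _one_entry_spec(entity_lexicons={"Dis": ("123456789",)})


def test_generation_records_exact_offsets():
    """An entry placed by a template is findable at the recorded span."""
    spec = _one_entry_spec()
    corpus = lf.generate_corpus(spec)
    assert len(corpus) == 3
    for sent in corpus:
        (span,) = sent.entities
        assert (span.start, span.end, span.entity_type) == (3, 5, "Dis")
        assert sent.text[span.start:span.end] == "xq"


def test_generation_is_deterministic():
    spec = lf.default_corpus_spec(n_sentences=50, seed=9)
    a, b = lf.generate_corpus(spec), lf.generate_corpus(spec)
    assert [(s.text, s.entities) for s in a] == [(s.text, s.entities) for s in b]
    c = lf.generate_corpus(lf.default_corpus_spec(n_sentences=50, seed=10))
    assert [s.text for s in a] != [s.text for s in c]


def test_spans_survive_tag_roundtrip(small_corpus):
    from layerfuse.tagging import tags_to_spans

    for sent in small_corpus:
        assert tuple(tags_to_spans(sent.tags())) == sent.entities


def test_column_file_roundtrip(tmp_path):
    corpus = lf.generate_corpus(lf.default_corpus_spec(n_sentences=1000, seed=2))
    path = tmp_path / "corpus.conll"
    lf.write_column_file(corpus, path)
    back = lf.read_column_file(path)
    assert [(s.tokens, s.entities) for s in back] == \
        [(s.tokens, s.entities) for s in corpus]
    # write(read(x)) is byte-identical
    path2 = tmp_path / "again.conll"
    lf.write_column_file(back, path2)
    assert path.read_bytes() == path2.read_bytes()


def test_empty_file_gives_empty_corpus(tmp_path):
    path = tmp_path / "empty.conll"
    path.write_text("")
    assert lf.read_column_file(path) == []


def test_malformed_line_reports_line_number(tmp_path):
    path = tmp_path / "bad.conll"
    path.write_text("a\tO\nbadline\n")
    with pytest.raises(ColumnFormatError, match=":2"):
        lf.read_column_file(path)


def test_unknown_tag_rejected_on_read(tmp_path):
    path = tmp_path / "bad.conll"
    path.write_text("a\tB-Xyz\n")
    with pytest.raises(TagVocabularyError, match="B-Xyz"):
        lf.read_column_file(path)


class TestSplit:
    @pytest.mark.parametrize("n,expected", [
        (4000, (2400, 800, 800)),
        (10, (6, 2, 2)),
        (5, (3, 1, 1)),   # largest remainder: 3.0, 1.0, 1.0
        (7, (4, 2, 1)),   # 4.2, 1.4, 1.4 -> leftover to valid (tie by order)
    ])
    def test_sizes(self, n, expected):
        assert tuple(_largest_remainder_sizes(n, (0.6, 0.2, 0.2))) == expected

    def test_partition_is_disjoint_and_exhaustive(self, small_corpus):
        tr, va, te = lf.split_corpus(small_corpus, (0.6, 0.2, 0.2), seed=4)
        assert len(tr) + len(va) + len(te) == len(small_corpus)
        ids = [id(s) for part in (tr, va, te) for s in part]
        assert len(set(ids)) == len(ids)
        assert sorted(ids) == sorted(id(s) for s in small_corpus)

    def test_split_deterministic_under_seed(self, small_corpus):
        a = lf.split_corpus(small_corpus, seed=11)
        b = lf.split_corpus(small_corpus, seed=11)
        assert all([x is y for p, q in zip(a, b) for x, y in zip(p, q)])
        c = lf.split_corpus(small_corpus, seed=12)
        assert [s.text for s in a[0]] != [s.text for s in c[0]]

    def test_bad_fractions_rejected(self, small_corpus):
        with pytest.raises(CorpusConfigError, match="sum to 1"):
            lf.split_corpus(small_corpus, (0.5, 0.2, 0.2))
        with pytest.raises(CorpusConfigError, match="positive"):
            lf.split_corpus(small_corpus, (1.2, -0.1, -0.1))


def test_entity_character_fraction_matches_template_design():
    """Over >=1000 sentences the realized entity-character fraction sits
    within 5 points of the expectation implied by templates+lexicons."""
    spec = lf.default_corpus_spec(n_sentences=1500, seed=3)
    mean_len = {t: np.mean([len(e) for e in lex])
                for t, lex in spec.entity_lexicons.items()}
    import re
    slot_re = re.compile(r"\{(\w+)\}")
    exp_entity, exp_total = 0.0, 0.0
    for tpl in spec.templates:
        slots = slot_re.findall(tpl)
        ent = sum(mean_len[t] for t in slots)
        exp_entity += ent
        exp_total += ent + len(slot_re.sub("", tpl))
    expected = exp_entity / exp_total
    corpus = lf.generate_corpus(spec)
    ent = sum(s.end - s.start for c in corpus for s in c.entities)
    tot = sum(len(c.tokens) for c in corpus)
    assert abs(ent / tot - expected) < 0.05
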