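"""Corpus I/O, tokenization, sentence splitting and the BIOE codec."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from kbrelex.corpus import (
    EntityMention,
    IntegrityError,
    bioe_to_spans,
    candidate_pairs,
    read_standoff,
    spans_to_bioe,
    split_sentences,
    tokenize,
    write_standoff,
)
from kbrelex.synth import SynthConfig, generate_corpus

from conftest import make_sentence


class TestTokenize:
    def test_punctuation_peeling_with_exact_offsets(self):
        toks = tokenize("LEC1 (LEAFY)")
        assert [t.surface for t in toks] == ["LEC1", "(", "LEAFY", ")"]
        assert [(t.char_start, t.char_end) for t in toks] == [
            (0, 4),
            (5, 6),
            (6, 11),
            (11, 12),
        ]

    def test_empty_text(self):
        assert tokenize("") == []

    def test_two_words(self):
        assert len(tokenize("a b")) == 2

    def test_hyphenated_names_stay_whole(self):
        assert [t.surface for t in tokenize("a 14-3-3 protein")] == [
            "a",
            "14-3-3",
            "protein",
        ]

    def test_internal_slash_split(self):
        assert [t.surface for t in tokenize("Ras/Raf")] == ["Ras", "/", "Raf"]

    @given(
        st.text(
            alphabet=st.characters(
                whitelist_categories=("Lu", "Ll", "Nd", "Po", "Zs")
            ),
            max_size=80,
        )
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_offset_fidelity(self, text):
        for tok in tokenize(text):
            assert text[tok.char_start : tok.char_end] == tok.surface


class TestSplitSentences:
    def test_two_sentences(self):
        assert len(split_sentences("A binds B. C binds D.")) == 2

    def test_no_terminator(self):
        assert len(split_sentences("A binds B without any end")) == 1

    def test_protected_abbreviation(self):
        assert len(split_sentences("Fig. 2 shows X.")) == 1

    def test_spans_cover_content(self):
        text = "One thing. Another thing."
        spans = split_sentences(text)
        assert [text[s:e] for s, e in spans] == ["One thing.", "Another thing."]


class TestStandoff:
    def test_minimal_document(self, tmp_path):
        (tmp_path / "d.txt").write_text("LEC1 binds X.")
        (tmp_path / "d.a1").write_text("T1\tGene 0 4\tLEC1\n")
        doc = read_standoff(tmp_path / "d.txt", tmp_path / "d.a1")
        assert len(doc.entities) == 1 and len(doc.relations) == 0
        assert doc.entities[0].surface == "LEC1"

    def test_non_gene_protein_entity_dropped(self, tmp_path, caplog):
        (tmp_path / "d.txt").write_text("LEC1 binds ABA.")
        (tmp_path / "d.a1").write_text(
            "T1\tGene 0 4\tLEC1\nT2\tRNA 11 14\tABA\n"
        )
        doc = read_standoff(tmp_path / "d.txt", tmp_path / "d.a1")
        assert [e.id for e in doc.entities] == ["T1"]

    def test_dangling_relation_reference(self, tmp_path):
        (tmp_path / "d.txt").write_text("LEC1 binds FUS3.")
        (tmp_path / "d.a1").write_text(
            "T1\tGene 0 4\tLEC1\nT2\tProtein 11 15\tFUS3\n"
        )
        (tmp_path / "d.a2").write_text("R1\tBinds_To Arg1:T1 Arg2:T9\n")
        with pytest.raises(IntegrityError):
            read_standoff(
                tmp_path / "d.txt", tmp_path / "d.a1", tmp_path / "d.a2"
            )

    def test_read_write_identity_on_synthetic_corpus(self, tmp_path):
        docs = generate_corpus(
            SynthConfig(n_documents=3, sentences_per_doc=3, embed_dim=16, seed=3)
        )
        for doc in docs:
            write_standoff(
                doc,
                tmp_path / f"{doc.id}.txt",
                tmp_path / f"{doc.id}.a1",
                tmp_path / f"{doc.id}.a2",
            )
            doc2 = read_standoff(
                tmp_path / f"{doc.id}.txt",
                tmp_path / f"{doc.id}.a1",
                tmp_path / f"{doc.id}.a2",
            )
            assert doc2.text == doc.text
            assert [(e.id, e.etype, e.char_start, e.char_end) for e in doc2.entities] == [
                (e.id, e.etype, e.char_start, e.char_end) for e in doc.entities
            ]
            assert [r.key for r in doc2.relations] == [r.key for r in doc.relations]


class TestBioeCodec:
    def test_two_token_entity(self):
        sent = make_sentence("LEAFY COTYLEDON1 activates X.")
        ent = EntityMention("T1", "Gene", 0, 16, "LEAFY COTYLEDON1")
        assert spans_to_bioe(sent, [ent]) == ["B", "E", "O", "O", "O"]

    def test_single_token_entity_is_bare_b(self):
        sent = make_sentence("LEC1 activates X.")
        ent = EntityMention("T1", "Gene", 0, 4, "LEC1")
        assert spans_to_bioe(sent, [ent])[0] == "B"

    def test_no_entities_all_o(self):
        sent = make_sentence("Nothing here.")
        assert set(spans_to_bioe(sent, [])) == {"O"}

    def test_misaligned_entity_raises(self):
        sent = make_sentence("LEC1 activates X.")
        ent = EntityMention("T1", "Gene", 1, 4, "EC1")
        with pytest.raises(ValueError):
            spans_to_bioe(sent, [ent])

    @pytest.mark.parametrize(
        "tags,expected_token_spans",
        [
            (["B", "E", "O"], [(0, 1)]),
            (["O", "O", "O"], []),
            (["I", "E", "O"], [(0, 1)]),  # lenient: I opens a span
            (["B", "I", "O"], [(0, 1)]),  # unclosed run closes at last I
            (["B", "B", "E"], [(0, 0), (1, 2)]),
            (["E", "O", "B"], [(0, 0), (2, 2)]),
        ],
    )
    def test_decode_including_repairs(self, tags, expected_token_spans):
        sent = make_sentence("aa bb cc")
        spans = bioe_to_spans(tags, sent)
        expected = [
            (sent.tokens[i].char_start, sent.tokens[j].char_end)
            for i, j in expected_token_spans
        ]
        assert spans == expected

    def test_round_trip_random_configurations(self, rng):
        """spans -> tags -> spans is the identity for valid configurations."""
        words = ["w%d" % i for i in range(12)]
        text = " ".join(words)
        sent = make_sentence(text)
        for trial in range(1000):
            # sample non-overlapping token spans
            n_spans = rng.integers(0, 4)
            taken = np.zeros(len(words), dtype=bool)
            entities = []
            for k in range(n_spans):
                i = int(rng.integers(len(words)))
                j = min(len(words) - 1, i + int(rng.integers(0, 3)))
                if taken[i : j + 1].any():
                    continue
                taken[i : j + 1] = True
                s = sent.tokens[i].char_start
                e = sent.tokens[j].char_end
                entities.append(EntityMention(f"T{k}", "Gene", s, e, text[s:e]))
            tags = spans_to_bioe(sent, entities)
            decoded = bioe_to_spans(tags, sent)
            assert sorted(decoded) == sorted(
                (e.char_start, e.char_end) for e in entities
            )


class TestCandidatePairs:
    @pytest.mark.parametrize("n,expected", [(1, 0), (2, 2), (3, 6)])
    def test_ordered_pair_count(self, n, expected):
        text = " ".join(f"E{i}" for i in range(n))
        sent = make_sentence(text) if text else None
        ents = [
            EntityMention(
                f"T{i}",
                "Gene",
                sent.tokens[i].char_start,
                sent.tokens[i].char_end,
                sent.tokens[i].surface,
            )
            for i in range(n)
        ]
        pairs = candidate_pairs(sent, ents)
        assert len(pairs) == expected == n * (n - 1)
        assert all(a is not b for a, b in pairs)
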