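"""Feature extraction: tokenization, negation, gazetteer NER, interactor
lookup, positional counts, link-path heuristic, encoding, corpus I/O."""

import json
import re

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ppispotter import (
    MISSING,
    EncodingSpec,
    HeuristicLinkPath,
    Lexicons,
    Sentence,
    count_proteins,
    detect_negation,
    extract_features,
    find_interactor,
    link_path_status,
    positional_features,
    read_corpus,
    stem,
    tokenize,
    vectorize,
    write_corpus,
)
from ppispotter.features import EmptyTextError

from helpers import brute_force_gazetteer_count


class TestTokenize:
    @pytest.mark.parametrize("text, expected", [
        ("GerE binds ykuD.", ["GerE", "binds", "ykuD", "."]),
        ("p53-mediated response", ["p53", "-", "mediated", "response"]),
        ("A,B and C", ["A", ",", "B", "and", "C"]),
    ])
    def test_punctuation_split(self, text, expected):
        assert tokenize(text) == expected

    def test_empty_text_raises(self):
        with pytest.raises(EmptyTextError):
            tokenize("")
        with pytest.raises(EmptyTextError):
            tokenize("   ")

    def test_offsets_recover_tokens(self):
        text = "The SigK factor, (activated) by GerE."
        toks, offs = tokenize(text, with_offsets=True)
        for t, o in zip(toks, offs):
            assert text[o:o + len(t)] == t

    @given(st.text(alphabet=st.characters(categories=["L", "N", "P", "Z"]), min_size=1))
    def test_tokens_reconstruct_text_modulo_whitespace(self, text):
        try:
            toks = tokenize(text)
        except EmptyTextError:
            return
        assert "".join(toks) == re.sub(r"\s+", "", text)


class TestStem:
    @pytest.mark.parametrize("word, expected", [
        ("binds", "bind"),
        ("activates", "activate"),
        ("activated", "activate"),
        ("activating", "activate"),
        ("binding", "bind"),
        ("modifies", "modify"),
        ("stopped", "stop"),
        ("interacts", "interact"),
        ("response", "response"),
        ("is", "is"),           # never below 3 chars / short words untouched
        ("classes", "class"),
    ])
    def test_conservative_suffix_rules(self, word, expected):
        assert stem(word) == expected


class TestNegation:
    RENIN = ("No relevant changes in heart rate , body weight , and plasma "
             "levels of renin activity and aldosterone concentration were observed")

    def test_renin_sentence_negated(self, lexicons):
        s = Sentence(id="renin", text=self.RENIN)
        is_neg, terms = detect_negation(s, lexicons)
        assert is_neg
        assert "renin" in {t["text"] for t in terms}

    def test_no_trigger_no_negation(self, tiny_lexicons):
        s = Sentence(id="a", text="GerE binds ykuD in vitro .")
        assert detect_negation(s, tiny_lexicons) == (False, [])

    def test_window_excludes_six_token_gap(self, tiny_lexicons):
        s = Sentence(id="b", text="no w1 w2 w3 w4 w5 w6 renin")
        is_neg, _ = detect_negation(s, tiny_lexicons, window=5)
        assert not is_neg

    def test_window_includes_five_token_gap(self, tiny_lexicons):
        s = Sentence(id="c", text="no w1 w2 w3 w4 w5 renin")
        is_neg, terms = detect_negation(s, tiny_lexicons, window=5)
        assert is_neg and terms[0]["text"] == "renin"

    def test_pseudo_phrase_blocks_trigger(self, tiny_lexicons):
        s = Sentence(id="d", text="not only renin but also gere was measured")
        assert detect_negation(s, tiny_lexicons)[0] is False

    def test_case_insensitive_triggers(self, tiny_lexicons):
        lower = Sentence(id="e", text="no renin was measured")
        upper = Sentence(id="f", text="NO renin was measured")
        assert detect_negation(lower, tiny_lexicons)[0]
        assert detect_negation(upper, tiny_lexicons)[0]

    def test_post_negation_phrase(self, tiny_lexicons):
        s = Sentence(id="g", text="involvement of renin was ruled out")
        is_neg, terms = detect_negation(s, tiny_lexicons)
        assert is_neg and "renin" in {t["text"] for t in terms}

    def test_boundary_punctuation_closes_scope(self, tiny_lexicons):
        s = Sentence(id="h", text="no data were shown ; renin was measured")
        assert detect_negation(s, tiny_lexicons)[0] is False


class TestProteinNER:
    def test_direct_match(self, tiny_lexicons):
        s = Sentence(id="a", text="GerE binds ykuD")
        assert count_proteins(s, tiny_lexicons) == 2
        assert s.protein_mentions == [(0, 1), (2, 3)]

    def test_zero_hits(self, tiny_lexicons):
        s = Sentence(id="b", text="nothing to see here")
        assert count_proteins(s, tiny_lexicons) == 0

    def test_longest_match_wins(self, tiny_lexicons):
        s = Sentence(id="c", text="the SigK factor binds GerE")
        assert count_proteins(s, tiny_lexicons) == 2  # "sigk factor" + "gere"
        assert (1, 3) in s.protein_mentions

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_enumeration(self, seed, tiny_lexicons):
        rng = np.random.default_rng(seed)
        vocab = ["gere", "ykud", "sigk", "factor", "renin", "the", "binds", "xx"]
        toks = [vocab[i] for i in rng.integers(0, len(vocab), size=12)]
        s = Sentence(id=f"r{seed}", text=" ".join(toks))
        expected = brute_force_gazetteer_count(toks, tiny_lexicons.protein_gazetteer)
        assert count_proteins(s, tiny_lexicons) == expected


class TestInteractor:
    def test_stemmed_lookup_with_char_offset(self, tiny_lexicons):
        s = Sentence(id="a", text="GerE binds ykuD")
        count_proteins(s, tiny_lexicons)
        name, pos, off = find_interactor(s, tiny_lexicons)
        assert (name, pos) == ("bind", "VB")
        assert s.text[off:off + 5] == "binds"

    def test_no_match_is_missing(self, tiny_lexicons):
        s = Sentence(id="b", text="GerE and ykuD exist")
        count_proteins(s, tiny_lexicons)
        assert find_interactor(s, tiny_lexicons) == (MISSING, MISSING, -1)

    def test_prefers_match_between_outermost_mentions(self, tiny_lexicons):
        s = Sentence(id="c", text="activated GerE binds ykuD")
        count_proteins(s, tiny_lexicons)
        name, _, off = find_interactor(s, tiny_lexicons)
        assert name == "bind"  # not the earlier "activate"


class TestPositionalFeatures:
    def test_two_mentions_with_left_sentinel(self, tiny_lexicons):
        s = Sentence(id="a", text="GerE binds ykuD in vitro")
        count_proteins(s, tiny_lexicons)
        assert positional_features(s) == (1, -1, 2)

    def test_no_mentions_all_undefined(self):
        s = Sentence(id="b", text="w0 w1 w2")
        assert positional_features(s) == (-1, -1, -1)

    def test_single_mention_counts_both_sides(self):
        s = Sentence(id="c", text=" ".join(f"w{i}" for i in range(10)))
        s.protein_mentions = [(3, 4)]
        assert positional_features(s) == (-1, 3, 6)

    @pytest.mark.parametrize("seed", range(5))
    def test_count_identity_for_two_single_token_mentions(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 15))
        i, j = sorted(rng.choice(n, size=2, replace=False))
        if j == i:
            return
        s = Sentence(id=f"r{seed}", text=" ".join(f"w{k}" for k in range(n)))
        s.protein_mentions = [(i, i + 1), (j, j + 1)]
        nb, nl, nr = positional_features(s)
        assert max(nl, 0) + 1 + nb + 1 + max(nr, 0) == n


class TestLinkPath:
    def test_interactor_between_mentions_yes(self, tiny_lexicons):
        s = Sentence(id="a", text="GerE binds ykuD")
        count_proteins(s, tiny_lexicons)
        assert link_path_status(s, HeuristicLinkPath(tiny_lexicons)) is True

    def test_boundary_punctuation_no(self, tiny_lexicons):
        s = Sentence(id="b", text="GerE is small ; ykuD binds too")
        count_proteins(s, tiny_lexicons)
        # ';' lies between the outermost mentions
        assert link_path_status(s, HeuristicLinkPath(tiny_lexicons)) is False

    def test_single_mention_missing(self, tiny_lexicons):
        s = Sentence(id="c", text="GerE binds something")
        count_proteins(s, tiny_lexicons)
        assert link_path_status(s, HeuristicLinkPath(tiny_lexicons)) is MISSING


class TestExtractFeatures:
    def test_composed_record(self, tiny_lexicons):
        s = Sentence(id="a", text="GerE binds ykuD .")
        rec = extract_features(s, tiny_lexicons)
        assert rec.is_negated is False
        assert rec.n_protein_occurrences == 2
        assert rec.interactor_name == "bind"
        assert rec.interactor_pos == "VB"
        assert rec.interactor_position == s.text.index("binds")
        assert (rec.n_words_between, rec.n_left_words, rec.n_right_words) == (1, -1, 1)
        assert rec.link_path is True

    def test_no_matches_all_missing(self, tiny_lexicons):
        s = Sentence(id="b", text="totally unrelated words here")
        rec = extract_features(s, tiny_lexicons)
        assert rec == type(rec)(False, 0, MISSING, MISSING, -1, -1, -1, -1, MISSING)

    def test_pure_function(self, tiny_lexicons):
        s1 = Sentence(id="a", text="GerE binds ykuD .")
        s2 = Sentence(id="a", text="GerE binds ykuD .")
        assert extract_features(s1, tiny_lexicons) == extract_features(s2, tiny_lexicons)


class TestVectorize:
    def _records(self, tiny_lexicons, texts):
        return [extract_features(Sentence(id=str(i), text=t), tiny_lexicons)
                for i, t in enumerate(texts)]

    def test_identical_records_identical_rows(self, tiny_lexicons):
        recs = self._records(tiny_lexicons, ["GerE binds ykuD ."] * 2)
        X, _, _ = vectorize(recs)
        assert np.array_equal(X[0], X[1])

    def test_hand_applied_encoding(self, tiny_lexicons):
        recs = self._records(tiny_lexicons,
                             ["GerE binds ykuD .", "no renin was measured"])
        X, cols, spec = vectorize(recs)
        row = dict(zip(cols, X[0]))
        assert row["is_negated"] == 0.0
        assert row["link_path"] == 1.0 and row["link_path__missing"] == 0.0
        # z-score of n_proteins: values [2, 1] -> mean 1.5, std 0.5 -> (2-1.5)/0.5
        assert row["n_protein_occurrences"] == pytest.approx(1.0)
        assert sum(v for c, v in row.items() if c.startswith("interactor_hash_")) == 1.0
        assert row["pos_VB"] == 1.0

    def test_sentinels_use_indicator_columns(self, tiny_lexicons):
        recs = self._records(tiny_lexicons,
                             ["GerE binds ykuD .", "totally unrelated words"])
        X, cols, _ = vectorize(recs)
        row = dict(zip(cols, X[1]))
        assert row["n_words_between__undef"] == 1.0
        assert row["n_words_between"] == 0.0
        assert row["interactor__missing"] == 1.0
        assert row["link_path__missing"] == 1.0

    def test_test_rows_use_train_statistics_only(self, tiny_lexicons):
        train = self._records(tiny_lexicons, ["GerE binds ykuD .", "renin binds GerE"])
        test = self._records(tiny_lexicons, ["SigK binds renin now now now"])
        spec = EncodingSpec().fit(train)
        means_before = dict(spec.means_)
        spec.transform(test)
        assert spec.means_ == means_before  # transform never refits

    def test_unknown_pos_maps_to_other(self):
        lex = Lexicons({"gere", "ykud"}, {"bind": "WEIRD"}, ["no"],
                       ["was ruled out"], ["not only"])
        rec = extract_features(Sentence(id="a", text="GerE binds ykuD"), lex)
        X, cols, _ = vectorize([rec])
        assert dict(zip(cols, X[0]))["pos_OTHER"] == 1.0


class TestCorpusIO:
    def test_jsonl_round_trip_byte_stable(self, tmp_path, tiny_lexicons):
        sents = [Sentence(id="s1", text="GerE binds ykuD .",
                          protein_mentions=[(0, 1), (2, 3)], label=1),
                 Sentence(id="s2", text="nothing here", label=-1),
                 Sentence(id="s3", text="maybe renin", label=None)]
        p1, p2 = tmp_path / "a.jsonl", tmp_path / "b.jsonl"
        write_corpus(sents, p1)
        write_corpus(read_corpus(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_labels_round_trip(self, tmp_path):
        sents = [Sentence(id="x", text="a b", label=lab) for lab in (1, -1, None)]
        path = tmp_path / "c.jsonl"
        write_corpus(sents, path)
        assert [s.label for s in read_corpus(path)] == [1, -1, None]
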