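"""POS-filtered lexicon matching and weak labeling."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

from deplex.corpus import clean_post
from deplex.labeling import (
    POSRetentionPolicy,
    UnnormalizedLexiconError,
    label_corpus,
    label_post,
    match_lexicon,
    retain_pos,
    tokenize_with_pos,
)
from deplex.lexicon import DepressionLexicon, LexiconEntry, normalize_entries
from deplex.synthetic import SyntheticCorpusSpec, generate_corpus, generate_vocab
from deplex.taggers import UnsupportedLanguageError, get_tagger


class TestTokenize:
    def test_empty_text_gives_no_tokens(self):
        assert tokenize_with_pos("", "en").tokens == ()

    def test_tokens_tagged_from_tagset(self, en_tagger):
        tp = tokenize_with_pos("sad songs", "en")
        assert len(tp.tokens) == 2
        assert all(tag in en_tagger.tagset for _, tag in tp.tokens)

    def test_deterministic(self):
        text = "feeling hopeless about tomorrow again"
        assert tokenize_with_pos(text, "en") == tokenize_with_pos(text, "en")

    def test_unregistered_language_raises(self):
        with pytest.raises(UnsupportedLanguageError):
            tokenize_with_pos("hola", "xx")


class TestRetainPos:
    def test_full_tagset_keeps_everything(self, en_tagger):
        tp = tokenize_with_pos("the gloomy rain kept falling", "en")
        policy = POSRetentionPolicy("en", frozenset(en_tagger.tagset))
        assert retain_pos(tp, policy).retained_tokens == tp.tokens

    def test_disjoint_tagset_keeps_nothing(self):
        tp = tokenize_with_pos("the gloomy rain", "en")
        assert retain_pos(tp, POSRetentionPolicy("en", frozenset({"ZZZ"}))).retained_tokens == ()

    def test_equals_list_comprehension(self, en_policy):
        tp = tokenize_with_pos("i was feeling very hopeless about it", "en")
        out = retain_pos(tp, en_policy)
        assert out.retained_tokens == tuple(
            t for t in tp.tokens if t[1] in en_policy.retained_tags
        )
        # order preserved as a subsequence
        it = iter(tp.tokens)
        assert all(any(t == u for u in it) for t in out.retained_tokens)


class TestMatchLexicon:
    def test_simple_containment(self, toy_lexicon, en_policy):
        tp = retain_pos(tokenize_with_pos("everything feels hopeless today", "en"), en_policy)
        assert match_lexicon(tp, toy_lexicon) == ["hopeless"]

    def test_empty_retained_tokens_no_match(self, toy_lexicon, en_policy):
        tp = retain_pos(tokenize_with_pos("", "en"), en_policy)
        assert match_lexicon(tp, toy_lexicon) == []

    def test_multiword_entry_requires_contiguity(self, toy_lexicon, en_policy):
        hit = retain_pos(tokenize_with_pos("listening sad songs tonight", "en"), en_policy)
        assert "sad songs" in match_lexicon(hit, toy_lexicon)
        gap = retain_pos(tokenize_with_pos("sad gloomy songs tonight", "en"), en_policy)
        assert "sad songs" not in match_lexicon(gap, toy_lexicon)

    def test_case_folding_latin(self, toy_lexicon, en_policy):
        tp = retain_pos(tokenize_with_pos("SO HOPELESS", "en"), en_policy)
        assert match_lexicon(tp, toy_lexicon) == ["hopeless"]

    def test_unnormalized_lexicon_rejected(self, en_policy):
        raw = DepressionLexicon("en", [LexiconEntry("hopeless", "en", (5,))])
        tp = retain_pos(tokenize_with_pos("hopeless", "en"), en_policy)
        with pytest.raises(UnnormalizedLexiconError):
            match_lexicon(tp, raw)

    def test_matches_deduplicated_in_entry_order(self, toy_lexicon, en_policy):
        tp = retain_pos(
            tokenize_with_pos("misery hopeless misery hopeless misery", "en"), en_policy
        )
        assert match_lexicon(tp, toy_lexicon) == ["hopeless", "misery"]


class TestLabelPost:
    def test_post_with_lexicon_term_is_depression(self, toy_lexicon):
        lp = label_post("my insomnia is back again", toy_lexicon)
        assert lp.label == 1 and lp.matches == ("insomnia",)

    def test_empty_post_is_non_depression(self, toy_lexicon):
        lp = label_post("", toy_lexicon)
        assert lp.label == 0 and lp.matches == ()

    def test_monotone_in_lexicon_growth(self, en_policy):
        base = normalize_entries(
            DepressionLexicon("en", [LexiconEntry("misery", "en", (5,))]), en_policy
        )
        bigger = normalize_entries(
            DepressionLexicon(
                "en",
                [LexiconEntry("misery", "en", (5,)), LexiconEntry("numb", "en", (5,))],
            ),
            en_policy,
        )
        for text in ("pure misery", "feeling numb", "fine day", "misery and numb"):
            if label_post(text, base).label == 1:
                assert label_post(text, bigger).label == 1


class TestLabelCorpus:
    def test_class_counts(self, toy_lexicon):
        posts = ["fine day here"] * 7 + ["hopeless night", "so much misery", "crying again"]
        labeled, summary = label_corpus(posts, toy_lexicon)
        assert summary.class_counts == (7, 3)
        assert [lp.label for lp in labeled] == [0] * 7 + [1] * 3

    def test_empty_corpus(self, toy_lexicon):
        labeled, summary = label_corpus([], toy_lexicon)
        assert labeled == [] and summary.class_counts == (0, 0)

    def test_entry_frequencies_cover_depression_posts(self, toy_lexicon):
        posts = ["hopeless and worthless", "crying", "ok day", "misery misery"]
        labeled, summary = label_corpus(posts, toy_lexicon)
        assert sum(summary.entry_frequencies.values()) >= summary.n_depression
        # recount from the labeled output itself
        assert sum(summary.entry_frequencies.values()) == sum(len(lp.matches) for lp in labeled)


class TestOracleEquivalence:
    def test_500_synthetic_posts_match_brute_force(self, oracle_labeler, en_policy, en_tagger):
        spec = SyntheticCorpusSpec(n_posts=500, depression_rate=0.3, seed=42)
        vocab = generate_vocab(spec)
        posts, _, _ = generate_corpus(spec, vocab)
        lexicon = normalize_entries(vocab.to_lexicon(), en_policy)
        texts = [clean_post(p.text, "en") for p in posts]
        labeled, _ = label_corpus(texts, lexicon)
        for text, lp in zip(texts, labeled):
            expected = oracle_labeler(text, lexicon, en_policy, en_tagger)
            assert list(lp.matches) == expected
            assert lp.label == (1 if expected else 0)

    def test_handcrafted_posts_match_brute_force(self, oracle_labeler, toy_lexicon, en_policy, en_tagger):
        texts = [
            "sad songs on repeat",
            "Sad gloomy songs again",
            "BROKEN heart broken hearts",
            "insomnia insomnia",
            "nothing matters anymore",
            "",
        ]
        for text in texts:
            lp = label_post(text, toy_lexicon)
            assert list(lp.matches) == oracle_labeler(text, toy_lexicon, en_policy, en_tagger)


def test_label_distribution_concentrates_at_generator_rate(en_policy):
    rate = 0.3
    spec = SyntheticCorpusSpec(n_posts=1500, depression_rate=rate, seed=5)
    vocab = generate_vocab(spec)
    posts, _, _ = generate_corpus(spec, vocab)
    lexicon = normalize_entries(vocab.to_lexicon(), en_policy)
    _, summary = label_corpus([clean_post(p.text, "en") for p in posts], lexicon)
    lo, hi = stats.binom.interval(0.9999, 1500, rate)
    assert lo <= summary.n_depression <= hi
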