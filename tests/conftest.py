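"""Shared fixtures: toy lexicons, synthetic corpora, the brute-force oracle."""

from __future__ import annotations

import numpy as np
import pytest

from deplex.labeling import POSRetentionPolicy, default_policy
from deplex.lexicon import DepressionLexicon, LexiconEntry, normalize_entries
from deplex.taggers import EnglishRuleTagger, get_tagger


@pytest.fixture
def en_tagger():
    return get_tagger("en")


@pytest.fixture
def en_policy():
    return default_policy("en")


@pytest.fixture
def toy_lexicon(en_policy):
    """Small normalized English lexicon including a multi-word entry."""
    words = ["hopeless", "lonely", "insomnia", "worthless", "sad songs",
             "crying", "despair", "numb", "broken heart", "misery"]
    entries = [LexiconEntry(w, "en", rater_scores=(5, 4)) for w in words]
    return normalize_entries(DepressionLexicon("en", entries), en_policy)


def brute_force_label(text: str, lexicon: DepressionLexicon, policy: POSRetentionPolicy, tagger) -> list[str]:
    """Naive O(n*m) reference scanner, written independently of the library
    matcher: tag, filter by retained tags, fold, then scan every offset."""

    def fold(tok: str, tag: str) -> str:
        t = tok.lower()
        if tag == "NNS" and len(t) > 3 and t.endswith("s") and not t.endswith("ss"):
            t = t[:-1]
        return t

    def retained_folded(s: str) -> list[str]:
        return [fold(tok, tag) for tok, tag in tagger.tag(s) if tag in policy.retained_tags]

    post_toks = retained_folded(text)
    found = []
    for entry in lexicon.entries:
        needle = retained_folded(entry.surface)
        hit = False
        for i in range(len(post_toks) - len(needle) + 1):
            if post_toks[i : i + len(needle)] == needle and needle:
                hit = True
                break
        if hit:
            found.append(entry.surface)
    return found


@pytest.fixture
def oracle_labeler():
    return brute_force_label
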