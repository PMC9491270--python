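"""POS-filtered lexicon matching and binary weak labeling.

A post is weakly labeled *depression* (1) when, after POS tagging and
restriction to the language's retained tag set, it contains at least one
lexicon entry as a contiguous token subsequence; otherwise *non-depression*
(0).  The same retention policy is applied to both the posts and the lexicon,
so matching happens in one filtered token space.

Default retained tags follow the per-language sets used for weak labeling:
Korean Sejong tags NNG/NNB/VV/VA/XR, English Penn tags
NN/NNS/JJ/VB/VBG/VBN/RP/DT/IN/TO, and the noun/verb/adjective classes of the
active Japanese tagger.  All are overridable per run.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .lexicon import DepressionLexicon, LexiconEntry
from .taggers import TaggedToken, Tagger, get_tagger

DEPRESSION, NON_DEPRESSION = 1, 0


@dataclass(frozen=True)
class POSRetentionPolicy:
    """The set of part-of-speech tags kept before matching."""

    language: str
    retained_tags: frozenset[str]

    def __post_init__(self) -> None:
        if not self.retained_tags:
            raise ValueError("retention policy must keep at least one tag")


DEFAULT_POLICIES: dict[str, POSRetentionPolicy] = {
    "ko": POSRetentionPolicy("ko", frozenset({"NNG", "NNB", "VV", "VA", "XR"})),
    "en": POSRetentionPolicy(
        "en", frozenset({"NN", "NNS", "JJ", "VB", "VBG", "VBN", "RP", "DT", "IN", "TO"})
    ),
    # The Japanese retained classes are the tagger's noun/verb/adjective tags.
    "ja": POSRetentionPolicy("ja", frozenset({"meishi", "doushi", "keiyoushi"})),
}


def default_policy(language: str) -> POSRetentionPolicy:
    try:
        return DEFAULT_POLICIES[language]
    except KeyError:
        raise KeyError(f"no default POS retention policy for language {language!r}") from None


@dataclass(frozen=True)
class TokenizedPost:
    post_id: str
    language: str
    tokens: tuple[TaggedToken, ...]
    retained_tokens: tuple[TaggedToken, ...] = ()


@dataclass(frozen=True)
class LabeledPost:
    post_id: str
    text: str
    label: int
    matches: tuple[str, ...]

    def __post_init__(self) -> None:
        if (self.label == DEPRESSION) != bool(self.matches):
            raise ValueError("label must be 1 exactly when matches are non-empty")


class UnnormalizedLexiconError(ValueError):
    """match_lexicon requires normalize_entries to have been applied."""


def tokenize_with_pos(text: str, language: str, tagger: Tagger | None = None) -> TokenizedPost:
    """Deterministic token/tag sequence for one post."""
    if tagger is None:
        tagger = get_tagger(language)
    return TokenizedPost(post_id="", language=language, tokens=tuple(tagger.tag(text)))


def retain_pos(tokenized: TokenizedPost, policy: POSRetentionPolicy) -> TokenizedPost:
    """Order-preserving restriction of the token stream to retained tags."""
    if policy.language != tokenized.language:
        raise ValueError(
            f"policy language {policy.language!r} does not match post {tokenized.language!r}"
        )
    retained = tuple(t for t in tokenized.tokens if t[1] in policy.retained_tags)
    return TokenizedPost(tokenized.post_id, tokenized.language, tokenized.tokens, retained)


def _fold(token: str, tag: str, language: str) -> str:
    # Latin-script case folding; the English rule tagger additionally strips
    # plural -s so NN/NNS surface variants compare equal.
    if language == "en":
        token = token.lower()
        if tag == "NNS" and len(token) > 3 and token.endswith("s") and not token.endswith("ss"):
            token = token[:-1]
    return token


def _folded(tokens: Iterable[TaggedToken], language: str) -> list[str]:
    return [_fold(tok, tag, language) for tok, tag in tokens]


def match_lexicon(tokenized: TokenizedPost, lexicon: DepressionLexicon) -> list[str]:
    """Surfaces of all lexicon entries occurring contiguously in the retained
    tokens, deduplicated, in lexicon entry order."""
    if not lexicon.is_normalized:
        raise UnnormalizedLexiconError(
            "lexicon entries lack normalized_tokens; run normalize_entries first"
        )
    haystack = _folded(tokenized.retained_tokens, lexicon.language)
    matches: list[str] = []
    for entry in lexicon:
        needle = _folded(entry.normalized_tokens, lexicon.language)
        if _contains_contiguous(haystack, needle):
            matches.append(entry.surface)
    return matches


def _contains_contiguous(haystack: Sequence[str], needle: Sequence[str]) -> bool:
    n, m = len(haystack), len(needle)
    if m == 0 or m > n:
        return False
    return any(haystack[i : i + m] == list(needle) for i in range(n - m + 1))


def label_post(
    post,
    lexicon: DepressionLexicon,
    policy: POSRetentionPolicy | None = None,
    tagger: Tagger | None = None,
) -> LabeledPost:
    """tokenize -> retain POS -> match lexicon -> binary weak label.

    ``post`` is anything with ``post_id`` and (cleaned) ``text`` attributes,
    or a plain string.
    """
    post_id = getattr(post, "post_id", "")
    text = post if isinstance(post, str) else post.text
    if policy is None:
        policy = default_policy(lexicon.language)
    tokenized = tokenize_with_pos(text, lexicon.language, tagger)
    tokenized = TokenizedPost(post_id, tokenized.language, tokenized.tokens)
    retained = retain_pos(tokenized, policy)
    matches = tuple(match_lexicon(retained, lexicon))
    return LabeledPost(post_id, text, DEPRESSION if matches else NON_DEPRESSION, matches)


@dataclass
class LabelingSummary:
    n_depression: int
    n_non_depression: int
    entry_frequencies: Counter = field(default_factory=Counter)

    @property
    def class_counts(self) -> tuple[int, int]:
        """(non-depression, depression) counts."""
        return self.n_non_depression, self.n_depression


def label_corpus(
    posts: Iterable,
    lexicon: DepressionLexicon,
    policy: POSRetentionPolicy | None = None,
    tagger: Tagger | None = None,
) -> tuple[list[LabeledPost], LabelingSummary]:
    """Order-preserving weak labeling of a whole corpus with match statistics."""
    labeled: list[LabeledPost] = []
    freq: Counter = Counter()
    for post in posts:
        lp = label_post(post, lexicon, policy, tagger)
        labeled.append(lp)
        freq.update(lp.matches)
    n_dep = sum(1 for lp in labeled if lp.label == DEPRESSION)
    return labeled, LabelingSummary(n_dep, len(labeled) - n_dep, freq)


def write_labels_tsv(labeled: Sequence[LabeledPost], path) -> None:
    """``post_id  label  matches(comma-joined)`` alongside the input corpus."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("post_id\tlabel\tmatches\n")
        for lp in labeled:
            fh.write(f"{lp.post_id}\t{lp.label}\t{','.join(lp.matches)}\n")
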