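"""Rule-lite part-of-speech taggers.

Depression-lexicon matching only needs a *consistent* token/tag stream on both
the lexicon side and the post side, not state-of-the-art tagging.  The package
therefore ships small deterministic rule taggers (closed-class word lists plus
suffix heuristics) with no model downloads.  External morphological analyzers
(e.g. an NLTK, khaiii or fugashi wrapper) can be plugged in by registering any
object with the same ``tag(text)`` contract.
"""

from __future__ import annotations

import re
from typing import Protocol

TaggedToken = tuple[str, str]


class Tagger(Protocol):
    language: str

    def tag(self, text: str) -> list[TaggedToken]: ...


class UnsupportedLanguageError(KeyError):
    """No tagger is registered for the requested language."""


# Penn-style closed classes for the English rule tagger.
_DETERMINERS = {"the", "a", "an", "this", "that", "these", "those", "some", "any", "no", "every", "each"}
_PREPOSITIONS = {
    "in", "on", "of", "at", "by", "for", "with", "about", "against", "between",
    "into", "through", "during", "before", "after", "above", "below", "from",
    "up", "down", "over", "under", "if", "because", "while", "as",
}
_PARTICLES = {"out", "off", "away", "back"}
_PRONOUNS = {"i", "you", "he", "she", "it", "we", "they", "me", "him", "her", "us", "them", "my", "your", "his", "its", "our", "their"}
_MODALS = {"can", "could", "will", "would", "shall", "should", "may", "might", "must"}
_BE_HAVE = {"am", "is", "are", "was", "were", "be", "been", "being", "have", "has", "had", "do", "does", "did"}
_ADVERB_WORDS = {"not", "never", "always", "very", "too", "so", "just", "now", "then", "here", "there"}
_ADJ_SUFFIXES = ("ful", "less", "ous", "ive", "able", "ible", "al", "ic", "ish")

_WORD_RE = re.compile(r"[\w@#'-]+", re.UNICODE)


class EnglishRuleTagger:
    """Whitespace/word tokenizer with suffix-heuristic Penn-like tags.

    Tagset used: NN NNS JJ VB VBG VBN VBD RB RP DT IN TO PRP MD CD SYM.
    Deterministic; lowercasing is left to the matcher (tags only here).
    """

    language = "en"
    tagset = frozenset({"NN", "NNS", "JJ", "VB", "VBG", "VBN", "VBD", "RB", "RP", "DT", "IN", "TO", "PRP", "MD", "CD", "SYM"})

    def tag(self, text: str) -> list[TaggedToken]:
        return [(tok, self._tag_word(tok.lower())) for tok in _WORD_RE.findall(text)]

    @staticmethod
    def _tag_word(w: str) -> str:
        if w == "to":
            return "TO"
        if w in _DETERMINERS:
            return "DT"
        if w in _PREPOSITIONS:
            return "IN"
        if w in _PARTICLES:
            return "RP"
        if w in _PRONOUNS:
            return "PRP"
        if w in _MODALS:
            return "MD"
        if w in _BE_HAVE:
            return "VB"
        if w in _ADVERB_WORDS:
            return "RB"
        if w.replace(".", "").replace(",", "").isdigit():
            return "CD"
        if not any(c.isalpha() for c in w):
            return "SYM"
        if len(w) > 4:
            if w.endswith("ing"):
                return "VBG"
            if w.endswith("ed"):
                return "VBN"
            if w.endswith("ly"):
                return "RB"
            if w.endswith(_ADJ_SUFFIXES):
                return "JJ"
            if w.endswith("ss"):
                return "NN"
            if w.endswith("s"):
                return "NNS"
        return "NN"


class KoreanRuleTagger:
    """Whitespace eojeol splitter with ending heuristics.

    Emulates the Sejong-style tag subset used for matching: NNG (general
    noun, default), VV (verb, ``-da`` dictionary ending), VA (adjective
    endings), XR (roots).  A real morphological analyzer plugs in via
    :func:`register_tagger`.
    """

    language = "ko"
    tagset = frozenset({"NNG", "NNB", "VV", "VA", "XR", "SY"})

    def tag(self, text: str) -> list[TaggedToken]:
        out: list[TaggedToken] = []
        for tok in text.split():
            tok = tok.strip(".,!?~…\"'()[]")
            if not tok:
                continue
            if not any(self._is_word_char(c) for c in tok):
                out.append((tok, "SY"))
            elif tok.endswith(("하다", "있다", "없다", "지다", "되다")):
                out.append((tok, "VV"))
            elif tok.endswith(("프다", "쁘다", "롭다", "립다")):
                out.append((tok, "VA"))
            else:
                out.append((tok, "NNG"))
        return out

    @staticmethod
    def _is_word_char(c: str) -> bool:
        return c.isalnum()


class JapaneseRuleTagger:
    """Character-class run splitter for unspaced Japanese text.

    Splits on script boundaries (kanji / hiragana / katakana / latin) and tags
    runs with coarse classes: meishi (noun, default for kanji and katakana
    runs), doushi (verb, hiragana run ending in u-row kana), keiyoushi
    (adjective, run ending in い).  Space-separated text also works.
    """

    language = "ja"
    tagset = frozenset({"meishi", "doushi", "keiyoushi", "joshi", "SY"})

    _U_ROW = "うくすつぬふむゆるぐずづぶぷ"

    def tag(self, text: str) -> list[TaggedToken]:
        out: list[TaggedToken] = []
        for run in self._split_runs(text):
            kind = self._script(run[0])
            if kind == "sym":
                out.append((run, "SY"))
            elif kind == "hira":
                if run.endswith("い"):
                    out.append((run, "keiyoushi"))
                elif run[-1] in self._U_ROW:
                    out.append((run, "doushi"))
                elif len(run) <= 2:
                    out.append((run, "joshi"))
                else:
                    out.append((run, "meishi"))
            else:  # kanji, katakana, latin runs default to nouns
                out.append((run, "meishi"))
        return out

    @classmethod
    def _split_runs(cls, text: str) -> list[str]:
        runs: list[str] = []
        cur, cur_kind = "", None
        for c in text:
            if c.isspace():
                if cur:
                    runs.append(cur)
                cur, cur_kind = "", None
                continue
            kind = cls._script(c)
            if kind == cur_kind:
                cur += c
            else:
                if cur:
                    runs.append(cur)
                cur, cur_kind = c, kind
        if cur:
            runs.append(cur)
        return runs

    @staticmethod
    def _script(c: str) -> str:
        o = ord(c)
        if 0x3040 <= o <= 0x309F:
            return "hira"
        if 0x30A0 <= o <= 0x30FF:
            return "kata"
        if 0x4E00 <= o <= 0x9FFF:
            return "kanji"
        if c.isalnum():
            return "latin"
        return "sym"


_REGISTRY: dict[str, Tagger] = {}


def register_tagger(language: str, tagger: Tagger) -> None:
    _REGISTRY[language] = tagger


def get_tagger(language: str) -> Tagger:
    try:
        return _REGISTRY[language]
    except KeyError:
        raise UnsupportedLanguageError(
            f"no tagger registered for language {language!r}; "
            f"available: {sorted(_REGISTRY)}"
        ) from None


register_tagger("en", EnglishRuleTagger())
register_tagger("ko", KoreanRuleTagger())
register_tagger("ja", JapaneseRuleTagger())
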