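"""Per-language depression lexicons: loading, expert-score verification, POS
normalization.

A lexicon is a curated set of keywords judged to signal depressive content.
Each entry carries the relevance scores assigned by raters on a 5-point scale
(5 = significantly relevant) and, for translated lexicons, the outcome of the
translation-review step (0 correct / 1 not correct / 2 needs complement).
Verification keeps entries whose aggregated (mean) score reaches a threshold,
3 by default; entries scoring below it are excluded.  Before matching, every
surviving entry is normalized to its POS-tagged token form restricted to the
language's retention set, so that lexicon and post are filtered identically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Iterator, Optional

import pandas as pd

from .taggers import TaggedToken, Tagger, get_tagger

if TYPE_CHECKING:  # pragma: no cover
    from .labeling import POSRetentionPolicy

logger = logging.getLogger(__name__)

LANGUAGES = ("ko", "en", "ja")


class LexiconFormatError(ValueError):
    """The lexicon file does not have the expected TSV schema."""


class EmptyLexiconError(ValueError):
    """The lexicon file contains a header but no entries."""


@dataclass(frozen=True)
class LexiconEntry:
    """One keyword with its rater relevance scores.

    ``normalized_tokens`` is populated by :func:`normalize_entries`; it is the
    entry's POS-tagged token sequence restricted to the retention set.
    """

    surface: str
    language: str
    rater_scores: tuple[int, ...]
    review_label: Optional[int] = None
    normalized_tokens: Optional[tuple[TaggedToken, ...]] = None

    def __post_init__(self) -> None:
        if not self.surface:
            raise ValueError("lexicon entry surface must be non-empty")
        if any(not (1 <= s <= 5) for s in self.rater_scores):
            raise ValueError(
                f"rater scores for {self.surface!r} must lie in 1..5, got {self.rater_scores}"
            )
        if self.review_label is not None and self.review_label not in (0, 1, 2):
            raise ValueError(f"review label must be 0, 1 or 2, got {self.review_label}")

    @property
    def aggregated_score(self) -> float:
        """Arithmetic mean of the rater scores."""
        if not self.rater_scores:
            raise ValueError(f"entry {self.surface!r} has no rater scores")
        return sum(self.rater_scores) / len(self.rater_scores)


@dataclass
class DepressionLexicon:
    """Ordered, duplicate-free keyword set for one language."""

    language: str
    entries: list[LexiconEntry] = field(default_factory=list)
    relevance_threshold: float = 3.0

    def __post_init__(self) -> None:
        surfaces = [e.surface for e in self.entries]
        if len(surfaces) != len(set(surfaces)):
            raise ValueError("duplicate surfaces within a lexicon")
        for e in self.entries:
            if e.language != self.language:
                raise ValueError(
                    f"entry {e.surface!r} has language {e.language!r}, lexicon is {self.language!r}"
                )

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[LexiconEntry]:
        return iter(self.entries)

    @property
    def surfaces(self) -> list[str]:
        return [e.surface for e in self.entries]

    @property
    def is_normalized(self) -> bool:
        return bool(self.entries) and all(e.normalized_tokens is not None for e in self.entries)


def load_lexicon(path: str | Path, language: str) -> DepressionLexicon:
    """Read a lexicon TSV: columns ``surface  language  score_1..score_k
    [review_label]``.

    All rows are returned unfiltered (run :func:`apply_relevance_filter`
    afterwards); duplicate surfaces are collapsed keep-first with a warning.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise EmptyLexiconError(f"{path} has no content") from None
    score_cols = [c for c in df.columns if c.startswith("score")]
    missing = {"surface", "language"} - set(df.columns)
    if missing or not score_cols:
        raise LexiconFormatError(
            f"{path} lacks required columns: need surface, language and >=1 score_* "
            f"column, found {list(df.columns)}"
        )
    if df.empty:
        raise EmptyLexiconError(f"{path} contains a header but no entries")
    bad_lang = df.loc[df["language"] != language, "language"].unique()
    if len(bad_lang):
        raise LexiconFormatError(
            f"{path} declares language(s) {sorted(bad_lang)} but {language!r} was requested"
        )

    entries: list[LexiconEntry] = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        surface = row["surface"].strip()
        if surface in seen:
            logger.warning("duplicate lexicon surface %r in %s collapsed (keep-first)", surface, path)
            continue
        seen.add(surface)
        scores = tuple(int(row[c]) for c in score_cols if str(row[c]).strip() != "")
        review = None
        if "review_label" in df.columns and str(row["review_label"]).strip() != "":
            review = int(row["review_label"])
        entries.append(LexiconEntry(surface, language, scores, review))
    return DepressionLexicon(language=language, entries=entries)


def write_lexicon_tsv(lexicon: DepressionLexicon, path: str | Path) -> None:
    """Inverse of :func:`load_lexicon` (normalized forms are not persisted)."""
    k = max((len(e.rater_scores) for e in lexicon.entries), default=1)
    cols = ["surface", "language"] + [f"score_{i + 1}" for i in range(k)] + ["review_label"]
    rows = []
    for e in lexicon.entries:
        scores = list(e.rater_scores) + [""] * (k - len(e.rater_scores))
        rows.append([e.surface, e.language, *scores, "" if e.review_label is None else e.review_label])
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def apply_relevance_filter(
    lexicon: DepressionLexicon, threshold: float | None = None
) -> DepressionLexicon:
    """Keep entries whose mean rater score is >= ``threshold`` (inclusive).

    Mirrors the verification step that excludes keywords scoring below 3 on
    the 5-point relevance scale.  Order-preserving and idempotent.
    """
    if threshold is None:
        threshold = lexicon.relevance_threshold
    for e in lexicon.entries:
        if not e.rater_scores:
            raise ValueError(f"entry {e.surface!r} has no rater scores; cannot verify")
    kept = [e for e in lexicon.entries if e.aggregated_score >= threshold]
    if not kept:
        logger.warning("relevance filter at %.2f removed every entry (%s)", threshold, lexicon.language)
    return DepressionLexicon(lexicon.language, kept, relevance_threshold=threshold)


def normalize_entries(
    lexicon: DepressionLexicon,
    policy: "POSRetentionPolicy",
    tagger: Tagger | None = None,
) -> DepressionLexicon:
    """POS-tag each keyword and restrict it to the retention set.

    Entries whose normalized form is empty (made only of non-retained POS) are
    dropped with a warning.  The same policy must be applied to posts before
    matching so both sides live in the same filtered token space.
    """
    if policy.language != lexicon.language:
        raise ValueError(
            f"policy language {policy.language!r} does not match lexicon {lexicon.language!r}"
        )
    if tagger is None:
        tagger = get_tagger(lexicon.language)
    out: list[LexiconEntry] = []
    for e in lexicon.entries:
        tagged = tagger.tag(e.surface)
        retained = tuple(t for t in tagged if t[1] in policy.retained_tags)
        if not retained:
            logger.warning(
                "lexicon entry %r normalizes to nothing under policy %s; dropped",
                e.surface, sorted(policy.retained_tags),
            )
            continue
        out.append(replace(e, normalized_tokens=retained))
    return DepressionLexicon(lexicon.language, out, relevance_threshold=lexicon.relevance_threshold)
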