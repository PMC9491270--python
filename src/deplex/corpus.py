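"""Account- and post-level eligibility filtering and text cleaning.

Filters mirror the data-collection rules for a microblog corpus: an account
is excluded when it posted nothing in the observed window, when it posts more
than 20 times per day, when its profile description announces a move to
another account, or when the description carries a hyperlink (promotional /
abandoned accounts).  An account's main language is declared by inspecting
its five most recent posts.  Post cleaning strips e-mail addresses, URLs and
off-language script spans; short posts can be dropped by a minimum word
count (10 words in the community-forum study).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Callable, Iterable, Optional, Sequence

EXCLUSION_REASONS = (
    "rate_zero",
    "rate_over_limit",
    "moved_to",
    "hyperlink_description",
    "no_target_language",
)

# Profile markers announcing that the account is abandoned.  The rule covers
# the English marker plus its common Korean/Japanese renderings.
DEFAULT_MOVED_MARKERS = ("moved to", "이사", "移転")

EMAIL_RE = re.compile(r"\S+@\S+\.\S+")
URL_RE = re.compile(r"(?:https?://\S+|www\.\S+)")

_HANGUL = "가-힯ᄀ-ᇿ㄰-㆏"
_KANA = "぀-ゟ゠-ヿ"
_CJK = "一-鿿"
_LATIN = "a-zA-Z"

# Foreign-script spans removed per declared post language.  Latin is never
# removed (it is ubiquitous in ko/ja posts); the CJK block is shared between
# Japanese and Korean hanja so it is only stripped from English posts.
OFFSCRIPT_PATTERNS: dict[str, re.Pattern] = {
    "en": re.compile(f"[{_HANGUL}{_KANA}{_CJK}]+"),
    "ko": re.compile(f"[{_KANA}]+"),
    "ja": re.compile(f"[{_HANGUL}]+"),
}

_SCRIPT_RES = {
    "ko": re.compile(f"[{_HANGUL}]"),
    "ja": re.compile(f"[{_KANA}{_CJK}]"),
    "en": re.compile(f"[{_LATIN}]"),
}


@dataclass(frozen=True)
class RawPost:
    post_id: str
    user_id: str
    language: str
    timestamp: datetime
    text: str

    def __post_init__(self) -> None:
        if self.text is None:
            raise ValueError("post text must be non-null (may be empty)")


@dataclass
class UserAccount:
    """An account with its observed posts, newest first."""

    user_id: str
    description: str = ""
    posts: list[RawPost] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.posts.sort(key=lambda p: p.timestamp, reverse=True)

    @property
    def posts_per_day(self) -> float:
        """Posts divided by the observed span in days, span floored at 1."""
        if not self.posts:
            return 0.0
        span = (self.posts[0].timestamp - self.posts[-1].timestamp).total_seconds() / 86400.0
        return len(self.posts) / max(span, 1.0)

    @property
    def recent_posts(self) -> list[RawPost]:
        return self.posts[:5]


@dataclass
class FilterReport:
    retained: list[str] = field(default_factory=list)
    excluded: list[tuple[str, str]] = field(default_factory=list)

    def reason_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for _, reason in self.excluded:
            counts[reason] = counts.get(reason, 0) + 1
        return counts

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("id\tstatus\treason\n")
            for uid in self.retained:
                fh.write(f"{uid}\tretained\t\n")
            for uid, reason in self.excluded:
                fh.write(f"{uid}\texcluded\t{reason}\n")


def contains_language(text: str, language: str) -> bool:
    """Unicode-script heuristic: Hangul -> ko, kana/CJK -> ja, Latin -> en."""
    pat = _SCRIPT_RES.get(language)
    return bool(pat and pat.search(text))


def assign_main_language(
    recent_posts: Sequence[RawPost],
    targets: Sequence[str],
    detector: Callable[[str, str], bool] = contains_language,
) -> Optional[str]:
    """Declare an account's main language from its <=5 most recent posts.

    Returns the first target language (in the given priority order) detected
    in any of the posts, or None when no target is detected.
    """
    posts = list(recent_posts)[:5]
    for lang in targets:
        if any(detector(p.text, lang) for p in posts):
            return lang
    return None


def filter_accounts(
    accounts: Iterable[UserAccount],
    max_rate: float = 20.0,
    moved_markers: Sequence[str] = DEFAULT_MOVED_MARKERS,
    hyperlink_pattern: re.Pattern = URL_RE,
    targets: Optional[Sequence[str]] = None,
) -> FilterReport:
    """Apply the account eligibility rules; one (first-matching) reason each.

    Rule order: no posts -> rate above ``max_rate`` -> "moved to" marker in
    the description -> hyperlink in the description -> (if ``targets`` given)
    no target language among the five most recent posts.
    """
    report = FilterReport()
    for acct in accounts:
        desc = (acct.description or "").lower()
        if not acct.posts:
            report.excluded.append((acct.user_id, "rate_zero"))
        elif acct.posts_per_day > max_rate:
            report.excluded.append((acct.user_id, "rate_over_limit"))
        elif any(marker.lower() in desc for marker in moved_markers):
            report.excluded.append((acct.user_id, "moved_to"))
        elif hyperlink_pattern.search(acct.description or ""):
            report.excluded.append((acct.user_id, "hyperlink_description"))
        elif targets is not None and assign_main_language(acct.recent_posts, targets) is None:
            report.excluded.append((acct.user_id, "no_target_language"))
        else:
            report.retained.append(acct.user_id)
    return report


def clean_post(text: str, language: str) -> str:
    """Remove e-mail addresses, URLs and off-language script spans; collapse
    whitespace.  Deterministic and idempotent; empty output is allowed."""
    text = EMAIL_RE.sub(" ", text)
    text = URL_RE.sub(" ", text)
    offscript = OFFSCRIPT_PATTERNS.get(language)
    if offscript is not None:
        text = offscript.sub(" ", text)
    return " ".join(text.split())


def word_count(text: str) -> int:
    return len(text.split())


def filter_min_words(posts: Iterable[RawPost], min_words: int = 10) -> list[RawPost]:
    """Keep posts with at least ``min_words`` whitespace-delimited tokens
    (a 10-word post is kept; a 9-word post is dropped)."""
    return [p for p in posts if word_count(p.text) >= min_words]


# ---------------------------------------------------------------------------
# JSON-lines corpus I/O: one post per line, fields id/user/lang/ts/text.

def read_posts_jsonl(path: str | Path) -> list[RawPost]:
    posts = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            rec = json.loads(line)
            posts.append(
                RawPost(
                    post_id=str(rec["id"]),
                    user_id=str(rec["user"]),
                    language=rec["lang"],
                    timestamp=datetime.fromisoformat(rec["ts"]),
                    text=rec["text"],
                )
            )
    return posts


def write_posts_jsonl(posts: Iterable[RawPost], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for p in posts:
            rec = {
                "id": p.post_id,
                "user": p.user_id,
                "lang": p.language,
                "ts": p.timestamp.isoformat(),
                "text": p.text,
            }
            fh.write(json.dumps(rec, ensure_ascii=False, sort_keys=True) + "\n")
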