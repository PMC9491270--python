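"""Synthetic short-post corpora with the statistical structure the pipeline
assumes, so every stage runs and is testable with no external download.

The generator emulates a microblog crawl: short posts (negative-binomial
token counts, default mean 8 words as observed for Korean posts; English and
Japanese means in the motivating datasets range roughly 3–13), heavy class
imbalance (a small depression_rate), weak-label structure (each "depressed"
post carries at least one injected lexicon term; the injection indicator IS
the ground-truth label, which makes labeling-oracle checks exact), noise
artifacts (URLs, e-mail addresses, off-language script spans) and account
metadata exercising every eligibility filter (empty accounts, >20 posts/day
burst accounts, "moved to" and hyperlink descriptions).

The synthetic "language" is an abstract token alphabet that the fallback
English tagger tags as nouns, i.e. retained POS; realism of any natural
language is out of scope — only the statistical structure matters.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, timedelta
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .corpus import RawPost, UserAccount
from .lexicon import DepressionLexicon, LexiconEntry, write_lexicon_tsv


@dataclass(frozen=True)
class SyntheticCorpusSpec:
    n_posts: int = 2000
    depression_rate: float = 0.05
    mean_len: float = 8.0
    len_dispersion: float = 1.2
    vocab_size: int = 500
    n_lexicon_terms: int = 20
    url_rate: float = 0.05
    email_rate: float = 0.03
    offlang_rate: float = 0.05
    # Topical correlation: depressed posts draw part of their background from
    # a depression-context sub-vocabulary (the first context_fraction of the
    # background types), emulating the non-keyword contextual signal that is
    # lost when a classifier moves to a new platform.
    context_fraction: float = 0.1
    context_strength: float = 0.3
    n_accounts: int = 50
    rate_outlier_fraction: float = 0.05
    moved_to_fraction: float = 0.05
    hyperlink_fraction: float = 0.05
    empty_account_fraction: float = 0.05
    language: str = "en"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("depression_rate", "url_rate", "email_rate", "offlang_rate",
                     "context_fraction", "context_strength",
                     "rate_outlier_fraction", "moved_to_fraction", "hyperlink_fraction",
                     "empty_account_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_lexicon_terms >= self.vocab_size:
            raise ValueError("n_lexicon_terms must be smaller than vocab_size")
        if self.mean_len <= 0 or self.len_dispersion <= 0:
            raise ValueError("mean_len and len_dispersion must be positive")


@dataclass
class SyntheticVocab:
    """Background word list plus the designated depression lexemes (disjoint)."""

    background: list[str]
    lexicon_terms: list[str]

    def to_lexicon(self, language: str = "en") -> DepressionLexicon:
        entries = [
            LexiconEntry(term, language, rater_scores=(5, 5), review_label=0)
            for term in self.lexicon_terms
        ]
        return DepressionLexicon(language, entries)

    def write_lexicon(self, path: str | Path, language: str = "en") -> None:
        write_lexicon_tsv(self.to_lexicon(language), path)


def generate_vocab(spec: SyntheticCorpusSpec) -> SyntheticVocab:
    """vocab_size synthetic word strings, n_lexicon_terms of them marked as
    depression lexemes; the two sets never overlap."""
    n_bg = spec.vocab_size - spec.n_lexicon_terms
    background = [f"w{i:04d}" for i in range(n_bg)]
    lexicon = [f"dlex{i:03d}" for i in range(spec.n_lexicon_terms)]
    return SyntheticVocab(background, lexicon)


def _post_lengths(spec: SyntheticCorpusSpec, rng: np.random.Generator, n: int) -> np.ndarray:
    # negative binomial parameterized by mean/dispersion: var = m + m^2/k
    k = spec.len_dispersion
    p = k / (k + spec.mean_len)
    return np.maximum(1, rng.negative_binomial(k, p, size=n))


_OFFLANG_SPANS = ("우울한 하루", "嬉しい気分", "ありがとう")


def generate_corpus(
    spec: SyntheticCorpusSpec,
    vocab: Optional[SyntheticVocab] = None,
) -> tuple[list[RawPost], dict[str, int], list[UserAccount]]:
    """Posts + ground-truth labels + account metadata.

    Each post is depressed with probability ``depression_rate``, in which
    case one lexicon term is injected at a random position; noise artifacts
    are injected at the spec rates.  A fraction of accounts are constructed
    to trip each account filter.  Fully deterministic under the spec seed.
    """
    if vocab is None:
        vocab = generate_vocab(spec)
    rng = np.random.default_rng(spec.seed)
    base_ts = datetime(2020, 1, 1)

    n_empty = max(0, int(round(spec.empty_account_fraction * spec.n_accounts)))
    n_outlier = max(0, int(round(spec.rate_outlier_fraction * spec.n_accounts)))
    n_moved = max(0, int(round(spec.moved_to_fraction * spec.n_accounts)))
    n_hyper = max(0, int(round(spec.hyperlink_fraction * spec.n_accounts)))

    descriptions: list[str] = []
    roles: list[str] = []
    for i in range(spec.n_accounts):
        if i < n_empty:
            roles.append("empty")
            descriptions.append("synthetic account")
        elif i < n_empty + n_outlier:
            roles.append("outlier")
            descriptions.append("synthetic burst account")
        elif i < n_empty + n_outlier + n_moved:
            roles.append("moved")
            descriptions.append("moved to @elsewhere")
        elif i < n_empty + n_outlier + n_moved + n_hyper:
            roles.append("hyperlink")
            descriptions.append("see https://example.com/promo")
        else:
            roles.append("normal")
            descriptions.append("synthetic account")
    account_ids = [f"a{i:04d}" for i in range(spec.n_accounts)]

    # Outlier accounts post in a one-day burst; everyone else spreads posts
    # over 60 days so their rate stays far below the 20/day limit.
    outlier_quota = 25
    posting = [i for i, r in enumerate(roles) if r not in ("empty",)]
    burst = [i for i, r in enumerate(roles) if r == "outlier"]
    normal_pool = [i for i in posting if roles[i] != "outlier"] or posting

    lengths = _post_lengths(spec, rng, spec.n_posts)
    depressed = rng.random(spec.n_posts) < spec.depression_rate

    posts: list[RawPost] = []
    truth: dict[str, int] = {}
    per_account_counter = dict.fromkeys(range(spec.n_accounts), 0)
    burst_remaining = {i: outlier_quota for i in burst}

    n_context = int(round(spec.context_fraction * len(vocab.background)))
    context_words = vocab.background[:n_context]

    for i in range(spec.n_posts):
        tokens = list(rng.choice(vocab.background, size=lengths[i]))
        if depressed[i]:
            if context_words and spec.context_strength > 0:
                from_context = rng.random(lengths[i]) < spec.context_strength
                for j in np.flatnonzero(from_context):
                    tokens[j] = str(rng.choice(context_words))
            term = str(rng.choice(vocab.lexicon_terms))
            pos = int(rng.integers(0, len(tokens) + 1))
            tokens.insert(pos, term)
        if rng.random() < spec.url_rate:
            tokens.insert(int(rng.integers(0, len(tokens) + 1)),
                          f"https://t.co/{rng.integers(0, 16**6):06x}")
        if rng.random() < spec.email_rate:
            tokens.insert(int(rng.integers(0, len(tokens) + 1)),
                          f"user{rng.integers(0, 1000):03d}@example.com")
        if rng.random() < spec.offlang_rate:
            tokens.insert(int(rng.integers(0, len(tokens) + 1)),
                          str(rng.choice(_OFFLANG_SPANS)))

        # account assignment: fill burst accounts first, then round-robin
        pending_burst = [a for a in burst if burst_remaining.get(a, 0) > 0]
        if pending_burst:
            acct = pending_burst[0]
            burst_remaining[acct] -= 1
            ts = base_ts + timedelta(minutes=int(per_account_counter[acct]) * 3)
        else:
            acct = normal_pool[i % len(normal_pool)]
            j = per_account_counter[acct]
            ts = base_ts + timedelta(days=int(j % 60), hours=int(j // 60) % 24, minutes=i % 60)
        per_account_counter[acct] += 1

        pid = f"p{i:06d}"
        posts.append(RawPost(pid, account_ids[acct], spec.language, ts, " ".join(tokens)))
        truth[pid] = int(depressed[i])

    accounts = []
    by_user: dict[str, list[RawPost]] = {uid: [] for uid in account_ids}
    for p in posts:
        by_user[p.user_id].append(p)
    for i, uid in enumerate(account_ids):
        accounts.append(UserAccount(uid, descriptions[i], list(by_user[uid])))
    return posts, truth, accounts


def write_truth_tsv(truth: dict[str, int], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("post_id\tlabel\n")
        for pid in sorted(truth):
            fh.write(f"{pid}\t{truth[pid]}\n")


def read_truth_tsv(path: str | Path) -> dict[str, int]:
    truth: dict[str, int] = {}
    with open(path, encoding="utf-8") as fh:
        next(fh)
        for line in fh:
            pid, label = line.rstrip("\n").split("\t")
            truth[pid] = int(label)
    return truth


def inject_domain_shift(
    posts: Sequence[RawPost],
    shift_fraction: float,
    seed: int = 0,
    preserve: Sequence[str] = (),
) -> list[RawPost]:
    """Replace a fraction of background vocabulary *types* with unseen tokens.

    Emulates moving the classifier to a new platform: the depression lexemes
    (``preserve``) and the labels stay fixed while the surrounding vocabulary
    drifts.  fraction 0 is the identity; fraction 1 leaves no background type
    shared with the source corpus.
    """
    if not 0.0 <= shift_fraction <= 1.0:
        raise ValueError(f"shift_fraction must lie in [0, 1], got {shift_fraction}")
    preserve_set = set(preserve)
    types = sorted({tok for p in posts for tok in p.text.split()} - preserve_set)
    rng = np.random.default_rng(seed)
    n_shift = int(round(shift_fraction * len(types)))
    shifted = rng.choice(len(types), size=n_shift, replace=False)
    mapping = {types[j]: f"shifted{i:05d}" for i, j in enumerate(sorted(shifted))}
    out = []
    for p in posts:
        text = " ".join(mapping.get(tok, tok) for tok in p.text.split())
        out.append(RawPost(p.post_id, p.user_id, p.language, p.timestamp, text))
    return out
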