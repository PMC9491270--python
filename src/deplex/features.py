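"""Token-index encodings: vocabulary, fixed-length feature matrices, splits.

Posts are encoded as length-``max_len`` vectors of token indices with pad
index 0 and a reserved unknown-token index, optionally wrapped in begin/end
boundary markers (the [CLS]/[SEP]-style special tokens whose duplication
under naive interpolation the sampling module guards against).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

import numpy as np

PAD, UNK, BOS, EOS = "<pad>", "<unk>", "<s>", "</s>"


class Vocabulary:
    """Frozen token -> index mapping with reserved special indices.

    Index 0 is the pad token and index 1 the unknown token; when
    ``boundaries`` is on, indices 2 and 3 are begin/end sequence markers.
    """

    def __init__(self, tokens: Iterable[str], boundaries: bool = False):
        self.boundaries = boundaries
        specials = [PAD, UNK] + ([BOS, EOS] if boundaries else [])
        self._itos: list[str] = list(specials)
        seen = set(specials)
        for tok in tokens:
            if tok not in seen:
                seen.add(tok)
                self._itos.append(tok)
        if len(self._itos) == len(specials):
            raise ValueError("cannot build a vocabulary from zero tokens")
        self._stoi = {t: i for i, t in enumerate(self._itos)}

    def __len__(self) -> int:
        return len(self._itos)

    def __contains__(self, token: str) -> bool:
        return token in self._stoi

    @property
    def pad_index(self) -> int:
        return 0

    @property
    def unk_index(self) -> int:
        return 1

    @property
    def bos_index(self) -> Optional[int]:
        return 2 if self.boundaries else None

    @property
    def eos_index(self) -> Optional[int]:
        return 3 if self.boundaries else None

    def index(self, token: str) -> int:
        return self._stoi.get(token, self.unk_index)

    def token(self, index: int) -> str:
        return self._itos[index]

    def encode(self, tokens: Sequence[str], max_len: int) -> np.ndarray:
        idx = [self.index(t) for t in tokens]
        if self.boundaries:
            idx = [self.bos_index] + idx[: max_len - 2] + [self.eos_index]
        else:
            idx = idx[:max_len]
        vec = np.zeros(max_len, dtype=np.int64)
        vec[: len(idx)] = idx
        return vec

    def decode(self, indices: Sequence[int]) -> list[str]:
        """Tokens for non-pad, non-boundary indices (round-trip of encode for
        in-vocabulary posts shorter than max_len)."""
        skip = {self.pad_index}
        if self.boundaries:
            skip |= {self.bos_index, self.eos_index}
        return [self._itos[i] for i in indices if i not in skip]

    @classmethod
    def build(cls, token_lists: Iterable[Sequence[str]], boundaries: bool = False) -> "Vocabulary":
        """Build from the training split's token lists only (first-seen order)."""
        def stream():
            for toks in token_lists:
                yield from toks
        return cls(stream(), boundaries=boundaries)


@dataclass
class FeatureMatrix:
    """n x L token-index matrix plus binary labels.

    ``boundary_indices`` lists the reserved marker indices (begin/end) whose
    per-row multiplicity must be preserved by any resampling step.
    """

    X: np.ndarray
    y: np.ndarray
    vocab_size: int
    pad_index: int = 0
    boundary_indices: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.int64)
        self.y = np.asarray(self.y, dtype=np.int64)
        if self.X.ndim != 2 or len(self.X) != len(self.y):
            raise ValueError("X must be n x L with one label per row")
        if self.X.size and (self.X.min() < 0 or self.X.max() >= self.vocab_size):
            raise ValueError("token indices must lie in [0, vocab_size)")

    def __len__(self) -> int:
        return len(self.y)

    @property
    def max_len(self) -> int:
        return self.X.shape[1]

    def class_counts(self) -> tuple[int, int]:
        """(negatives, positives)."""
        pos = int(self.y.sum())
        return len(self.y) - pos, pos

    def subset(self, indices: np.ndarray) -> "FeatureMatrix":
        return replace(self, X=self.X[indices], y=self.y[indices])


def encode_posts(
    token_lists: Sequence[Sequence[str]],
    vocabulary: Vocabulary,
    max_len: int,
    labels: Optional[Sequence[int]] = None,
) -> FeatureMatrix:
    """Encode tokenized posts into a FeatureMatrix (truncate tail, pad 0)."""
    if len(vocabulary) == 0:
        raise ValueError("empty vocabulary")
    X = np.stack([vocabulary.encode(toks, max_len) for toks in token_lists]) if token_lists else np.zeros((0, max_len), dtype=np.int64)
    y = np.zeros(len(X), dtype=np.int64) if labels is None else np.asarray(labels, dtype=np.int64)
    boundaries = ()
    if vocabulary.boundaries:
        boundaries = (vocabulary.bos_index, vocabulary.eos_index)
    return FeatureMatrix(X, y, vocab_size=len(vocabulary), boundary_indices=boundaries)


def stratified_split(
    y: Sequence[int],
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Label-stratified train/validation/test index split."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    train, val, test = [], [], []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        n = len(idx)
        n_train = int(round(fractions[0] * n))
        n_val = int(round(fractions[1] * n))
        train.append(idx[:n_train])
        val.append(idx[n_train : n_train + n_val])
        test.append(idx[n_train + n_val :])
    return (
        np.sort(np.concatenate(train)),
        np.sort(np.concatenate(val)),
        np.sort(np.concatenate(test)),
    )
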