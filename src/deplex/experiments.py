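"""Reusable end-to-end experiment harnesses on synthetic corpora.

These drive the full stack — generate → clean → weak-label → encode →
resample → split → train → evaluate — and exist so that the imbalance and
domain-shift comparisons are computed one way everywhere (library users,
tests, reproduction script).

Resampling happens on the whole labeled dataset *before* the stratified
split by default, which is the protocol under which balanced resampling
reports near-ceiling metrics for both classes; pass
``sampling_stage="train_only"`` for the leakage-free variant (its evaluation
set then keeps the raw class imbalance).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .corpus import clean_post
from .evaluation import EvalReport, cross_domain_evaluate, evaluate
from .features import Vocabulary, encode_posts, stratified_split
from .labeling import default_policy, label_corpus
from .lexicon import normalize_entries
from .models import (
    ModelConfig,
    TrainedClassifier,
    build_classifier,
    embedding_matrix,
    train_classifier,
    train_word_embeddings,
)
from .sampling import SamplingConfig, apply_sampling
from .synthetic import SyntheticCorpusSpec, SyntheticVocab, generate_corpus, generate_vocab, inject_domain_shift
from .taggers import get_tagger


@dataclass
class ExperimentResult:
    report: EvalReport
    trained: TrainedClassifier
    spec: SyntheticCorpusSpec
    synth_vocab: SyntheticVocab
    weak_labels: np.ndarray
    test_indices: np.ndarray  # rows of the (possibly resampled) matrix


def _tokenize(texts: Sequence[str], language: str) -> list[list[str]]:
    tagger = get_tagger(language)
    return [[tok for tok, _ in tagger.tag(t)] for t in texts]


def run_synthetic_experiment(
    spec: SyntheticCorpusSpec,
    model: Optional[ModelConfig] = None,
    sampling: Optional[SamplingConfig] = None,
    sampling_stage: str = "before_split",
    use_word2vec: bool = False,
    split_seed: Optional[int] = None,
) -> ExperimentResult:
    """Generate one synthetic corpus and train/evaluate one classifier on its
    weak labels."""
    if sampling_stage not in ("before_split", "train_only"):
        raise ValueError(f"unknown sampling_stage {sampling_stage!r}")
    model = model or ModelConfig.for_family("cnn", max_len=24, seed=spec.seed)
    sampling = sampling or SamplingConfig(seed=spec.seed)
    split_seed = spec.seed if split_seed is None else split_seed

    synth_vocab = generate_vocab(spec)
    posts, _, _ = generate_corpus(spec, synth_vocab)
    texts = [clean_post(p.text, spec.language) for p in posts]
    lexicon = normalize_entries(synth_vocab.to_lexicon(spec.language), default_policy(spec.language))
    labeled, _ = label_corpus(texts, lexicon)
    y = np.array([lp.label for lp in labeled])
    tokens = _tokenize(texts, spec.language)

    if sampling_stage == "before_split":
        vocab = Vocabulary.build(tokens)
        fm = apply_sampling(encode_posts(tokens, vocab, model.max_len, labels=y), sampling)
        tr, va, te = stratified_split(fm.y, seed=split_seed)
        train_fm, val_fm, test_fm = fm.subset(tr), fm.subset(va), fm.subset(te)
        train_tokens = tokens  # resampled rows have no token-level form
    else:
        tr, va, te = stratified_split(y, seed=split_seed)
        vocab = Vocabulary.build([tokens[i] for i in tr])
        fm = encode_posts(tokens, vocab, model.max_len, labels=y)
        train_fm = apply_sampling(fm.subset(tr), sampling)
        val_fm, test_fm = fm.subset(va), fm.subset(te)
        train_tokens = [tokens[i] for i in tr]

    clf = build_classifier(model, vocab_size=len(vocab))
    if use_word2vec and model.family in ("cnn", "bilstm"):
        w2v = train_word_embeddings(train_tokens, dim=model.embed_dim, seed=model.seed)
        clf.set_embeddings(embedding_matrix(w2v, vocab, model.embed_dim, seed=model.seed))
    trained = train_classifier(clf, train_fm, val_fm, model, vocabulary=vocab)
    report = evaluate(trained, test_fm)
    return ExperimentResult(report, trained, spec, synth_vocab, y, te)


def imbalance_comparison(
    seed: int,
    n_posts: int = 4000,
    depression_rate: float = 0.01,
    model: Optional[ModelConfig] = None,
    **spec_overrides,
) -> dict[str, float]:
    """Minority-class F1 with no resampling vs with under-sampling, on one
    heavily imbalanced synthetic corpus."""
    spec = SyntheticCorpusSpec(
        n_posts=n_posts, depression_rate=depression_rate, seed=seed, **spec_overrides
    )
    model = model or ModelConfig.for_family("cnn", max_len=24, seed=seed)
    out = {}
    for mode in ("normal", "under"):
        res = run_synthetic_experiment(spec, model=model, sampling=SamplingConfig(mode=mode, seed=seed))
        out[mode] = res.report.per_class[1].f1
    return out


def domain_shift_comparison(
    seed: int,
    shift_fraction: float = 0.5,
    n_posts: int = 4000,
    n_eval_posts: int = 12000,
    depression_rate: float = 0.5,
    model: Optional[ModelConfig] = None,
    **spec_overrides,
) -> dict[str, float]:
    """Depression-class F1 on a fresh evaluation corpus, before and after a
    background-vocabulary shift.

    The classifier is trained on one synthetic corpus, then scored on an
    independent corpus drawn from the same generator — once as-is
    (in-domain) and once after ``shift_fraction`` of the background
    vocabulary types are replaced with tokens unseen at training time
    (cross-domain).  The two evaluations are item-matched and large, so the
    measured difference isolates the vocabulary drift.  The default encoder
    window (max_len 12) is deliberately shorter than the longest posts:
    part of the label evidence then lies beyond the window, so the
    classifier must also rely on contextual vocabulary — the signal that a
    platform change destroys.
    """
    spec = SyntheticCorpusSpec(
        n_posts=n_posts, depression_rate=depression_rate, seed=seed, **spec_overrides
    )
    model = model or ModelConfig.for_family("cnn", max_len=12, seed=seed)
    res = run_synthetic_experiment(spec, model=model)

    eval_spec = dataclasses.replace(spec, n_posts=n_eval_posts, seed=spec.seed + 90001)
    eval_posts, _, _ = generate_corpus(eval_spec, res.synth_vocab)
    shifted = inject_domain_shift(
        eval_posts, shift_fraction, seed=seed + 1, preserve=res.synth_vocab.lexicon_terms
    )
    lexicon = normalize_entries(res.synth_vocab.to_lexicon(spec.language), default_policy(spec.language))
    eval_texts = [clean_post(p.text, spec.language) for p in eval_posts]
    labeled, _ = label_corpus(eval_texts, lexicon)
    y_eval = np.array([lp.label for lp in labeled])  # unchanged by the shift
    out = {}
    for tag, texts in (("in_domain", eval_texts),
                       ("cross_domain", [clean_post(p.text, spec.language) for p in shifted])):
        report = cross_domain_evaluate(res.trained, _tokenize(texts, spec.language), y_eval)
        out[tag] = report.per_class[1].f1
    return out
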