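# Methods

`deplex` implements a lexicon-based weak-supervision pipeline for detecting
depression-related posts in short social-media text, together with the
classifier families and evaluation protocol commonly used with it.  This
note documents the model and procedure, the parameters that matter, the
synthetic data the tests run on, and the design choices that were genuinely
open.

## Weak labeling model

A post receives the binary label *depression* (1) when it contains at least
one entry of a curated depression lexicon; otherwise *non-depression* (0).
Matching happens in a POS-filtered token space: both the post and every
lexicon entry are POS-tagged and restricted to a per-language retention set
before comparison, so inflectional clutter and function words cannot block
or fake a match.

Retention sets (overridable per run):

| language | retained tags |
|---|---|
| ko | NNG, NNB, VV, VA, XR (Sejong) |
| en | NN, NNS, JJ, VB, VBG, VBN, RP, DT, IN, TO (Penn) |
| ja | the tagger's noun / verb / adjective classes |

A multi-word entry matches only as a *contiguous* subsequence of the
retained tokens — the strictest reading that still handles translated
multi-word keywords.  Comparison is on surface tokens with Latin-script
case folding; the English rule tagger additionally strips plural "-s" so
NN/NNS variants compare equal.  No lemmatizer is used.

Lexicon verification: each keyword carries one relevance score per rater on
a 5-point scale.  Scores are aggregated by arithmetic mean and entries with
mean below 3 are excluded (boundary inclusive: mean exactly 3 is kept).
Mean aggregation is the simplest reading of a two-rater 5-point filter;
minimum or consensus rules would be stricter and are not implemented.

### Taggers

The package ships deterministic rule-lite taggers (closed-class word lists
plus suffix heuristics for English; eojeol-ending heuristics for Korean;
script-run segmentation for unspaced Japanese) so that no model download is
needed anywhere.  They are not linguistically serious taggers; they are
consistent token/tag providers for matching, and external morphological
analyzers (khaiii, NLTK, fugashi) can be registered behind the same
`tag(text)` contract.

## Corpus filters

Account level: exclude accounts that posted nothing in the observed window,
that post more than 20 times per day (rate = posts / span in days, span
floored at one day), whose profile announces a move to another account, or
whose profile contains a hyperlink.  Each exclusion carries exactly one
(first-matching) reason.  An account's main language is the first target
language (in configured priority order) detected in any of its five most
recent posts; detection defaults to Unicode-script heuristics (Hangul → ko,
kana/CJK → ja, Latin → en) and is pluggable.

Post level: e-mail addresses, URLs and foreign-script spans are removed and
whitespace collapsed (`clean_post` is idempotent); a minimum word count can
then be applied (10 in the community-forum setting; a 10-word post is kept,
9 dropped; word = whitespace token).

## Class rebalancing

Random under-sampling discards majority rows (without replacement) down to
the minority count.  SMOTE generates synthetic minority rows directly in
the padded token-index space: `a + λ(b − a)`, λ ~ U(0,1), `b` one of `a`'s
k = 5 nearest minority neighbours, rounded to the nearest valid index.
Interpolating index vectors is deliberately faithful to applying SMOTE to
token sequences, and it reproduces a real pathology: begin/end boundary
markers ([CLS]/[SEP]-style) sitting at different positions in `a` and `b`
are averaged away or duplicated, so a transformer-style consumer sees
malformed sequences and can collapse to predicting a single class (the
degenerate accuracy 0.5 / recall 1.0 / F1 0.6667 pattern on balanced data).
`guard_special_tokens` copies every position where either parent holds a
pad or boundary index verbatim from `a`, which preserves each row's marker
multiset exactly; with the guard off the corruption is observable on any
fixture with heterogeneous marker positions.

**Resampling happens before the train/validation/test split by default.**
This is the protocol under which balanced resampling yields the familiar
near-ceiling scores for both classes, because the evaluation set is itself
balanced (and, for SMOTE, contains synthetic rows — a form of leakage).
The alternative `sampling_stage="train_only"` keeps the evaluation set at
the raw class ratio and is the right choice when an unbiased deployment
estimate is wanted; note that an under-sampled model evaluated on a 99:1
test set has near-zero minority precision, so its minority F1 is *lower*
than an unresampled model's — the two protocols answer different questions.

## Classifiers

All three families run on a small numpy reverse-mode autodiff engine
(`deplex.nn`); training is deterministic given the config seed.

* **cnn** — embedding (dim 128, rows for pad/unknown initialized to zero so
  reserved tokens carry no arbitrary signal) → 1-D convolution, 128 filters
  of width 4 → dropout → max-over-time pooling (one value per filter;
  output size 128) → fully connected 128→64 (ReLU) → 64→1 → sigmoid.
  Binary cross-entropy, Adam.
* **bilstm** — same embedding → bidirectional LSTM, 64 units per direction,
  final states concatenated (128) → the same two fully connected layers and
  sigmoid.  Binary cross-entropy, Adam.
* **transformer_head** — any sentence encoder producing 768-d pooled
  features, feeding one fully connected layer (768→2) with softmax.
  Cross-entropy, AdamW.  The shipped default encoder is a tiny *frozen
  random-projection* encoder (synthetic; it carries no pretrained
  knowledge) so the head trains at desk scale; pretrained per-language
  transformers plug in behind the same callable contract.

Embeddings are optionally initialized from skip-gram word2vec with negative
sampling trained on the training corpus (dim 128, window 5, min count 1,
5 negatives; per-token-averaged minibatch gradients keep tiny vocabularies
stable; a seeded random fallback is used when the corpus yields no pairs).

Defaults left open by the setting and fixed here: dropout 0.5, fully
connected widths 64→1, learning rate 1e-3 (Adam) / 2e-5 (AdamW), batch 32,
10 epochs, max sequence length 64, decision threshold 0.5 with the boundary
counted positive.  All are exposed in `ModelConfig`.

## Evaluation

Reports contain one accuracy per run and per-class precision / recall / F1
for both classes, with the 0/0 convention equal to 0 (so a degenerate
constant predictor prints 0.0000 rows for the dead class).  Cross-domain
evaluation encodes the target corpus with the *source* model's frozen
vocabulary, mapping out-of-vocabulary tokens to the unknown index, so the
in-domain and cross-domain reports are directly comparable.

## Synthetic corpora

`synthetic.generate_corpus` emulates a microblog crawl with the statistical
structure the pipeline assumes; it does **not** emulate natural language:

* post lengths ~ negative binomial, default mean 8 tokens, dispersion 1.2
  (short-post regime; means of 3–13 words are typical of the motivating
  platforms);
* a post is "depressed" with probability `depression_rate` (default 0.05:
  heavy imbalance), in which case exactly one lexicon term is injected at a
  random position — the injection indicator *is* the ground-truth label, so
  weak labeling is the generative rule and oracle checks are exact;
* depressed posts additionally draw a fraction (`context_strength` = 0.3)
  of their background tokens from a depression-context sub-vocabulary
  (`context_fraction` = 0.1 of background types), modeling the non-keyword
  contextual signal that real depressive posts carry and that does not
  transfer across platforms;
* noise artifacts (URLs, e-mail addresses, off-script spans) are injected
  at configurable rates and disappear under `clean_post`;
* accounts include empty ones, one-day burst posters (> 20 posts/day),
  "moved to" and hyperlink descriptions, so every account filter fires.

Because vocabulary items are abstract noun-like strings, passing tests
demonstrate the pipeline's mechanics (filtering, matching, rebalancing,
optimization, evaluation) — not robustness to real morphology, spelling
variation, sarcasm or lexical ambiguity (e.g. "isolation"), which remain
open problems for lexicon-based labeling.

## Experiment harnesses

`experiments.imbalance_comparison` trains the CNN on a 1%-minority corpus
(n = 4000) with and without under-sampling and reports the depression-class
F1 of both runs under the before-split protocol; under-sampling wins
because its evaluation set is balanced while the unresampled run faces the
raw 99:1 ratio.

`experiments.domain_shift_comparison` trains on one corpus (n = 4000,
balanced) and evaluates on a fresh 12,000-post corpus from the same
generator, once unchanged and once with 50% of background vocabulary types
replaced by unseen tokens (lexicon terms and labels preserved).  The
harness uses a 12-token encoder window — deliberately shorter than the
longest posts — so that part of the label evidence lies beyond the window
and the classifier must also rely on contextual vocabulary; that reliance
is exactly what the vocabulary shift removes, producing a systematic
in-domain > cross-domain gap.  The two evaluations are item-matched and
large so the gap is resolved well above per-item noise.

Problem sizes throughout (2–6k posts, vocabulary 500, 10 epochs) are chosen
so the full suite runs in minutes on one CPU while every compared effect is
resolved clearly; they are not the scale of a platform crawl.

## Numerical and degenerate-input choices

* Resampling requires both classes; single-class inputs raise.
* SMOTE requires minority count > k; the error message says which knob to
  turn.
* When the two classes are equally frequent, the stable convention treats
  the first label value as "minority".
* Metric ratios define 0/0 = 0.
* Probability 0.5 maps to the positive label.
* Empty lexicons after filtering and empty cleaned posts are legal (logged,
  never fatal).
* All randomness flows from explicit seeds; pipeline stages derive their
  seeds from the run's global seed as `(seed * 1000003 + stage_index) mod
  2^31`.

## Known limitations

* Weak labels inherit every blind spot of the lexicon: negated mentions,
  quoted speech, and ambiguous lexemes are labeled positive.
* The rule taggers are heuristics; tagging quality bounds matching quality
  for real text.
* The shipped transformer encoder is a random projection; conclusions about
  real pretrained encoders only carry over at the interface level (e.g. the
  special-token guard), not at the representation level.
* The before-split resampling protocol leaks information into the
  evaluation set by construction; use `train_only` for deployment
  estimates.
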