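# deplex

Lexicon-based weak labeling and depression-post classification for short
social-media text.

Large-scale mental-health studies on platforms like Twitter cannot hand-label
millions of posts.  A practical alternative is *weak supervision*: a post is
labeled **depression** when, after part-of-speech filtering, it contains at
least one keyword from an expert-verified depression lexicon, and
**non-depression** otherwise.  `deplex` packages that whole workflow — for
researchers in health informatics and computational social science — as a
tested, offline-runnable pipeline:

1. **corpus** — account eligibility filters (no posts, > 20 posts/day,
   "moved to" or hyperlink profile descriptions), main-language assignment
   from the five most recent posts, and post cleaning (e-mail/URL/off-script
   removal, minimum word count);
2. **lexicon** — per-language keyword lists with rater relevance scores on a
   5-point scale; entries with mean score < 3 are excluded, the rest are
   POS-normalized;
3. **labeling** — POS-filtered contiguous matching that yields the binary
   weak label;
4. **sampling** — random under-sampling and SMOTE on token-index vectors,
   with a guard for the special-token corruption that naive SMOTE inflicts
   on [CLS]/[SEP]-style boundary markers;
5. **models** — 1-D CNN (128 filters of width 4 over 128-d word2vec-initialized
   embeddings, max-over-time pooling, two dense layers, sigmoid), BiLSTM
   (64 units per direction), and a pluggable 768-d transformer-head, on a
   small self-contained numpy autodiff engine;
6. **evaluation** — accuracy plus per-class precision/recall/F1
   (positive class `p = tp/(tp+fp)`, `r = tp/(tp+fn)`, `F1 = 2pr/(p+r)`,
   0/0 := 0) and a cross-domain harness that encodes a second platform's
   posts with the source model's frozen vocabulary;
7. **synthetic** — a seeded corpus generator (negative-binomial post
   lengths, controllable class imbalance, lexicon-term injection as the
   ground-truth rule, URL/e-mail/off-script noise, filter-tripping
   accounts) so everything runs with no external data or downloads.

See `docs/methods.md` for the full model description and design rationale.

## Worked example

Generate a synthetic corpus whose lexicon file and ground truth are written
alongside it, clean it, weak-label it, and train the CNN with an
under-sampled training split:

```bash
deplex synth --n-posts 2000 --depression-rate 0.3 --seed 7 \
       --out corpus.jsonl --lexicon lex.tsv --truth truth.tsv
deplex filter --corpus corpus.jsonl --out kept.jsonl --report report.tsv
deplex label  --corpus kept.jsonl --lexicon lex.tsv --lang en --out labels.tsv
deplex train  --corpus kept.jsonl --labels labels.tsv --model cnn \
       --sampling under --max-len 24 --epochs 5 --seed 7 --no-word2vec \
       --out model.npz
```

which prints

```
wrote 2000 posts to corpus.jsonl
kept 2000/2000 posts
class counts (non-depression, depression): (1427, 573)
Label             Accuracy  Precision   Recall  F1-score
non-depression      0.9800     1.0000   0.9718    0.9857
depression                     0.9355   1.0000    0.9667
```

The label stage reports the weak-label class counts (here ~29% depression,
matching the 0.3 injection rate).  The final table is the held-out test
report in the standard two-row layout: one accuracy for the run and
precision/recall/F1 per class — the trained CNN recovers the lexicon
labeling rule almost perfectly (depression-class F1 0.9667; recall 1.0
means no depression post in the test split was missed, precision 0.9355
means a few clean posts were over-flagged).

The same stages are callable as a library (`deplex.synthetic`,
`deplex.corpus`, `deplex.labeling`, `deplex.sampling`, `deplex.models`,
`deplex.evaluation`), and `deplex run --config run.yaml` executes the whole
pipeline from one YAML file into a run directory with labels, model,
reports and a manifest of seeds and per-stage counts.

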