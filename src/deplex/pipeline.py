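"""End-to-end orchestration: filter → label → split → sample → train → evaluate.

One YAML run configuration drives every stage; all randomness flows from the
single global seed through a documented derivation (stage_seed =
(seed * 1000003 + stage_index) mod 2^31), and a manifest records versions,
seeds and per-stage counts.  Stages write their artifacts into the run
directory and are individually resumable: with ``resume=True`` a stage whose
artifact already exists is reloaded instead of recomputed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import yaml

from . import __version__
from .corpus import clean_post, filter_min_words, read_posts_jsonl, write_posts_jsonl
from .evaluation import evaluate
from .features import Vocabulary, encode_posts, stratified_split
from .labeling import default_policy, label_corpus, write_labels_tsv
from .lexicon import apply_relevance_filter, load_lexicon, normalize_entries
from .models import (
    ModelConfig,
    build_classifier,
    embedding_matrix,
    load_model,
    save_model,
    train_classifier,
    train_word_embeddings,
)
from .sampling import SamplingConfig, apply_sampling
from .taggers import get_tagger

logger = logging.getLogger(__name__)

_STAGES = ("filter", "label", "split", "sample", "train", "evaluate")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    corpus: str
    lexicon: str
    out_dir: str
    language: str = "en"
    seed: int = 0
    max_rate: float = 20.0
    min_words: int = 0
    relevance_threshold: float = 3.0
    split_fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    # "before_split" resamples the whole labeled dataset and then splits
    # (the protocol under which balanced resampling reports balanced
    # evaluation sets); "train_only" is the leakage-free alternative.
    sampling_stage: str = "before_split"
    sampling: SamplingConfig = field(default_factory=SamplingConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    use_word2vec: bool = True
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        sampling = SamplingConfig(**raw.pop("sampling", {}))
        model_raw = raw.pop("model", {})
        model = ModelConfig.for_family(model_raw.pop("family", "cnn"), **model_raw)
        if "split_fractions" in raw:
            raw["split_fractions"] = tuple(raw["split_fractions"])
        return cls(sampling=sampling, model=model, **raw)


def stage_seed(global_seed: int, stage: str) -> int:
    return (global_seed * 1000003 + _STAGES.index(stage)) % (2**31)


def run_pipeline(config: RunConfig, resume: bool = False) -> Path:
    """Execute all stages; returns the run directory.

    Fails before writing anything when a referenced input is missing; any
    stage failure aborts with the stage name and cause.
    """
    corpus_path, lexicon_path = Path(config.corpus), Path(config.lexicon)
    for p in (corpus_path, lexicon_path):
        if not p.exists():
            raise FileNotFoundError(f"configured input does not exist: {p}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    log_handler = logging.FileHandler(out / "run.log")
    logging.getLogger().addHandler(log_handler)

    manifest: dict = {
        "deplex_version": __version__,
        "numpy_version": np.__version__,
        "seed": config.seed,
        "stage_seeds": {s: stage_seed(config.seed, s) for s in _STAGES},
        "counts": {},
    }
    counts = manifest["counts"]
    try:
        # ---- filter --------------------------------------------------
        kept_path = out / "kept.jsonl"
        posts = read_posts_jsonl(corpus_path)
        counts["posts_in"] = len(posts)
        if resume and kept_path.exists():
            kept = read_posts_jsonl(kept_path)
        else:
            try:
                cleaned = [
                    dataclasses.replace(p, text=clean_post(p.text, p.language))
                    for p in posts
                ]
                kept = filter_min_words(cleaned, config.min_words)
                write_posts_jsonl(kept, kept_path)
            except Exception as e:  # noqa: BLE001
                raise StageError("filter", e) from e
        counts["posts_kept"] = len(kept)
        counts["posts_excluded"] = counts["posts_in"] - len(kept)

        # ---- label ---------------------------------------------------
        labels_path = out / "labels.tsv"
        try:
            lexicon = load_lexicon(lexicon_path, config.language)
            lexicon = apply_relevance_filter(lexicon, config.relevance_threshold)
            policy = default_policy(config.language)
            lexicon = normalize_entries(lexicon, policy)
            labeled, summary = label_corpus(kept, lexicon, policy)
            write_labels_tsv(labeled, labels_path)
        except Exception as e:  # noqa: BLE001
            raise StageError("label", e) from e
        counts["label_counts"] = {
            "non_depression": summary.n_non_depression,
            "depression": summary.n_depression,
        }

        # ---- encode + sample + split --------------------------------
        y = np.array([lp.label for lp in labeled])
        tagger = get_tagger(config.language)
        token_lists = [[tok for tok, _ in tagger.tag(lp.text)] for lp in labeled]
        samp_cfg = dataclasses.replace(config.sampling, seed=stage_seed(config.seed, "sample"))
        split_s = stage_seed(config.seed, "split")
        try:
            if config.sampling_stage == "before_split":
                vocab = Vocabulary.build(token_lists)
                fm = apply_sampling(
                    encode_posts(token_lists, vocab, config.model.max_len, labels=y), samp_cfg
                )
                tr, va, te = stratified_split(fm.y, config.split_fractions, seed=split_s)
                train_fm, val_fm, test_fm = fm.subset(tr), fm.subset(va), fm.subset(te)
                train_tokens = token_lists
            elif config.sampling_stage == "train_only":
                tr, va, te = stratified_split(y, config.split_fractions, seed=split_s)
                vocab = Vocabulary.build([token_lists[i] for i in tr])
                fm = encode_posts(token_lists, vocab, config.model.max_len, labels=y)
                train_fm = apply_sampling(fm.subset(tr), samp_cfg)
                val_fm, test_fm = fm.subset(va), fm.subset(te)
                train_tokens = [token_lists[i] for i in tr]
            else:
                raise ValueError(f"unknown sampling_stage {config.sampling_stage!r}")
        except Exception as e:  # noqa: BLE001
            raise StageError("sample", e) from e
        (out / "splits.json").write_text(
            json.dumps({"train": tr.tolist(), "val": va.tolist(), "test": te.tolist()})
        )
        counts["split_sizes"] = {"train": len(tr), "val": len(va), "test": len(te)}
        counts["train_after_sampling"] = dict(
            zip(("non_depression", "depression"), train_fm.class_counts())
        )

        # ---- train ---------------------------------------------------
        model_path = out / "model.npz"
        try:
            if resume and model_path.exists():
                trained = load_model(model_path)
            else:
                model_cfg = dataclasses.replace(config.model, seed=stage_seed(config.seed, "train"))
                clf = build_classifier(model_cfg, vocab_size=len(vocab))
                if config.use_word2vec and model_cfg.family in ("cnn", "bilstm"):
                    w2v = train_word_embeddings(
                        train_tokens,
                        dim=model_cfg.embed_dim,
                        seed=stage_seed(config.seed, "train"),
                    )
                    clf.set_embeddings(
                        embedding_matrix(w2v, vocab, model_cfg.embed_dim, seed=model_cfg.seed)
                    )
                trained = train_classifier(clf, train_fm, val_fm, model_cfg, vocabulary=vocab)
                save_model(trained, model_path)
        except Exception as e:  # noqa: BLE001
            raise StageError("train", e) from e

        # ---- evaluate ------------------------------------------------
        try:
            report = evaluate(trained, test_fm)
        except Exception as e:  # noqa: BLE001
            raise StageError("evaluate", e) from e
        report.to_json(out / "report.json")
        (out / "report.txt").write_text(report.to_table() + "\n")
        counts["test_accuracy"] = report.accuracy

        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return out
    finally:
        logging.getLogger().removeHandler(log_handler)
        log_handler.close()
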