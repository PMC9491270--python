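"""deplex — lexicon-based weak labeling and depression-post classification.

A reusable pipeline for short social-media text: corpus eligibility
filtering and cleaning, POS-filtered depression-lexicon weak labeling,
class rebalancing (random under-sampling / SMOTE with a special-token
guard), CNN / BiLSTM / transformer-head classifiers, per-class evaluation,
and a synthetic corpus generator so the whole pipeline runs offline.
"""

__version__ = "0.1.0"

from .evaluation import confusion_counts, evaluate, precision_recall_f1
from .labeling import label_corpus, label_post
from .lexicon import apply_relevance_filter, load_lexicon, normalize_entries
from .sampling import SamplingConfig, apply_sampling, smote, undersample
from .synthetic import SyntheticCorpusSpec, generate_corpus, generate_vocab

__all__ = [
    "__version__",
    "load_lexicon",
    "apply_relevance_filter",
    "normalize_entries",
    "label_post",
    "label_corpus",
    "undersample",
    "smote",
    "apply_sampling",
    "SamplingConfig",
    "confusion_counts",
    "precision_recall_f1",
    "evaluate",
    "SyntheticCorpusSpec",
    "generate_vocab",
    "generate_corpus",
]
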