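"""Sentence triage: one balanced binary classifier per character.

Each sentence of a description may mention zero, one, or several
characters ("Cells are 0.3–0.5 μm wide and 8.0–15.0 μm long" mentions
both Cell Width and Cell Length).  A bank of independent binary
classifiers — one linear max-margin model (SVM) per character — votes on
every sentence, and the sentence is passed to the extractors of every
character whose model fires.

Training sentences labeled with a character are its positives; the same
number of negatives is drawn uniformly (seeded, without replacement)
from the sentences not labeled with that character, keeping the classes
balanced because margin classifiers are sensitive to class imbalance.
Features are lower-cased word unigrams and bigrams with numerals mapped
to a ``NUM`` placeholder (so "0.3–0.5 μm" and "1.2 μm" share the feature
"NUM μm"); the vocabulary is built on the training split only.

Everything is deterministic given (instances, seed): identical seeds
reproduce identical negative samples, models and predictions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.feature_extraction.text import CountVectorizer
from sklearn.svm import LinearSVC

from .characters import CHARACTER_IDS
from .corpus_io import TrainingInstance
from .preprocess import AnnotatedSentence, FallbackParser, NUMERIC_TOKEN

logger = logging.getLogger(__name__)

_tokenizer = FallbackParser()


def _feature_tokens(text: str) -> list[str]:
    toks = []
    for t in _tokenizer.tokenize(text):
        if NUMERIC_TOKEN.match(t):
            toks.append("NUM")
        elif any(ch.isalnum() for ch in t):
            toks.append(t.lower())
    return toks


def analyze(text: str) -> list[str]:
    """Unigram + bigram features with the NUM placeholder."""
    toks = _feature_tokens(text)
    return toks + [f"{a} {b}" for a, b in zip(toks, toks[1:])]


class Featurizer:
    """Binary bag of word n-grams; vocabulary fixed at fit time."""

    spec = "unigram+bigram, lowercase, NUM placeholder, binary counts"

    def __init__(self) -> None:
        self._vec = CountVectorizer(analyzer=analyze, binary=True)

    def fit(self, texts: list[str]) -> "Featurizer":
        self._vec.fit(texts)
        return self

    def transform(self, texts: list[str]):
        return self._vec.transform(texts)

    @property
    def vocabulary(self) -> dict[str, int]:
        return self._vec.vocabulary_


@dataclass
class BalancedTrainingSet:
    """Positives and an equally sized seeded negative sample."""

    character_id: str
    positives: list[str]
    negatives: list[str]
    seed: int


@dataclass
class ClassifierBank:
    """One trained binary decision function per character."""

    models: dict[str, tuple[Featurizer, LinearSVC]]
    featurizer_spec: str
    training_seed: int

    def character_ids(self) -> list[str]:
        return sorted(self.models)


@dataclass(frozen=True)
class CVReport:
    character_id: str
    folds: int
    precision: float
    recall: float


def build_balanced_training_sets(
    instances: list[TrainingInstance], seed: int
) -> dict[str, BalancedTrainingSet]:
    """Per character: all positives, and as many negatives sampled
    uniformly without replacement from sentences not carrying that label."""
    if not instances:
        raise ValueError("no training instances")
    by_char: dict[str, list[str]] = {}
    labels_of: dict[str, set[str]] = {}
    order: list[str] = []
    for inst in instances:
        by_char.setdefault(inst.character_id, []).append(inst.sentence_text)
        labels_of.setdefault(inst.sentence_text, set()).add(inst.character_id)
    all_texts = sorted(labels_of)
    out: dict[str, BalancedTrainingSet] = {}
    for idx, cid in enumerate(CHARACTER_IDS):
        positives = by_char.get(cid, [])
        if not positives:
            continue
        pool = [t for t in all_texts if cid not in labels_of[t]]
        n = len(positives)
        rng = np.random.default_rng([seed % (2**31), idx])
        if len(pool) < n:
            logger.warning(
                "character %s: only %d negatives available for %d positives",
                cid, len(pool), n,
            )
            negatives = list(pool)
        else:
            negatives = [pool[i] for i in sorted(
                rng.choice(len(pool), size=n, replace=False)
            )]
        out[cid] = BalancedTrainingSet(cid, list(positives), negatives, seed)
    missing = {i.character_id for i in instances} - set(out)
    for cid in sorted(missing):
        logger.warning("character %s excluded: no positive examples", cid)
    return out


def train_classifiers(
    sets: dict[str, BalancedTrainingSet], seed: int = 0
) -> ClassifierBank:
    """Fit one linear max-margin model (C=1) per non-degenerate set."""
    models: dict[str, tuple[Featurizer, LinearSVC]] = {}
    for cid, ts in sets.items():
        if not ts.positives or not ts.negatives:
            logger.warning("character %s skipped: degenerate training set", cid)
            continue
        texts = ts.positives + ts.negatives
        y = np.array([1] * len(ts.positives) + [0] * len(ts.negatives))
        fz = Featurizer().fit(texts)
        clf = LinearSVC(C=1.0, random_state=seed % (2**31))
        clf.fit(fz.transform(texts), y)
        models[cid] = (fz, clf)
    return ClassifierBank(models, Featurizer.spec, seed)


def predict_characters(
    bank: ClassifierBank, sentence: AnnotatedSentence | str
) -> set[str]:
    """Character ids whose model votes positive; may be empty or plural."""
    text = sentence.text if isinstance(sentence, AnnotatedSentence) else sentence
    out = set()
    for cid, (fz, clf) in bank.models.items():
        if clf.predict(fz.transform([text]))[0] == 1:
            out.add(cid)
    return out


def cross_validate(
    instances: list[TrainingInstance], k: int = 10, seed: int = 0
) -> list[CVReport]:
    """k-fold cross-validation over unique sentences.

    Folds are formed on shuffled unique sentences (a sentence and all
    its labels stay in one fold); balanced negative sampling is redone
    inside each training fold.  Characters with fewer than ``k``
    positives are skipped with a warning.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    labels_of: dict[str, set[str]] = {}
    for inst in instances:
        labels_of.setdefault(inst.sentence_text, set()).add(inst.character_id)
    texts = sorted(labels_of)
    if k > len(texts):
        raise ValueError(f"k={k} exceeds the {len(texts)} unique sentences")
    rng = np.random.default_rng(seed % (2**31))
    order = list(rng.permutation(len(texts)))
    folds = [order[i::k] for i in range(k)]

    pos_count: dict[str, int] = {}
    for labels in labels_of.values():
        for cid in labels:
            pos_count[cid] = pos_count.get(cid, 0) + 1
    eligible = {cid for cid, n in pos_count.items() if n >= k}
    for cid in sorted(set(pos_count) - eligible):
        logger.warning("character %s skipped in CV: fewer than %d positives",
                       cid, k)

    tp: dict[str, int] = {c: 0 for c in eligible}
    fp: dict[str, int] = {c: 0 for c in eligible}
    fn: dict[str, int] = {c: 0 for c in eligible}
    for fold_idx, test_ids in enumerate(folds):
        test_texts = {texts[i] for i in test_ids}
        train_insts = [
            TrainingInstance(t, cid)
            for t in texts if t not in test_texts
            for cid in sorted(labels_of[t])
        ]
        bank = train_classifiers(
            build_balanced_training_sets(train_insts, seed + fold_idx + 1),
            seed,
        )
        for t in sorted(test_texts):
            predicted = predict_characters(bank, t) & eligible
            true = labels_of[t] & eligible
            for cid in predicted & true:
                tp[cid] += 1
            for cid in predicted - true:
                fp[cid] += 1
            for cid in true - predicted:
                fn[cid] += 1

    reports = []
    for cid in sorted(eligible):
        p = tp[cid] / (tp[cid] + fp[cid]) if tp[cid] + fp[cid] else 1.0
        r = tp[cid] / (tp[cid] + fn[cid]) if tp[cid] + fn[cid] else 1.0
        reports.append(CVReport(cid, k, p, r))
    return reports


def macro_average(reports: list[CVReport]) -> tuple[float, float]:
    """Macro precision and recall over per-character reports."""
    if not reports:
        return 0.0, 0.0
    return (
        float(np.mean([r.precision for r in reports])),
        float(np.mean([r.recall for r in reports])),
    )
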