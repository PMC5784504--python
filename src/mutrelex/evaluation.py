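"""Metrics, validation protocols, the no-learning baseline, relation-table
export and gold-list comparison.

Two protocols mirror the two classifier families: balanced k-fold
cross-validation for the feature-based document-level models (see
``docclassifier``) and repeated random sub-sampling for the sentence-level
network, which is too slow to re-train ten times per configuration — each
repetition draws a balanced held-out test set, balances the remaining
training data, and trains a fresh model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .corpus import Corpus

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MetricReport:
    precision: float
    recall: float
    f1: float
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    @staticmethod
    def mean(reports: Sequence["MetricReport"]) -> "MetricReport":
        return MetricReport(
            precision=float(np.mean([r.precision for r in reports])),
            recall=float(np.mean([r.recall for r in reports])),
            f1=float(np.mean([r.f1 for r in reports])),
            tp=sum(r.tp for r in reports),
            fp=sum(r.fp for r in reports),
            fn=sum(r.fn for r in reports),
            tn=sum(r.tn for r in reports),
        )


def prf(tp: int, fp: int, fn: int, tn: int = 0) -> MetricReport:
    """Precision / recall / F1 from a confusion matrix.

    Zero-division cases return 0 (not NaN) so that fold averaging is total.
    """
    if min(tp, fp, fn, tn) < 0:
        raise ValueError("confusion-matrix counts must be non-negative")
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    if precision + recall > 0:
        f1 = 2 * precision * recall / (precision + recall)
    else:
        f1 = 0.0
        logger.debug("zero precision+recall; F1 reported as 0")
    return MetricReport(precision, recall, f1, tp, fp, fn, tn)


def prf_from_predictions(truth: np.ndarray, predicted: np.ndarray) -> MetricReport:
    truth = np.asarray(truth, dtype=bool)
    predicted = np.asarray(predicted, dtype=bool)
    tp = int(np.sum(truth & predicted))
    fp = int(np.sum(~truth & predicted))
    fn = int(np.sum(truth & ~predicted))
    tn = int(np.sum(~truth & ~predicted))
    return prf(tp, fp, fn, tn)


# ---------------------------------------------------------------------------
# Repeated random sub-sampling validation


def subsampling_validation(
    positives: Sequence,
    negatives: Sequence,
    trainer: Callable[[Sequence, Sequence, int], Callable[[Sequence], np.ndarray]],
    repetitions: int = 5,
    test_pos: int = 100,
    test_neg: int = 100,
    seed: int = 0,
) -> tuple[MetricReport, list[MetricReport]]:
    """Repeated random sub-sampling: per repetition draw a balanced test set,
    balance the remaining training data, train fresh, and score held-out.

    ``trainer(train_pos, train_neg, rep_seed)`` must return a predictor
    mapping a list of examples to a boolean array.  Test draws are
    independent across repetitions.  Deterministic for a fixed seed.
    """
    if len(positives) <= test_pos or len(negatives) <= test_neg:
        raise ValueError(
            f"need more than {test_pos} positives and {test_neg} negatives, "
            f"have {len(positives)} / {len(negatives)}"
        )
    rng = np.random.default_rng(seed)
    reports: list[MetricReport] = []
    for rep in range(repetitions):
        test_p = rng.choice(len(positives), size=test_pos, replace=False)
        test_n = rng.choice(len(negatives), size=test_neg, replace=False)
        train_p = [positives[i] for i in range(len(positives)) if i not in set(test_p)]
        train_n = [negatives[i] for i in range(len(negatives)) if i not in set(test_n)]
        n_train = min(len(train_p), len(train_n))
        train_p = [train_p[i] for i in rng.choice(len(train_p), size=n_train, replace=False)]
        train_n = [train_n[i] for i in rng.choice(len(train_n), size=n_train, replace=False)]
        rep_seed = int(rng.integers(0, 2**31 - 1))
        predictor = trainer(train_p, train_n, rep_seed)
        test = [positives[i] for i in test_p] + [negatives[i] for i in test_n]
        truth = np.array([True] * test_pos + [False] * test_neg)
        reports.append(prf_from_predictions(truth, predictor(test)))
    return MetricReport.mean(reports), reports


# ---------------------------------------------------------------------------
# No-learning co-occurrence baseline


def cooccurrence_baseline(candidates: Sequence) -> np.ndarray:
    """Classify every candidate positive: candidates exist exactly because
    the entities co-occur, so this is the all-positive no-learning floor
    (recall 1 by construction; F1 = 2/3 on balanced sets)."""
    return np.ones(len(candidates), dtype=bool)


# ---------------------------------------------------------------------------
# Relation-table export and gold-list comparison


@dataclass(frozen=True)
class ExportRow:
    doc_id: str
    sentence_index: int
    mutation: str
    partner: str
    partner_kind: str
    probability: float
    sentence: str


def export_relation_table(
    examples: Sequence,
    probabilities: np.ndarray,
    threshold: float = 0.5,
    deduplicate: bool = False,
) -> list[ExportRow]:
    """Rows for predicted-positive sentence pairs, sorted by descending
    probability; optional dedup keeps the best row per (doc, mutation,
    partner) triple."""
    rows = [
        ExportRow(ex.doc_id, ex.sentence_index, ex.mutation, ex.partner,
                  ex.partner_mention.kind, float(p), ex.text)
        for ex, p in zip(examples, probabilities)
        if p >= threshold
    ]
    rows.sort(key=lambda r: (-r.probability, r.doc_id, r.sentence_index, r.mutation, r.partner))
    if deduplicate:
        seen: set[tuple[str, str, str]] = set()
        unique = []
        for r in rows:
            key = (r.doc_id, r.mutation, r.partner)
            if key not in seen:
                seen.add(key)
                unique.append(r)
        rows = unique
    return rows


def write_export_table(rows: Sequence[ExportRow], stream) -> None:
    stream.write("doc_id\tsentence_index\tmutation\tpartner\tpartner_kind\tprobability\tsentence\n")
    for r in rows:
        stream.write(
            f"{r.doc_id}\t{r.sentence_index}\t{r.mutation}\t{r.partner}\t"
            f"{r.partner_kind}\t{r.probability:.6f}\t{r.sentence}\n"
        )


def compare_to_gold_list(
    extracted: Iterable[tuple[str, str]],
    gold: Iterable[tuple[str, str]],
    corpus: Corpus,
) -> dict[str, list[tuple[str, str]]]:
    """Partition a gold pair list against extracted pairs and the corpus.

    Buckets: ``found`` (extracted), ``missed_no_cooccurrence`` (the pair never
    shares a sentence anywhere in the corpus, so no sentence-level extractor
    could have found it), and ``missed_other``.
    """
    extracted_set = set(extracted)
    cooccurring: set[tuple[str, str]] = set()
    for doc in corpus:
        for idx, _, _ in doc.sentences:
            mentions = doc.mentions_in_sentence(idx)
            muts = {m.normalized for m in mentions if m.kind == "mutation"}
            partners = {m.normalized for m in mentions if m.kind != "mutation"}
            cooccurring |= {(m, p) for m in muts for p in partners}
    buckets: dict[str, list[tuple[str, str]]] = {
        "found": [], "missed_no_cooccurrence": [], "missed_other": [],
    }
    for pair in sorted(set(gold)):
        if pair in extracted_set:
            buckets["found"].append(pair)
        elif pair not in cooccurring:
            buckets["missed_no_cooccurrence"].append(pair)
        else:
            buckets["missed_other"].append(pair)
    return buckets


# ---------------------------------------------------------------------------
# Feature ablation harness


def feature_ablation(
    features,
    model_kind: str,
    feature_subsets: Mapping[str, Sequence[str]],
    folds: int = 10,
    seed: int = 0,
) -> dict[str, MetricReport]:
    """One balanced-CV run per named feature subset under identical seeds,
    so rows differ only in the features the model may see."""
    from .docclassifier import cross_validate

    table: dict[str, MetricReport] = {}
    for name, subset in feature_subsets.items():
        mean, _ = cross_validate(features, model_kind, folds=folds, seed=seed,
                                 feature_subset=subset)
        table[name] = mean
    return table
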