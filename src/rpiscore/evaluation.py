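"""Performance measures and cross-validation.

Discriminative power (DP) counts ordered comparisons between interactive
and non-interactive scores, with ties contributing to BOTH directions
(theta(0) = 1), which makes an all-tied score set evaluate to exactly 0.5.
Note this differs from the rank-based AUC convention, which counts a tie
once with weight 1/2. MCC follows the usual 2x2 formula with the
zero-denominator convention MCC = 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .discriminant import DEFAULT_RIDGE, DEFAULT_THRESHOLD, train
from .errors import DomainError
from .seq_io import INTERACTIVE, LabeledPair, ProteinSequence, RnaSequence


def discriminative_power(
    pos_scores: Sequence[float], neg_scores: Sequence[float]
) -> float:
    """Fraction of ordered (interactive, non-interactive) comparisons won.

    DP = sum theta(pi - pn) / (sum theta(pi - pn) + sum theta(pn - pi))
    with theta(x) = 1 for x >= 0 and 0 otherwise; equals 1 when every
    interactive score strictly exceeds every non-interactive score and 0 in
    the fully inverted case.
    """
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise DomainError("both score lists must be nonempty")
    diff = pos[:, None] - neg[None, :]
    forward = int(np.count_nonzero(diff >= 0))
    backward = int(np.count_nonzero(diff <= 0))
    return forward / (forward + backward)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise DomainError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(truth: Sequence[str], predicted: Sequence[str]) -> ConfusionCounts:
    """2x2 cross-tabulation with ``interactive`` as the positive label."""
    if len(truth) != len(predicted):
        raise DomainError(
            f"length mismatch: {len(truth)} truth vs {len(predicted)} predicted"
        )
    tp = fp = tn = fn = 0
    for t, p in zip(truth, predicted):
        t_pos = t == INTERACTIVE
        p_pos = p == INTERACTIVE
        if t_pos and p_pos:
            tp += 1
        elif not t_pos and p_pos:
            fp += 1
        elif not t_pos and not p_pos:
            tn += 1
        else:
            fn += 1
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def matthews(counts: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 if any denominator factor is 0."""
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    denom_sq = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom_sq == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom_sq)


def accuracy(counts: ConfusionCounts) -> float:
    if counts.total == 0:
        raise DomainError("accuracy is undefined for zero evaluated pairs")
    return (counts.tp + counts.tn) / counts.total


@dataclass
class EvaluationResult:
    """DP, MCC and accuracy over a scored labeled pair set."""

    dp: float
    mcc: float
    accuracy: float
    counts: ConfusionCounts
    fold_dp: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0.0 <= self.dp <= 1.0:
            raise DomainError(f"DP out of [0, 1]: {self.dp}")
        if not -1.0 <= self.mcc <= 1.0:
            raise DomainError(f"MCC out of [-1, 1]: {self.mcc}")


def evaluate_scores(
    labels: Sequence[str], scores: Sequence[float], threshold: float = DEFAULT_THRESHOLD
) -> EvaluationResult:
    """Compute DP/MCC/accuracy for final scores against truth labels."""
    if len(labels) != len(scores):
        raise DomainError("labels and scores must align")
    pos = [s for l, s in zip(labels, scores) if l == INTERACTIVE]
    neg = [s for l, s in zip(labels, scores) if l != INTERACTIVE]
    predicted = [
        INTERACTIVE if s > threshold else "non-interactive" for s in scores
    ]
    counts = confusion(labels, predicted)
    return EvaluationResult(
        dp=discriminative_power(pos, neg),
        mcc=matthews(counts),
        accuracy=accuracy(counts),
        counts=counts,
    )


def stratified_folds(
    pairs: Sequence[LabeledPair], k: int, seed: int
) -> list[list[int]]:
    """Seeded label-stratified fold assignment (indices into ``pairs``)."""
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    for positive in (True, False):
        idx = [i for i, p in enumerate(pairs) if p.is_interactive == positive]
        if len(idx) < k:
            raise DomainError(
                f"{'interactive' if positive else 'non-interactive'} class has "
                f"{len(idx)} members; need >= {k} for {k}-fold CV"
            )
        idx = list(rng.permutation(idx))
        for j, i in enumerate(idx):
            folds[j % k].append(int(i))
    return folds


def cross_validate(
    pairs: Sequence[LabeledPair],
    rnas: Mapping[str, RnaSequence],
    proteins: Mapping[str, ProteinSequence],
    encoder,
    k: int = 4,
    seed: int = 0,
    ridge: float = DEFAULT_RIDGE,
    threshold: float = DEFAULT_THRESHOLD,
) -> EvaluationResult:
    """Stratified k-fold CV: mean held-out DP plus pooled MCC/accuracy.

    Each fold's model is trained on the other k-1 folds and scores the
    held-out fold; the reported DP is the mean of per-fold DP values and
    the confusion counts pool every held-out prediction at ``threshold``.
    """
    folds = stratified_folds(pairs, k=k, seed=seed)
    fold_dp: list[float] = []
    all_labels: list[str] = []
    all_scores: list[float] = []
    for held_out in folds:
        held_set = set(held_out)
        train_pairs = [p for i, p in enumerate(pairs) if i not in held_set]
        model = train(
            train_pairs, rnas, proteins, encoder, ridge=ridge, threshold=threshold
        )
        pos_scores, neg_scores = [], []
        for i in held_out:
            pair = pairs[i]
            report = model.score_features(
                pair.rna_id,
                pair.protein_id,
                encoder.encode_rna(rnas[pair.rna_id]),
                encoder.encode_protein(proteins[pair.protein_id]),
            )
            (pos_scores if pair.is_interactive else neg_scores).append(report.final)
            all_labels.append(pair.label)
            all_scores.append(report.final)
        fold_dp.append(discriminative_power(pos_scores, neg_scores))
    pooled = evaluate_scores(all_labels, all_scores, threshold=threshold)
    return EvaluationResult(
        dp=float(np.mean(fold_dp)),
        mcc=pooled.mcc,
        accuracy=pooled.accuracy,
        counts=pooled.counts,
        fold_dp=fold_dp,
    )
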