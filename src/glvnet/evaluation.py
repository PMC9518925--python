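"""Scoring inferred correlation networks against the true interaction matrix.

A correlation matrix is symmetric while the interaction matrix A is not, so
pairs are scored on unordered (lower-triangle) species pairs. Each pair has
an ecological type from the signs of (alpha_ij, alpha_ji): mutualism (+,+),
competition (-,-), commensalism (+,0 / 0,+), amensalism (-,0 / 0,-),
exploitation (+,- / -,+), or no interaction (0,0).

Three matching rules translate a significant partial correlation into a
confusion-matrix cell:

* ``either_sign`` — a significant correlation is a true positive when its
  sign matches either of the pair's nonzero interaction signs (the default;
  note it credits both signs on exploitative pairs, an acknowledged bias).
* ``strongest_sign`` — the intended sign is that of the larger |alpha|; a
  significant correlation of the other sign is a false positive. A tie with
  opposite signs accepts either.
* ``strict_both`` — both interaction signs must be reflected: only mutualism
  and competition can be recovered; a significant correlation on an
  asymmetric interacting pair is a false positive.

Non-significant pairs are false negatives when an interaction exists and true
negatives otherwise, under every rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .inference import PartialCorrelationResult
from .networks import InteractionMatrix

__all__ = [
    "MatchingRule",
    "PairInteractionType",
    "ConfusionCounts",
    "pair_type",
    "classify_pair",
    "confusion_counts",
    "precision_recall_f1",
    "detection_rate_by_type",
]

MATCHING_RULES = ("either_sign", "strongest_sign", "strict_both")


class MatchingRule(str, Enum):
    EITHER_SIGN = "either_sign"
    STRONGEST_SIGN = "strongest_sign"
    STRICT_BOTH = "strict_both"


class PairInteractionType(str, Enum):
    NONE = "none"
    MUTUALISM = "mutualism"
    COMPETITION = "competition"
    COMMENSALISM = "commensalism"
    AMENSALISM = "amensalism"
    EXPLOITATIVE = "exploitative"


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int
    rule: str

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def pair_type(a_ij: float, a_ji: float) -> PairInteractionType:
    """Ecological type of an unordered pair from its two coefficient signs."""
    s1, s2 = np.sign(a_ij), np.sign(a_ji)
    if s1 == 0 and s2 == 0:
        return PairInteractionType.NONE
    if s1 > 0 and s2 > 0:
        return PairInteractionType.MUTUALISM
    if s1 < 0 and s2 < 0:
        return PairInteractionType.COMPETITION
    if s1 * s2 < 0:
        return PairInteractionType.EXPLOITATIVE
    # exactly one side zero
    return (
        PairInteractionType.COMMENSALISM
        if max(s1, s2) > 0
        else PairInteractionType.AMENSALISM
    )


def _accepted_signs(a_ij: float, a_ji: float, rule: str) -> set:
    """Correlation signs counted as a true positive for an interacting pair."""
    signs = {int(np.sign(a)) for a in (a_ij, a_ji) if a != 0}
    if rule == "either_sign":
        return signs
    if rule == "strongest_sign":
        if abs(a_ij) > abs(a_ji):
            return {int(np.sign(a_ij))}
        if abs(a_ji) > abs(a_ij):
            return {int(np.sign(a_ji))}
        return signs  # exact tie: either sign accepted
    if rule == "strict_both":
        # only symmetric types are recoverable
        return signs if len(signs) == 1 and np.sign(a_ij) == np.sign(a_ji) != 0 else set()
    raise ValueError(f"unknown matching rule {rule!r}")


def classify_pair(
    a_ij: float, a_ji: float, rho_ij: float, significant: bool, rule: str = "either_sign"
) -> str:
    """Assign one unordered pair to TP/FP/TN/FN under a matching rule."""
    rule = str(getattr(rule, "value", rule))
    interacting = a_ij != 0 or a_ji != 0
    if not significant:
        return "FN" if interacting else "TN"
    if not interacting:
        return "FP"
    return "TP" if int(np.sign(rho_ij)) in _accepted_signs(a_ij, a_ji, rule) else "FP"


def confusion_counts(
    A: InteractionMatrix | np.ndarray,
    result: PartialCorrelationResult,
    rule: str = "either_sign",
) -> ConfusionCounts:
    """Apply ``classify_pair`` to every unordered pair exactly once."""
    Av = A.values if isinstance(A, InteractionMatrix) else np.asarray(A, float)
    if Av.shape[0] != result.n_species:
        raise ValueError("interaction matrix and correlation result disagree in size")
    rule = str(getattr(rule, "value", rule))
    counts = {"TP": 0, "FP": 0, "TN": 0, "FN": 0}
    for (i, j), sig in zip(result.pairs, result.significant):
        label = classify_pair(Av[i, j], Av[j, i], result.rho[i, j], bool(sig), rule)
        counts[label] += 1
    return ConfusionCounts(
        tp=counts["TP"], fp=counts["FP"], tn=counts["TN"], fn=counts["FN"], rule=rule
    )


def precision_recall_f1(counts: ConfusionCounts) -> tuple[float, float, float]:
    """Precision, recall and their harmonic mean; 0/0 ratios are defined as 0."""
    tp, fp, fn = counts.tp, counts.fp, counts.fn
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (
        2.0 * precision * recall / (precision + recall) if precision + recall else 0.0
    )
    return precision, recall, f1


def detection_rate_by_type(
    A: InteractionMatrix | np.ndarray, result: PartialCorrelationResult
) -> pd.DataFrame:
    """Per-type detection counts for one dataset.

    A pair counts as detected when its partial correlation is significant and
    its sign matches an interaction in either direction. Returns one row per
    interaction type present plus per-correlation-sign detected counts;
    rates are percentages in [0, 100]. Types absent from A get NaN rates.
    Aggregate over replicates by summing ``n_pairs``/``n_detected``.
    """
    Av = A.values if isinstance(A, InteractionMatrix) else np.asarray(A, float)
    rows = {
        t.value: {"n_pairs": 0, "n_detected": 0, "n_pos": 0, "n_neg": 0}
        for t in PairInteractionType
    }
    for (i, j), sig in zip(result.pairs, result.significant):
        t = pair_type(Av[i, j], Av[j, i]).value
        rows[t]["n_pairs"] += 1
        if sig and classify_pair(
            Av[i, j], Av[j, i], result.rho[i, j], True, "either_sign"
        ) == "TP":
            rows[t]["n_detected"] += 1
            if result.rho[i, j] > 0:
                rows[t]["n_pos"] += 1
            else:
                rows[t]["n_neg"] += 1
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "type"
    df["rate_pct"] = np.where(
        df["n_pairs"] > 0, 100.0 * df["n_detected"] / df["n_pairs"].replace(0, 1), np.nan
    )
    return df.reset_index()
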