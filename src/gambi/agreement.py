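"""Agreement between two categorical pollution-level classifications.

Unweighted Cohen's kappa over the quality-class confusion matrix, with the
Monserud & Leemans verbal scale for interpretation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from gambi._errors import GambiError
from gambi.core_index import QUALITY_CLASSES


@dataclass(frozen=True)
class ConfusionMatrix:
    """Station counts cross-classified by two raters (rows = A, columns = B)."""

    classes: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        k = len(self.classes)
        if counts.shape != (k, k):
            raise GambiError(f"confusion matrix shape {counts.shape} does not match {k} classes")
        if (counts < 0).any():
            raise GambiError("confusion matrix counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    @property
    def n(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    p_observed: float
    p_expected: float
    n: int
    interpretation: str


def confusion_matrix(
    classes_a: Sequence[str],
    classes_b: Sequence[str],
    classes: Sequence[str] = QUALITY_CLASSES,
) -> ConfusionMatrix:
    """Tally paired class labels into a k x k matrix.

    All classes in the vocabulary appear in the axis ordering even when empty.
    """
    if len(classes_a) != len(classes_b):
        raise GambiError(
            f"classification length mismatch: {len(classes_a)} vs {len(classes_b)}"
        )
    if len(classes_a) == 0:
        raise GambiError("cannot build a confusion matrix from zero stations")
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    for a, b in zip(classes_a, classes_b):
        if a not in index:
            raise GambiError(f"unknown class token {a!r}")
        if b not in index:
            raise GambiError(f"unknown class token {b!r}")
        counts[index[a], index[b]] += 1
    return ConfusionMatrix(classes=tuple(classes), counts=counts)


def interpret_kappa(kappa: float) -> str:
    """Verbal agreement label for a kappa value (lower-inclusive half-open bins)."""
    if not (-1.0 <= kappa <= 1.0):
        raise GambiError(f"kappa {kappa} outside [-1, 1]")
    if kappa == 1.0:
        return "perfect"
    if kappa < 0.05:
        return "no agreement"
    bins = [
        (0.20, "very poor"),
        (0.40, "poor"),
        (0.55, "fair"),
        (0.70, "good"),
        (0.85, "very good"),
        (1.00, "excellent"),
    ]
    for upper, label in bins:
        if kappa < upper:
            return label
    return "excellent"  # pragma: no cover - unreachable


def cohens_kappa(cm: ConfusionMatrix) -> KappaResult:
    """Unweighted Cohen's kappa: (p_o - p_e) / (1 - p_e).

    p_o is the observed agreement (trace / n); p_e is chance agreement from
    the marginals.  When both raters are constant and identical (p_e = 1),
    kappa is defined as 1.
    """
    n = cm.n
    if n == 0:
        raise GambiError("cannot compute kappa on an empty confusion matrix")
    counts = cm.counts.astype(float)
    p_o = float(np.trace(counts)) / n
    row = counts.sum(axis=1) / n
    col = counts.sum(axis=0) / n
    p_e = float(row @ col)
    if p_e >= 1.0 - 1e-15:
        kappa = 1.0
    else:
        kappa = (p_o - p_e) / (1.0 - p_e)
    return KappaResult(
        kappa=kappa,
        p_observed=p_o,
        p_expected=p_e,
        n=n,
        interpretation=interpret_kappa(max(-1.0, min(1.0, kappa))),
    )


def per_class_agreement(cm: ConfusionMatrix) -> dict[str, float | None]:
    """Percent of each row class kept on the diagonal; None where the row is empty."""
    if cm.n == 0:
        raise GambiError("empty confusion matrix")
    out: dict[str, float | None] = {}
    row_totals = cm.counts.sum(axis=1)
    for i, cls in enumerate(cm.classes):
        if row_totals[i] == 0:
            out[cls] = None
        else:
            out[cls] = 100.0 * cm.counts[i, i] / row_totals[i]
    return out
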