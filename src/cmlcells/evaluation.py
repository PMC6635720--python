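"""Agreement metrics between two cell-label sequences.

Per-class one-vs-rest confusion counts, sensitivity / specificity /
accuracy (reported in percent, with unweighted macro averages), and
Cohen's kappa

    kappa = (p0 - pe) / (1 - pe)

where p0 is the observed agreement fraction and pe the chance agreement
sum over classes of the two raters' marginal frequencies.  kappa = 1 is
perfect agreement, 0 chance-level, negative values systematic
disagreement.

When a reference panel consists of two experts, the "joint" reference is
taken as the subset of cells on which both agree; disagreeing cells are
excluded and reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConfusionSummary",
    "KappaResult",
    "confusion",
    "metrics",
    "cohen_kappa",
    "joint_reference",
]


@dataclass
class ConfusionSummary:
    """One-vs-rest tp/fp/fn/tn per class; counts sum to n_total per class."""

    classes: tuple
    counts: dict  # class -> {"tp", "fp", "fn", "tn"}
    n_total: int


@dataclass
class KappaResult:
    p0: float
    pe: float
    kappa: float


def _check_pair(a, b):
    a, b = list(a), list(b)
    if len(a) != len(b):
        raise ValueError(f"label sequences differ in length ({len(a)} vs {len(b)})")
    if len(a) == 0:
        raise ValueError("empty label sequences")
    return a, b


def confusion(pred, ref, classes=None) -> ConfusionSummary:
    """One-vs-rest confusion counts per class.

    ``classes`` defaults to the sorted union of labels seen; labels
    outside an explicit class set raise.
    """
    pred, ref = _check_pair(pred, ref)
    if classes is None:
        classes = tuple(sorted(set(pred) | set(ref)))
    else:
        classes = tuple(classes)
        unknown = (set(pred) | set(ref)) - set(classes)
        if unknown:
            raise ValueError(f"labels outside the class set: {sorted(unknown)}")
    n = len(pred)
    counts = {}
    for c in classes:
        tp = sum(1 for p, r in zip(pred, ref) if p == c and r == c)
        fp = sum(1 for p, r in zip(pred, ref) if p == c and r != c)
        fn = sum(1 for p, r in zip(pred, ref) if p != c and r == c)
        counts[c] = {"tp": tp, "fp": fp, "fn": fn, "tn": n - tp - fp - fn}
    return ConfusionSummary(classes, counts, n)


def metrics(cs: ConfusionSummary) -> dict:
    """Per-class and macro-average sensitivity/specificity/accuracy (%).

    A ratio with zero denominator is reported as ``None`` and excluded
    from the macro average with a warning.
    """
    per_class = {}
    for c in cs.classes:
        k = cs.counts[c]
        sens = 100.0 * k["tp"] / (k["tp"] + k["fn"]) if k["tp"] + k["fn"] else None
        spec = 100.0 * k["tn"] / (k["tn"] + k["fp"]) if k["tn"] + k["fp"] else None
        acc = 100.0 * (k["tp"] + k["tn"]) / cs.n_total
        per_class[c] = {"sensitivity": sens, "specificity": spec, "accuracy": acc}
    macro = {}
    for name in ("sensitivity", "specificity", "accuracy"):
        vals = [per_class[c][name] for c in cs.classes if per_class[c][name] is not None]
        if len(vals) < len(cs.classes):
            warnings.warn(
                f"{name}: undefined for some classes, macro average over "
                f"{len(vals)}/{len(cs.classes)} classes",
                stacklevel=2,
            )
        macro[name] = float(np.mean(vals)) if vals else None
    return {"per_class": per_class, "macro": macro}


def cohen_kappa(a, b) -> KappaResult:
    """Cohen's kappa between two label sequences.

    p0 is the fraction of positions where the sequences agree; pe is
    sum_c (n_a(c)/n) * (n_b(c)/n).  When both raters are constant and
    identical (pe = 1) kappa is 1 by convention.
    """
    a, b = _check_pair(a, b)
    n = len(a)
    p0 = sum(1 for x, y in zip(a, b) if x == y) / n
    classes = set(a) | set(b)
    pe = sum((a.count(c) / n) * (b.count(c) / n) for c in classes)
    if pe >= 1.0:
        return KappaResult(p0, pe, 1.0)
    return KappaResult(p0, pe, (p0 - pe) / (1.0 - pe))


def joint_reference(e1, e2, ids=None):
    """Subset of cells where two expert labelings agree.

    Returns ``(kept_indices, labels)``; cells with disagreement are
    excluded (the conservative joint reading of a two-expert panel).
    """
    e1, e2 = _check_pair(e1, e2)
    kept = [i for i, (x, y) in enumerate(zip(e1, e2)) if x == y]
    labels = [e1[i] for i in kept]
    if ids is not None:
        kept = [ids[i] for i in kept]
    return kept, labels
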