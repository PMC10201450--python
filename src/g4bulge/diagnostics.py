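"""Diagnostic-accuracy evaluation of model predictions against experiments.

Predictions (does a sequence match one of the accepted bulged models?) are
compared with experimental structure calls from NMR/CD/UV assays. An
experimental call counts as *positive* G4 formation when the spectrum shows
a single major, major + minor, or multiple G4 conformations; weak G4,
duplex + G4, two-layer G4, plain duplex and non-G4 outcomes are negative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import math

import pandas as pd

from .core import ACCEPTED_BS_MODELS
from .scan import scan_bulged, scan_canonical

POSITIVE_CALLS = frozenset({"single_major", "major_minor", "multiple"})
NEGATIVE_CALLS = frozenset(
    {"weak", "duplex_plus_g4", "two_layer", "duplex", "non_g4"}
)


@dataclass(frozen=True)
class ConfusionMetrics:
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float          # percent
    sensitivity: Optional[float]  # percent; None when tp + fn == 0
    specificity: Optional[float]  # percent; None when tn + fp == 0
    lr_positive: Optional[float]  # sens/(1-spec) on proportions; None when spec == 100%
    kappa: float
    kappa_ci: Tuple[float, float]

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion_metrics(tp: int, fp: int, tn: int, fn: int) -> ConfusionMetrics:
    """Diagnostic statistics from a 2x2 confusion table.

    Accuracy/sensitivity/specificity as percentages; the positive likelihood
    ratio LR+ = sensitivity / (1 - specificity) on the proportion scale;
    Cohen's kappa (po - pe)/(1 - pe) with pe from the marginal products and
    a 95% CI from the large-sample standard error
    sqrt(po(1-po)) / ((1-pe) sqrt(n)). On a 2x2 table the linearly weighted
    kappa coincides with the unweighted one.
    """
    if min(tp, fp, tn, fn) < 0:
        raise ValueError("counts must be nonnegative")
    n = tp + fp + tn + fn
    if n == 0:
        raise ValueError("empty confusion table")
    accuracy = 100.0 * (tp + tn) / n
    sensitivity = 100.0 * tp / (tp + fn) if tp + fn else None
    specificity = 100.0 * tn / (tn + fp) if tn + fp else None
    lr_positive = None
    if sensitivity is not None and specificity is not None and specificity < 100.0:
        lr_positive = (sensitivity / 100.0) / (1.0 - specificity / 100.0)
    po = (tp + tn) / n
    pe = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / (n * n)
    kappa = (po - pe) / (1 - pe) if pe < 1 else 1.0
    se = math.sqrt(po * (1 - po)) / ((1 - pe) * math.sqrt(n)) if pe < 1 else 0.0
    return ConfusionMetrics(
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        accuracy=accuracy,
        sensitivity=sensitivity,
        specificity=specificity,
        lr_positive=lr_positive,
        kappa=kappa,
        kappa_ci=(kappa - 1.96 * se, kappa + 1.96 * se),
    )


def predict_bs(sequence: str) -> bool:
    """True iff the sequence contains an accepted bulged-model match."""
    return any(h.model in ACCEPTED_BS_MODELS for h in scan_bulged(sequence))


def evaluate_predictions(table: pd.DataFrame) -> ConfusionMetrics:
    """Confront scanner predictions with experimental structure calls.

    ``table`` needs columns ``sequence`` and ``experimental_call`` (one of
    the positive/negative labels above). Sequences matching only the
    canonical grammar are outside the bulged-model evaluation and are
    excluded (they would be scored against the wrong model family); unknown
    call labels raise.
    """
    tp = fp = tn = fn = 0
    for _, row in table.iterrows():
        call = row["experimental_call"]
        if call in POSITIVE_CALLS:
            exp_positive = True
        elif call in NEGATIVE_CALLS:
            exp_positive = False
        else:
            raise ValueError(f"unknown experimental call {call!r}")
        seq = row["sequence"].upper()
        predicted = predict_bs(seq)
        if not predicted and scan_canonical(seq):
            continue  # canonical-only sequence: out of scope for this model family
        if predicted and exp_positive:
            tp += 1
        elif predicted and not exp_positive:
            fp += 1
        elif not predicted and exp_positive:
            fn += 1
        else:
            tn += 1
    return confusion_metrics(tp, fp, tn, fn)
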