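"""ROC analysis of the relative-risk score and cutoff selection.

The RR cutoff separating "non-risk" from "at some risk" is chosen on the
model population itself: RR scores against prevalent-diabetes labels, the
full ROC swept over distinct score values (ties grouped into one step), AUC
by the trapezoidal rule (equal to the concordance probability with half
credit for ties), and the operating point closest to the ideal corner
(0, 1) in (FPR, TPR) space taken as the cutoff.  For assessment-only runs
the cutoff is a configuration constant, default 2.2.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn import metrics

#: Cutoff of the shipped model when selection is skipped (dimensionless RR).
DEFAULT_RR_CUTOFF = 2.2


@dataclass
class RocResult:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    cutoff: float | None = None
    sensitivity: float | None = None
    specificity: float | None = None
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "fpr": self.fpr.tolist(),
            "tpr": self.tpr.tolist(),
            "thresholds": [None if not np.isfinite(t) else float(t)
                           for t in self.thresholds],
            "auc": float(self.auc),
            "cutoff": self.cutoff,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kw)


def roc_curve(scores, labels) -> RocResult:
    """Full ROC (no intermediate points dropped) with trapezoidal AUC.

    ``labels`` are 0/1; both classes must be present and scores finite.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    if labels.min() == labels.max():
        raise ValueError("both outcome classes must be present")
    fpr, tpr, thr = metrics.roc_curve(labels, scores, drop_intermediate=False)
    auc = float(metrics.auc(fpr, tpr))
    return RocResult(fpr=fpr, tpr=tpr, thresholds=thr, auc=auc)


def closest_to_01_cutoff(roc: RocResult) -> RocResult:
    """Select the operating point minimizing the Euclidean distance to the
    ideal corner (0, 1); ties break toward higher specificity.

    Returns the same :class:`RocResult` with cutoff, sensitivity and
    specificity filled in.
    """
    if len(roc.fpr) < 2:
        raise ValueError("ROC needs at least 2 operating points")
    d = np.hypot(roc.fpr, 1.0 - roc.tpr)
    # distances within 1e-12 of the minimum count as tied; ties resolve
    # toward the lower false-positive rate (higher specificity)
    tied = np.nonzero(d <= d.min() + 1e-12)[0]
    best = tied[int(np.argmin(roc.fpr[tied]))]
    roc.cutoff = float(roc.thresholds[best])
    roc.sensitivity = float(roc.tpr[best])
    roc.specificity = float(1.0 - roc.fpr[best])
    return roc


def choose_rr_cutoff(rr_scores, prevalent_labels) -> RocResult:
    """Train the RR cutoff on the model population (ROC + closest-to-(0,1))."""
    return closest_to_01_cutoff(roc_curve(rr_scores, prevalent_labels))
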