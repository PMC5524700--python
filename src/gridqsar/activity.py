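"""Activity table, kcat classification and limit-based confusion metrics.

The twelve FXIa assays (five Gly193 substitutions plus wild type, against
the chromogenic substrates S-2288 and S-2366) are bundled as the canonical
activity table. kcat bands (low / moderate / high / very_high) follow the
complete assignment of that table; the two decision limits 52/sec and
85/sec split low-activity from high-activity variants for sensitivity and
specificity scoring of predictions.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import GridQSARError

__all__ = [
    "ACTIVITY_CLASSES", "DEFAULT_LIMITS", "load_activity_table",
    "classify_activity", "ConfusionCounts", "confusion_at_limit",
    "sensitivity", "specificity",
]

ACTIVITY_CLASSES = ("low", "moderate", "high", "very_high")

#: class band upper edges (inclusive): low <= 40.8 < moderate <= 71.2 <
#: high <= 117 < very_high
_BAND_EDGES = ((40.8, "low"), (71.2, "moderate"), (117.0, "high"))

#: decision limits separating low- from high-activity variants (per sec)
DEFAULT_LIMITS = (52.0, 85.0)


def load_activity_table(path=None) -> pd.DataFrame:
    """The bundled code -> (mutation, substrate, kcat, class) table, indexed
    by code; pass ``path`` to load a user table of the same shape."""
    if path is None:
        ref = importlib.resources.files("gridqsar.data") / "fxia_kcat.csv"
        with importlib.resources.as_file(ref) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    if "code" not in df.columns or "kcat" not in df.columns:
        raise GridQSARError("activity table needs 'code' and 'kcat' columns")
    return df.set_index("code")


def classify_activity(kcat: float) -> str:
    """Band a turnover number into low / moderate / high / very_high."""
    kcat = float(kcat)
    if kcat <= 0:
        raise GridQSARError(f"kcat must be positive, got {kcat}")
    for edge, label in _BAND_EDGES:
        if kcat <= edge:
            return label
    return "very_high"


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/TN/FP/FN of predicted-vs-experimental kcat at one limit."""

    limit: float
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion_at_limit(predicted, experimental, limit: float,
                       polarity: str = "high_is_positive") -> ConfusionCounts:
    """Count TP/TN/FP/FN of a prediction set against a kcat limit.

    ``high_is_positive`` (the 85/sec convention): values above the limit
    are positive, so both > limit is TP and both <= limit is TN.
    ``low_is_positive`` (the 52/sec convention) inverts the positive side.
    Values exactly at the limit count as "below".
    """
    pred = np.asarray(predicted, dtype=float)
    exp = np.asarray(experimental, dtype=float)
    if pred.shape != exp.shape or pred.ndim != 1 or pred.size < 1:
        raise GridQSARError("predicted and experimental must be equal-length "
                            "non-empty vectors")
    if polarity not in ("high_is_positive", "low_is_positive"):
        raise ValueError(f"unknown polarity {polarity!r}")
    below_p = pred <= limit
    below_e = exp <= limit
    if polarity == "high_is_positive":
        pos_p, pos_e = ~below_p, ~below_e
    else:
        pos_p, pos_e = below_p, below_e
    return ConfusionCounts(
        limit=limit,
        tp=int(np.sum(pos_p & pos_e)),
        tn=int(np.sum(~pos_p & ~pos_e)),
        fp=int(np.sum(pos_p & ~pos_e)),
        fn=int(np.sum(~pos_p & pos_e)),
    )


def sensitivity(counts: ConfusionCounts) -> float:
    """TP / (TP + FN); raises if no actual positives exist."""
    denom = counts.tp + counts.fn
    if denom == 0:
        raise GridQSARError("sensitivity undefined: no actual positives")
    return counts.tp / denom


def specificity(counts: ConfusionCounts) -> float:
    """TN / (TN + FP); raises if no actual negatives exist."""
    denom = counts.tn + counts.fp
    if denom == 0:
        raise GridQSARError("specificity undefined: no actual negatives")
    return counts.tn / denom
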