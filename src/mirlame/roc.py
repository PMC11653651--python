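"""Single-marker ROC/AUC evaluation with predictiveness bands.

The AUC of one miRNA's RPM values against a binary class label is the
Mann-Whitney concordance probability (ties counted 1/2). Orientation is
resolved automatically so the reported AUC is >= 0.5, and the chosen direction
(">" = class-1 samples tend higher, "<" = lower) is recorded.

Point AUCs are banded as excellent [0.9, 1], good [0.8, 0.9), fair [0.7, 0.8),
weak [0.6, 0.7), fail [0.5, 0.6); anything below 0.5 (only possible with a
fixed direction) is labeled "below".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .errors import ValidationError

BANDS = ("excellent", "good", "fair", "weak", "fail", "below")

ROC_COLUMNS = ("marker", "contrast", "auc", "direction", "n0", "n1", "band")


@dataclass(frozen=True)
class RocResult:
    marker: str
    contrast: tuple[str, str]
    auc: float
    direction: str   # ">" class-1 values higher; "<" class-1 values lower
    n0: int
    n1: int
    band: str


def classify_band(auc_value: float) -> str:
    """Predictiveness band for a point AUC (lower-inclusive intervals)."""
    if not 0.0 <= auc_value <= 1.0:
        raise ValidationError(f"AUC must lie in [0, 1], got {auc_value}")
    for lower, band in ((0.9, "excellent"), (0.8, "good"), (0.7, "fair"),
                        (0.6, "weak"), (0.5, "fail")):
        if auc_value >= lower:
            return band
    return "below"


def auc(values, labels, direction: str = "auto",
        marker: str = "", contrast: tuple[str, str] = ("0", "1")
        ) -> RocResult:
    """Empirical AUC of ``values`` for separating the two label classes.

    ``labels`` is binary (0 = class0, 1 = class1). ``direction`` "auto"
    orients so the AUC is >= 0.5; ">" scores class 1 above class 0; "<" is the
    complement.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.shape != labels.shape:
        raise ValidationError("values and labels must have the same length")
    pos = values[labels == 1]
    neg = values[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValidationError(
            f"both classes must be present (n0={len(neg)}, n1={len(pos)})")
    u1 = mannwhitneyu(pos, neg, alternative="two-sided").statistic
    a = float(u1) / (len(pos) * len(neg))
    if direction == "auto":
        if a >= 0.5:
            resolved = ">"
        else:
            resolved, a = "<", 1.0 - a
    elif direction == ">":
        resolved = ">"
    elif direction == "<":
        resolved, a = "<", 1.0 - a
    else:
        raise ValidationError(f"direction must be 'auto', '>' or '<', got {direction!r}")
    return RocResult(marker=marker, contrast=tuple(contrast), auc=a,
                     direction=resolved, n0=len(neg), n1=len(pos),
                     band=classify_band(a))


def _results_frame(results: list[RocResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"marker": r.marker,
          "contrast": f"{r.contrast[0]}_vs_{r.contrast[1]}",
          "auc": r.auc, "direction": r.direction,
          "n0": r.n0, "n1": r.n1, "band": r.band}
         for r in results],
        columns=["marker", "contrast", "auc", "direction", "n0", "n1", "band"])


def evaluate_differentiation(rpm: pd.DataFrame, meta: pd.DataFrame, markers,
                             phenotype_a: str, phenotype_b: str,
                             week: str = "W0") -> pd.DataFrame:
    """Per-marker AUC for separating two phenotypes from week-``week`` RPM."""
    missing = [m for m in markers if m not in rpm.index]
    if missing:
        raise ValidationError(f"markers absent from the RPM matrix: {missing}")
    ids_a = meta.loc[(meta["phenotype"] == phenotype_a)
                     & (meta["week"] == week), "sample_id"]
    ids_b = meta.loc[(meta["phenotype"] == phenotype_b)
                     & (meta["week"] == week), "sample_id"]
    if len(ids_a) == 0 or len(ids_b) == 0:
        raise ValidationError(
            f"both phenotypes need samples at {week} "
            f"({phenotype_a}: {len(ids_a)}, {phenotype_b}: {len(ids_b)})")
    values = rpm.loc[:, list(ids_a) + list(ids_b)]
    labels = np.r_[np.zeros(len(ids_a), dtype=int), np.ones(len(ids_b), dtype=int)]
    results = [auc(values.loc[m].to_numpy(), labels, marker=m,
                   contrast=(phenotype_a, phenotype_b)) for m in markers]
    return _results_frame(results)


def evaluate_recovery_prediction(rpm: pd.DataFrame, meta: pd.DataFrame,
                                 markers, phenotype: str, week: str
                                 ) -> pd.DataFrame:
    """Per-marker AUC for predicting recovery (RE vs UNR) at one week."""
    missing = [m for m in markers if m not in rpm.index]
    if missing:
        raise ValidationError(f"markers absent from the RPM matrix: {missing}")
    sub = meta.loc[(meta["phenotype"] == phenotype) & (meta["week"] == week)]
    if len(sub) == 0:
        raise ValidationError(f"no {phenotype} samples at week {week}")
    ids_re = sub.loc[sub["recovery"] == "RE", "sample_id"]
    ids_unr = sub.loc[sub["recovery"] == "UNR", "sample_id"]
    if len(ids_re) == 0 or len(ids_unr) == 0:
        raise ValidationError(
            f"{phenotype} at {week} has a single recovery class "
            f"(RE: {len(ids_re)}, UNR: {len(ids_unr)})")
    values = rpm.loc[:, list(ids_re) + list(ids_unr)]
    labels = np.r_[np.zeros(len(ids_re), dtype=int), np.ones(len(ids_unr), dtype=int)]
    results = [auc(values.loc[m].to_numpy(), labels, marker=m,
                   contrast=("RE", "UNR")) for m in markers]
    out = _results_frame(results)
    out.insert(1, "week", week)
    return out
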