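"""Dice-overlap evaluation of registration quality.

Dice(S_f, S_w) = 2|S_f ∩ S_w| / (|S_f| + |S_w|) per anatomical label, with
optional merging of left/right hemisphere label pairs into one structure
score (arithmetic mean) and an unweighted average over all evaluated
labels.  Both sets empty is scored 1.0 (vacuous agreement); exactly one
empty is 0.0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .volumes import DisplacementField, LabelMap
from .warp import WarpConfig, warp_labels

__all__ = ["DiceReport", "dice", "dice_all", "evaluate_registration"]


@dataclass
class DiceReport:
    per_label: dict
    merged: dict
    avg: float

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"kind": "label", "name": str(k), "dice": v}
            for k, v in sorted(self.per_label.items())
        ]
        rows += [
            {"kind": "merged", "name": k, "dice": v}
            for k, v in self.merged.items()
        ]
        rows.append({"kind": "average", "name": "avg", "dice": self.avg})
        return pd.DataFrame(rows)


def dice(a: LabelMap, b: LabelMap, label: int) -> float:
    """Volume overlap of one label between two maps, in [0, 1]."""
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    ma = a.labels == label
    mb = b.labels == label
    na, nb = int(ma.sum()), int(mb.sum())
    if na == 0 and nb == 0:
        return 1.0
    if na == 0 or nb == 0:
        return 0.0
    return 2.0 * int(np.logical_and(ma, mb).sum()) / (na + nb)


def dice_all(a: LabelMap, b: LabelMap, labels=None) -> dict:
    """Per-label Dice for all non-background labels of ``a`` (or ``labels``)."""
    labels = labels if labels is not None else a.label_values()
    return {int(l): dice(a, b, int(l)) for l in labels}


def evaluate_registration(
    ref_labels: LabelMap,
    moving_labels: LabelMap,
    phi: DisplacementField,
    label_pairs: dict | None = None,
    warp_cfg: WarpConfig | None = None,
) -> DiceReport:
    """Warp the moving label map by ``phi`` and score it against the
    reference.

    ``label_pairs`` maps structure name -> (left label, right label); each
    merged score is the mean of the two per-label Dice values, as done when
    collapsing hemispheres into one anatomical structure.
    The average is the unweighted mean over all per-label scores.
    """
    warped = warp_labels(moving_labels, phi, warp_cfg)
    per_label = dice_all(ref_labels, warped)
    merged = {}
    if label_pairs:
        for name, (left, right) in label_pairs.items():
            scores = [per_label[l] for l in (int(left), int(right)) if l in per_label]
            if scores:
                merged[name] = float(np.mean(scores))
    avg = float(np.mean(list(per_label.values()))) if per_label else 1.0
    return DiceReport(per_label=per_label, merged=merged, avg=avg)
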