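"""Detection-quality accounting against reference lesion annotations.

A reference lesion counts as detected (TP) when at least one detected mask
overlaps it; unmatched references are misses (FN) and detections touching no
reference are false alarms (FP). One detection can validate at most one
reference — extra detections landing on an already validated reference are
merged duplicates and counted neither way. Sensitivity and precision
summarise the counts; references are stratified by equivalent diameter, with
false positives tallied overall only (a false alarm has no reference size).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core import LesionRecord
from .morphometry import record_overlap

__all__ = [
    "ConfusionCounts",
    "MatchResult",
    "match_detections",
    "sensitivity",
    "precision",
    "stratify",
    "stratum_names",
    "DETECTION_STRATA",
    "GEOMETRY_STRATA",
    "counts_table",
]

#: the two standard stratifications: detection accounting and geometry accuracy
DETECTION_STRATA: tuple[float, ...] = (1.0, 2.0, 5.0)
GEOMETRY_STRATA: tuple[float, ...] = (1.0, 3.0)


@dataclass
class StratumCounts:
    t: int = 0
    tp: int = 0
    fn: int = 0


@dataclass
class ConfusionCounts:
    """TP/FN per stratum plus overall counts; FP is tallied overall only."""

    per_stratum: dict[str, StratumCounts] = field(default_factory=dict)
    t: int = 0
    tp: int = 0
    fn: int = 0
    fp: int = 0

    def validate(self) -> None:
        for name, s in self.per_stratum.items():
            if s.t != s.tp + s.fn:
                raise ValueError(f"stratum {name}: T != TP + FN")
        if self.t != self.tp + self.fn:
            raise ValueError("overall T != TP + FN")


@dataclass
class MatchResult:
    counts: ConfusionCounts
    pairs: list[tuple[LesionRecord, LesionRecord]]  # (detected, reference)
    false_positives: list[LesionRecord]
    missed: list[LesionRecord]


def match_detections(
    detected: Sequence[LesionRecord],
    truth: Sequence[LesionRecord],
    rule: str = "overlap",
    min_iou: float = 0.3,
    boundaries_mm: Sequence[float] = DETECTION_STRATA,
    mm_per_px: float = 1.0,
) -> MatchResult:
    """Match detections to reference lesions and tally the confusion counts.

    ``rule="overlap"`` accepts any mask overlap (>= 1 px, the default);
    ``rule="iou"`` additionally requires mask IoU >= ``min_iou``.
    Candidate pairs are ranked by overlap (descending, deterministic
    tie-break on record ids) and assigned greedily one-to-one. References
    below the first stratum boundary are excluded from the per-stratum
    table but still participate in matching (a detection landing on one is
    not a false positive).
    """
    if rule not in ("overlap", "iou"):
        raise ValueError(f"unknown matching rule {rule!r}")
    candidates = []
    touches_truth = [False] * len(detected)
    for i, det in enumerate(detected):
        for j, ref in enumerate(truth):
            ov = record_overlap(det, ref)
            if ov < 1:
                continue
            if rule == "iou":
                union = det.area_px + ref.area_px - ov
                if ov / union < min_iou:
                    continue  # an insufficient-IoU graze does not protect from FP
            touches_truth[i] = True
            candidates.append((ov, i, j))
    candidates.sort(key=lambda c: (-c[0], c[1], c[2]))

    det_used = [False] * len(detected)
    ref_matched: dict[int, int] = {}
    for ov, i, j in candidates:
        if det_used[i] or j in ref_matched:
            continue
        det_used[i] = True
        ref_matched[j] = i

    counts = ConfusionCounts()
    diam = [2.0 * np.sqrt(r.area_px / np.pi) * mm_per_px for r in truth]
    strata = stratify(np.asarray(diam, dtype=float), boundaries_mm)
    for name in stratum_names(boundaries_mm):
        counts.per_stratum[name] = StratumCounts()
    pairs = []
    missed = []
    for j, ref in enumerate(truth):
        hit = j in ref_matched
        if strata[j]:
            s = counts.per_stratum[strata[j]]
            s.t += 1
            s.tp += hit
            s.fn += not hit
        counts.t += 1
        counts.tp += hit
        counts.fn += not hit
        if hit:
            pairs.append((detected[ref_matched[j]], ref))
        else:
            missed.append(ref)
    false_positives = [d for i, d in enumerate(detected) if not touches_truth[i]]
    counts.fp = len(false_positives)
    counts.validate()
    return MatchResult(counts=counts, pairs=pairs, false_positives=false_positives, missed=missed)


def sensitivity(tp: int, fn: int, ndigits: int | None = None) -> float:
    """TP / (TP + FN); undefined (error) when no reference lesions exist."""
    if tp + fn <= 0:
        raise ValueError("sensitivity undefined: TP + FN = 0")
    value = tp / (tp + fn)
    return round(value, ndigits) if ndigits is not None else value


def precision(tp: int, fp: int, ndigits: int | None = None) -> float:
    """TP / (TP + FP); undefined (error) when there are no detections."""
    if tp + fp <= 0:
        raise ValueError("precision undefined: TP + FP = 0")
    value = tp / (tp + fp)
    return round(value, ndigits) if ndigits is not None else value


def stratum_names(boundaries_mm: Sequence[float]) -> list[str]:
    """Human-readable stratum labels, e.g. (1, 2, 5) -> 1-2, 2-5, >5."""
    b = [float(x) for x in boundaries_mm]
    names = [f"{lo:g}-{hi:g}" for lo, hi in zip(b[:-1], b[1:])]
    names.append(f">{b[-1]:g}")
    return names


def stratify(diameters_mm: np.ndarray, boundaries_mm: Sequence[float]) -> list[str]:
    """Assign each diameter to a half-open stratum ``[low, high)``.

    Values below the first boundary map to ``""`` (excluded: below the
    smallest size the study accounts for); the last stratum is unbounded
    above. The half-open convention puts a 2.0 mm lesion in "2-5", not
    "1-2".
    """
    b = [float(x) for x in boundaries_mm]
    if sorted(b) != b:
        raise ValueError("boundaries must be ascending")
    names = stratum_names(b)
    out = []
    for d in np.asarray(diameters_mm, dtype=float):
        if d < b[0]:
            out.append("")
            continue
        idx = int(np.searchsorted(b, d, side="right")) - 1
        out.append(names[idx])
    return out


def counts_table(per_method: dict[str, ConfusionCounts], boundaries_mm=DETECTION_STRATA) -> pd.DataFrame:
    """Long-format table of T/TP/FN per stratum (FP on the overall row only)."""
    rows = []
    for method, counts in per_method.items():
        for name in stratum_names(boundaries_mm):
            s = counts.per_stratum.get(name)
            if s is None or s.t == 0:
                continue
            rows.append(
                {"method": method, "stratum": name, "T": s.t, "TP": s.tp, "FN": s.fn, "FP": None}
            )
        rows.append(
            {
                "method": method,
                "stratum": "all",
                "T": counts.t,
                "TP": counts.tp,
                "FN": counts.fn,
                "FP": counts.fp,
            }
        )
    return pd.DataFrame(rows)
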