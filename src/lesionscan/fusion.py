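"""Majority-vote fusion of detections and union fusion of segmentations.

Three detectors (histogram tail, template correlation, boxed segmentation)
see the same image; a lesion is accepted when at least two of them report it.
Records from different methods are grouped when their masks overlap (or,
optionally, when their centroids are close), and an accepted group's fused
mask is the logical union of its members' masks — individual methods tend to
segment slightly small, and the union counteracts that bias.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import LesionRecord, labels_from_records
from .morphometry import record_overlap

__all__ = ["FusedLesion", "match_across_methods", "majority_vote", "union_masks", "fuse"]


@dataclass
class FusedLesion:
    """A lesion confirmed by >= 2 methods, with the union of their masks."""

    members: dict[str, LesionRecord]  # method name -> contributing record
    record: LesionRecord  # fused mask as a record (sources = voting methods)

    @property
    def votes(self) -> int:
        return len(self.members)


def match_across_methods(
    sets: dict[str, list[LesionRecord]],
    rule: str = "overlap",
    centroid_dist_px: float = 20.0,
) -> list[dict[str, LesionRecord]]:
    """Group records across methods into putative same-lesion clusters.

    Two records from *different* methods are linked when their masks overlap
    by at least one pixel (``rule="overlap"``, default) or their centroids
    are within ``centroid_dist_px`` (``rule="centroid"``); groups are the
    transitive closure of links. Within a group each method contributes at
    most one record — the one with the largest total overlap with the other
    methods' members — and displaced records fall back to singleton groups.
    """
    if rule not in ("overlap", "centroid"):
        raise ValueError(f"unknown grouping rule {rule!r}")
    nodes = [(m, i) for m, recs in sorted(sets.items()) for i in range(len(recs))]
    index = {node: k for k, node in enumerate(nodes)}
    parent = list(range(len(nodes)))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def linked(ra: LesionRecord, rb: LesionRecord) -> bool:
        if rule == "overlap":
            return record_overlap(ra, rb) >= 1
        da = np.hypot(ra.centroid[0] - rb.centroid[0], ra.centroid[1] - rb.centroid[1])
        return da <= centroid_dist_px

    methods = sorted(sets)
    for ai, ma in enumerate(methods):
        for mb in methods[ai + 1 :]:
            for i, ra in enumerate(sets[ma]):
                for j, rb in enumerate(sets[mb]):
                    if linked(ra, rb):
                        pa, pb = find(index[(ma, i)]), find(index[(mb, j)])
                        if pa != pb:
                            parent[pb] = pa

    clusters: dict[int, list[tuple[str, int]]] = {}
    for node, k in index.items():
        clusters.setdefault(find(k), []).append(node)

    groups: list[dict[str, LesionRecord]] = []
    for members in clusters.values():
        by_method: dict[str, list[int]] = {}
        for m, i in members:
            by_method.setdefault(m, []).append(i)
        chosen: dict[str, LesionRecord] = {}
        leftovers: list[tuple[str, LesionRecord]] = []
        for m, idxs in sorted(by_method.items()):
            if len(idxs) == 1:
                chosen[m] = sets[m][idxs[0]]
                continue
            # best-overlap wins: the record most supported by other methods
            others = [sets[mo][io] for mo, io in members if mo != m]

            def support(i: int) -> tuple[int, int]:
                rec = sets[m][i]
                return (sum(record_overlap(rec, o) for o in others), -i)

            best = max(idxs, key=support)
            chosen[m] = sets[m][best]
            leftovers.extend((m, sets[m][i]) for i in idxs if i != best)
        groups.append(chosen)
        groups.extend({m: rec} for m, rec in leftovers)
    # deterministic order: by first member's centroid
    groups.sort(key=lambda g: min((r.centroid, m) for m, r in g.items()))
    return groups


def majority_vote(
    groups: list[dict[str, LesionRecord]], min_votes: int = 2
) -> list[FusedLesion]:
    """Keep groups indicated by at least ``min_votes`` distinct methods.

    The fused mask is the logical union of the member masks.
    """
    fused: list[FusedLesion] = []
    for group in groups:
        if len(group) < min_votes:
            continue
        r0 = min(rec.offset[0] for rec in group.values())
        c0 = min(rec.offset[1] for rec in group.values())
        r1 = max(rec.offset[0] + rec.mask_crop.shape[0] for rec in group.values())
        c1 = max(rec.offset[1] + rec.mask_crop.shape[1] for rec in group.values())
        crop = np.zeros((r1 - r0, c1 - c0), dtype=bool)
        for rec in group.values():
            rr, cc = rec.offset
            crop[
                rr - r0 : rr - r0 + rec.mask_crop.shape[0],
                cc - c0 : cc - c0 + rec.mask_crop.shape[1],
            ] |= rec.mask_crop
        rows, cols = np.nonzero(crop)
        rec = LesionRecord(
            id=len(fused) + 1,
            centroid=(float(rows.mean() + r0), float(cols.mean() + c0)),
            mask_crop=crop,
            offset=(r0, c0),
            sources=frozenset(group.keys()),
            score=float(np.mean([m.score for m in group.values()])),
        )
        fused.append(FusedLesion(members=dict(group), record=rec))
    return fused


def union_masks(masks: list[np.ndarray]) -> np.ndarray:
    """Pixel-wise logical OR of same-shape binary masks."""
    if not masks:
        raise ValueError("no masks to union")
    out = np.zeros_like(np.asarray(masks[0], dtype=bool))
    for m in masks:
        m = np.asarray(m, dtype=bool)
        if m.shape != out.shape:
            raise ValueError("mask shapes differ")
        out |= m
    return out


def fuse(
    sets: dict[str, list[LesionRecord]],
    image_shape: tuple[int, int],
    min_votes: int = 2,
    rule: str = "overlap",
    centroid_dist_px: float = 20.0,
) -> tuple[np.ndarray, list[FusedLesion]]:
    """Group, vote, and rasterise the fused lesions into a label mask."""
    groups = match_across_methods(sets, rule=rule, centroid_dist_px=centroid_dist_px)
    fused = majority_vote(groups, min_votes=min_votes)
    labels = labels_from_records([f.record for f in fused], image_shape)
    return labels, fused
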