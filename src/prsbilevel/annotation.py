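"""Annotation-group structure: copy expansion and overlap metrics.

A variant belonging to several annotation groups is represented once per
group ("copies"); the bilevel prior shrinks each copy with its own local
scale and its group's scale, and the variant's total effect is the sum of
its copies' effects.
"""

from __future__ import annotations

import numpy as np

from .datatypes import (
    NO_ANNOTATION,
    AnnotationMap,
    ExpandedDesign,
    SummaryStats,
    ValidationError,
)


def expand_overlap(am: AnnotationMap, ss: SummaryStats) -> ExpandedDesign:
    """Build the per-(variant, group) copy layout of size M'.

    Copies are ordered variant-major (summary-statistic variant order, then
    group order), which fixes the Gibbs update order. For a non-overlapping
    map M' equals the number of variants.
    """
    group_index = {g: k for k, g in enumerate(am.groups)}
    variant_ids = ss.variant_ids
    copy_variant: list[int] = []
    copy_group: list[int] = []
    for j, vid in enumerate(variant_ids):
        labels = am.labels_for(vid)
        ks = sorted(group_index[g] for g in labels)
        copy_variant.extend([j] * len(ks))
        copy_group.extend(ks)
    return ExpandedDesign(
        variant_ids=variant_ids,
        groups=list(am.groups),
        copy_variant=np.array(copy_variant, dtype=np.int64),
        copy_group=np.array(copy_group, dtype=np.int64),
    )


def iou(am: AnnotationMap, g1: str, g2: str) -> float:
    """Intersection-over-union of two groups' variant sets."""
    s1, s2 = am.members(g1), am.members(g2)
    union = s1 | s2
    if not union:
        raise ValidationError(f"groups {g1!r} and {g2!r} are both empty")
    return len(s1 & s2) / len(union)


def make_overlap_assignment(
    sizes: list[int],
    pattern: str = "none",
    target_iou: float = 0.5,
    seed: int = 0,
    variant_prefix: str = "v",
) -> AnnotationMap:
    """Construct an annotation map with a controlled overlap pattern.

    ``sizes`` are the group cardinalities M_k. Pattern ``none`` partitions
    sum(M_k) distinct variants. Pattern ``overlap_I`` shares variants between
    the first two groups (the low-heritability groups in the simulation
    presets) at the target IOU; ``overlap_II`` shares between the last two
    (high-heritability) groups. Shared variants are counted once, so the
    distinct-variant total is sum(M_k) minus the constructed intersection.
    Group labels are ``g1..gK``; variant ids ``{prefix}000001...`` assigned in
    a seed-shuffled order.
    """
    sizes = [int(s) for s in sizes]
    if any(s < 1 for s in sizes):
        raise ValidationError("group sizes must be positive")
    k = len(sizes)
    if pattern in ("overlap_I", "overlap_II") and k != 4:
        raise ValidationError(f"pattern {pattern} requires K=4, got K={k}")
    if pattern not in ("none", "overlap_I", "overlap_II"):
        raise ValidationError(f"unknown pattern {pattern!r}")
    if not (0.0 <= target_iou < 1.0):
        raise ValidationError("target_iou must be in [0, 1)")

    if pattern == "none":
        shared_pair, n_shared = None, 0
    else:
        pair = (0, 1) if pattern == "overlap_I" else (2, 3)
        a, b = sizes[pair[0]], sizes[pair[1]]
        # |A∩B| = t(|A|+|B|)/(1+t) from IOU = o/(|A|+|B|-o) = t
        n_shared = int(round(target_iou * (a + b) / (1.0 + target_iou)))
        if n_shared > min(a, b):
            raise ValidationError(
                f"target IOU {target_iou} infeasible for sizes {a}, {b}"
            )
        shared_pair = pair

    m_distinct = sum(sizes) - n_shared
    rng = np.random.default_rng(seed)
    width = max(6, len(str(m_distinct)))
    ids = [f"{variant_prefix}{i + 1:0{width}d}" for i in range(m_distinct)]
    order = rng.permutation(m_distinct)

    groups = [f"g{i + 1}" for i in range(k)]
    assignment: dict[str, list[str]] = {vid: [] for vid in ids}
    pos = 0
    for gi, size in enumerate(sizes):
        if shared_pair is not None and gi == shared_pair[1]:
            pos -= n_shared  # rewind so this group re-uses the tail of the previous
        for idx in order[pos : pos + size]:
            assignment[ids[idx]].append(groups[gi])
        pos += size
    return AnnotationMap(
        groups=groups,
        assignment={v: tuple(labs) for v, labs in assignment.items()},
    )


def assign_sentinel(am: AnnotationMap, variant_ids: list[str]) -> AnnotationMap:
    """Extend a map so every listed variant has at least one label.

    Variants absent from ``am`` receive the ``"__none__"`` sentinel group,
    which is appended to the group list if needed.
    """
    missing = [v for v in variant_ids if v not in am.assignment]
    if not missing:
        return am
    groups = list(am.groups)
    if NO_ANNOTATION not in groups:
        groups.append(NO_ANNOTATION)
    assignment = dict(am.assignment)
    for v in missing:
        assignment[v] = (NO_ANNOTATION,)
    return AnnotationMap(groups=groups, assignment=assignment)
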