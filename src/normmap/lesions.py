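"""White-matter hyperintensity (WMH) frequency maps and group comparison.

Binary lesion masks are aggregated into per-group frequency maps (voxelwise
lesion proportion) and compared between groups with a voxelwise pooled
two-sample t test on the 0/1 indicators, thresholded at an uncorrected
two-sided p (0.001 by default). Voxels lesioned in no subject of either group
(or in every subject of both) carry no information and are excluded rather
than assigned t = 0; voxels lesioned in all of one group and none of the
other are kept and reach the significance floor.
"""

from __future__ import annotations

import numpy as np

from .errors import DataError
from .stats import pooled_two_sample_t
from .types import FrequencyMap, LesionMask, StatMap


def _stack_masks(masks: list[LesionMask]) -> np.ndarray:
    if not masks:
        raise DataError("no masks supplied")
    shape = masks[0].voxels.shape
    for m in masks:
        if m.voxels.shape != shape:
            raise DataError(
                f"mask for {m.subject_id}: grid {m.voxels.shape} != {shape}"
            )
    return np.stack([m.voxels for m in masks]).astype(float)


def build_frequency_map(masks: list[LesionMask], group: str = "") -> FrequencyMap:
    """Voxelwise lesion proportion across a group's masks."""
    stack = _stack_masks(masks)
    return FrequencyMap(stack.mean(axis=0), n_subjects=len(masks), group=group)


def compare_lesion_frequency(
    masks_a: list[LesionMask],
    masks_b: list[LesionMask],
    alpha: float = 0.001,
    contrast: tuple[str, str] = ("A", "B"),
) -> StatMap:
    """Voxelwise pooled two-sample t on lesion indicators (A minus B).

    Returns an uncorrected StatMap on the flattened grid; ``in_mask`` is False
    at voxels with zero variance in both groups. Significance flags mark
    two-sided p < alpha, uncorrected.
    """
    if len(masks_a) < 2 or len(masks_b) < 2:
        raise DataError("each group needs at least 2 masks")
    A = _stack_masks(masks_a)
    B = _stack_masks(masks_b)
    if A.shape[1:] != B.shape[1:]:
        raise DataError(f"grid mismatch between groups: {A.shape[1:]} vs {B.shape[1:]}")
    shape = A.shape[1:]
    A = A.reshape(len(masks_a), -1)
    B = B.reshape(len(masks_b), -1)
    # exclude voxels carrying no information: zero variance in both groups
    # with equal means (e.g. lesioned in nobody, or in everybody). All-of-A /
    # none-of-B voxels stay in and yield signed-infinite t (p = 0).
    novar = (A.var(axis=0) == 0) & (B.var(axis=0) == 0)
    informative = ~(novar & (A.mean(axis=0) == B.mean(axis=0)))
    t = np.full(A.shape[1], np.nan)
    p = np.full(A.shape[1], np.nan)
    t[informative], p[informative], df = pooled_two_sample_t(
        A[:, informative], B[:, informative]
    )
    significant = np.zeros(A.shape[1], dtype=bool)
    significant[informative] = p[informative] < alpha
    return StatMap(
        t=t,
        p=p,
        significant=significant,
        in_mask=informative,
        df=df,
        correction="none",
        contrast=contrast,
        alpha=alpha,
        space="volume",
        grid_shape=shape,
    )


def classify_fazekas(periventricular_mm: float, deep_mm: float) -> str:
    """Modified-Fazekas eligibility from maximal WMH diameters.

    ``svci_eligible``: periventricular >= 10 mm and deep >= 25 mm
    (significant ischaemia); ``control_eligible``: both < 10 mm (no or mild
    WMH); anything between is ``neither``.
    """
    if periventricular_mm < 0 or deep_mm < 0:
        raise DataError("WMH extents must be >= 0 mm")
    if periventricular_mm >= 10 and deep_mm >= 25:
        return "svci_eligible"
    if periventricular_mm < 10 and deep_mm < 10:
        return "control_eligible"
    return "neither"
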