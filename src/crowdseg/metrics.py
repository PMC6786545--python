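"""Dice similarity scoring of individuals and panels.

The central statistic is the Dice similarity coefficient between two pixel
sets A and B::

    Dice(A, B) = 2 |A ∩ B| / (|A| + |B|)

ranging from 0 (disjoint) to 1 (identical).  This module scores individual
annotators against a reference consensus, one panel's consensus against
another's, and all annotator pairs within a panel, and summarizes the
resulting score tables per image and per annotator.

Degenerate masks follow the convention Dice(∅, ∅) = 1 and
Dice(∅, non-empty) = 0; real outlines never produce empty masks, but
synthetic edge cases can, and the convention keeps every score defined
(a warning marks its use).
"""

from __future__ import annotations

import itertools
import warnings
from typing import Mapping, NamedTuple, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .consensus import ConsensusSegmentation, build_consensus_map, threshold_consensus
from .geometry import BinaryMask, GridMismatchError, ImageGrid, OutlineRecord, rasterize_record

__all__ = [
    "DiceResult",
    "AgreementTable",
    "dice",
    "dice_within",
    "score_individuals",
    "score_consensus_vs_consensus",
    "pairwise_panel_agreement",
    "threshold_sensitivity",
]

MaskLike = Union[BinaryMask, ConsensusSegmentation]


class DiceResult(NamedTuple):
    image_id: str
    subject: str
    reference: str
    dice: float


def _as_mask(m: MaskLike) -> BinaryMask:
    return m.mask if isinstance(m, ConsensusSegmentation) else m


def dice(a: BinaryMask, b: BinaryMask) -> float:
    """Dice similarity coefficient between two masks on the same grid."""
    if a.grid != b.grid:
        raise GridMismatchError("Dice requires masks on the same grid")
    na, nb = a.area, b.area
    if na == 0 and nb == 0:
        warnings.warn("Dice of two empty masks: returning 1.0 by convention", stacklevel=2)
        return 1.0
    inter = int(np.count_nonzero(a.pixels & b.pixels))
    return 2.0 * inter / (na + nb)


def dice_within(a: BinaryMask, b: BinaryMask, roi: BinaryMask) -> float:
    """Dice restricted to a region of interest (e.g. one anatomical part)."""
    if not (a.grid == b.grid == roi.grid):
        raise GridMismatchError("Dice requires masks on the same grid")
    return dice(BinaryMask(a.grid, a.pixels & roi.pixels), BinaryMask(b.grid, b.pixels & roi.pixels))


class AgreementTable:
    """A table of Dice scores plus per-image / per-annotator summaries.

    Wraps a DataFrame with columns ``image_id, subject, reference, dice``.
    """

    COLUMNS = ["image_id", "subject", "reference", "dice"]

    def __init__(self, scores: Union[pd.DataFrame, Sequence[DiceResult]]):
        if not isinstance(scores, pd.DataFrame):
            scores = pd.DataFrame(list(scores), columns=self.COLUMNS)
        missing = set(self.COLUMNS) - set(scores.columns)
        if missing:
            raise ValueError(f"score table missing columns {sorted(missing)}")
        self.scores = scores.reset_index(drop=True)[self.COLUMNS]

    def __len__(self) -> int:
        return len(self.scores)

    @staticmethod
    def _summarize(grouped: pd.core.groupby.DataFrameGroupBy, level: str) -> pd.DataFrame:
        out = grouped["dice"].agg(n="size", median="median", mean="mean", sd="std",
                                  min="min", max="max").reset_index()
        out.insert(0, "level", level)
        return out.rename(columns={out.columns[1]: "id"})

    def by_image(self) -> pd.DataFrame:
        """n / median / mean / sd / min / max of scores for each image."""
        return self._summarize(self.scores.groupby("image_id"), "image")

    def by_annotator(self) -> pd.DataFrame:
        """n / median / mean / sd / min / max of scores for each subject."""
        return self._summarize(self.scores.groupby("subject"), "annotator")

    def summary(self) -> pd.DataFrame:
        """Both summary levels stacked (export format)."""
        return pd.concat([self.by_image(), self.by_annotator()], ignore_index=True)


def score_individuals(
    records: Sequence[OutlineRecord],
    reference: Mapping[str, MaskLike],
    grid: ImageGrid,
    *,
    reference_name: str = "consensus",
    mask_cache: Optional[Mapping[tuple[str, str], BinaryMask]] = None,
) -> AgreementTable:
    """Score each (annotator, image) record against a per-image reference.

    ``records`` should already be deduplicated (accuracy analyses exclude
    repeat segmentations).  Records for images without a reference are
    dropped; an annotator with no scorable image at all is excluded with a
    warning.  ``mask_cache`` can supply pre-rasterized masks keyed by
    (annotator_id, image_id) to avoid repeated rasterization.
    """
    rows: list[DiceResult] = []
    seen: set[str] = set()
    scored: set[str] = set()
    for rec in records:
        seen.add(rec.annotator_id)
        ref = reference.get(rec.image_id)
        if ref is None:
            continue
        key = (rec.annotator_id, rec.image_id)
        mask = mask_cache.get(key) if mask_cache is not None else None
        if mask is None:
            mask = rasterize_record(rec, grid)
        rows.append(
            DiceResult(rec.image_id, rec.annotator_id, reference_name, dice(mask, _as_mask(ref)))
        )
        scored.add(rec.annotator_id)
    unscored = seen - scored
    if unscored:
        warnings.warn(
            f"annotator(s) with zero scorable images excluded: {sorted(unscored)}", stacklevel=2
        )
    return AgreementTable(rows)


def score_individuals_leave_one_out(
    panel_masks: Mapping[str, Mapping[str, BinaryMask]],
    threshold: float = 0.5,
) -> AgreementTable:
    """Score each panel member against the consensus of the *others*.

    Optional alternative to :func:`score_individuals` for the case where
    subjects are scored against their own panel's consensus and
    self-inclusion would flatter them.  ``panel_masks`` maps image_id ->
    {annotator_id: mask}; images with fewer than 2 annotators are skipped
    (no one else to form a consensus).
    """
    rows: list[DiceResult] = []
    for img in sorted(panel_masks):
        panel = panel_masks[img]
        if len(panel) < 2:
            continue
        for ann in sorted(panel):
            others = [m for a, m in panel.items() if a != ann]
            ref = threshold_consensus(build_consensus_map(others), threshold)
            rows.append(DiceResult(img, ann, "loo_consensus", dice(panel[ann], ref.mask)))
    return AgreementTable(rows)


def score_consensus_vs_consensus(
    panel_a: Mapping[str, MaskLike],
    panel_b: Mapping[str, MaskLike],
    *,
    name_a: str = "panel_a",
    name_b: str = "panel_b",
) -> AgreementTable:
    """Dice between two panels' consensus segmentations, per shared image."""
    shared = sorted(set(panel_a) & set(panel_b))
    if not shared:
        raise ValueError("the two panels share no images")
    rows = [
        DiceResult(img, name_a, name_b, dice(_as_mask(panel_a[img]), _as_mask(panel_b[img])))
        for img in shared
    ]
    return AgreementTable(rows)


def pairwise_panel_agreement(
    masks: Mapping[str, BinaryMask], image_id: str = ""
) -> list[DiceResult]:
    """Dice for every unordered annotator pair on one image.

    With fewer than two annotators there is nothing to compare; an empty
    list is returned with a warning.
    """
    ids = sorted(masks)
    if len(ids) < 2:
        warnings.warn(
            f"pairwise agreement needs >= 2 annotators, got {len(ids)} for {image_id!r}",
            stacklevel=2,
        )
        return []
    return [
        DiceResult(image_id, a, b, dice(masks[a], masks[b]))
        for a, b in itertools.combinations(ids, 2)
    ]


def threshold_sensitivity(
    subject_masks: Mapping[str, Sequence[BinaryMask]],
    reference_masks: Mapping[str, Sequence[BinaryMask]],
    thresholds: Sequence[float] = (0.25, 0.5, 0.75),
) -> pd.DataFrame:
    """Consensus-vs-consensus accuracy as a function of the vote threshold.

    For each threshold t, both panels' consensus maps (built once per image)
    are thresholded at t and the subject consensus is scored against the
    reference consensus; the table reports mean and SD of Dice across the
    shared images at each threshold.
    """
    thresholds = list(thresholds)
    for t in thresholds:
        if not (0.0 < t < 1.0):
            raise ValueError(f"threshold must lie strictly in (0, 1), got {t}")
    shared = sorted(set(subject_masks) & set(reference_masks))
    if not shared:
        raise ValueError("the two panels share no images")
    sub_maps = {img: build_consensus_map(subject_masks[img]) for img in shared}
    ref_maps = {img: build_consensus_map(reference_masks[img]) for img in shared}
    rows = []
    for t in thresholds:
        scores = [
            dice(
                threshold_consensus(sub_maps[img], t).mask,
                threshold_consensus(ref_maps[img], t).mask,
            )
            for img in shared
        ]
        arr = np.asarray(scores)
        rows.append(
            {
                "threshold": t,
                "n_images": len(shared),
                "mean": float(arr.mean()),
                "sd": float(arr.std(ddof=1)) if len(arr) > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows)
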