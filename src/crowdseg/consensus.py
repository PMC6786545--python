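"""Label fusion: per-pixel consensus maps and majority-vote segmentations.

A consensus map records, for each pixel, the fraction of annotators whose
segment included it (0 = nobody, 1 = everybody).  Thresholding the map with
a strict ``fraction > t`` rule yields a consensus segmentation; t = 0.5 is
the majority vote, and 0.25 / 0.75 are used for sensitivity analysis.

The denominator of each map is the number of annotators who segmented that
particular image, not the whole panel roster: annotators covered random
subsets of the dataset, so a roster-wide denominator would make consensus
unattainable on sparsely covered images.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .geometry import BinaryMask, GridMismatchError, ImageGrid, OutlineRecord

__all__ = [
    "ConsensusMap",
    "ConsensusSegmentation",
    "build_consensus_map",
    "threshold_consensus",
    "deduplicate_records",
    "DEFAULT_MIN_COVERAGE",
]

#: Images fused from fewer annotators than this are flagged (still processed).
DEFAULT_MIN_COVERAGE = 3


@dataclass(frozen=True)
class ConsensusMap:
    """Per-pixel inclusion fractions for one image.

    ``fraction[r, c] = counts[r, c] / n_annotators`` where ``counts`` is the
    number of contributing masks that include the pixel.  Every fraction is
    therefore an exact multiple of ``1 / n_annotators``.
    """

    grid: ImageGrid
    counts: np.ndarray = field(repr=False)
    n_annotators: int = 0

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.shape != self.grid.shape:
            raise GridMismatchError("counts shape does not match grid")
        if self.n_annotators < 1:
            raise ValueError("n_annotators must be >= 1")
        if counts.min() < 0 or counts.max() > self.n_annotators:
            raise ValueError("counts must lie in [0, n_annotators]")
        counts.setflags(write=False)
        object.__setattr__(self, "counts", counts)

    @property
    def fraction(self) -> np.ndarray:
        return self.counts / self.n_annotators


@dataclass(frozen=True)
class ConsensusSegmentation:
    """Pixels whose consensus fraction strictly exceeds ``threshold``."""

    mask: BinaryMask
    threshold: float
    source: Optional[str] = None


def build_consensus_map(masks: Sequence[BinaryMask]) -> ConsensusMap:
    """Fuse one image's masks into a consensus map.

    All masks must share a grid and should come only from annotators who
    actually segmented the image (the per-image denominator rule).
    """
    masks = list(masks)
    if not masks:
        raise ValueError("cannot build a consensus map from zero masks")
    grid = masks[0].grid
    for m in masks[1:]:
        if m.grid != grid:
            raise GridMismatchError("all masks must share one grid")
    counts = np.zeros(grid.shape, dtype=np.int64)
    for m in masks:
        counts += m.pixels
    return ConsensusMap(grid=grid, counts=counts, n_annotators=len(masks))


def threshold_consensus(
    cmap: ConsensusMap, threshold: float = 0.5, *, source: Optional[str] = None
) -> ConsensusSegmentation:
    """Strict-majority thresholding: keep pixels with fraction > threshold.

    The strict inequality means that with an even panel an exact 50/50 pixel
    is excluded, and with 3 annotators the 0.5-consensus requires >= 2 votes.
    Comparison is done on integer vote counts so no float rounding can flip
    a pixel at an exactly attained threshold.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError(f"threshold must lie strictly in (0, 1), got {threshold}")
    # counts > t * n, robust at exactly representable thresholds
    needed = threshold * cmap.n_annotators
    mask = BinaryMask(cmap.grid, cmap.counts > needed)
    return ConsensusSegmentation(mask=mask, threshold=float(threshold), source=source)


def deduplicate_records(
    records: Sequence[OutlineRecord],
) -> tuple[list[OutlineRecord], list[OutlineRecord]]:
    """Drop repeat segmentations of an image by the same annotator.

    Annotators occasionally re-segmented an image in a later session; those
    repeats count toward throughput but are excluded from accuracy analyses.
    For each (annotator_id, image_id) seen more than once, the record from
    the earliest session is kept (records without a session sort after those
    with one; order of arrival breaks remaining ties).

    Returns
    -------
    (kept, removed)
        ``kept`` preserves the input order of the retained records;
        ``removed`` holds the discarded duplicates.
    """
    best: dict[tuple[str, str], tuple[float, int]] = {}
    for i, rec in enumerate(records):
        key = (rec.annotator_id, rec.image_id)
        sess = float("inf") if rec.session is None else float(rec.session)
        if key not in best or (sess, i) < best[key]:
            best[key] = (sess, i)
    keep_idx = {i for _, i in best.values()}
    kept = [rec for i, rec in enumerate(records) if i in keep_idx]
    removed = [rec for i, rec in enumerate(records) if i not in keep_idx]
    return kept, removed


def flag_low_coverage(
    image_ids_to_n: dict[str, int], min_coverage: int = DEFAULT_MIN_COVERAGE
) -> list[str]:
    """Return image ids fused from fewer than ``min_coverage`` annotators.

    Low-coverage images are still processed; this is a reporting aid.
    """
    flagged = sorted(i for i, n in image_ids_to_n.items() if n < min_coverage)
    if flagged:
        warnings.warn(
            f"{len(flagged)} image(s) have fewer than {min_coverage} annotators", stacklevel=2
        )
    return flagged
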