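"""Fuse a noisy annotator panel into a majority-vote consensus.

Seven simulated annotators outline the same ground-truth shape with
different boundary jitter; their masks are fused into a per-pixel consensus
map and thresholded at 0.25 / 0.5 / 0.75.  The 0.5 (majority-vote)
consensus is closer to the truth than a typical individual.
"""

import numpy as np

from crowdseg import (
    AnnotatorModel,
    ImageGrid,
    StudyDesign,
    build_consensus_map,
    dice,
    generate_shapes,
    rasterize_record,
    simulate_outline,
    threshold_consensus,
)

design = StudyDesign(n_images=1, grid=ImageGrid(96, 96), seed=7)
shape = generate_shapes(design)[0]
truth = shape.ground_truth_mask()

masks, scores = [], []
for i in range(7):
    model = AnnotatorModel(f"ann{i}", sigma=1.0 + 0.4 * i, n_points=70, seed=7)
    mask = rasterize_record(simulate_outline(shape, model), design.grid)
    masks.append(mask)
    scores.append(dice(mask, truth))
print(f"individual Dice vs truth: median {np.median(scores):.3f} "
      f"(range {min(scores):.3f}-{max(scores):.3f})")

cmap = build_consensus_map(masks)
print(f"consensus map: {cmap.n_annotators} annotators, "
      f"fractions are multiples of 1/{cmap.n_annotators}")
for t in (0.25, 0.5, 0.75):
    seg = threshold_consensus(cmap, t)
    print(f"  threshold {t:.2f}: area {seg.mask.area:4d} px, "
          f"Dice vs truth {dice(seg.mask, truth):.3f}")
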