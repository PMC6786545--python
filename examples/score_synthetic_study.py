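"""Score a full synthetic annotation study, panel against panel.

Simulates a small study (20 images; 10 citizens covering random subsets,
3 experts covering everything), then reproduces the accuracy analyses:
individuals vs the expert consensus, citizen consensus vs expert consensus,
and inter-expert pairwise agreement.
"""

import numpy as np

from crowdseg import (
    ImageGrid,
    StudyDesign,
    build_consensus_map,
    deduplicate_records,
    pairwise_panel_agreement,
    score_consensus_vs_consensus,
    score_individuals,
    simulate_study,
    threshold_consensus,
)
from crowdseg.pipeline import rasterize_all

design = StudyDesign(n_images=20, n_citizens=10, n_experts=3,
                     workload_mean=12, workload_sd=5,
                     grid=ImageGrid(96, 96), seed=42)
study = simulate_study(design)
kept, dropped = deduplicate_records(study.records)
masks = rasterize_all(kept, design.grid)
print(f"{len(kept)} records ({len(dropped)} duplicates dropped), "
      f"{design.n_images} images")

citizens = {m.annotator_id for m in study.citizen_models}
cit_by_img, exp_by_img = {}, {}
for (ann, img), m in masks.items():
    (cit_by_img if ann in citizens else exp_by_img).setdefault(img, {})[ann] = m

cons = {
    panel: {img: threshold_consensus(build_consensus_map(list(d.values())), 0.5, source=panel)
            for img, d in by_img.items()}
    for panel, by_img in (("citizens", cit_by_img), ("experts", exp_by_img))
}

individual = score_individuals([r for r in kept if r.annotator_id in citizens],
                               cons["experts"], design.grid, mask_cache=masks)
med = individual.by_image()["median"]
print(f"individuals vs expert consensus: per-image median Dice "
      f"mean {med.mean():.3f}, SD {med.std(ddof=1):.3f}")

cvc = score_consensus_vs_consensus(cons["citizens"], cons["experts"],
                                   name_a="citizen_consensus", name_b="expert_consensus")
d = cvc.scores["dice"]
print(f"citizen consensus vs expert consensus: mean {d.mean():.3f}, SD {d.std(ddof=1):.3f}")

pw = [r.dice for img, panel in exp_by_img.items()
      for r in pairwise_panel_agreement(panel, img)]
print(f"inter-expert pairwise Dice: mean {np.mean(pw):.3f} over {len(pw)} pairs")
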