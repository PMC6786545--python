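"""Annotator behaviour statistics on a simulated study.

Per-session throughput is compared with a Mann-Whitney U test, and the
trade-off between outline detail (points per image) and volume (images
analysed) with a Pearson correlation.
"""

from crowdseg import (
    StudyDesign,
    build_annotator_summaries,
    points_vs_images_correlation,
    session_counts,
    session_throughput_test,
    simulate_study,
)

study = simulate_study(StudyDesign(seed=3))
annotations = study.annotations[
    study.annotations["annotator_id"].str.startswith("citizen")
]

throughput = session_counts(annotations)
s1 = throughput.loc[throughput["session"] == 1, "n_images"]
s2 = throughput.loc[throughput["session"] == 2, "n_images"]
u, p = session_throughput_test(s1, s2)
print(f"session 1 vs 2 throughput: median {s1.median():.0f} vs {s2.median():.0f} "
      f"images; Mann-Whitney U = {u:.1f}, p = {p:.3f}")
print("(the simulator plants no learning effect, so p should be large)")

summaries = build_annotator_summaries(annotations, study.metadata)
r, p = points_vs_images_correlation(summaries)
print(f"mean points per image vs images analysed: Pearson r = {r:.3f}, p = {p:.3f}")
print("(point budgets and workloads are drawn independently here)")
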