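"""The synthetic study generator: determinism, noise model, recovery."""

import numpy as np
import pandas as pd
import pytest

from crowdseg import (
    AnnotatorModel,
    ImageGrid,
    StudyDesign,
    dice,
    dice_within,
    estimate_annotator_noise,
    generate_shapes,
    pairwise_panel_agreement,
    rasterize_record,
    simulate_outline,
    simulate_study,
)
from crowdseg.synthetic import sample_workloads, workload_moments

SMALL = StudyDesign(n_images=6, n_citizens=4, n_experts=2, grid=ImageGrid(64, 64), seed=3)


class TestGenerateShapes:
    def test_same_seed_is_bit_identical(self):
        a = generate_shapes(SMALL)
        b = generate_shapes(SMALL)
        for s, t in zip(a, b):
            assert s.center == t.center and s.radii == t.radii
            assert np.array_equal(s.ground_truth_mask().pixels, t.ground_truth_mask().pixels)

    def test_single_image_design(self):
        shapes = generate_shapes(StudyDesign(n_images=1, grid=ImageGrid(64, 64), seed=0))
        assert len(shapes) == 1

    def test_default_design_yields_150_nonempty_shapes(self):
        shapes = generate_shapes(StudyDesign(seed=5))
        assert len(shapes) == 150
        assert all(s.ground_truth_mask().area > 0 for s in shapes)

    def test_process_thinner_than_body(self):
        for shape in generate_shapes(SMALL):
            if shape.process is None:
                continue
            body, proc = shape.body_mask(), shape.process_mask()
            # min-width proxy: area / bounding-box diagonal extent
            assert proc.area < body.area / 2

    def test_too_small_grid_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            StudyDesign(grid=ImageGrid(16, 16), seed=0)


class TestSimulateOutline:
    shape = generate_shapes(SMALL)[0]

    def test_deterministic_given_inputs(self):
        model = AnnotatorModel("a", sigma=1.5, seed=9)
        r1 = simulate_outline(self.shape, model)
        r2 = simulate_outline(self.shape, model)
        for p, q in zip(r1.regions, r2.regions):
            assert np.array_equal(p.points, q.points)

    def test_noiseless_outline_is_nearly_exact(self):
        model = AnnotatorModel("a", sigma=0.0, bias=0.0, n_points=200, seed=1)
        mask = rasterize_record(simulate_outline(self.shape, model), SMALL.grid)
        assert dice(mask, self.shape.ground_truth_mask()) > 0.98

    def test_positive_bias_dilates(self):
        model = AnnotatorModel("a", sigma=0.0, bias=2.0, n_points=150, seed=1)
        mask = rasterize_record(simulate_outline(self.shape, model), SMALL.grid)
        assert mask.area > self.shape.ground_truth_mask().area

    def test_accuracy_decreases_with_sigma(self):
        gt = self.shape.ground_truth_mask()
        means = []
        for sigma in (0.5, 1.0, 2.0, 4.0):
            scores = [
                dice(
                    rasterize_record(
                        simulate_outline(
                            self.shape, AnnotatorModel("a", sigma=sigma, n_points=80, seed=rep)
                        ),
                        SMALL.grid,
                    ),
                    gt,
                )
                for rep in range(20)
            ]
            means.append(np.mean(scores))
        assert all(a > b for a, b in zip(means, means[1:]))

    def test_gross_error_produces_poor_outline(self):
        model = AnnotatorModel("a", sigma=0.5, gross_error_rate=1.0, n_points=80, seed=2)
        mask = rasterize_record(simulate_outline(self.shape, model), SMALL.grid)
        assert dice(mask, self.shape.ground_truth_mask()) < 0.5


class TestStudyStructure:
    def test_same_seed_gives_identical_tables(self, tmp_path):
        a = simulate_study(SMALL)
        b = simulate_study(SMALL)
        pd.testing.assert_frame_equal(a.annotations, b.annotations)
        pd.testing.assert_frame_equal(a.metadata, b.metadata)
        fa, fb = tmp_path / "a.csv", tmp_path / "b.csv"
        a.annotations.to_csv(fa, index=False)
        b.annotations.to_csv(fb, index=False)
        assert fa.read_bytes() == fb.read_bytes()

    def test_experts_cover_all_images(self):
        study = simulate_study(SMALL)
        exp = study.annotations[study.annotations["annotator_id"].str.startswith("expert")]
        per_expert = exp.groupby("annotator_id")["image_id"].nunique()
        assert (per_expert == SMALL.n_images).all()

    def test_citizen_workloads_within_bounds(self):
        study = simulate_study(SMALL)
        cit = study.annotations[study.annotations["annotator_id"].str.startswith("citizen")]
        per_cit = cit.groupby("annotator_id")["image_id"].nunique()
        assert per_cit.between(1, SMALL.n_images).all()

    def test_uncovered_images_reported(self):
        design = StudyDesign(n_images=40, n_citizens=2, n_experts=1,
                             workload_mean=3, workload_sd=1,
                             grid=ImageGrid(64, 64), seed=11)
        study = simulate_study(design)
        cit = study.annotations[study.annotations["annotator_id"].str.startswith("citizen")]
        covered = set(cit["image_id"].unique())
        assert set(study.uncovered_images) == set(f"img_{i + 1:03d}" for i in range(40)) - covered
        assert study.uncovered_images  # 2 citizens x ~3 images cannot cover 40

    def test_expert_sigma_zero_pairwise_dice_near_one(self):
        models = [AnnotatorModel(f"expert_{i + 1}", sigma=0.0, bias=0.0, n_points=150, seed=4)
                  for i in range(2)]
        study = simulate_study(SMALL, expert_models=models)
        img = study.shapes[0].image_id
        masks = {
            r.annotator_id: rasterize_record(r, SMALL.grid)
            for r in study.records
            if r.image_id == img and r.annotator_id.startswith("expert")
        }
        for res in pairwise_panel_agreement(masks, img):
            assert res.dice > 0.97

    def test_mismatched_model_counts_rejected(self):
        models = [AnnotatorModel("only_one", sigma=1.0)]
        with pytest.raises(ValueError, match="match the design"):
            simulate_study(SMALL, citizen_models=models)


class TestWorkloadDistribution:
    def test_empirical_moments_match_exact_truncated_moments(self):
        design = StudyDesign(seed=0)
        rng = np.random.default_rng(99)
        draws = sample_workloads(design, 1000, rng)
        m, sd = workload_moments(design)
        assert np.mean(draws) == pytest.approx(m, rel=0.05)
        assert np.std(draws, ddof=1) == pytest.approx(sd, rel=0.05)
        assert draws.min() >= 1 and draws.max() <= design.n_images


class TestRegionTypeContrast:
    def test_agreement_lower_on_thin_process_than_body(self):
        """Pairwise agreement restricted to the thin posterior structure
        should be systematically worse than on the round body."""
        design = StudyDesign(n_images=8, n_citizens=3, n_experts=1,
                             grid=ImageGrid(96, 96), seed=21)
        shapes = generate_shapes(design)
        models = [AnnotatorModel(f"c{i}", sigma=1.5, n_points=90, seed=13 + i)
                  for i in range(3)]
        body_scores, proc_scores = [], []
        for shape in shapes:
            if shape.process is None:
                continue
            body_roi, proc_roi = shape.body_mask(), shape.process_mask()
            masks = [rasterize_record(simulate_outline(shape, m), design.grid)
                     for m in models]
            for i in range(3):
                for j in range(i + 1, 3):
                    body_scores.append(dice_within(masks[i], masks[j], body_roi))
                    proc_scores.append(dice_within(masks[i], masks[j], proc_roi))
        assert np.mean(proc_scores) < np.mean(body_scores)


class TestParameterRecovery:
    def test_sigma_and_bias_recovered_from_outlines(self):
        design = StudyDesign(n_images=30, n_citizens=1, n_experts=1,
                             grid=ImageGrid(96, 96), seed=8)
        shapes = generate_shapes(design)
        by_id = {s.image_id: s for s in shapes}
        planted = [("tight", 0.8, 0.5), ("mid", 1.6, -0.8), ("loose", 3.0, 0.0)]
        records = [
            simulate_outline(s, AnnotatorModel(name, sigma=sig, bias=b,
                                               n_points=70, seed=17))
            for name, sig, b in planted for s in shapes
        ]
        est = estimate_annotator_noise(records, by_id).set_index("annotator_id")
        for name, sig, b in planted:
            assert est.loc[name, "sigma_hat"] == pytest.approx(sig, rel=0.15)
            assert est.loc[name, "bias_hat"] == pytest.approx(b, abs=0.25)
            assert est.loc[name, "n_vertices"] >= 30 * 8
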