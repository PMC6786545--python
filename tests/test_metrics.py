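"""Dice scoring of individuals and panels."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crowdseg import (
    BinaryMask,
    ImageGrid,
    OutlineRecord,
    Polygon,
    build_consensus_map,
    dice,
    dice_within,
    pairwise_panel_agreement,
    score_consensus_vs_consensus,
    score_individuals,
    threshold_consensus,
    threshold_sensitivity,
)

GRID = ImageGrid(8, 8)


def mask_at(cells):
    px = np.zeros((8, 8), bool)
    for r, c in cells:
        px[r, c] = True
    return BinaryMask(GRID, px)


def random_mask(rng, p=0.5, grid=GRID):
    return BinaryMask(grid, rng.uniform(size=grid.shape) < p)


class TestDice:
    def test_identical_nonempty_is_one(self, rng):
        m = random_mask(rng, 0.4)
        assert dice(m, m) == 1.0

    def test_disjoint_is_zero(self):
        a = mask_at([(0, 0), (0, 1)])
        b = mask_at([(5, 5), (5, 6)])
        assert dice(a, b) == 0.0

    def test_half_overlap_case(self):
        # |A| = |B| = 4 with |A ∩ B| = 2  ->  2*2 / 8 = 0.5 exactly
        a = mask_at([(0, 0), (0, 1), (0, 2), (0, 3)])
        b = mask_at([(0, 2), (0, 3), (1, 0), (1, 1)])
        assert dice(a, b) == 0.5

    def test_empty_mask_conventions(self):
        empty = mask_at([])
        full = mask_at([(1, 1)])
        with pytest.warns(UserWarning, match="empty"):
            assert dice(empty, empty) == 1.0
        assert dice(empty, full) == 0.0
        assert dice(full, empty) == 0.0

    def test_grid_mismatch_rejected(self):
        other = BinaryMask(ImageGrid(8, 9), np.zeros((8, 9), bool))
        with pytest.raises(ValueError):
            dice(mask_at([(0, 0)]), other)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_symmetry_bounds_and_iou_identity(self, seed):
        rng = np.random.default_rng(seed)
        a, b = random_mask(rng), random_mask(rng)
        if a.area == 0 and b.area == 0:
            return
        d = dice(a, b)
        assert 0.0 <= d <= 1.0
        assert d == dice(b, a)
        # cross-check against an independently computed Jaccard index
        union = int(np.count_nonzero(a.pixels | b.pixels))
        inter = int(np.count_nonzero(a.pixels & b.pixels))
        iou = inter / union if union else 1.0
        assert d == pytest.approx(2 * iou / (1 + iou))

    def test_dice_within_restricts_to_roi(self):
        a = mask_at([(0, 0), (0, 1), (5, 5)])
        b = mask_at([(0, 0), (0, 1), (6, 6)])
        roi = mask_at([(0, 0), (0, 1), (0, 2)])
        assert dice_within(a, b, roi) == 1.0
        assert dice(a, b) < 1.0


def square_record(ann, img, x0, y0, side=4, session=1):
    poly = Polygon([(x0, y0), (x0 + side, y0), (x0 + side, y0 + side), (x0, y0 + side)])
    return OutlineRecord(ann, img, [poly], session)


class TestScoreIndividuals:
    def test_identical_to_reference_scores_one(self):
        records = [square_record("a", f"i{k}", 1, 1) for k in range(3)]
        ref_mask = mask_at([(r, c) for r in range(1, 5) for c in range(1, 5)])
        reference = {f"i{k}": ref_mask for k in range(3)}
        table = score_individuals(records, reference, GRID)
        assert len(table) == 3
        assert (table.scores["dice"] == 1.0).all()

    def test_images_without_reference_are_dropped(self):
        records = [square_record("a", "i0", 1, 1), square_record("a", "missing", 1, 1)]
        reference = {"i0": mask_at([(r, c) for r in range(1, 5) for c in range(1, 5)])}
        table = score_individuals(records, reference, GRID)
        assert set(table.scores["image_id"]) == {"i0"}

    def test_annotator_with_no_scorable_image_warns(self):
        records = [square_record("ghost", "missing", 1, 1)]
        with pytest.warns(UserWarning, match="zero scorable"):
            table = score_individuals(records, {}, GRID)
        assert len(table) == 0

    def test_hand_computed_scores_on_8x8_masks(self):
        # annotator squares vs reference squares with hand-counted overlaps:
        # full overlap 16/16, half-shifted 2*8/(16+16) = 0.5
        records = [
            square_record("a", "i0", 0, 0), square_record("a", "i1", 2, 0),
            square_record("b", "i0", 0, 0), square_record("b", "i1", 0, 2),
        ]
        ref = {
            "i0": mask_at([(r, c) for r in range(4) for c in range(4)]),
            "i1": mask_at([(r, c) for r in range(4) for c in range(4)]),
        }
        table = score_individuals(records, ref, GRID)
        got = table.scores.set_index(["subject", "image_id"])["dice"]
        assert got[("a", "i0")] == 1.0
        assert got[("a", "i1")] == 0.5
        assert got[("b", "i0")] == 1.0
        assert got[("b", "i1")] == 0.5

    def test_summaries_have_consistent_bounds(self, rng):
        records = [
            square_record(f"ann{a}", f"i{k}", int(rng.integers(0, 3)), int(rng.integers(0, 3)))
            for a in range(3) for k in range(4)
        ]
        ref = {f"i{k}": mask_at([(r, c) for r in range(1, 5) for c in range(1, 5)])
               for k in range(4)}
        table = score_individuals(records, ref, GRID)
        for summary in (table.by_image(), table.by_annotator()):
            assert ((summary["min"] <= summary["median"]) & (summary["median"] <= summary["max"])).all()


class TestConsensusVsConsensus:
    def test_identical_stacks_score_one(self):
        stack = {f"i{k}": [mask_at([(0, 0), (0, 1)]), mask_at([(0, 0), (1, 1)])]
                 for k in range(3)}
        panels = {
            img: threshold_consensus(build_consensus_map(masks), 0.5)
            for img, masks in stack.items()
        }
        table = score_consensus_vs_consensus(panels, panels)
        assert len(table) == 3
        assert (table.scores["dice"] == 1.0).all()

    def test_no_shared_images_is_error(self):
        a = {"i0": mask_at([(0, 0)])}
        b = {"i1": mask_at([(0, 0)])}
        with pytest.raises(ValueError, match="share no images"):
            score_consensus_vs_consensus(a, b)

    def test_matches_bruteforce_on_noisy_panels(self, rng):
        # independent recomputation of Dice from raw pixel sets
        panel_a, panel_b = {}, {}
        for k in range(4):
            stack_a = [random_mask(rng, 0.5) for _ in range(3)]
            stack_b = [random_mask(rng, 0.5) for _ in range(3)]
            panel_a[f"i{k}"] = threshold_consensus(build_consensus_map(stack_a), 0.5)
            panel_b[f"i{k}"] = threshold_consensus(build_consensus_map(stack_b), 0.5)
        table = score_consensus_vs_consensus(panel_a, panel_b)
        for _, row in table.scores.iterrows():
            a = panel_a[row["image_id"]].mask.pixels
            b = panel_b[row["image_id"]].mask.pixels
            na, nb = a.sum(), b.sum()
            want = 1.0 if na + nb == 0 else 2 * (a & b).sum() / (na + nb)
            assert row["dice"] == pytest.approx(want)


class TestPairwisePanelAgreement:
    def test_three_annotators_give_three_pairs(self, rng):
        masks = {f"a{k}": random_mask(rng, 0.5) for k in range(3)}
        results = pairwise_panel_agreement(masks, "img")
        assert len(results) == 3
        assert {(r.subject, r.reference) for r in results} == {
            ("a0", "a1"), ("a0", "a2"), ("a1", "a2")
        }

    def test_identical_annotators_all_one(self, rng):
        m = random_mask(rng, 0.5)
        results = pairwise_panel_agreement({"a": m, "b": m, "c": m})
        assert all(r.dice == 1.0 for r in results)

    def test_fewer_than_two_warns_and_returns_empty(self, rng):
        with pytest.warns(UserWarning, match=">= 2 annotators"):
            assert pairwise_panel_agreement({"a": random_mask(rng)}) == []

    def test_hand_built_six_by_six_masks(self):
        g = ImageGrid(6, 6)

        def row_mask(rows):
            px = np.zeros((6, 6), bool)
            px[rows, :] = True
            return BinaryMask(g, px)

        masks = {"a": row_mask([0, 1]), "b": row_mask([1, 2]), "c": row_mask([0, 1])}
        got = {(r.subject, r.reference): r.dice for r in pairwise_panel_agreement(masks)}
        # |each| = 12; a∩b = row1 = 6 -> 12/24; a∩c = 12 -> 1; b∩c = 6 -> 0.5
        assert got[("a", "b")] == 0.5
        assert got[("a", "c")] == 1.0
        assert got[("b", "c")] == 0.5


class TestThresholdSensitivity:
    def test_unanimous_panels_invariant_across_thresholds(self, rng):
        subject = {f"i{k}": [random_mask(rng, 0.5)] * 3 for k in range(3)}
        reference = {f"i{k}": [subject[f"i{k}"][0]] * 3 for k in range(3)}
        table = threshold_sensitivity(subject, reference, [0.25, 0.5, 0.75])
        assert table["mean"].nunique() == 1
        assert (table["mean"] == 1.0).all()

    def test_single_threshold_matches_consensus_scoring(self, rng):
        subject = {f"i{k}": [random_mask(rng, 0.6) for _ in range(5)] for k in range(4)}
        reference = {f"i{k}": [random_mask(rng, 0.6) for _ in range(3)] for k in range(4)}
        table = threshold_sensitivity(subject, reference, [0.5])
        panels_s = {i: threshold_consensus(build_consensus_map(m), 0.5)
                    for i, m in subject.items()}
        panels_r = {i: threshold_consensus(build_consensus_map(m), 0.5)
                    for i, m in reference.items()}
        direct = score_consensus_vs_consensus(panels_s, panels_r).scores["dice"]
        assert table.loc[0, "mean"] == pytest.approx(direct.mean())
        assert table.loc[0, "sd"] == pytest.approx(direct.std(ddof=1))

    def test_noisy_panels_match_independent_recomputation(self, rng):
        subject = {f"i{k}": [random_mask(rng, 0.55) for _ in range(5)] for k in range(3)}
        reference = {f"i{k}": [random_mask(rng, 0.55) for _ in range(3)] for k in range(3)}
        table = threshold_sensitivity(subject, reference, [0.25, 0.75])
        for _, row in table.iterrows():
            t = row["threshold"]
            scores = []
            for img in subject:
                cs = np.stack([m.pixels for m in subject[img]]).mean(0) > t
                cr = np.stack([m.pixels for m in reference[img]]).mean(0) > t
                tot = cs.sum() + cr.sum()
                scores.append(1.0 if tot == 0 else 2 * (cs & cr).sum() / tot)
            assert row["mean"] == pytest.approx(np.mean(scores))

    def test_invalid_threshold_rejected(self, rng):
        stacks = {"i0": [random_mask(rng)]}
        with pytest.raises(ValueError):
            threshold_sensitivity(stacks, stacks, [0.5, 1.0])


class TestLeaveOneOut:
    def test_self_excluded_from_reference(self, rng):
        from crowdseg.metrics import score_individuals_leave_one_out

        # two agreeing annotators plus one outlier: with self excluded, the
        # outlier is scored against the agreeing pair only
        m = random_mask(rng, 0.5)
        outlier = BinaryMask(GRID, ~m.pixels)
        panel = {"i0": {"a": m, "b": m, "c": outlier}}
        table = score_individuals_leave_one_out(panel, 0.5)
        got = table.scores.set_index("subject")["dice"]
        assert got["c"] == pytest.approx(dice(outlier, m))
        assert got["a"] < 1.0  # a's reference is consensus of {b, c}, not itself

    def test_single_annotator_images_skipped(self, rng):
        from crowdseg.metrics import score_individuals_leave_one_out

        table = score_individuals_leave_one_out({"i0": {"a": random_mask(rng)}})
        assert len(table) == 0
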