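"""Pairwise confusion matrices, per-layer metrics, annotator summaries."""

from __future__ import annotations

import math

import numpy as np
import pytest

from gonioagree import (
    ConfusionMatrix,
    LabelMap,
    LayerLabel,
    LAYERS,
    accumulate,
    annotator_summary,
    confusion_matrix,
    layer_metrics,
)
from oracles import confusion_oracle, random_label_grid

IR, CBB, SS, TM, C = (int(l) for l in LAYERS)


def lm(grid, annotator="a1", image="img") -> LabelMap:
    return LabelMap(image, annotator, np.asarray(grid, dtype=np.uint8))


class TestConfusionMatrix:
    def test_identical_maps_are_diagonal(self):
        rng = np.random.default_rng(1)
        grid = random_label_grid(rng, 10, 8)
        cm = confusion_matrix(lm(grid, "a1"), lm(grid, "a2"))
        assert (cm.counts == np.diag(np.diag(cm.counts))).all()
        assert cm.total == int(np.count_nonzero(grid))

    def test_na_pixels_contribute_to_no_cell(self):
        first = lm([[IR, IR]], "a1")
        ref = lm([[IR, 0]], "a2")  # second pixel NA for the reference
        cm = confusion_matrix(first, ref)
        assert cm.total == 1
        assert cm.counts[IR - 1, IR - 1] == 1

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_brute_force_tally(self, seed):
        rng = np.random.default_rng(seed)
        g1, g2 = random_label_grid(rng, 4, 4), random_label_grid(rng, 4, 4)
        cm = confusion_matrix(lm(g1, "a1"), lm(g2, "a2"))
        np.testing.assert_array_equal(cm.counts, confusion_oracle(g1, g2))

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ValueError, match="mismatch"):
            confusion_matrix(lm(np.zeros((4, 4))), lm(np.zeros((4, 5)), "a2"))

    def test_transpose_duality(self, jittered_maps):
        keys = list(jittered_maps)
        m1 = jittered_maps[keys[0]]
        m2 = next(jittered_maps[k] for k in keys if k[1] == keys[0][1] and k[0] != keys[0][0])
        ab = confusion_matrix(m1, m2)
        ba = confusion_matrix(m2, m1)
        np.testing.assert_array_equal(ab.counts, ba.counts.T)


class TestAccumulate:
    def test_single_matrix_identity(self):
        cm = ConfusionMatrix("a1", "a2", np.arange(25).reshape(5, 5), scope="im0")
        pooled = accumulate([cm])
        np.testing.assert_array_equal(pooled.counts, cm.counts)
        assert pooled.scope == "pooled"

    def test_disjoint_images_add(self):
        c1 = ConfusionMatrix("a1", "a2", np.eye(5, dtype=int) * 3, scope="im0")
        c2 = ConfusionMatrix("a1", "a2", np.eye(5, dtype=int) * 4, scope="im1")
        np.testing.assert_array_equal(accumulate([c1, c2]).counts, np.eye(5, dtype=int) * 7)

    def test_mixed_pairs_rejected(self):
        c1 = ConfusionMatrix("a1", "a2", np.zeros((5, 5), int))
        c2 = ConfusionMatrix("a1", "a3", np.zeros((5, 5), int))
        with pytest.raises(ValueError, match="pairs"):
            accumulate([c1, c2])

    def test_pooled_metrics_differ_from_per_image_averages(self):
        # image 1: SS TP=1, FP=9; image 2: TP=90, FP=0.
        # pooled precision = 91/100; per-image average = (0.1 + 1.0)/2
        m1 = np.zeros((5, 5), int)
        m1[SS - 1, SS - 1], m1[SS - 1, TM - 1] = 1, 9
        m2 = np.zeros((5, 5), int)
        m2[SS - 1, SS - 1] = 90
        c1 = ConfusionMatrix("a1", "a2", m1, "im0")
        c2 = ConfusionMatrix("a1", "a2", m2, "im1")
        pooled = layer_metrics(accumulate([c1, c2]), LayerLabel.SS).precision
        per_image = np.mean(
            [layer_metrics(c, LayerLabel.SS).precision for c in (c1, c2)]
        )
        assert pooled == pytest.approx(0.91)
        assert per_image == pytest.approx(0.55)
        assert pooled != per_image


class TestLayerMetrics:
    def test_perfect_agreement_gives_ones(self):
        cm = ConfusionMatrix("a1", "a2", np.diag([5, 4, 3, 2, 1]))
        for layer in LAYERS:
            m = layer_metrics(cm, layer)
            assert m.precision == m.sensitivity == m.dice == 1.0

    def test_direct_formula_evaluation(self):
        counts = np.zeros((5, 5), int)
        counts[SS - 1, SS - 1] = 6
        counts[SS - 1, TM - 1] = 2  # FP for SS
        m = layer_metrics(ConfusionMatrix("a1", "a2", counts), LayerLabel.SS)
        assert (m.tp, m.fp, m.fn) == (6, 2, 0)
        assert m.precision == pytest.approx(0.75)
        assert m.sensitivity == pytest.approx(1.0)
        assert m.dice == pytest.approx(6 / 7)

    def test_absent_layer_is_undefined(self):
        counts = np.zeros((5, 5), int)
        counts[IR - 1, IR - 1] = 10
        m = layer_metrics(ConfusionMatrix("a1", "a2", counts), LayerLabel.SS)
        assert math.isnan(m.precision) and math.isnan(m.sensitivity) and math.isnan(m.dice)

    def test_dice_is_harmonic_mean_and_matches_count_form(self, jittered_maps, jittered_panel):
        aset = jittered_panel.annotations
        m = aset.image_ids[0]
        cm = confusion_matrix(
            jittered_maps[("annotator1", m)], jittered_maps[("annotator2", m)]
        )
        for layer in LAYERS:
            met = layer_metrics(cm, layer)
            if math.isnan(met.dice):
                continue
            denom = 2 * met.tp + met.fp + met.fn
            if denom:
                assert met.dice == pytest.approx(2 * met.tp / denom)

    def test_precision_sensitivity_swap_and_dice_symmetry(self, jittered_maps, jittered_panel):
        aset = jittered_panel.annotations
        for m in aset.image_ids:
            ab = confusion_matrix(
                jittered_maps[("annotator1", m)], jittered_maps[("annotator3", m)]
            )
            ba = confusion_matrix(
                jittered_maps[("annotator3", m)], jittered_maps[("annotator1", m)]
            )
            for layer in LAYERS:
                f, r = layer_metrics(ab, layer), layer_metrics(ba, layer)
                assert f.precision == pytest.approx(r.sensitivity, nan_ok=True)
                assert f.dice == pytest.approx(r.dice, nan_ok=True)

    def test_thinner_inside_signature(self):
        # annotation strictly inside the reference: precision 1, sensitivity < 1
        ref = np.full((6, 10), SS, dtype=np.uint8)
        thin = np.full((6, 10), TM, dtype=np.uint8)  # rest labeled, not NA
        thin[2:4] = SS
        m = layer_metrics(confusion_matrix(lm(thin, "a1"), lm(ref, "a2")), LayerLabel.SS)
        assert m.precision == 1.0
        assert m.sensitivity < 1.0


class TestAnnotatorSummary:
    def test_identical_annotators_mean_one_sd_zero(self):
        rng = np.random.default_rng(9)
        grid = random_label_grid(rng, 12, 10, p_na=0.2)
        maps = {
            (a, "im0"): lm(grid, a, "im0") for a in ("a1", "a2", "a3")
        }
        summary = annotator_summary(maps, ["a1", "a2", "a3"], ["im0"])
        defined = summary[summary.n_comparisons > 0]
        assert defined["mean"].to_numpy() == pytest.approx(1.0)
        assert defined["sd"].to_numpy() == pytest.approx(0.0)

    def test_two_annotators_single_comparison_flagged(self):
        rng = np.random.default_rng(9)
        grid = random_label_grid(rng, 12, 10, p_na=0.2)
        maps = {(a, "im0"): lm(grid, a, "im0") for a in ("a1", "a2")}
        summary = annotator_summary(maps, ["a1", "a2"], ["im0"])
        defined = summary[summary.n_comparisons > 0]
        assert (defined.n_comparisons == 1).all()
        assert defined["sd"].isna().all()  # sample SD undefined at n = 1

    def test_undefined_metrics_excluded_and_counted(self):
        # annotator a3 never labels SS; comparisons vs a3 are undefined for SS
        rng = np.random.default_rng(2)
        grid = random_label_grid(rng, 12, 10, p_na=0.2)
        no_ss = grid.copy()
        no_ss[no_ss == SS] = 0
        maps = {
            ("a1", "im0"): lm(grid, "a1", "im0"),
            ("a2", "im0"): lm(grid, "a2", "im0"),
            ("a3", "im0"): lm(no_ss, "a3", "im0"),
        }
        summary = annotator_summary(maps, ["a1", "a2", "a3"], ["im0"])
        row = summary[
            (summary.annotator == "a1") & (summary.layer == "SS") & (summary.metric == "dice")
        ].iloc[0]
        assert row.n_comparisons == 1  # only vs a2
        assert row.n_undefined == 1  # vs a3
        assert row["mean"] == pytest.approx(1.0)

    def test_per_image_scope_collects_one_value_per_image(self, jittered_maps, jittered_panel):
        aset = jittered_panel.annotations
        summary = annotator_summary(
            jittered_maps, aset.annotator_ids, aset.image_ids, scope="per-image"
        )
        row = summary[
            (summary.annotator == "annotator1")
            & (summary.layer == "IR")
            & (summary.metric == "dice")
        ].iloc[0]
        assert row.n_comparisons + row.n_undefined == (aset.n_annotators - 1) * aset.n_images

    def test_invalid_scope_rejected(self, jittered_maps, jittered_panel):
        aset = jittered_panel.annotations
        with pytest.raises(ValueError, match="scope"):
            annotator_summary(jittered_maps, aset.annotator_ids, aset.image_ids, scope="bogus")
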