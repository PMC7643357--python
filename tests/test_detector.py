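"""Detector architecture contracts: pyramid, anchors, ROI pooling,
losses, training determinism, and the matched-filter reference."""

import numpy as np
import pytest

import ssedetect as sd
from ssedetect import detector as dt
from ssedetect import nn
from ssedetect.template import TemplateConfig, pattern_template


@pytest.fixture(scope="module")
def small_model():
    return dt.untrained_model(seed=0)


class TestFeaturePyramid:
    def test_level_shapes_follow_strides(self, small_model):
        feats = sd.build_feature_pyramid(np.zeros((64, 64)), small_model)
        assert {s: f.shape[1:] for s, f in feats.items()} == {
            4: (16, 16), 8: (8, 8), 16: (4, 4)
        }
        assert all(f.shape[0] == small_model.config.channels for f in feats.values())

    def test_zero_input_with_zero_biases_gives_zero_features(self, small_model):
        feats = sd.build_feature_pyramid(np.zeros((64, 64)), small_model)
        for f in feats.values():
            assert not f.any()

    def test_top_down_pathway_feeds_the_finest_level(self, small_model):
        rng = np.random.default_rng(0)
        x = rng.random((64, 64))
        x = np.triu((x + x.T) / 2, 1)
        x = x + x.T
        before = sd.build_feature_pyramid(x, small_model)[4].copy()
        # perturb only the coarsest level's lateral projection
        small_model.params["lat16_b"].data += 0.5
        after = sd.build_feature_pyramid(x, small_model)[4]
        small_model.params["lat16_b"].data -= 0.5
        assert not np.allclose(before, after)

    def test_map_smaller_than_max_stride_is_a_config_error(self, small_model):
        with pytest.raises(sd.ConfigError):
            sd.build_feature_pyramid(np.zeros((8, 8)), small_model)


class TestAnchors:
    def test_anchor_count_per_level(self):
        config = dt.DetectorConfig()
        anchors = sd.generate_anchors(config, 64)
        assert len(anchors[4]) == 16 * 16 * 9
        assert len(anchors[8]) == 8 * 8 * 9
        assert len(anchors[16]) == 4 * 4 * 9

    def test_area_cap_never_violated(self):
        config = dt.DetectorConfig(
            anchor_scales=(8.0, 32.0, 80.0), anchor_ratios=(0.5, 1.0, 2.0)
        )
        for L in (64, 100):
            for boxes in sd.generate_anchors(config, L).values():
                areas = (boxes[:, 2] - boxes[:, 0]) * (boxes[:, 3] - boxes[:, 1])
                assert areas.max() <= 0.25 * L * L + 1e-9

    def test_centered_unit_ratio_anchor_geometry(self):
        config = dt.DetectorConfig(
            anchor_scales=(8.0,), anchor_ratios=(1.0,), anchors_per_loc=1
        )
        anchors = sd.generate_anchors(config, 64)[8]
        # location (4, 4) at stride 8 backs onto map coordinate 36
        idx = 4 * 8 + 4
        y0, x0, y1, x1 = anchors[idx]
        assert (y0, x0, y1, x1) == (32.0, 32.0, 40.0, 40.0)


class TestRoiAlign:
    def test_constant_feature_map_pools_to_constant(self):
        fm = np.full((3, 10, 10), 2.5)
        pooled = sd.roi_align(fm, sd.RectRegion(1, 7, 2, 9), 5)
        assert np.allclose(pooled, 2.5)

    def test_single_cell_region_center_sample(self):
        fm = np.arange(16, dtype=float).reshape(1, 4, 4)
        pooled = sd.roi_align(fm, sd.RectRegion(2, 3, 1, 2), 1)
        assert pooled[0, 0, 0] == pytest.approx(fm[0, 2, 1])

    def test_bilinear_midpoint(self):
        fm = np.array([[0.0, 1.0], [0.0, 1.0]])
        pooled = sd.roi_align(fm, np.array([0.0, 0.0, 2.0, 2.0]), 1)
        assert pooled[0, 0] == pytest.approx(0.5)


class TestProposalsAndHeads:
    def test_untrained_model_emits_valid_proposals(self, small_model):
        rng = np.random.default_rng(1)
        x = rng.random((96, 96))
        x = (x + x.T) / 2
        feats = sd.build_feature_pyramid(x, small_model)
        props = sd.propose_regions(feats, small_model)
        config = small_model.config
        assert 0 < len(props) <= config.proposal_cap
        for p in props:
            assert 0.0 <= p.objectness <= 1.0
            r = p.region
            assert 0 <= r.i0 < r.i1 <= 96 and 0 <= r.j0 < r.j1 <= 96
            assert r.area <= config.max_region_area_frac * 96 * 96

    def test_class_distribution_normalised(self, small_model):
        rng = np.random.default_rng(2)
        pooled = rng.random((5, small_model.config.channels + 1, 14, 14))
        probs, _, masks = dt.classify_and_refine(pooled, small_model)
        assert probs.shape == (5, 4)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert masks.shape == (5, 14, 14)

    def test_zero_deltas_decode_to_the_proposal_itself(self):
        ref = np.array([[3.0, 10.0, 9.0, 18.0]])
        out = dt.decode_boxes(ref, np.zeros((1, 4)), 64)
        assert np.allclose(out, ref)

    def test_detect_is_deterministic_and_well_formed(self, small_model):
        rng = np.random.default_rng(3)
        x = rng.random((96, 96))
        x = (x + x.T) / 2
        cmap = sd.ContactMap(id="t", P=np.clip(x, 0, 1))
        d1 = sd.detect(cmap, small_model)
        d2 = sd.detect(cmap, small_model)
        assert [(d.region, d.type, d.score) for d in d1] == [
            (d.region, d.type, d.score) for d in d2
        ]
        for d in d1:
            assert d.type in sd.CONTACT_TYPES
            assert 0.0 <= d.score <= 1.0
            assert d.region.i0 <= d.region.j0  # upper-triangle representative


class TestMultitaskLoss:
    def _preds(self, logits, deltas, masks):
        return dt.HeadPredictions(
            cls_logits=nn.Tensor(logits),
            box_deltas=nn.Tensor(deltas),
            mask_logits=nn.Tensor(masks) if masks is not None else None,
        )

    def test_perfect_predictions_vanish(self):
        big = 50.0
        logits = np.full((2, 4), -big)
        logits[0, 1] = logits[1, 2] = big
        masks = np.full((2, 1, 4, 4), -big)
        masks[:, :, 1, 1] = big
        mask_t = np.zeros((2, 4, 4))
        mask_t[:, 1, 1] = 1.0
        truth = dt.HeadTargets(
            labels=np.array([1, 2]), pos_idx=np.array([0, 1]),
            box_targets=np.zeros((2, 4)), mask_targets=mask_t,
        )
        terms = dt.multitask_loss(
            self._preds(logits, np.zeros((2, 4)), masks), truth, (1.0, 1.0, 0.1)
        )
        assert terms.total.item() == pytest.approx(0.0, abs=1e-6)

    def test_half_probability_gives_ln_two(self):
        logits = np.array([[0.0, 0.0, -1e9, -1e9]])
        truth = dt.HeadTargets(
            labels=np.array([0]), pos_idx=np.array([], dtype=int),
            box_targets=np.zeros((0, 4)), mask_targets=np.zeros((0, 4, 4)),
        )
        terms = dt.multitask_loss(
            self._preds(logits, np.zeros((1, 4)), None), truth, (1.0, 0.0, 0.0)
        )
        assert terms.total.item() == pytest.approx(np.log(2), rel=1e-9)

    def test_mask_weight_scales_only_the_mask_component(self):
        rng = np.random.default_rng(0)
        logits = rng.normal(size=(3, 4))
        deltas = rng.normal(size=(3, 4))
        masks = rng.normal(size=(2, 1, 6, 6))
        truth = dt.HeadTargets(
            labels=np.array([1, 0, 2]), pos_idx=np.array([0, 2]),
            box_targets=rng.normal(size=(2, 4)),
            mask_targets=(rng.random((2, 6, 6)) > 0.5).astype(float),
        )
        t1 = dt.multitask_loss(self._preds(logits, deltas, masks), truth, (1.0, 1.0, 0.1))
        t2 = dt.multitask_loss(self._preds(logits, deltas, masks), truth, (1.0, 1.0, 0.2))
        assert t2.total.item() - t1.total.item() == pytest.approx(0.1 * t1.mask)

    def test_no_positive_assignments_flagged(self):
        truth = dt.HeadTargets(
            labels=np.array([0, 0]), pos_idx=np.array([], dtype=int),
            box_targets=np.zeros((0, 4)), mask_targets=np.zeros((0, 4, 4)),
        )
        terms = dt.multitask_loss(
            self._preds(np.zeros((2, 4)), np.zeros((2, 4)), None),
            truth, (1.0, 1.0, 0.1),
        )
        assert not terms.has_positives
        assert terms.box == 0.0 and terms.mask == 0.0


class TestTraining:
    def test_mask_weight_must_stay_smallest(self):
        with pytest.raises(sd.ConfigError):
            dt.DetectorConfig(loss_weights=(1.0, 1.0, 1.0))
        with pytest.raises(sd.ConfigError):
            dt.DetectorConfig(loss_weights=(0.1, 1.0, 0.5))

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            dt.train([], dt.DetectorConfig())

    def test_loss_descends_on_a_single_sample(self):
        sample = sd.make_dataset(1, sd.SyntheticSpec(seed=5))[0]
        config = dt.DetectorConfig(train=dt.TrainConfig(epochs=50, seed=0))
        model = dt.train([sample], config)
        assert model.history[-1]["total"] < model.history[0]["total"]

    def test_same_seed_reproduces_losses(self):
        dataset = sd.make_dataset(3, sd.SyntheticSpec(seed=6))
        config = dt.DetectorConfig(train=dt.TrainConfig(epochs=2, seed=42))
        m1 = dt.train(dataset, config)
        m2 = dt.train(dataset, config)
        for h1, h2 in zip(m1.history, m2.history):
            assert h1["total"] == pytest.approx(h2["total"], abs=1e-6)

    def test_checkpoint_round_trip_is_bit_exact(self, tmp_path):
        dataset = sd.make_dataset(2, sd.SyntheticSpec(seed=6))
        config = dt.DetectorConfig(train=dt.TrainConfig(epochs=1, seed=1))
        model = dt.train(dataset, config)
        path = tmp_path / "model.npz"
        model.save(path)
        back = dt.DetectorModel.load(path)
        assert back.config == model.config
        assert set(back.params) == set(model.params)
        for k in model.params:
            assert np.array_equal(back.params[k].data, model.params[k].data)
        cmap = dataset[0].map
        a = sd.detect(cmap, model, compute_masks=False)
        b = sd.detect(cmap, back, compute_masks=False)
        assert [(d.region, d.score) for d in a] == [(d.region, d.score) for d in b]


class TestTemplateDetector:
    def test_noise_free_pattern_recovered_exactly(self, noise_free_spec):
        sample = sd.make_dataset(1, noise_free_spec)[0]
        dets = sd.template_detect(sample.map)
        assert dets
        top = dets[0]
        best = max(sample.truth, key=lambda c: sd.iou(top.region, c.region))
        assert sd.iou(top.region, best.region) == 1.0
        assert top.type == best.type
        assert top.score == pytest.approx(1.0)

    def test_all_zero_map_yields_nothing(self):
        assert sd.template_detect(np.zeros((64, 64))) == []

    def test_templates_match_their_own_generator(self):
        t = pattern_template("HH", 8, dash_period=4)
        on = {(i, j) for i, j in zip(*np.nonzero(t))}
        assert on == {(k, 7 - k) for k in range(8) if k % 4 in (0, 1)}

    def test_noisy_f_measure_stays_high(self, default_spec):
        samples = sd.make_dataset(15, default_spec)
        report = None
        for s in samples:
            sel = sd.select_detections(sd.template_detect(s.map))
            r = sd.match_detections(sel, s.truth)
            report = r if report is None else report.merge(r)
        assert report.overall.f_measure >= 0.9
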