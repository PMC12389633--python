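"""Anchors, proposals, RoI pooling, losses, letterboxing, training."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plantdet.detector import (AnchorSpec, Detection, FasterRCNN, RPNSpec,
                               TrainSpec, decode_boxes, encode_boxes,
                               generate_anchors, letterbox_boxes,
                               letterbox_image, letterbox_params, nms, propose,
                               train, unletterbox_boxes)
from plantdet.detector.train import detection_loss, train_step
from plantdet.eval_metrics import box_iou
from plantdet.light_backbone import BackboneSpec
from plantdet.nn import functional as F
from plantdet.nn.tensor import Tensor


def tiny_model(seed=0, input_size=64, classes=("a", "b")):
    spec = BackboneSpec(stage_block_counts=(1, 1, 1, 1),
                        stage_mid_channels=(4, 4, 8, 8), stem_channels=4)
    return FasterRCNN(list(classes), spec, AnchorSpec(scales=(2, 4, 6)),
                      RPNSpec(pre_nms_top_n=200, post_nms_top_n=30),
                      input_size=input_size, rpn_channels=16, seed=seed)


def brute_force_nms(boxes, scores, thr):
    """O(n^2) oracle over the score ordering."""
    order = np.argsort(-np.asarray(scores), kind="stable")
    keep = []
    for i in order:
        if all(box_iou(boxes[i], boxes[j]) <= thr for j in keep):
            keep.append(i)
    return keep


class TestAnchors:
    def test_nine_per_cell(self):
        spec = AnchorSpec()
        assert spec.anchors_per_cell == 9
        assert len(generate_anchors(spec, 2, 3)) == 2 * 3 * 9

    def test_scale16_ratio1_gives_256_square(self):
        spec = AnchorSpec(ratios=(1.0,), scales=(16,), feat_stride=16)
        a = generate_anchors(spec, 1, 1)[0]
        assert a[2] - a[0] == pytest.approx(256.0)
        assert a[3] - a[1] == pytest.approx(256.0)

    def test_38x38_map_yields_12996(self):
        assert len(generate_anchors(AnchorSpec(), 38, 38)) == 12_996

    def test_ratio_preserves_area(self):
        spec = AnchorSpec(ratios=(0.5, 1.0, 2.0), scales=(8,), feat_stride=16)
        anchors = generate_anchors(spec, 1, 1)
        areas = (anchors[:, 2] - anchors[:, 0]) * (anchors[:, 3] - anchors[:, 1])
        np.testing.assert_allclose(areas, areas[0])
        hw = (anchors[:, 3] - anchors[:, 1]) / (anchors[:, 2] - anchors[:, 0])
        np.testing.assert_allclose(hw, [0.5, 1.0, 2.0])

    def test_invalid_map_dims(self):
        with pytest.raises(ValueError):
            generate_anchors(AnchorSpec(), 0, 4)


class TestBoxCoding:
    def test_encode_decode_round_trip(self, rng):
        anchors = np.array([[0, 0, 32, 32], [16, 16, 64, 48]], dtype=float)
        gt = np.array([[4, 2, 30, 36], [20, 10, 70, 44]], dtype=float)
        deltas = encode_boxes(anchors, gt)
        np.testing.assert_allclose(decode_boxes(anchors, deltas), gt, atol=1e-9)


class TestNMS:
    def test_identical_boxes_keep_one(self):
        boxes = np.array([[0, 0, 10, 10], [0, 0, 10, 10]], dtype=float)
        assert len(nms(boxes, np.array([0.9, 0.8]), 0.7)) == 1

    def test_disjoint_boxes_all_survive(self):
        boxes = np.array([[0, 0, 10, 10], [20, 20, 30, 30], [50, 0, 60, 10]],
                         dtype=float)
        assert len(nms(boxes, np.array([0.5, 0.9, 0.7]), 0.7)) == 3

    def test_matches_oracle_20_random(self, rng):
        boxes = np.stack([rng.uniform(0, 50, 20), rng.uniform(0, 50, 20),
                          np.zeros(20), np.zeros(20)], axis=1)
        boxes[:, 2] = boxes[:, 0] + rng.uniform(5, 30, 20)
        boxes[:, 3] = boxes[:, 1] + rng.uniform(5, 30, 20)
        scores = rng.uniform(0, 1, 20)
        got = sorted(nms(boxes, scores, 0.5).tolist())
        assert got == sorted(brute_force_nms(boxes, scores, 0.5))

    @given(st.integers(1, 50), st.integers(0, 10_000),
           st.floats(0.2, 0.8))
    @settings(max_examples=50, deadline=None)
    def test_oracle_equivalence_property(self, n, seed, thr):
        rng = np.random.default_rng(seed)
        x1 = rng.uniform(0, 60, n)
        y1 = rng.uniform(0, 60, n)
        boxes = np.stack([x1, y1, x1 + rng.uniform(1, 40, n),
                          y1 + rng.uniform(1, 40, n)], axis=1)
        scores = rng.uniform(0, 1, n)
        assert sorted(nms(boxes, scores, thr).tolist()) == \
            sorted(brute_force_nms(boxes, scores, thr))


class TestPropose:
    def test_clipping_and_nms(self):
        anchors = np.array([[0, 0, 10, 10], [0, 0, 10, 10], [30, 30, 40, 40]],
                           dtype=float)
        obj = np.array([0.9, 0.8, 0.7])
        deltas = np.zeros((3, 4))
        boxes, scores = propose(obj, deltas, anchors, RPNSpec(), 64)
        assert len(boxes) == 2  # duplicates collapse
        assert (boxes >= 0).all() and (boxes <= 64).all()

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            propose(np.zeros(3), np.zeros((2, 4)), np.zeros((3, 4)),
                    RPNSpec(), 64)

    def test_degenerate_boxes_dropped(self):
        anchors = np.array([[-100, -100, -90, -90]], dtype=float)  # clips away
        boxes, _ = propose(np.array([0.9]), np.zeros((1, 4)), anchors,
                           RPNSpec(), 64)
        assert len(boxes) == 0


class TestRoIPool:
    def test_whole_map_1x1_is_global_max(self, rng):
        feat = Tensor(rng.normal(size=(1, 3, 8, 8)).astype(np.float32))
        out = F.roi_max_pool(feat, np.array([[0.0, 0.0, 8.0, 8.0]]), 1)
        np.testing.assert_allclose(out.numpy()[0, :, 0, 0],
                                   feat.numpy()[0].max(axis=(1, 2)))

    def test_identity_when_bins_match_cells(self, rng):
        feat = Tensor(rng.normal(size=(1, 2, 4, 4)).astype(np.float32))
        out = F.roi_max_pool(feat, np.array([[0.0, 0.0, 4.0, 4.0]]), 4)
        np.testing.assert_allclose(out.numpy()[0], feat.numpy()[0])

    def test_matches_per_bin_oracle(self, rng):
        feat = Tensor(rng.normal(size=(1, 2, 8, 8)).astype(np.float32))
        out = F.roi_max_pool(feat, np.array([[0.0, 0.0, 8.0, 8.0]]), 2)
        f = feat.numpy()[0]
        for c in range(2):
            for i in range(2):
                for j in range(2):
                    ref = f[c, i * 4:(i + 1) * 4, j * 4:(j + 1) * 4].max()
                    assert out.numpy()[0, c, i, j] == ref

    def test_empty_roi_clamped_not_error(self, rng):
        feat = Tensor(rng.normal(size=(1, 2, 8, 8)).astype(np.float32))
        out = F.roi_max_pool(feat, np.array([[3.0, 3.0, 3.0, 3.0]]), 2)
        assert out.shape == (1, 2, 2, 2)
        assert np.isfinite(out.numpy()).all()


class TestDetectionLoss:
    def test_perfect_one_hot_zero_cls_loss(self):
        logits = np.full((2, 3), -40.0)
        logits[0, 1] = 40.0
        logits[1, 2] = 40.0
        losses = detection_loss(Tensor(logits), Tensor(np.zeros((2, 4))),
                                np.array([1, 2]), np.zeros(2, dtype=bool),
                                np.zeros((0, 4)))
        assert float(losses["cls"].data) == pytest.approx(0.0, abs=1e-6)

    def test_exact_deltas_zero_box_loss(self, rng):
        deltas = rng.normal(size=(3, 4))
        losses = detection_loss(Tensor(rng.normal(size=(3, 3))),
                                Tensor(deltas), np.array([1, 1, 2]),
                                np.ones(3, dtype=bool), deltas)
        assert float(losses["reg"].data) == 0.0

    def test_uniform_scores_log6(self):
        losses = detection_loss(Tensor(np.zeros((4, 6))),
                                Tensor(np.zeros((4, 4))), np.zeros(4, dtype=int),
                                np.zeros(4, dtype=bool), np.zeros((0, 4)))
        assert float(losses["cls"].data) == pytest.approx(np.log(6), rel=1e-6)

    def test_no_positives_still_defined(self):
        losses = detection_loss(Tensor(np.zeros((2, 3))), Tensor(np.zeros((2, 4))),
                                np.array([0, 0]), np.zeros(2, dtype=bool),
                                np.zeros((0, 4)))
        assert losses["reg"] is None
        assert float(losses["total"].data) > 0


class TestLetterbox:
    def test_portrait_maps_into_unpadded_region(self):
        scale, px, py, nw, nh = letterbox_params(300, 600, 600)
        assert (nw, nh) == (300, 600)
        assert px == 150 and py == 0
        boxes = letterbox_boxes(np.array([[0.0, 0.0, 300.0, 600.0]]), scale, px, py)
        np.testing.assert_allclose(boxes, [[150, 0, 450, 600]])
        back = unletterbox_boxes(boxes, scale, px, py, 300, 600)
        np.testing.assert_allclose(back, [[0, 0, 300, 600]])

    def test_image_canvas_and_fill(self, rng):
        img = rng.integers(0, 255, size=(60, 30, 3), dtype=np.uint8)
        out, (scale, px, py) = letterbox_image(img, 64)
        assert out.shape == (64, 64, 3)
        assert scale == pytest.approx(64 / 60)
        # padding columns are gray
        assert (out[:, 0] == 128).all()


class TestTraining:
    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            train(tiny_model(), [])

    def test_zero_lr_leaves_params_unchanged(self, rng):
        model = tiny_model()
        before = {k: v.copy() for k, v in model.state_dict().items()
                  if not k.endswith(("running_mean", "running_var"))}
        img = rng.integers(0, 255, size=(64, 64, 3), dtype=np.uint8)
        data = [(img, np.array([[10.0, 10.0, 40.0, 40.0]]), np.array([0]))]
        spec = TrainSpec(input_size=64, learning_rate=0.0, batch_size=1,
                         max_steps=1, rpn_batch=16, roi_batch=8)
        train(model, data, spec, seed=0)
        after = model.state_dict()
        for k, v in before.items():
            np.testing.assert_array_equal(v, after[k])

    def test_same_seed_identical_traces(self, rng):
        img = rng.integers(0, 255, size=(64, 64, 3), dtype=np.uint8)
        data = [(img, np.array([[8.0, 8.0, 44.0, 44.0]]), np.array([1]))]
        spec = TrainSpec(input_size=64, learning_rate=1e-3, batch_size=1,
                         max_steps=3, rpn_batch=16, roi_batch=8)
        t1 = train(tiny_model(seed=4), data, spec, seed=11)
        t2 = train(tiny_model(seed=4), data, spec, seed=11)
        assert t1 == t2

    def test_loss_decreases_30_steps(self):
        from plantdet.synthetic_fixtures import SceneSpec, make_scene

        classes = ("a", "b")
        model = tiny_model(input_size=64, classes=classes)
        data = []
        for i in range(5):
            img, ann = make_scene(SceneSpec(width=64, height=64, n_objects=1,
                                            class_names=("Acanthus mollis",),
                                            min_object_frac=0.5,
                                            max_object_frac=0.7, seed=i))
            boxes = np.array([o.xyxy() for o in ann.objects])
            data.append((img, boxes, np.zeros(len(boxes), dtype=int)))
        spec = TrainSpec(input_size=64, learning_rate=1e-3, batch_size=1,
                         max_steps=30, rpn_batch=32, roi_batch=16)
        trace = train(model, data, spec, seed=0)
        assert trace[-1] < trace[0]


class TestPredict:
    def test_threshold_one_gives_empty(self, rng):
        model = tiny_model()
        img = rng.integers(0, 255, size=(64, 64, 3), dtype=np.uint8)
        assert model.predict(img, score_threshold=1.0) == []

    def test_untrained_boxes_inside_image(self, rng):
        model = tiny_model()
        img = rng.integers(0, 255, size=(50, 80, 3), dtype=np.uint8)
        dets = model.predict(img, score_threshold=0.0)
        for d in dets:
            x1, y1, x2, y2 = d.box
            assert 0 <= x1 < x2 <= 80
            assert 0 <= y1 < y2 <= 50
            assert 0 <= d.score <= 1

    def test_detection_validation(self):
        with pytest.raises(ValueError):
            Detection((10, 10, 5, 20), "x", 0.5)
        with pytest.raises(ValueError):
            Detection((0, 0, 5, 5), "x", 1.5)

    def test_checkpoint_round_trip(self, tmp_path, rng):
        model = tiny_model(seed=3)
        path = tmp_path / "m.pkl"
        model.save(path)
        other = tiny_model(seed=99)
        other.load(path)
        img = rng.integers(0, 255, size=(64, 64, 3), dtype=np.uint8)
        d1 = model.predict(img, score_threshold=0.0)
        d2 = other.predict(img, score_threshold=0.0)
        assert [(d.box, d.label, d.score) for d in d1] == \
            [(d.box, d.label, d.score) for d in d2]
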