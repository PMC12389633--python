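"""Detection metrics: matching, P/R/F1, AP, summaries, deltas."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plantdet.eval_metrics import (ClassMetrics, MatchResult, average_precision,
                                   ablation_deltas, box_iou, match_detections,
                                   precision_recall_f1, round_half_up,
                                   summarize, Summary, evaluate)


def greedy_match_oracle(dets, gts, iou_thr):
    """Independent re-implementation: plain loops, no arrays."""
    order = sorted(dets, key=lambda d: -d[1])
    matched = set()
    tp = 0
    for img, _score, box in order:
        best_iou, best_j = -1.0, None
        for j, (gimg, gbox) in enumerate(gts):
            if gimg != img or j in matched:
                continue
            iou = box_iou(box, gbox)
            if iou > best_iou:
                best_iou, best_j = iou, j
        if best_j is not None and best_iou >= iou_thr:
            matched.add(best_j)
            tp += 1
    return MatchResult(tp, len(dets) - tp, len(gts) - tp)


def random_boxes(rng, n, span=50):
    x1 = rng.uniform(0, span, n)
    y1 = rng.uniform(0, span, n)
    return np.stack([x1, y1, x1 + rng.uniform(1, span, n),
                     y1 + rng.uniform(1, span, n)], axis=1)


class TestMatchDetections:
    def test_perfect_detections(self):
        gts = [(0, (0, 0, 10, 10)), (0, (20, 20, 30, 30))]
        dets = [(0, 0.9, (0, 0, 10, 10)), (0, 0.8, (20, 20, 30, 30))]
        m = match_detections(dets, gts, 0.5)
        assert (m.tp, m.fp, m.fn) == (2, 0, 0)

    def test_duplicate_is_fp(self):
        gts = [(0, (0, 0, 10, 10))]
        dets = [(0, 0.9, (0, 0, 10, 10)), (0, 0.8, (1, 1, 11, 11))]
        m = match_detections(dets, gts, 0.5)
        assert (m.tp, m.fp, m.fn) == (1, 1, 0)

    def test_matches_exhaustive_oracle_fixture(self, rng):
        gts = [(0, tuple(b)) for b in random_boxes(rng, 3)]
        dets = [(0, float(s), tuple(b))
                for s, b in zip(rng.uniform(0, 1, 6), random_boxes(rng, 6))]
        got = match_detections([(d[0], d[1], d[2]) for d in dets], gts, 0.5)
        assert got == greedy_match_oracle(dets, gts, 0.5)

    @given(st.integers(0, 8), st.integers(0, 8), st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_oracle_equivalence_property(self, n_dets, n_gts, seed):
        rng = np.random.default_rng(seed)
        gts = [(int(rng.integers(2)), tuple(b)) for b in random_boxes(rng, n_gts)]
        dets = [(int(rng.integers(2)), float(s), tuple(b))
                for s, b in zip(rng.uniform(0, 1, n_dets),
                                random_boxes(rng, n_dets))]
        got = match_detections(dets, gts, 0.5)
        assert got == greedy_match_oracle(dets, gts, 0.5)
        assert got.tp + got.fn == n_gts  # per-class gt conservation


class TestPrecisionRecallF1:
    def test_paper_row_cirsium(self):
        """P 75.00%, R 66.67% -> F1 0.71 (2 dp)."""
        cm = ClassMetrics("c", 0.7500, 0.6667, 0.0)
        f1 = 2 * cm.precision * cm.recall / (cm.precision + cm.recall)
        assert round_half_up(f1, 2) == 0.71

    def test_paper_row_acanthus(self):
        """P 32.00%, R 80.00% -> F1 0.46 (2 dp)."""
        f1 = 2 * 0.32 * 0.80 / (0.32 + 0.80)
        assert round_half_up(f1, 2) == 0.46

    def test_equal_p_r_gives_f1_p(self):
        m = MatchResult(tp=3, fp=1, fn=1)
        cm = precision_recall_f1(m)
        assert cm.precision == cm.recall == cm.f1 == 0.75

    def test_zero_denominators(self):
        cm = precision_recall_f1(MatchResult(0, 0, 0))
        assert (cm.precision, cm.recall, cm.f1) == (0.0, 0.0, 0.0)

    def test_counts_formula(self):
        cm = precision_recall_f1(MatchResult(tp=6, fp=2, fn=3))
        assert cm.precision == pytest.approx(6 / 8)
        assert cm.recall == pytest.approx(6 / 9)


class TestAveragePrecision:
    def test_single_perfect_detection(self):
        gts = [(0, (0, 0, 10, 10))]
        dets = [(0, 0.9, (0, 0, 10, 10))]
        assert average_precision(dets, gts, 0.5) == 1.0

    def test_no_detections(self):
        assert average_precision([], [(0, (0, 0, 10, 10))], 0.5) == 0.0

    def test_hand_computed_step_integral(self):
        """5 dets / 3 gts; ranking TP,FP,TP,FP,TP -> AP = 34/45."""
        gts = [(0, (0, 0, 10, 10)), (0, (20, 0, 30, 10)), (0, (40, 0, 50, 10))]
        dets = [(0, 0.9, (0, 0, 10, 10)),
                (0, 0.8, (100, 100, 110, 110)),
                (0, 0.7, (20, 0, 30, 10)),
                (0, 0.6, (0.5, 0, 10.5, 10)),   # duplicate hit on gt 1
                (0, 0.5, (40, 0, 50, 10))]
        ap = average_precision(dets, gts, 0.5)
        assert ap == pytest.approx(34 / 45)

    def test_monotone_score_transform_invariance(self, rng):
        gts = [(0, tuple(b)) for b in random_boxes(rng, 4)]
        scores = rng.uniform(0.1, 0.9, 7)
        boxes = random_boxes(rng, 7)
        dets = [(0, float(s), tuple(b)) for s, b in zip(scores, boxes)]
        dets2 = [(0, float(s) ** 3, tuple(b)) for s, b in zip(scores, boxes)]
        assert average_precision(dets, gts, 0.5) == \
            pytest.approx(average_precision(dets2, gts, 0.5))

    def test_low_fp_never_increases_ap(self, rng):
        gts = [(0, tuple(b)) for b in random_boxes(rng, 3)]
        dets = [(0, float(s), tuple(b))
                for s, b in zip(rng.uniform(0.5, 1.0, 5), random_boxes(rng, 5))]
        base = average_precision(dets, gts, 0.5)
        worse = dets + [(0, 0.01, (900.0, 900.0, 910.0, 910.0))]
        assert average_precision(worse, gts, 0.5) <= base + 1e-12

    @given(st.integers(0, 12), st.integers(1, 6), st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None)
    def test_ap_in_unit_interval(self, n_dets, n_gts, seed):
        rng = np.random.default_rng(seed)
        gts = [(0, tuple(b)) for b in random_boxes(rng, n_gts)]
        dets = [(0, float(s), tuple(b))
                for s, b in zip(rng.uniform(0, 1, n_dets),
                                random_boxes(rng, n_dets))]
        assert 0.0 <= average_precision(dets, gts, 0.5) <= 1.0

    def test_eleven_point_close_to_all_point(self):
        gts = [(0, (0, 0, 10, 10))]
        dets = [(0, 0.9, (0, 0, 10, 10))]
        assert average_precision(dets, gts, 0.5, eleven_point=True) == \
            pytest.approx(1.0)


class TestSummarize:
    def test_paper_map_full_scheme(self):
        """Mean of printed per-class APs: 63.98% (2 dp)."""
        aps = [78.60, 68.33, 53.30, 46.91, 72.74]
        per_class = [ClassMetrics(str(i), 0, 0, 0, ap=a / 100)
                     for i, a in enumerate(aps)]
        s = summarize(per_class)
        assert round_half_up(s.m_ap * 100, 2) == 63.98

    def test_paper_mprecision_full_scheme(self):
        """Mean of printed per-class precisions: 39.27% (2 dp)."""
        ps = [40.00, 75.00, 20.59, 30.77, 30.00]
        per_class = [ClassMetrics(str(i), p / 100, 0, 0) for i, p in enumerate(ps)]
        assert round_half_up(summarize(per_class).m_precision * 100, 2) == 39.27

    def test_single_class(self):
        s = summarize([ClassMetrics("a", 0.4, 0.5, 0.44, ap=0.6)])
        assert (s.m_precision, s.m_recall, s.m_f1, s.m_ap) == (0.4, 0.5, 0.44, 0.6)

    def test_mean_within_min_max(self, rng):
        per_class = [ClassMetrics(str(i), *rng.uniform(0, 1, 3), ap=rng.uniform())
                     for i in range(5)]
        s = summarize(per_class)
        aps = [c.ap for c in per_class]
        assert min(aps) <= s.m_ap <= max(aps)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize([])


class TestAblationDeltas:
    def test_paper_acanthus_ap_improvement(self):
        """AP 51.66% -> 78.60% is +26.94%."""
        d = ablation_deltas({"ap": 51.66}, {"ap": 78.60})
        assert d["ap"]["abs"] == pytest.approx(26.94)

    def test_paper_wild_leek_relative_increase(self):
        """AP 16.42% -> 36.37% is a relative increase of 121.5% (1 dp)."""
        d = ablation_deltas({"ap": 16.42}, {"ap": 36.37})
        assert round_half_up(d["ap"]["rel"] * 100, 1) == 121.5

    def test_identical_summaries_zero(self):
        s = Summary(0.5, 0.4, 0.3, 0.35, 5)
        d = ablation_deltas(s, s)
        assert all(v["abs"] == 0 and v["rel"] == 0 for v in d.values())

    def test_zero_baseline_undefined(self):
        d = ablation_deltas({"ap": 0.0}, {"ap": 0.3})
        assert d["ap"]["rel"] is None

    def test_mismatched_metrics_rejected(self):
        with pytest.raises(ValueError):
            ablation_deltas({"a": 1}, {"b": 1})


class TestEvaluate:
    def test_end_to_end_counts(self):
        gts = [(0, "rose", (0, 0, 10, 10)), (0, "fern", (20, 20, 30, 30)),
               (1, "rose", (5, 5, 15, 15))]
        dets = [(0, "rose", 0.9, (0, 0, 10, 10)),
                (1, "rose", 0.8, (5, 5, 15, 15)),
                (0, "fern", 0.7, (20, 20, 30, 30)),
                (1, "fern", 0.6, (50, 50, 60, 60))]
        per_class, summary = evaluate(dets, gts, iou_thr=0.5, score_thr=0.5)
        by_name = {c.class_name: c for c in per_class}
        assert by_name["rose"].ap == 1.0
        assert by_name["fern"].fp == 1
        assert summary.n_classes == 2
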