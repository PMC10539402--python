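"""SVM classification, diameter gating, ROC/AUC, group tests, fouling QC."""

import numpy as np
import pytest

from cdcyto import benchmarks, stratify, tracking
from cdcyto.device import build_geometry
from cdcyto.errors import InputError
from cdcyto.rheology import DEFAULT_C2_UM, forward_creep_time
from cdcyto.stratify import (
    diameter_gate,
    fouling_qc,
    group_tests,
    roc_auc,
    significance_stars,
    svm_classify,
)


def _benchmark_features(rng, n=250):
    """Two populations with distinct creep-driven passage times and
    overlapping sizes (the default synthetic benchmark conditions)."""
    def one(c1_med):
        a = rng.uniform(547.1357, 1034.096, n)
        c1 = c1_med * np.exp(rng.normal(0, np.log(1.25), n))
        t = forward_creep_time(a, c1, 0.5, DEFAULT_C2_UM)
        pt = t + 0.06 + rng.normal(0, 0.005, n)  # transit + timing noise
        aic = a * (1 + rng.normal(0, 0.02, n))
        return np.column_stack([pt, a, aic])

    x = np.vstack([one(0.48), one(0.12)])
    y = np.array(["stiff"] * n + ["soft"] * n)
    return x, y


class TestSVM:
    def test_separable_clusters_perfect_accuracy(self, rng):
        x = np.vstack([rng.normal(0, 0.2, (40, 2)), rng.normal(5, 0.2, (40, 2))])
        y = np.array([0] * 40 + [1] * 40)
        assert svm_classify(x, y, seed=0).accuracy == 1.0

    def test_null_case_near_chance(self, rng):
        x = rng.normal(0, 1, (200, 3))
        y = np.array([0, 1] * 100)
        acc = svm_classify(x, y, seed=0).accuracy
        assert 0.35 <= acc <= 0.65

    def test_single_class_raises(self, rng):
        with pytest.raises(InputError):
            svm_classify(rng.normal(size=(20, 2)), np.zeros(20), seed=0)

    def test_benchmark_accuracy_above_preregistered_bound(self, rng):
        x, y = _benchmark_features(rng)
        res = svm_classify(x, y, seed=0)
        assert res.accuracy >= 0.9
        assert res.hyperparams["kernel"] == "poly"
        assert res.hyperparams["degree"] == 3

    def test_adding_morphometric_features_does_not_hurt(self, rng):
        # passage time alone vs passage time + size + area-in-constriction:
        # extra features may not reduce CV accuracy by more than the CI half-width
        x, y = _benchmark_features(rng)
        acc1 = svm_classify(x[:, :1], y, seed=0)
        acc3 = svm_classify(x, y, seed=0)
        half_width = 1.96 * acc1.fold_scores.std(ddof=1) / np.sqrt(len(acc1.fold_scores))
        assert acc3.accuracy >= acc1.accuracy - half_width


class TestDiameterGate:
    def test_fully_separated(self):
        d = [8, 9, 10, 15, 16, 17]
        y = [0, 0, 0, 1, 1, 1]
        thr, acc = diameter_gate(d, y)
        assert acc == 1.0
        assert 10 < thr < 15

    def test_null_distributions_near_chance(self, rng):
        d = rng.normal(10, 1, 400)
        y = rng.integers(0, 2, 400)
        _, acc = diameter_gate(d, y)
        assert 0.5 <= acc <= 0.62

    def test_matches_exhaustive_scan_on_toy_set(self):
        d = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0, 10.0])
        y = np.array([0, 0, 1, 0, 1, 1, 0, 1, 1, 1])
        thr, acc = diameter_gate(d, y)
        # brute force over every cut position and both orientations
        best = 0.0
        for cut in np.concatenate([[0.5], (d[:-1] + d[1:]) / 2, [10.5]]):
            pred = d > cut
            best = max(best, (pred == y).mean(), (pred == (1 - y)).mean())
        assert acc == pytest.approx(best)

    def test_never_worse_than_prevalence(self, rng):
        for _ in range(10):
            d = rng.normal(10, 2, 60)
            y = rng.integers(0, 2, 60)
            if len(np.unique(y)) < 2:
                continue
            _, acc = diameter_gate(d, y)
            prevalence = max(np.mean(y), 1 - np.mean(y))
            assert acc >= prevalence

    def test_single_class_raises(self):
        with pytest.raises(InputError):
            diameter_gate([1.0, 2.0], [0, 0])


class TestRocAuc:
    def test_perfect_ranking(self):
        auc, _ = roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert auc == 1.0

    def test_null_near_half(self, rng):
        scores = rng.normal(size=2000)
        labels = rng.integers(0, 2, 2000)
        auc, _ = roc_auc(scores, labels)
        assert auc == pytest.approx(0.5, abs=0.05)

    def test_equals_normalized_u_on_toy_set(self):
        scores = [0.1, 0.4, 0.35, 0.8, 0.7, 0.2]
        labels = [0, 0, 1, 1, 1, 0]
        auc, _ = roc_auc(scores, labels)
        pos = [s for s, l in zip(scores, labels) if l == 1]
        neg = [s for s, l in zip(scores, labels) if l == 0]
        u = sum(1.0 if p > q else 0.5 if p == q else 0.0 for p in pos for q in neg)
        assert auc == pytest.approx(u / (len(pos) * len(neg)))

    def test_u_oracle_with_ties_4v4(self):
        scores = [1.0, 2.0, 2.0, 3.0, 2.0, 3.0, 4.0, 5.0]
        labels = [0, 0, 0, 0, 1, 1, 1, 1]
        auc, _ = roc_auc(scores, labels)
        pos, neg = scores[4:], scores[:4]
        u = sum(1.0 if p > q else 0.5 if p == q else 0.0 for p in pos for q in neg)
        assert auc == pytest.approx(u / 16.0)

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.normal(size=100)
        labels = rng.integers(0, 2, 100)
        auc1, _ = roc_auc(scores, labels)
        auc2, _ = roc_auc(np.exp(3 * scores) + 7, labels)
        assert auc1 == pytest.approx(auc2, abs=1e-12)


class TestGroupTests:
    def test_identical_groups_not_significant(self, rng):
        vals = rng.normal(0, 1, 40)
        out = group_tests({"a": vals, "b": vals.copy()})
        assert out[0].t_stars == "ns" and out[0].mw_stars == "ns"

    def test_extreme_separation_four_stars(self, rng):
        out = group_tests({"a": rng.normal(0, 1, 50), "b": rng.normal(10, 1, 50)})
        assert out[0].t_stars == "****" and out[0].mw_stars == "****"

    def test_all_pairs_compared(self, rng):
        groups = {k: rng.normal(0, 1, 10) for k in "abcd"}
        out = group_tests(groups)
        assert len(out) == 6

    def test_small_group_skipped_with_warning(self, rng):
        with pytest.warns(UserWarning, match="skipped"):
            out = group_tests({"a": rng.normal(0, 1, 10), "b": [1.0]})
        assert out == []

    def test_star_convention_boundaries(self):
        assert significance_stars(0.06) == "ns"
        assert significance_stars(0.05) == "ns"  # strictly below 0.05 earns a star
        assert significance_stars(0.049) == "*"
        assert significance_stars(0.009) == "**"
        assert significance_stars(0.0009) == "***"
        assert significance_stars(0.00009) == "****"

    def test_holm_correction_is_conservative(self, rng):
        groups = {k: rng.normal(i * 0.5, 1, 30) for i, k in enumerate("abc")}
        plain = group_tests(groups)
        holm = group_tests(groups, holm=True)
        for p, h in zip(plain, holm):
            assert h.t_p >= p.t_p


def _stalled_track(cid, geom, n_frames=400, track_id=0):
    x = float(geom.entrance_x[cid]) + geom.constriction_length_px / 2
    y = float(geom.lane_y[cid])
    hist = [(f, (x - 5, y - 5, x + 5, y + 5), (x, y)) for f in range(n_frames)]
    return tracking.Track(track_id=track_id, history=hist, state="confirmed")


class TestFoulingQC:
    def test_clean_run_keeps(self, rng):
        geom = build_geometry()
        # a normally transiting cell: brief stay inside the constriction
        x0 = float(geom.entrance_x[0])
        hist = [
            (f, (x0 + f - 5, 20, x0 + f + 5, 40), (x0 + f, float(geom.lane_y[0])))
            for f in range(30)
        ]
        t = tracking.Track(track_id=0, history=hist, state="confirmed")
        res = fouling_qc([t], geom, fps=988.0, stall_frames_threshold=100)
        assert res.verdict == "keep" and res.fouled_constrictions == []

    def test_exactly_three_fouled_keeps(self):
        geom = build_geometry()
        tracks = [_stalled_track(cid, geom, track_id=cid) for cid in (0, 1, 2)]
        res = fouling_qc(tracks, geom, fps=988.0, stall_frames_threshold=100)
        assert res.fouled_by_group[0] == 3
        assert res.verdict == "keep"  # the rule is "over 3"

    def test_four_fouled_in_one_group_discards(self):
        geom = build_geometry()
        tracks = [_stalled_track(cid, geom, track_id=cid) for cid in (0, 1, 2, 3)]
        res = fouling_qc(tracks, geom, fps=988.0, stall_frames_threshold=100)
        assert res.fouled_by_group[0] == 4
        assert res.verdict == "discard"

    def test_four_fouled_across_groups_keeps(self):
        geom = build_geometry()
        tracks = [
            _stalled_track(cid, geom, track_id=i)
            for i, cid in enumerate((0, 9, 18, 27))  # one per group
        ]
        res = fouling_qc(tracks, geom, fps=988.0, stall_frames_threshold=100)
        assert res.verdict == "keep"

    def test_interrupted_stay_not_fouled(self):
        geom = build_geometry()
        x = float(geom.entrance_x[0]) + 10
        y = float(geom.lane_y[0])
        hist = []
        for f in range(200):
            xx = x if f % 50 != 0 else x - 200  # leaves the span periodically
            hist.append((f, (xx - 5, y - 5, xx + 5, y + 5), (xx, y)))
        t = tracking.Track(track_id=0, history=hist, state="confirmed")
        res = fouling_qc([t], geom, fps=988.0, stall_frames_threshold=60)
        assert res.verdict == "keep" and res.fouled_constrictions == []
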