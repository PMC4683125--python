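"""AUC, aggregation, binary, stability, funnel and discrimination metrics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nabench import metrics
from nabench.binding_annotation import BindingAnnotation
from nabench.metrics import (
    ConfusionCounts,
    PerProteinEval,
    aggregate_auc,
    binary_metrics,
    confusion_counts,
    discrimination_auc,
    evaluate_protein,
    funnel_correlation,
    min_performance,
    pooled_auc,
    roc_auc,
    sauc,
    stability,
)
from nabench.prediction_io import PredictionSet


def brute_force_auc(scores, labels):
    """Independent oracle: count positive–negative pairs, ties scored ½."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    if not pos or not neg:
        return None
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestRocAuc:
    @pytest.mark.parametrize(
        "scores,labels,expected",
        [
            ([0.9, 0.8, 0.1], [1, 1, 0], 1.0),
            ([0.5, 0.5, 0.5, 0.5], [1, 0, 1, 0], 0.5),  # all ties → midrank ½
            ([0.8, 0.6, 0.6, 0.2], [1, 0, 1, 0], 0.875),
            ([0.1, 0.9], [1, 0], 0.0),  # perfectly inverted
        ],
    )
    def test_known_values(self, scores, labels, expected):
        assert roc_auc(scores, labels) == pytest.approx(expected, abs=1e-12)

    def test_single_class_undefined(self):
        assert roc_auc([0.1, 0.9], [1, 1]) is None
        assert roc_auc([0.1, 0.9], [0, 0]) is None

    def test_equals_pair_counting_oracle_on_1000_random_instances(self):
        """Mann–Whitney midrank formulation ≡ brute-force pair counting,
        exact, over 1,000 seeded instances with heavy ties."""
        rng = np.random.default_rng(2024)
        for _ in range(1000):
            n = int(rng.integers(2, 51))
            scores = rng.integers(0, 6, size=n) / 5.0  # coarse grid → ties
            labels = rng.integers(0, 2, size=n)
            expected = brute_force_auc(scores.tolist(), labels.tolist())
            got = roc_auc(scores, labels)
            if expected is None:
                assert got is None
            else:
                assert got == pytest.approx(expected, abs=1e-12)

    def test_agrees_with_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(7)
        for _ in range(50):
            n = int(rng.integers(4, 40))
            scores = rng.normal(size=n)
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                continue
            assert roc_auc(scores, labels) == pytest.approx(
                roc_auc_score(labels, scores), abs=1e-12
            )

    def test_complement_symmetry(self):
        rng = np.random.default_rng(3)
        scores = rng.integers(0, 4, size=30) / 3.0
        labels = np.array([1] * 12 + [0] * 18)
        a = roc_auc(scores, labels)
        b = roc_auc(scores, 1 - labels)
        assert a + b == pytest.approx(1.0, abs=1e-12)


class TestAggregation:
    def _ev(self, auc, length, pid="p"):
        n_pos = max(1, length // 4)
        return PerProteinEval(pid, auc, length, n_pos, length - n_pos)

    @pytest.mark.parametrize(
        "aucs,lengths,wauc,mauc",
        [
            ([1.0, 0.5], [100, 100], 0.75, 0.75),
            ([1.0, 0.5], [300, 100], 0.875, 0.75),
            ([0.63], [80], 0.63, 0.63),
        ],
    )
    def test_weighted_and_unweighted_means(self, aucs, lengths, wauc, mauc):
        evals = [self._ev(a, l, f"p{i}") for i, (a, l) in enumerate(zip(aucs, lengths))]
        agg = aggregate_auc(evals)
        assert agg.wauc == pytest.approx(wauc)
        assert agg.mauc == pytest.approx(mauc)

    def test_undefined_auc_excluded_and_counted(self):
        evals = [self._ev(0.8, 100), self._ev(None, 500), self._ev(0.6, 100)]
        agg = aggregate_auc(evals)
        assert agg.wauc == pytest.approx(0.7)  # the 500-residue protein is out
        assert agg.n_excluded_undefined_auc == 1
        assert agg.n_proteins == 2

    def test_all_undefined_is_an_error(self):
        with pytest.raises(ValueError):
            aggregate_auc([self._ev(None, 100)])

    @settings(max_examples=50, deadline=None)
    @given(
        aucs=st.lists(st.floats(0.0, 1.0), min_size=1, max_size=12),
        length=st.integers(10, 500),
    )
    def test_wauc_equals_mauc_for_equal_lengths(self, aucs, length):
        evals = [self._ev(a, length, f"p{i}") for i, a in enumerate(aucs)]
        agg = aggregate_auc(evals)
        assert agg.wauc == pytest.approx(agg.mauc, abs=1e-12)

    def test_means_bounded_by_extremes(self):
        evals = [self._ev(a, l) for a, l in [(0.4, 10), (0.9, 300), (0.7, 50)]]
        agg = aggregate_auc(evals)
        assert 0.4 <= agg.mauc <= 0.9
        assert 0.4 <= agg.wauc <= 0.9

    def test_pooled_auc_mixes_all_residues(self):
        per = [([1.0, 0.0], [1, 0]), ([0.4, 0.3], [1, 0])]
        # pooled: positives {1.0, 0.4}, negatives {0.0, 0.3}
        assert pooled_auc(per) == pytest.approx(
            brute_force_auc([1.0, 0.0, 0.4, 0.3], [1, 0, 1, 0])
        )


class TestSauc:
    @pytest.mark.parametrize(
        "aucs,expected",
        [
            ([0.8, 0.8, 0.8], 0.0),
            ([0.7, 0.9], math.sqrt(0.02)),  # 0.141421…
            ([0.5, 0.6, 0.7], 0.1),
        ],
    )
    def test_sample_standard_deviation(self, aucs, expected):
        evals = [PerProteinEval(f"p{i}", a, 100, 20, 80) for i, a in enumerate(aucs)]
        assert sauc(evals) == pytest.approx(expected, abs=1e-12)

    def test_fewer_than_two_defined_is_undefined(self):
        evals = [PerProteinEval("p", 0.7, 100, 20, 80),
                 PerProteinEval("q", None, 100, 20, 80)]
        assert sauc(evals) is None


class TestBinaryMetrics:
    def test_hand_computed_case(self):
        m = binary_metrics(ConfusionCounts(tp=3, tn=5, fp=1, fn=1))
        assert m.sen == pytest.approx(0.75)
        assert m.spc == pytest.approx(5 / 6, abs=1e-4)
        assert m.ppv == pytest.approx(0.75)
        assert m.acc == pytest.approx(0.8)
        assert m.f1 == pytest.approx(0.75)
        assert m.mcc == pytest.approx(14 / 24, abs=1e-4)  # 0.5833
        assert not m.degenerate

    def test_no_predicted_positives_is_degenerate_zero(self):
        m = binary_metrics(ConfusionCounts(tp=0, tn=8, fp=0, fn=2))
        assert m.ppv == 0.0 and "ppv" in m.degenerate
        assert m.f1 == pytest.approx(0.0)
        assert m.mcc == 0.0 and "mcc" in m.degenerate

    def test_perfect_prediction(self):
        m = binary_metrics(ConfusionCounts(tp=10, tn=30, fp=0, fn=0))
        assert (m.sen, m.spc, m.ppv, m.acc, m.f1, m.mcc) == (1, 1, 1, 1, 1, 1)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=-1, tn=0, fp=0, fn=0)

    def test_confusion_counts_from_labels(self):
        c = confusion_counts([1, 1, 0, 0, 1], [1, 0, 0, 1, 1])
        assert (c.tp, c.tn, c.fp, c.fn) == (2, 1, 1, 1)
        assert c.p_total == 3 and c.n_total == 2


class TestStability:
    def test_default_ladder_hand_computed(self):
        series = {3.5: 0.80, 4.0: 0.78, 4.5: 0.78, 5.0: 0.77, 5.5: 0.77, 6.0: 0.77}
        rep = stability(series)
        assert rep.mav == pytest.approx(0.02)
        assert rep.mavr == pytest.approx(0.04)
        assert rep.cavr == pytest.approx(0.06)
        # on the uniform 0.5 Å ladder MAVR = MAV / 0.5 by construction
        assert rep.mavr == pytest.approx(rep.mav / 0.5)
        assert rep.cavr >= rep.mavr

    def test_constant_series_is_perfectly_stable(self):
        rep = stability({c: 0.7 for c in (3.5, 4.0, 4.5, 5.0)})
        assert rep.mavr == rep.mav == rep.cavr == 0.0

    def test_single_pair_with_wide_spacing(self):
        rep = stability({3.5: 0.7, 6.0: 0.8})
        assert rep.mav == pytest.approx(0.1)
        assert rep.mavr == pytest.approx(0.04)
        assert rep.cavr == pytest.approx(0.04)

    def test_fewer_than_two_points_undefined(self):
        assert stability({3.5: 0.7}) is None

    def test_all_pairs_mode_adds_wider_spans(self):
        series = {3.5: 0.8, 4.0: 0.7, 4.5: 0.8}
        rep = stability(series, all_pairs=True)
        assert len(rep.deltas) == 3
        assert rep.mavr == pytest.approx(0.2)


class TestMinPerformance:
    def test_global_minimum_with_argmin(self):
        per_ds, gmin = min_performance(
            {("A", 3.5): 0.9, ("A", 6.0): 0.85, ("B", 6.0): 0.7}
        )
        assert gmin == ("B", 6.0, 0.7)
        assert per_ds["A"] == (6.0, 0.85)

    def test_single_entry_identity(self):
        per_ds, gmin = min_performance({("X", 4.0): 0.66})
        assert gmin == ("X", 4.0, 0.66)
        assert per_ds == {"X": (4.0, 0.66)}

    def test_ties_break_to_smallest_cutoff_then_dataset_name(self):
        per_ds, gmin = min_performance(
            {("B", 4.0): 0.5, ("A", 4.0): 0.5, ("A", 3.5): 0.5}
        )
        assert gmin == ("A", 3.5, 0.5)


def _ann(dists):
    return [
        BindingAnnotation(("A", i + 1, ""), d, 1.0, {6.0: d <= 6.0})
        for i, d in enumerate(dists)
    ]


def _pred(scores, program="prog"):
    return PredictionSet(
        program=program, protein_id="p",
        scores={("A", i + 1, ""): s for i, s in enumerate(scores)},
        kind="continuous",
    )


class TestFunnelCorrelation:
    def test_score_equal_minus_distance_is_perfectly_anticorrelated(self):
        d = [2.0, 3.5, 5.0, 8.0, 11.0]
        res = funnel_correlation(_ann(d), _pred([-x for x in d]))
        assert res.rho == pytest.approx(-1.0)
        assert res.abs_rho == pytest.approx(1.0)

    def test_affine_decay_is_perfectly_anticorrelated(self):
        res = funnel_correlation(
            _ann([2.0, 4.0, 6.0, 8.0]), _pred([0.8, 0.6, 0.4, 0.2])
        )
        assert res.rho == pytest.approx(-1.0)

    def test_only_residues_inside_radius_enter(self):
        d = [2.0, 5.0, 11.0, 30.0, 40.0]
        res = funnel_correlation(_ann(d), _pred([-x for x in d]), funnel_radius=12.0)
        assert res.n_residues == 3

    def test_constant_score_is_undefined(self):
        res = funnel_correlation(_ann([2.0, 4.0, 6.0]), _pred([0.5, 0.5, 0.5]))
        assert res.rho is None

    def test_independent_scores_stay_below_permutation_bound(self):
        """Scores unrelated to distance: |ρ| falls below the 95th percentile
        of the permutation null computed from the same data."""
        rng = np.random.default_rng(99)
        d = rng.uniform(2, 12, size=60)
        s = rng.permutation(d)  # same marginal, independent pairing
        res = funnel_correlation(_ann(d.tolist()), _pred(s.tolist()))
        null = []
        for _ in range(500):
            perm = rng.permutation(s)
            null.append(abs(np.corrcoef(d, perm)[0, 1]))
        assert abs(res.rho) < np.quantile(null, 0.95)


class TestDiscrimination:
    def test_perfect_separation(self):
        assert discrimination_auc([1.0] * 5, [0.0] * 7) == 1.0

    def test_perfect_inversion(self):
        assert discrimination_auc([0.0] * 5, [1.0] * 7) == 0.0

    def test_identical_distributions_are_chance_level(self):
        rng = np.random.default_rng(17)
        pos = rng.normal(size=500)
        neg = rng.normal(size=500)
        auc = discrimination_auc(pos, neg)
        assert auc == pytest.approx(0.5, abs=0.05)  # MC bound at n=500/side

    def test_empty_side_rejected(self):
        with pytest.raises(ValueError):
            discrimination_auc([], [0.1])


def test_evaluate_protein_counts():
    ev = evaluate_protein("p", [0.9, 0.2, 0.7, 0.1], [1, 0, 1, 0])
    assert ev.auc == 1.0
    assert (ev.length, ev.n_pos, ev.n_neg) == (4, 2, 2)
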