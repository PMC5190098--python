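"""Metrics, jackknife/k-fold protocols, and ROC analysis."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hydsite as h
from hydsite.classify import ForestConfig
from hydsite.coupling import encode_windows, fit_class_tables
from sklearn.ensemble import RandomForestClassifier


def standard_matthews(counts):
    """Textbook TP/TN/FP/FN Matthews formula (independent oracle)."""
    tp = counts.n_pos - counts.miss_pos
    fn = counts.miss_pos
    tn = counts.n_neg - counts.false_pos
    fp = counts.false_pos
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / denom


class TestComputeMetrics:
    @pytest.mark.parametrize(
        "n_pos,n_neg,miss,false,expect",
        [
            # printed corner cases of the four-metric formulation
            (10, 20, 0, 5, {"sn": 1.0}),
            (10, 20, 10, 5, {"sn": 0.0}),
            (10, 20, 3, 0, {"sp": 1.0}),
            (10, 20, 3, 20, {"sp": 0.0}),
            (50, 50, 0, 0, {"acc": 1.0, "mcc": 1.0}),
            (50, 50, 50, 50, {"acc": 0.0, "mcc": -1.0}),
            (200, 300, 100, 150, {"acc": 0.5, "mcc": 0.0}),
        ],
    )
    def test_corner_cases_exact(self, n_pos, n_neg, miss, false, expect):
        report = h.compute_metrics(h.ConfusionCounts(n_pos, n_neg, miss, false))
        for name, value in expect.items():
            assert getattr(report, name) == value

    @settings(derandomize=True, max_examples=300)
    @given(st.integers(1, 50), st.integers(1, 50),
           st.integers(0, 50), st.integers(0, 50))
    def test_misscount_form_equals_standard_matthews(self, n_pos, n_neg, miss, false):
        miss, false = min(miss, n_pos), min(false, n_neg)
        counts = h.ConfusionCounts(n_pos, n_neg, miss, false)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            report = h.compute_metrics(counts)
        assert report.mcc == pytest.approx(standard_matthews(counts), abs=1e-12)

    def test_invariant_identities(self):
        counts = h.ConfusionCounts(40, 70, 13, 22)
        r = h.compute_metrics(counts)
        assert r.sn == 1 - 13 / 40
        assert r.sp == 1 - 22 / 70
        assert r.acc == 1 - (13 + 22) / 110

    def test_single_class_predictions_give_mcc_zero_with_warning(self):
        counts = h.ConfusionCounts(10, 10, 10, 0)  # everything called negative
        with pytest.warns(UserWarning, match="MCC denominator"):
            assert h.compute_metrics(counts).mcc == 0.0

    def test_empty_class_rejected(self):
        with pytest.raises(h.ValidationError):
            h.compute_metrics(h.ConfusionCounts(0, 10, 0, 0))
        with pytest.raises(h.ValidationError):
            h.compute_metrics(h.ConfusionCounts(10, 0, 0, 0))

    def test_impossible_counts_rejected(self):
        with pytest.raises(h.ValidationError):
            h.ConfusionCounts(5, 5, 6, 0)


def brute_force_auc(scores, labels):
    """All-pairs Mann-Whitney oracle: concordant pairs, ties count one half."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestRocCurve:
    def test_perfect_ranking(self):
        _, auc = h.roc_curve([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert auc == 1.0

    def test_uninformative_scores(self):
        _, auc = h.roc_curve([0.5] * 6, [1, 1, 1, 0, 0, 0])
        assert auc == 0.5

    @pytest.mark.parametrize("seed", range(4))
    def test_trapezoid_equals_all_pairs_oracle(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=20)
        labels = rng.integers(0, 2, size=20)
        if len(set(labels.tolist())) == 1:
            labels[0] = 1 - labels[0]
        _, auc = h.roc_curve(scores, labels)
        assert auc == pytest.approx(brute_force_auc(scores, labels), abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(5)
        scores = rng.random(30)
        labels = rng.integers(0, 2, size=30)
        labels[:2] = [0, 1]
        _, auc1 = h.roc_curve(scores, labels)
        _, auc2 = h.roc_curve(np.exp(3 * scores) - 1, labels)
        assert auc1 == pytest.approx(auc2, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(h.ValidationError):
            h.roc_curve([0.1, 0.2], [1, 1])


def _toy_dataset():
    pos = ["ACPDE", "CAPEC", "AAPDD"]
    neg = ["DDPCA", "ECPAA", "CCPEE"]
    return h.BenchmarkDataset(
        target="P", xi=2,
        positives=tuple(h.PeptideSample(w, "P", "positive", "t", 3) for w in pos),
        negatives=tuple(h.PeptideSample(w, "P", "negative", "t", 3) for w in neg),
    )


class TestJackknife:
    def test_strict_protocol_matches_hand_enumerated_folds(self):
        """Each sample scored by encoder+forest refit on the other five."""
        ds = _toy_dataset()
        config = ForestConfig(n_trees=25, seed=3)
        windows = [s.window for s in ds.positives + ds.negatives]
        labels = np.array([1, 1, 1, 0, 0, 0])
        scores = np.empty(6)
        for i in range(6):
            keep = [j for j in range(6) if j != i]
            tr_windows = [windows[j] for j in keep]
            tr_labels = labels[keep]
            pos_t = fit_class_tables([w for w, l in zip(tr_windows, tr_labels) if l == 1], 2)
            neg_t = fit_class_tables([w for w, l in zip(tr_windows, tr_labels) if l == 0], 2)
            model = h.CouplingModel(target="P", positive=pos_t, negative=neg_t)
            rf = RandomForestClassifier(n_estimators=25, max_features="sqrt",
                                        random_state=3, n_jobs=1)
            rf.fit(encode_windows(tr_windows, model), tr_labels)
            votes = np.mean([t.predict(encode_windows([windows[i]], model)) == 1
                             for t in rf.estimators_], axis=0)
            scores[i] = votes[0]
        expected_pred = scores >= 0.5
        report = h.jackknife(ds, config, protocol="strict")
        assert report.counts.miss_pos == int((~expected_pred[:3]).sum())
        assert report.counts.false_pos == int(expected_pred[3:].sum())
        assert np.allclose(report.scores, scores)

    def test_high_signal_dataset_is_nearly_separable(self):
        spec = h.GeneratorSpec(xi=10, seed=11, coupling_strength=1.0)
        ds = h.generate_benchmark(spec, 100, 100)
        report = h.jackknife(ds, ForestConfig(n_trees=100, seed=0))
        assert report.acc >= 0.95

    def test_deterministic_across_runs(self):
        ds = h.generate_benchmark(h.GeneratorSpec(xi=3, seed=2), 10, 10)
        r1 = h.jackknife(ds, ForestConfig(n_trees=20, seed=1))
        r2 = h.jackknife(ds, ForestConfig(n_trees=20, seed=1))
        assert r1.counts == r2.counts
        assert np.array_equal(r1.scores, r2.scores)
        assert r1.auc == r2.auc

    def test_paper_style_differs_only_in_table_fitting(self):
        ds = h.generate_benchmark(h.GeneratorSpec(xi=3, seed=4), 12, 12)
        strict = h.jackknife(ds, ForestConfig(n_trees=20, seed=0), protocol="strict")
        paper = h.jackknife(ds, ForestConfig(n_trees=20, seed=0), protocol="paper_style")
        # both are valid leave-one-out runs over the same samples
        assert strict.counts.n_pos == paper.counts.n_pos == 12
        assert strict.counts.n_neg == paper.counts.n_neg == 12

    def test_tiny_subsets_rejected(self):
        ds = _toy_dataset()
        small = h.BenchmarkDataset(target="P", xi=2, positives=ds.positives[:1],
                                   negatives=ds.negatives)
        with pytest.raises(h.ValidationError, match="at least 2"):
            h.jackknife(small)

    def test_unknown_protocol_rejected(self):
        with pytest.raises(h.ValidationError, match="protocol"):
            h.jackknife(_toy_dataset(), ForestConfig(n_trees=5), protocol="loose")


class TestKFold:
    def test_k_equal_n_is_the_jackknife(self):
        ds = h.generate_benchmark(h.GeneratorSpec(xi=3, seed=6), 8, 8)
        config = ForestConfig(n_trees=20, seed=0)
        jk = h.jackknife(ds, config)
        kf = h.kfold(ds, k=len(ds), forest_config=config)
        assert np.array_equal(jk.scores, kf.scores)
        assert jk.counts == kf.counts

    def test_every_sample_tested_exactly_once(self):
        ds = h.generate_benchmark(h.GeneratorSpec(xi=3, seed=8), 50, 50)
        report = h.kfold(ds, k=5, forest_config=ForestConfig(n_trees=10, seed=0))
        assert report.scores.shape == (len(ds),)
        assert not np.isnan(report.scores).any()
        assert report.counts.n_pos == len(ds.positives)
        assert report.counts.n_neg == len(ds.negatives)

    def test_folds_are_stratified(self):
        ds = h.generate_benchmark(h.GeneratorSpec(xi=3, seed=9), 20, 80)
        from sklearn.model_selection import StratifiedKFold

        y = np.r_[np.ones(len(ds.positives)), np.zeros(len(ds.negatives))]
        splitter = StratifiedKFold(n_splits=5, shuffle=True, random_state=0)
        global_frac = y.mean()
        for _, test_idx in splitter.split(np.zeros((len(y), 1)), y):
            fold_pos = y[test_idx].sum()
            assert abs(fold_pos - global_frac * len(test_idx)) <= 1

    def test_fold_assignment_reproducible_from_seed(self):
        ds = h.generate_benchmark(h.GeneratorSpec(xi=3, seed=10), 15, 15)
        r1 = h.kfold(ds, k=5, forest_config=ForestConfig(n_trees=10), seed=4)
        r2 = h.kfold(ds, k=5, forest_config=ForestConfig(n_trees=10), seed=4)
        assert np.array_equal(r1.scores, r2.scores)

    def test_k_out_of_range_rejected(self):
        ds = _toy_dataset()
        with pytest.raises(h.ValidationError, match="k must be"):
            h.kfold(ds, k=1)
        with pytest.raises(h.ValidationError, match="k must be"):
            h.kfold(ds, k=7)


class TestSelectWindowSize:
    def test_single_value_sweep(self):
        proteins = h.generate_proteins(h.GeneratorSpec(
            xi=2, seed=12, n_proteins=40, length_range=(30, 60)))
        table = h.select_window_size(proteins, "P", [2], k=5,
                                     forest_config=ForestConfig(n_trees=10))
        assert list(table.index) == [2]
        assert {"acc", "mcc", "sn", "sp", "auc"} <= set(table.columns)

    def test_wider_window_captures_confined_coupling(self):
        """Coupling confined to +-3: xi=3 should beat xi=1 on average.

        With identical +-1 marginals in both classes, a 1-wide window carries
        no signal at all, while xi=3 sees the full coupled flank.  A wider
        flank alphabet keeps 3-mer windows diverse enough to survive the
        duplicate/conflict screening.
        """
        diffs = []
        for seed in range(5):
            proteins = h.generate_proteins(h.GeneratorSpec(
                xi=3, seed=seed, n_proteins=60, length_range=(40, 80),
                coupling_strength=1.0, support_size=10))
            table = h.select_window_size(proteins, "P", [1, 3], k=5,
                                         forest_config=ForestConfig(n_trees=50))
            diffs.append(table.loc[3, "acc"] - table.loc[1, "acc"])
        assert np.mean(diffs) >= 0.0

    def test_empty_sweep_rejected(self):
        with pytest.raises(h.ValidationError):
            h.select_window_size([], "P", [])


def test_report_serialization(tmp_path):
    ds = h.generate_benchmark(h.GeneratorSpec(xi=3, seed=14), 10, 10)
    report = h.jackknife(ds, ForestConfig(n_trees=10))
    out = tmp_path / "report.json"
    report.to_json(out)
    import json

    payload = json.loads(out.read_text())
    assert payload["acc_percent"] == pytest.approx(100 * report.acc)
    roc_path = tmp_path / "roc.tsv"
    report.write_roc_tsv(roc_path)
    lines = roc_path.read_text().strip().splitlines()
    assert lines[0] == "fpr\ttpr"
    assert len(lines) == len(report.roc) + 1
    table = report.format_table()
    assert "Acc (%)" in table and "MCC" in table
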