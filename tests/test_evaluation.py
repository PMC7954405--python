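"""AUROC, stratified folds, chronological split, bootstrap, repeated CV."""

from types import SimpleNamespace

import numpy as np
import pytest

from icu_acuity.evaluation import (
    CVSummary,
    MetricError,
    StratificationError,
    auroc,
    bootstrap_ci,
    chronological_split,
    make_fold_assignments,
    repeated_cv,
    stratified_kfold,
)


def brute_force_auroc(scores, labels):
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    acc = 0.0
    for p in pos:
        for n in neg:
            acc += 1.0 if p > n else (0.5 if p == n else 0.0)
    return acc / (len(pos) * len(neg))


class TestAuroc:
    def test_perfect_separation(self):
        assert auroc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_all_tied_scores(self):
        assert auroc([0.5] * 6, [0, 1, 0, 1, 0, 1]) == 0.5

    def test_matches_pairwise_oracle_with_ties(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(10, 60))
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            scores = rng.integers(0, 5, n).astype(float)  # heavy ties
            assert auroc(scores, labels) == pytest.approx(
                brute_force_auroc(scores, labels), abs=1e-12
            )

    def test_single_class_rejected(self):
        with pytest.raises(MetricError):
            auroc([0.1, 0.9], [1, 1])

    def test_score_negation_complements(self):
        rng = np.random.default_rng(1)
        labels = rng.integers(0, 2, 50)
        labels[:2] = [0, 1]
        scores = rng.normal(size=50)  # tie-free
        assert auroc(scores, labels) + auroc(-scores, labels) == pytest.approx(1.0)


class TestStratifiedKFold:
    def test_target_cohort_split_sizes(self):
        # 33 successful + 18 unsuccessful, five folds
        labels = np.array([0] * 33 + [1] * 18)
        folds = stratified_kfold(labels, k=5, rng=np.random.default_rng(3))
        sizes = sorted(len(f) for f in folds)
        assert sizes == [10, 10, 10, 10, 11]
        for f in folds:
            n_neg = int(labels[f].sum())
            assert n_neg in (3, 4)

    def test_folds_partition_the_data(self):
        labels = np.random.default_rng(4).integers(0, 2, 40)
        labels[:10] = 1
        labels[10:20] = 0
        folds = stratified_kfold(labels, k=5, rng=np.random.default_rng(5))
        all_idx = np.concatenate(folds)
        assert len(all_idx) == 40 and len(set(all_idx.tolist())) == 40

    def test_different_rng_states_differ(self):
        labels = np.array([0] * 33 + [1] * 18)
        f1 = stratified_kfold(labels, 5, np.random.default_rng(6))
        f2 = stratified_kfold(labels, 5, np.random.default_rng(7))
        assert any(not np.array_equal(a, b) for a, b in zip(f1, f2))

    def test_scarce_class_rejected(self):
        with pytest.raises(StratificationError):
            stratified_kfold([0] * 20 + [1] * 3, k=5, rng=np.random.default_rng(0))


def stays_at(times_ids):
    return [
        SimpleNamespace(admit_time=t, stay_id=i, label=0) for t, i in times_ids
    ]


class TestChronologicalSplit:
    def test_latest_fifth_validates(self):
        stays = stays_at([(i, f"s{i}") for i in range(10)])
        dev, val = chronological_split(stays, 0.20)
        assert [s.admit_time for s in val] == [8, 9]
        assert len(dev) == 8

    def test_ties_break_by_stay_id(self):
        stays = stays_at([(0, "c"), (0, "a"), (0, "b"), (0, "d"), (0, "e")])
        dev, val = chronological_split(stays, 0.20)
        assert val[0].stay_id == "e"

    def test_ceil_arithmetic_at_large_n(self):
        stays = stays_at([(i, str(i)) for i in range(48_400)])
        _, val = chronological_split(stays, 0.20)
        assert len(val) == 9680


class TestBootstrap:
    def test_perfect_separation_has_degenerate_ci(self):
        scores = np.array([0.1] * 20 + [0.9] * 20)
        labels = np.array([0] * 20 + [1] * 20)
        point, lo, hi, _ = bootstrap_ci(scores, labels, rng=np.random.default_rng(1))
        assert (point, lo, hi) == (1.0, 1.0, 1.0)

    def test_deterministic_given_rng(self):
        rng_scores = np.random.default_rng(2)
        labels = rng_scores.integers(0, 2, 100)
        labels[:2] = [0, 1]
        scores = rng_scores.normal(size=100) + labels
        a = bootstrap_ci(scores, labels, rng=np.random.default_rng(9))
        b = bootstrap_ci(scores, labels, rng=np.random.default_rng(9))
        assert a[:3] == b[:3]

    def test_ci_width_shrinks_roughly_root_n(self):
        widths = []
        for n in (200, 800, 3200):
            rng = np.random.default_rng(n)
            labels = (np.arange(n) % 2).astype(int)
            scores = rng.normal(size=n) + 0.8 * labels
            _, lo, hi, _ = bootstrap_ci(scores, labels, n_boot=100, rng=rng)
            widths.append(hi - lo)
        assert widths[0] > widths[1] > widths[2]
        assert 2.0 < widths[0] / widths[2] < 8.0  # expect ~4 under 1/sqrt(n)


class ConstantPipeline:
    def fit(self, stays, rng):
        return self

    def score(self, stays):
        return np.full(len(stays), 0.5)


class SeverityOraclePipeline:
    """Scores with the true generative severity signal (no fitting)."""

    def fit(self, stays, rng):
        return self

    def score(self, stays):
        return np.array([s.severity_mean for s in stays])


def synthetic_eval_stays(n=40, seed=0):
    rng = np.random.default_rng(seed)
    sev = rng.normal(size=n)
    from scipy.special import expit

    labels = (rng.random(n) < expit(2 * sev)).astype(int)
    if labels.min() == labels.max():
        labels[:5] = 1 - labels[0]
    return [
        SimpleNamespace(label=int(y), severity_mean=float(s), stay_id=str(i))
        for i, (y, s) in enumerate(zip(labels, sev))
    ]


class TestRepeatedCV:
    def test_constant_scorer_gives_degenerate_summary(self):
        stays = synthetic_eval_stays()
        summary = repeated_cv(stays, ConstantPipeline, reps=5, k=5, base_seed=0)
        np.testing.assert_array_equal(summary.rep_auroc, np.full(5, 0.5))
        assert (summary.ci_lower, summary.ci_upper) == (0.5, 0.5)

    def test_reproducible_from_base_seed(self):
        stays = synthetic_eval_stays(seed=1)
        a = repeated_cv(stays, SeverityOraclePipeline, reps=2, k=5, base_seed=7)
        b = repeated_cv(stays, SeverityOraclePipeline, reps=2, k=5, base_seed=7)
        np.testing.assert_array_equal(a.rep_auroc, b.rep_auroc)

    def test_informative_scorer_beats_constant(self):
        stays = synthetic_eval_stays(seed=2)
        oracle = repeated_cv(stays, SeverityOraclePipeline, reps=3, k=5, base_seed=3)
        const = repeated_cv(stays, ConstantPipeline, reps=3, k=5, base_seed=3)
        assert oracle.mean_auroc > const.mean_auroc

    def test_fit_sees_only_development_stays(self):
        stays = synthetic_eval_stays(seed=3)
        seen_per_fold = []

        class RecordingPipeline(ConstantPipeline):
            def fit(self, dev, rng):
                seen_per_fold.append({s.stay_id for s in dev})
                return self

        summary = repeated_cv(stays, RecordingPipeline, reps=2, k=5, base_seed=4)
        labels = np.array([s.label for s in stays])
        folds = make_fold_assignments(labels, 2, 5, 4)
        all_ids = {s.stay_id for s in stays}
        i = 0
        for rep_folds in folds:
            for val_idx in rep_folds:
                val_ids = {stays[j].stay_id for j in val_idx}
                assert seen_per_fold[i] == all_ids - val_ids
                i += 1
        assert len(summary.rep_auroc) == 2

    def test_percentile_ci_bounds_are_order_statistics(self):
        reps = np.linspace(0.4, 0.9, 100)
        s = CVSummary.from_reps(reps)
        np.testing.assert_allclose(s.ci_lower, np.percentile(reps, 2.5))
        np.testing.assert_allclose(s.ci_upper, np.percentile(reps, 97.5))
        assert reps.min() <= s.ci_lower <= s.ci_upper <= reps.max()
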