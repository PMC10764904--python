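"""Event-scheme geometry, labeling, balancing, normalization, selection."""

import numpy as np
import pytest

from chronofp.dataset import (EventScheme, LabeledSet, label_windows,
                              select_features_anova, split_train_test,
                              undersample, zscore_apply, zscore_fit)
from conftest import make_table

MIN = 60.0


class TestSplit:
    @pytest.mark.parametrize("n,n_test", [(5, 2), (4, 1)])
    def test_first_three_train(self, n, n_test):
        onsets = np.arange(1, n + 1) * 1000.0
        train, test = split_train_test(onsets)
        assert train.size == 3 and test.size == n_test
        np.testing.assert_array_equal(train, onsets[:3])

    def test_fewer_than_four_seizures_ineligible(self):
        with pytest.raises(ValueError, match="four"):
            split_train_test(np.array([1e3, 2e3, 3e3]))


class TestSchemeGeometry:
    def test_control_single_event(self):
        s = EventScheme("control", 20)
        assert s.events == [(1, 25.0, 5.0)]
        assert s.total_span_min == 25.0

    def test_chronological_tiles_three_sops(self):
        s = EventScheme("chronological", 10)
        assert s.events == [(1, 35.0, 25.0), (2, 25.0, 15.0), (3, 15.0, 5.0)]

    def test_cumulative_nested_shared_end(self):
        s = EventScheme("cumulative", 10)
        assert s.events == [(1, 35.0, 5.0), (2, 25.0, 5.0), (3, 15.0, 5.0)]
        # event 1 is three times, event 2 twice, the length of event 3
        d = [start - end for _, start, end in s.events]
        assert d == [30.0, 20.0, 10.0]

    def test_sop_outside_grid_rejected(self):
        with pytest.raises(ValueError, match="sop"):
            EventScheme("control", 12)


class TestLabeling:
    ONSET = 4800.0  # 80 min into a 120-min dummy table

    def _label(self, scheme, event=1, **kw):
        table = make_table(1440)  # 120 min of 5-s windows
        return label_windows(table, [self.ONSET], scheme, event, **kw)

    def test_control_sop20_zone(self):
        ls = self._label(EventScheme("control", 20))
        lo, hi = self.ONSET - 25 * MIN, self.ONSET - 5 * MIN
        pos = ls.times[ls.y == 1]
        assert pos.min() == lo + 5.0 and pos.max() == hi  # half-open (lo, hi]
        assert pos.size == 20 * 12

    def test_sph_windows_excluded(self):
        ls = self._label(EventScheme("control", 20))
        t_inside_sph = self.ONSET - 2 * MIN
        assert t_inside_sph not in ls.times

    def test_chronological_event1_sop10_zone(self):
        ls = self._label(EventScheme("chronological", 10), event=1)
        pos = ls.times[ls.y == 1]
        assert pos.min() == self.ONSET - 35 * MIN + 5.0
        assert pos.max() == self.ONSET - 25 * MIN

    def test_chronological_events_disjoint(self):
        zones = [set(self._label(EventScheme("chronological", 10), e).times[
            self._label(EventScheme("chronological", 10), e).y == 1])
            for e in (1, 2, 3)]
        assert not (zones[0] & zones[1]) and not (zones[1] & zones[2])

    def test_cumulative_zones_nested(self):
        zones = []
        for e in (1, 2, 3):
            ls = self._label(EventScheme("cumulative", 10), e)
            zones.append(set(ls.times[ls.y == 1]))
        assert zones[2] < zones[1] < zones[0]

    def test_post_onset_exclusion_zone_dropped(self):
        ls = self._label(EventScheme("control", 20), exclusion_min=10.0)
        post = (ls.times > self.ONSET) & (ls.times <= self.ONSET + 10 * MIN)
        assert not post.any()

    def test_labeling_idempotent(self):
        a = self._label(EventScheme("control", 20))
        b = self._label(EventScheme("control", 20))
        np.testing.assert_array_equal(a.y, b.y)
        np.testing.assert_array_equal(a.times, b.times)

    def test_truncated_preictal_warns(self):
        table = make_table(120)  # 10-min record, span cannot fit
        with pytest.warns(UserWarning, match="truncated"):
            label_windows(table, [9 * MIN], EventScheme("control", 20), 1)


def _toy_labeled(n_pos=120, n_neg=1200, seed=0):
    rng = np.random.default_rng(seed)
    n = n_pos + n_neg
    times = np.arange(n) * 5.0
    y = np.concatenate([np.zeros(n_neg, int), np.ones(n_pos, int)])
    return LabeledSet(X=rng.standard_normal((n, 4)), y=y, times=times,
                      seizure_ids=np.zeros(n, int))


class TestUndersample:
    def test_example_counts_120_1200(self):
        out = undersample(_toy_labeled(), seed=1)
        assert out.y.size == 240
        assert out.n_pos == 120 and (out.y == 0).sum() == 120

    def test_deterministic_under_seed(self):
        a = undersample(_toy_labeled(), seed=2)
        b = undersample(_toy_labeled(), seed=2)
        np.testing.assert_array_equal(a.times, b.times)

    def test_one_per_contiguous_group_covers_interictal(self):
        ls = _toy_labeled(n_pos=10, n_neg=100)
        out = undersample(ls, seed=3)
        kept_neg = np.sort(out.times[out.y == 0])
        groups = np.array_split(np.sort(ls.times[ls.y == 0]), 10)
        for g, t in zip(groups, kept_neg):
            assert g.min() <= t <= g.max()

    def test_interictal_deficit_rejected(self):
        with pytest.raises(ValueError, match="cannot balance"):
            undersample(_toy_labeled(n_pos=50, n_neg=10), seed=0)

    def test_per_seizure_balance(self):
        rng = np.random.default_rng(5)
        parts = []
        for sid, (npos, nneg) in enumerate([(20, 100), (30, 90)]):
            n = npos + nneg
            parts.append(LabeledSet(
                X=rng.standard_normal((n, 3)),
                y=np.concatenate([np.zeros(nneg, int), np.ones(npos, int)]),
                times=np.arange(n) * 5.0 + sid * 1e5,
                seizure_ids=np.full(n, sid)))
        ls = LabeledSet(
            X=np.vstack([p.X for p in parts]),
            y=np.concatenate([p.y for p in parts]),
            times=np.concatenate([p.times for p in parts]),
            seizure_ids=np.concatenate([p.seizure_ids for p in parts]))
        out = undersample(ls, seed=6)
        for sid, npos in [(0, 20), (1, 30)]:
            m = out.seizure_ids == sid
            assert (out.y[m] == 1).sum() == (out.y[m] == 0).sum() == npos


class TestZScore:
    def test_train_columns_centered_unit(self):
        rng = np.random.default_rng(7)
        X = rng.normal(3.0, 2.0, size=(500, 6))
        params = zscore_fit(X)
        Z = zscore_apply(params, X)
        assert np.abs(Z.mean(axis=0)).max() < 1e-10
        np.testing.assert_allclose(Z.std(axis=0), 1.0, rtol=1e-10)

    def test_constant_column_maps_to_zero_with_warning(self):
        X = np.ones((50, 2))
        X[:, 1] = np.arange(50)
        with pytest.warns(UserWarning, match="zero-variance"):
            params = zscore_fit(X)
        Z = zscore_apply(params, X)
        assert np.all(Z[:, 0] == 0.0)

    def test_test_set_generally_not_centered(self):
        rng = np.random.default_rng(8)
        params = zscore_fit(rng.normal(0, 1, (300, 3)))
        Z = zscore_apply(params, rng.normal(5, 1, (300, 3)))
        assert np.abs(Z.mean(axis=0)).min() > 1.0


def _brute_force_f(X, y):
    """One-way ANOVA F via the textbook between/within decomposition."""
    F = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        groups = [X[y == c, j] for c in np.unique(y)]
        gm = X[:, j].mean()
        ssb = sum(len(g) * (g.mean() - gm) ** 2 for g in groups)
        ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
        dfb, dfw = len(groups) - 1, X.shape[0] - len(groups)
        F[j] = (ssb / dfb) / (ssw / dfw)
    return F


class TestAnovaSelection:
    def test_planted_feature_ranked_first_matches_brute_force(self):
        rng = np.random.default_rng(9)
        y = rng.integers(0, 2, 300)
        X = rng.standard_normal((300, 8))
        X[:, 5] += np.where(y == 1, 2.0, -2.0)
        idx = select_features_anova(X, y, 3)
        assert idx[0] == 5
        F = _brute_force_f(X, y)
        np.testing.assert_array_equal(idx, np.argsort(-F, kind="stable")[:3])

    def test_uninformative_feature_never_beats_informative(self):
        rng = np.random.default_rng(10)
        y = np.repeat([0, 1], 100)
        X = rng.standard_normal((200, 3))
        X[:, 0] = 1.0  # identical in both classes
        X[:, 2] += np.where(y == 1, 1.5, -1.5)
        idx = select_features_anova(X, y, 1)
        assert idx[0] == 2

    def test_k_distinct_indices(self):
        rng = np.random.default_rng(11)
        idx = select_features_anova(rng.standard_normal((100, 50)),
                                    rng.integers(0, 2, 100), 40)
        assert len(idx) == 40 and len(set(idx)) == 40

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="classes"):
            select_features_anova(np.ones((10, 2)), np.zeros(10, int), 1)
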