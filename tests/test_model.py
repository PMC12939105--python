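"""Split, standardizer, LASSO selection, pseudo-labeling, self-training."""

import numpy as np
import pandas as pd
import pytest

from radpdl1.model import (Standardizer, lasso_select, pseudo_label,
                           self_train, split_cohort, train_supervised)
from radpdl1.synthetic import make_semisup_benchmark, make_tabular


def _frame(X, prefix="f"):
    return pd.DataFrame(X, columns=[f"{prefix}{i}"
                                    for i in range(X.shape[1])])


class TestSplit:
    def test_482_patients_split_80_20(self):
        ids = [f"p{i}" for i in range(482)]
        y = np.r_[np.zeros(241), np.ones(241)]
        train, test = split_cohort(ids, y, 0.8, seed=0)
        assert len(train) in (385, 386)
        assert len(test) in (96, 97)

    def test_disjoint_for_many_seeds(self):
        ids = [f"p{i}" for i in range(50)]
        y = np.arange(50) % 2
        for seed in range(10):
            train, test = split_cohort(ids, y, seed=seed)
            assert not set(train) & set(test)
            assert len(train) + len(test) == 50

    def test_stratification_preserved(self):
        ids = [f"p{i}" for i in range(100)]
        y = np.r_[np.zeros(80), np.ones(20)]
        train, test = split_cohort(ids, y, 0.8, seed=1)
        train_y = [1 if int(t[1:]) >= 80 else 0 for t in train]
        assert sum(train_y) == 16  # 80% of the 20 positives

    def test_fixed_seed_reproducible(self):
        ids = [f"p{i}" for i in range(40)]
        y = np.arange(40) % 2
        assert split_cohort(ids, y, seed=7) == split_cohort(ids, y, seed=7)

    def test_small_class_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            split_cohort(["a", "b", "c"], [0, 0, 1])


class TestStandardizer:
    def test_fit_set_maps_to_zero_mean_unit_sd(self):
        X = _frame(np.random.default_rng(0).normal(5, 3, (50, 4)))
        Z = Standardizer().fit(X).transform(X)
        assert np.abs(Z.mean(axis=0)).max() < 1e-10
        assert np.abs(Z.std(axis=0, ddof=0) - 1).max() < 1e-10

    def test_no_refit_on_shifted_test_data(self):
        X = _frame(np.random.default_rng(1).normal(0, 1, (50, 3)))
        s = Standardizer().fit(X)
        Z_shift = s.transform(X + 10.0)
        assert Z_shift.mean(axis=0).min() > 5  # shift visible, no leakage

    def test_constant_column_dropped_with_warning(self, caplog):
        X = _frame(np.random.default_rng(2).normal(size=(30, 3)))
        X["const"] = 4.2
        with caplog.at_level("WARNING"):
            s = Standardizer().fit(X)
        assert "const" not in s.columns_
        assert s.transform(X).shape[1] == 3
        assert any("constant" in r.message for r in caplog.records)


class TestLasso:
    def test_recovers_planted_support(self):
        hits, sizes = [], []
        for seed in range(5):
            t = make_tabular(500, 100, 5, 1.0, seed=seed)
            X = _frame(t.X)
            sel = lasso_select(X, t.y, seed=seed)
            true = {f"f{i}" for i in range(5)}
            hits.append(len(true & set(sel.support)))
            sizes.append(len(sel.support))
        assert np.median(hits) >= 4
        assert np.median(sizes) <= 15

    def test_huge_lambda_empty_support(self):
        t = make_tabular(100, 10, 2, 1.0, seed=0)
        from sklearn.linear_model import LogisticRegression
        clf = LogisticRegression(penalty="l1", solver="liblinear", C=1e-6)
        clf.fit(t.X, t.y)
        assert (clf.coef_ != 0).sum() == 0  # full shrinkage limit

    def test_same_seed_same_support(self):
        t = make_tabular(200, 30, 3, 1.0, seed=1)
        X = _frame(t.X)
        assert (lasso_select(X, t.y, seed=4).support
                == lasso_select(X, t.y, seed=4).support)

    def test_one_class_labels_rejected(self):
        t = make_tabular(50, 5, 1, 1.0, seed=0)
        with pytest.raises(ValueError, match="one class"):
            lasso_select(_frame(t.X), np.zeros(50))


@pytest.fixture(scope="module")
def toy_model(bench_net_config):
    rng = np.random.default_rng(0)
    n = 120
    y = rng.integers(0, 2, n)
    X = rng.standard_normal((n, 3))
    X[:, 0] += 2.0 * y
    frame = _frame(X)
    frame.index = [f"pt{i}" for i in range(n)]
    model = train_supervised(frame, y, bench_net_config(seed=0,
                                                        max_epochs=30))
    return model, frame, y


class TestPseudoLabel:
    def test_gate_partitions_scores(self, toy_model):
        model, X, _ = toy_model
        pool = X.copy()
        pool.index = [f"u{i}" for i in range(len(pool))]
        ps = pseudo_label(model, pool, 0.3, 0.7)
        scores = model.predict_scores(pool)
        keep = (scores <= 0.3) | (scores >= 0.7)
        assert len(ps) == keep.sum()
        assert np.all((ps.confidences <= 0.3) | (ps.confidences >= 0.7))
        assert np.array_equal(ps.labels, (ps.confidences >= 0.7).astype(int))

    def test_degenerate_gate_keeps_everything(self, toy_model):
        model, X, _ = toy_model
        pool = X.copy()
        pool.index = [f"u{i}" for i in range(len(pool))]
        eps = 1e-12
        ps = pseudo_label(model, pool, 0.5 - eps, 0.5 + eps)
        assert len(ps) == len(pool)

    def test_maximal_gate_keeps_almost_nothing(self, toy_model):
        model, X, _ = toy_model
        pool = X.copy()
        pool.index = [f"u{i}" for i in range(len(pool))]
        ps = pseudo_label(model, pool, 0.0, 1.0)
        scores = model.predict_scores(pool)
        assert len(ps) == ((scores == 0) | (scores == 1)).sum()

    def test_monotone_gate_property(self, toy_model):
        model, X, _ = toy_model
        pool = X.copy()
        pool.index = [f"u{i}" for i in range(len(pool))]
        wide = pseudo_label(model, pool, 0.1, 0.9)
        narrow = pseudo_label(model, pool, 0.3, 0.7)
        assert set(wide.ids) <= set(narrow.ids)

    def test_invalid_gate_rejected(self, toy_model):
        model, X, _ = toy_model
        with pytest.raises(ValueError):
            pseudo_label(model, X, 0.6, 0.9)

    def test_gated_pseudo_labels_beat_band_inclusive_ones(
            self, bench_net_config):
        # errors concentrate near the decision boundary, so gating should
        # lower the pseudo-label error rate vs labeling the whole pool
        gated, ungated = [], []
        for seed in range(6):
            Xl, yl, Xu, yu, _, _ = make_semisup_benchmark(seed=seed)
            frame = _frame(Xl)
            frame.index = [f"l{i}" for i in range(len(frame))]
            model = train_supervised(frame, yl, bench_net_config(
                seed=seed, max_epochs=30))
            pool = _frame(Xu)
            pool.index = [f"u{i}" for i in range(len(pool))]
            scores = model.predict_scores(pool)
            pred_all = (scores >= 0.5).astype(int)
            keep = (scores <= 0.2) | (scores >= 0.8)
            if keep.sum() == 0:
                continue
            gated.append((pred_all[keep] != yu[keep]).mean())
            ungated.append((pred_all != yu).mean())
        assert np.median(gated) < np.median(ungated)


class TestCheckpoint:
    def test_save_load_roundtrip_preserves_scores(self, toy_model, tmp_path):
        from radpdl1.model import load_model, save_model
        model, X, _ = toy_model
        save_model(model, tmp_path / "model.pkl")
        back = load_model(tmp_path / "model.pkl")
        assert np.array_equal(back.predict_scores(X),
                              model.predict_scores(X))
        assert back.selection.support == model.selection.support

    def test_non_checkpoint_rejected(self, tmp_path):
        import pickle
        from radpdl1.model import load_model
        with (tmp_path / "junk.pkl").open("wb") as fh:
            pickle.dump({"not": "a model"}, fh)
        with pytest.raises(ValueError, match="checkpoint"):
            load_model(tmp_path / "junk.pkl")


class TestSelfTrain:
    def _pools(self, seed, bench_net_config):
        Xl, yl, Xu, yu, Xt, yt = make_semisup_benchmark(
            n_labeled=40, n_unlabeled=120, n_test=100, seed=seed)
        lab = _frame(Xl)
        lab.index = [f"l{i}" for i in range(len(lab))]
        unlab = _frame(Xu)
        unlab.index = [f"u{i}" for i in range(len(unlab))]
        return lab, yl, unlab, _frame(Xt), yt

    def test_empty_pool_returns_supervised_model(self, bench_net_config):
        lab, yl, unlab, _, _ = self._pools(0, bench_net_config)
        cfg = bench_net_config(seed=0, max_epochs=20)
        m_self = self_train(lab, yl, unlab.iloc[:0], cfg)
        m_sup = train_supervised(lab, yl, cfg)
        for key in m_self.net.params:
            assert np.array_equal(m_self.net.params[key],
                                  m_sup.net.params[key])

    def test_test_id_in_pool_raises_leakage_error(self, bench_net_config):
        lab, yl, unlab, _, _ = self._pools(1, bench_net_config)
        with pytest.raises(ValueError, match="leakage"):
            self_train(lab, yl, unlab, bench_net_config(seed=1),
                       test_ids=[unlab.index[0]])

    def test_labeled_overlap_raises(self, bench_net_config):
        lab, yl, unlab, _, _ = self._pools(2, bench_net_config)
        bad = unlab.copy()
        bad.index = [lab.index[0]] + list(bad.index[1:])
        with pytest.raises(ValueError, match="overlaps labeled"):
            self_train(lab, yl, bad, bench_net_config(seed=2))

    def test_records_pseudo_label_provenance(self, bench_net_config):
        lab, yl, unlab, _, _ = self._pools(3, bench_net_config)
        model = self_train(lab, yl, unlab,
                           bench_net_config(seed=3, max_epochs=20))
        rec = model.pseudo_label_record
        assert rec is not None
        assert set(rec.ids) <= set(unlab.index)
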