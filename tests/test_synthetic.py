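"""Generator behaviour: determinism, label-link calibration, survival."""

import numpy as np
import pytest
from scipy import stats

from radpdl1.synthetic import (PhantomSpec, SyntheticCohort, make_cohort,
                               make_phantom, make_semisup_benchmark,
                               make_survival, make_tabular)


class TestPhantom:
    def test_zero_heterogeneity_interior_is_constant(self):
        spec = PhantomSpec(grid_shape=(24, 24, 24), radii_mm=(8, 7, 6),
                           base_hu=-100.0, heterogeneity=0.0, seed=1)
        vol = make_phantom(spec)
        assert np.all(vol.intensities[vol.mask] == -100.0)
        assert np.all(vol.intensities[~vol.mask] == -900.0)

    def test_same_seed_bit_identical(self):
        spec = PhantomSpec(grid_shape=(24, 24, 24), radii_mm=(8, 7, 6),
                           heterogeneity=35.0, seed=9)
        a, b = make_phantom(spec), make_phantom(spec)
        assert np.array_equal(a.intensities, b.intensities)
        assert np.array_equal(a.mask, b.mask)

    def test_interior_sd_tracks_heterogeneity(self):
        spec = PhantomSpec(grid_shape=(48, 48, 48), radii_mm=(14, 13, 12),
                           heterogeneity=50.0, seed=1)
        vol = make_phantom(spec)
        sd = vol.intensities[vol.mask].std()
        assert 0.8 * 50 <= sd <= 1.2 * 50

    def test_oversized_radii_rejected(self):
        with pytest.raises(ValueError, match="fit"):
            PhantomSpec(grid_shape=(24, 24, 24), radii_mm=(20, 8, 8))


class TestCohort:
    def test_prevalence_within_binomial_bounds(self):
        cohort = make_cohort(n_labeled=200, n_unlabeled=0, prevalence=0.5,
                             seed=3, make_volumes=False)
        n1 = int(cohort.labeled["true_label"].sum())
        lo, hi = stats.binom.ppf([0.005, 0.995], 200, 0.5)
        assert lo <= n1 <= hi

    def test_null_label_effect_heterogeneity_indistinguishable(self):
        pvals = []
        for seed in range(20):
            c = make_cohort(n_labeled=200, n_unlabeled=0, label_effect=0.0,
                            seed=seed, make_volumes=False)
            t = c.labeled
            het1 = t.loc[t["true_label"] == 1, "heterogeneity"]
            het0 = t.loc[t["true_label"] == 0, "heterogeneity"]
            pvals.append(stats.ks_2samp(het1, het0).pvalue)
        assert np.median(pvals) > 0.01

    def test_positive_label_effect_raises_heterogeneity_of_class1(self):
        c = make_cohort(n_labeled=300, n_unlabeled=0, label_effect=3.0,
                        seed=0, make_volumes=False)
        t = c.labeled
        assert (t.loc[t["true_label"] == 1, "heterogeneity"].mean()
                > t.loc[t["true_label"] == 0, "heterogeneity"].mean())

    def test_no_unlabeled_is_valid(self):
        c = make_cohort(n_labeled=20, n_unlabeled=0, seed=1,
                        grid_shape=(32, 32, 32))
        assert len(c.unlabeled) == 0
        assert len(c.volumes) == 20

    def test_too_few_labeled_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            make_cohort(n_labeled=3, make_volumes=False)

    def test_duplicate_ids_rejected(self):
        c = make_cohort(n_labeled=6, n_unlabeled=0, make_volumes=False)
        tbl = c.table.copy()
        tbl.loc[1, "patient_id"] = tbl.loc[0, "patient_id"]
        with pytest.raises(ValueError, match="unique"):
            SyntheticCohort([], tbl)


class TestTabular:
    def test_reproducible_given_seed(self):
        a = make_tabular(50, 10, 3, 1.0, seed=5)
        b = make_tabular(50, 10, 3, 1.0, seed=5)
        assert np.array_equal(a.X, b.X) and np.array_equal(a.y, b.y)

    def test_sparsity_structure(self):
        t = make_tabular(100, 30, 5, 0.8, seed=1)
        assert (t.beta_true != 0).sum() == 5
        assert np.isfinite(t.X).all()

    def test_null_effect_gives_chance_level_auc(self):
        from sklearn.linear_model import LogisticRegression
        from sklearn.metrics import roc_auc_score
        t = make_tabular(2000, 10, 5, 0.0, seed=2)
        half = 1000
        clf = LogisticRegression().fit(t.X[:half], t.y[:half])
        auc = roc_auc_score(t.y[half:], clf.predict_proba(t.X[half:])[:, 1])
        assert 0.4 <= auc <= 0.6


class TestSurvival:
    def test_zero_censoring_observes_all_events(self):
        labels = np.random.default_rng(0).integers(0, 2, 100)
        _, event = make_survival(labels, censor_fraction=0.0, seed=1)
        assert event.all()

    def test_censor_fraction_calibrated(self):
        labels = np.random.default_rng(0).integers(0, 2, 400)
        for target in (0.2, 0.4):
            fracs = [1 - make_survival(labels, censor_fraction=target,
                                       seed=s)[1].mean() for s in range(5)]
            assert abs(np.mean(fracs) - target) < 0.05

    def test_null_hazard_ratio_gives_uniform_logrank(self):
        from lifelines.statistics import logrank_test
        labels = np.random.default_rng(3).integers(0, 2, 200)
        rejections = 0
        for seed in range(20):
            t, e = make_survival(labels, hazard_ratio=1.0,
                                 censor_fraction=0.2, seed=seed)
            res = logrank_test(t[labels == 1], t[labels == 0],
                               e[labels == 1], e[labels == 0])
            rejections += res.p_value < 0.05
        assert rejections <= 4  # ~binomial(20, 0.05) upper range

    def test_protective_hazard_lengthens_survival(self):
        labels = np.concatenate([np.zeros(300, int), np.ones(300, int)])
        t, e = make_survival(labels, hazard_ratio=0.4, censor_fraction=0.0,
                             seed=4)
        assert np.median(t[labels == 1]) > np.median(t[labels == 0])


class TestLabelEffectMonotonicity:
    def test_stronger_label_link_raises_achievable_auc(self):
        """A logistic baseline on extracted radiomics features should
        discriminate better as the heterogeneity-label link strengthens."""
        from sklearn.linear_model import LogisticRegression
        from sklearn.model_selection import cross_val_score
        from sklearn.pipeline import make_pipeline
        from sklearn.preprocessing import StandardScaler

        from radpdl1.features import (ExtractionConfig, extract_cohort)
        from radpdl1.filters import FilterBankConfig
        from radpdl1.preprocess import preprocess

        cfg = ExtractionConfig(filters=FilterBankConfig(
            log_sigmas_mm=(1.0,)))  # reduced bank keeps the test fast
        med_aucs = []
        for effect in (0.5, 2.0, 5.0):
            aucs = []
            for seed in range(2):
                c = make_cohort(n_labeled=24, n_unlabeled=0,
                                label_effect=effect, seed=seed,
                                grid_shape=(32, 32, 32))
                vols = [preprocess(v) for v in c.volumes]
                X = extract_cohort(vols, cfg).to_numpy()
                y = c.labeled["true_label"].to_numpy()
                if len(np.unique(y)) < 2:
                    continue
                clf = make_pipeline(StandardScaler(),
                                    LogisticRegression(max_iter=2000))
                aucs.append(cross_val_score(clf, X, y, cv=3,
                                            scoring="roc_auc").mean())
            med_aucs.append(float(np.median(aucs)))
        assert med_aucs[2] > med_aucs[0]


class TestSemisupBenchmark:
    def test_shapes_and_determinism(self):
        out1 = make_semisup_benchmark(seed=2)
        out2 = make_semisup_benchmark(seed=2)
        Xl, yl, Xu, yu, Xt, yt = out1
        assert Xl.shape == (60, 20) and Xu.shape == (600, 20)
        assert Xt.shape == (400, 20)
        for a, b in zip(out1, out2):
            assert np.array_equal(a, b)

    def test_clusters_are_separable_in_the_limit(self):
        from sklearn.linear_model import LogisticRegression
        from sklearn.metrics import roc_auc_score
        Xl, yl, Xu, yu, Xt, yt = make_semisup_benchmark(
            n_labeled=2000, seed=0)
        clf = LogisticRegression().fit(Xl, yl)
        assert roc_auc_score(yt, clf.predict_proba(Xt)[:, 1]) > 0.9
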