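import numpy as np
import pandas as pd
import pytest
from scipy import stats

from helpers import pair_count_auroc
from regulonml import classify as cl
from regulonml.features import FeatureMatrix
from regulonml.genome_io import Regulon


class TestAuroc:
    def test_perfect_separation(self):
        assert cl.auroc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_two_of_four_concordant_pairs(self):
        # pos {0.8, 0.2} vs neg {0.6, 0.4}: concordant pairs (0.8,0.6),(0.8,0.4)
        assert cl.auroc([0.8, 0.2, 0.6, 0.4], [1, 1, 0, 0]) == 0.5

    def test_all_ties_give_half(self):
        assert cl.auroc([0.5] * 6, [1, 1, 1, 0, 0, 0]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            cl.auroc([0.1, 0.2], [1, 1])

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_pair_count_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 40))
        scores = np.round(rng.normal(size=n), 1)  # rounding forces ties
        labels = rng.integers(0, 2, size=n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        assert cl.auroc(scores, labels) == pytest.approx(
            pair_count_auroc(scores, labels), abs=1e-12
        )


class TestSmoteTomek:
    def test_synthetic_points_are_convex_combinations(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0]] + [[10 + i, 10.0] for i in range(8)])
        y = np.array([1, 1] + [0] * 8)
        Xr, yr = cl.smote_tomek(X, y, k=1, seed=0)
        new = Xr[len(X):]
        # every synthetic point lies on the segment between (0,0) and (1,1)
        assert np.allclose(new[:, 0], new[:, 1])
        assert ((new >= 0) & (new <= 1)).all()

    def test_classes_balanced_before_tomek(self):
        # classes far apart: no Tomek links form, so balance is observable
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(0, 0.1, (4, 2)), rng.normal(50, 0.1, (20, 2))])
        y = np.r_[np.ones(4, int), np.zeros(20, int)]
        Xr, yr = cl.smote_tomek(X, y, k=3, seed=2)
        assert (yr == 1).sum() == (yr == 0).sum() == 20

    def test_tomek_removes_majority_member_only(self):
        # minority (0,0) and majority (0.01, 0.01) are mutual nearest
        # neighbors of each other across classes
        X = np.array([[0.0, 0.0], [0.01, 0.01], [5.0, 5.0], [6.0, 6.0],
                      [-4.0, 2.0], [1.0, 1.0]])
        y = np.array([1, 0, 0, 0, 0, 1])
        Xr, yr, origin = cl.smote_tomek(X, y, k=1, seed=3, return_indices=True)
        kept_originals = set(origin[origin < len(X)])
        assert 1 not in kept_originals  # majority partner removed
        assert 0 in kept_originals      # minority member retained

    def test_singleton_minority_duplicates_with_warning(self):
        X = np.array([[0.0, 0.0], [5.0, 5.0], [6.0, 5.0], [5.5, 6.0]])
        y = np.array([1, 0, 0, 0])
        with pytest.warns(UserWarning, match="size 1"):
            Xr, yr = cl.smote_tomek(X, y, k=5, seed=0)
        assert (yr == 1).sum() >= 3


def make_matrix(n=60, n_pos=12, n_features=4, seed=0, signal=2.0, groups=None):
    rng = np.random.default_rng(seed)
    y = np.zeros(n, int)
    y[rng.choice(n, size=n_pos, replace=False)] = 1
    X = rng.normal(size=(n, n_features))
    X[y == 1, 0] += signal
    idx = [f"P{i}" for i in range(n)]
    if groups is None:
        groups = [f"G{i // 2}" for i in range(n)]
    return FeatureMatrix(
        X=pd.DataFrame(X, index=idx, columns=[f"f{j}" for j in range(n_features)]),
        labels=pd.DataFrame({"reg": y}, index=idx),
        groups=pd.Series(groups, index=idx),
    )


class TestCrossValidate:
    def test_separable_signal_yields_high_auroc(self):
        m = make_matrix(n=120, n_pos=24, signal=4.0, seed=1)
        res = cl.cross_validate(m, "reg", cl.ClassifierConfig(seed=1))
        assert res.mean_auroc >= 0.9
        assert res.status == "good"

    def test_fewer_than_two_positives_is_data_limited(self):
        m = make_matrix(n=40, n_pos=1, seed=2)
        res = cl.cross_validate(m, "reg", cl.ClassifierConfig(seed=2))
        assert res.status == "data-limited" and res.per_fold_auroc == ()

    def test_small_regulon_oversamples_and_shrinks_folds(self):
        m = make_matrix(n=40, n_pos=3, signal=4.0, seed=3,
                        groups=[f"G{i}" for i in range(40)])
        res = cl.cross_validate(m, "reg", cl.ClassifierConfig(seed=3))
        assert 0 < len(res.per_fold_auroc) <= 3

    @pytest.mark.parametrize("seed", range(10))
    def test_groups_never_span_folds(self, seed):
        """Grouped-CV contract on random datasets (assert inside the splitter)."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(30, 60))
        m = make_matrix(n=n, n_pos=max(5, n // 5), seed=seed,
                        groups=[f"G{rng.integers(0, n // 3)}" for _ in range(n)])
        cl.cross_validate(m, "reg", cl.ClassifierConfig(seed=seed, max_iter=500))

    def test_resample_before_split_mode_runs(self):
        m = make_matrix(n=80, n_pos=16, signal=4.0, seed=4)
        res = cl.cross_validate(
            m, "reg", cl.ClassifierConfig(seed=4, resample_before_split=True)
        )
        assert res.mean_auroc > 0.8


class TestFitFinal:
    def test_weight_sign_matches_separation(self):
        m = make_matrix(n=80, n_pos=20, n_features=2, signal=4.0, seed=5)
        model = cl.fit_final(m, "reg", cl.ClassifierConfig(seed=5))
        assert model.weights["f0"] > 0

    def test_stronger_regularization_shrinks_l1_norm(self):
        m = make_matrix(n=80, n_pos=20, signal=2.0, seed=6)
        weak = cl.fit_final(m, "reg", cl.ClassifierConfig(seed=6, inverse_regularization=1.0))
        strong = cl.fit_final(m, "reg", cl.ClassifierConfig(seed=6, inverse_regularization=0.01))
        assert strong.weights.abs().sum() < weak.weights.abs().sum()

    def test_refit_identical(self):
        m = make_matrix(n=60, n_pos=12, seed=7)
        a = cl.fit_final(m, "reg", cl.ClassifierConfig(seed=7))
        b = cl.fit_final(m, "reg", cl.ClassifierConfig(seed=7))
        pd.testing.assert_series_equal(a.weights, b.weights)


class TestShapLinear:
    def test_worked_example_and_efficiency(self):
        model = cl.FittedModel(
            regulon="r",
            weights=pd.Series([2.0, -1.0], index=["a", "b"]),
            intercept=0.0,
        )
        X = pd.DataFrame([[1.0, 0.0]], columns=["a", "b"])
        bg = pd.Series([0.5, 0.5], index=["a", "b"])
        rep = cl.shap_linear(model, X, background=bg)
        assert rep.shap_values.iloc[0].tolist() == [1.0, 0.5]
        f_x = model.decision_function(X)[0]
        f_bg = 2.0 * 0.5 - 1.0 * 0.5
        assert rep.shap_values.iloc[0].sum() == pytest.approx(f_x - f_bg, abs=1e-9)

    def test_zero_weight_feature_gets_zero_attribution(self):
        rng = np.random.default_rng(8)
        X = pd.DataFrame(rng.normal(size=(20, 3)), columns=["a", "b", "c"])
        model = cl.FittedModel("r", pd.Series([1.0, 0.0, -2.0], index=["a", "b", "c"]), 0.1)
        rep = cl.shap_linear(model, X)
        assert (rep.shap_values["b"] == 0).all()

    def test_background_row_gets_all_zeros(self):
        X = pd.DataFrame([[1.0, 2.0], [1.0, 2.0]], columns=["a", "b"])
        model = cl.FittedModel("r", pd.Series([3.0, 4.0], index=["a", "b"]), 0.0)
        rep = cl.shap_linear(model, X)  # background = column means = the rows
        assert np.allclose(rep.shap_values.to_numpy(), 0.0)

    def test_top5_ties_broken_lexicographically(self):
        X = pd.DataFrame(np.ones((4, 6)), columns=list("fedcba"))
        X.iloc[0] = 0.0
        model = cl.FittedModel("r", pd.Series(1.0, index=list("fedcba")), 0.0)
        rep = cl.shap_linear(model, X)
        assert list(rep.top5) == ["a", "b", "c", "d", "e"]


class TestCompareRegulons:
    def test_set_partition(self):
        ica = Regulon("X", "ICA", frozenset("abc"))
        chip = Regulon("X", "ChIP", frozenset("bcd"))
        cmp = cl.compare_regulons(ica, chip, {g: 1.0 for g in "abcd"})
        assert cmp.shared == {"b", "c"}
        assert cmp.ica_only == {"a"} and cmp.chip_only == {"d"}

    def test_maximal_u_when_shared_dominate(self):
        ica = Regulon("X", "ICA", frozenset(["a", "b", "c"]))
        chip = Regulon("X", "ChIP", frozenset(["a", "b", "d"]))
        scores = {"a": 10.0, "b": 9.0, "c": 1.0, "d": 0.5}
        cmp = cl.compare_regulons(ica, chip, scores)
        assert cmp.u_statistic == len(cmp.shared) * (len(cmp.ica_only) + len(cmp.chip_only))

    def test_empty_intersection_reports_undefined(self):
        ica = Regulon("X", "ICA", frozenset("ab"))
        chip = Regulon("X", "ChIP", frozenset("cd"))
        cmp = cl.compare_regulons(ica, chip, {g: 1.0 for g in "abcd"})
        assert cmp.u_statistic is None and cmp.p_value is None

    def test_type_i_error_controlled_under_null(self):
        rng = np.random.default_rng(9)
        ica = Regulon("X", "ICA", frozenset(f"g{i}" for i in range(25)))
        chip = Regulon("X", "ChIP", frozenset(f"g{i}" for i in range(10, 35)))
        genes = sorted(ica.members | chip.members)
        rejections = 0
        reps = 1000
        for _ in range(reps):
            scores = dict(zip(genes, rng.normal(size=len(genes))))
            cmp = cl.compare_regulons(ica, chip, scores)
            if cmp.p_value is not None and cmp.p_value < 0.05:
                rejections += 1
        assert rejections / reps <= 0.07
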