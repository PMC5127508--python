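"""Random-baseline and 1NN survival predictors and their comparison stats."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ironsig import (
    GenePanel,
    PredictionResult,
    compare_residuals,
    median_residual,
    one_nn_predict,
    prediction_correlation,
    random_baseline,
)


def clinical_frame(times, events=None, ids=None):
    n = len(times)
    return pd.DataFrame(
        {
            "os_months": list(map(float, times)),
            "event": [True] * n if events is None else events,
        },
        index=pd.Index(ids or [f"s{i + 1}" for i in range(n)], name="sample_id"),
    )


def zmatrix(rows, ids, genes=("g1",)):
    return pd.DataFrame(np.atleast_2d(rows), index=list(genes), columns=ids)


class TestRandomBaseline:
    def test_two_samples_forced_swap(self):
        clin = clinical_frame([10, 20])
        pred = random_baseline(clin, n_reps=5, seed=0)
        assert list(pred.predicted_months) == [20.0, 10.0]

    def test_degenerate_equal_survivals(self):
        clin = clinical_frame([12, 12, 12, 12])
        pred = random_baseline(clin, seed=1)
        assert np.allclose(pred.residuals, 0.0)

    def test_censored_samples_excluded(self):
        clin = clinical_frame([10, 20, 99], events=[True, True, False])
        pred = random_baseline(clin, seed=2)
        assert pred.sample_ids == ["s1", "s2"]
        assert list(pred.predicted_months) == [20.0, 10.0]

    def test_mean_prediction_converges_to_leave_one_out_mean(self):
        rng = np.random.default_rng(3)
        times = rng.exponential(40, size=200)
        clin = clinical_frame(times)
        total = times.sum()
        exact = (total - times) / (len(times) - 1)
        err_small = np.abs(
            random_baseline(clin, n_reps=20, seed=4).predicted_months - exact
        ).mean()
        err_large = np.abs(
            random_baseline(clin, n_reps=2000, seed=4).predicted_months - exact
        ).mean()
        assert err_large < err_small / 3  # Monte-Carlo error shrinks ~1/sqrt(reps)

    def test_requires_two_evaluable(self):
        with pytest.raises(ValueError):
            random_baseline(clinical_frame([5], events=[True]))


class TestOneNN:
    def test_duplicated_sample_predicts_its_twin(self):
        z = zmatrix([[0.3, 0.3, 5.0]], ["s1", "s2", "s3"])
        clin = clinical_frame([11, 22, 33])
        pred = one_nn_predict(z, GenePanel("p", ("g1",)), clin)
        assert list(pred.predicted_months)[:2] == [22.0, 11.0]

    def test_three_points_on_a_line(self):
        # coordinates 0, 1, 10 with survivals 5, 8, 30 -> neighbors are
        # (s2, s1, s2) by exhaustive pairwise distances.
        z = zmatrix([[0.0, 1.0, 10.0]], ["s1", "s2", "s3"])
        clin = clinical_frame([5, 8, 30])
        pred = one_nn_predict(z, GenePanel("p", ("g1",)), clin)
        assert list(pred.predicted_months) == [8.0, 5.0, 8.0]

    def test_invariant_to_sample_order(self):
        rng = np.random.default_rng(5)
        ids = [f"s{i}" for i in range(12)]
        z = pd.DataFrame(rng.standard_normal((3, 12)), index=list("abc"), columns=ids)
        clin = clinical_frame(rng.exponential(30, 12), ids=ids)
        panel = GenePanel("p", ("a", "b", "c"))
        base = one_nn_predict(z, panel, clin)
        shuffled = one_nn_predict(
            z[ids[::-1]], panel, clin.loc[ids[::-1]]
        )
        mapped = dict(zip(shuffled.sample_ids, shuffled.predicted_months))
        assert [mapped[s] for s in base.sample_ids] == list(base.predicted_months)

    def test_invariant_to_adding_constant_gene(self):
        rng = np.random.default_rng(6)
        ids = [f"s{i}" for i in range(10)]
        z = pd.DataFrame(rng.standard_normal((2, 10)), index=["a", "b"], columns=ids)
        clin = clinical_frame(rng.exponential(30, 10), ids=ids)
        base = one_nn_predict(z, GenePanel("p", ("a", "b")), clin)
        z2 = pd.concat([z, pd.DataFrame([[0.7] * 10], index=["const"], columns=ids)])
        plus = one_nn_predict(z2, GenePanel("q", ("a", "b", "const")), clin)
        assert list(base.predicted_months) == list(plus.predicted_months)

    def test_missing_zscores_rejected(self):
        z = zmatrix([[0.0, np.nan, 1.0]], ["s1", "s2", "s3"])
        clin = clinical_frame([5, 8, 30])
        with pytest.raises(ValueError, match="missing"):
            one_nn_predict(z, GenePanel("p", ("g1",)), clin)

    def test_censored_neighbors_optional(self):
        z = zmatrix([[0.0, 0.1, 5.0]], ["s1", "s2", "s3"])
        clin = clinical_frame([5, 99, 30], events=[True, False, True])
        default = one_nn_predict(z, GenePanel("p", ("g1",)), clin)
        assert list(default.predicted_months) == [30.0, 5.0]  # s2 not a donor
        wide = one_nn_predict(
            z, GenePanel("p", ("g1",)), clin, include_censored_neighbors=True
        )
        assert list(wide.predicted_months) == [99.0, 99.0]  # s2 nearest to both


class TestResidualStats:
    def make(self, residuals):
        r = np.asarray(residuals, dtype=float)
        return PredictionResult(
            sample_ids=[f"s{i}" for i in range(len(r))],
            predicted_months=r,
            observed_months=np.zeros(len(r)),
        )

    @pytest.mark.parametrize(
        "residuals,expected",
        [([1, 2, 100], 2.0), ([1, 3], 2.0), ([0, 0, 0], 0.0)],
    )
    def test_median_residual(self, residuals, expected):
        assert median_residual(self.make(residuals)) == expected

    def test_identical_multisets_give_p_one(self):
        a = self.make([3, 1, 4, 1, 5])
        b = self.make([1, 1, 3, 4, 5])
        assert compare_residuals(a, b) == pytest.approx(1.0)

    def test_exact_enumeration_of_separated_groups(self):
        # U = 0; all C(6,3) = 20 assignments enumerated; two are as extreme.
        a, b = self.make([1, 2, 3]), self.make([10, 11, 12])
        assert compare_residuals(a, b) == pytest.approx(0.1)

    def test_symmetry(self):
        a, b = self.make([1, 5, 9, 2]), self.make([4, 4, 7])
        assert compare_residuals(a, b) == pytest.approx(compare_residuals(b, a))

    def test_large_sample_branch_matches_scipy(self):
        rng = np.random.default_rng(7)
        a = self.make(rng.exponential(10, 40))
        b = self.make(rng.exponential(14, 35))
        expected = stats.mannwhitneyu(
            a.residuals, b.residuals, alternative="two-sided", method="asymptotic"
        ).pvalue
        assert compare_residuals(a, b) == pytest.approx(float(expected))


class TestCorrelation:
    def test_perfect_linear(self):
        x = np.arange(10, dtype=float)
        assert prediction_correlation(x, 2 * x + 1) == pytest.approx(1.0)

    def test_perfect_inverse(self):
        x = np.arange(10, dtype=float)
        assert prediction_correlation(x, -x) == pytest.approx(-1.0)

    def test_independent_pairs_near_zero(self):
        rng = np.random.default_rng(8)
        r = prediction_correlation(
            rng.standard_normal(10_000), rng.standard_normal(10_000)
        )
        assert abs(r) < 0.05

    def test_zero_variance_warns_nan(self):
        with pytest.warns(UserWarning, match="zero variance"):
            r = prediction_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert np.isnan(r)
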