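"""Chained-equations engine: elementary methods, structures, pooling."""

import numpy as np
import pandas as pd
import pytest

from cesdimpute import (
    ITEM_COLUMNS,
    MCARAmputer,
    MICEImputer,
    build_model,
    mice_run,
    pool_rubin,
    pooled_prevalence,
)
from cesdimpute.mice import (
    ImputationSpec,
    logreg_impute_variable,
    pmm_impute_variable,
    polyreg_impute_variable,
)
from cesdimpute.scale import attach_score_columns


class TestPoolRubin:
    def test_direct_formula_evaluation(self):
        pooled = pool_rubin([10, 11, 12, 13, 14], [1, 1, 1, 1, 1])
        assert pooled.estimate == 12
        assert pooled.between_var == pytest.approx(2.5)
        assert pooled.total_var == pytest.approx(4.0)
        assert pooled.se == pytest.approx(2.0)

    def test_degenerate_between_variance(self):
        pooled = pool_rubin([7.0] * 4, [0.25] * 4)
        assert pooled.estimate == 7.0
        assert pooled.between_var == 0.0
        assert pooled.se == pytest.approx(0.5)

    def test_permutation_invariant(self):
        a = pool_rubin([1.0, 2.0, 4.0], [0.1, 0.2, 0.3])
        b = pool_rubin([4.0, 1.0, 2.0], [0.3, 0.1, 0.2])
        assert a.estimate == pytest.approx(b.estimate)
        assert a.total_var == pytest.approx(b.total_var)

    def test_single_estimate_rejected(self):
        with pytest.raises(ValueError, match="m >= 2"):
            pool_rubin([1.0], [0.1])

    def test_total_at_least_within(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            est = rng.normal(size=5)
            var = rng.random(5)
            pooled = pool_rubin(est, var)
            assert pooled.total_var >= pooled.within_var


class TestBuildModel:
    def test_parsimonious_predictor_rows(self, small_cohort):
        spec = build_model("items_parsimonious", small_cohort, method="pmm")
        sums = spec.predictors.sum(axis=1)
        assert (sums == 19).all()
        assert len(spec.methods) == 20

    def test_full_predictor_rows(self, small_cohort):
        spec = build_model("items_full", small_cohort, method="polyreg")
        assert (spec.predictors.sum(axis=1) == 19 + 17).all()

    def test_score_structure_single_target(self, small_cohort):
        data = attach_score_columns(small_cohort)
        spec = build_model("score_pmm", data)
        assert list(spec.methods) == ["cesd_score"]
        assert spec.predictors.loc["cesd_score"].sum() == 17

    def test_unknown_structure_rejected(self, small_cohort):
        with pytest.raises(ValueError, match="unknown structure"):
            build_model("items_quadratic", small_cohort)

    def test_no_self_prediction(self, small_cohort):
        spec = build_model("items_full", small_cohort)
        for v in spec.predictors.index:
            assert not spec.predictors.loc[v, v]


class TestElementaryMethods:
    def test_pmm_no_missing_is_identity(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=30)
        out = pmm_impute_variable(
            y, np.zeros(30, bool), rng.normal(size=(30, 2)), 5, 1e-4, rng
        )
        np.testing.assert_array_equal(out, y)

    def test_pmm_uniform_donor_under_constant_predictors(self):
        """With constant predictions and donor_k=1, imputation reduces to a
        uniform draw from the observed values (Monte-Carlo oracle)."""
        rng = np.random.default_rng(12)
        y_obs = np.repeat([0.0, 1.0, 2.0, 3.0], [10, 20, 30, 40])
        n_mis = 20000
        y = np.concatenate([y_obs, np.zeros(n_mis)])
        miss = np.zeros(len(y), bool)
        miss[len(y_obs):] = True
        out = pmm_impute_variable(
            y, miss, np.zeros((len(y), 1)), 1, 1e-4, rng
        )
        freqs = pd.Series(out[miss]).value_counts(normalize=True).sort_index()
        np.testing.assert_allclose(freqs.to_numpy(), [0.1, 0.2, 0.3, 0.4], atol=0.02)

    def test_pmm_confined_to_observed_support(self):
        rng = np.random.default_rng(5)
        y = rng.integers(0, 4, 300).astype(float)
        miss = rng.random(300) < 0.3
        X = rng.normal(size=(300, 3))
        out = pmm_impute_variable(y, miss, X, 5, 1e-4, rng)
        assert set(np.unique(out[miss])) <= {0.0, 1.0, 2.0, 3.0}

    def test_polyreg_recovers_marginal_with_uninformative_predictors(self):
        rng = np.random.default_rng(42)
        probs = np.array([0.1, 0.2, 0.3, 0.4])
        y_obs = rng.choice(4, size=2000, p=probs).astype(float)
        n_mis = 12000
        y = np.concatenate([y_obs, np.zeros(n_mis)])
        miss = np.zeros(len(y), bool)
        miss[len(y_obs):] = True
        X = rng.normal(size=(len(y), 2))  # independent of y
        out = polyreg_impute_variable(
            y, miss, X, (0.0, 1.0, 2.0, 3.0), 1e-4, rng
        )
        freqs = pd.Series(out[miss]).value_counts(normalize=True).sort_index()
        np.testing.assert_allclose(freqs.to_numpy(), probs, atol=0.03)

    def test_logreg_recovers_prevalence(self):
        rng = np.random.default_rng(7)
        y_obs = (rng.random(3000) < 0.3).astype(float)
        y = np.concatenate([y_obs, np.zeros(10000)])
        miss = np.zeros(len(y), bool)
        miss[3000:] = True
        X = rng.normal(size=(len(y), 2))
        out = logreg_impute_variable(y, miss, X, 1e-4, rng)
        assert out[miss].mean() == pytest.approx(y_obs.mean(), abs=0.03)

    def test_logreg_near_degenerate_target(self):
        """A single positive case under heavy ridge yields almost-all-zero
        imputations (the penalised fit shrinks toward the majority)."""
        rng = np.random.default_rng(9)
        y_obs = np.zeros(500)
        y_obs[0] = 1.0
        y = np.concatenate([y_obs, np.zeros(2000)])
        miss = np.zeros(len(y), bool)
        miss[500:] = True
        X = rng.normal(size=(len(y), 2))
        out = logreg_impute_variable(y, miss, X, ridge=1.0, rng=rng)
        assert out[miss].mean() < 0.05


class TestMiceRun:
    def test_no_missing_gives_identical_copies(self, small_cohort):
        sets = MICEImputer(m=3, n_iter=2, random_state=0).fit_impute(small_cohort)
        assert len(sets) == 3
        for ds in sets.datasets:
            pd.testing.assert_frame_equal(
                ds[list(ITEM_COLUMNS)], small_cohort[list(ITEM_COLUMNS)]
            )

    def test_observed_cells_bit_identical(self, small_cohort):
        amputed = MCARAmputer(k=6, random_state=3).fit(small_cohort).transform(small_cohort)
        mask = amputed[list(ITEM_COLUMNS)].isna().to_numpy()
        sets = MICEImputer(m=2, n_iter=2, random_state=1).fit_impute(amputed)
        for ds in sets.datasets:
            done = ds[list(ITEM_COLUMNS)].to_numpy()
            orig = amputed[list(ITEM_COLUMNS)].to_numpy()
            assert (done[~mask] == orig[~mask]).all()
            assert not np.isnan(done).any()

    def test_item_imputations_on_grid(self, small_cohort):
        amputed = MCARAmputer(k=6, random_state=3).fit(small_cohort).transform(small_cohort)
        sets = MICEImputer(m=2, n_iter=2, random_state=1).fit_impute(amputed)
        for ds in sets.datasets:
            vals = ds[list(ITEM_COLUMNS)].to_numpy()
            assert set(np.unique(vals)) <= {0.0, 1.0, 2.0, 3.0}

    def test_seed_reproducibility(self, small_cohort):
        amputed = MCARAmputer(k=4, random_state=8).fit(small_cohort).transform(small_cohort)
        a = MICEImputer(m=2, n_iter=2, random_state=99).fit_impute(amputed)
        b = MICEImputer(m=2, n_iter=2, random_state=99).fit_impute(amputed)
        for da, db in zip(a.datasets, b.datasets):
            pd.testing.assert_frame_equal(da, db)

    def test_distinct_imputations_differ(self, small_cohort):
        amputed = MCARAmputer(k=6, random_state=8).fit(small_cohort).transform(small_cohort)
        sets = MICEImputer(m=2, n_iter=2, random_state=0).fit_impute(amputed)
        a, b = (ds[list(ITEM_COLUMNS)].to_numpy() for ds in sets.datasets)
        assert (a != b).any()

    def test_fully_missing_variable_rejected(self, small_cohort):
        broken = small_cohort.copy()
        broken["item_01"] = np.nan
        with pytest.raises(ValueError, match="100% missing"):
            MICEImputer(m=2, n_iter=1).fit(broken)

    def test_m_below_two_rejected(self, small_cohort):
        amputed = MCARAmputer(k=2, random_state=0).fit(small_cohort).transform(small_cohort)
        with pytest.raises(ValueError, match="m must be"):
            MICEImputer(m=1).fit(amputed)

    def test_trace_shape(self, small_cohort):
        amputed = MCARAmputer(k=3, random_state=2).fit(small_cohort).transform(small_cohort)
        sets = MICEImputer(m=2, n_iter=3, random_state=0).fit_impute(amputed)
        trace = sets.trace
        # every (imputation, iteration, variable-with-missing) combination
        n_targets = trace["variable"].nunique()
        assert len(trace) == 2 * 3 * n_targets

    def test_pooled_prevalence_mean_of_identical_sets(self, small_cohort):
        sets = MICEImputer(m=3, n_iter=1, random_state=0).fit_impute(small_cohort)
        prev = pooled_prevalence(sets)
        direct = (
            small_cohort[list(ITEM_COLUMNS)].sum(axis=1) >= 16
        ).mean()
        assert prev.estimate == pytest.approx(float(direct))
        assert prev.between_var == 0.0


def test_spec_validation_rejects_missing_predictor(small_cohort):
    data = attach_score_columns(small_cohort)
    data.loc[data.index[:50], "age"] = np.nan
    spec = build_model("score_pmm", data)
    data.loc[data.index[:10], "cesd_score"] = np.nan
    with pytest.raises(ValueError, match="predictor 'age'"):
        spec.validate(data)
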