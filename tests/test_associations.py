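"""Kruskal-Wallis comparisons, GLM associations and grouped FDR."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from cadpipe.associations import (
    compare_groups,
    fdr_adjust,
    fit_association,
    kruskal_wallis,
    results_to_frame,
    run_association_suite,
)
from cadpipe.config import AnalysisConfig


def _cad_and_cohort(cad_values, group="CUA-V-", **factors):
    n = len(cad_values)
    ids = [f"P{i}" for i in range(n)]
    cad = pd.DataFrame({"id": ids, "group": group, "cad": cad_values})
    cohort = pd.DataFrame({"id": ids, "group": group, **factors})
    return cad, cohort


class TestKruskalWallis:
    def test_h_matches_rank_sum_oracle(self):
        samples = [np.array([1.0, 2, 3]), np.array([4.0, 5, 6]), np.array([7.0, 8, 9])]
        result = kruskal_wallis(samples)
        # independent oracle: direct rank computation, no ties
        pooled = np.concatenate(samples)
        ranks = stats.rankdata(pooled)
        n = len(pooled)
        offsets = np.cumsum([0] + [len(s) for s in samples[:-1]])
        h = 12.0 / (n * (n + 1)) * sum(
            len(s) * ranks[o : o + len(s)].mean() ** 2
            for s, o in zip(samples, offsets)
        ) - 3 * (n + 1)
        assert result.H == pytest.approx(h, abs=1e-12)
        assert result.df == 2
        assert result.p == pytest.approx(stats.chi2.sf(h, 2), abs=1e-12)

    def test_relabeling_invariance(self):
        a = [np.array([1.0, 5, 9]), np.array([2.0, 6, 7]), np.array([3.0, 4, 8])]
        h1 = kruskal_wallis(a).H
        h2 = kruskal_wallis([a[2], a[0], a[1]]).H
        assert h1 == pytest.approx(h2, abs=1e-12)

    def test_identical_observations_degenerate_to_null(self):
        result = kruskal_wallis([np.full(5, 2.0), np.full(4, 2.0)])
        assert result.H == 0.0
        assert result.p == 1.0

    def test_group_summaries_are_median_and_iqr(self):
        result = kruskal_wallis(
            [np.array([1.0, 2, 3, 4, 5]), np.array([10.0, 20, 30])],
            group_names=["a", "b"],
        )
        med, q1, q3 = result.group_summaries["a"]
        assert (med, q1, q3) == (3.0, 2.0, 4.0)

    def test_requires_two_nonempty_groups(self):
        with pytest.raises(ValueError):
            kruskal_wallis([np.array([1.0, 2])])
        with pytest.raises(ValueError):
            kruskal_wallis([np.array([1.0]), np.array([])])


class TestFitAssociation:
    def test_exact_linear_cad_recovers_beta(self):
        rng = np.random.default_rng(1)
        factor = rng.normal(50, 10, 40)
        z = (factor - factor.mean()) / factor.std(ddof=1)
        cad, cohort = _cad_and_cohort(3.0 * z, factor=factor)
        res = fit_association(cad, cohort, "factor", "CUA-V-")
        assert res.beta == pytest.approx(3.0, abs=1e-8)
        assert res.p_raw < 1e-10

    def test_beta_p_and_ci_match_closed_form_oracle(self):
        rng = np.random.default_rng(2)
        factor = rng.normal(0, 2, 35)
        cad_values = -1.2 * (factor - factor.mean()) / factor.std(ddof=1) + rng.normal(
            0, 2, 35
        )
        cad, cohort = _cad_and_cohort(cad_values, factor=factor)
        res = fit_association(cad, cohort, "factor", "CUA-V-")
        # independent oracle: normal equations + t distribution
        z = (factor - factor.mean()) / factor.std(ddof=1)
        X = np.column_stack([np.ones(35), z])
        beta = np.linalg.solve(X.T @ X, X.T @ cad_values)
        resid = cad_values - X @ beta
        sigma2 = resid @ resid / (35 - 2)
        se = np.sqrt(sigma2 * np.linalg.inv(X.T @ X)[1, 1])
        t = beta[1] / se
        p = 2 * stats.t.sf(abs(t), 35 - 2)
        tq = stats.t.ppf(0.975, 35 - 2)
        assert res.beta == pytest.approx(beta[1], abs=1e-10)
        assert res.p_raw == pytest.approx(p, abs=1e-10)
        assert res.ci_low == pytest.approx(beta[1] - tq * se, abs=1e-10)
        assert res.ci_high == pytest.approx(beta[1] + tq * se, abs=1e-10)

    @given(scale=st.floats(0.01, 100), shift=st.floats(-50, 50))
    def test_affine_rescaling_of_factor_changes_nothing(self, scale, shift):
        rng = np.random.default_rng(3)
        factor = rng.normal(10, 3, 30)
        cad_values = 0.5 * factor + rng.normal(0, 1, 30)
        cad, cohort = _cad_and_cohort(cad_values, factor=factor)
        base = fit_association(cad, cohort, "factor", "CUA-V-")
        cohort2 = cohort.copy()
        cohort2["factor"] = cohort2["factor"] * scale + shift
        rescaled = fit_association(cad, cohort2, "factor", "CUA-V-")
        assert rescaled.beta == pytest.approx(base.beta, rel=1e-9)
        assert rescaled.p_raw == pytest.approx(base.p_raw, rel=1e-6)

    def test_constant_factor_rejected(self):
        cad, cohort = _cad_and_cohort(np.arange(10.0), factor=np.full(10, 5.0))
        with pytest.raises(ValueError, match="constant factor"):
            fit_association(cad, cohort, "factor", "CUA-V-")

    def test_too_few_rows_rejected(self):
        cad, cohort = _cad_and_cohort(np.array([1.0, 2.0]), factor=np.array([1.0, 2.0]))
        with pytest.raises(ValueError, match="complete rows"):
            fit_association(cad, cohort, "factor", "CUA-V-")

    def test_unknown_factor_raises_key_error(self):
        cad, cohort = _cad_and_cohort(np.arange(5.0), factor=np.arange(5.0))
        with pytest.raises(KeyError):
            fit_association(cad, cohort, "nope", "CUA-V-")

    def test_covariate_adjustment_uses_same_code_path(self):
        rng = np.random.default_rng(6)
        n = 60
        factor = rng.normal(0, 1, n)
        education = rng.normal(14, 3, n)
        sex = rng.choice(["female", "male"], n)
        apoe = rng.choice([0, 1, 2], n)
        cad_values = -1.0 * factor + 0.3 * education + rng.normal(0, 1, n)
        cad, cohort = _cad_and_cohort(
            cad_values, factor=factor, education=education, sex=sex, apoe4_load=apoe
        )
        res = fit_association(
            cad, cohort, "factor", "CUA-V-",
            covariates=("sex", "apoe4_load", "education"),
        )
        assert res.model == "covariate_adjusted"
        assert res.n == n
        assert res.beta == pytest.approx(-1.0, abs=0.5)


class TestFDRAdjust:
    def test_worked_example(self):
        np.testing.assert_allclose(
            fdr_adjust([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04], atol=1e-12
        )

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(fdr_adjust([0.2]), [0.2], atol=0)

    def test_equal_p_fixed_point(self):
        np.testing.assert_allclose(fdr_adjust([0.2] * 4), [0.2] * 4, atol=1e-12)

    def test_empty_vector(self):
        assert fdr_adjust([]).size == 0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.2])

    @given(
        st.lists(st.floats(0.0, 1.0, allow_nan=False), min_size=1, max_size=20)
    )
    def test_bh_bounds_and_order_preservation(self, pvals):
        adjusted = fdr_adjust(pvals)
        assert ((adjusted >= 0) & (adjusted <= 1)).all()
        assert (adjusted >= np.asarray(pvals) - 1e-12).all()
        order = np.argsort(pvals)
        assert (np.diff(adjusted[order]) >= -1e-12).all()


class TestAssociationSuite:
    def _config(self, factor_groups, **kw):
        return AnalysisConfig(
            factor_groups=factor_groups, adjusted_factor_groups={}, **kw
        )

    def test_family_shares_one_bh_block(self):
        rng = np.random.default_rng(8)
        n = 50
        factors = {f"f{i}": rng.normal(0, 1, n) for i in range(3)}
        cad, cohort = _cad_and_cohort(rng.normal(0, 2, n), **factors)
        config = self._config({"block": ["f0", "f1", "f2"]})
        results = run_association_suite(cad, cohort, config, clinical_groups=("CUA-V-",))
        univ = [r for r in results if r.model == "univariate"]
        assert len(univ) == 3
        expected = fdr_adjust([r.p_raw for r in univ])
        np.testing.assert_allclose([r.p_fdr for r in univ], expected, atol=1e-12)

    def test_no_significant_factor_means_no_sensitivity_models(self):
        rng = np.random.default_rng(9)
        n = 40
        cad, cohort = _cad_and_cohort(
            rng.normal(0, 2, n),
            f0=rng.normal(0, 1, n),
            sex=rng.choice(["female", "male"], n),
            apoe4_load=rng.choice([0, 1], n),
            education=rng.normal(14, 3, n),
        )
        config = self._config({"block": ["f0"]})
        results = run_association_suite(cad, cohort, config, clinical_groups=("CUA-V-",))
        assert all(r.model == "univariate" for r in results)

    def test_planted_effect_triggers_sensitivity_model(self):
        rng = np.random.default_rng(10)
        n = 120
        factor = rng.normal(0, 1, n)
        cad, cohort = _cad_and_cohort(
            -2.0 * factor + rng.normal(0, 1, n),
            f0=factor,
            f1=rng.normal(0, 1, n),
            sex=rng.choice(["female", "male"], n),
            apoe4_load=rng.choice([0, 1, 2], n),
            education=rng.normal(14, 3, n),
        )
        config = self._config({"block": ["f0", "f1"]})
        results = run_association_suite(cad, cohort, config, clinical_groups=("CUA-V-",))
        sens = [r for r in results if r.model == "covariate_adjusted"]
        assert [r.factor for r in sens] == ["f0"]
        assert sens[0].p_fdr is None  # decision inherited, raw p reported
        assert sens[0].significant is True
        assert sens[0].beta == pytest.approx(-2.0, abs=0.5)

    def test_unknown_factor_skipped_with_warning(self, caplog):
        rng = np.random.default_rng(11)
        cad, cohort = _cad_and_cohort(rng.normal(0, 1, 30), f0=rng.normal(0, 1, 30))
        config = self._config({"block": ["f0", "ghost"]})
        with caplog.at_level("WARNING"):
            results = run_association_suite(
                cad, cohort, config, clinical_groups=("CUA-V-",)
            )
        assert len(results) == 1
        assert any("ghost" in r.message for r in caplog.records)

    def test_results_frame_is_long_format(self, pipeline_result):
        frame = results_to_frame(pipeline_result.associations)
        assert {"clinical_group", "factor_group", "factor", "beta", "p_raw"} <= set(
            frame.columns
        )
        assert len(frame) == len(pipeline_result.associations)


def test_compare_groups_on_pipeline_output(pipeline_result):
    comparison = pipeline_result.group_comparison
    assert comparison.df == 2
    assert comparison.H >= 0
    assert 0 <= comparison.p <= 1
    assert set(comparison.group_summaries) == {"CUA-V-", "CUA+", "CUV+"}
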