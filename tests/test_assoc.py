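import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from mirseed.assoc import (
    AssociationResult,
    association_screen,
    bh_fdr,
    confounder_check,
    dabg_filter,
    expression_filter,
    fit_trait_model,
    select_candidates,
)
from mirseed.errors import SingularDesignError, ValidationError
from mirseed.synthetic import gen_cohort


def brute_force_bh(pvals):
    """Independent step-up implementation: q_i = min_{j: p_j >= p_i} p_(j) * m / j."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * m / rank)
        q[i] = running
    return q


class TestDabgFilter:
    def test_majority_rule(self):
        kept = dabg_filter({
            "ps1": [0.01, 0.02, 0.03, 0.2],   # 3/4 -> kept
            "ps2": [0.01, 0.02, 0.2, 0.2],    # exactly half -> dropped
            "ps3": [0.5, 0.6, 0.7, 0.8],      # none -> dropped
        })
        assert kept == {"ps1"}

    def test_empty_probe_list_rejected(self):
        with pytest.raises(ValidationError, match="ps1"):
            dabg_filter({"ps1": []})


class TestExpressionFilter:
    def _expr(self, means_a, means_b):
        return pd.DataFrame(
            {"s1": means_a, "s2": means_a, "s3": means_b, "s4": means_b},
            index=["mir-a", "mir-b"],
        )

    def test_max_group_mean_strictly_above_threshold(self):
        expr = pd.DataFrame({"s1": [2.4, 2.3], "s2": [2.4, 2.3],
                             "s3": [1.0, 2.3], "s4": [1.0, 2.3]},
                            index=["hi", "boundary"])
        groups = {"s1": "ND", "s2": "ND", "s3": "T2D", "s4": "T2D"}
        assert expression_filter(expr, groups) == {"hi"}

    def test_unlabelled_sample_rejected(self):
        expr = pd.DataFrame({"s1": [3.0]}, index=["m"])
        with pytest.raises(ValidationError):
            expression_filter(expr, {"other": "ND"})


class TestFitTraitModel:
    def test_recovers_planted_effect_on_hba1c(self):
        effects = {("sim-miR-000", "HbA1c"): 0.8}
        expr, pheno, _ = gen_cohort(n_samples=500, n_mirnas=3, effects=effects, seed=42)
        res = fit_trait_model(expr, pheno, "sim-miR-000", "HbA1c")
        assert res.model == "linear" and res.converged
        assert res.beta_mirna == pytest.approx(0.8, abs=0.1)
        assert res.p_value < 1e-6

    def test_logistic_t2d_model_detects_planted_effect(self):
        effects = {("sim-miR-000", "T2D"): 1.0}
        expr, pheno, _ = gen_cohort(n_samples=500, n_mirnas=3, effects=effects, seed=7)
        res = fit_trait_model(expr, pheno, "sim-miR-000", "T2D")
        assert res.model == "logistic" and res.converged
        assert res.beta_mirna > 0.5
        assert res.p_value < 1e-4

    def test_nas_response_drops_nas_from_design(self):
        expr, pheno, _ = gen_cohort(n_samples=100, n_mirnas=2, seed=1)
        res = fit_trait_model(expr, pheno, "sim-miR-000", "NAS")
        assert "NAS" not in res.betas
        assert set(res.betas) == {"const", "age", "sex", "BMI", "log2miRNA"}

    def test_ols_matches_normal_equations_oracle(self):
        expr, pheno, _ = gen_cohort(n_samples=80, n_mirnas=2, seed=3)
        res = fit_trait_model(expr, pheno, "sim-miR-001", "glucose")
        X = np.column_stack([
            np.ones(len(pheno)),
            pheno[["NAS", "age", "sex", "BMI"]].to_numpy(dtype=float),
            expr.loc["sim-miR-001"].to_numpy(),
        ])
        y = pheno["glucose"].to_numpy()
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        got = [res.betas[k] for k in ("const", "NAS", "age", "sex", "BMI", "log2miRNA")]
        np.testing.assert_allclose(got, beta, atol=1e-8)

    def test_constant_response_is_degenerate(self):
        expr, pheno, _ = gen_cohort(n_samples=50, n_mirnas=2, seed=4)
        pheno = pheno.copy()
        pheno["glucose"] = 100.0
        with pytest.raises(SingularDesignError):
            fit_trait_model(expr, pheno, "sim-miR-000", "glucose")

    def test_constant_mirna_is_degenerate(self):
        expr, pheno, _ = gen_cohort(n_samples=50, n_mirnas=2, seed=5)
        expr = expr.copy()
        expr.loc["sim-miR-000"] = 5.0
        with pytest.raises(SingularDesignError):
            fit_trait_model(expr, pheno, "sim-miR-000", "HbA1c")

    def test_missing_values_complete_case(self):
        expr, pheno, _ = gen_cohort(n_samples=60, n_mirnas=2, seed=6)
        pheno = pheno.copy()
        pheno.loc[pheno.index[:5], "HbA1c"] = np.nan
        res = fit_trait_model(expr, pheno, "sim-miR-000", "HbA1c")
        assert res.n == 55


class TestConfounderCheck:
    def test_age_proxy_flagged(self):
        expr, pheno, _ = gen_cohort(
            n_samples=400, n_mirnas=4, confounder_proxies=["sim-miR-001"], seed=8
        )
        flags = confounder_check(expr, pheno, "sim-miR-001")
        assert flags["age_associated"] is True

    def test_independent_mirna_unflagged(self):
        expr, pheno, _ = gen_cohort(n_samples=400, n_mirnas=4, seed=9)
        flags = confounder_check(expr, pheno, "sim-miR-000")
        assert flags == {"age_associated": False, "bmi_associated": False}


class TestBhFdr:
    def test_hand_computed_example(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_p(self):
        assert bh_fdr([0.2])[0] == pytest.approx(0.2)

    def test_order_invariance(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0.001, 1, 20)
        perm = rng.permutation(20)
        q = bh_fdr(p)
        q_perm = bh_fdr(p[perm])
        np.testing.assert_allclose(q_perm, q[perm])

    @given(st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=1, max_size=40))
    def test_matches_brute_force_step_up(self, pvals):
        np.testing.assert_allclose(bh_fdr(pvals), brute_force_bh(pvals), rtol=1e-12)
        assert (bh_fdr(pvals) >= np.asarray(pvals) - 1e-12).all()

    def test_invalid_p_rejected(self):
        for bad in ([0.0], [1.5], [-0.1], [float("nan")]):
            with pytest.raises(ValidationError):
                bh_fdr(bad)


def _result(mirna, response, p, converged=True):
    return AssociationResult(
        mirna_id=mirna, response=response, model="linear",
        betas={"log2miRNA": 1.0}, p_value=p, n=100, converged=converged,
    )


class TestSelectCandidates:
    def test_multi_trait_unconfounded_conserved_is_candidate(self):
        results = [
            _result("m1", "T2D", 0.001),
            _result("m1", "HbA1c", 0.01),
            _result("m1", "glucose", 0.02),
        ]
        report = select_candidates(
            results, {"m1": {"age_associated": False, "bmi_associated": False}},
            expressed={"m1"}, conserved={"m1"},
        )
        assert report.candidates == ["m1"]

    def test_age_association_excludes(self):
        results = [_result("m1", "T2D", 0.001), _result("m1", "HbA1c", 0.01)]
        report = select_candidates(
            results, {"m1": {"age_associated": True, "bmi_associated": False}},
            expressed={"m1"}, conserved={"m1"},
        )
        assert report.candidates == []

    def test_single_association_insufficient(self):
        results = [_result("m1", "T2D", 0.001), _result("m1", "HbA1c", 0.5)]
        report = select_candidates(
            results, {"m1": {"age_associated": False, "bmi_associated": False}},
            expressed={"m1"}, conserved={"m1"},
        )
        assert report.candidates == []

    def test_nonconverged_fits_never_count(self):
        results = [
            _result("m1", "T2D", 0.001, converged=False),
            _result("m1", "HbA1c", 0.001),
        ]
        report = select_candidates(
            results, {"m1": {"age_associated": False, "bmi_associated": False}},
            expressed={"m1"}, conserved={"m1"},
        )
        assert report.candidates == []
        assert report.table.loc["m1", "n_associated"] == 1

    def test_unexpressed_and_unconserved_excluded(self):
        results = [_result("m1", "T2D", 0.001), _result("m1", "glucose", 0.01)]
        conf = {"m1": {"age_associated": False, "bmi_associated": False}}
        assert select_candidates(results, conf, expressed=set(), conserved={"m1"}).candidates == []
        assert select_candidates(results, conf, expressed={"m1"}, conserved=set()).candidates == []
        report = select_candidates(results, conf, expressed={"m1"}, conserved=set(),
                                   require_conserved=False)
        assert report.candidates == ["m1"]


class TestAssociationScreen:
    def test_screen_attaches_qvalues_per_response(self):
        expr, pheno, _ = gen_cohort(n_samples=100, n_mirnas=5, seed=10)
        results, confounders = association_screen(expr, pheno)
        assert len(confounders) == 5
        for r in results:
            if r.converged:
                assert r.q_value >= r.p_value - 1e-12
        by_resp = {}
        for r in results:
            by_resp.setdefault(r.response, []).append(r)
        assert set(by_resp) == {"T2D", "HbA1c", "glucose", "NAS", "insulin", "triglycerides"}
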