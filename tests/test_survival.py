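"""Cox screening, DerSimonian–Laird pooling, filter cascade, KM/log-rank."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from lifelines import CoxPHFitter

from metamodule import (
    CoxGeneResult,
    FilterPolicy,
    SimConfig,
    cox_covariates,
    cox_per_gene,
    forest_data,
    km_stratify,
    pool_dl,
    screen_locus,
    simulate_cohorts,
)
from metamodule.survival import CoxDesign


def dl_reference(estimates, variances):
    """Brute-force DerSimonian–Laird, written independently with plain loops."""
    k = len(estimates)
    w = [1.0 / v for v in variances]
    sw = sum(w)
    beta_f = sum(wi * yi for wi, yi in zip(w, estimates)) / sw
    q = sum(wi * (yi - beta_f) ** 2 for wi, yi in zip(w, estimates))
    if k > 1:
        tau2 = max(0.0, (q - (k - 1)) / (sw - sum(wi * wi for wi in w) / sw))
    else:
        tau2 = 0.0
    w_star = [1.0 / (v + tau2) for v in variances]
    beta = sum(wi * yi for wi, yi in zip(w_star, estimates)) / sum(w_star)
    se = 1.0 / math.sqrt(sum(w_star))
    return beta, se, tau2, q


def _result(gene="G", cohort="c", beta=0.0, se=0.1, p=None):
    z = beta / se
    if p is None:
        from scipy.stats import norm

        p = 2 * norm.sf(abs(z))
    return CoxGeneResult(
        cohort_id=cohort, gene=gene, beta=beta, se=se, wald_z=z, p=p, n=100, events=50
    )


class TestPoolDL:
    def test_homogeneous_three_studies(self):
        meta = pool_dl([_result(cohort=f"c{i}", beta=0.5, se=0.1) for i in range(3)])
        assert meta.beta_re == pytest.approx(0.5)
        assert meta.tau2 == pytest.approx(0.0)
        assert meta.se_re == pytest.approx(0.1 / np.sqrt(3))
        assert meta.hr == pytest.approx(np.exp(0.5))

    def test_two_study_heterogeneous_hand_example(self):
        meta = pool_dl([_result(cohort="a", beta=0.0, se=0.1), _result(cohort="b", beta=1.0, se=0.1)])
        assert meta.q_stat == pytest.approx(50.0)
        assert meta.tau2 == pytest.approx(0.49)
        assert meta.beta_re == pytest.approx(0.5)

    def test_single_study_passes_through(self):
        meta = pool_dl([_result(beta=0.3, se=0.2)])
        assert (meta.beta_re, meta.se_re, meta.tau2) == pytest.approx((0.3, 0.2, 0.0))
        assert meta.k == 1

    def test_empty_and_bad_se_rejected(self):
        with pytest.raises(ValueError):
            pool_dl([])
        with pytest.raises(ValueError):
            pool_dl([_result(se=0.1), _result(se=-1.0)])

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(
        data=st.lists(
            st.tuples(
                st.floats(-3, 3, allow_nan=False),
                st.floats(0.01, 2.0, allow_nan=False),
            ),
            min_size=1,
            max_size=12,
        )
    )
    def test_matches_bruteforce_reference_and_bounds(self, data):
        betas = [b for b, _ in data]
        results = [_result(cohort=f"c{i}", beta=b, se=s) for i, (b, s) in enumerate(data)]
        meta = pool_dl(results)
        ref_beta, ref_se, ref_tau2, ref_q = dl_reference(betas, [s * s for _, s in data])
        assert meta.beta_re == pytest.approx(ref_beta, abs=1e-10)
        assert meta.se_re == pytest.approx(ref_se, abs=1e-10)
        assert meta.tau2 == pytest.approx(ref_tau2, abs=1e-10)
        assert meta.q_stat == pytest.approx(ref_q, abs=1e-8)
        # pooled estimate is a convex combination of the study estimates
        assert min(betas) - 1e-12 <= meta.beta_re <= max(betas) + 1e-12
        # pooling never loses precision relative to the worst single study
        # at the estimated heterogeneity level
        assert meta.se_re <= np.sqrt(max(s * s for _, s in data) + meta.tau2) + 1e-12
        if meta.tau2 == 0.0:
            assert meta.se_re <= min(s for _, s in data) + 1e-12
        assert meta.tau2 >= 0.0


class TestCoxPerGene:
    def test_agrees_with_lifelines_with_ties(self, small_bundles):
        bundle = small_bundles[0]
        for gene in ["G0001", "G0020"]:
            mine = cox_per_gene(bundle, gene)
            x = bundle.expression.loc[gene]
            x = (x - x.mean()) / x.std(ddof=1)
            df = pd.DataFrame(
                {
                    # rounding times forces heavy ties to exercise the Efron terms
                    "t": np.round(bundle.clinical["time"].to_numpy(), 0) + 0.5,
                    "e": bundle.clinical["event"].to_numpy(),
                    "x": x.to_numpy(),
                }
            )
            tied = CoxDesign(df["t"], df["e"])
            beta, se, ok = tied.fit(df["x"].to_numpy())
            cph = CoxPHFitter().fit(df, "t", "e")
            assert ok
            # agreement limited by lifelines' own convergence tolerance
            assert beta == pytest.approx(cph.summary["coef"].iloc[0], abs=1e-4)
            assert se == pytest.approx(cph.summary["se(coef)"].iloc[0], abs=1e-4)
            assert mine.wald_z == pytest.approx(mine.beta / mine.se, abs=1e-9)

    def test_constant_expression_flagged_unusable(self, small_bundles):
        bundle = small_bundles[0]
        expr = bundle.expression.copy()
        expr.loc["G0005"] = 3.14
        flat = type(bundle)(
            cohort_id=bundle.cohort_id, expression=expr, clinical=bundle.clinical,
            channel=bundle.channel,
        )
        res = cox_per_gene(flat, "G0005")
        assert not res.usable

    def test_missing_gene_raises(self, small_bundles):
        with pytest.raises(KeyError):
            cox_per_gene(small_bundles[0], "NOT_A_GENE")

    def test_null_gene_small_effect(self, small_bundles):
        res = cox_per_gene(small_bundles[1], "G0050")  # outside module, no planted effect
        assert res.usable
        assert abs(res.beta) < 0.2
        assert 0.0 < res.p <= 1.0


class TestScreen:
    def test_toy_threshold_enumeration(self):
        strong = [_result(cohort=f"c{i}", beta=0.5, se=0.5 / 3.5) for i in range(3)]
        weak = [_result(cohort=f"c{i + 3}", beta=0.05, se=0.5) for i in range(3)]
        meta = pool_dl(strong + weak)
        assert meta.n_sig_cohorts == 3
        assert meta.p_combined < 0.005
        assert meta.passes

        # only 2 cohorts below the per-cohort threshold -> fails the cascade
        meta2 = pool_dl(strong[:2] + weak)
        assert meta2.n_sig_cohorts == 2
        assert not meta2.passes

    def test_tightening_policy_never_adds_passers(self):
        rng = np.random.default_rng(0)
        results = [
            [_result(cohort=f"c{i}", beta=rng.normal(0.3, 0.3), se=rng.uniform(0.05, 0.4)) for i in range(6)]
            for _ in range(50)
        ]
        base = FilterPolicy()
        tighter = [
            FilterPolicy(alpha_cohort=0.001),
            FilterPolicy(min_sig_cohorts=4),
            FilterPolicy(alpha_combined=0.001),
            FilterPolicy(min_measured_cohorts=7),
        ]
        for policy in tighter:
            for rs in results:
                if pool_dl(rs, policy).passes:
                    assert pool_dl(rs, base).passes

    def test_screen_table_sorted_and_complete(self, small_bundles, small_config):
        table = screen_locus(small_bundles, small_config.gene_names)
        assert set(table["gene"]) == set(small_config.gene_names)
        assert table["p_combined"].is_monotonic_increasing
        assert (table["tau2"] >= 0).all()
        assert (table["hr"] > 0).all()
        # planted prognostic seed gene tops the screen
        assert table.iloc[0]["gene"] == "G0001"
        assert bool(table.iloc[0]["passes"])

    def test_empty_universe_rejected(self, small_bundles):
        with pytest.raises(ValueError):
            screen_locus(small_bundles, [])

    def test_ci_coverage_of_pooled_estimate(self):
        """~95% CI from the random-effects pool covers a homogeneous planted
        log-HR at close-to-nominal rate (scaled-down simulation)."""
        beta_true, covered = 0.5, 0
        n_rep = 150
        for rep in range(n_rep):
            cfg = SimConfig(
                n_cohorts=3, samples_per_cohort=[150] * 3, n_genes=6, module_size=2,
                prognostic_genes={"G0006": beta_true}, noise_sd=[1.0] * 3, seed=5000 + rep,
            )
            bundles = simulate_cohorts(cfg)
            meta = pool_dl([cox_per_gene(b, "G0006") for b in bundles])
            lo = meta.beta_re - 1.96 * meta.se_re
            hi = meta.beta_re + 1.96 * meta.se_re
            covered += lo <= beta_true <= hi
        assert 0.90 <= covered / n_rep <= 0.99


class TestKMAndCovariates:
    def test_identical_groups_logrank_zero(self):
        times = np.tile([5.0, 10.0, 15.0, 20.0], 6)
        events = np.tile([1, 0, 1, 1], 6)
        clinical = pd.DataFrame({"time": times, "event": events})
        score = np.array([0.0, 0.0, 0.0, 0.0] * 3 + [1.0, 1.0, 1.0, 1.0] * 3)
        # both arms see the same outcome pattern
        clinical = pd.concat([clinical.iloc[:12], clinical.iloc[:12]], ignore_index=True)
        score = np.array([0.0] * 12 + [1.0] * 12)
        res = km_stratify(clinical, score)
        assert res.logrank_stat == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_km_closed_form_all_events(self):
        # high arm: times 1,2,3 (x4), all events -> S = 2/3, 1/3, 0
        high_times = np.tile([1.0, 2.0, 3.0], 4)
        low_times = np.full(12, 10.0)
        clinical = pd.DataFrame(
            {"time": np.concatenate([high_times, low_times]), "event": 1}
        )
        score = np.array([1.0] * 12 + [0.0] * 12)
        res = km_stratify(clinical, score)
        surv = res.curves["high"].iloc[:, 0]
        assert surv.loc[1.0] == pytest.approx(2 / 3)
        assert surv.loc[2.0] == pytest.approx(1 / 3)
        assert surv.loc[3.0] == pytest.approx(0.0)

    def test_median_ties_go_low_and_degenerate_split_rejected(self):
        clinical = pd.DataFrame({"time": np.arange(1.0, 25.0), "event": 1})
        score = np.array([1.0] * 12 + [2.0] * 12)
        res = km_stratify(clinical, score)
        # median = 1.5 -> clean split; now make everything tie at the median
        assert set(res.groups) == {"high", "low"}
        with pytest.raises(ValueError, match="degenerate"):
            km_stratify(clinical, np.ones(24))

    def test_planted_module_score_separates_survival(self, small_bundles, small_config):
        bundle = small_bundles[1]
        score = bundle.expression.loc[small_config.module_genes].mean(axis=0)
        res = km_stratify(bundle, score)
        assert res.p < 0.01

    def test_multivariate_score_significant_without_confounding(self, small_bundles):
        bundle = small_bundles[0]
        x = bundle.expression.loc["G0001"]
        binary = (x > x.median()).astype(float)
        table = cox_covariates(bundle, binary, ["age", "size", "grade", "er", "node"], mode="multivariate")
        assert table.loc[table["variable"] == "score", "p"].iloc[0] < 0.05
        uni = cox_covariates(bundle, binary, ["age", "er"], mode="univariate")
        assert set(uni["variable"]) == {"score", "age", "er"}

    def test_constant_covariate_dropped_with_warning(self, small_bundles):
        bundle = small_bundles[0]
        clin = bundle.clinical.copy()
        clin["grade"] = 2
        mono = type(bundle)(
            cohort_id=bundle.cohort_id, expression=bundle.expression, clinical=clin,
            channel=bundle.channel,
        )
        x = bundle.expression.loc["G0001"]
        binary = (x > x.median()).astype(float)
        with pytest.warns(UserWarning, match="constant"):
            table = cox_covariates(mono, binary, ["age", "grade"], mode="multivariate")
        assert "grade" not in set(table["variable"])


def test_forest_data_has_per_cohort_and_pooled_rows(small_bundles):
    results = [cox_per_gene(b, "G0001") for b in small_bundles]
    table = forest_data(results)
    assert len(table) == len(small_bundles) + 1
    assert bool(table.iloc[-1]["pooled"])
    assert (table["ci_lower"] <= table["hr"]).all() and (table["hr"] <= table["ci_upper"]).all()
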