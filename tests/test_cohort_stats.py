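import dataclasses

import numpy as np
import pandas as pd
import pytest

from pvgamma import cohort_stats as cs
from pvgamma import synthetic_cohort as sc
from pvgamma.measures import subject_means


class TestOneWayAnova:
    def test_identical_groups(self):
        res = cs.one_way_anova_tukey({"a": [1, 2, 3], "b": [1, 2, 3],
                                      "c": [1, 2, 3]})
        assert res.F == 0.0
        assert res.p == 1.0

    def test_sums_of_squares_oracle(self):
        # groups {1,2} and {3,4}: SSB=4 (df 1), SSW=1 (df 2) -> F=8
        res = cs.one_way_anova_tukey({"a": [1, 2], "b": [3, 4]})
        assert res.F == pytest.approx(8.0)
        assert (res.df_between, res.df_within) == (1, 2)

    def test_matches_scipy_on_random_groups(self, rng):
        from scipy.stats import f_oneway

        groups = {k: rng.normal(i, 1, 12) for i, k in enumerate("abc")}
        res = cs.one_way_anova_tukey(groups)
        F, p = f_oneway(*groups.values())
        assert res.F == pytest.approx(F)
        assert res.p == pytest.approx(p)

    def test_tukey_adjusted_ge_unadjusted(self, rng):
        from scipy.stats import ttest_ind

        groups = {k: rng.normal(0.3 * i, 1, 10) for i, k in enumerate("abcd")}
        res = cs.one_way_anova_tukey(groups)
        for (ga, gb), adj_p, _ in res.tukey:
            _, raw_p = ttest_ind(groups[ga], groups[gb])
            assert adj_p >= raw_p - 1e-12

    def test_subtype_panel_posthoc_pattern(self):
        # with realistic between-subject spread at n=3, PVI vs CRI comes out
        # Tukey-significant more often than CBI vs CRI, and the exact
        # reported pattern (PVI/CRI significant, CBI/CRI not) occurs
        cfg = sc.CohortConfig(cells_per_subject=60, between_subject_cv=0.6)
        hits_pvi, hits_cbi, exact_pattern = 0, 0, 0
        n_seeds = 20
        for seed in range(n_seeds):
            panel = sc.generate_interneuron_panel(cfg, n_subjects=3, seed=seed)
            groups = {
                st: subject_means(panel.cells[panel.cells.subtype == st],
                                  "total_rbfox1", subtype=st).tolist()
                for st in ("CRI", "CBI", "PVI")
            }
            res = cs.one_way_anova_tukey(groups)
            sig = {frozenset(pair): s for pair, _, s in res.tukey}
            pvi = sig[frozenset(("PVI", "CRI"))]
            cbi = sig[frozenset(("CBI", "CRI"))]
            hits_pvi += pvi
            hits_cbi += cbi
            exact_pattern += pvi and not cbi
        assert hits_pvi > hits_cbi
        assert exact_pattern >= 1

    def test_small_group_rejected(self):
        with pytest.raises(cs.StatsError):
            cs.one_way_anova_tukey({"a": [1.0], "b": [1, 2]})


def _statsmodels_partial_f(tbl, measure_col, model, covariates):
    """Independent oracle: statsmodels OLS, F test for diagnosis."""
    import statsmodels.formula.api as smf

    terms = ["C(diagnosis)"]
    if model == "paired":
        terms.append("C(pair_id)")
    terms += list(covariates)
    formula = f"{measure_col} ~ " + " + ".join(terms)
    fit = smf.ols(formula, data=tbl).fit()
    ftest = fit.f_test("C(diagnosis)[T.schizophrenia] = 0")
    return float(ftest.fvalue), float(ftest.pvalue)


class TestAncova:
    def test_matches_statsmodels_oracle(self, default_cohort):
        for model in ("paired", "unpaired"):
            covs = cs.default_covariates("cytoplasmic_rbfox1", model)
            covs = tuple(c for c in covs if c != "sex")
            res = cs.ancova(default_cohort, "cytoplasmic_rbfox1", model,
                            covariates=covs)
            tbl = default_cohort.subjects.copy()
            means = subject_means(default_cohort.cells, "cytoplasmic_rbfox1")
            tbl["y"] = tbl.subject_id.map(means)
            F, p = _statsmodels_partial_f(tbl, "y", model, covs)
            assert res.diagnosis_F == pytest.approx(F, rel=1e-8)
            assert res.p == pytest.approx(p, rel=1e-6)

    def test_hand_built_exact_difference(self):
        # 4 pairs, constant within-pair difference d, no covariate effects
        d = 2.0
        base = 10.0
        rows_s, rows_c = [], []
        rng = np.random.default_rng(0)
        for pid in range(1, 5):
            shift = rng.normal(0, 1)
            for diag, suffix, y in (("comparison", "C", base + shift),
                                    ("schizophrenia", "Z", base + shift - d)):
                sid = f"S{pid}{suffix}"
                rows_s.append({"subject_id": sid, "pair_id": pid,
                               "diagnosis": diag, "sex": "M", "age": 50.0,
                               "brain_pH": 6.6, "pmi": 15.0, "rin": 8.0,
                               "storage": 100.0})
                rows_c.append({"cell_id": sid, "subject_id": sid,
                               "subtype": "PVI", "cytoplasmic_intensity": y,
                               "nuclear_intensity": 1.0})
        ds = sc.CohortDataset(subjects=pd.DataFrame(rows_s),
                              cells=pd.DataFrame(rows_c),
                              config=sc.CohortConfig(), seed=0)
        res = cs.ancova(ds, "cytoplasmic_rbfox1", "paired", covariates=())
        comp_mean = np.mean([r["cytoplasmic_intensity"] for r in rows_c
                             if r["subject_id"].endswith("C")])
        assert res.percent_difference == pytest.approx(100 * d / comp_mean)
        # perfectly constant difference -> zero residual; F blows up, p ~ 0
        assert res.p < 1e-6

    def test_default_cohort_percent_difference(self):
        pcts = [
            cs.run_diagnosis_test(
                sc.generate_cohort(sc.CohortConfig(), seed=s),
                "cytoplasmic_rbfox1", "paired").percent_difference
            for s in range(15)
        ]
        assert np.mean(pcts) == pytest.approx(29.0, abs=4.0)

    def test_incomplete_pair_rejected(self, default_cohort):
        broken = dataclasses.replace(
            default_cohort,
            subjects=default_cohort.subjects.iloc[1:].reset_index(drop=True))
        with pytest.raises(cs.StatsError):
            cs.ancova(broken, "cytoplasmic_rbfox1", "paired")

    def test_rank_deficient_design_names_alias(self, default_cohort):
        tbl = default_cohort.subjects.copy()
        tbl["dup"] = tbl["brain_pH"]
        ds = dataclasses.replace(default_cohort, subjects=tbl)
        with pytest.raises(cs.StatsError, match="alias"):
            cs.ancova(ds, "cytoplasmic_rbfox1", "paired",
                      covariates=("brain_pH", "dup"))

    def test_paired_and_unpaired_agree_on_significance(self):
        agree = 0
        n_seeds = 12
        for s in range(n_seeds):
            ds = sc.generate_cohort(sc.CohortConfig(), seed=1000 + s)
            pp = cs.run_diagnosis_test(ds, "cytoplasmic_rbfox1", "paired").p
            up = cs.run_diagnosis_test(ds, "cytoplasmic_rbfox1", "unpaired").p
            agree += (pp < 0.05) == (up < 0.05)
        assert agree >= 0.9 * n_seeds

    def test_rin_candidate_only_for_mrna(self):
        assert "rin" in cs.default_covariates("vamp1_grain_density", "paired")
        assert "rin" not in cs.default_covariates("cytoplasmic_rbfox1", "paired")


class TestCovariateRetention:
    def test_null_covariates_rarely_retained(self, null_config):
        retained_any = 0
        n_seeds = 30
        for s in range(n_seeds):
            ds = sc.generate_cohort(null_config, seed=s)
            kept = cs.retain_significant_covariates(ds, "cytoplasmic_rbfox1",
                                                    "paired")
            retained_any += bool(kept)
        # ~5% chance per covariate, 3 candidates -> mostly empty
        assert retained_any <= 0.35 * n_seeds

    def test_programmed_covariate_always_retained(self):
        cfg = sc.CohortConfig(
            covariate_effects={("cytoplasmic_rbfox1", "brain_pH"): 0.6})
        for s in range(5):
            ds = sc.generate_cohort(cfg, seed=s)
            kept = cs.retain_significant_covariates(ds, "cytoplasmic_rbfox1",
                                                    "paired")
            assert "brain_pH" in kept

    def test_no_candidates_gives_empty(self, default_cohort):
        assert cs.retain_significant_covariates(
            default_cohort, "cytoplasmic_rbfox1", "paired", candidates=()) == []


class TestCooccurringScan:
    def test_null_factors_not_significant(self):
        n_sig = 0
        for s in range(10):
            ds = sc.generate_cohort(sc.CohortConfig(), seed=s)
            out = cs.cooccurring_factor_scan(ds, "cytoplasmic_rbfox1",
                                             sc.COOCCURRING_FACTORS)
            n_sig += (out.p_adjusted < 0.05).sum()
        assert n_sig <= 2

    def test_constructed_factor_is_most_significant(self):
        ds = sc.generate_cohort(sc.CohortConfig(), seed=3)
        means = subject_means(ds.cells, "cytoplasmic_rbfox1")
        tbl = ds.subjects.copy()
        sz = tbl.diagnosis == "schizophrenia"
        med = means[tbl[sz].subject_id].median()
        tbl.loc[sz, "suicide"] = (tbl[sz].subject_id.map(means) > med).values
        ds = dataclasses.replace(ds, subjects=tbl)
        out = cs.cooccurring_factor_scan(ds, "cytoplasmic_rbfox1",
                                         sc.COOCCURRING_FACTORS)
        out = out.set_index("factor")
        assert out.p_adjusted.idxmin() == "suicide"

    def test_empty_factor_list(self, default_cohort):
        out = cs.cooccurring_factor_scan(default_cohort,
                                         "cytoplasmic_rbfox1", ())
        assert len(out) == 0

    def test_constant_factor_skipped_with_warning(self, default_cohort):
        tbl = default_cohort.subjects.copy()
        tbl["valproic_acid"] = False
        ds = dataclasses.replace(default_cohort, subjects=tbl)
        with pytest.warns(UserWarning, match="valproic_acid"):
            out = cs.cooccurring_factor_scan(ds, "cytoplasmic_rbfox1",
                                             ("valproic_acid",))
        assert len(out) == 0


class TestCorrelation:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        r, p, n = cs.correlation(x, 2 * x)
        assert r == pytest.approx(1.0)
        assert n == 10

    def test_generator_correlation_recovered(self, null_config):
        cfg = dataclasses.replace(null_config, n_pairs=30,
                                  cells_per_subject=100)
        ds = sc.generate_cohort(cfg, seed=8)
        r, p, n = cs.correlation(ds.cells.cytoplasmic_intensity,
                                 ds.cells.nuclear_intensity)
        assert r == pytest.approx(0.6, abs=0.05)
        assert p < 1e-10

    def test_constant_input_error(self):
        with pytest.raises(cs.StatsError):
            cs.correlation(np.ones(10), np.arange(10.0))


class TestFoldChange:
    def test_paper_value(self):
        assert cs.fold_change(9.6, 1.0) == pytest.approx(9.6)

    def test_equal_means(self):
        assert cs.fold_change(3.3, 3.3) == 1.0

    def test_hand_average_oracle(self, rng):
        a, b = rng.random(50) + 1, rng.random(50) + 0.5
        assert cs.fold_change(a.mean(), b.mean()) == pytest.approx(
            np.mean(a) / np.mean(b))

    def test_nonpositive_denominator(self):
        with pytest.raises(cs.StatsError):
            cs.fold_change(1.0, 0.0)


class TestOracleEquivalence:
    def test_partial_f_matches_normal_equations_oracle(self, rng):
        # brute-force oracle: explicit projection via pinv on random designs
        from scipy.stats import f as fdist

        for _ in range(10):
            n, k = 24, 4
            X = np.column_stack([np.ones(n), rng.normal(size=(n, k))])
            y = rng.normal(size=n)
            drop = np.zeros(k + 1, dtype=bool)
            drop[1] = True
            F, p, q, dfr = cs._partial_f(X, y, drop)

            def rss(M):
                beta = np.linalg.pinv(M.T @ M) @ M.T @ y
                r = y - M @ beta
                return r @ r

            rss_f, rss_r = rss(X), rss(X[:, ~drop])
            F_oracle = ((rss_r - rss_f) / 1) / (rss_f / (n - k - 1))
            assert F == pytest.approx(F_oracle, abs=1e-8 * max(1, F_oracle))
            assert p == pytest.approx(float(fdist.sf(F_oracle, 1, n - k - 1)))

    def test_type_i_error_rate(self, null_config):
        # diagnosis rejection rate on null cohorts ~ alpha = 0.05
        cfg = dataclasses.replace(null_config, cells_per_subject=10)
        n_reps = 300  # the acceptance suite runs the full 1,000-cohort check
        rejections = 0
        for s in range(n_reps):
            ds = sc.generate_cohort(cfg, seed=50_000 + s)
            res = cs.ancova(ds, "cytoplasmic_rbfox1", "paired", covariates=())
            rejections += res.p < 0.05
        rate = rejections / n_reps
        assert 0.02 <= rate <= 0.08
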