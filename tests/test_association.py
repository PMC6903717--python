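"""Genetic-model encodings, frequency tests, conditional logistic
regression and the association scan."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import hypergeom

import snpcc
from snpcc.association import (clr_fit, codominant_omnibus_p, encode_genotype,
                               freq_test, mark_x_linked, reference_dose,
                               run_association)
from snpcc.errors import (NonIdentifiableError, SeparationError,
                          ValidationError)
from snpcc.panel import Cohort, DosageMatrix, Panel, SubjectRecord
from snpcc.simulate import SimulationConfig, simulate_cohort


class TestEncoding:
    @pytest.mark.parametrize("dose,model,ref,expected", [
        (1, "dominant", 0, (1.0,)),
        (0, "dominant", 0, (0.0,)),
        (1, "recessive", 0, (0.0,)),
        (2, "recessive", 0, (1.0,)),
        (2, "codominant", 0, (0.0, 1.0)),
        (1, "codominant", 0, (1.0, 0.0)),
        (0, "codominant", 2, (0.0, 1.0)),  # non-risk hom vs risk-hom ref
        (2, "allelic", 0, (2.0,)),
    ])
    def test_design_columns(self, dose, model, ref, expected):
        assert encode_genotype(dose, model, ref) == expected

    def test_missing_dose_rejected(self):
        with pytest.raises(ValidationError):
            encode_genotype(float("nan"), "dominant")

    def test_reference_most_frequent_homozygote(self):
        assert reference_dose({0: 100, 1: 80, 2: 30}) == 0
        assert reference_dose({0: 30, 1: 80, 2: 100}) == 2
        # tie breaks toward the non-risk homozygote
        assert reference_dose({0: 50, 1: 10, 2: 50}) == 0


class TestFreqTables:
    def test_published_genotype_counts(self, table3_cohort):
        cohort, dm = table3_cohort
        t = snpcc.freq_table(dm, cohort, "rs6687758", "genotype")
        assert list(t.loc["case"]) == [136, 87, 7]
        assert list(t.loc["control"]) == [169, 51, 9]

    def test_published_allele_counts(self, table3_cohort):
        cohort, dm = table3_cohort
        t = snpcc.freq_table(dm, cohort, "rs6687758", "allele")
        assert t.loc["case", "risk"] == 101
        assert t.loc["case", "other"] == 359
        assert t.loc["control", "risk"] == 69
        assert t.loc["control", "other"] == 389

    def test_allele_count_conservation(self, table3_cohort):
        cohort, dm = table3_cohort
        t = snpcc.freq_table(dm, cohort, "rs6687758", "allele")
        n_complete = int(dm.column("rs6687758").notna().sum())
        assert t.to_numpy().sum() == 2 * n_complete

    def test_unknown_rsid(self, table3_cohort):
        cohort, dm = table3_cohort
        with pytest.raises(ValidationError):
            snpcc.freq_table(dm, cohort, "rs0", "genotype")

    def test_empty_cohort(self, table3_cohort):
        _, dm = table3_cohort
        with pytest.raises(ValidationError):
            snpcc.freq_table(dm, Cohort([]), "rs6687758")


class TestFreqTest:
    def test_perfect_independence(self):
        assert freq_test([[10, 10], [10, 10]]).p_value == pytest.approx(1.0)

    def test_small_2x2_matches_hypergeometric_enumeration(self):
        table = np.array([[1, 9], [8, 2]])
        res = freq_test(table)
        assert res.method == "fisher"
        # brute-force two-sided hypergeometric p
        n, K, k = table.sum(), table[0].sum(), table[:, 0].sum()
        rv = hypergeom(n, K, k)
        probs = rv.pmf(np.arange(0, min(K, k) + 1))
        p_obs = rv.pmf(table[0, 0])
        oracle = probs[probs <= p_obs * (1 + 1e-9)].sum()
        assert res.p_value == pytest.approx(oracle, rel=1e-9)

    def test_published_genotype_table_chi2_significant(self, table3_cohort):
        cohort, dm = table3_cohort
        t = snpcc.freq_table(dm, cohort, "rs6687758", "genotype")
        res = freq_test(t)
        assert res.method == "chi2"  # all expected counts >= 5
        assert res.p_value < 0.05

    def test_2x3_exact_enumeration_used_when_sparse(self):
        t = np.array([[1, 2, 12], [9, 3, 1]])
        res = freq_test(t)
        assert res.method == "exact_enum"
        assert 0.0 < res.p_value <= 1.0

    def test_2x3_exact_agrees_with_mc(self):
        t = np.array([[1, 2, 12], [9, 3, 1]])
        from snpcc.association import _exact_2x3_p, _exact_mc_p
        p_enum = _exact_2x3_p(t)
        p_mc = _exact_mc_p(t, seed=1, n_mc=200_000)
        assert p_mc == pytest.approx(p_enum, abs=0.01)

    def test_zero_margin_undefined(self):
        res = freq_test([[0, 0], [3, 4]])
        assert res.method == "undefined"
        assert np.isnan(res.p_value)


class TestCrudeOr:
    def test_published_allele_cross_product(self):
        or_, lo, hi = snpcc.crude_or_2x2([[101, 359], [69, 389]])
        assert or_ == pytest.approx(1.586, abs=5e-4)
        assert lo < or_ < hi

    def test_symmetric_table_is_one(self):
        or_, _, _ = snpcc.crude_or_2x2([[20, 30], [20, 30]])
        assert or_ == pytest.approx(1.0)

    def test_zero_cell_haldane_corrected(self, caplog):
        with caplog.at_level("WARNING"):
            or_, lo, hi = snpcc.crude_or_2x2([[0, 10], [5, 5]])
        assert np.isfinite(or_) and or_ > 0
        assert "correction" in caplog.text

    def test_zero_margin_undefined(self):
        with pytest.raises(ValidationError):
            snpcc.crude_or_2x2([[0, 10], [0, 5]])


class TestClrFit:
    def test_discordant_pair_closed_form(self):
        """1:1 conditional MLE for a binary covariate is the discordant-pair
        ratio: 10 case-exposed vs 5 control-exposed -> OR 2."""
        d = np.concatenate([np.ones(10), -np.ones(5), np.zeros(20)])
        fit = clr_fit(d)
        assert fit.beta[0] == pytest.approx(np.log(2.0), abs=1e-6)

    def test_balanced_discordance_gives_null(self):
        d = np.concatenate([np.ones(7), -np.ones(7), np.zeros(6)])
        fit = clr_fit(d)
        assert fit.beta[0] == pytest.approx(0.0, abs=1e-10)
        assert np.exp(fit.beta[0]) == pytest.approx(1.0)

    def test_all_concordant_not_identifiable(self):
        with pytest.raises(NonIdentifiableError):
            clr_fit(np.zeros(12))

    def test_complete_separation_detected(self):
        with pytest.raises(SeparationError):
            clr_fit(np.ones(15), names=["exposure"])

    def test_grid_search_oracle_single_covariate(self):
        """Newton solution matches a fine 1-D likelihood grid search."""
        rng = np.random.default_rng(7)
        d = rng.choice([-1.0, 0.0, 1.0, 2.0], size=200,
                       p=[0.25, 0.35, 0.3, 0.1])
        fit = clr_fit(d)

        def nll(b):
            return np.logaddexp(0.0, -d * b).sum()

        grid = np.linspace(fit.beta[0] - 0.01, fit.beta[0] + 0.01, 20001)
        best = grid[np.argmin([nll(b) for b in grid])]
        assert fit.beta[0] == pytest.approx(best, abs=1e-6)

    def test_matches_statsmodels_conditional_logit(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(5)
        n = 250
        xc = rng.binomial(2, 0.3, n).astype(float)
        xk = rng.binomial(2, 0.25, n).astype(float)
        zc, zk = rng.normal(size=n), rng.normal(size=n)
        fit = clr_fit(np.column_stack([xc - xk, zc - zk]), names=["x", "z"])
        y = np.r_[np.ones(n), np.zeros(n)]
        X = np.column_stack([np.r_[xc, xk], np.r_[zc, zk]])
        ref = sm.ConditionalLogit(y, X,
                                  groups=np.r_[np.arange(n),
                                               np.arange(n)]).fit(disp=0)
        assert fit.beta == pytest.approx(ref.params, abs=1e-4)
        assert fit.se == pytest.approx(ref.bse, abs=1e-4)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(derandomize=True, max_examples=15, deadline=None)
    def test_pair_constant_shift_invariance(self, seed):
        """Adding a constant to a covariate cannot change the fit: the
        within-pair difference formulation eliminates pair-constant terms."""
        rng = np.random.default_rng(seed)
        n = 80
        xc = rng.binomial(2, 0.4, n).astype(float)
        xk = rng.binomial(2, 0.4, n).astype(float)
        if np.all(xc == xk):
            return
        zc, zk = rng.normal(size=n), rng.normal(size=n)
        f1 = clr_fit(np.column_stack([xc - xk, zc - zk]))
        f2 = clr_fit(np.column_stack([(xc + 100) - (xk + 100),
                                      zc - zk]))
        assert f1.beta == pytest.approx(f2.beta, abs=1e-9)


@pytest.fixture(scope="module")
def effect_cohort(mini_panel, mini_freqs):
    cfg = SimulationConfig(n_pairs=400, allele_freqs=mini_freqs,
                           effect_ors={"rs_eff": 2.0}, seed=21)
    return simulate_cohort(cfg, mini_panel)


class TestScan:
    def test_effect_snp_ci_covers_truth(self, effect_cohort, mini_panel):
        cohort, dm, _ = effect_cohort
        res = run_association(dm, cohort, mini_panel, models=("dominant",))
        r = next(x for x in res if x.rsid == "rs_eff")
        assert r.ci_low < r.ci_high
        # dominant OR for a per-allele OR-2 SNP exceeds 1 comfortably
        assert r.or_estimate > 1.3
        allelic = run_association(dm, cohort, mini_panel,
                                  models=("allelic",))
        ra = next(x for x in allelic if x.rsid == "rs_eff")
        assert ra.ci_low <= 2.0 <= ra.ci_high

    def test_row_count_contract(self, effect_cohort, mini_panel):
        cohort, dm, _ = effect_cohort
        res = run_association(dm, cohort, mini_panel)
        # codominant has 2 contrasts, other models 1: 3 SNPs x 5 rows
        assert len(res) == 3 * 5

    def test_adjusted_run_with_all_missing_covariate(self, mini_panel,
                                                     mini_freqs):
        cfg = SimulationConfig(n_pairs=80, allele_freqs=mini_freqs, seed=2)
        cohort, dm, _ = simulate_cohort(cfg, mini_panel)
        records = [SubjectRecord(
            subject_id=r.subject_id, status=r.status, pair_id=r.pair_id,
            sex=r.sex, age_group=r.age_group, bmi_class="missing",
            pa_level=r.pa_level, smoking=r.smoking,
            alcohol_tertile=r.alcohol_tertile, di_group=r.di_group,
            energy_intake=r.energy_intake) for r in cohort]
        degraded = Cohort(records)
        res = run_association(dm, degraded, mini_panel,
                              models=("dominant",), adjustment="adjusted")
        assert all(r.fit_ok for r in res)

    def test_fixture_het_estimate_brackets_cross_product(self,
                                                         table3_cohort,
                                                         panel):
        """Pairing-averaged crude codominant heterozygote OR sits within
        +/-0.05 of the marginal cross-product 2.12 (the published
        pair-conditioned estimate prints as 2.13)."""
        sub = Panel([panel["rs6687758"]])
        logs = []
        for seed in range(40):
            cohort, dm = snpcc.cohort_from_genotype_counts(
                "rs6687758", (136, 87, 7), (169, 51, 9), seed=seed)
            res = run_association(dm, cohort, sub, models=("codominant",))
            het = next(r for r in res if r.contrast.startswith("het"))
            logs.append(np.log(het.or_estimate))
        pooled = float(np.exp(np.mean(logs)))
        assert pooled == pytest.approx(2.12, abs=0.05)

    def test_bonferroni_threshold_values(self):
        assert snpcc.bonferroni_threshold(0.05, 48) == pytest.approx(
            0.0010417, abs=5e-8)
        assert float(f"{snpcc.bonferroni_threshold(0.05, 48):.1g}") == 0.001
        assert snpcc.bonferroni_threshold(0.05, 1) == 0.05
        with pytest.raises(ValidationError):
            snpcc.bonferroni_threshold(0.05, 0)
        with pytest.raises(ValidationError):
            snpcc.bonferroni_threshold(1.5, 10)

    def test_omnibus_p_defined_per_snp(self, effect_cohort, mini_panel):
        cohort, dm, _ = effect_cohort
        ps = codominant_omnibus_p(dm, cohort, mini_panel)
        assert set(ps) == {"rs_eff", "rs_null1", "rs_null2"}
        assert ps["rs_eff"] < 0.05
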