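"""Count and weighted genetic risk scores."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import snpcc
from snpcc.errors import NonIdentifiableError, ValidationError
from snpcc.panel import Cohort, DosageMatrix, Panel, SubjectRecord
from snpcc.simulate import SimulationConfig, simulate_cohort

from conftest import make_pairs


def full_dose_matrix(panel, cohort, fill):
    """Dose matrix with every autosomal dose = fill*2 and X dose = fill
    (fill in {0, 1} selects minimal/maximal)."""
    sex = cohort.sex_of()
    data = {}
    for e in panel:
        col = {}
        for s in cohort:
            if e.chrom_class == "x_linked":
                col[s.subject_id] = float(fill) if sex[s.subject_id] == "male" \
                    else 2.0 * fill
            else:
                col[s.subject_id] = 2.0 * fill
        data[e.rsid] = pd.Series(col)
    return DosageMatrix(pd.DataFrame(data))


class TestScores:
    def test_maximal_doses_hit_published_ranges(self, panel):
        cohort = Cohort(make_pairs(1, sex="male"))
        dm = full_dose_matrix(panel, cohort, fill=1)
        c = snpcc.count_grs(dm, panel, cohort)
        w = snpcc.weighted_grs(dm, panel, cohort, weight_mode="or")
        assert c["c_grs"].iloc[0] == pytest.approx(95.0)
        assert w["w_grs"].iloc[0] == pytest.approx(105.28, abs=1e-9)
        assert round(w["w_grs"].iloc[0]) == 105

    def test_all_zero_doses(self, panel):
        cohort = Cohort(make_pairs(1))
        dm = full_dose_matrix(panel, cohort, fill=0)
        assert snpcc.count_grs(dm, panel, cohort)["c_grs"].eq(0).all()
        assert snpcc.weighted_grs(dm, panel, cohort)["w_grs"].eq(0).all()

    def test_single_heterozygote_contributions(self, panel):
        cohort = Cohort(make_pairs(1))
        dm = full_dose_matrix(panel, cohort, fill=0)
        dm.df.loc["ca0", "rs6687758"] = 2.0
        w = snpcc.weighted_grs(dm, panel, cohort)
        assert w.loc["ca0", "w_grs"] == pytest.approx(2 * 1.04)  # 2.08
        dm.df.loc["ca0", "rs6687758"] = 1.0
        c = snpcc.count_grs(dm, panel, cohort)
        assert c.loc["ca0", "c_grs"] == pytest.approx(1.0)

    def test_x_coding_half_for_female_het(self, panel):
        cohort = Cohort(make_pairs(1, sex="female"))
        dm = full_dose_matrix(panel, cohort, fill=0)
        dm.df.loc["ca0", "rs5934683"] = 1.0  # female heterozygote
        c = snpcc.count_grs(dm, panel, cohort)
        assert c.loc["ca0", "c_grs"] == pytest.approx(0.5)

    def test_missing_snps_flagged_not_imputed(self, panel):
        cohort = Cohort(make_pairs(1))
        dm = full_dose_matrix(panel, cohort, fill=1)
        dm.df.loc["ca0", ["rs6687758", "rs719725"]] = np.nan
        c = snpcc.count_grs(dm, panel, cohort)
        assert c.loc["ca0", "n_missing_snps"] == 2
        assert c.loc["ca0", "c_grs"] == pytest.approx(95.0 - 4.0)

    def test_additive_over_panel_split(self, panel):
        rng = np.random.default_rng(3)
        cohort = Cohort(make_pairs(4))
        dm = full_dose_matrix(panel, cohort, fill=0)
        dm.df.iloc[:, :] = rng.choice([0.0, 1.0, 2.0],
                                      size=dm.df.shape)
        # keep male X doses legal
        half_a = Panel(panel.entries[:24])
        half_b = Panel(panel.entries[24:])
        total = snpcc.weighted_grs(dm, panel, cohort)["w_grs"]
        part = (snpcc.weighted_grs(dm, half_a, cohort)["w_grs"]
                + snpcc.weighted_grs(dm, half_b, cohort)["w_grs"])
        assert total.to_numpy() == pytest.approx(part.to_numpy())

    def test_unit_weights_reduce_to_count(self, panel):
        unit = Panel([
            snpcc.PanelEntry(e.rsid, e.gene_label, e.locus_label, 1.0,
                             e.risk_allele, e.chrom_class) for e in panel])
        rng = np.random.default_rng(4)
        cohort = Cohort(make_pairs(5))
        dm = full_dose_matrix(panel, cohort, fill=0)
        dm.df.iloc[:, :] = rng.choice([0.0, 1.0, 2.0], size=dm.df.shape)
        c = snpcc.count_grs(dm, unit, cohort)["c_grs"]
        w = snpcc.weighted_grs(dm, unit, cohort, weight_mode="or")["w_grs"]
        assert w.to_numpy() == pytest.approx(c.to_numpy())

    @given(st.integers(0, 47), st.sampled_from([0.0, 1.0]))
    @settings(derandomize=True, max_examples=25, deadline=None)
    def test_monotone_in_any_dose(self, snp_idx, start):
        panel = snpcc.load_panel()
        cohort = Cohort(make_pairs(1, sex="female"))
        dm = full_dose_matrix(panel, cohort, fill=0)
        rsid = panel.rsids[snp_idx]
        dm.df.loc["ca0", rsid] = start
        before_c = snpcc.count_grs(dm, panel, cohort).loc["ca0", "c_grs"]
        before_w = snpcc.weighted_grs(dm, panel, cohort).loc["ca0", "w_grs"]
        dm.df.loc["ca0", rsid] = start + 1.0
        after_c = snpcc.count_grs(dm, panel, cohort).loc["ca0", "c_grs"]
        after_w = snpcc.weighted_grs(dm, panel, cohort).loc["ca0", "w_grs"]
        assert after_c >= before_c
        assert after_w >= before_w

    def test_scores_within_theoretical_bounds(self, panel, mini_panel):
        bounds = snpcc.score_bounds(panel)
        assert bounds["c_grs"] == (0.0, 95.0)
        assert bounds["w_grs"][1] == pytest.approx(105.28)
        freqs = {e.rsid: 0.25 for e in panel}
        cfg = SimulationConfig(n_pairs=60, allele_freqs=freqs, seed=8)
        cohort, dm, _ = simulate_cohort(cfg, panel)
        scores = snpcc.grs_table(dm, panel, cohort)
        assert scores["c_grs"].between(0, 95).all()
        assert scores["w_grs"].between(*bounds["w_grs"]).all()


class TestAssociationAndComparison:
    def test_null_cohort_or_near_one(self, mini_panel, mini_freqs):
        cfg = SimulationConfig(n_pairs=300, allele_freqs=mini_freqs, seed=15)
        cohort, dm, _ = simulate_cohort(cfg, mini_panel)
        scores = snpcc.grs_table(dm, mini_panel, cohort)
        res = snpcc.grs_association(scores["c_grs"], cohort)
        assert res["ci_low"] <= 1.0 <= res["ci_high"]

    def test_score_effect_recovered(self, mini_panel, mini_freqs):
        """A cohort generated with per-allele log-odds ~0.35 on every SNP
        yields a per-unit count-GRS OR whose CI covers the truth."""
        cfg = SimulationConfig(
            n_pairs=800, allele_freqs=mini_freqs,
            effect_ors={r: float(np.exp(0.35)) for r in mini_freqs},
            seed=16)
        cohort, dm, _ = simulate_cohort(cfg, mini_panel)
        scores = snpcc.grs_table(dm, mini_panel, cohort)
        res = snpcc.grs_association(scores["c_grs"], cohort)
        assert res["ci_low"] <= np.exp(0.35) <= res["ci_high"]

    def test_constant_scores_not_identifiable(self):
        cohort = Cohort(make_pairs(5))
        scores = pd.Series(3.0, index=[r.subject_id for r in cohort])
        with pytest.raises(NonIdentifiableError):
            snpcc.grs_association(scores, cohort)

    def test_identical_groups_mean_difference_zero(self):
        cohort = Cohort(make_pairs(10))
        vals = {}
        for k, pid in enumerate(cohort.pair_ids):
            case, control = cohort.pair(pid)
            vals[case.subject_id] = 30.0 + k
            vals[control.subject_id] = 30.0 + k
        out = snpcc.compare_grs(pd.Series(vals), cohort)
        assert out["mean_difference"] == 0.0
        assert out["p_paired_t"] == pytest.approx(1.0)

    def test_constant_shift_always_significant(self):
        """Cases = controls + 1.25 with zero-variance differences is
        detected at any conventional level (the published means differ by
        about this much: 39.2 vs 37.95)."""
        cohort = Cohort(make_pairs(230))
        rng = np.random.default_rng(0)
        vals = {}
        for pid in cohort.pair_ids:
            case, control = cohort.pair(pid)
            base = rng.normal(38.0, 4.6)
            vals[control.subject_id] = base
            vals[case.subject_id] = base + 1.25
        out = snpcc.compare_grs(pd.Series(vals), cohort)
        assert out["p_paired_t"] < 1e-10
        assert out["mean_difference"] == pytest.approx(1.25)

    def test_single_pair_rejected(self):
        cohort = Cohort(make_pairs(1))
        scores = pd.Series({r.subject_id: 1.0 for r in cohort})
        with pytest.raises(ValidationError):
            snpcc.compare_grs(scores, cohort)
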