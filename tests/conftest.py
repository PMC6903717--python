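from fractions import Fraction
from math import factorial

import numpy as np
import pytest

import snpcc
from snpcc.panel import Panel, PanelEntry, SubjectRecord


@pytest.fixture(scope="session")
def panel():
    """The packaged 48-SNP susceptibility panel."""
    return snpcc.load_panel()


@pytest.fixture(scope="session")
def mini_panel():
    """Three-SNP panel: one effect SNP, two nulls (fast simulations)."""
    return Panel([
        PanelEntry("rs_eff", "GENE1", "1q00", 2.0, "A", "autosomal"),
        PanelEntry("rs_null1", "GENE2", "2q00", 1.0, "C", "autosomal"),
        PanelEntry("rs_null2", "GENE3", "3q00", 1.0, "G", "autosomal"),
    ])


@pytest.fixture(scope="session")
def mini_freqs():
    return {"rs_eff": 0.3, "rs_null1": 0.25, "rs_null2": 0.4}


@pytest.fixture(scope="session")
def table3_cohort():
    """Cohort whose rs6687758 marginal genotype counts reproduce the
    published case/control distribution (136/87/7 vs 169/51/9)."""
    return snpcc.cohort_from_genotype_counts(
        "rs6687758", (136, 87, 7), (169, 51, 9), seed=0)


def make_pairs(n, sex="female", age_group="60-69"):
    """n well-formed case-control pairs with minimal covariates."""
    records = []
    for k in range(n):
        for status in ("case", "control"):
            records.append(SubjectRecord(
                subject_id=f"{status[:2]}{k}", status=status,
                pair_id=f"P{k}", sex=sex, age_group=age_group))
    return records


def hwe_oracle_p(n_hom_ref, n_het, n_hom_alt):
    """Brute-force exact HWE p by full enumeration in rational arithmetic."""
    n = n_hom_ref + n_het + n_hom_alt
    n_a = 2 * n_hom_ref + n_het
    n_b = 2 * n_hom_alt + n_het
    rare = min(n_a, n_b)
    probs = {}
    for h in range(rare % 2, rare + 1, 2):
        a = (n_a - h) // 2
        b = (n_b - h) // 2
        probs[h] = Fraction(
            factorial(n) * 2 ** h * factorial(n_a) * factorial(n_b),
            factorial(a) * factorial(h) * factorial(b) * factorial(2 * n))
    total = sum(probs.values())
    obs = probs[n_het] / total
    return float(sum(p for p in (v / total for v in probs.values())
                     if p <= obs))
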