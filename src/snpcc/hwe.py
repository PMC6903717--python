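"""Exact tests for deviation from Hardy-Weinberg equilibrium.

The primary test is the exact conditional test: given the observed allele
totals, every compatible heterozygote count is enumerated and weighted by
its conditional probability

    P(n_het | n, n_A) = n! 2^{n_het} n_A! n_a! /
                        (n_AA! n_het! n_aa! (2n)!),

and the two-sided p-value is the summed probability of all configurations
no more probable than the observed one. Factorials are evaluated in log
space so counts in the hundreds are exact to floating precision. A
chi-square variant is provided for cross-checking only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln
from scipy.stats import chi2

from .errors import ValidationError
from .panel import Cohort, DosageMatrix, Panel

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class HweResult:
    rsid: str
    group: str  # "case" | "control"
    n_hom_ref: int
    n_het: int
    n_hom_alt: int
    p_value: float  # nan when the group has no complete observations
    deviates: bool


def _check_counts(*counts: int) -> None:
    for c in counts:
        if c != int(c) or c < 0:
            raise ValidationError(f"genotype counts must be non-negative "
                                  f"integers, got {counts}")


def hwe_exact_p(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Two-sided exact conditional HWE p-value for one genotype triple."""
    _check_counts(n_hom_ref, n_het, n_hom_alt)
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        raise ValidationError("at least one genotype count must be positive")
    n_a = 2 * n_hom_ref + n_het
    n_b = 2 * n_hom_alt + n_het
    rare = min(n_a, n_b)
    # heterozygote counts compatible with the allele totals share parity
    hets = np.arange(rare % 2, rare + 1, 2)
    homs_rare = (rare - hets) // 2
    homs_common = (max(n_a, n_b) - hets) // 2
    logp = (
        gammaln(n + 1) + hets * np.log(2.0) + gammaln(n_a + 1)
        + gammaln(n_b + 1)
        - gammaln(homs_rare + 1) - gammaln(hets + 1)
        - gammaln(homs_common + 1) - gammaln(2 * n + 1)
    )
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    observed = probs[hets == n_het][0]
    # 1e-12 relative slack absorbs roundoff when summing ties
    p = probs[probs <= observed * (1 + 1e-12)].sum()
    return float(min(p, 1.0))


def hwe_chi2_p(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """One-df chi-square HWE test (cross-check only, no exact guarantee)."""
    _check_counts(n_hom_ref, n_het, n_hom_alt)
    n = n_hom_ref + n_het + n_hom_alt
    p = (2 * n_hom_ref + n_het) / (2 * n)
    q = 1 - p
    exp = np.array([p * p * n, 2 * p * q * n, q * q * n])
    obs = np.array([n_hom_ref, n_het, n_hom_alt], dtype=float)
    if np.any(exp == 0):
        return 1.0
    stat = ((obs - exp) ** 2 / exp).sum()
    return float(chi2.sf(stat, df=1))


def hwe_scan(dosages: DosageMatrix, cohort: Cohort, panel: Panel,
             alpha: float = 0.001) -> list[HweResult]:
    """Exact HWE test per SNP, separately in cases and controls.

    X-linked SNPs are tested on female subjects only (males are hemizygous
    and carry no genotype-frequency information). Missing doses are
    excluded; a group with zero complete observations yields a missing p.
    """
    sex = cohort.sex_of()
    groups = {
        "case": [r.subject_id for r in cohort.cases()],
        "control": [r.subject_id for r in cohort.controls()],
    }
    results: list[HweResult] = []
    for entry in panel:
        if entry.rsid not in dosages.df.columns:
            continue
        col = dosages.column(entry.rsid)
        for group, ids in groups.items():
            use = [s for s in ids if s in col.index]
            if entry.chrom_class == "x_linked":
                use = [s for s in use if sex[s] == "female"]
            obs = col.loc[use].dropna()
            counts = (
                int((obs == 0).sum()),
                int((obs == 1).sum()),
                int((obs == 2).sum()),
            )
            if obs.empty:
                logger.warning("%s/%s: no complete observations for HWE",
                               entry.rsid, group)
                p = float("nan")
            else:
                p = hwe_exact_p(*counts)
            results.append(HweResult(
                rsid=entry.rsid, group=group,
                n_hom_ref=counts[0], n_het=counts[1], n_hom_alt=counts[2],
                p_value=p,
                deviates=bool(not np.isnan(p) and p < alpha),
            ))
    return results
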