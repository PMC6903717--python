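"""Genetic Risk Scores for the susceptibility panel.

Two scores are computed per subject:

* **c-GRS** (count): the sum of risk-allele contributions, each SNP
  weighted equally. Autosomal SNPs contribute their dose (0/1/2); the
  X-linked SNP is coded 0/0.5/1 (female heterozygote = 0.5, hemizygous
  male carrier = 1), which makes the theoretical maximum of the packaged
  48-SNP panel 2 x 47 + 1 = 95.
* **w-GRS** (weighted): the same coded doses multiplied by per-SNP weights.
  The default weight is the published per-allele odds ratio, under which
  the packaged panel's maximum is 2 x 52.12 + 1.04 = 105.28, i.e. 105 to
  the nearest integer; ``log_or`` weighting (weight = ln OR) is available
  as an alternative convention.

Missing genotypes are never imputed: a subject's score is computed over
the observed SNPs and flagged with the number of missing panel SNPs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import ttest_rel, wilcoxon

from .association import clr_fit, covariate_design, ADJUSTMENT_COVARIATES
from .errors import NonIdentifiableError, ValidationError
from .panel import Cohort, DosageMatrix, Panel

WEIGHT_MODES = ("or", "log_or")


def _coded_doses(dosages: DosageMatrix, panel: Panel,
                 cohort: Cohort) -> pd.DataFrame:
    """Risk-allele doses with the X-linked 0/0.5/1 coding applied."""
    sex = cohort.sex_of()
    coded = dosages.df.copy()
    for e in panel:
        if e.chrom_class != "x_linked" or e.rsid not in coded.columns:
            continue
        females = [s for s in coded.index if sex.get(s) == "female"]
        coded.loc[females, e.rsid] = coded.loc[females, e.rsid] / 2.0
        # male doses are already 0/1
    return coded[[e.rsid for e in panel if e.rsid in coded.columns]]


def _weights(panel: Panel, weight_mode: str) -> pd.Series:
    if weight_mode not in WEIGHT_MODES:
        raise ValidationError(f"unknown weight_mode {weight_mode!r}")
    w = {e.rsid: (e.published_or if weight_mode == "or"
                  else float(np.log(e.published_or)))
         for e in panel}
    return pd.Series(w)


def count_grs(dosages: DosageMatrix, panel: Panel,
              cohort: Cohort) -> pd.DataFrame:
    """Per-subject count GRS; columns ``c_grs`` and ``n_missing_snps``."""
    coded = _coded_doses(dosages, panel, cohort)
    return pd.DataFrame({
        "c_grs": coded.sum(axis=1, skipna=True),
        "n_missing_snps": coded.isna().sum(axis=1),
    })


def weighted_grs(dosages: DosageMatrix, panel: Panel, cohort: Cohort,
                 weight_mode: str = "or") -> pd.DataFrame:
    """Per-subject weighted GRS; columns ``w_grs`` and ``n_missing_snps``."""
    coded = _coded_doses(dosages, panel, cohort)
    w = _weights(panel, weight_mode).reindex(coded.columns)
    if w.isna().any():
        missing = list(w.index[w.isna()])
        raise ValidationError(f"missing weight for {missing}")
    return pd.DataFrame({
        "w_grs": (coded * w).sum(axis=1, skipna=True),
        "n_missing_snps": coded.isna().sum(axis=1),
    })


def grs_table(dosages: DosageMatrix, panel: Panel, cohort: Cohort,
              weight_mode: str = "or") -> pd.DataFrame:
    """Both scores per subject, with status and pair id attached."""
    c = count_grs(dosages, panel, cohort)
    w = weighted_grs(dosages, panel, cohort, weight_mode)
    meta = cohort.to_frame().set_index("subject_id")[["status", "pair_id"]]
    out = meta.join(c).join(w[["w_grs"]])
    return out[["status", "pair_id", "c_grs", "w_grs", "n_missing_snps"]]


def score_bounds(panel: Panel, weight_mode: str = "or"
                 ) -> dict[str, tuple[float, float]]:
    """Theoretical (min, max) of each score on a panel."""
    w = _weights(panel, weight_mode)
    cmax = wmax = wmin = 0.0
    for e in panel:
        top = 1.0 if e.chrom_class == "x_linked" else 2.0
        cmax += top
        contrib = top * w[e.rsid]
        # a negative weight (log_or mode, OR < 1) is maximised at dose 0
        wmax += max(0.0, contrib)
        wmin += min(0.0, contrib)
    return {"c_grs": (0.0, cmax), "w_grs": (wmin, wmax)}


def grs_association(scores: pd.Series, cohort: Cohort,
                    adjustment: str = "crude"
                    ) -> dict[str, float]:
    """Per-unit odds ratio for a score from conditional logistic regression.

    Returns a dict with or, ci_low, ci_high, p, beta, se, n_pairs.
    """
    covars = covariate_design(cohort, ADJUSTMENT_COVARIATES) \
        if adjustment == "adjusted" else None
    rows = []
    for pid in cohort.pair_ids:
        case, control = cohort.pair(pid)
        try:
            sc, sk = scores[case.subject_id], scores[control.subject_id]
        except KeyError:
            continue
        if np.isnan(sc) or np.isnan(sk):
            continue
        diff = [sc - sk]
        if covars is not None:
            diff.extend(
                covars.loc[case.subject_id].to_numpy(dtype=float)
                - covars.loc[control.subject_id].to_numpy(dtype=float)
            )
        rows.append(diff)
    if not rows:
        raise NonIdentifiableError("no complete pairs with scores")
    names = ["score"] + (list(covars.columns) if covars is not None else [])
    fit = clr_fit(pd.DataFrame(rows, columns=names))
    if "score" in fit.dropped:
        raise NonIdentifiableError("score constant within every pair")
    or_, lo, hi, p = fit.wald("score")
    b, se = fit.coef("score")
    return {"or": or_, "ci_low": lo, "ci_high": hi, "p": p,
            "beta": b, "se": se, "n_pairs": fit.n_pairs,
            "analysis": adjustment}


def compare_grs(scores: pd.Series, cohort: Cohort) -> dict[str, float]:
    """Case/control score summaries and paired two-sided tests.

    Reports means, s.d. and ranges per group, the paired t-test p and a
    Wilcoxon signed-rank p as the rank-based alternative.
    """
    if cohort.n_pairs < 2:
        raise ValidationError("need at least 2 pairs to compare scores")
    case_v, ctrl_v = [], []
    for pid in cohort.pair_ids:
        case, control = cohort.pair(pid)
        if case.subject_id in scores and control.subject_id in scores:
            sc, sk = scores[case.subject_id], scores[control.subject_id]
            if not (np.isnan(sc) or np.isnan(sk)):
                case_v.append(sc)
                ctrl_v.append(sk)
    case_v = np.asarray(case_v, dtype=float)
    ctrl_v = np.asarray(ctrl_v, dtype=float)
    if len(case_v) < 2:
        raise ValidationError("need at least 2 complete pairs")
    d = case_v - ctrl_v
    if np.allclose(d, d[0]):
        # zero-variance differences: a constant shift is either null (=0)
        # or overwhelmingly significant; the t statistic is degenerate
        p_t = 1.0 if np.allclose(d, 0.0) else 0.0
        p_w = p_t
    else:
        p_t = float(ttest_rel(case_v, ctrl_v).pvalue)
        nz = d[d != 0]
        p_w = float(wilcoxon(nz).pvalue) if len(nz) else 1.0
    return {
        "n_pairs": int(len(case_v)),
        "case_mean": float(case_v.mean()), "case_sd": float(case_v.std(ddof=1)),
        "case_min": float(case_v.min()), "case_max": float(case_v.max()),
        "control_mean": float(ctrl_v.mean()),
        "control_sd": float(ctrl_v.std(ddof=1)),
        "control_min": float(ctrl_v.min()), "control_max": float(ctrl_v.max()),
        "mean_difference": float(d.mean()),
        "p_paired_t": p_t, "p_wilcoxon": p_w,
    }
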