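"""Per-SNP case-control association for 1:1 matched cohorts.

Implements the four classical genetic encodings (codominant, dominant,
recessive, allelic), genotype/allele frequency tests with the expected-count
rule for switching to exact tests, crude cross-product odds ratios, and
conditional logistic regression.

For 1:1 matched pairs the conditional likelihood is

    L(beta) = prod_pairs exp(x_case . beta) /
              (exp(x_case . beta) + exp(x_control . beta)),

which is a no-intercept logistic likelihood on the within-pair covariate
differences d = x_case - x_control with all responses equal to 1. It is
maximised here by Newton-Raphson with step-halving; standard errors come
from the inverse observed information and confidence intervals and p-values
are Wald-based.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln
from scipy.stats import (chi2, chi2_contingency, fisher_exact, norm,
                         random_table)

from .errors import (NonIdentifiableError, SeparationError, ValidationError)
from .panel import (COVARIATE_LEVELS, MISSING, Cohort, DosageMatrix, Panel)

logger = logging.getLogger(__name__)

GENETIC_MODELS = ("codominant", "dominant", "recessive", "allelic")

Z95 = norm.ppf(0.975)


# ---------------------------------------------------------------------------
# conditional logistic regression


@dataclass
class ClrFit:
    """Fitted 1:1 conditional logistic model."""

    names: list[str]
    beta: np.ndarray
    se: np.ndarray
    cov: np.ndarray
    loglik: float
    iterations: int
    converged: bool
    n_pairs: int
    dropped: list[str] = field(default_factory=list)

    def coef(self, name: str) -> tuple[float, float]:
        """(beta, se) for a named column."""
        i = self.names.index(name)
        return float(self.beta[i]), float(self.se[i])

    def wald(self, name: str) -> tuple[float, float, float, float]:
        """(OR, ci_low, ci_high, p) for a named column."""
        b, s = self.coef(name)
        lo, hi = b - Z95 * s, b + Z95 * s
        p = 2 * norm.sf(abs(b) / s) if s > 0 else float("nan")
        return float(np.exp(b)), float(np.exp(lo)), float(np.exp(hi)), p


def clr_fit(diffs: np.ndarray | pd.DataFrame, names: list[str] | None = None,
            tol: float = 1e-8, max_iter: int = 50) -> ClrFit:
    """Maximise the 1:1 conditional likelihood on within-pair differences.

    Parameters
    ----------
    diffs
        (n_pairs, k) matrix of case-minus-control covariate differences.
    names
        Column names; taken from the DataFrame when one is passed.

    Raises
    ------
    NonIdentifiableError
        If every pair is concordant on every covariate.
    SeparationError
        If the likelihood is unbounded (complete separation), naming the
        offending covariate.
    """
    if isinstance(diffs, pd.DataFrame):
        names = list(diffs.columns)
        D = diffs.to_numpy(dtype=float)
    else:
        D = np.asarray(diffs, dtype=float)
        if D.ndim == 1:
            D = D[:, None]
        if names is None:
            names = [f"x{i}" for i in range(D.shape[1])]
    n_pairs, k = D.shape
    if n_pairs < 1:
        raise NonIdentifiableError("no pairs to fit")

    active = [j for j in range(k) if np.any(D[:, j] != 0)]
    dropped = [names[j] for j in range(k) if j not in active]
    if dropped:
        # matched-on covariates (sex, often age group) are concordant in
        # every pair and carry no conditional information
        logger.debug("dropping pair-concordant columns: %s", dropped)
    if not active:
        raise NonIdentifiableError(
            "all pairs concordant on every covariate; model not identifiable"
        )
    Da = D[:, active]
    beta = np.zeros(len(active))

    def ll(b: np.ndarray) -> float:
        return float(-np.logaddexp(0.0, -(Da @ b)).sum())

    current = ll(beta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        p = expit(Da @ beta)          # P(pair observed as observed)
        g = Da.T @ (1.0 - p)
        if np.max(np.abs(g)) < tol:
            converged = True
            break
        w = p * (1.0 - p)
        H = (Da * w[:, None]).T @ Da
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError as exc:
            raise NonIdentifiableError(
                f"singular information matrix: {exc}"
            ) from exc
        # step-halving
        scale = 1.0
        for _ in range(30):
            candidate = beta + scale * step
            if ll(candidate) >= current - 1e-12:
                break
            scale /= 2.0
        beta = beta + scale * step
        current = ll(beta)
        if np.max(np.abs(beta)) > 30.0:
            worst = names[active[int(np.argmax(np.abs(beta)))]]
            raise SeparationError(
                f"complete separation; unbounded coefficient for {worst!r}"
            )
    else:
        it = max_iter
    if not converged:
        p = expit(Da @ beta)
        g = Da.T @ (1.0 - p)
        if np.max(np.abs(g)) < tol:
            converged = True
    # a "converged" coefficient this large means the likelihood flattened
    # out along a separated direction, not a finite optimum
    if np.max(np.abs(beta)) > 15.0:
        worst = names[active[int(np.argmax(np.abs(beta)))]]
        raise SeparationError(
            f"complete separation; unbounded coefficient for {worst!r}")

    p = expit(Da @ beta)
    w = p * (1.0 - p)
    H = (Da * w[:, None]).T @ Da
    try:
        cov_a = np.linalg.inv(H)
    except np.linalg.LinAlgError as exc:
        raise NonIdentifiableError(
            f"singular information at optimum: {exc}"
        ) from exc

    full_beta = np.full(k, np.nan)
    full_se = np.full(k, np.nan)
    full_cov = np.full((k, k), np.nan)
    full_beta[active] = beta
    full_se[active] = np.sqrt(np.diag(cov_a))
    for ii, j in enumerate(active):
        full_cov[j, active] = cov_a[ii]
    return ClrFit(names=names, beta=full_beta, se=full_se, cov=full_cov,
                  loglik=current, iterations=it, converged=converged,
                  n_pairs=n_pairs, dropped=dropped)


# ---------------------------------------------------------------------------
# genotype encodings


def reference_dose(pooled_counts: dict[int, int]) -> int:
    """Reference genotype (as risk-allele dose 0 or 2) under the
    most-frequent-homozygote rule; ties break toward the non-risk
    homozygote (dose 0)."""
    n0 = pooled_counts.get(0, 0)
    n2 = pooled_counts.get(2, 0)
    return 2 if n2 > n0 else 0


def encode_genotype(dose: float, model: str, ref: int = 0) -> tuple[float, ...]:
    """Design columns for one subject under a genetic model.

    codominant -> (het, non-reference homozygote); dominant -> carrier
    indicator (dose >= 1); recessive -> risk-homozygote indicator; allelic
    -> risk-allele dose as a single continuous column.
    """
    if model not in GENETIC_MODELS:
        raise ValidationError(f"unknown genetic model {model!r}")
    if np.isnan(dose):
        raise ValidationError("missing dose must be excluded before encoding")
    d = int(dose)
    if model == "codominant":
        other_hom = 2 - ref
        return (float(d == 1), float(d == other_hom and d != 1))
    if model == "dominant":
        return (float(d >= 1),)
    if model == "recessive":
        return (float(d == 2),)
    return (float(d),)  # allelic


def codominant_labels(ref: int) -> tuple[str, str]:
    if ref == 0:
        return ("het vs hom_nonrisk", "hom_risk vs hom_nonrisk")
    return ("het vs hom_risk", "hom_nonrisk vs hom_risk")


# ---------------------------------------------------------------------------
# frequency tables and tests


def freq_table(dosages: DosageMatrix, cohort: Cohort, rsid: str,
               level: str = "genotype") -> pd.DataFrame:
    """Case/control contingency table for one SNP.

    ``genotype`` level counts subjects per dose (columns dropped when a
    genotype is absent in both groups); ``allele`` level counts risk/other
    alleles with two per diploid subject and one per X-linked male.
    """
    if rsid not in dosages.df.columns:
        raise ValidationError(f"unknown rsid {rsid}")
    if len(cohort) == 0:
        raise ValidationError("empty subject set")
    col = dosages.column(rsid)
    rows = {}
    for group, ids in (("case", [r.subject_id for r in cohort.cases()]),
                       ("control", [r.subject_id for r in cohort.controls()])):
        obs = col.loc[[s for s in ids if s in col.index]].dropna()
        if level == "genotype":
            rows[group] = [int((obs == d).sum()) for d in (0, 1, 2)]
        elif level == "allele":
            ploidy = np.array([1 if _is_haploid(dosages, cohort, rsid, s)
                               else 2 for s in obs.index])
            risk = int(obs.to_numpy().sum())
            total = int(ploidy.sum())
            rows[group] = [risk, total - risk]
        else:
            raise ValidationError(f"unknown level {level!r}")
    if level == "genotype":
        df = pd.DataFrame(rows, index=["0", "1", "2"]).T
        keep = [c for c in df.columns if df[c].sum() > 0]
        return df[keep]
    return pd.DataFrame(rows, index=["risk", "other"]).T


def _is_haploid(dosages: DosageMatrix, cohort: Cohort, rsid: str,
                subject: str) -> bool:
    # haploid only for males at X-linked SNPs; the panel class is not
    # carried on the matrix, so infer from the stored dose range instead
    return getattr(dosages, "_x_linked", {}).get(rsid, False) \
        and cohort.subject(subject).sex == "male"


def mark_x_linked(dosages: DosageMatrix, panel: Panel) -> None:
    """Annotate the matrix with the panel's X-linked SNPs (allele counting
    needs to know which male doses are haploid)."""
    dosages._x_linked = {e.rsid: e.chrom_class == "x_linked" for e in panel}


@dataclass(frozen=True)
class FreqTest:
    p_value: float
    method: str  # "chi2" | "fisher" | "exact_enum" | "exact_mc" | "undefined"
    statistic: float = float("nan")


def expected_counts(table: np.ndarray) -> np.ndarray:
    t = np.asarray(table, dtype=float)
    return np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()


def freq_test(table: pd.DataFrame | np.ndarray, *,
              seed: int = 0, n_mc: int = 200_000) -> FreqTest:
    """Chi-square test of case-control frequency differences, switching to
    an exact test when any expected cell count is below 5.

    2x2 exact tests use the two-sided hypergeometric rule; 2x3 tables are
    enumerated exactly; larger tables fall back to a seeded Monte-Carlo
    exact test (flagged ``exact_mc``).
    """
    t = np.asarray(table, dtype=float)
    if t.min() < 0 or not np.allclose(t, np.round(t)):
        raise ValidationError("table must hold non-negative integers")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        return FreqTest(float("nan"), "undefined")
    t = np.round(t).astype(int)
    if np.all(expected_counts(t) >= 5):
        stat, p, _, _ = chi2_contingency(t, correction=False)
        return FreqTest(float(p), "chi2", float(stat))
    if t.shape == (2, 2):
        _, p = fisher_exact(t, alternative="two-sided")
        return FreqTest(float(p), "fisher")
    if t.shape in ((2, 3), (3, 2)):
        return FreqTest(_exact_2x3_p(t if t.shape == (2, 3) else t.T),
                        "exact_enum")
    return FreqTest(_exact_mc_p(t, seed=seed, n_mc=n_mc), "exact_mc")


def _log_table_prob(t: np.ndarray) -> float:
    t = np.asarray(t, dtype=float)
    return float(
        gammaln(t.sum(axis=1) + 1).sum() + gammaln(t.sum(axis=0) + 1).sum()
        - gammaln(t.sum() + 1) - gammaln(t + 1).sum()
    )


def _exact_2x3_p(t: np.ndarray) -> float:
    """Exact conditional p for a 2x3 table: enumerate all tables with the
    observed margins, sum probabilities <= the observed one."""
    r1 = int(t[0].sum())
    c = t.sum(axis=0).astype(int)
    obs_logp = _log_table_prob(t)
    total = 0.0
    p_obs_tol = obs_logp + 1e-9
    for a in range(0, min(r1, c[0]) + 1):
        rem = r1 - a
        b_lo = max(0, rem - c[2])
        b_hi = min(c[1], rem)
        if b_hi < b_lo:
            continue
        b = np.arange(b_lo, b_hi + 1)
        cc = rem - b
        row1 = np.stack([np.full_like(b, a), b, cc], axis=1)
        row2 = c[None, :] - row1
        tables = np.stack([row1, row2], axis=1)  # (m, 2, 3)
        logp = (
            gammaln(np.array([r1, t.sum() - r1]) + 1).sum()
            + gammaln(c + 1).sum()
            - gammaln(t.sum() + 1)
            - gammaln(tables + 1).sum(axis=(1, 2))
        )
        total += np.exp(logp[logp <= p_obs_tol]).sum()
    return float(min(total, 1.0))


def _exact_mc_p(t: np.ndarray, seed: int, n_mc: int) -> float:
    rng = np.random.default_rng(seed)
    dist = random_table(t.sum(axis=1), t.sum(axis=0))
    draws = dist.rvs(n_mc, random_state=rng)
    obs_logp = _log_table_prob(t)
    logps = np.array([_log_table_prob(d) for d in draws])
    return float((logps <= obs_logp + 1e-9).mean())


def crude_or_2x2(table: pd.DataFrame | np.ndarray
                 ) -> tuple[float, float, float]:
    """Cross-product odds ratio with a Woolf (log-normal) 95% CI.

    Layout: rows (case, control), columns (exposed/risk, unexposed/other);
    OR = (a*d)/(b*c). A +0.5 Haldane-Anscombe correction is applied to all
    cells when any single cell is zero.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or t.min() < 0:
        raise ValidationError("need a non-negative 2x2 table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValidationError("zero margin: odds ratio undefined")
    if (t == 0).any():
        logger.warning("zero cell: applying +0.5 continuity correction")
        t = t + 0.5
    a, b = t[0]
    c, d = t[1]
    log_or = np.log(a * d / (b * c))
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return (float(np.exp(log_or)), float(np.exp(log_or - Z95 * se)),
            float(np.exp(log_or + Z95 * se)))


# ---------------------------------------------------------------------------
# covariate design for adjusted models

ADJUSTMENT_COVARIATES = ("age_group", "sex", "bmi_class", "pa_level",
                         "smoking", "alcohol_tertile", "di_group",
                         "energy_intake")


def covariate_design(cohort: Cohort,
                     covariates: tuple[str, ...] = ADJUSTMENT_COVARIATES
                     ) -> pd.DataFrame:
    """Per-subject design columns for the adjustment covariates.

    Categorical covariates are dummy-coded against their first level, with
    missing values kept as an explicit category (a separate dummy). Energy
    intake enters as a quantitative column; missing intakes are mean-imputed
    with a companion missing-indicator column.
    """
    df = cohort.to_frame().set_index("subject_id")
    out: dict[str, np.ndarray] = {}
    for cov in covariates:
        if cov == "energy_intake":
            vals = df["energy_intake"].astype(float)
            miss = vals.isna()
            mean = vals.mean() if not vals.dropna().empty else 0.0
            out["energy_intake"] = vals.fillna(mean).to_numpy()
            if miss.any():
                out["energy_intake=missing"] = miss.to_numpy(dtype=float)
        elif cov == "sex":
            out["sex=male"] = (df["sex"] == "male").to_numpy(dtype=float)
        else:
            levels = COVARIATE_LEVELS[cov]
            for level in levels[1:]:
                out[f"{cov}={level}"] = (df[cov] == level).to_numpy(float)
            if (df[cov] == MISSING).any():
                out[f"{cov}={MISSING}"] = (df[cov] == MISSING).to_numpy(float)
    return pd.DataFrame(out, index=df.index)


# ---------------------------------------------------------------------------
# the per-SNP scan


@dataclass(frozen=True)
class AssociationResult:
    rsid: str
    model: str
    contrast: str
    or_estimate: float
    ci_low: float
    ci_high: float
    p_value: float
    analysis: str  # "crude" | "adjusted"
    n_cases: int
    n_controls: int
    fit_ok: bool = True
    note: str = ""


def _pair_differences(doses: pd.Series, cohort: Cohort, model: str,
                      ref: int, covars: pd.DataFrame | None
                      ) -> tuple[pd.DataFrame, int, int] | None:
    """Build the case-minus-control difference matrix for one SNP,
    dropping pairs with a missing dose in either member."""
    if model == "codominant":
        geno_names = list(codominant_labels(ref))
    elif model == "dominant":
        geno_names = ["carrier"]
    elif model == "recessive":
        geno_names = ["hom_risk"]
    else:
        geno_names = ["per_allele"]
    rows = []
    n_cases = 0
    for pid in cohort.pair_ids:
        case, control = cohort.pair(pid)
        try:
            dc = doses[case.subject_id]
            dk = doses[control.subject_id]
        except KeyError:
            continue
        if np.isnan(dc) or np.isnan(dk):
            continue
        xc = np.array(encode_genotype(dc, model, ref))
        xk = np.array(encode_genotype(dk, model, ref))
        diff = xc - xk
        if covars is not None:
            diff = np.concatenate([
                diff,
                covars.loc[case.subject_id].to_numpy(dtype=float)
                - covars.loc[control.subject_id].to_numpy(dtype=float),
            ])
        rows.append(diff)
        n_cases += 1
    if not rows:
        return None
    names = geno_names + (list(covars.columns) if covars is not None else [])
    return pd.DataFrame(rows, columns=names), n_cases, n_cases


def run_association(dosages: DosageMatrix, cohort: Cohort, panel: Panel,
                    models: tuple[str, ...] = GENETIC_MODELS,
                    adjustment: str = "crude",
                    covariates: tuple[str, ...] = ADJUSTMENT_COVARIATES
                    ) -> list[AssociationResult]:
    """Conditional-logistic association scan: one result per SNP x model x
    contrast. Per-SNP fit failures are flagged, not fatal."""
    if adjustment not in ("crude", "adjusted"):
        raise ValidationError(f"unknown adjustment {adjustment!r}")
    covars = covariate_design(cohort, covariates) \
        if adjustment == "adjusted" else None
    results: list[AssociationResult] = []
    for entry in panel:
        if entry.rsid not in dosages.df.columns:
            continue
        doses = dosages.column(entry.rsid)
        pooled = {d: int((doses.dropna() == d).sum()) for d in (0, 1, 2)}
        ref = reference_dose(pooled)
        for model in models:
            built = _pair_differences(doses, cohort, model, ref, covars)
            if built is None:
                results.append(AssociationResult(
                    entry.rsid, model, "-", *(float("nan"),) * 4,
                    adjustment, 0, 0, fit_ok=False,
                    note="no complete pairs"))
                continue
            diffs, n_ca, n_co = built
            if model == "codominant":
                contrasts = list(codominant_labels(ref))
            elif model == "dominant":
                contrasts = ["carrier"]
            elif model == "recessive":
                contrasts = ["hom_risk"]
            else:
                contrasts = ["per_allele"]
            try:
                fit = clr_fit(diffs)
            except (NonIdentifiableError, SeparationError) as exc:
                for contrast in contrasts:
                    results.append(AssociationResult(
                        entry.rsid, model, contrast, *(float("nan"),) * 4,
                        adjustment, n_ca, n_co, fit_ok=False,
                        note=str(exc)))
                continue
            for contrast in contrasts:
                if contrast in fit.dropped:
                    results.append(AssociationResult(
                        entry.rsid, model, contrast, *(float("nan"),) * 4,
                        adjustment, n_ca, n_co, fit_ok=False,
                        note="contrast concordant in all pairs"))
                    continue
                or_, lo, hi, p = fit.wald(contrast)
                results.append(AssociationResult(
                    entry.rsid, model, contrast, or_, lo, hi, p,
                    adjustment, n_ca, n_co, fit_ok=fit.converged,
                    note="" if fit.converged else "not converged"))
    return results


def codominant_omnibus_p(dosages: DosageMatrix, cohort: Cohort, panel: Panel
                         ) -> dict[str, float]:
    """Per-SNP likelihood-ratio omnibus p from the crude codominant fit.

    This is the single primary p-value per SNP to which the Bonferroni
    threshold is applied (one test per SNP, not per contrast). Under the
    null the conditional log-likelihood is -n_pairs * ln 2.
    """
    out: dict[str, float] = {}
    for entry in panel:
        if entry.rsid not in dosages.df.columns:
            continue
        doses = dosages.column(entry.rsid)
        pooled = {d: int((doses.dropna() == d).sum()) for d in (0, 1, 2)}
        ref = reference_dose(pooled)
        built = _pair_differences(doses, cohort, "codominant", ref, None)
        if built is None:
            out[entry.rsid] = float("nan")
            continue
        diffs, _, _ = built
        try:
            fit = clr_fit(diffs)
        except (NonIdentifiableError, SeparationError):
            out[entry.rsid] = float("nan")
            continue
        df_model = len(fit.names) - len(fit.dropped)
        lr = 2.0 * (fit.loglik + fit.n_pairs * np.log(2.0))
        out[entry.rsid] = float(chi2.sf(max(lr, 0.0), df=df_model))
    return out


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise corrected significance threshold alpha / m."""
    if not 0 < alpha < 1:
        raise ValidationError(f"alpha must be in (0,1), got {alpha}")
    if not isinstance(m, (int, np.integer)) or m < 1:
        raise ValidationError(f"number of tests must be a positive integer, "
                              f"got {m}")
    return alpha / m


def results_frame(results: list[AssociationResult]) -> pd.DataFrame:
    """Tidy DataFrame of association results (one row per contrast)."""
    return pd.DataFrame([vars(r) for r in results])
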