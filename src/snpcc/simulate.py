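"""Synthetic matched case-control cohorts.

The generator emulates the design the analysis assumes: a screening-age
source population (integer ages uniform on 50-69, roughly two-thirds male),
genotypes drawn in Hardy-Weinberg proportions at specified risk-allele
frequencies, disease assigned by a logistic model with per-SNP log-odds
effects (and optional covariate effects), and 1:1 case-control pairs
matched on sex and age within a +/-9-year tolerance. Covariate category
prevalences default to values typical of a faecal-occult-blood screening
cohort; a small fraction of covariate values is set missing so the
missing-as-category adjustment path is exercised.

Everything is driven by a single integer seed: identical configurations
produce byte-identical output tables. Panel SNPs are simulated independently
(no linkage disequilibrium) and without genotyping error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import MatchingError, ValidationError
from .panel import Cohort, DosageMatrix, Panel, SubjectRecord

#: default category prevalences (probability of each level)
DEFAULT_COVARIATE_SPEC: dict[str, dict] = {
    "bmi_class": {"probs": {"non_ov_ob": 0.33, "ov_ob": 0.67}},
    "pa_level": {"probs": {"low": 0.774, "medium_high": 0.226}},
    "smoking": {"probs": {"never": 0.391, "ever": 0.609}},
    "alcohol_tertile": {"probs": {"T1": 0.339, "T2": 0.357, "T3": 0.304}},
    "di_group": {"probs": {"Q1-Q3": 0.696, "Q4-Q5": 0.304}},
}


@dataclass
class SimulationConfig:
    """Generative parameters of a synthetic matched cohort.

    ``effect_ors`` maps rsid to the true per-allele odds ratio (SNPs not
    listed act as null, OR = 1). ``covariate_spec`` may add a per-level
    ``effects`` mapping of log-odds contributions (default: none, pure
    confounder-free genetics).
    """

    n_pairs: int
    allele_freqs: Mapping[str, float]
    effect_ors: Mapping[str, float] = field(default_factory=dict)
    covariate_spec: Mapping[str, Mapping] = field(
        default_factory=lambda: DEFAULT_COVARIATE_SPEC)
    baseline_logit: float = -1.5
    age_tolerance_years: float = 9.0
    seed: int = 0
    pop_size: int | None = None  # default 10 x n_pairs
    male_fraction: float = 0.662
    missing_rate: float = 0.05
    energy_mean: float = 2100.0  # kcal/day
    energy_sd: float = 600.0

    def __post_init__(self) -> None:
        if self.n_pairs < 1:
            raise ValidationError("n_pairs must be positive")
        for rsid, f in self.allele_freqs.items():
            if not 0.0 < f < 1.0:
                raise ValidationError(
                    f"{rsid}: allele frequency must be in (0,1), got {f}")
        for rsid, o in self.effect_ors.items():
            if o <= 0:
                raise ValidationError(f"{rsid}: effect OR must be positive")
        if self.age_tolerance_years <= 0:
            raise ValidationError("age tolerance must be positive")


def simulate_genotype(freq: float, chrom_class: str, sex: str,
                      rng: np.random.Generator, size: int | None = None):
    """Draw risk-allele doses under Hardy-Weinberg proportions.

    Autosomal (and X-linked female) doses are Binomial(2, freq), i.e.
    P(2) = p^2, P(1) = 2p(1-p), P(0) = (1-p)^2; X-linked male doses are
    Bernoulli(freq).
    """
    if not 0.0 <= freq <= 1.0:
        raise ValidationError(f"allele frequency must be in [0,1], got {freq}")
    n_trials = 1 if (chrom_class == "x_linked" and sex == "male") else 2
    out = rng.binomial(n_trials, freq, size=size)
    return out if size is not None else int(out)


def _sample_covariates(spec: Mapping[str, Mapping], n: int,
                       rng: np.random.Generator) -> pd.DataFrame:
    cols = {}
    for cov, cfg in spec.items():
        levels = list(cfg["probs"])
        probs = np.array([cfg["probs"][lv] for lv in levels], dtype=float)
        probs = probs / probs.sum()
        cols[cov] = rng.choice(levels, size=n, p=probs)
    return pd.DataFrame(cols)


def _covariate_logodds(spec: Mapping[str, Mapping],
                       cov_df: pd.DataFrame) -> np.ndarray:
    eta = np.zeros(len(cov_df))
    for cov, cfg in spec.items():
        effects = cfg.get("effects")
        if not effects:
            continue
        eta += cov_df[cov].map(lambda lv: effects.get(lv, 0.0)).to_numpy()
    return eta


def simulate_cohort(config: SimulationConfig, panel: Panel
                    ) -> tuple[Cohort, DosageMatrix, dict]:
    """Simulate a source population, assign disease, and match 1:1.

    Returns the matched cohort (n_pairs cases + n_pairs controls), the
    dosage matrix of the selected subjects (panel column order), and a
    record of the true generative parameters.
    """
    for e in panel:
        if e.rsid not in config.allele_freqs:
            raise ValidationError(f"no allele frequency for {e.rsid}")
    rng = np.random.default_rng(config.seed)
    n_pop = config.pop_size or 10 * config.n_pairs

    sex = np.where(rng.random(n_pop) < config.male_fraction,
                   "male", "female")
    age = rng.integers(50, 70, size=n_pop)

    doses = np.empty((n_pop, len(panel)), dtype=float)
    for j, e in enumerate(panel):
        p = config.allele_freqs[e.rsid]
        if e.chrom_class == "x_linked":
            male = sex == "male"
            col = np.empty(n_pop)
            col[male] = rng.binomial(1, p, size=int(male.sum()))
            col[~male] = rng.binomial(2, p, size=int((~male).sum()))
        else:
            col = rng.binomial(2, p, size=n_pop).astype(float)
        doses[:, j] = col

    cov_df = _sample_covariates(config.covariate_spec, n_pop, rng)
    log_ors = np.array([np.log(config.effect_ors.get(e.rsid, 1.0))
                        for e in panel])
    eta = (config.baseline_logit + doses @ log_ors
           + _covariate_logodds(config.covariate_spec, cov_df))
    is_case = rng.random(n_pop) < 1.0 / (1.0 + np.exp(-eta))

    case_idx = np.flatnonzero(is_case)
    ctrl_idx = np.flatnonzero(~is_case)
    if len(case_idx) < config.n_pairs:
        raise MatchingError(
            f"only {len(case_idx)} cases in the simulated population; "
            f"{config.n_pairs} requested (raise pop_size or baseline_logit)")
    case_idx = rng.permutation(case_idx)[:config.n_pairs]

    # bucket available controls by (sex, age); ages are integers 50..69
    buckets: dict[tuple[str, int], list[int]] = {}
    for i in rng.permutation(ctrl_idx):
        buckets.setdefault((sex[i], int(age[i])), []).append(int(i))
    tol = int(config.age_tolerance_years)
    matched: list[tuple[int, int]] = []
    unmatched = 0
    for ci in case_idx:
        found = None
        for delta in range(0, tol + 1):
            for candidate_age in ({int(age[ci])} if delta == 0 else
                                  {int(age[ci]) - delta, int(age[ci]) + delta}):
                b = buckets.get((sex[ci], candidate_age))
                if b:
                    found = b.pop()
                    break
            if found is not None:
                break
        if found is None:
            unmatched += 1
        else:
            matched.append((int(ci), found))
    if unmatched:
        raise MatchingError(
            f"{unmatched} of {config.n_pairs} cases have no eligible "
            f"age/sex-matched control left")

    # assemble records; apply covariate missingness on selected subjects only
    records: list[SubjectRecord] = []
    dose_rows: dict[str, np.ndarray] = {}
    energy_all = np.clip(
        rng.normal(config.energy_mean, config.energy_sd, size=n_pop),
        800.0, None)
    miss_cols = list(config.covariate_spec) + ["energy_intake"]
    miss_draw = rng.random((len(matched) * 2, len(miss_cols)))

    def make_record(idx: int, status: str, pair_id: str,
                    row: int) -> SubjectRecord:
        kwargs = {
            "subject_id": f"S{idx:06d}",
            "status": status,
            "pair_id": pair_id,
            "sex": str(sex[idx]),
            "age_group": "50-59" if age[idx] < 60 else "60-69",
            "energy_intake": float(energy_all[idx]),
        }
        for k, cov in enumerate(config.covariate_spec):
            missing = miss_draw[row, k] < config.missing_rate
            kwargs[cov] = "missing" if missing else str(cov_df[cov].iloc[idx])
        if miss_draw[row, len(miss_cols) - 1] < config.missing_rate:
            kwargs["energy_intake"] = float("nan")
        return SubjectRecord(**kwargs)

    row = 0
    for k, (ci, ki) in enumerate(matched):
        pid = f"P{k:05d}"
        records.append(make_record(ci, "case", pid, row))
        row += 1
        records.append(make_record(ki, "control", pid, row))
        row += 1
        dose_rows[f"S{ci:06d}"] = doses[ci]
        dose_rows[f"S{ki:06d}"] = doses[ki]

    cohort = Cohort(records)
    dm = DosageMatrix(pd.DataFrame.from_dict(
        dose_rows, orient="index", columns=panel.rsids))
    dm.validate(panel, cohort)
    truth = {
        "seed": config.seed,
        "n_pairs": config.n_pairs,
        "pop_size": n_pop,
        "baseline_logit": config.baseline_logit,
        "allele_freqs": dict(config.allele_freqs),
        "effect_ors": {e.rsid: config.effect_ors.get(e.rsid, 1.0)
                       for e in panel},
        "covariate_spec": {k: dict(v) for k, v in
                           config.covariate_spec.items()},
        "n_cases_population": int(is_case.sum()),
    }
    return cohort, dm, truth


def cohort_from_genotype_counts(rsid: str, case_counts: tuple[int, int, int],
                                control_counts: tuple[int, int, int],
                                seed: int = 0
                                ) -> tuple[Cohort, DosageMatrix]:
    """Build a 1:1 cohort whose marginal genotype counts at one SNP equal
    the given (dose-0, dose-1, dose-2) triples, with cases paired to
    controls uniformly at random.

    Useful for reconstructing a cohort from a published genotype-count
    table; the pairing is the only unknown and is drawn from the seed.
    When the group totals differ (per-SNP denominators often do, through
    genotyping dropout), the smaller group is padded with missing doses so
    the 1:1 pair structure holds; padded pairs drop out of any per-SNP
    analysis.
    """
    rng = np.random.default_rng(seed)
    n = max(sum(case_counts), sum(control_counts))
    case_doses = np.concatenate([
        np.repeat([0.0, 1.0, 2.0], case_counts),
        np.full(n - sum(case_counts), np.nan)])
    ctrl_doses = np.concatenate([
        np.repeat([0.0, 1.0, 2.0], control_counts),
        np.full(n - sum(control_counts), np.nan)])
    rng.shuffle(case_doses)
    rng.shuffle(ctrl_doses)
    records = []
    dose_map = {}
    for k in range(len(case_doses)):
        pid = f"P{k:05d}"
        for status, dose in (("case", case_doses[k]),
                             ("control", ctrl_doses[k])):
            sid = f"{status[:2]}{k:05d}"
            records.append(SubjectRecord(
                subject_id=sid, status=status, pair_id=pid, sex="female",
                age_group="60-69"))
            dose_map[sid] = dose
    cohort = Cohort(records)
    dm = DosageMatrix(pd.DataFrame({rsid: pd.Series(dose_map)}))
    return cohort, dm
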