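"""Correspondence analysis of lifestyle/demographic indicators and
risk-genotype carrier status.

Simple CA of a non-negative table: the correspondence matrix P = N / n has
row masses r and column masses c, the standardised residual matrix is

    S = D_r^{-1/2} (P - r c^T) D_c^{-1/2},

and its singular value decomposition S = U Sigma V^T gives principal
coordinates F = D_r^{-1/2} U Sigma (rows) and G = D_c^{-1/2} V Sigma
(columns). The squared singular values are the principal inertias; their
total equals the table's chi-square statistic divided by the grand total.

The cohort-facing entry point codes each binary variable (and one carrier
flag per selected SNP) as a pair of 0/1 indicator columns per subject,
mirroring how gene-environment structure among cases is usually displayed
as a Cartesian diagram of category points.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .panel import MISSING, Cohort, DosageMatrix

logger = logging.getLogger(__name__)

#: variable -> (label of the 0 level, label of the 1 level, coding fn)
DEFAULT_CA_VARIABLES = ("age_group", "sex", "bmi_class", "pa_level",
                        "smoking", "alcohol_group", "di_group")


def _binary_code(record, variable: str) -> float | None:
    """0/1 coding of a subject's value for a CA variable; None if missing."""
    if variable == "age_group":
        v = record.age_group
        return None if v == MISSING else float(v == "60-69")
    if variable == "sex":
        return float(record.sex == "male")
    if variable == "bmi_class":
        v = record.bmi_class
        return None if v == MISSING else float(v == "ov_ob")
    if variable == "pa_level":
        v = record.pa_level
        return None if v == MISSING else float(v == "medium_high")
    if variable == "smoking":
        v = record.smoking
        return None if v == MISSING else float(v == "ever")
    if variable == "alcohol_group":
        v = record.alcohol_tertile
        return None if v == MISSING else float(v == "T3")  # top tertile
    if variable == "di_group":
        v = record.di_group
        return None if v == MISSING else float(v == "Q4-Q5")
    raise ValidationError(f"no binary coding defined for {variable!r}")


def build_indicator_table(cohort: Cohort,
                          variables: tuple[str, ...] = DEFAULT_CA_VARIABLES,
                          dosages: DosageMatrix | None = None,
                          carrier_snps: tuple[str, ...] = ("rs6687758",),
                          cases_only: bool = True) -> pd.DataFrame:
    """Subjects x category-indicator 0/1 matrix for correspondence analysis.

    Each binary variable contributes two columns (``var=0``, ``var=1``);
    a missing value leaves both columns of that block zero (logged). A
    carrier flag (dose >= 1 of the risk allele) is added per selected SNP
    when a dosage matrix is supplied.
    """
    records = cohort.cases() if cases_only else list(cohort)
    columns: list[str] = []
    for v in variables:
        columns += [f"{v}=0", f"{v}=1"]
    for rsid in (carrier_snps if dosages is not None else ()):
        columns += [f"{rsid}_carrier=0", f"{rsid}_carrier=1"]
    mat = pd.DataFrame(0.0, index=[r.subject_id for r in records],
                       columns=columns)
    n_missing = 0
    for r in records:
        for v in variables:
            code = _binary_code(r, v)
            if code is None:
                n_missing += 1
                continue
            mat.at[r.subject_id, f"{v}={int(code)}"] = 1.0
        if dosages is not None:
            for rsid in carrier_snps:
                d = dosages.dose(r.subject_id, rsid)
                if np.isnan(d):
                    n_missing += 1
                    continue
                mat.at[r.subject_id, f"{rsid}_carrier={int(d >= 1)}"] = 1.0
    if n_missing:
        logger.warning("%d missing values left as all-zero indicator blocks",
                       n_missing)
    return mat


@dataclass
class CaResult:
    row_coords: pd.DataFrame     # rows x axes, principal coordinates
    col_coords: pd.DataFrame     # columns x axes
    singular_values: np.ndarray
    inertia: np.ndarray          # squared singular values per axis
    inertia_pct: np.ndarray      # percent of total inertia per axis
    total_inertia: float


def ca_fit(table: pd.DataFrame | np.ndarray, n_axes: int | None = None
           ) -> CaResult:
    """Simple correspondence analysis of a non-negative table."""
    if isinstance(table, pd.DataFrame):
        row_names = list(table.index)
        col_names = list(table.columns)
        N = table.to_numpy(dtype=float)
    else:
        N = np.asarray(table, dtype=float)
        row_names = [f"r{i}" for i in range(N.shape[0])]
        col_names = [f"c{j}" for j in range(N.shape[1])]
    if N.min() < 0:
        raise ValidationError("table must be non-negative")
    total = N.sum()
    if total <= 0:
        raise ValidationError("table must have a positive grand total")
    zero_rows = np.where(N.sum(axis=1) == 0)[0]
    zero_cols = np.where(N.sum(axis=0) == 0)[0]
    if len(zero_rows) or len(zero_cols):
        raise ValidationError(
            f"all-zero rows {[row_names[i] for i in zero_rows]} / columns "
            f"{[col_names[j] for j in zero_cols]}; remove before fitting"
        )
    P = N / total
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, sv, Vt = np.linalg.svd(S, full_matrices=False)
    # discard numerically-null axes
    keep = sv > 1e-12
    U, sv, Vt = U[:, keep], sv[keep], Vt[keep]
    max_axes = min(N.shape) - 1
    if len(sv) > max_axes:
        U, sv, Vt = U[:, :max_axes], sv[:max_axes], Vt[:max_axes]
    if n_axes is not None:
        if n_axes > len(sv):
            logger.warning("requested %d axes but rank supports %d",
                           n_axes, len(sv))
        U, sv, Vt = U[:, :n_axes], sv[:n_axes], Vt[:n_axes]
    F = U * sv / np.sqrt(r)[:, None]
    G = Vt.T * sv / np.sqrt(c)[:, None]
    # deterministic orientation: largest-|column loading| positive per axis
    for k in range(G.shape[1]):
        j = int(np.argmax(np.abs(G[:, k])))
        if G[j, k] < 0:
            G[:, k] *= -1
            F[:, k] *= -1
    inertia = sv ** 2
    total_inertia = float((S ** 2).sum())
    pct = (100.0 * inertia / total_inertia if total_inertia > 0
           else np.zeros_like(inertia))
    axes = [f"axis{k + 1}" for k in range(len(sv))]
    return CaResult(
        row_coords=pd.DataFrame(F, index=row_names, columns=axes),
        col_coords=pd.DataFrame(G, index=col_names, columns=axes),
        singular_values=sv,
        inertia=inertia,
        inertia_pct=pct,
        total_inertia=total_inertia,
    )
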