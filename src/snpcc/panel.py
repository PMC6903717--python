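"""Susceptibility-panel, genotype and subject-table I/O.

The analysis is keyed entirely by rsID: a *panel* lists the candidate SNPs
with their published per-allele odds ratios and risk alleles, genotypes are
reduced to risk-allele dosages (0/1/2 autosomal; 0/1 for hemizygous males on
the X), and subjects carry case-control status, a matched-pair identifier
and the lifestyle/demographic covariates used for adjustment.

Genotypes are accepted either as a VCF (sites with GT calls) or as a plain
TSV of rsID rows by subject columns holding allele pairs (``AG``) or numeric
doses; the TSV dialect is the canonical fixture format. Alleles are matched
by nucleotide identity only — strand-ambiguous (A/T, C/G) sites are taken
as-is with a warning, never flipped. Missing genotypes are never imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import StructuralError, ValidationError

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")
AMBIGUOUS_PAIRS = ({"A", "T"}, {"C", "G"})

#: Categorical covariates used for adjustment, with their non-missing levels.
COVARIATE_LEVELS: Mapping[str, tuple[str, ...]] = {
    "age_group": ("50-59", "60-69"),
    "bmi_class": ("non_ov_ob", "ov_ob"),
    "pa_level": ("low", "medium_high"),
    "smoking": ("never", "ever"),
    "alcohol_tertile": ("T1", "T2", "T3"),
    "di_group": ("Q1-Q3", "Q4-Q5"),
}

MISSING = "missing"

SUBJECT_COLUMNS = (
    "subject_id",
    "status",
    "pair_id",
    "sex",
    "age_group",
    "bmi_class",
    "pa_level",
    "smoking",
    "alcohol_tertile",
    "di_group",
    "energy_intake",
)


@dataclass(frozen=True)
class PanelEntry:
    """One susceptibility SNP of the candidate panel."""

    rsid: str
    gene_label: str
    locus_label: str
    published_or: float
    risk_allele: str
    chrom_class: str  # "autosomal" | "x_linked"

    def __post_init__(self) -> None:
        if self.published_or <= 0:
            raise ValidationError(
                f"{self.rsid}: published OR must be positive, got "
                f"{self.published_or}"
            )
        if self.risk_allele not in VALID_ALLELES:
            raise ValidationError(
                f"{self.rsid}: risk allele {self.risk_allele!r} not one of "
                "A/C/G/T"
            )
        if self.chrom_class not in ("autosomal", "x_linked"):
            raise ValidationError(
                f"{self.rsid}: unknown chrom_class {self.chrom_class!r}"
            )


class Panel:
    """Ordered collection of :class:`PanelEntry` with unique rsIDs."""

    def __init__(self, entries: Iterable[PanelEntry]):
        self.entries: list[PanelEntry] = list(entries)
        seen: set[str] = set()
        for e in self.entries:
            if e.rsid in seen:
                raise ValidationError(f"duplicate rsid in panel: {e.rsid}")
            seen.add(e.rsid)
        self._by_rsid = {e.rsid: e for e in self.entries}

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __getitem__(self, rsid: str) -> PanelEntry:
        return self._by_rsid[rsid]

    def __contains__(self, rsid: str) -> bool:
        return rsid in self._by_rsid

    @property
    def rsids(self) -> list[str]:
        return [e.rsid for e in self.entries]

    def count_by_class(self) -> dict[str, int]:
        out: dict[str, int] = {"autosomal": 0, "x_linked": 0}
        for e in self.entries:
            out[e.chrom_class] += 1
        return out


@dataclass(frozen=True)
class SubjectRecord:
    """Case/control status, matched-pair membership and covariates.

    Categorical covariates hold the string :data:`MISSING` when absent;
    ``energy_intake`` (kcal/day) is ``nan`` when absent.
    """

    subject_id: str
    status: str  # "case" | "control"
    pair_id: str
    sex: str  # "male" | "female"
    age_group: str = MISSING
    bmi_class: str = MISSING
    pa_level: str = MISSING
    smoking: str = MISSING
    alcohol_tertile: str = MISSING
    di_group: str = MISSING
    energy_intake: float = float("nan")

    def __post_init__(self) -> None:
        if self.status not in ("case", "control"):
            raise ValidationError(f"bad status {self.status!r}")
        if self.sex not in ("male", "female"):
            raise ValidationError(f"bad sex {self.sex!r}")
        for cov, levels in COVARIATE_LEVELS.items():
            val = getattr(self, cov)
            if val != MISSING and val not in levels:
                raise ValidationError(
                    f"subject {self.subject_id}: {cov}={val!r} not in "
                    f"{levels} or {MISSING!r}"
                )
        if not np.isnan(self.energy_intake) and self.energy_intake < 0:
            raise ValidationError(
                f"subject {self.subject_id}: negative energy intake"
            )


class Cohort:
    """A validated matched case-control cohort (1:1 pairs)."""

    def __init__(self, records: Iterable[SubjectRecord]):
        self.records: list[SubjectRecord] = list(records)
        ids = [r.subject_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise StructuralError("duplicate subject_id in cohort")
        self._validate_pairs()
        self._by_id = {r.subject_id: r for r in self.records}

    def _validate_pairs(self) -> None:
        pairs: dict[str, list[SubjectRecord]] = {}
        for r in self.records:
            pairs.setdefault(r.pair_id, []).append(r)
        for pid, members in pairs.items():
            statuses = sorted(m.status for m in members)
            if statuses != ["case", "control"]:
                raise StructuralError(
                    f"pair {pid}: expected one case and one control, got "
                    f"{statuses}"
                )
            if members[0].sex != members[1].sex:
                raise StructuralError(f"pair {pid}: sexes differ")
        self.pair_ids = sorted(pairs)
        self._pairs = pairs

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def subject(self, subject_id: str) -> SubjectRecord:
        return self._by_id[subject_id]

    @property
    def n_pairs(self) -> int:
        return len(self.pair_ids)

    def pair(self, pair_id: str) -> tuple[SubjectRecord, SubjectRecord]:
        """Return the (case, control) records of a pair."""
        a, b = self._pairs[pair_id]
        return (a, b) if a.status == "case" else (b, a)

    def cases(self) -> list[SubjectRecord]:
        return [r for r in self.records if r.status == "case"]

    def controls(self) -> list[SubjectRecord]:
        return [r for r in self.records if r.status == "control"]

    def sex_of(self) -> dict[str, str]:
        return {r.subject_id: r.sex for r in self.records}

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame([vars(r) for r in self.records])
        return df[list(SUBJECT_COLUMNS)]


class DosageMatrix:
    """Subjects x panel-SNPs risk-allele dose matrix.

    Stored as a float DataFrame (index = subject ids, columns = rsids);
    ``nan`` marks a missing genotype. Doses are 0/1/2 for autosomal SNPs
    and for females at X-linked SNPs, 0/1 for hemizygous males.
    """

    def __init__(self, df: pd.DataFrame):
        if df.index.has_duplicates or df.columns.has_duplicates:
            raise ValidationError("duplicate subject or snp identifiers")
        self.df = df.astype(float)

    @property
    def subjects(self) -> list[str]:
        return list(self.df.index)

    @property
    def snps(self) -> list[str]:
        return list(self.df.columns)

    def dose(self, subject: str, rsid: str) -> float:
        return float(self.df.at[subject, rsid])

    def column(self, rsid: str) -> pd.Series:
        return self.df[rsid]

    def validate(self, panel: Panel, cohort: Cohort) -> None:
        """Assert every dose lies in the sex/chromosome-permitted set."""
        sex = cohort.sex_of()
        for e in panel:
            if e.rsid not in self.df.columns:
                continue
            col = self.df[e.rsid]
            obs = col.dropna()
            if e.chrom_class == "x_linked":
                males = [s for s in obs.index if sex.get(s) == "male"]
                if males and not obs.loc[males].isin([0.0, 1.0]).all():
                    bad = obs.loc[males][~obs.loc[males].isin([0.0, 1.0])]
                    raise ValidationError(
                        f"{e.rsid}: male X-linked dose outside {{0,1}} for "
                        f"{list(bad.index)[:5]}"
                    )
                females = [s for s in obs.index if sex.get(s) == "female"]
                vals = obs.loc[females]
            else:
                vals = obs
            if not vals.isin([0.0, 1.0, 2.0]).all():
                bad = vals[~vals.isin([0.0, 1.0, 2.0])]
                raise ValidationError(
                    f"{e.rsid}: dose outside {{0,1,2}} for "
                    f"{list(bad.index)[:5]}"
                )

    # -- canonical TSV dialect (rsID rows x subject columns) ---------------

    def to_tsv(self, path: str | Path) -> None:
        out = self.df.T.copy()
        out.index.name = "rsid"

        def fmt(v: float) -> str:
            return "NA" if np.isnan(v) else str(int(v)) if v == int(v) else str(v)

        out = out.map(fmt)
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DosageMatrix":
        raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str,
                          keep_default_na=False)
        df = raw.map(lambda v: np.nan if v == "NA" else float(v)).T
        df.index.name = None
        df.columns.name = None
        return cls(df)


# ---------------------------------------------------------------------------
# loaders


def default_panel_path() -> Path:
    """Path of the packaged 48-SNP colorectal-cancer susceptibility panel."""
    return Path(str(resources.files("snpcc").joinpath("data/panel_table1.tsv")))


def load_panel(path: str | Path | None = None) -> Panel:
    """Read a panel TSV (columns rsid, gene, locus, or, risk_allele,
    chrom_class) and return validated entries in file order."""
    if path is None:
        path = default_panel_path()
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"rsid", "gene", "locus", "or", "risk_allele", "chrom_class"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"panel file missing columns: {sorted(missing)}")
    entries = [
        PanelEntry(
            rsid=row["rsid"],
            gene_label=row["gene"],
            locus_label=row["locus"],
            published_or=float(row["or"]),
            risk_allele=row["risk_allele"],
            chrom_class=row["chrom_class"],
        )
        for row in df.to_dict("records")
    ]
    return Panel(entries)


def load_subjects(path: str | Path) -> Cohort:
    """Read the subject/covariate TSV; missing values are encoded ``NA``."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing_cols = set(SUBJECT_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValidationError(
            f"subject file missing columns: {sorted(missing_cols)}"
        )
    records = []
    for row in df.to_dict("records"):
        kwargs = dict(row)
        for cov in COVARIATE_LEVELS:
            if kwargs[cov] in ("NA", ""):
                kwargs[cov] = MISSING
        ei = kwargs["energy_intake"]
        kwargs["energy_intake"] = float("nan") if ei in ("NA", "") else float(ei)
        records.append(SubjectRecord(**{k: kwargs[k] for k in SUBJECT_COLUMNS}))
    return Cohort(records)


def save_subjects(cohort: Cohort, path: str | Path) -> None:
    df = cohort.to_frame().copy()
    for cov in COVARIATE_LEVELS:
        df[cov] = df[cov].replace(MISSING, "NA")
    df["energy_intake"] = df["energy_intake"].map(
        lambda v: "NA" if np.isnan(v) else f"{v:.1f}"
    )
    df.to_csv(path, sep="\t", index=False)


def _dose_from_alleles(cell: str, entry: PanelEntry, subject: str,
                       sex: str) -> float:
    alleles = list(cell)
    bad = [a for a in alleles if a not in VALID_ALLELES]
    if bad:
        raise ValidationError(
            f"{entry.rsid}/{subject}: invalid allele call {cell!r}"
        )
    dose = float(sum(a == entry.risk_allele for a in alleles))
    if entry.chrom_class == "x_linked" and sex == "male":
        if len(alleles) == 2:
            if alleles[0] != alleles[1]:
                logger.warning(
                    "%s: heterozygous X call for male %s set to missing",
                    entry.rsid, subject,
                )
                return np.nan
            dose = dose / 2  # pseudo-diploid homozygote recorded twice
    return dose


def load_genotypes(path: str | Path, panel: Panel,
                   cohort: Cohort) -> DosageMatrix:
    """Convert raw genotypes (VCF or the TSV dialect) to risk-allele doses.

    SNPs absent from the panel are skipped with a warning; panel SNPs
    absent from the file are marked missing for every subject.
    """
    path = Path(path)
    if path.suffix.lower() in (".vcf", ".gz", ".bcf"):
        return _load_vcf(path, panel, cohort)
    return _load_dosage_tsv(path, panel, cohort)


def _warn_if_ambiguous(entry: PanelEntry, ref: str, alt: str) -> None:
    if {ref, alt} in AMBIGUOUS_PAIRS:
        logger.warning(
            "%s: strand-ambiguous site %s/%s accepted as-is", entry.rsid,
            ref, alt,
        )


def _load_vcf(path: Path, panel: Panel, cohort: Cohort) -> DosageMatrix:
    import pysam

    sex = cohort.sex_of()
    subjects = [r.subject_id for r in cohort]
    df = pd.DataFrame(np.nan, index=subjects, columns=panel.rsids)
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            rsid = rec.id
            if rsid is None or rsid not in panel:
                logger.warning("skipping off-panel record %s", rsid)
                continue
            entry = panel[rsid]
            ref = rec.ref
            alts = rec.alts or ()
            alt = alts[0] if alts else None
            site_alleles = {ref} | set(alts)
            if entry.risk_allele not in site_alleles:
                raise ValidationError(
                    f"{rsid}: risk allele {entry.risk_allele} matches "
                    f"neither REF={ref} nor ALT={','.join(alts) or '.'}"
                )
            if alt is not None:
                _warn_if_ambiguous(entry, ref, alt)
            for sample in samples:
                if sample not in df.index:
                    continue
                gt = rec.samples[sample].get("GT")
                if gt is None or all(g is None for g in gt):
                    continue
                called = [g for g in gt if g is not None]
                allele_strs = [rec.alleles[g] for g in called]
                dose = float(
                    sum(a == entry.risk_allele for a in allele_strs)
                )
                if (entry.chrom_class == "x_linked"
                        and sex.get(sample) == "male"):
                    if len(set(allele_strs)) > 1:
                        logger.warning(
                            "%s: heterozygous X call for male %s set to "
                            "missing", rsid, sample,
                        )
                        continue
                    if len(allele_strs) == 2:
                        dose = dose / 2
                df.at[sample, rsid] = dose
    dm = DosageMatrix(df)
    dm.validate(panel, cohort)
    return dm


def _load_dosage_tsv(path: Path, panel: Panel, cohort: Cohort) -> DosageMatrix:
    sex = cohort.sex_of()
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str,
                      keep_default_na=False)
    subjects = [r.subject_id for r in cohort]
    df = pd.DataFrame(np.nan, index=subjects, columns=panel.rsids)
    for rsid, row in raw.iterrows():
        if rsid not in panel:
            logger.warning("skipping off-panel record %s", rsid)
            continue
        entry = panel[rsid]
        for subject, cell in row.items():
            if subject not in df.index or cell in ("NA", ""):
                continue
            if cell[0] in VALID_ALLELES and not cell.isdigit():
                dose = _dose_from_alleles(cell, entry, str(subject),
                                          sex.get(str(subject), "female"))
            else:
                dose = float(cell)
            df.at[subject, rsid] = dose
    dm = DosageMatrix(df)
    dm.validate(panel, cohort)
    return dm
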