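"""End-to-end orchestration: load inputs, run every analysis stage, write a
deterministic results bundle.

Stage order mirrors the study workflow: load and validate -> HWE scan per
group -> conditional-logistic association scan (crude and adjusted, all
genetic models) with Bonferroni flags -> genetic risk scores (count and
weighted, association and paired comparison) -> correspondence analysis of
cases. All floats are written with a fixed format and JSON keys are sorted,
so identical inputs and configuration yield byte-identical bundles; a
manifest records input checksums, the seed and the package version.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .association import (GENETIC_MODELS, bonferroni_threshold,
                          codominant_omnibus_p, freq_test, mark_x_linked,
                          results_frame, run_association)
from .ca import DEFAULT_CA_VARIABLES, build_indicator_table, ca_fit
from .errors import ValidationError
from .grs import compare_grs, grs_association, grs_table
from .hwe import hwe_scan
from .panel import (COVARIATE_LEVELS, Cohort, load_genotypes, load_panel,
                    load_subjects, save_subjects)
from .simulate import SimulationConfig, simulate_cohort

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.6g"


@dataclass
class PipelineConfig:
    panel_path: str | Path | None  # None -> packaged default panel
    genotypes_path: str | Path
    subjects_path: str | Path
    out_dir: str | Path
    alpha: float = 0.05
    models: tuple[str, ...] = GENETIC_MODELS
    weight_mode: str = "or"
    ca_variables: tuple[str, ...] = DEFAULT_CA_VARIABLES
    carrier_snps: tuple[str, ...] = ("rs6687758",)
    seed: int = 0


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FMT,
              lineterminator="\n")


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, sort_keys=True, indent=1,
                               allow_nan=True) + "\n")


def describe_cohort(cohort: Cohort, seed: int = 0) -> pd.DataFrame:
    """Per-covariate case/control comparison (frequencies with a
    chi-square/exact p for categories; mean (s.d.) with a paired t for
    energy intake)."""
    from scipy.stats import ttest_rel

    df = cohort.to_frame()
    cases = df[df.status == "case"]
    ctrls = df[df.status == "control"]
    rows = []
    for cov in ("age_group", "sex", *COVARIATE_LEVELS):
        if cov == "sex":
            levels = ["female", "male"]
        else:
            levels = [lv for lv in
                      (("50-59", "60-69") if cov == "age_group"
                       else COVARIATE_LEVELS[cov])]
        observed_levels = [lv for lv in levels + ["missing"]
                           if (df[cov] == lv).any()]
        table = np.array([[ (cases[cov] == lv).sum()
                            for lv in observed_levels],
                          [ (ctrls[cov] == lv).sum()
                            for lv in observed_levels]])
        ft = freq_test(table, seed=seed)
        for i, lv in enumerate(observed_levels):
            n_case = int(table[0, i])
            n_ctrl = int(table[1, i])
            rows.append({
                "variable": cov, "level": lv,
                "case_pct": 100.0 * n_case / max(len(cases), 1),
                "control_pct": 100.0 * n_ctrl / max(len(ctrls), 1),
                "p_value": ft.p_value if i == 0 else np.nan,
                "test": ft.method if i == 0 else "",
            })
    # quantitative: energy intake, paired on complete pairs
    e_case, e_ctrl = [], []
    for pid in cohort.pair_ids:
        case, control = cohort.pair(pid)
        if not (np.isnan(case.energy_intake)
                or np.isnan(control.energy_intake)):
            e_case.append(case.energy_intake)
            e_ctrl.append(control.energy_intake)
    if len(e_case) >= 2 and np.std(np.array(e_case) - np.array(e_ctrl)) > 0:
        p_e = float(ttest_rel(e_case, e_ctrl).pvalue)
    else:
        p_e = float("nan")
    all_case = cases["energy_intake"].astype(float)
    all_ctrl = ctrls["energy_intake"].astype(float)
    rows.append({
        "variable": "energy_intake", "level": "mean(sd)",
        "case_pct": float(all_case.mean()),
        "control_pct": float(all_ctrl.mean()),
        "p_value": p_e, "test": "paired_t",
    })
    return pd.DataFrame(rows)


def emit_synthetic_inputs(config: SimulationConfig, out_dir: str | Path,
                          panel_path: str | Path | None = None
                          ) -> dict[str, Path]:
    """Simulate a cohort and write the three pipeline input files plus the
    true-parameter record (for harnesses that check recovery)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    panel = load_panel(panel_path)
    cohort, dosages, truth = simulate_cohort(config, panel)
    paths = {
        "panel": out / "panel.tsv",
        "genotypes": out / "genotypes.tsv",
        "subjects": out / "subjects.tsv",
        "truth": out / "true_parameters.json",
    }
    src = Path(panel_path) if panel_path else None
    if src is None:
        from .panel import default_panel_path
        src = default_panel_path()
    paths["panel"].write_bytes(src.read_bytes())
    dosages.to_tsv(paths["genotypes"])
    save_subjects(cohort, paths["subjects"])
    _write_json(truth, paths["truth"])
    return paths


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis and write the results bundle.

    Returns a summary dict (also written as ``summary.json``).
    """
    for label, p in (("genotypes", config.genotypes_path),
                     ("subjects", config.subjects_path)):
        if not Path(p).exists():
            raise ValidationError(f"{label} file not found: {p}")
    if config.panel_path is not None and not Path(config.panel_path).exists():
        raise ValidationError(f"panel file not found: {config.panel_path}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    panel = load_panel(config.panel_path)
    cohort = load_subjects(config.subjects_path)
    dosages = load_genotypes(config.genotypes_path, panel, cohort)
    mark_x_linked(dosages, panel)

    # cohort description (Table-2 style)
    _write_tsv(describe_cohort(cohort, seed=config.seed),
               out / "cohort_summary.tsv")

    # HWE per group
    threshold = bonferroni_threshold(config.alpha, len(panel))
    hwe_results = hwe_scan(dosages, cohort, panel, alpha=threshold)
    _write_tsv(pd.DataFrame([vars(r) for r in hwe_results]), out / "hwe.tsv")

    # association: crude + adjusted, all requested models
    assoc_frames = []
    for adjustment in ("crude", "adjusted"):
        res = run_association(dosages, cohort, panel,
                              models=config.models, adjustment=adjustment)
        assoc_frames.append(results_frame(res))
    assoc = pd.concat(assoc_frames, ignore_index=True)
    omnibus = codominant_omnibus_p(dosages, cohort, panel)
    assoc["omnibus_p"] = assoc["rsid"].map(omnibus)
    assoc["significant_bonferroni"] = assoc["omnibus_p"] < threshold
    _write_tsv(assoc, out / "association.tsv")

    # genetic risk scores
    scores = grs_table(dosages, panel, cohort, weight_mode=config.weight_mode)
    _write_tsv(scores, out / "grs_scores.tsv", index=True)
    grs_summary: dict = {}
    for score_col in ("c_grs", "w_grs"):
        s = scores[score_col]
        entry = {"comparison": compare_grs(s, cohort)}
        for adjustment in ("crude", "adjusted"):
            try:
                entry[adjustment] = grs_association(s, cohort, adjustment)
            except Exception as exc:  # per-stage failures are reported
                entry[adjustment] = {"error": str(exc)}
        grs_summary[score_col] = entry
    _write_json(grs_summary, out / "grs_summary.json")

    # correspondence analysis on cases
    indicator = build_indicator_table(
        cohort, variables=config.ca_variables, dosages=dosages,
        carrier_snps=[s for s in config.carrier_snps
                      if s in dosages.df.columns],
        cases_only=True)
    keep_rows = indicator.sum(axis=1) > 0
    keep_cols = indicator.sum(axis=0) > 0
    ca_res = ca_fit(indicator.loc[keep_rows, keep_cols])
    coords = pd.concat([
        ca_res.col_coords.assign(point_type="column"),
        ca_res.row_coords.assign(point_type="row"),
    ])
    coords.index.name = "label"
    _write_tsv(coords, out / "ca_coordinates.tsv", index=True)
    _write_json({
        "total_inertia": ca_res.total_inertia,
        "inertia_pct": [float(v) for v in ca_res.inertia_pct],
        "singular_values": [float(v) for v in ca_res.singular_values],
    }, out / "ca_inertia.json")

    # manifest
    inputs = {"genotypes": Path(config.genotypes_path),
              "subjects": Path(config.subjects_path)}
    if config.panel_path is not None:
        inputs["panel"] = Path(config.panel_path)
    manifest = {
        "package": "snpcc",
        "version": __version__,
        "seed": config.seed,
        "alpha": config.alpha,
        "bonferroni_threshold": threshold,
        "n_snps": len(panel),
        "n_pairs": cohort.n_pairs,
        "weight_mode": config.weight_mode,
        "input_sha256": {k: _sha256(p) for k, p in sorted(inputs.items())},
    }
    _write_json(manifest, out / "manifest.json")

    summary = {
        "n_snps": len(panel),
        "n_pairs": cohort.n_pairs,
        "bonferroni_threshold": threshold,
        "n_hwe_deviations": int(sum(r.deviates for r in hwe_results)),
        "n_significant_snps": int(
            sum(1 for rsid, p in omnibus.items()
                if not np.isnan(p) and p < threshold)),
        "outputs": ["association.tsv", "ca_coordinates.tsv",
                    "ca_inertia.json", "cohort_summary.tsv",
                    "grs_scores.tsv", "grs_summary.json", "hwe.tsv",
                    "manifest.json", "summary.json"],
    }
    _write_json(summary, out / "summary.json")
    return summary
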