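"""End-to-end wiring: simulate -> analyze -> stats -> report.

Each stage reads/writes plain-text files so the pipeline can be driven
from the command line or from Python:

* ``run_simulate`` writes the per-animal cohort CSV and one per-beat CSV
  per animal (columns beat_time_s, pi_ms, sap_mmHg, dap_mmHg);
* ``run_analyze`` turns per-beat files (or in-memory beat series) into one
  autonomic-profile row per animal, logging per-animal QC (fragment count,
  AR orders) and skipping animals whose recording yields no stationary
  fragment;
* ``run_stats`` computes the two-way ANOVA per outcome;
* ``run_report`` lays out the two group tables (metabolic and
  cardiovascular) with mean +- dispersion columns and the three p-value
  columns, plus a derived-quantity appendix in which every number carries
  the formula that produced it.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .indices import PROFILE_FIELDS, build_profile, profile_row
from .spectral import NoStationaryFragmentError, ShortInputError
from .stats import (SummaryCell, fold_change, log_transform_outcome,
                    percent_difference, pooled_summary, two_way_anova)
from .synthetic import (AnimalRecord, CohortDesign, apply_inclusion,
                        beats_frame, beats_from_frame, cohort_frame,
                        default_design, default_design_dict, load_design,
                        simulate_cohort)

logger = logging.getLogger("ratvar")

#: outcome columns of the metabolic table, with display labels
METABOLIC_ROWS = {
    "weight_initial_g": "Initial weight (g)",
    "weight_day45_g": "Weight 45 days after STZ injection (g)",
    "glycemia_initial_mg_dl": "Initial plasma glucose (mg/dl)",
    "glycemia_day45_mg_dl": "Plasma glucose 45 days after STZ injection (mg/dl)",
    "diuresis_ml_24h": "Diuresis (mL/24 h)",
    "urinary_glucose_mg_24h": "24-h urinary glucose (mg/24 h)",
    "urinary_sodium_meq_24h": "24-h urinary sodium (mEq/24 h)",
    "urinary_albumin_mg_24h": "24-h urinary albumin (mg)",
    "densitometry_au": "Renal cortical densitometry (AU)",
}

#: profile columns of the cardiovascular table, with display labels
CARDIOVASCULAR_ROWS = {
    "hr_bpm": "Heart rate (bpm)",
    "sap_mmhg": "Systolic AP (mmHg)",
    "dap_mmhg": "Diastolic AP (mmHg)",
    "map_mmhg": "Mean AP (mmHg)",
    "hrv_ms2": "HRV (ms^2)",
    "hrv_lf_peak_hz": "LF peak (Hz)",
    "hrv_lf_ms2": "LF absolute (ms^2)",
    "hrv_lf_nu": "LF nu",
    "hrv_hf_peak_hz": "HF (Hz)",
    "hrv_hf_ms2": "HF absolute (ms^2)",
    "hrv_hf_nu": "HF nu",
    "lf_hf": "LF/HF index",
    "sapv_mmhg2": "SAPV (mmHg^2)",
    "sapv_vlf_mmhg2": "VLF (mmHg^2)",
    "sapv_lf_peak_hz": "LF (Hz)",
    "sapv_lf_mmhg2": "LF absolute (mmHg^2)",
    "sapv_hf_peak_hz": "HF peak (Hz)",
    "sapv_hf_mmhg2": "HF absolute (mmHg^2)",
    "alpha_lf": "alpha_LF index (ms/mmHg)",
}

GROUP_ORDER = ("SHR", "RD-SHR", "STZ-SHR", "RD-STZ-SHR")


def _resolve_design(config: PipelineConfig) -> CohortDesign:
    if config.design_path is not None:
        design = load_design(config.design_path)
    else:
        design = default_design()
    design.seed = config.seed
    if config.albumin_interval != "iqr":
        for g in design.groups:
            if g.albumin is not None:
                g.albumin = type(g.albumin)(
                    median=g.albumin.median, lower=g.albumin.lower,
                    upper=g.albumin.upper,
                    interpretation=config.albumin_interval)
    return design


def run_simulate(config: PipelineConfig, outdir: str | Path,
                 include_beats: bool = True) -> list[AnimalRecord]:
    """Simulate a cohort and write cohort.csv plus beats/<animal>.csv."""
    outdir = Path(outdir)
    if not outdir.parent.exists():
        raise FileNotFoundError(f"output directory {outdir.parent} does not exist")
    outdir.mkdir(exist_ok=True)
    design = _resolve_design(config)
    records = apply_inclusion(
        simulate_cohort(design, include_beats=include_beats))
    cohort_frame(records).to_csv(outdir / "cohort.csv", index=False)
    if include_beats:
        beats_dir = outdir / "beats"
        beats_dir.mkdir(exist_ok=True)
        for rec in records:
            if rec.beats is not None:
                beats_frame(rec.beats).to_csv(beats_dir / f"{rec.id}.csv",
                                              index=False)
    logger.info("simulated %d animals in %d groups", len(records),
                len(design.groups))
    return records


def analyze_records(records: list[AnimalRecord],
                    config: PipelineConfig) -> pd.DataFrame:
    """Per-animal autonomic profiles for in-memory records with beats."""
    rows = []
    failures = 0
    for rec in records:
        if rec.beats is None:
            continue
        try:
            profile = build_profile(
                rec.beats, target_len=config.fragment_len,
                k_mean=config.k_mean, k_var=config.k_var,
                order_range=config.order_range, bands=config.bands)
        except (NoStationaryFragmentError, ShortInputError) as exc:
            logger.warning("animal %s skipped: %s", rec.id, exc)
            failures += 1
            continue
        logger.info("animal %s: %d fragment(s), AR orders %s", rec.id,
                    profile.n_fragments, profile.ar_orders)
        row = {"animal_id": rec.id, "group": rec.group,
               "diabetes": rec.diabetes, "denervation": rec.denervation,
               "n_fragments": profile.n_fragments}
        row.update(profile_row(profile))
        rows.append(row)
    if not rows:
        raise ValueError("no animal could be analyzed")
    if failures:
        logger.warning("%d animal(s) skipped during analysis", failures)
    return pd.DataFrame(rows)


def run_analyze(config: PipelineConfig, cohort_csv: str | Path,
                beats_dir: str | Path, out_tsv: str | Path | None = None,
                ) -> pd.DataFrame:
    """Analyze per-beat CSV files into a per-animal profile table."""
    cohort = pd.read_csv(cohort_csv)
    if len(cohort) == 0:
        raise ValueError("empty cohort input")
    beats_dir = Path(beats_dir)
    records = []
    for _, row in cohort.iterrows():
        path = beats_dir / f"{row['animal_id']}.csv"
        if not path.exists():
            logger.warning("no beat file for %s", row["animal_id"])
            continue
        beats = beats_from_frame(pd.read_csv(path))
        records.append(AnimalRecord(
            id=row["animal_id"], group=row["group"],
            diabetes=bool(row["diabetes"]),
            denervation=bool(row["denervation"]), outcomes={}, beats=beats))
    if not records:
        raise ValueError("no beat files found for the cohort")
    profiles = analyze_records(records, config)
    if out_tsv is not None:
        profiles.to_csv(out_tsv, sep="\t", index=False)
    return profiles


def run_stats(records: pd.DataFrame, outcomes: list[str],
              config: PipelineConfig) -> pd.DataFrame:
    """Two-way ANOVA per outcome; albumin is log-transformed first."""
    rows = []
    for outcome in outcomes:
        data = records
        if outcome == "urinary_albumin_mg_24h":
            data = log_transform_outcome(records, outcome)
        table = two_way_anova(data, outcome)
        rows.append({"outcome": outcome,
                     "p_denervation": table.p("denervation"),
                     "p_diabetes": table.p("diabetes"),
                     "p_interaction": table.p("interaction")})
    return pd.DataFrame(rows).set_index("outcome")


def _format_cell(values: pd.Series, dispersion: str) -> str:
    mean = values.mean(skipna=True)
    sd = values.std(skipna=True, ddof=1)
    if dispersion == "sem":
        sd = sd / math.sqrt(values.notna().sum())
    if np.isnan(mean):
        return "NA"
    return f"{mean:.2f} ± {sd:.2f}"


def _group_table(records: pd.DataFrame, rows: dict[str, str],
                 config: PipelineConfig) -> pd.DataFrame:
    groups = [g for g in GROUP_ORDER if g in set(records["group"])]
    missing = set(GROUP_ORDER) - set(groups)
    if missing:
        raise ValueError(f"cohort is missing group(s): {sorted(missing)}")
    anova = run_stats(records, [c for c in rows if c in records.columns],
                      config)
    out_rows = []
    for col, label in rows.items():
        if col not in records.columns:
            continue
        row = {"Variable": label}
        for g in groups:
            sub = records.loc[records["group"] == g, col]
            if col == "urinary_albumin_mg_24h":
                q1, med, q3 = sub.quantile([0.25, 0.5, 0.75])
                row[g] = f"{med:.0f} [{q1:.0f}-{q3:.0f}]"
            else:
                row[g] = _format_cell(sub, config.dispersion)
        row["P (Denervation)"] = f"{anova.loc[col, 'p_denervation']:.3f}"
        row["P (Diabetes)"] = f"{anova.loc[col, 'p_diabetes']:.3f}"
        row["P (Interaction)"] = f"{anova.loc[col, 'p_interaction']:.3f}"
        out_rows.append(row)
    return pd.DataFrame(out_rows)


def derived_quantities(reference: dict | None = None) -> pd.DataFrame:
    """Derived-quantity appendix from per-group summary rows.

    Uses the shipped reference summaries unless a dict of the same shape
    is given.  Every row records the formula applied, so each number in
    the appendix is traceable.
    """
    if reference is None:
        reference = default_design_dict()["reference_summaries"]

    def cells(outcome):
        return {g: SummaryCell(**reference[outcome][g])
                for g in reference[outcome]}

    w = cells("weight_initial_g")
    grand_mean, pooled_sd = pooled_summary([w[g] for g in GROUP_ORDER])
    hr = cells("hr_bpm")
    sapv = cells("sapv_mmhg2")
    rows = [
        {"quantity": "baseline weight grand mean (g)",
         "value": grand_mean,
         "formula": "sum(n_i * mean_i) / sum(n_i) over the 4 groups"},
        {"quantity": "baseline weight pooled SD (g)",
         "value": pooled_sd,
         "formula": "sqrt(sum((n_i - 1) sd_i^2) / sum(n_i - 1))"},
        {"quantity": "HR percent difference RD-SHR vs SHR (%)",
         "value": percent_difference(hr["SHR"].mean, hr["RD-SHR"].mean),
         "formula": "100 * (mean_RD-SHR - mean_SHR) / mean_SHR"},
        {"quantity": "HR percent difference STZ-SHR vs SHR (%)",
         "value": percent_difference(hr["SHR"].mean, hr["STZ-SHR"].mean),
         "formula": "100 * (mean_STZ-SHR - mean_SHR) / mean_SHR"},
        {"quantity": "SAPV fold reduction by diabetes (x)",
         "value": fold_change(sapv["SHR"].mean, sapv["STZ-SHR"].mean,
                              direction="reduction"),
         "formula": "mean_SHR / mean_STZ-SHR"},
    ]
    return pd.DataFrame(rows)


def run_report(config: PipelineConfig, cohort: pd.DataFrame,
               profiles: pd.DataFrame, outdir: str | Path,
               sep: str = "\t") -> dict[str, pd.DataFrame]:
    """Write the metabolic table, cardiovascular table and appendix."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    metabolic = _group_table(cohort, METABOLIC_ROWS, config)
    cardiovascular = _group_table(profiles, CARDIOVASCULAR_ROWS, config)
    derived = derived_quantities()
    ext = "tsv" if sep == "\t" else "csv"
    metabolic.to_csv(outdir / f"metabolic_table.{ext}", sep=sep, index=False)
    cardiovascular.to_csv(outdir / f"cardiovascular_table.{ext}", sep=sep,
                          index=False)
    derived.to_csv(outdir / f"derived_quantities.{ext}", sep=sep, index=False)
    return {"metabolic": metabolic, "cardiovascular": cardiovascular,
            "derived": derived}
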