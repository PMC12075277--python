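"""Pipeline orchestration: simulate -> fit -> compose -> correlate -> report.

Each stage is a plain function over files in ``config.out_dir`` so stages
can be rerun independently from the CLI or the analysis drivers; a stage
failure raises with the stage name attached.  A manifest with content
hashes is written at the end; a rerun with identical config and seed is
bit-identical.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from .composition import GravimetrySample, porosity, water_content
from .config import PipelineConfig
from .fitting import fit_biphasic
from .stats import (
    BONES,
    VOLAR_REGIONS,
    bonferroni_adjust,
    ligament_cartilage_correlation,
    measure_names,
    pairwise_group_comparisons,
    summarize,
)
from .synthetic import default_spec, generate_cohort

__all__ = ["simulate_stage", "fit_stage", "compose_stage", "correlate_stage",
           "report_stage", "run_pipeline"]

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raised with stage name
                raise StageError(f"stage '{name}' failed: {exc}") from exc
        inner.__name__ = fn.__name__
        inner.__doc__ = fn.__doc__
        return inner
    return wrap


@_stage("simulate")
def simulate_stage(config: PipelineConfig) -> list[Path]:
    """Generate the synthetic cohort and write curves + tables."""
    out = Path(config.out_dir)
    (out / "curves").mkdir(parents=True, exist_ok=True)
    spec = default_spec(seed=config.seed,
                        n_donors_per_group=config.n_donors_per_group,
                        noise_sd_um=config.noise_sd_um,
                        protocol=config.protocol,
                        rho_ratio=config.rho_ratio)
    cohort = generate_cohort(spec)
    written = []
    thickness = {(r.donor_id, r.bone, r.region): r.thickness_mm
                 for r in cohort.records}
    for (donor, bone, region), curve in cohort.curves.items():
        stem = out / "curves" / f"{donor}_{bone}_{region}"
        cio.write_curve(stem, curve, thickness[(donor, bone, region)],
                        meta={"donor": donor, "bone": bone, "region": region,
                              "group": next(r.group for r in cohort.records
                                            if r.donor_id == donor)})
        written += [stem.with_suffix(".csv"), stem.with_suffix(".json")]
    cio.write_gravimetry_csv(out / "gravimetry.csv", cohort.records)
    cio.write_ligament_csv(out / "ligaments.csv", cohort.ligaments)
    cohort.truth.to_csv(out / "truth.csv", index=False, float_format="%.10g")
    written += [out / "gravimetry.csv", out / "ligaments.csv", out / "truth.csv"]
    log.info("simulate: %d curves, %d records", len(cohort.curves),
             len(cohort.records))
    return written


@_stage("fit")
def fit_stage(config: PipelineConfig) -> list[Path]:
    """Fit every curve in out_dir/curves; write fits.jsonl."""
    out = Path(config.out_dir)
    curve_files = sorted((out / "curves").glob("*.csv"))
    if not curve_files:
        raise FileNotFoundError(f"no curve CSVs under {out / 'curves'}")
    records = []
    n_dropped = 0
    from .stats import RegionalRecord  # local to avoid cycle at import time
    for csv_path in curve_files:
        curve, thickness_mm, meta = cio.read_curve(csv_path.with_suffix(""))
        fit = fit_biphasic(curve, thickness_mm, config.fit)
        if not fit.permeability_valid:
            n_dropped += 1
        records.append(RegionalRecord(
            donor_id=meta["donor"], group=meta["group"], bone=meta["bone"],
            region=meta["region"], thickness_mm=thickness_mm, fit=fit))
    cio.write_fits_jsonl(out / "fits.jsonl", records)
    log.info("fit: %d curves fitted, %d permeability records dropped by gates",
             len(records), n_dropped)
    return [out / "fits.jsonl"]


@_stage("compose")
def compose_stage(config: PipelineConfig) -> list[Path]:
    """Append porosity and water-content columns to the gravimetry table."""
    out = Path(config.out_dir)
    frame = cio.read_gravimetry_csv(out / "gravimetry.csv", config.rho_ratio)
    phis, wcs, flags = [], [], []
    for row in frame.itertuples():
        sample = GravimetrySample(row.w_wet_mg, row.w_pbs_mg, row.w_dry_mg,
                                  rho_ratio=config.rho_ratio)
        phis.append(porosity(sample))
        wcs.append(water_content(sample))
        flags.append(sample.low_mass_flag)
    frame["porosity"] = phis
    frame["water_content_pct"] = wcs
    frame["low_mass_flag"] = flags
    frame.to_csv(out / "composition.csv", index=False, float_format="%.10g")
    return [out / "composition.csv"]


def _load_fit_records_with_composition(config: PipelineConfig):
    out = Path(config.out_dir)
    records = cio.read_fits_jsonl(out / "fits.jsonl")
    comp_path = out / "composition.csv"
    if comp_path.exists():
        comp = pd.read_csv(comp_path).set_index(["donor", "bone", "region"])
        enriched = []
        for rec in records:
            key = (rec.donor_id, rec.bone, rec.region)
            if key in comp.index:
                row = comp.loc[key]
                rec = dataclasses.replace(rec, porosity=float(row["porosity"]),
                                          water_content=float(row["water_content_pct"]))
            enriched.append(rec)
        records = enriched
    return records


@_stage("correlate")
def correlate_stage(config: PipelineConfig) -> list[Path]:
    """VLC stiffness vs volar-half cartilage properties, per bone, advanced group.

    Four tests (2 bones x {modulus, permeability}) with Bonferroni adjustment
    over the family.
    """
    out = Path(config.out_dir)
    records = _load_fit_records_with_composition(config)
    ligaments = cio.read_ligament_csv(out / "ligaments.csv")
    rows = []
    for bone in BONES:
        for measure in ("eq_modulus_mpa", "permeability_m4_ns"):
            try:
                res = ligament_cartilage_correlation(
                    records, ligaments, group="advanced_oa", bone=bone,
                    measure=measure, region_set=VOLAR_REGIONS)
                rows.append({"group": "advanced_oa", "bone": bone,
                             "region_set": "volar", "measure": measure,
                             "r": res.r, "r_squared": res.r_squared,
                             "p_value": res.p_value, "n": res.n, "note": ""})
            except ValueError as exc:
                rows.append({"group": "advanced_oa", "bone": bone,
                             "region_set": "volar", "measure": measure,
                             "r": np.nan, "r_squared": np.nan,
                             "p_value": np.nan, "n": 0, "note": str(exc)})
    frame = pd.DataFrame(rows)
    ok = frame["p_value"].notna()
    frame.loc[ok, "p_bonferroni"] = bonferroni_adjust(
        frame.loc[ok, "p_value"].to_numpy(), m=len(frame))
    frame.to_csv(out / "correlations.csv", index=False, float_format="%.6g")
    return [out / "correlations.csv"]


@_stage("report")
def report_stage(config: PipelineConfig) -> list[Path]:
    """Mean +/- SEM cell summaries and pairwise group comparisons per measure."""
    out = Path(config.out_dir)
    records = _load_fit_records_with_composition(config)
    written = []
    summaries, comparisons = [], []
    for measure in measure_names():
        try:
            summaries.append(summarize(records, measure).assign(measure=measure))
            comparisons.append(pairwise_group_comparisons(records, measure))
        except ValueError as exc:
            log.warning("report: skipping %s (%s)", measure, exc)
    pd.concat(summaries, ignore_index=True).to_csv(
        out / "summary.csv", index=False, float_format="%.6g")
    pd.concat(comparisons, ignore_index=True).to_csv(
        out / "group_comparisons.csv", index=False, float_format="%.6g")
    written += [out / "summary.csv", out / "group_comparisons.csv"]
    return written


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all five stages; returns the manifest dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: list[Path] = []
    files += simulate_stage(config)
    files += fit_stage(config)
    files += compose_stage(config)
    files += correlate_stage(config)
    files += report_stage(config)
    manifest = cio.write_manifest(out / "manifest.json", files, base=out)
    log.info("pipeline complete: %d artifacts under %s", manifest["n_files"], out)
    return manifest
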