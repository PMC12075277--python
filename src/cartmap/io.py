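"""Readers and writers for the pipeline's plain-text interchange formats.

One CSV per creep curve (columns ``time_s,deformation_um``) with a JSON
sidecar holding the protocol constants and the sample thickness; gravimetry
and ligament tables as CSV; fit results as JSON lines; a manifest with
SHA-256 content hashes for bit-identical rerun checks.  Every writer's
output round-trips through its reader.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .biphasic import CreepCurve, IndentationProtocol
from .composition import GravimetrySample
from .fitting import BiphasicFit
from .stats import LigamentRecord, RegionalRecord

__all__ = [
    "write_curve", "read_curve", "write_gravimetry_csv", "read_gravimetry_csv",
    "write_ligament_csv", "read_ligament_csv", "write_fits_jsonl",
    "read_fits_jsonl", "write_manifest", "sha256_file",
]

GRAVIMETRY_COLUMNS = ["donor", "group", "bone", "region",
                      "w_wet_mg", "w_pbs_mg", "w_dry_mg"]
LIGAMENT_COLUMNS = ["donor", "group", "vlc_stiffness_n_per_mm"]
_FLOAT_FMT = "%.10g"


def write_curve(path: Path, curve: CreepCurve, thickness_mm: float,
                meta: dict | None = None) -> None:
    """Write ``<path>.csv`` plus ``<path>.json`` sidecar."""
    path = Path(path)
    frame = pd.DataFrame({"time_s": curve.time_s,
                          "deformation_um": curve.deformation_um})
    frame.to_csv(path.with_suffix(".csv"), index=False, float_format=_FLOAT_FMT)
    sidecar = {
        "protocol": dataclasses.asdict(curve.protocol),
        "thickness_mm": thickness_mm,
    }
    if meta:
        sidecar.update(meta)
    path.with_suffix(".json").write_text(
        json.dumps(sidecar, indent=1, sort_keys=True) + "\n")


def read_curve(path: Path) -> tuple[CreepCurve, float, dict]:
    """Read a curve CSV + sidecar; returns (curve, thickness_mm, sidecar)."""
    path = Path(path)
    frame = pd.read_csv(path.with_suffix(".csv"))
    if list(frame.columns) != ["time_s", "deformation_um"]:
        raise ValueError(f"{path}: expected header 'time_s,deformation_um'")
    sidecar = json.loads(path.with_suffix(".json").read_text())
    protocol = IndentationProtocol(**sidecar["protocol"])
    curve = CreepCurve(time_s=frame["time_s"].to_numpy(),
                       deformation_um=frame["deformation_um"].to_numpy(),
                       protocol=protocol)
    return curve, float(sidecar["thickness_mm"]), sidecar


def write_gravimetry_csv(path: Path, records: Iterable[RegionalRecord]) -> None:
    rows = []
    for rec in records:
        if rec.gravimetry is None:
            continue
        g = rec.gravimetry
        rows.append([rec.donor_id, rec.group, rec.bone, rec.region,
                     g.w_wet_mg, g.w_pbs_mg, g.w_dry_mg])
    pd.DataFrame(rows, columns=GRAVIMETRY_COLUMNS).to_csv(
        path, index=False, float_format=_FLOAT_FMT)


def read_gravimetry_csv(path: Path, rho_ratio: float) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = set(GRAVIMETRY_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    frame["rho_ratio"] = rho_ratio
    return frame


def write_ligament_csv(path: Path, ligaments: Iterable[LigamentRecord]) -> None:
    rows = [[l.donor_id, l.group, l.vlc_stiffness_n_per_mm] for l in ligaments]
    pd.DataFrame(rows, columns=LIGAMENT_COLUMNS).to_csv(
        path, index=False, float_format=_FLOAT_FMT)


def read_ligament_csv(path: Path) -> list[LigamentRecord]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"ligament stiffness table not found: {path}")
    frame = pd.read_csv(path)
    missing = set(LIGAMENT_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [LigamentRecord(str(r.donor), str(r.group),
                           float(r.vlc_stiffness_n_per_mm))
            for r in frame.itertuples()]


def write_fits_jsonl(path: Path, records: Iterable[RegionalRecord]) -> None:
    """One JSON record per region with all fit fields (converged or not)."""
    with open(path, "w") as fh:
        for rec in records:
            if rec.fit is None:
                continue
            row = {"donor": rec.donor_id, "group": rec.group, "bone": rec.bone,
                   "region": rec.region, "thickness_mm": rec.thickness_mm}
            row.update(dataclasses.asdict(rec.fit))
            fh.write(json.dumps(row, sort_keys=True, allow_nan=True) + "\n")


def read_fits_jsonl(path: Path) -> list[RegionalRecord]:
    records = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        row = json.loads(line)
        fit_fields = {f.name for f in dataclasses.fields(BiphasicFit)}
        fit = BiphasicFit(**{k: row[k] for k in fit_fields})
        records.append(RegionalRecord(
            donor_id=row["donor"], group=row["group"], bone=row["bone"],
            region=row["region"], thickness_mm=row["thickness_mm"], fit=fit))
    return records


def sha256_file(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(path: Path, files: Iterable[Path], base: Path) -> dict:
    """Manifest of every artifact written, with content hashes."""
    entries = {str(Path(f).relative_to(base)): sha256_file(f)
               for f in sorted(files, key=str)}
    manifest = {"n_files": len(entries), "files": entries}
    Path(path).write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return manifest
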