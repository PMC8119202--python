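"""CSV/YAML readers and writers for the pipeline's exchange formats.

Plate export CSV: columns Measurement (1-based), Well, Group, Time_min and
one column per channel (OCR, ECAR). The injection schedule and per-well
protein content travel in a YAML sidecar:

    events:
      - {name: oligomycin, compound: oligomycin, after_measurement: 3}
    protein_ug:
      control_w1: 11.8

Isotopolog CSV: metabolite, n_carbons, mass_shift (0-based), intensity,
sample_id, protein_ug. Morphometry vertex CSV: mito_id, image_id,
tracing_index, vertex_index, x_nm, y_nm with a YAML sidecar mapping
image_id -> field_area_um2.
"""
from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .flux import FluxTrace, InjectionSchedule, PlateRecord
from .morphometry import OutlinePolygon
from .sita import IsotopologSpectrum

_PLATE_COLUMNS = ["Measurement", "Well", "Group", "Time_min"]


def write_plate(plate: PlateRecord, csv_path: str | Path, config_path: str | Path) -> None:
    """Write a plate to the export CSV + YAML sidecar dialect."""
    channels = sorted({t.channel for t in plate.traces})
    frames = {}
    for t in plate.traces:
        key = t.well_id
        df = frames.setdefault(
            key,
            pd.DataFrame(
                {
                    "Measurement": t.indices,
                    "Well": t.well_id,
                    "Group": t.group,
                    "Time_min": t.times,
                }
            ),
        )
        df[t.channel] = t.values
    table = pd.concat(frames.values(), ignore_index=True)
    table = table[_PLATE_COLUMNS + [c for c in channels if c in table.columns]]
    table.to_csv(csv_path, index=False)

    config = {
        "events": [
            {"name": e.name, "compound": e.compound, "after_measurement": e.after_measurement}
            for e in plate.schedule.events
        ],
        "protein_ug": {k: float(v) for k, v in plate.protein_ug.items()},
        "meta": plate.meta,
    }
    Path(config_path).write_text(yaml.safe_dump(config, sort_keys=False))


def read_plate(csv_path: str | Path, config_path: str | Path) -> PlateRecord:
    """Read a plate export CSV and its YAML sidecar."""
    table = pd.read_csv(csv_path)
    missing = set(_PLATE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"plate CSV missing columns: {sorted(missing)}")
    config = yaml.safe_load(Path(config_path).read_text())
    schedule = InjectionSchedule.from_events(config.get("events", []))
    protein = {str(k): float(v) for k, v in config.get("protein_ug", {}).items()}

    channels = [c for c in table.columns if c not in _PLATE_COLUMNS]
    traces = []
    for (well, group), sub in table.groupby(["Well", "Group"], sort=False):
        sub = sub.sort_values("Measurement")
        for ch in channels:
            if sub[ch].isna().all():
                continue
            traces.append(
                FluxTrace(
                    well_id=str(well),
                    group=str(group),
                    channel=ch,
                    indices=sub["Measurement"].to_numpy(dtype=int),
                    times=sub["Time_min"].to_numpy(dtype=float),
                    values=sub[ch].to_numpy(dtype=float),
                )
            )
    return PlateRecord(traces, protein, schedule, dict(config.get("meta", {}) or {}))


def write_mids_csv(
    spectra: Mapping[str, Mapping[str, IsotopologSpectrum]] | list[IsotopologSpectrum],
    path: str | Path,
) -> None:
    """Write raw isotopolog spectra (one row per mass shift)."""
    rows = []
    if isinstance(spectra, list):
        items = [("s1", s) for s in spectra]
    else:
        items = [(sid, s) for sid, by_met in spectra.items() for s in by_met.values()]
    for sample_id, s in items:
        for shift, intensity in enumerate(s.intensities):
            rows.append(
                {
                    "metabolite": s.metabolite,
                    "n_carbons": s.n_carbons,
                    "mass_shift": shift,
                    "intensity": float(intensity),
                    "sample_id": sample_id,
                    "protein_ug": s.protein_ug,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_mids_csv(path: str | Path) -> dict[str, dict[str, IsotopologSpectrum]]:
    """sample_id -> metabolite -> IsotopologSpectrum."""
    table = pd.read_csv(path)
    required = {"metabolite", "n_carbons", "mass_shift", "intensity", "sample_id"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"isotopolog CSV missing columns: {sorted(missing)}")
    out: dict[str, dict[str, IsotopologSpectrum]] = {}
    for (sample, met), sub in table.groupby(["sample_id", "metabolite"], sort=False):
        n = int(sub["n_carbons"].iloc[0])
        intensities = np.zeros(n + 1)
        for _, row in sub.iterrows():
            intensities[int(row["mass_shift"])] = float(row["intensity"])
        protein = float(sub["protein_ug"].iloc[0]) if "protein_ug" in sub.columns else 1.0
        out.setdefault(str(sample), {})[str(met)] = IsotopologSpectrum(
            str(met), n, intensities, protein
        )
    return out


def write_outlines(outlines: list[OutlinePolygon], csv_path: str | Path, sidecar_path: str | Path) -> None:
    rows = []
    fields: dict[str, float] = {}
    for o in outlines:
        fields[o.image_id] = o.field_area_um2
        for ti, tracing in enumerate(o.tracings, start=1):
            for vi, (x, y) in enumerate(tracing, start=1):
                rows.append(
                    {
                        "mito_id": o.mito_id,
                        "image_id": o.image_id,
                        "tracing_index": ti,
                        "vertex_index": vi,
                        "x_nm": float(x),
                        "y_nm": float(y),
                    }
                )
    pd.DataFrame(rows).to_csv(csv_path, index=False)
    Path(sidecar_path).write_text(yaml.safe_dump({"field_area_um2": fields}, sort_keys=False))


def read_outlines(csv_path: str | Path, sidecar_path: str | Path) -> list[OutlinePolygon]:
    table = pd.read_csv(csv_path)
    sidecar = yaml.safe_load(Path(sidecar_path).read_text())
    fields = {str(k): float(v) for k, v in sidecar["field_area_um2"].items()}
    outlines = []
    for (mito, image), sub in table.groupby(["mito_id", "image_id"], sort=False):
        tracings = []
        for _, tsub in sub.groupby("tracing_index", sort=True):
            tsub = tsub.sort_values("vertex_index")
            tracings.append(tsub[["x_nm", "y_nm"]].to_numpy(dtype=float))
        outlines.append(
            OutlinePolygon(str(mito), str(image), tracings, fields[str(image)])
        )
    return outlines
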