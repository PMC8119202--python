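"""Assemble pipeline outputs into one report bundle.

A bundle is a directory of tidy CSV tables plus ``manifest.json``
recording the package version, the seed, the analysis conventions in force
(extremal-measurement convention per phase, PER conversion constants,
natural-abundance constants, morphology cutoffs, statistics defaults) and
the table inventory, so a bundle is reproducible byte for byte from the
same inputs and seed.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import __version__
from .flux import PerConversion
from .morphometry import DEFAULT_THRESHOLDS
from .sita import P13_NATURAL, TRACER_PURITY
from .assay_stats import ALPHA


def default_conventions() -> dict:
    """The configurable analysis conventions and their active defaults."""
    per = PerConversion()
    return {
        "injection_measurement_convention": {
            "inhibitor_phases": "minimum within phase",
            "stimulation_phases": "maximum within phase",
            "before_injection": "last measurement of preceding phase",
        },
        "per_conversion": {
            "buffer_factor_mmol_per_l_ph": per.buffer_factor,
            "chamber_volume_ul": per.chamber_volume_ul,
            "volume_scaling": per.volume_scaling,
            "ccf": per.ccf,
        },
        "natural_abundance": {
            "p13_natural": P13_NATURAL,
            "tracer_purity": TRACER_PURITY,
            "solver": "nonnegative least squares, renormalized",
        },
        "morphology_thresholds": {
            "frag_cut": DEFAULT_THRESHOLDS[0],
            "long_cut": DEFAULT_THRESHOLDS[1],
            "diameter": "Feret (max pairwise vertex distance)",
        },
        "statistics": {
            "two_group": "unpaired two-tailed t (pooled variance default)",
            "multi_vs_control": "one-way ANOVA + Dunnett",
            "alpha": ALPHA,
            "replicates": "technical wells averaged to one biological value",
            "dispersion": "mean±SD technical, mean±SEM biological",
        },
    }


def build_report(
    outdir: str | Path,
    tables: Mapping[str, pd.DataFrame] | None = None,
    inputs: Mapping[str, str] | None = None,
    seed: int | None = None,
    extra_conventions: Mapping | None = None,
) -> Path:
    """Write all tables and a run manifest under ``outdir``; returns the path.

    With no tables, a manifest-only bundle is produced. The same tables and
    seed always yield byte-identical output.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tables = dict(tables or {})
    for name, df in tables.items():
        df.to_csv(outdir / f"{name}.csv", index=False)

    conventions = default_conventions()
    if extra_conventions:
        conventions.update(extra_conventions)
    manifest = {
        "package": "metaboflux",
        "version": __version__,
        "seed": seed,
        "inputs": dict(inputs or {}),
        "tables": sorted(tables),
        "conventions": conventions,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return outdir
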