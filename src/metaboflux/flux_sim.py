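"""Seeded synthetic plate generator for the flux-analysis pipeline.

Each well's trace is piecewise constant across injection phases:

    value(t) = baseline * phase_multiplier * (1 + drift_per_min * t) + N(0, noise_sd)

clipped at zero (rates cannot be negative), with per-well protein content
drawn once per well. Presets encode the scenarios the analysis pipeline is
exercised against: an acute LPS injection raising ECAR 1.5-fold while
lowering OCR, a poly(I:C)-style rise in oxidative metabolism, IL-33
treatment / knockdown / overexpression scenarios with shifted FCCP-phase
(maximal respiration) and glucose-phase (glycolysis) responses. Magnitudes
other than the 1.5-fold acute ECAR response are directional choices, not
published numbers.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .flux import (
    BASELINE_PHASE,
    FluxTrace,
    InjectionSchedule,
    PlateRecord,
)

MITO_PHASES = ("baseline", "oligomycin", "fccp", "rotenone_antimycin")
GLYCO_PHASES = ("baseline", "glucose", "oligomycin", "2dg")
RATE_PHASES = ("baseline", "rotenone_antimycin", "2dg")

_COMPOUNDS = {
    "oligomycin": "oligomycin",
    "fccp": "FCCP",
    "rotenone_antimycin": "antimycin A/rotenone",
    "glucose": "glucose",
    "2dg": "2-deoxyglucose",
    "uk5099": "UK5099",
    "etomoxir": "etomoxir",
    "lps": "LPS",
    "polyic": "poly(I:C)",
}


@dataclass(frozen=True)
class ScenarioConfig:
    """Ground truth for one simulated plate.

    ``group_multipliers`` maps group -> channel -> phase -> multiplier
    (baseline multiplier is implicitly 1; missing phases default to 1).
    ``noise_sd`` is an absolute rate SD, either shared or per channel.
    """

    phases: tuple[str, ...] = MITO_PHASES
    channels: Mapping[str, float] = field(default_factory=lambda: {"OCR": 100.0, "ECAR": 20.0})
    group_multipliers: Mapping[str, Mapping[str, Mapping[str, float]]] = field(
        default_factory=lambda: {"control": {}}
    )
    noise_sd: float | Mapping[str, float] = 0.0
    drift_per_min: float = 0.0
    wells_per_group: int = 2
    protein_mean: float = 12.0
    protein_sd: float = 1.0
    measurements_per_phase: int = 3
    interval_min: float = 6.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.phases[0] != BASELINE_PHASE:
            raise ValueError("first phase must be 'baseline'")
        if self.wells_per_group < 1:
            raise ValueError("wells_per_group must be >= 1")
        if self.measurements_per_phase < 1:
            raise ValueError("measurements_per_phase must be >= 1")
        for sd in self._noise_map().values():
            if sd < 0:
                raise ValueError("noise_sd must be >= 0")
        for group, chans in self.group_multipliers.items():
            for ch, mults in chans.items():
                for phase, m in mults.items():
                    if m <= 0:
                        raise ValueError(
                            f"multiplier for {group}/{ch}/{phase} must be positive, got {m}"
                        )

    def _noise_map(self) -> dict[str, float]:
        if isinstance(self.noise_sd, Mapping):
            return {ch: float(self.noise_sd.get(ch, 0.0)) for ch in self.channels}
        return {ch: float(self.noise_sd) for ch in self.channels}

    def multiplier(self, group: str, channel: str, phase: str) -> float:
        if phase == BASELINE_PHASE:
            return 1.0
        return float(self.group_multipliers.get(group, {}).get(channel, {}).get(phase, 1.0))

    def schedule(self) -> InjectionSchedule:
        events = []
        for i, phase in enumerate(self.phases[1:], start=1):
            events.append(
                (phase, _COMPOUNDS.get(phase, phase), i * self.measurements_per_phase)
            )
        return InjectionSchedule.from_events(events)


def simulate_plate(config: ScenarioConfig, seed: int | None = None) -> PlateRecord:
    """Generate one plate; identical config + seed gives an identical plate."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    mpp = config.measurements_per_phase
    n_meas = mpp * len(config.phases)
    indices = np.arange(1, n_meas + 1)
    times = (indices - 1) * config.interval_min
    phase_of = [config.phases[(i - 1) // mpp] for i in indices]
    noise = config._noise_map()

    traces: list[FluxTrace] = []
    protein: dict[str, float] = {}
    for group in config.group_multipliers:
        for w in range(1, config.wells_per_group + 1):
            well = f"{group}_w{w}"
            protein[well] = float(
                max(1e-3, rng.normal(config.protein_mean, config.protein_sd))
            )
            for channel, baseline in config.channels.items():
                mult = np.array([config.multiplier(group, channel, p) for p in phase_of])
                mean = baseline * mult * (1.0 + config.drift_per_min * times)
                values = mean + rng.normal(0.0, noise[channel], size=n_meas)
                values = np.clip(values, 0.0, None)
                traces.append(
                    FluxTrace(
                        well_id=well,
                        group=group,
                        channel=channel,
                        indices=indices.copy(),
                        times=times.copy(),
                        values=values,
                    )
                )
    return PlateRecord(
        traces=traces,
        protein_ug=protein,
        schedule=config.schedule(),
        meta={"scenario": "custom", "seed": int(config.seed if seed is None else seed)},
    )


def simulate_experiments(
    config: ScenarioConfig, n_experiments: int, seed: int | None = None
) -> list[PlateRecord]:
    """Independent plates, one per biological experiment, with spawned seeds."""
    root = np.random.SeedSequence(config.seed if seed is None else seed)
    plates = []
    for i, child in enumerate(root.spawn(n_experiments)):
        plate = simulate_plate(config, seed=int(child.generate_state(1)[0] % (2**31)))
        plate.meta["experiment"] = i + 1
        plates.append(plate)
    return plates


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

_STRESS_OCR = {"oligomycin": 0.45, "fccp": 1.5, "rotenone_antimycin": 0.18}
_STRESS_ECAR = {"oligomycin": 1.25, "fccp": 1.1, "rotenone_antimycin": 1.0}


def _mito_config(groups: dict, *, wells: int = 2, seed: int = 0) -> ScenarioConfig:
    return ScenarioConfig(
        phases=MITO_PHASES,
        channels={"OCR": 100.0, "ECAR": 20.0},
        group_multipliers=groups,
        noise_sd={"OCR": 5.0, "ECAR": 1.0},  # 5% of each baseline
        wells_per_group=wells,
        seed=seed,
    )


def preset(name: str, seed: int = 0) -> ScenarioConfig:
    """Named scenario configs anchored to the study's qualitative readouts.

    ``lps_acute``: single LPS injection, ECAR multiplier 1.5 and OCR 0.8 in
    the treated group (aerobic-glycolysis switch); ``polyic`` raises
    FCCP-phase OCR; ``il33_treatment``/``il33_oe`` raise, and ``il33_kd``
    lowers, the FCCP-phase OCR multiplier, with ``il33_kd`` also raising the
    glucose-phase ECAR multiplier. Every treatment preset includes its own
    untreated reference group on the same plate.
    """
    if name == "control":
        return _mito_config(
            {"control": {"OCR": dict(_STRESS_OCR), "ECAR": dict(_STRESS_ECAR)}}, seed=seed
        )
    if name == "lps_acute":
        return ScenarioConfig(
            phases=("baseline", "lps"),
            channels={"OCR": 100.0, "ECAR": 20.0},
            group_multipliers={
                "lps": {"ECAR": {"lps": 1.5}, "OCR": {"lps": 0.8}},
                "control": {},
            },
            noise_sd={"OCR": 5.0, "ECAR": 1.0},  # 5% of each baseline
            wells_per_group=2,
            seed=seed,
        )
    if name == "polyic":
        return _mito_config(
            {
                "polyic": {
                    "OCR": {"oligomycin": 0.45, "fccp": 1.8, "rotenone_antimycin": 0.18},
                    "ECAR": {**_STRESS_ECAR, "oligomycin": 1.4},
                },
                "control": {"OCR": dict(_STRESS_OCR), "ECAR": dict(_STRESS_ECAR)},
            },
            seed=seed,
        )
    if name in ("il33_treatment", "il33_oe"):
        label = "il33" if name == "il33_treatment" else "il33_oe"
        return _mito_config(
            {
                label: {
                    "OCR": {"oligomycin": 0.45, "fccp": 1.9, "rotenone_antimycin": 0.18},
                    "ECAR": {**_STRESS_ECAR, "glucose": 1.3},
                },
                "scrambled": {"OCR": dict(_STRESS_OCR), "ECAR": dict(_STRESS_ECAR)},
            },
            seed=seed,
        )
    if name == "il33_kd":
        return _mito_config(
            {
                "il33_kd": {
                    "OCR": {"oligomycin": 0.45, "fccp": 1.15, "rotenone_antimycin": 0.18},
                    "ECAR": {**_STRESS_ECAR, "glucose": 1.5},
                },
                "scrambled": {
                    "OCR": dict(_STRESS_OCR),
                    "ECAR": {**_STRESS_ECAR, "glucose": 1.2},
                },
            },
            seed=seed,
        )
    raise ValueError(
        f"unknown preset {name!r}; available: control, lps_acute, polyic, "
        "il33_treatment, il33_kd, il33_oe"
    )
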