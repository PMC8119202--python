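"""Extracellular-flux (Seahorse-style) trace analysis.

Turns per-well OCR/ECAR time series plus an injection schedule into the
standard stress-test parameters:

* mitochondrial stress test (oligomycin -> FCCP -> rotenone/antimycin A):
  non-mitochondrial respiration, basal respiration, proton leak, ATP-linked
  respiration, maximal respiration, spare respiratory capacity, OCR/ECAR;
* glycolysis stress test (glucose -> oligomycin -> 2-deoxyglucose):
  non-glycolytic acidification, glycolysis, glycolytic capacity and reserve;
* glycolytic rate assay (rotenone/antimycin A -> 2-DG): basal and
  compensatory glycolysis on the glycoPER scale, mitoOCR/glycoPER,
  %PER from glycolysis;
* single-inhibitor assays (UK5099, etomoxir): pathway-dependent respiration
  as the OCR drop across the injection;
* acute-injection fold-change of one channel between a treated and a
  control group.

Conventions where a single "measurement after injection" must be picked:
the minimum of the phase for inhibitor injections (oligomycin, rot/AA,
UK5099, etomoxir), the maximum for stimulation phases (FCCP, glucose);
"before an injection" always means the last measurement of the preceding
phase. Rates are per-minute instrument units, optionally normalized to
total protein (ug) per well.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._core import Undefined

CHANNELS = ("OCR", "ECAR", "PER", "glycoPER")
_BASE_UNITS = {
    "OCR": "pmol O2/min",
    "ECAR": "mpH/min",
    "PER": "pmol H+/min",
    "glycoPER": "pmol H+/min",
}

BASELINE_PHASE = "baseline"


@dataclass(frozen=True)
class InjectionEvent:
    name: str
    compound: str
    after_measurement: int


@dataclass(frozen=True)
class InjectionSchedule:
    """Ordered injections; each takes effect after a 1-based measurement index."""

    events: tuple[InjectionEvent, ...]

    def __post_init__(self) -> None:
        afters = [e.after_measurement for e in self.events]
        if any(b <= a for a, b in zip(afters, afters[1:])):
            raise ValueError("injection after_measurement indices must be strictly increasing")
        names = [e.name for e in self.events]
        if len(set(names)) != len(names):
            raise ValueError("injection event names must be unique")

    @classmethod
    def from_events(cls, events: Iterable[tuple[str, str, int] | Mapping]) -> "InjectionSchedule":
        out = []
        for e in events:
            if isinstance(e, Mapping):
                out.append(InjectionEvent(e["name"], e.get("compound", e["name"]), int(e["after_measurement"])))
            else:
                name, compound, after = e
                out.append(InjectionEvent(name, compound, int(after)))
        return cls(tuple(out))

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(e.name for e in self.events)


@dataclass
class FluxTrace:
    """One well's time-ordered measurements on a single channel."""

    well_id: str
    group: str
    channel: str
    indices: np.ndarray  # 1-based measurement indices, strictly increasing
    times: np.ndarray  # minutes, nondecreasing
    values: np.ndarray  # rates in channel units
    phases: list[str] | None = None  # set by segment_phases
    unit: str = ""

    def __post_init__(self) -> None:
        if self.channel not in CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}; expected one of {CHANNELS}")
        self.indices = np.asarray(self.indices, dtype=int)
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.indices)
        if not (len(self.times) == len(self.values) == n):
            raise ValueError(f"trace {self.well_id}: indices/times/values length mismatch")
        if n == 0:
            raise ValueError(f"trace {self.well_id}: empty trace")
        if np.any(np.diff(self.indices) <= 0):
            raise ValueError(f"trace {self.well_id}: measurement indices must be strictly increasing")
        if np.any(np.diff(self.times) < 0):
            raise ValueError(f"trace {self.well_id}: times must be nondecreasing")
        if self.phases is not None and len(self.phases) != n:
            raise ValueError(f"trace {self.well_id}: phase labels must cover every measurement")
        if not self.unit:
            self.unit = _BASE_UNITS[self.channel]

    def __len__(self) -> int:
        return len(self.values)

    def phase_values(self, phase: str) -> np.ndarray:
        if self.phases is None:
            raise ValueError(f"trace {self.well_id} is not segmented; call segment_phases first")
        mask = np.array([p == phase for p in self.phases])
        if not mask.any():
            raise ValueError(
                f"trace {self.well_id}: phase {phase!r} not present "
                f"(available: {sorted(set(self.phases))})"
            )
        return self.values[mask]

    def phase_names(self) -> list[str]:
        if self.phases is None:
            raise ValueError(f"trace {self.well_id} is not segmented")
        seen: list[str] = []
        for p in self.phases:
            if p not in seen:
                seen.append(p)
        return seen


@dataclass
class PlateRecord:
    """All traces of one plate run, sharing one injection schedule."""

    traces: list[FluxTrace]
    protein_ug: dict[str, float]
    schedule: InjectionSchedule
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = {t.well_id for t in self.traces} - set(self.protein_ug)
        if missing:
            raise ValueError(f"wells without a protein entry: {sorted(missing)}")

    def traces_for(self, group: str | None = None, channel: str | None = None) -> list[FluxTrace]:
        out = self.traces
        if group is not None:
            out = [t for t in out if t.group == group]
        if channel is not None:
            out = [t for t in out if t.channel == channel]
        return out

    def groups(self) -> list[str]:
        seen: list[str] = []
        for t in self.traces:
            if t.group not in seen:
                seen.append(t.group)
        return seen


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MitoStressParams:
    nonmito_respiration: float
    basal_respiration: float
    proton_leak: float
    atp_production: float
    maximal_respiration: float
    spare_respiratory_capacity_pct: float
    ocr_ecar_ratio: float
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class GlycoStressParams:
    nonglycolytic_acidification: float
    glycolysis: float
    glycolytic_capacity: float
    glycolytic_reserve: float
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class GlycoRateParams:
    basal_glycolysis: float
    compensatory_glycolysis: float
    mito_ocr_over_glycoper: float
    pct_per_from_glycolysis: float
    basal_per: float
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class PerConversion:
    """Constants converting ECAR (mpH/min) to a proton efflux rate.

    PER = ECAR * buffer_factor * chamber_volume_ul * volume_scaling;
    glycoPER = PER - ccf * OCR, where ccf is the CO2 contribution factor.
    ``neutral()`` gives scale 1 / ccf 0 so glycoPER == ECAR numerically.
    """

    buffer_factor: float = 2.6  # mmol/L/pH
    chamber_volume_ul: float = 2.28
    volume_scaling: float = 1.6
    ccf: float = 0.61

    @classmethod
    def neutral(cls) -> "PerConversion":
        return cls(buffer_factor=1.0, chamber_volume_ul=1.0, volume_scaling=1.0, ccf=0.0)

    @property
    def scale(self) -> float:
        return self.buffer_factor * self.chamber_volume_ul * self.volume_scaling


@dataclass(frozen=True)
class AcuteResponse:
    """Group-level fold change of per-well injection responses."""

    fold_change: float
    treated_biological: tuple[float, ...]
    control_biological: tuple[float, ...]
    n_biological: int
    excluded_wells: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def normalize_to_protein(trace: FluxTrace, protein_ug: float) -> FluxTrace:
    """Divide every measurement by the well's total protein (ug)."""
    if not protein_ug > 0:
        raise ValueError(f"well {trace.well_id}: nonpositive protein content ({protein_ug} ug)")
    return replace(
        trace,
        values=trace.values / protein_ug,
        unit=f"{_BASE_UNITS[trace.channel]}/ug",
        phases=None if trace.phases is None else list(trace.phases),
    )


def normalize_plate(plate: PlateRecord) -> PlateRecord:
    """Protein-normalize every trace of a plate."""
    traces = [normalize_to_protein(t, plate.protein_ug[t.well_id]) for t in plate.traces]
    return PlateRecord(traces, dict(plate.protein_ug), plate.schedule, dict(plate.meta))


def segment_phases(trace: FluxTrace, schedule: InjectionSchedule) -> FluxTrace:
    """Label each measurement 'baseline' or the most recent preceding injection."""
    last_index = int(trace.indices[-1])
    for ev in schedule.events:
        if ev.after_measurement >= last_index:
            raise ValueError(
                f"injection {ev.name!r} after measurement {ev.after_measurement} leaves no "
                f"measurements in trace {trace.well_id} (last index {last_index})"
            )
        if ev.after_measurement < 1:
            raise ValueError(f"injection {ev.name!r}: after_measurement must be >= 1")
    phases = []
    for idx in trace.indices:
        label = BASELINE_PHASE
        for ev in schedule.events:
            if idx > ev.after_measurement:
                label = ev.name
        phases.append(label)
    return replace(trace, phases=phases)


def segment_plate(plate: PlateRecord) -> PlateRecord:
    traces = [segment_phases(t, plate.schedule) for t in plate.traces]
    return PlateRecord(traces, dict(plate.protein_ug), plate.schedule, dict(plate.meta))


def mito_stress_params(
    ocr: FluxTrace,
    ecar_first: float,
    *,
    baseline: str = BASELINE_PHASE,
    oligomycin: str = "oligomycin",
    fccp: str = "fccp",
    rot_aa: str = "rotenone_antimycin",
) -> MitoStressParams:
    """Mitochondrial stress-test parameters from a segmented OCR trace.

    nonmito = min OCR after rot/AA; basal = last baseline OCR - nonmito;
    proton leak = min OCR after oligomycin - nonmito; ATP-linked = basal - leak;
    maximal = max OCR after FCCP - nonmito; spare% = 100 * maximal / basal;
    OCR/ECAR = first OCR / first ECAR.
    """
    base = ocr.phase_values(baseline)
    oligo = ocr.phase_values(oligomycin)
    fccp_v = ocr.phase_values(fccp)
    rot = ocr.phase_values(rot_aa)

    flags: list[str] = []
    nonmito = float(rot.min())
    basal = float(base[-1]) - nonmito
    leak = float(oligo.min()) - nonmito
    atp = basal - leak
    maximal = float(fccp_v.max()) - nonmito
    if basal > 0:
        spare: float = 100.0 * maximal / basal
    else:
        spare = Undefined("spare_capacity_nonpositive_basal")
        flags.append("spare_capacity_nonpositive_basal")
    if ecar_first != 0:
        ocr_ecar: float = float(ocr.values[0]) / float(ecar_first)
    else:
        ocr_ecar = Undefined("ocr_ecar_zero_ecar")
        flags.append("ocr_ecar_zero_ecar")
    return MitoStressParams(nonmito, basal, leak, atp, maximal, spare, ocr_ecar, tuple(flags))


def glyco_stress_params(
    ecar: FluxTrace,
    *,
    baseline: str = BASELINE_PHASE,
    glucose: str = "glucose",
    oligomycin: str = "oligomycin",
    dg2: str = "2dg",
) -> GlycoStressParams:
    """Glycolysis stress-test parameters from a segmented ECAR trace."""
    base = ecar.phase_values(baseline)
    glc = ecar.phase_values(glucose)
    oligo = ecar.phase_values(oligomycin)
    ecar.phase_values(dg2)  # enforce the phase is present

    nonglyco = float(base[-1])
    glycolysis = float(glc.max()) - nonglyco
    capacity = float(oligo.max()) - nonglyco
    reserve = capacity - glycolysis
    return GlycoStressParams(nonglyco, glycolysis, capacity, reserve)


def per_trace(ecar: FluxTrace, conversion: PerConversion) -> FluxTrace:
    """Convert an ECAR trace to a proton efflux rate (PER) trace."""
    if ecar.channel != "ECAR":
        raise ValueError(f"PER conversion expects an ECAR trace, got {ecar.channel}")
    return replace(
        ecar,
        channel="PER",
        values=ecar.values * conversion.scale,
        unit=_BASE_UNITS["PER"],
        phases=None if ecar.phases is None else list(ecar.phases),
    )


def glycoper_trace(ocr: FluxTrace, ecar: FluxTrace, conversion: PerConversion) -> FluxTrace:
    """glycoPER = PER - ccf * OCR, aligned measurement by measurement."""
    if len(ocr) != len(ecar) or np.any(ocr.indices != ecar.indices):
        raise ValueError("OCR and ECAR traces must share measurement indices")
    per = per_trace(ecar, conversion)
    return replace(
        per,
        channel="glycoPER",
        values=per.values - conversion.ccf * ocr.values,
        unit=_BASE_UNITS["glycoPER"],
        phases=None if per.phases is None else list(per.phases),
    )


def glyco_rate_params(
    ocr: FluxTrace,
    ecar: FluxTrace,
    conversion: PerConversion = PerConversion(),
    *,
    baseline: str = BASELINE_PHASE,
    rot_aa: str = "rotenone_antimycin",
    dg2: str = "2dg",
) -> GlycoRateParams:
    """Glycolytic-rate assay parameters from paired segmented OCR/ECAR traces."""
    gper = glycoper_trace(ocr, ecar, conversion)
    per = per_trace(ecar, conversion)

    gper_base = gper.phase_values(baseline)
    gper_rot = gper.phase_values(rot_aa)
    gper.phase_values(dg2)
    ocr_base = ocr.phase_values(baseline)
    ocr_rot = ocr.phase_values(rot_aa)

    flags: list[str] = []
    basal_glycolysis = float(gper_base[-1])
    compensatory = float(gper_rot.max())
    basal_per = float(per.phase_values(baseline)[-1])
    mito_ocr = float(ocr_base[-1]) - float(ocr_rot.min())
    if basal_glycolysis > 0:
        ratio: float = mito_ocr / basal_glycolysis
    else:
        ratio = Undefined("mito_ocr_over_glycoper_nonpositive_basal_glycolysis")
        flags.append("mito_ocr_over_glycoper_nonpositive_basal_glycolysis")
    if basal_per != 0:
        pct: float = 100.0 * basal_glycolysis / basal_per
    else:
        pct = Undefined("pct_per_zero_basal_per")
        flags.append("pct_per_zero_basal_per")
    return GlycoRateParams(basal_glycolysis, compensatory, ratio, pct, basal_per, tuple(flags))


def inhibitor_dependent_respiration(ocr: FluxTrace, event_name: str) -> float:
    """OCR drop across one inhibitor injection (e.g. UK5099, etomoxir).

    Returns (last OCR before the event) - (minimum OCR within the event's
    phase); a post-injection rise yields a negative value, reported as-is.
    """
    if ocr.phases is None:
        raise ValueError(f"trace {ocr.well_id} is not segmented")
    names = ocr.phase_names()
    if event_name not in names:
        raise ValueError(
            f"unknown event {event_name!r}; available events: {[n for n in names if n != BASELINE_PHASE]}"
        )
    pos = names.index(event_name)
    if pos == 0:
        raise ValueError(f"event {event_name!r} has no preceding measurements")
    before = ocr.phase_values(names[pos - 1])
    within = ocr.phase_values(event_name)
    return float(before[-1]) - float(within.min())


def well_injection_response(trace: FluxTrace, event_name: str) -> float:
    """Mean value in the event's phase divided by the mean of all earlier measurements."""
    if trace.phases is None:
        raise ValueError(f"trace {trace.well_id} is not segmented")
    names = trace.phase_names()
    if event_name not in names:
        raise ValueError(f"unknown event {event_name!r}; available: {names}")
    pos = names.index(event_name)
    pre_phases = set(names[:pos])
    pre = np.array([v for v, p in zip(trace.values, trace.phases) if p in pre_phases])
    post = trace.phase_values(event_name)
    pre_mean = float(pre.mean()) if len(pre) else 0.0
    if pre_mean == 0:
        return Undefined("zero_pre_event_mean")
    return float(post.mean()) / pre_mean


def acute_injection_response(
    plates: Sequence[PlateRecord],
    event_name: str,
    treated_group: str,
    control_group: str,
    channel: str = "ECAR",
) -> AcuteResponse:
    """Fold change of the acute injection response, treated over control.

    Each plate is one biological experiment: per-well responses (mean
    post-event / mean pre-event) are averaged over that plate's technical
    wells first, giving one biological value per group per plate; the fold
    change is the mean treated biological response over the mean control
    biological response. Wells with a zero pre-event mean are excluded with
    a warning.
    """
    treated_bio: list[float] = []
    control_bio: list[float] = []
    excluded: list[str] = []
    for plate in plates:
        for group, sink in ((treated_group, treated_bio), (control_group, control_bio)):
            responses = []
            for tr in plate.traces_for(group=group, channel=channel):
                r = well_injection_response(tr, event_name)
                if isinstance(r, Undefined):
                    warnings.warn(
                        f"well {tr.well_id} excluded from acute response: {r.flag}",
                        stacklevel=2,
                    )
                    excluded.append(tr.well_id)
                else:
                    responses.append(r)
            if not responses:
                raise ValueError(f"no usable {channel} wells for group {group!r} in a plate")
            sink.append(float(np.mean(responses)))
    fold = float(np.mean(treated_bio)) / float(np.mean(control_bio))
    return AcuteResponse(
        fold_change=fold,
        treated_biological=tuple(treated_bio),
        control_biological=tuple(control_bio),
        n_biological=len(treated_bio),
        excluded_wells=tuple(excluded),
    )
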