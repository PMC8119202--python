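import numpy as np
import pytest

from metaboflux.flux import FluxTrace, InjectionSchedule, segment_phases

MITO_EVENTS = [
    ("oligomycin", "oligomycin", 3),
    ("fccp", "FCCP", 6),
    ("rotenone_antimycin", "antimycin A/rotenone", 9),
]
GLYCO_EVENTS = [
    ("glucose", "glucose", 3),
    ("oligomycin", "oligomycin", 6),
    ("2dg", "2-deoxyglucose", 9),
]
RATE_EVENTS = [
    ("rotenone_antimycin", "antimycin A/rotenone", 3),
    ("2dg", "2-deoxyglucose", 6),
]


def make_trace(values, channel="OCR", well="w1", group="g", interval=6.5, schedule=None):
    """Build a trace from raw values; segment it if a schedule is given."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    tr = FluxTrace(
        well_id=well,
        group=group,
        channel=channel,
        indices=np.arange(1, n + 1),
        times=np.arange(n) * interval,
        values=values,
    )
    if schedule is not None:
        tr = segment_phases(tr, schedule)
    return tr


def phase_trace(phase_values, channel="OCR", events=MITO_EVENTS, per_phase=3, **kw):
    """Piecewise-constant trace: one level per phase, ``per_phase`` points each."""
    values = np.repeat(np.asarray(phase_values, dtype=float), per_phase)
    sched = InjectionSchedule.from_events(
        [(n, c, i * per_phase) for i, (n, c, _) in enumerate(events, start=1)]
    )
    return make_trace(values, channel=channel, schedule=sched, **kw)


@pytest.fixture
def mito_schedule():
    return InjectionSchedule.from_events(MITO_EVENTS)


@pytest.fixture
def glyco_schedule():
    return InjectionSchedule.from_events(GLYCO_EVENTS)
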