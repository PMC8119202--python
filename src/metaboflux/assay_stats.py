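"""Replicate policy, plate-assay arithmetic and group statistics.

The replicate convention: wells measured within one experiment are
technical repeats; their mean is that experiment's biological value (a
single well passes through unchanged), and only biological values enter
cross-group ratios or hypothesis tests. Summaries report mean +/- SD for
technical replicates and mean +/- SEM for biological replicates.

Group comparisons are an unpaired two-tailed t test (pooled variance by
default, Welch optional) for two groups, or a one-way ANOVA followed by
Dunnett's control-vs-each comparisons for several groups against a
control; the significance threshold is reported at 0.05.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._core import Undefined

ALPHA = 0.05


@dataclass(frozen=True)
class ComparisonResult:
    conditions: tuple[str, str]
    effect: float  # difference in means (condition - reference)
    test: str
    statistic: float
    p_value: float
    n_biological: tuple[int, int]
    significant: bool

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must lie in [0, 1]")
        if min(self.n_biological) < 2:
            raise ValueError("each condition needs >= 2 biological values for a test")


def aggregate_technical(table: pd.DataFrame) -> pd.DataFrame:
    """Collapse technical wells to one biological value per (experiment, condition).

    ``table`` needs columns experiment_id, condition, well_id, value (and
    optionally unit). Idempotent: aggregating an already-aggregated table
    changes nothing.
    """
    required = {"experiment_id", "condition", "well_id", "value"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"replicate table missing columns: {sorted(missing)}")
    if table.empty:
        raise ValueError("empty replicate table")
    keys = ["experiment_id", "condition"]
    agg = {"value": "mean", "well_id": "count"}
    if "unit" in table.columns:
        agg["unit"] = "first"
    out = table.groupby(keys, as_index=False, sort=False).agg(agg)
    out = out.rename(columns={"well_id": "n_technical"})
    return out


def biological_values(table: pd.DataFrame) -> dict[str, np.ndarray]:
    """Condition -> array of biological values (one per experiment)."""
    agg = aggregate_technical(table)
    return {
        cond: sub["value"].to_numpy(dtype=float)
        for cond, sub in agg.groupby("condition", sort=False)
    }


def consumption_production(sample_conc: float, unconditioned_conc: float, mode: str) -> float:
    """Metabolite consumption or production from media concentrations (mM).

    consumption = unconditioned - sample (glucose taken up);
    production = sample - unconditioned (lactate excreted).
    Negative results are returned as-is; express relative to a control with
    :func:`fold_change`.
    """
    if sample_conc < 0 or unconditioned_conc < 0:
        raise ValueError("concentrations must be >= 0")
    if mode == "consumption":
        return unconditioned_conc - sample_conc
    if mode == "production":
        return sample_conc - unconditioned_conc
    raise ValueError(f"mode must be 'consumption' or 'production', got {mode!r}")


def atp_adp_ratio(
    atp_signal: float, atp_background: float, adp_signal: float, adp_background: float
) -> float:
    """Background-subtracted ATP/ADP ratio; flagged if the ADP net is <= 0."""
    atp_net = atp_signal - atp_background
    adp_net = adp_signal - adp_background
    if adp_net <= 0:
        return Undefined("atp_adp_nonpositive_adp_net")
    return atp_net / adp_net


def relative_expression(
    ct_target: float, ct_reference: float, ct_target_ctrl: float, ct_reference_ctrl: float
) -> float:
    """Relative gene expression, 2^-ddCt, normalized to a reference gene."""
    for v in (ct_target, ct_reference, ct_target_ctrl, ct_reference_ctrl):
        if not np.isfinite(v):
            raise ValueError("Ct values must be finite")
    ddct = (ct_target - ct_reference) - (ct_target_ctrl - ct_reference_ctrl)
    return float(2.0 ** (-ddct))


def fold_change(value: float, control_value: float) -> float:
    """value / control; flagged when the control is zero."""
    if control_value == 0:
        return Undefined("fold_change_zero_control")
    return value / control_value


def compare_groups(
    values: Mapping[str, Sequence[float]],
    design: str = "two_group",
    control: str | None = None,
    equal_var: bool = True,
    alpha: float = ALPHA,
) -> list[ComparisonResult]:
    """Hypothesis tests on biological values per condition.

    ``two_group``: unpaired two-tailed t test between exactly two
    conditions (the second is the reference). ``multi_vs_control``:
    one-way ANOVA across all conditions, then Dunnett-adjusted
    control-vs-each comparisons.
    """
    arrays = {k: np.asarray(v, dtype=float) for k, v in values.items()}
    for name, arr in arrays.items():
        if len(arr) < 2:
            raise ValueError(f"condition {name!r} has fewer than 2 biological values")

    if design == "two_group":
        if len(arrays) != 2:
            raise ValueError("two_group design needs exactly 2 conditions")
        (name_a, a), (name_b, b) = arrays.items()
        res = stats.ttest_ind(a, b, equal_var=equal_var)
        test = "student_t" if equal_var else "welch_t"
        return [
            ComparisonResult(
                conditions=(name_a, name_b),
                effect=float(a.mean() - b.mean()),
                test=f"unpaired two-tailed {test}",
                statistic=float(res.statistic),
                p_value=float(res.pvalue),
                n_biological=(len(a), len(b)),
                significant=bool(res.pvalue < alpha),
            )
        ]

    if design == "multi_vs_control":
        if control is None or control not in arrays:
            raise ValueError("multi_vs_control design needs a valid control condition")
        others = [k for k in arrays if k != control]
        if not others:
            raise ValueError("multi_vs_control needs at least one non-control condition")
        ctrl = arrays[control]
        dunnett = stats.dunnett(*[arrays[k] for k in others], control=ctrl)
        results = []
        for i, name in enumerate(others):
            results.append(
                ComparisonResult(
                    conditions=(name, control),
                    effect=float(arrays[name].mean() - ctrl.mean()),
                    test="one-way ANOVA + Dunnett",
                    statistic=float(dunnett.statistic[i]),
                    p_value=float(dunnett.pvalue[i]),
                    n_biological=(len(arrays[name]), len(ctrl)),
                    significant=bool(dunnett.pvalue[i] < alpha),
                )
            )
        return results

    raise ValueError(f"unknown design {design!r}")


def anova_oneway(values: Mapping[str, Sequence[float]]) -> tuple[float, float]:
    """Overall one-way ANOVA (F, p) across all conditions."""
    res = stats.f_oneway(*[np.asarray(v, dtype=float) for v in values.values()])
    return float(res.statistic), float(res.pvalue)


def summarize(values: Sequence[float], level: str = "biological") -> dict[str, float]:
    """mean +/- SD (technical) or mean +/- SEM (biological)."""
    arr = np.asarray(values, dtype=float)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    if level == "technical":
        return {"mean": mean, "sd": sd, "n": len(arr)}
    if level == "biological":
        sem = sd / np.sqrt(len(arr)) if len(arr) > 1 else 0.0
        return {"mean": mean, "sem": float(sem), "n": len(arr)}
    raise ValueError(f"level must be 'technical' or 'biological', got {level!r}")
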