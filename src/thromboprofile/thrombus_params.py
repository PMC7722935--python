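"""Thrombus parameter registries, manual-score validation and fibrin kinetics.

Multiparameter flow-chamber assays summarize each run by a fixed panel of
parameters.  Under non-coagulant conditions (platelet activation on
collagen) the panel is P1-P8; under coagulant conditions (collagen +/-
tissue factor, fibrin formation) it is Pa-Pe, four of which are read at
the time points 0, 2, 4 and 6 min while Pc is a single kinetic statistic:

====  =======================================  ==============  =========
id    name                                     kind            scale
====  =======================================  ==============  =========
P1    morphological score                      ordinal          0-5
P2    platelet deposition                      %SAC             0-100
P3    aggregate contraction score              ordinal          0-3
P4    aggregate multilayer score               ordinal          0-3
P5    aggregate multilayer coverage            %SAC             0-100
P6    PS exposure (annexin A5)                 %SAC             0-100
P7    P-selectin expression                    %SAC             0-100
P8    integrin aIIbb3 activation (JON/A)       %SAC             0-100
Pa    DiOC6 platelet deposition                %SAC             0-100
Pb    DiOC6 platelet thrombus score            ordinal          0-5
Pc    time to first fibrin formation           -log minutes     --
Pd    AF647 fibrin score                       ordinal          0-3
Pe    AF647 fibrin-covered area                %SAC             0-100
====  =======================================  ==============  =========

Kinetic fibrin curves are %SAC-vs-time series sampled every 45 s over a
10-min observation window.  Two statistics are derived from them: the
time to first fibrin (first sample whose %SAC exceeds the labeling
threshold, reported as -log10 minutes) and the fibrin formation rate
(ordinary-least-squares slope over the steepest part of the curve,
1.5-3.75 min).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
from scipy import stats

from .image_quant import SacValue, average_run

ORDINAL_INCREMENT = 0.5  # manual scores are given in half-point steps
DEFAULT_FIBRIN_THRESHOLD = 1.0  # %SAC labeling threshold for "fibrin present"
DEFAULT_SLOPE_WINDOW = (1.5, 3.75)  # minutes; steepest part of the fibrin curve
COAGULANT_TIMEPOINTS = (0, 2, 4, 6)  # minutes

__all__ = [
    "ParameterDef",
    "PARAMETERS",
    "FlowRunProfile",
    "KineticSeries",
    "FibrinOnset",
    "validate_score",
    "time_to_first_fibrin",
    "fibrin_rate",
    "build_profile",
    "noncoagulant_required",
    "coagulant_required",
    "timepoint_key",
]


@dataclass(frozen=True)
class ParameterDef:
    id: str
    name: str
    kind: str  # percent_sac | ordinal_score | neg_log_minutes
    scale_max: float | None = None  # for ordinal scores: 3 or 5
    channel: str = "manual"  # source channel, or "manual" for scored params

    def __post_init__(self) -> None:
        if self.kind not in ("percent_sac", "ordinal_score", "neg_log_minutes"):
            raise ValueError(f"unknown parameter kind {self.kind!r}")
        if self.kind == "ordinal_score" and self.scale_max not in (3, 5):
            raise ValueError(f"ordinal parameter {self.id} needs scale_max 3 or 5")

    def check_value(self, value: float) -> None:
        """Raise if ``value`` violates this parameter's scale."""
        if self.kind == "percent_sac" and not 0.0 <= value <= 100.0:
            raise ValueError(f"{self.id} ({self.name}) must lie in [0, 100], got {value}")
        if self.kind == "ordinal_score" and not 0.0 <= value <= self.scale_max:
            raise ValueError(
                f"{self.id} ({self.name}) is scored on a 0-{self.scale_max:g} scale, got {value}"
            )


_DEFS = [
    ParameterDef("P1", "morphological score", "ordinal_score", 5, "manual"),
    ParameterDef("P2", "platelet deposition", "percent_sac", None, "brightfield"),
    ParameterDef("P3", "aggregate contraction score", "ordinal_score", 3, "manual"),
    ParameterDef("P4", "aggregate multilayer score", "ordinal_score", 3, "manual"),
    ParameterDef("P5", "aggregate multilayer coverage", "percent_sac", None, "brightfield"),
    ParameterDef("P6", "PS exposure", "percent_sac", None, "Cy5"),
    ParameterDef("P7", "P-selectin expression", "percent_sac", None, "GFP"),
    ParameterDef("P8", "integrin aIIbb3 activation", "percent_sac", None, "RFP"),
    ParameterDef("Pa", "DiOC6 platelet deposition", "percent_sac", None, "GFP"),
    ParameterDef("Pb", "DiOC6 platelet thrombus score", "ordinal_score", 5, "manual"),
    ParameterDef("Pc", "time to first fibrin formation", "neg_log_minutes", None, "Cy5"),
    ParameterDef("Pd", "AF647 fibrin score", "ordinal_score", 3, "manual"),
    ParameterDef("Pe", "AF647 fibrin-covered area", "percent_sac", None, "Cy5"),
]

#: Registry of the thirteen standard thrombus parameters, keyed by id.
PARAMETERS: Mapping[str, ParameterDef] = {d.id: d for d in _DEFS}


def timepoint_key(param_id: str, minutes: float) -> str:
    """Profile key for a parameter read at a specific time point."""
    return f"{param_id}_t{minutes:g}"


def base_param(key: str) -> ParameterDef:
    """Resolve a profile key (plain id or ``id_t<min>``) to its definition."""
    pid = key.split("_t")[0]
    if pid not in PARAMETERS:
        raise KeyError(f"unknown thrombus parameter {key!r}")
    return PARAMETERS[pid]


def noncoagulant_required() -> list[str]:
    """The eight mandatory parameters of a non-coagulant run."""
    return [f"P{i}" for i in range(1, 9)]


def coagulant_required(timepoints: Sequence[float] = COAGULANT_TIMEPOINTS) -> list[str]:
    """Mandatory keys of a coagulant run: Pa/Pb/Pd/Pe per time point plus Pc.

    With the standard four time points this yields 17 values per microspot.
    """
    keys = [timepoint_key(p, t) for p in ("Pa", "Pb", "Pd", "Pe") for t in timepoints]
    keys.append("Pc")
    return keys


@dataclass
class KineticSeries:
    """%SAC vs time for one fibrin channel, sampled on the 45 s grid."""

    times_min: np.ndarray
    sac_percent: np.ndarray
    fibrin_threshold: float = DEFAULT_FIBRIN_THRESHOLD
    duration_min: float = 10.0

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.sac_percent = np.asarray(self.sac_percent, dtype=float)
        if self.times_min.size == 0 or self.times_min.shape != self.sac_percent.shape:
            raise ValueError("times and values must be nonempty arrays of equal length")
        if np.any(np.diff(self.times_min) <= 0):
            raise ValueError("sample times must be strictly increasing")
        if self.sac_percent.min() < 0 or self.sac_percent.max() > 100:
            raise ValueError("%SAC values must lie in [0, 100]")
        if self.fibrin_threshold < 0:
            raise ValueError("fibrin_threshold must be >= 0")


class FibrinOnset(NamedTuple):
    t_first_min: float
    pc: float  # -log(minutes); the heatmap-ready parameter value
    censored: bool


def validate_score(param: ParameterDef, value: float,
                   increment: float = ORDINAL_INCREMENT) -> float:
    """Validate a manual ordinal score and snap it to the allowed increment.

    Scores must lie within ``[0, scale_max]``; values are rounded to the
    nearest multiple of ``increment`` (0.5 by default, matching half-point
    manual grading).  Out-of-range values raise with the parameter id and
    its bounds in the message.
    """
    if param.kind != "ordinal_score":
        raise ValueError(f"{param.id} is not an ordinal score parameter")
    if not np.isfinite(value):
        raise ValueError(f"{param.id} score must be finite")
    param.check_value(value)
    snapped = round(value / increment) * increment
    return float(min(snapped, param.scale_max))


def time_to_first_fibrin(
    series: KineticSeries,
    log_base: float = 10.0,
    interpolate: bool = False,
) -> FibrinOnset:
    """Earliest time the fibrin %SAC exceeds the labeling threshold.

    Returns the onset time in minutes, its ``-log`` transform (base 10 by
    default) as the heatmap parameter Pc, and a censoring flag.  Runs that
    never cross the threshold within the observation window are censored
    at ``duration_min`` so that Pc stays finite and ranks below every
    observed event (a 10-min window gives Pc = -1 for censored runs).

    With ``interpolate=True`` the crossing time is linearly interpolated
    between the last sub-threshold and the first supra-threshold sample
    instead of being reported on the 45 s grid.
    """
    # only samples at t > 0 can register an onset: the time-zero frame is
    # pre-perfusion background and -log(0) is undefined
    above = (series.sac_percent > series.fibrin_threshold) & (series.times_min > 0)
    idx = np.flatnonzero(above)
    if idx.size == 0:
        t_first = float(series.duration_min)
        censored = True
    else:
        i = int(idx[0])
        t_first = float(series.times_min[i])
        if interpolate and i > 0:
            t0, t1 = series.times_min[i - 1], series.times_min[i]
            v0, v1 = series.sac_percent[i - 1], series.sac_percent[i]
            t_first = float(t0 + (series.fibrin_threshold - v0) / (v1 - v0) * (t1 - t0))
        censored = False
    if t_first <= 0:
        raise ValueError("fibrin onset at non-positive time; first sample should be > 0")
    pc = -float(np.log(t_first) / np.log(log_base))
    return FibrinOnset(t_first, pc, censored)


def fibrin_rate(series: KineticSeries,
                window: tuple[float, float] = DEFAULT_SLOPE_WINDOW) -> float:
    """Fibrin formation rate: OLS slope of %SAC on time over the steepest part.

    The window endpoints (1.5 and 3.75 min by default) are inclusive; both
    lie on the 45 s sampling grid.  Requires at least two in-window samples.
    """
    lo, hi = window
    sel = (series.times_min >= lo) & (series.times_min <= hi)
    if np.count_nonzero(sel) < 2:
        raise ValueError(
            f"need >= 2 samples in the slope window [{lo}, {hi}] min, "
            f"got {int(np.count_nonzero(sel))}"
        )
    t = series.times_min[sel]
    y = series.sac_percent[sel]
    if np.allclose(y, y[0]):
        return 0.0
    return float(stats.linregress(t, y).slope)


@dataclass
class FlowRunProfile:
    """One flow run's parameter vector for one microspot."""

    run_id: str
    group_label: str
    values: dict = field(default_factory=dict)
    microspot: str = "single"  # Ma | Mb | single
    age_group: str | None = None
    timepoints_min: tuple = ()


def build_profile(
    run_id: str,
    group_label: str,
    measurements: Mapping[str, Sequence[float] | Sequence[SacValue]],
    kinetic_series: Mapping[str, KineticSeries] | None = None,
    required: Sequence[str] | None = None,
    microspot: str = "single",
    age_group: str | None = None,
    timepoints_min: Sequence[float] = (),
    fibrin_log_base: float = 10.0,
) -> FlowRunProfile:
    """Assemble a run profile from per-image values, scores and kinetics.

    ``measurements`` maps profile keys (``"P2"`` or ``"Pa_t4"``) to the
    per-image values of that parameter; each list is averaged into a single
    per-run value.  Ordinal raw scores are validated against their scale
    before averaging (the averages themselves are unconstrained, so e.g. a
    mean score of 2.17 is legal).  ``kinetic_series`` supplies the fibrin
    curve(s) from which Pc is computed.  Missing optional parameters are
    simply absent; missing *required* parameters raise an error listing
    every missing id.  Values are never imputed.
    """
    values: dict[str, float] = {}
    for key, raw in measurements.items():
        pdef = base_param(key)
        if pdef.kind == "ordinal_score":
            validated = [validate_score(pdef, float(v)) for v in raw]
            values[key] = average_run(validated)
        else:
            avg = average_run(list(raw))
            pdef.check_value(avg)
            values[key] = avg

    for key, series in (kinetic_series or {}).items():
        pdef = base_param(key)
        if pdef.kind != "neg_log_minutes":
            raise ValueError(f"{key} is not a kinetic-onset parameter")
        values[key] = time_to_first_fibrin(series, log_base=fibrin_log_base).pc

    if required is not None:
        missing = [k for k in required if k not in values]
        if missing:
            raise ValueError(f"missing mandatory parameters: {', '.join(missing)}")

    return FlowRunProfile(
        run_id=run_id,
        group_label=group_label,
        values=values,
        microspot=microspot,
        age_group=age_group,
        timepoints_min=tuple(timepoints_min),
    )
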