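"""Static-respirometry processing: chamber O2 traces to metabolic rates.

A sealed chamber containing one fish (or none, for the background control)
logs dissolved oxygen [mg L^-1] and temperature [degC] once per minute.
Processing follows the classic static protocol:

1. discard an acclimation period after sealing (default 30 min),
2. fit an ordinary least-squares line to dissolved O2 over the next
   analysis window (default 120 min) to get a volumetric depletion slope,
3. subtract the control chamber's slope (background respiration),
4. multiply by the net water volume (chamber minus fish, assuming tissue
   density 1000 kg m^-3) to obtain a whole-organism rate [mg O2 h^-1],
5. convert to J h^-1 (1.429 g O2 per L of gas, 20.1 J per mL O2) and flag
   runs whose regression had r^2 < 0.8 as failing quality control.

Raw slopes keep their sign (depletion is negative); whole-organism
consumption rates are reported positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .constants import J_PER_MG_O2, R2_QC_THRESHOLD


class InsufficientDurationError(ValueError):
    """Trace too short for the requested acclimation + analysis window."""


@dataclass(frozen=True)
class OxygenTrace:
    """Timed dissolved-oxygen/temperature series for one chamber.

    ``fish_id is None`` marks the fish-free background control.
    Timestamps are minutes since the chamber was sealed.
    """

    chamber_id: str
    fish_id: str | None
    timestamps: np.ndarray
    do_mgL: np.ndarray
    temp_C: np.ndarray

    def __post_init__(self):
        for name in ("timestamps", "do_mgL", "temp_C"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (len(self.timestamps) == len(self.do_mgL) == len(self.temp_C)):
            raise ValueError("timestamps, do_mgL and temp_C must have equal length")
        if len(self.timestamps) > 1 and np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if np.any(self.do_mgL < 0):
            raise ValueError("dissolved oxygen cannot be negative")

    @property
    def is_control(self) -> bool:
        return self.fish_id is None

    @property
    def duration_min(self) -> float:
        return float(self.timestamps[-1] - self.timestamps[0])


@dataclass(frozen=True)
class ChamberSpec:
    """Chamber geometry and the fish it holds.

    Fish volume follows from mass at an assumed tissue density of
    1000 kg m^-3, i.e. 1 g of fish displaces 1 mL.
    """

    volume_L: float = 7.2
    fish_mass_mg: float = 0.0
    fish_density_kg_m3: float = 1000.0

    @property
    def fish_volume_L(self) -> float:
        # mass[mg] * 1e-6 kg/mg / density[kg/m3] * 1e3 L/m3
        return self.fish_mass_mg * 1e-6 / self.fish_density_kg_m3 * 1e3

    @property
    def net_volume_L(self) -> float:
        return self.volume_L - self.fish_volume_L


@dataclass(frozen=True)
class SlopeResult:
    """OLS slope of dissolved O2 against time, in mg L^-1 h^-1."""

    slope_mgL_per_h: float
    r2: float
    window: tuple[float, float]
    n_points: int
    comparable: bool = True  # False when a correction mixed windows


@dataclass(frozen=True)
class MetabolicRate:
    """Whole-organism routine metabolic rate for one fish."""

    fish_id: str
    rate_mgO2_per_h: float
    rate_J_per_h: float
    mean_temp_C: float
    r2: float
    qc_pass: bool


def trim_acclimation(
    trace: OxygenTrace, skip_min: float = 30.0, keep_min: float = 120.0
) -> OxygenTrace:
    """Drop the acclimation period and truncate to the analysis window.

    Keeps the points with timestamps in ``(skip_min, skip_min + keep_min]``.
    The input trace is never modified.

    Raises
    ------
    InsufficientDurationError
        If the trace does not span ``skip_min + keep_min`` minutes; the
        message names the missing duration.
    """
    needed = skip_min + keep_min
    have = float(trace.timestamps[-1]) if len(trace.timestamps) else 0.0
    if have < needed:
        raise InsufficientDurationError(
            f"trace {trace.chamber_id} spans {have:g} min but "
            f"{needed:g} min are required (short by {needed - have:g} min)"
        )
    mask = (trace.timestamps > skip_min) & (trace.timestamps <= skip_min + keep_min)
    return replace(
        trace,
        timestamps=trace.timestamps[mask],
        do_mgL=trace.do_mgL[mask],
        temp_C=trace.temp_C[mask],
    )


def fit_o2_slope(trace: OxygenTrace) -> SlopeResult:
    """Least-squares volumetric O2 slope [mg L^-1 h^-1] with r^2.

    Time is converted from minutes to hours before the regression. A
    response with zero variance (constant O2) yields slope 0 and r^2 0.
    """
    if len(trace.timestamps) < 3:
        raise ValueError("need at least 3 points to fit a slope")
    t_h = trace.timestamps / 60.0
    if np.ptp(t_h) == 0:
        raise ValueError("singular design: all timestamps identical")
    if np.ptp(trace.do_mgL) == 0:
        slope, r2 = 0.0, 0.0
    else:
        res = stats.linregress(t_h, trace.do_mgL)
        slope, r2 = float(res.slope), float(res.rvalue**2)
    return SlopeResult(
        slope_mgL_per_h=slope,
        r2=r2,
        window=(float(trace.timestamps[0]), float(trace.timestamps[-1])),
        n_points=len(trace.timestamps),
    )


def background_correct(fish_slope: SlopeResult, control_slope: SlopeResult) -> SlopeResult:
    """Subtract the control chamber's volumetric slope from a fish slope.

    The r^2 and window of the fish regression are retained; if the two
    slopes were fitted over different windows the result is flagged
    non-comparable and a warning is emitted.
    """
    comparable = fish_slope.window == control_slope.window
    if not comparable:
        warnings.warn(
            "fish and control slopes were fitted over different windows "
            f"({fish_slope.window} vs {control_slope.window}); "
            "background correction may not be comparable",
            stacklevel=2,
        )
    return replace(
        fish_slope,
        slope_mgL_per_h=fish_slope.slope_mgL_per_h - control_slope.slope_mgL_per_h,
        comparable=comparable,
    )


def whole_organism_rate(
    corrected: SlopeResult,
    spec: ChamberSpec,
    fish_id: str = "",
    mean_temp_C: float = float("nan"),
) -> MetabolicRate:
    """Scale a background-corrected volumetric slope to a whole-organism rate.

    ``rate = -slope * (chamber volume - fish volume)`` so that oxygen
    consumption comes out positive, then converted to J h^-1 via the
    oxycaloric constants. ``qc_pass`` is True iff r^2 >= 0.8.
    """
    if not np.isfinite(corrected.slope_mgL_per_h):
        raise ValueError("corrected slope must be finite")
    net_vol = spec.net_volume_L
    if net_vol <= 0:
        raise ValueError(
            f"fish volume ({spec.fish_volume_L:g} L) is not smaller than "
            f"the chamber ({spec.volume_L:g} L)"
        )
    rate_mg = -corrected.slope_mgL_per_h * net_vol
    return MetabolicRate(
        fish_id=fish_id,
        rate_mgO2_per_h=rate_mg,
        rate_J_per_h=rate_mg * J_PER_MG_O2,
        mean_temp_C=mean_temp_C,
        r2=corrected.r2,
        qc_pass=corrected.r2 >= R2_QC_THRESHOLD,
    )


@dataclass
class RunResult:
    """Outcome of processing one respirometry run."""

    rates: list[MetabolicRate] = field(default_factory=list)
    n_excluded: int = 0
    excluded_ids: list[str] = field(default_factory=list)


def process_run(
    traces: list[OxygenTrace],
    specs: dict[str, ChamberSpec],
    skip_min: float = 30.0,
    keep_min: float = 120.0,
) -> RunResult:
    """Process one run: trim, fit, background-correct and QC every fish chamber.

    Exactly one control trace (``fish_id is None``) must be present; its
    slope over the same window is subtracted from every fish slope.
    ``specs`` maps fish_id to :class:`ChamberSpec`. All records, passing or
    not, are returned; ``n_excluded`` counts the QC failures.
    """
    controls = [t for t in traces if t.is_control]
    if len(controls) != 1:
        raise ValueError(f"expected exactly one control trace, found {len(controls)}")
    control_slope = fit_o2_slope(trim_acclimation(controls[0], skip_min, keep_min))

    result = RunResult()
    for trace in traces:
        if trace.is_control:
            continue
        trimmed = trim_acclimation(trace, skip_min, keep_min)
        corrected = background_correct(fit_o2_slope(trimmed), control_slope)
        rate = whole_organism_rate(
            corrected,
            specs[trace.fish_id],
            fish_id=trace.fish_id,
            mean_temp_C=float(np.mean(trimmed.temp_C)),
        )
        result.rates.append(rate)
        if not rate.qc_pass:
            result.n_excluded += 1
            result.excluded_ids.append(trace.fish_id)
    return result
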