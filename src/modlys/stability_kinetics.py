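"""Assay-side statistics: degree of modification, inactivation kinetics,
and activity-profile summaries.

Thermal inactivation is modeled as a first-order decay: an unweighted OLS
line through ln(activity) vs time gives the inactivation constant
kd = −slope (reported positive), half-life ln(2)/kd, and the stabilization
ratio R = t½(modified)/t½(control).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = [
    "StandardCurve",
    "DMResult",
    "DecaySeries",
    "InactivationFit",
    "StabilityRatio",
    "ProfileSummary",
    "fit_standard_curve",
    "degree_of_modification",
    "fit_inactivation",
    "half_life",
    "stability_ratio",
    "profile_summary",
    "residual_activity",
]


@dataclass
class StandardCurve:
    slope: float       # absorbance per mM lysine
    intercept: float
    r_squared: float


@dataclass
class DMResult:
    c_sample: float
    c_control: float
    dm_percent: float
    clamped: bool = False


@dataclass
class DecaySeries:
    times: np.ndarray          # minutes
    activities: np.ndarray     # same units throughout
    temperature: str = ""

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.activities = np.asarray(self.activities, dtype=float)
        if self.times.shape != self.activities.shape:
            raise ValueError("times/activities length mismatch")
        if not np.isfinite(self.times).all():
            raise ValueError("non-finite time values")
        if (self.activities < 0).any():
            raise ValueError("activities must be non-negative")


@dataclass
class InactivationFit:
    kd: float                  # min^-1, positive when decay is present
    ln_A0: float
    r_squared: float
    n_used: int
    t_half: float              # minutes; inf when no decay
    se_kd: float = math.nan
    no_decay: bool = False


@dataclass
class StabilityRatio:
    t_half_modified: float
    t_half_control: float
    R: float


@dataclass
class ProfileSummary:
    optimum_condition: object
    activity_at_optimum: float
    condition_labels: list = field(default_factory=list)
    normalized_profile: list = field(default_factory=list)  # max = 100


def fit_standard_curve(concentrations, absorbances) -> StandardCurve:
    """OLS line absorbance = slope·concentration + intercept."""
    conc = np.asarray(concentrations, dtype=float)
    absb = np.asarray(absorbances, dtype=float)
    if conc.size != absb.size:
        raise ValueError("length mismatch")
    if conc.size < 3:
        raise ValueError("need at least 3 points")
    if np.unique(conc).size < 2:
        raise ValueError("degenerate design: need ≥2 distinct concentrations")
    res = stats.linregress(conc, absb)
    r2 = float(res.rvalue**2) if math.isfinite(res.rvalue) else 1.0
    return StandardCurve(float(res.slope), float(res.intercept), r2)


def degree_of_modification(c_sample: float, c_control: float) -> DMResult:
    """Percent of amino groups modified: 100·(1 − c_sample/c_control).

    Clamped to [0, 100]; c_sample ≥ c_control yields 0% with a flag.
    """
    if c_control <= 0:
        raise ValueError("control concentration must be positive")
    if c_sample < 0:
        raise ValueError("sample concentration must be non-negative")
    raw = 100.0 * (1.0 - c_sample / c_control)
    clamped = raw < 0
    return DMResult(c_sample, c_control, max(0.0, raw), clamped=clamped)


def fit_inactivation(series: DecaySeries, nonlinear: bool = False) -> InactivationFit:
    """First-order inactivation fit on ln(activity) vs time.

    Non-positive activities cannot enter the log fit and are excluded with
    a warning (the retained count is reported in ``n_used``).  A
    non-negative slope is flagged as no-decay with infinite half-life.
    With ``nonlinear=True`` the log-linear estimate is refined by a direct
    least-squares fit of A0·exp(−kd·t) for sensitivity analysis.
    """
    mask = series.activities > 0
    n_excluded = int((~mask).sum())
    if n_excluded:
        warnings.warn(
            f"excluded {n_excluded} non-positive activity point(s) from log fit",
            stacklevel=2,
        )
    t = series.times[mask]
    a = series.activities[mask]
    if t.size < 2:
        raise ValueError("need at least 2 strictly positive activity points")

    if np.unique(t).size < 2:
        raise ValueError("need at least 2 distinct time points")
    res = stats.linregress(t, np.log(a))
    slope, intercept = float(res.slope), float(res.intercept)
    se = float(res.stderr) if res.stderr is not None else math.nan
    r2 = float(res.rvalue**2) if math.isfinite(res.rvalue) else 0.0

    if nonlinear and slope < 0:
        def model(tt, a0, kd):
            return a0 * np.exp(-kd * tt)

        try:
            popt, pcov = optimize.curve_fit(
                model, t, a, p0=(math.exp(intercept), -slope), maxfev=10000
            )
            slope = -float(popt[1])
            intercept = math.log(float(popt[0]))
            se = float(math.sqrt(pcov[1, 1]))
            ss_res = float(((a - model(t, *popt)) ** 2).sum())
            ss_tot = float(((a - a.mean()) ** 2).sum())
            r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        except RuntimeError:
            warnings.warn("nonlinear refinement failed; keeping log-linear fit",
                          stacklevel=2)

    kd = -slope
    if kd <= 0:
        return InactivationFit(
            kd=kd, ln_A0=intercept, r_squared=r2, n_used=int(t.size),
            t_half=math.inf, se_kd=se, no_decay=True,
        )
    return InactivationFit(
        kd=kd, ln_A0=intercept, r_squared=r2, n_used=int(t.size),
        t_half=half_life(kd), se_kd=se,
    )


def half_life(kd: float) -> float:
    """Half-life ln(2)/kd in minutes."""
    if kd <= 0:
        raise ValueError("kd must be positive")
    return math.log(2.0) / kd


def stability_ratio(kd_modified: float, kd_control: float) -> StabilityRatio:
    """Half-life ratio R = t½(modified)/t½(control) = kd_control/kd_modified."""
    if kd_modified <= 0 or kd_control <= 0:
        raise ValueError("rate constants must be positive")
    return StabilityRatio(
        t_half_modified=half_life(kd_modified),
        t_half_control=half_life(kd_control),
        R=kd_control / kd_modified,
    )


def profile_summary(table) -> ProfileSummary:
    """Optimum condition of an activity profile, normalized to 100% at max.

    Ties at the maximum resolve toward the condition closest to the median
    of the numeric condition grid, then to the lower label.
    """
    labels = list(table.condition_labels)
    acts = np.asarray(table.activities, dtype=float)
    if len(labels) < 2:
        raise ValueError("need at least 2 conditions")
    if not (acts > 0).any():
        raise ValueError("all activities are zero")
    peak = float(acts.max())
    tied = [i for i, a in enumerate(acts) if a == peak]
    if len(tied) == 1:
        best = tied[0]
    else:
        numeric = [x for x in labels if isinstance(x, (int, float))]
        if numeric and all(isinstance(labels[i], (int, float)) for i in tied):
            median = float(np.median(numeric))
            best = min(tied, key=lambda i: (abs(labels[i] - median), labels[i]))
        else:
            best = min(tied, key=lambda i: str(labels[i]))
    return ProfileSummary(
        optimum_condition=labels[best],
        activity_at_optimum=peak,
        condition_labels=labels,
        normalized_profile=[float(a) / peak * 100.0 for a in acts],
    )


def residual_activity(table, reference_condition):
    """Rescale activities to percent of the reference condition's activity."""
    from .structure_io import AssayTable  # local import to avoid cycle at load

    labels = list(table.condition_labels)
    try:
        idx = labels.index(reference_condition)
    except ValueError as exc:
        raise ValueError(
            f"reference condition {reference_condition!r} not found"
        ) from exc
    ref = float(table.activities[idx])
    if ref <= 0:
        raise ValueError("reference activity must be positive")
    return AssayTable(
        labels,
        [float(a) / ref * 100.0 for a in table.activities],
        metadata=f"% of activity at {reference_condition!r}",
    )
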