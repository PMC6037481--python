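"""First-order cleavage kinetics.

The cleaved fraction of a hairpin substrate follows the one-phase decay
f(t) = 1 - exp(-k_obs * t) with the plateau fixed at complete cleavage.
When less than 10% of the substrate is cleaved over the whole course the
substrate concentration is effectively constant and the initial-rate
(linear) regime f = k_obs * t is fitted instead, through the origin.
Reported uncertainty is the standard error of the fitted rate (square
root of the covariance diagonal).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
import numpy as np
from scipy.optimize import curve_fit

from .sequences import TimeCourse

LINEAR_REGIME_MAX_FRACTION = 0.10


@dataclass(frozen=True)
class KineticsFit:
    """Fitted observed rate constant.

    ``model`` records which branch produced the rate: "one_phase"
    (f = 1 - exp(-k t), optionally with a floating plateau) or "linear"
    (f = k t, engaged when max observed fraction < 10%).
    """

    k_obs: float          # s^-1
    stderr: float         # s^-1
    model: str
    max_fraction: float
    n_points: int
    plateau: float = 1.0


@dataclass(frozen=True)
class FoldDifference:
    """Ratio of two fitted rates with first-order error propagation.

    ``detection_limited`` flags a zero denominator (the slower reaction
    was below the detection limit); ``ratio`` is then +inf.
    """

    ratio: float
    stderr: float
    detection_limited: bool = False


def _linear_fit(times: np.ndarray, fractions: np.ndarray) -> tuple[float, float]:
    """Least-squares slope of f = k t through the origin, with SE."""
    ss_tt = float(np.sum(times * times))
    if ss_tt == 0:
        return 0.0, 0.0
    k = float(np.sum(fractions * times)) / ss_tt
    resid = fractions - k * times
    dof = max(len(times) - 1, 1)
    se = math.sqrt(float(np.sum(resid**2)) / dof / ss_tt)
    return k, se


def fit_kobs(tc: TimeCourse, floating_plateau: bool = False) -> KineticsFit:
    """Fit k_obs from a cleavage time course.

    Requires >= 3 points.  All-zero fractions return k_obs = 0 with a
    warning; non-convergence of the nonlinear fit is a hard error.
    Deterministic given the data.
    """
    if len(tc) < 3:
        raise ValueError(f"need at least 3 points to fit, got {len(tc)}")
    t = tc.times
    f = tc.fractions
    max_fraction = float(np.max(f))
    n = len(tc)

    if max_fraction == 0.0:
        warnings.warn("all cleaved fractions are zero; k_obs set to 0", stacklevel=2)
        return KineticsFit(0.0, 0.0, "linear", 0.0, n)

    if max_fraction < LINEAR_REGIME_MAX_FRACTION:
        k, se = _linear_fit(t, f)
        return KineticsFit(max(k, 0.0), se, "linear", max_fraction, n)

    # initial guess from the linear regime of the first half of the course
    half = max(3, n // 2)
    k0, _ = _linear_fit(t[:half], f[:half])
    if k0 <= 0:
        k0 = 1.0 / max(t[-1], 1.0)

    try:
        if floating_plateau:
            popt, pcov = curve_fit(
                lambda tt, k, a: a * (1.0 - np.exp(-k * tt)),
                t,
                f,
                p0=[k0, max(max_fraction, 0.5)],
                bounds=([0.0, 0.0], [np.inf, 1.5]),
                maxfev=10000,
            )
            k, plateau = float(popt[0]), float(popt[1])
        else:
            popt, pcov = curve_fit(
                lambda tt, k: 1.0 - np.exp(-k * tt),
                t,
                f,
                p0=[k0],
                bounds=(0.0, np.inf),
                maxfev=10000,
            )
            k, plateau = float(popt[0]), 1.0
    except RuntimeError as err:
        raise RuntimeError(
            f"one-phase fit failed to converge (n={n}, max_fraction={max_fraction:.3f}, "
            f"k0={k0:.3g}): {err}"
        ) from err
    se = float(np.sqrt(pcov[0, 0]))
    return KineticsFit(k, se, "one_phase", max_fraction, n, plateau)


def fold_difference(a: KineticsFit, b: KineticsFit) -> FoldDifference:
    """a.k_obs / b.k_obs with propagated relative uncertainty.

    A zero denominator mirrors a below-detection-limit reaction and is
    reported as a sentinel rather than an error.
    """
    if b.k_obs == 0:
        return FoldDifference(math.inf, math.nan, detection_limited=True)
    ratio = a.k_obs / b.k_obs
    rel = 0.0
    if a.k_obs > 0:
        rel = math.sqrt((a.stderr / a.k_obs) ** 2 + (b.stderr / b.k_obs) ** 2)
    return FoldDifference(ratio, ratio * rel)


__all__ = [
    "KineticsFit",
    "FoldDifference",
    "fit_kobs",
    "fold_difference",
    "LINEAR_REGIME_MAX_FRACTION",
]
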