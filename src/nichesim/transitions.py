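"""Two-state CTMC estimation of EMT/MET interconversion rates.

Breast cancer stem cells interconvert between a mesenchymal (EMT-like,
CD44+/CD24-, quiescent) state and an epithelial (MET-like, ALDH+,
proliferative) state.  Modeling the switch as a reversible two-state
continuous-time Markov chain, the stationary distribution and the
transition rates are tied by detailed balance,

    pi_1 * lambda_12 = pi_2 * lambda_21,

with state 1 = EMT (mesenchymal) and state 2 = MET (epithelial) throughout
this module.  ``lambda_met`` is the rate OF the mesenchymal-to-epithelial
transition and ``lambda_emt`` the rate of the reverse, so the epithelial
occupancy is ``pi_met = lambda_met / (lambda_emt + lambda_met)``.

Equilibria are estimated from marker frequencies (mesenchymal numerator vs
epithelial term); rates are completed from one measured rate via detailed
balance, or bounded by fitting an exponential to a decaying (or rising)
mesenchymal-marker expression series such as vimentin.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

#: Dedifferentiation benchmark from induced-pluripotency experiments:
#: fibroblasts reprogrammed over a 28-day culture with ~1% success.  The
#: source reports this as ~0.0036 cell^-1 day^-1, although 0.01/28 evaluates
#: to ~0.00036 — an apparent order-of-magnitude slip.  The printed constant
#: is stored verbatim; either value sits well over an order of magnitude
#: below the 0.02-0.08 day^-1 EMT/MET interconversion rates, which is the
#: comparison that matters.
DEDIFFERENTIATION_RATE = 0.0036


class EstimationError(ValueError):
    """The requested estimate is undefined for the given inputs."""


@dataclass(frozen=True)
class EquilibriumDistribution:
    """Stationary occupancy of the two BCSC states (fractions sum to 1)."""

    pi_emt: float
    pi_met: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.pi_emt <= 1.0 and 0.0 <= self.pi_met <= 1.0):
            raise EstimationError("occupancies must lie in [0, 1]")
        if abs(self.pi_emt + self.pi_met - 1.0) > 1e-9:
            raise EstimationError("occupancies must sum to 1")


@dataclass(frozen=True)
class TransitionRates:
    """Interconversion rates (cell^-1 day^-1), both strictly positive."""

    lambda_emt: float  # epithelial -> mesenchymal
    lambda_met: float  # mesenchymal -> epithelial

    def __post_init__(self) -> None:
        if self.lambda_emt <= 0 or self.lambda_met <= 0:
            raise EstimationError("transition rates must be positive")


@dataclass
class MarkerSeries:
    """A marker-expression time series (days, positive arbitrary units)."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")


def equilibrium_from_marker_fractions(
    f_mesenchymal: float, f_epithelial: float
) -> EquilibriumDistribution:
    """Occupancy from marker frequencies.

    ``pi_emt = f_mes / (f_mes + f_epi)``: e.g. the luminal-line scenario
    with 0.8% CD44+/CD24- and 0.3% ALDH+ gives pi_emt ~ 0.73, while 1%
    tumor-initiating vs 4% ALDH+ gives pi_emt = 0.2.
    """
    if f_mesenchymal < 0 or f_epithelial < 0:
        raise EstimationError("marker fractions must be non-negative")
    tot = f_mesenchymal + f_epithelial
    if tot <= 0:
        raise EstimationError("both marker fractions are zero")
    pi_emt = f_mesenchymal / tot
    return EquilibriumDistribution(pi_emt=pi_emt, pi_met=1.0 - pi_emt)


def met_fraction_from_rates(rates: TransitionRates) -> float:
    """Epithelial occupancy ``lambda_met / (lambda_emt + lambda_met)``."""
    return rates.lambda_met / (rates.lambda_emt + rates.lambda_met)


def complete_rates(
    eq: EquilibriumDistribution,
    lambda_met: float | None = None,
    lambda_emt: float | None = None,
) -> TransitionRates:
    """Complete the chain from one known rate via detailed balance.

    Detailed balance at stationarity reads
    ``pi_emt * lambda_met = pi_met * lambda_emt``, so either rate
    determines the other given the equilibrium.
    """
    if (lambda_met is None) == (lambda_emt is None):
        raise EstimationError("provide exactly one of lambda_met / lambda_emt")
    if eq.pi_emt <= 0 or eq.pi_met <= 0:
        raise EstimationError("degenerate chain: an occupancy is zero")
    if lambda_met is not None:
        return TransitionRates(
            lambda_emt=lambda_met * eq.pi_emt / eq.pi_met, lambda_met=lambda_met
        )
    return TransitionRates(
        lambda_emt=lambda_emt, lambda_met=lambda_emt * eq.pi_met / eq.pi_emt
    )


@dataclass(frozen=True)
class RateFit:
    """An exponential-rate estimate with its standard error."""

    rate: float
    stderr: float
    direction: str
    intercept: float
    n: int


def fit_exponential_rate(
    series: MarkerSeries,
    direction: Literal["decay", "rise"] = "decay",
    nonlinear: bool = False,
) -> RateFit:
    """Exponential rate of a marker series, as a transition-rate estimate.

    The default estimator is log-linear ordinary least squares: the slope
    of ``log(value)`` against time, negated for ``direction="decay"`` so
    the returned rate is non-negative for data that actually decay.  A
    declining vimentin series fitted this way bounds the mesenchymal-to-
    epithelial conversion rate from above.  ``nonlinear=True`` refits
    ``A * exp(s t)`` by nonlinear least squares starting from the
    log-linear solution.
    """
    if direction not in ("decay", "rise"):
        raise ValueError("direction must be 'decay' or 'rise'")
    t, v = series.times, series.values
    if len(t) < 3:
        raise EstimationError("need at least 3 points to fit a rate")
    if np.any(v <= 0):
        raise EstimationError("marker values must be positive")
    from scipy import stats

    res = stats.linregress(t, np.log(v))
    slope, stderr, intercept = res.slope, res.stderr, res.intercept
    if nonlinear:
        from scipy.optimize import curve_fit

        popt, pcov = curve_fit(
            lambda tt, a, s: a * np.exp(s * tt),
            t, v, p0=[np.exp(intercept), slope], maxfev=10000,
        )
        intercept, slope = np.log(popt[0]), popt[1]
        stderr = float(np.sqrt(pcov[1, 1]))
    sign = -1.0 if direction == "decay" else 1.0
    return RateFit(
        rate=sign * slope,
        stderr=float(stderr),
        direction=direction,
        intercept=float(intercept),
        n=len(t),
    )


def round_rate(rate: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (reporting convention)."""
    if rate == 0:
        return 0.0
    from math import floor, log10

    return round(rate, -int(floor(log10(abs(rate)))) + sig - 1)
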