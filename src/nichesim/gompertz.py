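"""Gompertz growth law: evaluation and nonlinear least-squares fitting.

The Gompertz law used for bulk tumor growth is

    N(t) = N0 * exp[(A0 / c) * (1 - exp(-c t))],

where ``A0`` is the initial specific growth rate (day^-1), ``c`` the
proportional rate at which that specific growth rate decays (day^-1), and
``N0`` the initial population.  The specific growth rate is
``(1/N) dN/dt = A0 exp(-c t)``, so growth decelerates continuously and the
population approaches the asymptote ``K = N0 exp(A0 / c)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class FitError(RuntimeError):
    """The Gompertz fit failed to converge or the input is degenerate."""


@dataclass(frozen=True)
class GompertzParams:
    """(A0, c, N0); the asymptote K = N0 exp(A0/c) is derived."""

    a0: float
    c_decay: float
    n0: float

    def __post_init__(self) -> None:
        if self.a0 <= 0 or self.c_decay <= 0:
            raise ValueError("A0 and c must be positive")
        if self.n0 < 1:
            raise ValueError("N0 must be at least 1")

    @property
    def asymptote(self) -> float:
        # a0/c can exceed the float exponent range for steep short-run
        # fits; the asymptote is then legitimately infinite
        with np.errstate(over="ignore"):
            return self.n0 * float(np.exp(self.a0 / self.c_decay))


@dataclass(frozen=True)
class GompertzFit:
    params: GompertzParams
    r_squared: float
    ci: dict[str, tuple[float, float]]  # 95% CIs keyed a0 / c_decay / n0
    stderr: dict[str, float]

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise FitError("R^2 outside [0, 1]")


def gompertz_value(params: GompertzParams, t) -> np.ndarray | float:
    """N(t) = N0 exp[(A0/c)(1 - e^{-c t})] for t >= 0 (days)."""
    t = np.asarray(t, dtype=float)
    out = params.n0 * np.exp(
        (params.a0 / params.c_decay) * (1.0 - np.exp(-params.c_decay * t))
    )
    return float(out) if out.ndim == 0 else out


def inflection_time(params: GompertzParams) -> float:
    """Time of the inflection, where N = K/e: t* = ln(A0/c)/c."""
    return float(np.log(params.a0 / params.c_decay) / params.c_decay)


# the parameter region explored when fitting tumor-growth trajectories;
# multi-start initializations are drawn from this grid.
A0_RANGE = (0.02, 0.04)
C_RANGE = (0.001, 0.002)


def fit_gompertz(
    times,
    totals,
    fix_n0: float | None = None,
    n_starts: int = 4,
) -> GompertzFit:
    """Least-squares Gompertz fit to a total-population trajectory.

    Fits ``(A0, c, N0)`` — or ``(A0, c)`` with ``N0`` fixed — by nonlinear
    least squares on untransformed counts, multi-started on a small
    ``A0 x c`` grid spanning the plausible tumor-growth region plus a
    heuristic initialization derived from the data.  Confidence intervals
    are asymptotic (from the parameter covariance); R^2 is computed on the
    supplied points.
    """
    from scipy.optimize import curve_fit

    t = np.asarray(times, dtype=float)
    y = np.asarray(totals, dtype=float)
    if t.ndim != 1 or t.shape != y.shape:
        raise ValueError("times and totals must be equal-length 1-D arrays")
    if len(t) < 5:
        raise FitError("need at least 5 points for a Gompertz fit")
    if not np.all(np.diff(t) > 0):
        raise FitError("times must be strictly increasing")
    if np.ptp(y) <= 0:
        raise FitError("degenerate (flat) trajectory")

    # heuristic start: asymptote from the last points, c from the implied
    # e-folding of the remaining log-growth.
    n0_guess = max(float(fix_n0 if fix_n0 is not None else y[0]), 1.0)
    k_guess = max(float(y[-1]), n0_guess * 1.5)
    span = max(np.log(k_guess / n0_guess), 0.1)
    c_guess = min(max(2.0 / (t[-1] - t[0]), C_RANGE[0]), 0.1)
    starts = [(c_guess * span, c_guess)]
    for a0 in np.linspace(*A0_RANGE, max(n_starts // 2, 2)):
        for cc in np.linspace(*C_RANGE, max(n_starts // 2, 2)):
            starts.append((a0, cc))

    if fix_n0 is None:
        def model(tt, a0, cc, n0):
            return n0 * np.exp((a0 / cc) * (1.0 - np.exp(-cc * tt)))

        p0_extra, bounds = [n0_guess], ([1e-12, 1e-12, 1.0], [np.inf] * 3)
        names = ["a0", "c_decay", "n0"]
    else:
        def model(tt, a0, cc):
            return fix_n0 * np.exp((a0 / cc) * (1.0 - np.exp(-cc * tt)))

        p0_extra, bounds = [], ([1e-12, 1e-12], [np.inf, np.inf])
        names = ["a0", "c_decay"]

    best = None
    last_err: Exception | None = None
    for a0, cc in starts:
        try:
            popt, pcov = curve_fit(
                model, t, y, p0=[a0, cc, *p0_extra], bounds=bounds,
                maxfev=20000, x_scale=[1e-2, 1e-3, *([n0_guess] if fix_n0 is None else [])],
            )
        except (RuntimeError, ValueError) as exc:
            last_err = exc
            continue
        sse = float(np.sum((model(t, *popt) - y) ** 2))
        if best is None or sse < best[0]:
            best = (sse, popt, pcov)
    if best is None:
        raise FitError(f"Gompertz fit did not converge: {last_err}")

    sse, popt, pcov = best
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = max(0.0, 1.0 - sse / sst)
    se = np.sqrt(np.maximum(np.diag(pcov), 0.0))
    ci = {nm: (float(p - 1.96 * s), float(p + 1.96 * s))
          for nm, p, s in zip(names, popt, se)}
    stderr = {nm: float(s) for nm, s in zip(names, se)}
    if fix_n0 is not None:
        params = GompertzParams(a0=popt[0], c_decay=popt[1], n0=float(fix_n0))
        ci["n0"] = (float(fix_n0), float(fix_n0))
        stderr["n0"] = 0.0
    else:
        params = GompertzParams(a0=popt[0], c_decay=popt[1], n0=popt[2])
    return GompertzFit(params=params, r_squared=min(r2, 1.0), ci=ci, stderr=stderr)
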