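"""Synthetic data generators: every input the estimators assume.

The marker-expression series that underlie the EMT/MET rate estimates
(vimentin decay under induced mir-93, vimentin rise under high IL-6) are
not published as numbers, so parameter-recovery and pipeline tests run on
synthetic stand-ins generated here: exponential trends with multiplicative
log-normal noise, exact two-state CTMC occupancy data, noisy Gompertz
growth observations, and a set of small fixture networks with closed-form
moments.

Every generator is a pure function of its :class:`SyntheticSpec` — the same
spec (including seed) reproduces the same bytes — and datasets can be
written with their spec as a JSON sidecar and round-tripped.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np

from .gompertz import GompertzParams, gompertz_value
from .network import Reaction, ReactionNetwork, Species
from .transitions import MarkerSeries, TransitionRates


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator name, true parameters, noise level, size, and seed."""

    generator: str
    params: dict
    sigma: float = 0.05
    n: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.n < 1:
            raise ValueError("n must be >= 1")


def gen_marker_series(
    rate: float,
    direction: Literal["decay", "rise"] = "decay",
    sigma: float = 0.05,
    n: int = 20,
    t_max: float | None = None,
    seed: int = 0,
) -> tuple[MarkerSeries, SyntheticSpec]:
    """Exponential marker series with multiplicative log-normal noise.

    ``values = exp(+/- rate * t) * exp(eps)`` with ``eps ~ N(0, sigma^2)``
    on an even time grid.  ``t_max`` defaults to 3 e-foldings of the true
    rate so the trend dominates the noise.
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    if t_max is None:
        t_max = 3.0 / rate
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, t_max, n)
    sign = -1.0 if direction == "decay" else 1.0
    v = np.exp(sign * rate * t) * np.exp(rng.normal(0.0, sigma, n))
    spec = SyntheticSpec(
        "marker_series",
        {"rate": rate, "direction": direction, "t_max": t_max},
        sigma, n, seed,
    )
    return MarkerSeries(t, v), spec


def gen_two_state_data(
    rates: TransitionRates,
    n_cells: int = 100,
    t_max: float = 200.0,
    n_times: int = 101,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, SyntheticSpec]:
    """Exact per-cell simulation of the two-state EMT/MET switch.

    Each cell is an independent two-state CTMC started in the epithelial
    (MET) state, simulated by drawing exponential holding times with the
    state's exit rate.  Returns ``(times, emt_counts, spec)`` where
    ``emt_counts[k]`` is the number of cells in the mesenchymal state at
    ``times[k]``; the long-run EMT fraction converges to
    ``lambda_emt / (lambda_emt + lambda_met)``.
    """
    rng = np.random.default_rng(seed)
    times = np.linspace(0.0, t_max, n_times)
    emt_counts = np.zeros(n_times, dtype=np.int64)
    exit_rate = {0: rates.lambda_emt, 1: rates.lambda_met}  # 0 = MET, 1 = EMT
    for _ in range(n_cells):
        t, state = 0.0, 0
        k = 0
        while k < n_times:
            dwell = rng.exponential(1.0 / exit_rate[state])
            t_next = t + dwell
            while k < n_times and times[k] < t_next:
                emt_counts[k] += state
                k += 1
            t, state = t_next, 1 - state
    spec = SyntheticSpec(
        "two_state",
        {"lambda_emt": rates.lambda_emt, "lambda_met": rates.lambda_met,
         "n_cells": n_cells, "t_max": t_max},
        0.0, n_times, seed,
    )
    return times, emt_counts, spec


def holding_times(
    rates: TransitionRates, n_events: int = 200, seed: int = 0, state: int = 0
) -> np.ndarray:
    """Dwell times of one alternating cell, restricted to one state.

    ``state`` 0 = MET (exit rate lambda_emt), 1 = EMT (exit rate
    lambda_met).  Useful for distributional checks: dwell times are
    exponential with the state's exit rate.
    """
    rng = np.random.default_rng(seed)
    rate = rates.lambda_emt if state == 0 else rates.lambda_met
    return rng.exponential(1.0 / rate, n_events)


def gen_gompertz_data(
    params: GompertzParams,
    sigma: float = 0.05,
    n: int = 150,
    t_max: float = 4380.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, SyntheticSpec]:
    """Gompertz curve on an even grid with multiplicative log-normal noise."""
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, t_max, n)
    y = gompertz_value(params, t) * np.exp(rng.normal(0.0, sigma, n))
    spec = SyntheticSpec(
        "gompertz",
        {"a0": params.a0, "c_decay": params.c_decay, "n0": params.n0,
         "t_max": t_max},
        sigma, n, seed,
    )
    return t, y, spec


# ---------------------------------------------------------------------------
# fixture networks with closed-form expectations


def pure_death(rate: float = 1.0, x0: int = 1000) -> ReactionNetwork:
    """A -> 0.  Mean x0*exp(-rate*t); extinction certain."""
    return ReactionNetwork(
        [Species("A", "cell", x0)],
        [Reaction("death", ["A"], [], rate, "death")],
    )


def birth_death(b: float = 2.0, d: float = 1.0, x0: int = 100) -> ReactionNetwork:
    """A -> 2A at b, A -> 0 at d.  Mean x0*exp((b-d)t); for b <= d
    extinction is certain, with single-ancestor extinction probability
    min(1, d/b) as t -> infinity."""
    return ReactionNetwork(
        [Species("A", "cell", x0)],
        [
            Reaction("birth", ["A"], ["A", "A"], b, "renewal"),
            Reaction("death", ["A"], [], d, "death"),
        ],
    )


def dimerization(
    kon: float = 0.01, koff: float = 1.0, a0: int = 100, b0: int = 100
) -> ReactionNetwork:
    """A + B <-> AB.  Conserves the A-moiety (A + AB) and B-moiety (B + AB)."""
    return ReactionNetwork(
        [Species("A", "cell", a0), Species("B", "cell", b0),
         Species("AB", "complex", 0)],
        [
            Reaction("bind", ["A", "B"], ["AB"], kon, "binding"),
            Reaction("unbind", ["AB"], ["A", "B"], koff, "dissociation"),
        ],
    )


def two_state_switch(
    lambda_emt: float = 0.02, lambda_met: float = 0.08, n: int = 1
) -> ReactionNetwork:
    """MET <-> EMT for n independent particles (all started in MET).

    Stationary MET occupancy: lambda_met / (lambda_emt + lambda_met).
    """
    return ReactionNetwork(
        [Species("MET", "cell", n), Species("EMT", "cell", 0)],
        [
            Reaction("emt", ["MET"], ["EMT"], lambda_emt, "transition"),
            Reaction("met", ["EMT"], ["MET"], lambda_met, "transition"),
        ],
    )


def fixture_networks() -> dict[str, ReactionNetwork]:
    """The standard small oracle substrates, at their default parameters."""
    return {
        "pure_death": pure_death(),
        "birth_death": birth_death(),
        "dimerization": dimerization(),
        "two_state": two_state_switch(),
    }


def birth_death_mean(b: float, d: float, x0: int, t) -> np.ndarray:
    """E X_t = x0 exp((b-d) t) for the linear birth-death process."""
    return x0 * np.exp((b - d) * np.asarray(t, dtype=float))


def birth_death_var(b: float, d: float, x0: int, t) -> np.ndarray:
    """Var X_t of the linear birth-death process (closed form)."""
    t = np.asarray(t, dtype=float)
    if np.isclose(b, d):
        return x0 * (b + d) * t
    r = b - d
    return x0 * (b + d) / r * np.exp(r * t) * (np.exp(r * t) - 1.0)


# ---------------------------------------------------------------------------
# dataset round-trip


def save_dataset(
    path_csv: str | Path, columns: dict[str, np.ndarray], spec: SyntheticSpec
) -> None:
    """Write a dataset as CSV with its generating spec as a JSON sidecar."""
    import pandas as pd

    path_csv = Path(path_csv)
    pd.DataFrame(columns).to_csv(path_csv, index=False)
    path_csv.with_suffix(".spec.json").write_text(json.dumps(asdict(spec), indent=1))


def load_dataset(path_csv: str | Path):
    """Round-trip a dataset written by :func:`save_dataset`."""
    import pandas as pd

    path_csv = Path(path_csv)
    frame = pd.read_csv(path_csv)
    spec = SyntheticSpec(**json.loads(path_csv.with_suffix(".spec.json").read_text()))
    return frame, spec
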