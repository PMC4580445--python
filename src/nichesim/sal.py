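"""Stochastic simulation: exact SSA and step-anticipation tau-leaping (SAL).

Two simulators share the mass-action machinery of
:class:`~nichesim.network.ReactionNetwork`:

* :func:`ssa_exact` — the Gillespie direct method.  Exponential waiting
  times with the total propensity; the firing channel is chosen with
  probability proportional to its propensity.  Exact, and the oracle
  against which the leaping algorithm is validated.
* SAL tau-leaping — over a leap of length ``tau`` the number of firings of
  channel j is Poisson with the *anticipated* mean

      omega_j = r_j(X_t) * tau + (d r_j / d t) * tau^2 / 2,

  where the propensity drift ``d r_j/dt`` is obtained by the chain rule
  along the mean-field flow of the reaction rate equation (RRE)
  ``d mu/dt = sum_j r_j(mu) nu^j``.  The linear Taylor anticipation lets the
  simulation take larger steps at equal accuracy than plain tau-leaping.
  The production steppers pair the propensity-drift criterion with a
  species-level bound (see :func:`_species_tau_bound`) so that leaps stay
  accurate even where the mean-field flow is stationary.

The production entry points :func:`simulate` (one trajectory, every step
recorded) and :func:`simulate_ensemble` (many replicates on a common time
grid, vectorized across replicates) run a *hybrid* stepper: exact SSA while
any cell-critical reactant of an active channel is scarce (below
``ssa_threshold``), SAL otherwise.  Scarcity is judged on species of
category ``"cell"`` when the network has any (extinction statistics hinge
on exact handling of small cell counts); otherwise on all species.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .network import ReactionNetwork, SystemState

Method = Literal["hybrid", "sal", "ssa"]


class AbsorbingStateError(RuntimeError):
    """All propensities are zero: no further reaction can fire."""


@dataclass
class LeapSettings:
    """Error control and stepping policy for the hybrid SAL simulator.

    Parameters
    ----------
    epsilon
        Dimensionless error-control parameter: the leap is bounded so that
        each channel's anticipated propensity change satisfies
        ``|dr_j/dt| * tau <= epsilon * max(r_j, a_j)``.
    ssa_threshold
        Critical-species count below which stepping falls back to exact SSA.
    max_tau
        Upper bound on a single leap (days).
    rng_seed
        Root seed for reproducible runs when no explicit seed is passed.
    method
        ``"hybrid"`` (default), ``"sal"`` (leap always), or ``"ssa"``.
    max_retries
        Bounded halving retries when a leap would drive a count negative,
        after which the step falls back to a single exact SSA event.
    """

    epsilon: float = 0.03
    ssa_threshold: int = 10
    max_tau: float = 10.0
    rng_seed: int | None = None
    method: Method = "hybrid"
    max_retries: int = 10

    def __post_init__(self) -> None:
        if not 0 < self.epsilon < 1:
            raise ValueError("epsilon must lie in (0, 1)")
        if self.ssa_threshold < 0:
            raise ValueError("ssa_threshold must be non-negative")
        if self.max_tau <= 0:
            raise ValueError("max_tau must be positive")


@dataclass
class Trajectory:
    """A single realization: time-ordered states (times strictly increasing)."""

    times: np.ndarray
    states: np.ndarray  # (T, d) integer counts
    species_names: list[str]

    def counts_of(self, name: str) -> np.ndarray:
        return self.states[:, self.species_names.index(name)]

    def final_state(self) -> SystemState:
        return SystemState(float(self.times[-1]), self.states[-1])

    def to_frame(self):
        """Tidy (time, species, count) pandas frame."""
        import pandas as pd

        t = np.repeat(self.times, len(self.species_names))
        sp = np.tile(np.asarray(self.species_names, dtype=object), len(self.times))
        return pd.DataFrame(
            {"time": t, "species": sp, "count": self.states.reshape(-1)}
        )


@dataclass
class EnsembleSummary:
    """Replicate trajectories on a common time grid, plus summaries."""

    times: np.ndarray  # (G,)
    states: np.ndarray  # (n, G, d) integer counts
    species_names: list[str]
    seed: int | None = None
    settings: LeapSettings | None = None

    @property
    def n(self) -> int:
        return self.states.shape[0]

    def index(self, name: str) -> int:
        return self.species_names.index(name)

    def mean(self, name: str | None = None) -> np.ndarray:
        m = self.states.mean(axis=0)
        return m if name is None else m[:, self.index(name)]

    def var(self, name: str | None = None) -> np.ndarray:
        v = self.states.var(axis=0, ddof=1)
        return v if name is None else v[:, self.index(name)]

    def quantile(self, q, name: str | None = None) -> np.ndarray:
        qs = np.quantile(self.states, q, axis=0)
        return qs if name is None else qs[..., self.index(name)]

    def counts_of(self, name: str) -> np.ndarray:
        """(n, G) counts of one species across replicates."""
        return self.states[:, :, self.index(name)]

    def total(self, names: Sequence[str] | None = None) -> np.ndarray:
        """(n, G) summed counts over ``names`` (default: all species)."""
        if names is None:
            return self.states.sum(axis=2)
        idx = [self.index(nm) for nm in names]
        return self.states[:, :, idx].sum(axis=2)

    def to_frame(self):
        """Tidy (replicate, time, species, count) pandas frame."""
        import pandas as pd

        n, g, d = self.states.shape
        rep = np.repeat(np.arange(n), g * d)
        t = np.tile(np.repeat(self.times, d), n)
        sp = np.tile(np.asarray(self.species_names, dtype=object), n * g)
        return pd.DataFrame(
            {"replicate": rep, "time": t, "species": sp,
             "count": self.states.reshape(-1)}
        )

    def summary_dict(self) -> dict:
        """JSON-ready per-species mean/variance/quantiles on the grid."""
        out: dict = {"times": self.times.tolist(), "n": int(self.n), "species": {}}
        q = self.quantile([0.05, 0.5, 0.95])
        for k, name in enumerate(self.species_names):
            out["species"][name] = {
                "mean": self.mean()[:, k].tolist(),
                "var": self.var()[:, k].tolist(),
                "q05": q[0, :, k].tolist(),
                "median": q[1, :, k].tolist(),
                "q95": q[2, :, k].tolist(),
            }
        return out

    def save(self, csv_path: str | Path, json_path: str | Path | None = None) -> None:
        self.to_frame().to_csv(csv_path, index=False)
        if json_path is not None:
            Path(json_path).write_text(json.dumps(self.summary_dict()))


# ---------------------------------------------------------------------------
# spec'd scalar operations


def rre_derivative(network: ReactionNetwork, state: SystemState | np.ndarray) -> np.ndarray:
    """Reaction-rate-equation drift ``sum_j r_j(x) nu^j`` (particles/day)."""
    x = state.counts if isinstance(state, SystemState) else np.asarray(state)
    r = network.propensities(x)
    return r @ network.nu.T.astype(float)


def propensity_time_derivative(
    network: ReactionNetwork, state: SystemState | np.ndarray, j: int
) -> float:
    """Chain-rule time derivative of channel j's propensity along the RRE flow."""
    x = state.counts if isinstance(state, SystemState) else np.asarray(state)
    _, dr = network.propensity_derivatives(x)
    return float(dr[j])


def leap_mean(
    network: ReactionNetwork, state: SystemState | np.ndarray, j: int, tau: float
) -> float:
    """Anticipated Poisson mean ``max(0, r_j tau + (dr_j/dt) tau^2 / 2)``."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    x = state.counts if isinstance(state, SystemState) else np.asarray(state)
    r, dr = network.propensity_derivatives(x)
    return float(max(0.0, r[j] * tau + 0.5 * dr[j] * tau * tau))


def _tau_bound(
    r: np.ndarray,
    dr: np.ndarray,
    a: np.ndarray,
    epsilon: float,
    max_tau: float,
    strict: bool = True,
) -> np.ndarray:
    """Vectorized tau selection.  ``r``/``dr`` may be (c,) or (m, c).

    Largest tau <= max_tau with |dr_j| tau <= epsilon * max(r_j, a_j) for
    every channel that can fire, additionally bounded so every anticipated
    leap mean stays non-negative (tau <= 2 r_j / |dr_j| when dr_j < 0).

    With ``strict=False`` (the production stepper's mode), channels whose
    current propensity is zero are instead bounded so their anticipated
    leap mean ``(dr_j/dt) tau^2 / 2`` stays at or below one event.  For a
    dormant bimolecular channel the bare rate constant is not a propensity
    scale (its units differ), and holding such channels to
    ``epsilon * a_j`` collapses tau by several orders of magnitude without
    improving accuracy; capping the dormant channel's expected firings at
    one is the sharpest statement of "this channel barely turns on during
    the leap".
    """
    scale = np.maximum(r, a)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(np.abs(dr) > 0, epsilon * scale / np.abs(dr), np.inf)
        t2 = np.where(dr < 0, 2.0 * r / np.abs(dr), np.inf)
        if not strict:
            dormant = (r <= 0) & (dr > 0)
            t1 = np.where(dormant, np.sqrt(2.0 / np.where(dormant, dr, 1.0)), t1)
    relevant = (r > 0) | (dr > 0)
    t = np.where(relevant, np.minimum(t1, t2), np.inf)
    tau = np.min(t, axis=-1)
    return np.minimum(tau, max_tau)


def _reactant_orders(network: ReactionNetwork) -> np.ndarray:
    """Per-species highest order of any channel consuming it (>= 1)."""
    g = np.ones(network.d)
    for rxn in network.reactions:
        counts = rxn.reactant_counts()
        order = sum(counts.values())
        for name in counts:
            i = network.species_index(name)
            g[i] = max(g[i], order)
    return g


def _species_tau_bound(
    X: np.ndarray, r: np.ndarray, nuT: np.ndarray, g: np.ndarray, epsilon: float
) -> np.ndarray:
    """Bounded-relative-species-change leap cap (rows = replicates).

    The propensity-drift criterion alone leaves tau unbounded wherever the
    mean-field flow is stationary — e.g. a reversible pair at equilibrium —
    yet long leaps there fire the opposing channels as independent
    Poissons and overdisperse the state.  This companion bound caps both
    the expected change and the change variance of every species count at
    ``max(epsilon * x_i / g_i, 1)`` per leap (one expected event is always
    allowed, so scarce species do not stall the clock; exact handling of
    scarce counts is the hybrid threshold's job).
    """
    X = np.atleast_2d(X)
    r = np.atleast_2d(r)
    mu = r @ nuT  # (m, d) expected net change rate
    sig2 = r @ (nuT**2)  # (m, d) change variance rate
    bound = np.maximum(epsilon * X / g, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mu = np.where(mu != 0.0, bound / np.abs(mu), np.inf)
        t_sig = np.where(sig2 > 0.0, bound**2 / sig2, np.inf)
    return np.minimum(t_mu, t_sig).min(axis=1)


def select_tau(
    network: ReactionNetwork, state: SystemState | np.ndarray, settings: LeapSettings
) -> float:
    """Leap size satisfying the bounded-relative-propensity-change criterion."""
    x = state.counts if isinstance(state, SystemState) else np.asarray(state)
    r, dr = network.propensity_derivatives(x)
    if not (r > 0).any():
        raise AbsorbingStateError("all propensities are zero")
    return float(_tau_bound(r, dr, network.rate_constants, settings.epsilon, settings.max_tau))


def sal_step(
    network: ReactionNetwork,
    state: SystemState,
    settings: LeapSettings,
    rng: np.random.Generator,
    tau: float | None = None,
) -> SystemState:
    """One SAL leap from ``state``.

    Draws ``k_j ~ Poisson(omega_j)`` for every channel and applies
    ``sum_j k_j nu^j``.  If the update would drive any count negative, the
    leap is rejected and retried with tau halved (bounded retries), then
    falls back to a single exact-SSA event.  In an absorbing state the
    counts are unchanged and time advances by ``max_tau``.
    """
    x = state.counts
    r, dr = network.propensity_derivatives(x)
    if not (r > 0).any():
        return SystemState(state.time + settings.max_tau, x.copy())
    if tau is None:
        tau = float(
            _tau_bound(r, dr, network.rate_constants, settings.epsilon, settings.max_tau)
        )
    for _ in range(settings.max_retries):
        omega = np.maximum(0.0, r * tau + 0.5 * dr * tau * tau)
        k = rng.poisson(omega)
        new = x + k @ network.nu.T
        if (new >= 0).all():
            return SystemState(state.time + tau, new)
        tau /= 2.0
    # bounded retries exceeded: one exact event
    total = r.sum()
    dt = rng.exponential(1.0 / total)
    j = int(np.searchsorted(np.cumsum(r), rng.random() * total))
    return SystemState(state.time + dt, x + network.nu[:, min(j, network.c - 1)])


# ---------------------------------------------------------------------------
# single-trajectory simulators


def ssa_exact(
    network: ReactionNetwork,
    t_final: float,
    seed: int | None = None,
    x0: np.ndarray | None = None,
    t0: float = 0.0,
    rng: np.random.Generator | None = None,
) -> Trajectory:
    """Gillespie direct method; every reaction event is recorded."""
    rng = np.random.default_rng(seed) if rng is None else rng
    x = network.initial_counts() if x0 is None else np.asarray(x0, dtype=np.int64)
    t = float(t0)
    times, states = [t], [x.copy()]
    nu = network.nu
    while t < t_final:
        r = network.propensities(x)
        total = r.sum()
        if total <= 0.0:
            break
        dt = rng.exponential(1.0 / total)
        if t + dt > t_final:
            break
        t += dt
        j = int(np.searchsorted(np.cumsum(r), rng.random() * total))
        j = min(j, network.c - 1)
        x = x + nu[:, j]
        times.append(t)
        states.append(x.copy())
    if times[-1] < t_final:
        times.append(t_final)
        states.append(x.copy())
    return Trajectory(np.array(times), np.array(states), network.species_names)


def _critical_indices(network: ReactionNetwork) -> np.ndarray:
    cells = [i for i, s in enumerate(network.species) if s.category == "cell"]
    return np.array(cells if cells else range(network.d), dtype=np.int64)


def simulate(
    network: ReactionNetwork,
    t_final: float,
    settings: LeapSettings | None = None,
    seed: int | None = None,
    x0: np.ndarray | None = None,
    t0: float = 0.0,
) -> Trajectory:
    """One hybrid SSA/SAL trajectory, recording the state after every step.

    Exact SSA is used whenever a critical (cell-category, or any if the
    network has no cells) reactant of an active channel sits below
    ``settings.ssa_threshold``; SAL leaping otherwise.  Bit-reproducible for
    a given seed.
    """
    settings = settings or LeapSettings()
    if seed is None:
        seed = settings.rng_seed
    rng = np.random.default_rng(seed)
    x = network.initial_counts() if x0 is None else np.asarray(x0, dtype=np.int64)
    state = SystemState(float(t0), x)
    crit = _critical_indices(network)
    crit_mask = network.reactant_mask[:, crit]  # (c, k)
    nuT = network.nu.T.astype(float)
    g = _reactant_orders(network)
    times, states = [state.time], [state.counts.copy()]
    while state.time < t_final:
        r = network.propensities(state.counts)
        active = r > 0
        if not active.any():
            state = SystemState(t_final, state.counts)
        else:
            use_ssa = settings.method == "ssa"
            if settings.method == "hybrid":
                scarce = state.counts[crit] < settings.ssa_threshold
                use_ssa = bool((crit_mask[active] & scarce).any())
            if use_ssa:
                total = r.sum()
                dt = rng.exponential(1.0 / total)
                if state.time + dt >= t_final:
                    state = SystemState(t_final, state.counts)
                else:
                    j = int(np.searchsorted(np.cumsum(r), rng.random() * total))
                    j = min(j, network.c - 1)
                    state = SystemState(
                        state.time + dt, state.counts + network.nu[:, j]
                    )
            else:
                _, dr = network.propensity_derivatives(state.counts)
                tau = float(
                    _tau_bound(
                        r, dr, network.rate_constants, settings.epsilon,
                        settings.max_tau, strict=False,
                    )
                )
                tau = min(
                    tau,
                    float(_species_tau_bound(state.counts, r, nuT, g,
                                             settings.epsilon)[0]),
                )
                tau = min(tau, t_final - state.time)
                state = sal_step(network, state, settings, rng, tau=tau)
        if state.time > times[-1]:
            times.append(state.time)
            states.append(state.counts.copy())
        else:  # zero-length step guard
            states[-1] = state.counts.copy()
    return Trajectory(np.array(times), np.array(states), network.species_names)


# ---------------------------------------------------------------------------
# vectorized ensemble simulator


def _run_ensemble(
    network: ReactionNetwork,
    grid: np.ndarray,
    X0: np.ndarray,
    settings: LeapSettings,
    rng: np.random.Generator,
) -> np.ndarray:
    """Advance ``n`` replicates along ``grid`` (grid[0] is the start time).

    Returns states of shape (n, G, d).  All replicates are stepped in
    lock-step numpy operations; each iteration advances every unfinished
    replicate by one SSA event or one SAL leap.  Leaps are capped at the
    next grid time, so recorded states are exact at grid times.
    """
    n, d = X0.shape
    c = network.c
    G = len(grid)
    t_final = float(grid[-1])
    nuT = network.nu.T
    nuTf = nuT.astype(float)
    a = network.rate_constants
    g_order = _reactant_orders(network)
    crit = _critical_indices(network)
    crit_mask = network.reactant_mask[:, crit]  # (c, k)

    X = X0.astype(np.int64).copy()
    t = np.full(n, float(grid[0]))
    gi = np.ones(n, dtype=np.int64)  # next grid index to record
    states = np.zeros((n, G, d), dtype=np.int64)
    states[:, 0] = X
    done = np.zeros(n, dtype=bool)

    while not done.all():
        idx = np.flatnonzero(~done)
        x = X[idx]
        r = network.propensities(x)
        active = r > 0.0
        total = r.sum(axis=1)

        # absorbed replicates: state frozen to the horizon
        absorbed = total <= 0.0
        if absorbed.any():
            for i in idx[absorbed]:
                states[i, gi[i]:] = X[i]
                gi[i] = G
                t[i] = t_final
                done[i] = True
            keep = ~absorbed
            idx, x, r, active, total = (
                idx[keep], x[keep], r[keep], active[keep], total[keep],
            )
            if idx.size == 0:
                continue

        if settings.method == "ssa":
            ssa_mask = np.ones(idx.size, dtype=bool)
        elif settings.method == "sal":
            ssa_mask = np.zeros(idx.size, dtype=bool)
        else:
            scarce = x[:, crit] < settings.ssa_threshold  # (m, k)
            ssa_mask = ((scarce @ crit_mask.T.astype(np.int64)) > 0)
            ssa_mask = (ssa_mask & active).any(axis=1)

        # --- exact SSA events -------------------------------------------
        if ssa_mask.any():
            sub = np.flatnonzero(ssa_mask)
            ridx = idx[sub]
            rs = r[sub]
            tot = total[sub]
            dt = rng.exponential(1.0 / tot)
            u = rng.random(sub.size) * tot
            cum = np.cumsum(rs, axis=1)
            j = (cum >= u[:, None]).argmax(axis=1)
            t_new = t[ridx] + dt
            fired = t_new < t_final
            # common case (no grid time crossed, event fires): vectorized
            next_grid = grid[np.minimum(gi[ridx], G - 1)]
            plain = fired & (t_new < next_grid)
            if plain.any():
                pi = ridx[plain]
                X[pi] = X[pi] + nuT[j[plain]]
                t[pi] = t_new[plain]
            rest = np.flatnonzero(~plain)
            for m_i in rest:
                i = ridx[m_i]
                tn = t_new[m_i]
                # record pre-event state at crossed grid points
                while gi[i] < G and grid[gi[i]] < min(tn, t_final):
                    states[i, gi[i]] = X[i]
                    gi[i] += 1
                if fired[m_i]:
                    X[i] += nuT[j[m_i]]
                    t[i] = tn
                else:
                    while gi[i] < G:
                        states[i, gi[i]] = X[i]
                        gi[i] += 1
                    t[i] = t_final
                    done[i] = True

        # --- SAL leaps ----------------------------------------------------
        if (~ssa_mask).any():
            sub = np.flatnonzero(~ssa_mask)
            ridx = idx[sub]
            rs, drs = network.propensity_derivatives(x[sub])
            tau = _tau_bound(rs, drs, a, settings.epsilon, settings.max_tau, strict=False)
            tau = np.minimum(
                tau, _species_tau_bound(x[sub], rs, nuTf, g_order, settings.epsilon)
            )
            next_grid = grid[np.minimum(gi[ridx], G - 1)]
            tau = np.minimum(tau, next_grid - t[ridx])
            tau = np.maximum(tau, 1e-12)
            pend = np.arange(sub.size)
            new_x = np.empty((sub.size, d), dtype=np.int64)
            for _ in range(settings.max_retries):
                omega = np.maximum(
                    0.0,
                    rs[pend] * tau[pend, None]
                    + 0.5 * drs[pend] * tau[pend, None] ** 2,
                )
                k = rng.poisson(omega)
                cand = X[ridx[pend]] + k @ nuT
                ok = (cand >= 0).all(axis=1)
                new_x[pend[ok]] = cand[ok]
                pend = pend[~ok]
                if pend.size == 0:
                    break
                tau[pend] /= 2.0
            for m_i in pend:  # fallback: one exact event
                i = ridx[m_i]
                rr = rs[m_i]
                tot = rr.sum()
                dt = rng.exponential(1.0 / tot)
                tau[m_i] = dt
                if t[i] + dt >= t_final:
                    new_x[m_i] = X[i]
                    tau[m_i] = t_final - t[i]
                else:
                    jj = int(np.searchsorted(np.cumsum(rr), rng.random() * tot))
                    new_x[m_i] = X[i] + nuT[min(jj, c - 1)]
            t_new = t[ridx] + tau
            X[ridx] = new_x
            t[ridx] = t_new
            # only leaps that reach the next grid time (or the horizon)
            # need recording / completion bookkeeping
            cross = (t_new >= grid[np.minimum(gi[ridx], G - 1)] - 1e-9) | (
                t_new >= t_final - 1e-12
            )
            for m_i in np.flatnonzero(cross):
                i = ridx[m_i]
                if gi[i] < G and t[i] >= grid[gi[i]] - 1e-9:
                    states[i, gi[i]] = X[i]
                    gi[i] += 1
                if gi[i] >= G or t[i] >= t_final - 1e-12:
                    while gi[i] < G:
                        states[i, gi[i]] = X[i]
                        gi[i] += 1
                    done[i] = True
    return states


def simulate_ensemble(
    network: ReactionNetwork,
    t_final: float,
    settings: LeapSettings | None = None,
    n: int = 100,
    seed: int | None = None,
    grid: np.ndarray | None = None,
    x0: np.ndarray | None = None,
    t0: float = 0.0,
) -> EnsembleSummary:
    """Simulate ``n`` independent replicates, recorded on a common grid.

    The replicate ensemble is driven by a single counter-based (PCG64)
    stream derived from ``seed``, so a run is bit-reproducible for a given
    (seed, n, grid).  ``x0`` may be a single state vector or an (n, d)
    matrix of per-replicate starting states.
    """
    settings = settings or LeapSettings()
    if n < 1:
        raise ValueError("n must be >= 1")
    if t_final <= t0:
        raise ValueError("t_final must exceed t0")
    if seed is None:
        seed = settings.rng_seed
    rng = np.random.default_rng(seed)
    if grid is None:
        grid = np.linspace(t0, t_final, 101)
    grid = np.asarray(grid, dtype=float)
    if x0 is None:
        X0 = np.tile(network.initial_counts(), (n, 1))
    else:
        x0 = np.asarray(x0, dtype=np.int64)
        X0 = np.tile(x0, (n, 1)) if x0.ndim == 1 else x0.copy()
    states = _run_ensemble(network, grid, X0, settings, rng)
    return EnsembleSummary(grid, states, network.species_names, seed, settings)


# ---------------------------------------------------------------------------
# deterministic mean-field trajectory (RRE)


def rre_trajectory(
    network: ReactionNetwork,
    t_final: float,
    grid: np.ndarray | None = None,
    x0: np.ndarray | None = None,
    t0: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate the reaction rate equation (deterministic, non-stochastic).

    Returns ``(times, values)`` with values of shape (G, d).  Used for fast
    parameter calibration; it is the mean-field companion of the stochastic
    simulators, not a replacement for them.
    """
    from scipy.integrate import solve_ivp

    if grid is None:
        grid = np.linspace(t0, t_final, 201)
    grid = np.asarray(grid, dtype=float)
    x0 = network.initial_counts() if x0 is None else np.asarray(x0, dtype=float)
    nuT = network.nu.T.astype(float)

    def f(_t, y):
        return network.propensities(np.maximum(y, 0.0)) @ nuT

    sol = solve_ivp(
        f, (grid[0], grid[-1]), x0.astype(float), t_eval=grid,
        method="LSODA", rtol=1e-8, atol=1e-6,
    )
    if not sol.success:  # pragma: no cover - defensive
        raise RuntimeError(f"RRE integration failed: {sol.message}")
    return grid, sol.y.T
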