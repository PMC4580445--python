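"""Carcinogenesis hierarchy: BCSC -> bipotent progenitor -> differentiated.

The hierarchy couples the two-state BCSC switch to a progenitor cascade:
epithelial (MET-like) BCSCs divide by symmetric self-renewal (rate ``beta``,
two BCSC daughters), asymmetric self-renewal (rate ``alpha``, one BCSC and
one bipotent progenitor, BPP), or symmetric differentiation (rate ``rho``,
two BPPs); mesenchymal (EMT-like) BCSCs are quiescent (no division or death
channels).  BPPs divide symmetrically or differentiate into luminal or
basal cells, which die at a constant rate.

Carcinogenesis is modeled as a gradual shift from asymmetric to symmetric
division: the fraction ``f`` of symmetric divisions rises yearly (20% in
year 1 up to 80% from year 7 on) while ``alpha`` is held at 0.027
cell^-1 day^-1, with the symmetric budget split ``beta = 5 rho`` in years
1-4 and ``beta = rho`` thereafter.  The healthy baseline
``beta = rho ~ 0.0034`` (symmetric self-renewal about once every 42 weeks)
emerges as the ``f = 0.2``, ratio-1 case of the same rule.  This schedule
alone — no resource limitation — produces continuously decelerating,
Gompertz-like bulk growth.

Progenitor-compartment rates are not independently measured; the shipped
defaults are calibrated by :func:`calibrate_progenitor_rates` (grid search
minimizing the mean squared distance between the mean-field 12-year
trajectory and the reference Gompertz curve A0=0.0193, c=0.00133, N0=625)
and frozen in :data:`DEFAULT_HIERARCHY`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .gompertz import GompertzParams, gompertz_value
from .network import Reaction, ReactionNetwork, Species
from .sal import EnsembleSummary, LeapSettings, _run_ensemble, rre_trajectory

DAYS_PER_YEAR = 365.0

#: BCSC compartment totals at the start of carcinogenesis.
DEFAULT_INITIAL_POPULATIONS: dict[str, int] = {
    "EMT_BCSC": 5,
    "MET_BCSC": 20,
    "BPP": 100,
    "TC_luminal": 250,
    "TC_basal": 250,
}

GROWTH_SPECIES = list(DEFAULT_INITIAL_POPULATIONS)
BCSC_SPECIES = ["EMT_BCSC", "MET_BCSC"]


class ScheduleError(ValueError):
    """A queried day falls outside the division schedule."""


def symmetric_rate_from_interval(weeks: float = 42.0) -> float:
    """Per-day rate of an event occurring once every ``weeks`` weeks.

    The healthy symmetric self-renewal benchmark — once every 42 weeks —
    converts to 1/(42*7) ~ 0.0034 cell^-1 day^-1.
    """
    if weeks <= 0:
        raise ValueError("interval must be positive")
    return 1.0 / (weeks * 7.0)


@dataclass(frozen=True)
class HierarchyParams:
    """Division, transition, and death rates of the hierarchy (day^-1)."""

    alpha: float = 0.027  # asymmetric self-renewal
    lambda_emt: float = 0.02  # MET -> EMT
    lambda_met: float = 0.08  # EMT -> MET
    bcsc_death: float = 0.0
    # progenitor/differentiated rates frozen from calibrate_progenitor_rates
    bpp_division: float = 0.03
    bpp_differentiation: float = 0.0317
    tc_death: float = 0.022

    def __post_init__(self) -> None:
        for name in (
            "alpha", "lambda_emt", "lambda_met", "bcsc_death",
            "bpp_division", "bpp_differentiation", "tc_death",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


#: Calibrated defaults (see module docstring / calibrate_progenitor_rates).
DEFAULT_HIERARCHY = HierarchyParams()


@dataclass(frozen=True)
class SchedulePeriod:
    start_day: float
    end_day: float
    symmetric_fraction: float  # f = (beta + rho) / (alpha + beta + rho)
    beta_to_rho_ratio: float

    def __post_init__(self) -> None:
        if not 0.0 < self.symmetric_fraction < 1.0:
            raise ScheduleError("symmetric fraction must lie in (0, 1)")
        if self.beta_to_rho_ratio <= 0:
            raise ScheduleError("beta/rho ratio must be positive")
        if self.end_day <= self.start_day:
            raise ScheduleError("period must have positive length")


@dataclass(frozen=True)
class DivisionSchedule:
    """Contiguous, non-overlapping periods of (f, beta/rho ratio)."""

    periods: tuple[SchedulePeriod, ...]

    def __post_init__(self) -> None:
        for prev, cur in zip(self.periods, self.periods[1:]):
            if not np.isclose(prev.end_day, cur.start_day):
                raise ScheduleError("periods must be contiguous")

    @property
    def span(self) -> tuple[float, float]:
        return self.periods[0].start_day, self.periods[-1].end_day

    def period_at(self, day: float) -> SchedulePeriod:
        for p in self.periods:
            if p.start_day <= day < p.end_day:
                return p
        if np.isclose(day, self.periods[-1].end_day):
            return self.periods[-1]
        raise ScheduleError(f"day {day} outside schedule span {self.span}")


def default_schedule(years: int = 12) -> DivisionSchedule:
    """The carcinogenesis schedule: f rises 20%..80% yearly (capped at 80%
    from year 7), with beta = 5 rho in years 1-4 and beta = rho after."""
    fractions = [0.2, 0.3, 0.4, 0.5, 0.6, 0.7] + [0.8] * max(years - 6, 0)
    periods = []
    for year in range(years):
        f = fractions[min(year, len(fractions) - 1)]
        ratio = 5.0 if year < 4 else 1.0
        periods.append(
            SchedulePeriod(year * DAYS_PER_YEAR, (year + 1) * DAYS_PER_YEAR, f, ratio)
        )
    return DivisionSchedule(tuple(periods))


def flat_schedule(years: int = 12, f: float = 0.2, ratio: float = 1.0) -> DivisionSchedule:
    """A single-period schedule (e.g. the no-shift comparison scenario)."""
    return DivisionSchedule(
        (SchedulePeriod(0.0, years * DAYS_PER_YEAR, f, ratio),)
    )


def schedule_rates(
    schedule: DivisionSchedule, alpha: float, day: float
) -> tuple[float, float]:
    """(beta, rho) at ``day``: the symmetric budget ``beta + rho`` solves
    ``(beta + rho)/(alpha + beta + rho) = f`` and is split ``beta:rho``
    according to the period's ratio."""
    p = schedule.period_at(day)
    f, ratio = p.symmetric_fraction, p.beta_to_rho_ratio
    budget = alpha * f / (1.0 - f)
    beta = budget * ratio / (1.0 + ratio)
    rho = budget / (1.0 + ratio)
    return beta, rho


@dataclass
class GrowthModel:
    """A hierarchy network whose (beta, rho) follow a division schedule."""

    network: ReactionNetwork  # rates of renewal_sym/diff_sym set per period
    params: HierarchyParams
    schedule: DivisionSchedule

    def network_at(self, day: float) -> ReactionNetwork:
        beta, rho = schedule_rates(self.schedule, self.params.alpha, day)
        return self.network.with_rates({"renewal_sym": beta, "diff_sym": rho})


def build_growth_model(
    params: HierarchyParams | None = None,
    schedule: DivisionSchedule | None = None,
    init: dict[str, int] | None = None,
) -> GrowthModel:
    """Assemble the time-inhomogeneous hierarchy model.

    Mesenchymal BCSCs are quiescent: their only channels are the EMT/MET
    transitions.  ``renewal_sym`` (beta) and ``diff_sym`` (rho) are
    placeholders re-rated per schedule period during simulation.
    """
    params = params or DEFAULT_HIERARCHY
    schedule = schedule or default_schedule()
    counts = dict(DEFAULT_INITIAL_POPULATIONS)
    if init:
        counts.update(init)
    species = [
        Species("EMT_BCSC", "cell", counts["EMT_BCSC"], "EMT-like BCSC"),
        Species("MET_BCSC", "cell", counts["MET_BCSC"], "MET-like BCSC"),
        Species("BPP", "cell", counts["BPP"], "bipotent progenitor"),
        Species("TC_luminal", "cell", counts["TC_luminal"], "luminal cell"),
        Species("TC_basal", "cell", counts["TC_basal"], "basal cell"),
    ]
    beta0, rho0 = schedule_rates(schedule, params.alpha, schedule.span[0])
    half_diff = params.bpp_differentiation / 2.0
    reactions = [
        Reaction("renewal_sym", ["MET_BCSC"], ["MET_BCSC", "MET_BCSC"], beta0, "renewal"),
        Reaction("renewal_asym", ["MET_BCSC"], ["MET_BCSC", "BPP"], params.alpha, "renewal"),
        Reaction("diff_sym", ["MET_BCSC"], ["BPP", "BPP"], rho0, "renewal"),
        Reaction("death_MET", ["MET_BCSC"], [], params.bcsc_death, "death"),
        Reaction("emt", ["MET_BCSC"], ["EMT_BCSC"], params.lambda_emt, "transition"),
        Reaction("met", ["EMT_BCSC"], ["MET_BCSC"], params.lambda_met, "transition"),
        Reaction("bpp_division", ["BPP"], ["BPP", "BPP"], params.bpp_division, "renewal"),
        Reaction("bpp_diff_luminal", ["BPP"], ["TC_luminal"], half_diff, "transition"),
        Reaction("bpp_diff_basal", ["BPP"], ["TC_basal"], half_diff, "transition"),
        Reaction("death_TC_luminal", ["TC_luminal"], [], params.tc_death, "death"),
        Reaction("death_TC_basal", ["TC_basal"], [], params.tc_death, "death"),
    ]
    return GrowthModel(ReactionNetwork(species, reactions), params, schedule)


def simulate_growth(
    model: GrowthModel,
    years: float = 12.0,
    reps: int = 24,
    settings: LeapSettings | None = None,
    seed: int | None = None,
    grid_days: float = 30.0,
) -> EnsembleSummary:
    """Stochastic ensemble of the carcinogenesis run.

    Schedule switches are applied exactly at period boundaries: the rate
    constants are updated and the simulation continues from the current
    per-replicate states.  Returns per-compartment trajectories on a
    ``grid_days`` grid; totals via ``summary.total()``.
    """
    if years < 1:
        raise ValueError("simulate at least one year")
    settings = settings or LeapSettings(max_tau=grid_days)
    rng = np.random.default_rng(seed if seed is not None else settings.rng_seed)
    t_end = years * DAYS_PER_YEAR

    all_times: list[np.ndarray] = []
    all_states: list[np.ndarray] = []
    X = np.tile(model.network.initial_counts(), (reps, 1))
    t0 = model.schedule.span[0]
    for p in model.schedule.periods:
        if p.start_day >= t_end:
            break
        stop = min(p.end_day, t_end)
        net = model.network_at(p.start_day)
        n_pts = max(int(round((stop - p.start_day) / grid_days)), 1) + 1
        grid = np.linspace(p.start_day, stop, n_pts)
        states = _run_ensemble(net, grid, X, settings, rng)
        X = states[:, -1].copy()
        if all_times:
            all_times.append(grid[1:])
            all_states.append(states[:, 1:])
        else:
            all_times.append(grid)
            all_states.append(states)
        t0 = stop
    times = np.concatenate(all_times)
    states = np.concatenate(all_states, axis=1)
    return EnsembleSummary(times, states, model.network.species_names, seed, settings)


def rre_growth(
    model: GrowthModel, years: float = 12.0, grid_days: float = 10.0
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic mean-field trajectory of the growth model.

    Exact for this hierarchy (all channels are first-order, so the RRE is
    the ensemble mean).  Returns ``(times, states)`` with states (G, d).
    """
    t_end = years * DAYS_PER_YEAR
    x = model.network.initial_counts().astype(float)
    all_t, all_y = [], []
    for p in model.schedule.periods:
        if p.start_day >= t_end:
            break
        stop = min(p.end_day, t_end)
        net = model.network_at(p.start_day)
        n_pts = max(int(round((stop - p.start_day) / grid_days)), 2)
        grid = np.linspace(p.start_day, stop, n_pts)
        tt, yy = rre_trajectory(net, stop, grid=grid, x0=x, t0=p.start_day)
        x = yy[-1]
        if all_t:
            all_t.append(tt[1:])
            all_y.append(yy[1:])
        else:
            all_t.append(tt)
            all_y.append(yy)
    return np.concatenate(all_t), np.concatenate(all_y, axis=0)


def calibrate_progenitor_rates(
    target: GompertzParams = GompertzParams(0.0193, 0.00133, 625),
    bpp_division_grid: np.ndarray | None = None,
    net_loss_grid: np.ndarray | None = None,
    tc_death_grid: np.ndarray | None = None,
    years: float = 12.0,
    base: HierarchyParams | None = None,
) -> tuple[HierarchyParams, float]:
    """Grid-search calibration of the unprinted progenitor-compartment rates.

    Searches (bpp_division, bpp_differentiation - bpp_division, tc_death)
    minimizing the mean squared distance (normalized by the squared
    asymptote) between the mean-field 12-year total-population trajectory
    and the reference Gompertz curve.  Returns the best
    :class:`HierarchyParams` and its objective value.  The shipped
    :data:`DEFAULT_HIERARCHY` was frozen from this procedure with the
    default grids below (a coarse logarithmic sweep followed by this local
    refinement around its optimum).
    """
    base = base or HierarchyParams()
    if bpp_division_grid is None:
        bpp_division_grid = np.array([0.015, 0.02, 0.025, 0.03])
    if net_loss_grid is None:
        net_loss_grid = np.arange(0.0015, 0.00225, 0.0001)
    if tc_death_grid is None:
        tc_death_grid = np.arange(0.010, 0.0265, 0.002)
    best: tuple[HierarchyParams, float] | None = None
    for b_div in bpp_division_grid:
        for loss in net_loss_grid:
            for d_tc in tc_death_grid:
                params = replace(
                    base,
                    bpp_division=float(b_div),
                    bpp_differentiation=float(b_div + loss),
                    tc_death=float(d_tc),
                )
                model = build_growth_model(params)
                tt, yy = rre_growth(model, years=years, grid_days=30.0)
                total = yy.sum(axis=1)
                ref = gompertz_value(target, tt)
                obj = float(np.mean((total - ref) ** 2)) / target.asymptote**2
                if best is None or obj < best[1]:
                    best = (params, obj)
    assert best is not None
    return best
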