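"""In-silico inhibition screens over the BCSC niche.

An inhibition is simulated by multiplying the rate constants of the
channels attributed to a target by a factor of 1e-10 while keeping the
initial conditions unchanged.  The default target set — IL-6, IL-8,
TGF-beta, BMP, mir-93, HER2, Akt, Stat3, Lin-28 — spans every ligand,
microRNA and signaling node of the niche that can be scaled, and the
target-to-channel attribution is an explicit, user-editable table carried
on the network (``metadata["inhibition_map"]``).

Screens run the baseline plus each condition (singles, or all unordered
pairs) with matched seeds, and summarize extinction frequencies — the
fraction of replicates in which a BCSC population count has reached zero
by a given day — and mean population sizes at the horizon.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np

from .network import ConfigurationError, ReactionNetwork
from .sal import EnsembleSummary, LeapSettings, simulate_ensemble

#: the inhibition convention: rate constants are scaled by this factor.
INHIBITION_FACTOR = 1e-10


@dataclass(frozen=True)
class InhibitionTarget:
    """A named niche element and the reaction channels its blockade scales."""

    name: str
    affected_reactions: tuple[str, ...]
    factor: float = INHIBITION_FACTOR

    def __post_init__(self) -> None:
        if not self.affected_reactions:
            raise ConfigurationError(
                f"target {self.name!r} affects no reactions"
            )
        if not 0.0 < self.factor <= 1.0:
            raise ConfigurationError("inhibition factor must lie in (0, 1]")


def default_targets(network: ReactionNetwork) -> dict[str, InhibitionTarget]:
    """The network's inhibitable elements, from its inhibition map."""
    mapping = network.metadata.get("inhibition_map")
    if not mapping:
        raise ConfigurationError("network carries no inhibition map")
    return {
        name: InhibitionTarget(name, tuple(labels))
        for name, labels in mapping.items()
    }


def apply_inhibition(
    network: ReactionNetwork, targets: Iterable[InhibitionTarget]
) -> ReactionNetwork:
    """A copy of the network with each target's channels scaled by its factor.

    Initial counts are untouched; channels named by several targets are
    scaled once per naming target (independent multiplicative effects).
    """
    labels = {r.label for r in network.reactions}
    scales: dict[str, float] = {}
    for tgt in targets:
        missing = set(tgt.affected_reactions) - labels
        if missing:
            raise ConfigurationError(
                f"target {tgt.name!r} names unknown reactions: {sorted(missing)}"
            )
        for lbl in tgt.affected_reactions:
            scales[lbl] = scales.get(lbl, 1.0) * tgt.factor
    return network.with_scaled_rates(scales)


@dataclass
class ScreenResult:
    """Per-condition ensembles of a screen, baseline included."""

    conditions: list[str]  # condition names, "baseline" first
    summaries: dict[str, EnsembleSummary]
    horizon: float
    mode: str
    emt_species: str = "EMT"
    met_species: str = "MET"
    seed: int | None = None

    def bcsc_counts(
        self, condition: str, population: Literal["EMT", "MET", "total"]
    ) -> np.ndarray:
        """(n, G) counts of the selected BCSC population."""
        s = self.summaries[condition]
        if population == "EMT":
            return s.counts_of(self.emt_species)
        if population == "MET":
            return s.counts_of(self.met_species)
        if population == "total":
            return s.total([self.emt_species, self.met_species])
        raise ValueError("population must be 'EMT', 'MET' or 'total'")

    def mean_at(
        self, condition: str, population: Literal["EMT", "MET", "total"],
        at_day: float | None = None,
    ) -> float:
        s = self.summaries[condition]
        k = int(np.searchsorted(s.times, self.horizon if at_day is None else at_day))
        k = min(k, len(s.times) - 1)
        return float(self.bcsc_counts(condition, population)[:, k].mean())

    def extinction_frequency(
        self, condition: str, population: Literal["EMT", "MET", "total"],
        at_day: float | None = None,
    ) -> float:
        return extinction_frequency(
            self.summaries[condition], population, at_day or self.horizon,
            emt_species=self.emt_species, met_species=self.met_species,
        )


def extinction_frequency(
    summary: EnsembleSummary,
    population: Literal["EMT", "MET", "total"] = "total",
    at_day: float | None = None,
    emt_species: str = "EMT",
    met_species: str = "MET",
) -> float:
    """Fraction of replicates whose population has reached zero by ``at_day``.

    A replicate counts as extinct once its selected population first hits
    zero on the recording grid, so the frequency is non-decreasing in time
    (for the total BCSC population, zero is truly absorbing: cells arise
    only from cells).
    """
    if population == "EMT":
        counts = summary.counts_of(emt_species)
    elif population == "MET":
        counts = summary.counts_of(met_species)
    elif population == "total":
        counts = summary.total([emt_species, met_species])
    else:
        raise ValueError("population must be 'EMT', 'MET' or 'total'")
    at_day = float(summary.times[-1]) if at_day is None else float(at_day)
    if at_day > summary.times[-1] + 1e-9:
        raise ValueError("at_day exceeds the simulated horizon")
    mask = summary.times <= at_day + 1e-9
    ever_zero = (counts[:, mask] == 0).any(axis=1)
    return float(ever_zero.mean())


def run_screen(
    network: ReactionNetwork,
    targets: Mapping[str, InhibitionTarget] | None = None,
    mode: Literal["single", "pairwise"] = "pairwise",
    horizon_days: float = 1000.0,
    reps: int = 100,
    settings: LeapSettings | None = None,
    seed: int | None = None,
    grid_points: int = 101,
) -> ScreenResult:
    """Baseline plus every single or pairwise inhibition condition.

    All conditions run with the same seed (matched randomness), so the
    baseline condition reproduces an unmodified ensemble bit-for-bit and
    condition contrasts are variance-reduced.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    targets = default_targets(network) if targets is None else dict(targets)
    if mode == "single":
        combos: list[tuple[str, ...]] = [(n,) for n in targets]
    elif mode == "pairwise":
        combos = list(combinations(sorted(targets), 2))
    else:
        raise ValueError("mode must be 'single' or 'pairwise'")
    settings = settings or LeapSettings(ssa_threshold=5)
    grid = np.linspace(0.0, horizon_days, grid_points)

    conditions = ["baseline"] + ["+".join(c) for c in combos]
    summaries: dict[str, EnsembleSummary] = {}
    summaries["baseline"] = simulate_ensemble(
        network, horizon_days, settings, reps, seed=seed, grid=grid
    )
    for combo in combos:
        net_c = apply_inhibition(network, [targets[n] for n in combo])
        summaries["+".join(combo)] = simulate_ensemble(
            net_c, horizon_days, settings, reps, seed=seed, grid=grid
        )
    return ScreenResult(conditions, summaries, horizon_days, mode, seed=seed)


def rank_combinations(result: ScreenResult) -> list[dict]:
    """Conditions ordered by effectiveness against the total BCSC population.

    Primary key: total-BCSC extinction frequency at the horizon
    (descending).  Tie-breaks: mean total BCSC at the horizon (ascending),
    then condition name (lexicographic).  The baseline is excluded.
    """
    rows = []
    for cond in result.conditions:
        if cond == "baseline":
            continue
        rows.append(
            {
                "condition": cond,
                "extinction_total": result.extinction_frequency(cond, "total"),
                "extinction_emt": result.extinction_frequency(cond, "EMT"),
                "extinction_met": result.extinction_frequency(cond, "MET"),
                "mean_total_at_horizon": result.mean_at(cond, "total"),
            }
        )
    rows.sort(
        key=lambda r: (
            -r["extinction_total"], r["mean_total_at_horizon"], r["condition"],
        )
    )
    return rows


#: channels scaled by the "vary the EMT rate" sweep (the MET -> EMT channels)
EMT_RATE_CHANNELS = ("emt_via_IL6_gp130", "emt_via_TGFb")


def sensitivity_sweep(
    network: ReactionNetwork,
    parameter: Literal["lambda_emt", "met_death"],
    values: Sequence[float],
    condition: Literal["baseline", "HER2+IL6"] = "baseline",
    reps: int = 50,
    settings: LeapSettings | None = None,
    seed: int | None = None,
    horizon_days: float = 1000.0,
    grid_points: int = 101,
) -> dict[float, EnsembleSummary]:
    """Parameter sensitivity of the niche, untreated or under HER2+IL-6.

    ``lambda_emt`` values are multipliers on the epithelial-to-mesenchymal
    transition channels; ``met_death`` values are absolute rates for the
    epithelial-BCSC death channel.  Returns one matched-seed ensemble per
    value.
    """
    if not values:
        raise ValueError("values must be non-empty")
    settings = settings or LeapSettings(ssa_threshold=5)
    grid = np.linspace(0.0, horizon_days, grid_points)
    out: dict[float, EnsembleSummary] = {}
    for v in values:
        if parameter == "lambda_emt":
            net = network.with_scaled_rates({c: v for c in EMT_RATE_CHANNELS})
        elif parameter == "met_death":
            net = network.with_rates({"death_MET": v})
        else:
            raise ValueError("parameter must be 'lambda_emt' or 'met_death'")
        if condition == "HER2+IL6":
            tgts = default_targets(network)
            net = apply_inhibition(net, [tgts["HER2"], tgts["IL6"]])
        elif condition != "baseline":
            raise ValueError("condition must be 'baseline' or 'HER2+IL6'")
        out[float(v)] = simulate_ensemble(
            net, horizon_days, settings, reps, seed=seed, grid=grid
        )
    return out
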