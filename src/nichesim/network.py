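"""Mass-action reaction networks: species, reactions, stoichiometry.

The network object is the universal substrate for every simulator in the
package: it stores an ordered species list, an ordered reaction-channel list,
their mass-action rate constants, and the ``d x c`` stoichiometry matrix
``nu`` whose j-th column is the integer increment vector of channel j.

Conventions
-----------
* Propensities are mass-action: ``a_j * x_k`` for a unimolecular channel,
  ``a_j * x_k * x_m`` for a bimolecular channel on distinct species, and
  ``a_j * x_k * (x_k - 1) / 2`` for a homodimerization.  First-order rate
  constants are per day; second-order ones per particle per day.
* Catalytic species appear on both sides of a reaction, so ``nu`` leaves
  them unchanged.
* At most two reactant molecules per channel (no termolecular channels).
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

SPECIES_CATEGORIES = frozenset(
    {"cell", "cytokine", "receptor", "complex", "intracellular-signal"}
)
REACTION_CATEGORIES = frozenset(
    {
        "binding",
        "dissociation",
        "signaling",
        "transition",
        "renewal",
        "death",
        "transcription",
    }
)


class NetworkDefinitionError(ValueError):
    """A species or reaction definition is inconsistent."""


class ConfigurationError(ValueError):
    """A configuration file or rate table is incomplete or malformed."""


@dataclass(frozen=True)
class Species:
    """A reactant species (cell population, molecule, or complex)."""

    name: str
    category: str = "cell"
    initial_count: int = 0
    display_name: str | None = None

    def __post_init__(self) -> None:
        if not self.name or not isinstance(self.name, str):
            raise NetworkDefinitionError("species name must be a non-empty string")
        if self.category not in SPECIES_CATEGORIES:
            raise NetworkDefinitionError(
                f"unknown species category {self.category!r} for {self.name!r}"
            )
        if int(self.initial_count) < 0:
            raise NetworkDefinitionError(
                f"initial count of {self.name!r} must be non-negative"
            )


@dataclass(frozen=True)
class Reaction:
    """A reaction channel with mass-action rate constant ``rate_constant``.

    ``reactants`` and ``products`` are multisets of species names, stored as
    tuples (a species may appear twice, e.g. a homodimerization).
    """

    label: str
    reactants: tuple[str, ...]
    products: tuple[str, ...]
    rate_constant: float
    category: str = "signaling"

    def __init__(
        self,
        label: str,
        reactants: Iterable[str],
        products: Iterable[str],
        rate_constant: float,
        category: str = "signaling",
    ) -> None:
        object.__setattr__(self, "label", label)
        object.__setattr__(self, "reactants", tuple(reactants))
        object.__setattr__(self, "products", tuple(products))
        object.__setattr__(self, "rate_constant", float(rate_constant))
        object.__setattr__(self, "category", category)
        if not label:
            raise NetworkDefinitionError("reaction label must be non-empty")
        if len(self.reactants) > 2:
            raise NetworkDefinitionError(
                f"reaction {label!r} has more than two reactant molecules"
            )
        if self.rate_constant < 0:
            raise NetworkDefinitionError(f"reaction {label!r} has a negative rate")
        if category not in REACTION_CATEGORIES:
            raise NetworkDefinitionError(
                f"unknown reaction category {category!r} for {label!r}"
            )

    def reactant_counts(self) -> Counter:
        return Counter(self.reactants)

    def product_counts(self) -> Counter:
        return Counter(self.products)


@dataclass
class SystemState:
    """Integer particle counts at a time point (time in days)."""

    time: float
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if (self.counts < 0).any():
            raise ValueError("species counts must be non-negative")


class ReactionNetwork:
    """An immutable-ish mass-action network with precomputed index arrays.

    Attributes
    ----------
    species : list[Species]
    reactions : list[Reaction]
    nu : (d, c) int ndarray
        Stoichiometry matrix; column j is the increment vector of channel j.
    """

    def __init__(
        self,
        species: Sequence[Species],
        reactions: Sequence[Reaction],
        metadata: dict | None = None,
    ) -> None:
        names = [s.name for s in species]
        dupes = [n for n, k in Counter(names).items() if k > 1]
        if dupes:
            raise NetworkDefinitionError(f"duplicate species: {dupes}")
        labels = [r.label for r in reactions]
        dupe_labels = [n for n, k in Counter(labels).items() if k > 1]
        if dupe_labels:
            raise NetworkDefinitionError(f"duplicate reaction labels: {dupe_labels}")

        self.species = list(species)
        self.reactions = list(reactions)
        self.metadata = dict(metadata or {})
        self._index = {n: i for i, n in enumerate(names)}
        d, c = len(species), len(reactions)
        nu = np.zeros((d, c), dtype=np.int64)
        for j, rxn in enumerate(self.reactions):
            for name, k in rxn.reactant_counts().items():
                if name not in self._index:
                    raise NetworkDefinitionError(
                        f"reaction {rxn.label!r} uses unknown species {name!r}"
                    )
                nu[self._index[name], j] -= k
            for name, k in rxn.product_counts().items():
                if name not in self._index:
                    raise NetworkDefinitionError(
                        f"reaction {rxn.label!r} produces unknown species {name!r}"
                    )
                nu[self._index[name], j] += k
        self.nu = nu

        # index arrays for vectorized propensities; sentinel d = dummy species
        # with constant count 1 and zero time derivative.
        i1 = np.full(c, d, dtype=np.int64)
        i2 = np.full(c, d, dtype=np.int64)
        homo = np.zeros(c, dtype=bool)
        for j, rxn in enumerate(self.reactions):
            rc = list(rxn.reactants)
            if len(rc) >= 1:
                i1[j] = self._index[rc[0]]
            if len(rc) == 2:
                i2[j] = self._index[rc[1]]
                homo[j] = rc[0] == rc[1]
        self._i1, self._i2, self._homo = i1, i2, homo
        self.rate_constants = np.array(
            [r.rate_constant for r in self.reactions], dtype=float
        )
        # reactant incidence, used by the hybrid simulator's SSA criterion
        self.reactant_mask = np.zeros((c, d), dtype=bool)
        for j, rxn in enumerate(self.reactions):
            for name in rxn.reactants:
                self.reactant_mask[j, self._index[name]] = True

    # -- basic introspection -------------------------------------------------

    @property
    def d(self) -> int:
        return len(self.species)

    @property
    def c(self) -> int:
        return len(self.reactions)

    @property
    def species_names(self) -> list[str]:
        return [s.name for s in self.species]

    def species_index(self, name: str) -> int:
        return self._index[name]

    def reaction_index(self, label: str) -> int:
        for j, r in enumerate(self.reactions):
            if r.label == label:
                return j
        raise KeyError(label)

    def initial_counts(self) -> np.ndarray:
        return np.array([s.initial_count for s in self.species], dtype=np.int64)

    def initial_state(self) -> SystemState:
        return SystemState(0.0, self.initial_counts())

    # -- propensities --------------------------------------------------------

    def propensities(self, counts: np.ndarray) -> np.ndarray:
        """Mass-action propensity of every channel.

        ``counts`` may be a length-d vector or an (m, d) matrix of states;
        the result has shape (c,) or (m, c) accordingly.
        """
        x = np.asarray(counts, dtype=float)
        single = x.ndim == 1
        if single:
            x = x[None, :]
        xe = np.concatenate([x, np.ones((x.shape[0], 1))], axis=1)
        g1 = xe[:, self._i1]
        x2 = xe[:, self._i2]
        g2 = np.where(self._homo, (x2 - 1.0) * 0.5, x2)
        r = self.rate_constants * g1 * g2
        np.maximum(r, 0.0, out=r)
        return r[0] if single else r

    def propensity_derivatives(self, counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Propensities and their time derivatives along the mean-field flow.

        Returns ``(r, dr_dt)``.  The time derivative applies the chain rule
        d r_j/dt = sum_k (d r_j/d x_k)(d x_k/dt) with d x/dt taken from the
        reaction rate equation evaluated at the current counts.
        """
        x = np.asarray(counts, dtype=float)
        single = x.ndim == 1
        if single:
            x = x[None, :]
        xe = np.concatenate([x, np.ones((x.shape[0], 1))], axis=1)
        g1 = xe[:, self._i1]
        x2 = xe[:, self._i2]
        g2 = np.where(self._homo, (x2 - 1.0) * 0.5, x2)
        r = self.rate_constants * g1 * g2
        np.maximum(r, 0.0, out=r)
        dxdt = r @ self.nu.T.astype(float)
        dxe = np.concatenate([dxdt, np.zeros((x.shape[0], 1))], axis=1)
        dg1 = dxe[:, self._i1]
        dg2 = dxe[:, self._i2] * np.where(self._homo, 0.5, 1.0)
        dr = self.rate_constants * (dg1 * g2 + g1 * dg2)
        if single:
            return r[0], dr[0]
        return r, dr

    # -- copies and modification --------------------------------------------

    def copy(self) -> "ReactionNetwork":
        return ReactionNetwork(self.species, self.reactions, self.metadata)

    def with_rates(self, rates: Mapping[str, float]) -> "ReactionNetwork":
        """Return a copy with the given reaction labels' rate constants replaced."""
        unknown = set(rates) - {r.label for r in self.reactions}
        if unknown:
            raise ConfigurationError(f"unknown reaction labels: {sorted(unknown)}")
        new = [
            Reaction(
                r.label,
                r.reactants,
                r.products,
                rates.get(r.label, r.rate_constant),
                r.category,
            )
            for r in self.reactions
        ]
        return ReactionNetwork(self.species, new, self.metadata)

    def with_scaled_rates(self, scales: Mapping[str, float]) -> "ReactionNetwork":
        """Return a copy with the given labels' rate constants multiplied."""
        return self.with_rates(
            {
                lbl: self.reactions[self.reaction_index(lbl)].rate_constant * s
                for lbl, s in scales.items()
            }
        )

    def with_initial_counts(self, counts: Mapping[str, int]) -> "ReactionNetwork":
        unknown = set(counts) - set(self._index)
        if unknown:
            raise ConfigurationError(f"unknown species: {sorted(unknown)}")
        new = [
            Species(
                s.name,
                s.category,
                int(counts.get(s.name, s.initial_count)),
                s.display_name,
            )
            for s in self.species
        ]
        return ReactionNetwork(new, self.reactions, self.metadata)

    def apply_reaction(self, counts: np.ndarray, j: int) -> np.ndarray:
        """Fire channel j once: remove reactants, add products."""
        return np.asarray(counts, dtype=np.int64) + self.nu[:, j]

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<ReactionNetwork d={self.d} species, c={self.c} reactions>"


# ---------------------------------------------------------------------------
# module-level operations


def build_network(
    species: Sequence[Species], reactions: Sequence[Reaction]
) -> ReactionNetwork:
    """Validate and assemble a :class:`ReactionNetwork`."""
    return ReactionNetwork(species, reactions)


def propensity(network: ReactionNetwork, state: SystemState, j: int) -> float:
    """Propensity of channel ``j`` at ``state`` (events per day)."""
    if not 0 <= j < network.c:
        raise IndexError(f"reaction index {j} out of range")
    return float(network.propensities(state.counts)[j])


def conserved_moieties(network: ReactionNetwork) -> list[np.ndarray]:
    """Integer conservation vectors ``w`` with ``w^T nu = 0``.

    Returns a basis of the left null space of the stoichiometry matrix,
    scaled to primitive integer vectors.  Any integer combination of the
    returned vectors is itself conserved.
    """
    import sympy

    mat = sympy.Matrix(network.nu.T.tolist())
    basis = mat.nullspace()
    out = []
    for vec in basis:
        denoms = [sympy.fraction(sympy.nsimplify(v))[1] for v in vec]
        lcm = sympy.ilcm(*denoms) if denoms else 1
        ints = [int(v * lcm) for v in vec]
        from math import gcd

        g = 0
        for v in ints:
            g = gcd(g, abs(v))
        g = g or 1
        w = np.array([v // g for v in ints], dtype=np.int64)
        if (w <= 0).all():
            w = -w
        out.append(w)
    return out


def is_conserved(network: ReactionNetwork, weights: Sequence[float] | Mapping[str, float]) -> bool:
    """Whether the weighted species total is invariant under every channel."""
    if isinstance(weights, Mapping):
        w = np.zeros(network.d)
        for name, v in weights.items():
            w[network.species_index(name)] = v
    else:
        w = np.asarray(weights, dtype=float)
    return bool(np.all(np.abs(w @ network.nu) < 1e-12))


# ---------------------------------------------------------------------------
# YAML / JSON configuration


def network_to_config(network: ReactionNetwork) -> dict:
    """Serialize a network to the config-dict layout (YAML/JSON friendly)."""
    cfg: dict = {
        "species": [
            {
                "name": s.name,
                "category": s.category,
                **({"display_name": s.display_name} if s.display_name else {}),
            }
            for s in network.species
        ],
        "reactions": [
            {
                "label": r.label,
                "reactants": list(r.reactants),
                "products": list(r.products),
                "category": r.category,
            }
            for r in network.reactions
        ],
        "rates": {r.label: r.rate_constant for r in network.reactions},
        "initial_counts": {s.name: int(s.initial_count) for s in network.species},
    }
    if "inhibition_map" in network.metadata:
        cfg["inhibition_map"] = {
            k: list(v) for k, v in network.metadata["inhibition_map"].items()
        }
    return cfg


def network_from_config(cfg: dict) -> ReactionNetwork:
    """Build a network from a config dict (sections: species, reactions,
    rates, initial_counts, inhibition_map)."""
    try:
        init = cfg.get("initial_counts", {})
        species = [
            Species(
                s["name"],
                s.get("category", "cell"),
                int(init.get(s["name"], s.get("initial_count", 0))),
                s.get("display_name"),
            )
            for s in cfg["species"]
        ]
        rates = cfg.get("rates", {})
        reactions = []
        for r in cfg["reactions"]:
            if "rate_constant" in r:
                a = r["rate_constant"]
            elif r["label"] in rates:
                a = rates[r["label"]]
            else:
                raise ConfigurationError(
                    f"no rate constant for reaction {r['label']!r}"
                )
            reactions.append(
                Reaction(
                    r["label"],
                    r["reactants"],
                    r["products"],
                    a,
                    r.get("category", "signaling"),
                )
            )
    except KeyError as exc:
        raise ConfigurationError(f"missing config key: {exc}") from exc
    meta = {}
    if "inhibition_map" in cfg:
        meta["inhibition_map"] = {k: list(v) for k, v in cfg["inhibition_map"].items()}
    return ReactionNetwork(species, reactions, meta)


def save_network(network: ReactionNetwork, path: str | Path) -> None:
    path = Path(path)
    cfg = network_to_config(network)
    if path.suffix in {".yml", ".yaml"}:
        path.write_text(yaml.safe_dump(cfg, sort_keys=False))
    elif path.suffix == ".json":
        path.write_text(json.dumps(cfg, indent=1))
    elif path.suffix == ".xml" or path.suffix == ".sbml":
        from .sbml import write_sbml

        write_sbml(network, path)
    else:
        raise ConfigurationError(f"unknown network file format: {path.suffix}")


def load_network(path: str | Path) -> ReactionNetwork:
    path = Path(path)
    if path.suffix in {".yml", ".yaml"}:
        return network_from_config(yaml.safe_load(path.read_text()))
    if path.suffix == ".json":
        return network_from_config(json.loads(path.read_text()))
    if path.suffix in {".xml", ".sbml"}:
        from .sbml import read_sbml

        return read_sbml(path)
    raise ConfigurationError(f"unknown network file format: {path.suffix}")


# re-exported here so the network module presents the full model-building
# surface; the niche tables live in their own module for readability.
from .niche import build_niche_model  # noqa: E402,F401
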