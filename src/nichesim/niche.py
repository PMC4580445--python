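"""The breast cancer stem cell (BCSC) niche model: 37 reaction channels.

The model couples two interconverting BCSC populations — a proliferative
epithelial (MET-like, ALDH+) state and a quiescent invasive mesenchymal
(EMT-like, CD44+/CD24-) state — to the microenvironmental signaling that
regulates them: IL-6/gp130 and IL-8/CXCR1 cytokine-receptor binding,
HER2/EGFR dimerization, TGF-beta, BMP and mir-93 control of the state
transitions, Stat3/Akt activation converging on NF-kB (release of p50-RelA
from its IkB complex), NF-kB-driven transcription of IL-6 (an inflammatory
positive feedback loop) and of Lin-28, and beta-catenin activation driving
symmetric self-renewal of the epithelial BCSCs.

Identifiers are ASCII-normalized (``IL6_gp130``, ``act_Stat3``, ...);
``display_name`` carries the conventional notation (``IL-6 . gp130``).

Rate constants
--------------
Numeric rate constants for the niche channels are shipped as documented,
overridable defaults (:data:`DEFAULT_RATES`), chosen on category scales —
receptor binding and dissociation fast and on similar time scales,
intracellular signaling intermediate, transcription roughly an order of
magnitude slower — and calibrated so that the default niche reproduces the
qualitative behaviors the model is used to probe (untreated growth of both
BCSC populations, the EMT-refuge effect of IL-6, extinction under combined
HER2 + IL-6 blockade).  Every value can be overridden per channel.

Cytokines carry no degradation channels and quiescent mesenchymal cells
carry no death channel: the channel list is implemented exactly as the
model defines it.
"""

from __future__ import annotations

from typing import Mapping

from .network import ConfigurationError, Reaction, ReactionNetwork, Species

# name, category, default initial count, display name
NICHE_SPECIES: list[tuple[str, str, int, str]] = [
    # cells
    ("MET", "cell", 800, "MET-like BCSC"),
    ("EMT", "cell", 200, "EMT-like BCSC"),
    # cytokines
    ("IL6", "cytokine", 1000, "IL-6"),
    ("IL8", "cytokine", 100, "IL-8"),
    ("TGFb", "cytokine", 100, "TGF-beta"),
    ("BMP", "cytokine", 100, "BMP"),
    # receptors
    ("gp130", "receptor", 100, "gp130"),
    ("CXCR1", "receptor", 100, "CXCR1"),
    ("HER2", "receptor", 100, "HER2"),
    ("EGFR", "receptor", 100, "EGFR"),
    ("TGFbR2", "receptor", 100, "TGF-betaR2"),
    # complexes
    ("IL6_gp130", "complex", 0, "IL-6 . gp130"),
    ("IL8_CXCR1", "complex", 0, "IL-8 . CXCR1"),
    ("TGFb_TGFbR2", "complex", 0, "TGF-beta . TGF-betaR2"),
    ("HER2_EGFR", "complex", 0, "HER2 . EGFR"),
    ("Lin28_HER2mRNA", "complex", 0, "Lin-28 . HER2 mRNA"),
    ("Lin28_Let7", "complex", 0, "Lin-28 . Let-7"),
    ("Let7_IL6", "complex", 0, "Let-7 . IL-6"),
    ("mir93_TGFb", "complex", 0, "mir-93 . TGF-beta"),
    ("IkB_p50_RelA", "complex", 100, "IkB . p50 . RelA"),
    # intracellular signals
    ("Stat3", "intracellular-signal", 100, "Stat3"),
    ("act_Stat3", "intracellular-signal", 0, "activated Stat3"),
    ("Akt", "intracellular-signal", 100, "Akt"),
    ("act_Akt", "intracellular-signal", 0, "activated Akt"),
    ("bcat", "intracellular-signal", 100, "beta-catenin"),
    ("act_bcat", "intracellular-signal", 0, "activated beta-catenin"),
    ("Lin28", "intracellular-signal", 0, "Lin-28"),
    ("Let7", "intracellular-signal", 100, "Let-7"),
    ("mir93", "intracellular-signal", 100, "mir-93"),
    ("HER2_mRNA", "intracellular-signal", 100, "HER2 mRNA"),
    ("IkB", "intracellular-signal", 0, "IkB"),
    ("p50_RelA", "intracellular-signal", 0, "p50 . RelA"),
]

# label, reactants, products, category
NICHE_REACTIONS: list[tuple[str, list[str], list[str], str]] = [
    # receptor binding and dissociation
    ("bind_IL6_gp130", ["IL6", "gp130"], ["IL6_gp130"], "binding"),
    ("diss_IL6_gp130", ["IL6_gp130"], ["IL6", "gp130"], "dissociation"),
    ("bind_IL8_CXCR1", ["IL8", "CXCR1"], ["IL8_CXCR1"], "binding"),
    ("diss_IL8_CXCR1", ["IL8_CXCR1"], ["IL8", "CXCR1"], "dissociation"),
    ("bind_TGFb_TGFbR2", ["TGFb", "TGFbR2"], ["TGFb_TGFbR2"], "binding"),
    ("diss_TGFb_TGFbR2", ["TGFb_TGFbR2"], ["TGFb", "TGFbR2"], "dissociation"),
    ("bind_HER2_EGFR", ["HER2", "EGFR"], ["HER2_EGFR"], "binding"),
    ("diss_HER2_EGFR", ["HER2_EGFR"], ["HER2", "EGFR"], "dissociation"),
    # activation of intracellular signaling
    ("act_Stat3_via_IL6_gp130", ["IL6_gp130", "Stat3"], ["IL6_gp130", "act_Stat3"], "signaling"),
    ("act_Akt_via_IL8_CXCR1", ["IL8_CXCR1", "Akt"], ["IL8_CXCR1", "act_Akt"], "signaling"),
    ("act_Stat3_via_IL8_CXCR1", ["IL8_CXCR1", "Stat3"], ["IL8_CXCR1", "act_Stat3"], "signaling"),
    ("act_Akt_via_HER2_EGFR", ["HER2_EGFR", "Akt"], ["HER2_EGFR", "act_Akt"], "signaling"),
    ("nfkb_release_via_act_Akt", ["act_Akt", "IkB_p50_RelA"], ["act_Akt", "IkB", "p50_RelA"], "signaling"),
    ("deact_Akt", ["act_Akt"], ["Akt"], "signaling"),
    ("nfkb_release_via_act_Stat3", ["act_Stat3", "IkB_p50_RelA"], ["act_Stat3", "IkB", "p50_RelA"], "signaling"),
    ("deact_Stat3", ["act_Stat3"], ["Stat3"], "signaling"),
    ("bind_Lin28_HER2mRNA", ["Lin28", "HER2_mRNA"], ["Lin28_HER2mRNA"], "binding"),
    ("act_bcat_via_Lin28", ["Lin28", "bcat"], ["Lin28", "act_bcat"], "signaling"),
    ("act_bcat_via_HER2_EGFR", ["HER2_EGFR", "bcat"], ["HER2_EGFR", "act_bcat"], "signaling"),
    ("deact_bcat", ["act_bcat"], ["bcat"], "signaling"),
    ("bind_Lin28_Let7", ["Lin28", "Let7"], ["Lin28_Let7"], "binding"),
    ("diss_Lin28_Let7", ["Lin28_Let7"], ["Lin28", "Let7"], "dissociation"),
    ("bind_Let7_IL6", ["Let7", "IL6"], ["Let7_IL6"], "binding"),
    ("diss_Let7_IL6", ["Let7_IL6"], ["Let7", "IL6"], "dissociation"),
    ("bind_mir93_TGFb", ["mir93", "TGFb"], ["mir93_TGFb"], "binding"),
    ("diss_mir93_TGFb", ["mir93_TGFb"], ["mir93", "TGFb"], "dissociation"),
    ("reassoc_IkB_p50_RelA", ["IkB", "p50_RelA"], ["IkB_p50_RelA"], "binding"),
    # EMT/MET transitions, self-renewal and cell death
    ("emt_via_IL6_gp130", ["MET", "IL6_gp130"], ["EMT", "IL6_gp130"], "transition"),
    ("emt_via_TGFb", ["MET", "TGFb"], ["EMT", "TGFb"], "transition"),
    ("met_via_mir93", ["EMT", "mir93"], ["MET", "mir93"], "transition"),
    ("met_via_BMP", ["EMT", "BMP"], ["MET", "BMP"], "transition"),
    ("met_via_HER2_EGFR", ["EMT", "HER2_EGFR"], ["MET", "HER2_EGFR"], "transition"),
    ("death_MET", ["MET"], [], "death"),
    ("renewal_MET", ["MET", "act_bcat"], ["MET", "MET", "act_bcat"], "renewal"),
    # transcription events
    ("transcribe_HER2", ["Lin28_HER2mRNA"], ["Lin28", "HER2", "HER2_mRNA"], "transcription"),
    ("transcribe_IL6", ["p50_RelA"], ["IL6", "p50_RelA"], "transcription"),
    ("transcribe_Lin28", ["p50_RelA"], ["p50_RelA", "Lin28"], "transcription"),
]

# Default rate constants (first-order: day^-1; second-order:
# particle^-1 day^-1).  Category scales: binding/dissociation fast,
# signaling intermediate, transcription slow.  The IL-8/CXCR1 arm is kept
# weak relative to the IL-6/gp130 and HER2/EGFR arms, reflecting its role
# as a secondary input to Stat3/Akt in this niche.
DEFAULT_RATES: dict[str, float] = {
    "bind_IL6_gp130": 1e-4,
    "diss_IL6_gp130": 0.1,
    "bind_IL8_CXCR1": 1e-4,
    "diss_IL8_CXCR1": 0.1,
    "bind_TGFb_TGFbR2": 1e-4,
    "diss_TGFb_TGFbR2": 0.1,
    "bind_HER2_EGFR": 1e-3,
    "diss_HER2_EGFR": 0.1,
    "act_Stat3_via_IL6_gp130": 1e-3,
    "act_Akt_via_IL8_CXCR1": 2e-5,
    "act_Stat3_via_IL8_CXCR1": 2e-5,
    "act_Akt_via_HER2_EGFR": 1e-3,
    "nfkb_release_via_act_Akt": 1e-3,
    "deact_Akt": 0.1,
    "nfkb_release_via_act_Stat3": 1e-3,
    "deact_Stat3": 0.1,
    "bind_Lin28_HER2mRNA": 1e-4,
    "act_bcat_via_Lin28": 2e-4,
    "act_bcat_via_HER2_EGFR": 1e-3,
    "deact_bcat": 0.1,
    "bind_Lin28_Let7": 1e-4,
    "diss_Lin28_Let7": 0.1,
    "bind_Let7_IL6": 1e-4,
    "diss_Let7_IL6": 0.1,
    "bind_mir93_TGFb": 1e-4,
    "diss_mir93_TGFb": 0.1,
    "reassoc_IkB_p50_RelA": 1e-3,
    "emt_via_IL6_gp130": 1e-4,
    "emt_via_TGFb": 5e-5,
    "met_via_mir93": 1e-4,
    "met_via_BMP": 1e-4,
    "met_via_HER2_EGFR": 1e-4,
    "death_MET": 0.012,
    "renewal_MET": 4e-4,
    "transcribe_HER2": 0.05,
    "transcribe_IL6": 0.05,
    "transcribe_Lin28": 0.01,
}

# Which channels an "inhibit X" switch scales (user-editable; see
# therapy_screen).  Rule of thumb behind these defaults: scale every channel
# in which the target participates as a reactant (including catalytically)
# plus any channel that transcribes it de novo.  Downstream effects (e.g.
# complexes already formed) decay through the untouched dissociation
# channels.
DEFAULT_INHIBITION_MAP: dict[str, list[str]] = {
    "IL6": ["bind_IL6_gp130", "bind_Let7_IL6", "transcribe_IL6"],
    "IL8": ["bind_IL8_CXCR1"],
    "TGFb": ["bind_TGFb_TGFbR2", "bind_mir93_TGFb", "emt_via_TGFb"],
    "BMP": ["met_via_BMP"],
    "mir93": ["bind_mir93_TGFb", "met_via_mir93"],
    "HER2": ["bind_HER2_EGFR", "transcribe_HER2"],
    "Akt": ["act_Akt_via_IL8_CXCR1", "act_Akt_via_HER2_EGFR"],
    "Stat3": ["act_Stat3_via_IL6_gp130", "act_Stat3_via_IL8_CXCR1"],
    "Lin28": [
        "transcribe_Lin28",
        "bind_Lin28_HER2mRNA",
        "act_bcat_via_Lin28",
        "bind_Lin28_Let7",
    ],
}


def build_niche_model(
    params: Mapping[str, float] | None = None,
    init: Mapping[str, int] | None = None,
) -> ReactionNetwork:
    """Construct the 37-channel BCSC niche network.

    Parameters
    ----------
    params
        Per-channel rate-constant overrides, keyed by reaction label.
        Channels not named keep their documented defaults.
    init
        Initial-count overrides keyed by species name.

    Default initial counts: 800 epithelial (MET-like) and 200 mesenchymal
    (EMT-like) BCSCs, IL-6 at 1000 (elevated relative to the other
    cytokines), IL-8 and TGF-beta at 100, every receptor and free signaling
    molecule at 100, and all dimers, activated forms and Lin-28 at 0.
    """
    rates = dict(DEFAULT_RATES)
    if params:
        unknown = set(params) - set(rates)
        if unknown:
            raise ConfigurationError(
                f"unknown niche reaction labels: {sorted(unknown)}"
            )
        rates.update(params)
    counts = {name: n for name, _, n, _ in NICHE_SPECIES}
    if init:
        unknown = set(init) - set(counts)
        if unknown:
            raise ConfigurationError(f"unknown niche species: {sorted(unknown)}")
        counts.update(init)
    species = [
        Species(name, cat, counts[name], disp) for name, cat, _, disp in NICHE_SPECIES
    ]
    reactions = [
        Reaction(label, reac, prod, rates[label], cat)
        for label, reac, prod, cat in NICHE_REACTIONS
    ]
    return ReactionNetwork(
        species, reactions, {"inhibition_map": dict(DEFAULT_INHIBITION_MAP)}
    )
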