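"""SBML Level 3 import/export of reaction networks.

A compact reader/writer covering what mass-action particle-count models
need: species with integer initial amounts, reactions with reactant and
product stoichiometries, and one mass-action rate constant per reaction
(stored as the kinetic law's local parameter ``k``, with the corresponding
``k * reactants`` MathML).  Species categories and reaction categories are
carried in a ``nichesim``-namespaced annotation so a round trip preserves
the full network definition.
"""

from __future__ import annotations

from pathlib import Path

from lxml import etree

from .network import Reaction, ReactionNetwork, Species

SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"
ANNOT_NS = "urn:nichesim:annotations"

_NSMAP = {None: SBML_NS, "ns": ANNOT_NS}


def _q(tag: str, ns: str = SBML_NS) -> str:
    return f"{{{ns}}}{tag}"


def write_sbml(network: ReactionNetwork, path: str | Path) -> None:
    """Serialize a network as an SBML Level 3 Version 2 document."""
    root = etree.Element(_q("sbml"), nsmap=_NSMAP, level="3", version="2")
    model = etree.SubElement(root, _q("model"), id="nichesim_model")
    comps = etree.SubElement(model, _q("listOfCompartments"))
    etree.SubElement(
        comps, _q("compartment"), id="main", constant="true", spatialDimensions="3",
        size="1",
    )
    lspecies = etree.SubElement(model, _q("listOfSpecies"))
    for s in network.species:
        el = etree.SubElement(
            lspecies, _q("species"), id=s.name, compartment="main",
            initialAmount=str(float(s.initial_count)),
            hasOnlySubstanceUnits="true", boundaryCondition="false",
            constant="false",
        )
        el.set(_q("category", ANNOT_NS), s.category)
        if s.display_name:
            el.set("name", s.display_name)
    lrxn = etree.SubElement(model, _q("listOfReactions"))
    for r in network.reactions:
        el = etree.SubElement(
            lrxn, _q("reaction"), id=r.label, reversible="false",
        )
        el.set(_q("category", ANNOT_NS), r.category)
        if r.reactants:
            lr = etree.SubElement(el, _q("listOfReactants"))
            for name, k in sorted(r.reactant_counts().items()):
                etree.SubElement(
                    lr, _q("speciesReference"), species=name,
                    stoichiometry=str(float(k)), constant="true",
                )
        if r.products:
            lp = etree.SubElement(el, _q("listOfProducts"))
            for name, k in sorted(r.product_counts().items()):
                etree.SubElement(
                    lp, _q("speciesReference"), species=name,
                    stoichiometry=str(float(k)), constant="true",
                )
        kl = etree.SubElement(el, _q("kineticLaw"))
        math = etree.SubElement(kl, _q("math", MATHML_NS))
        terms = ["k", *r.reactants]
        if len(terms) == 1:
            ci = etree.SubElement(math, _q("ci", MATHML_NS))
            ci.text = " k "
        else:
            apply = etree.SubElement(math, _q("apply", MATHML_NS))
            etree.SubElement(apply, _q("times", MATHML_NS))
            for t in terms:
                ci = etree.SubElement(apply, _q("ci", MATHML_NS))
                ci.text = f" {t} "
        lparams = etree.SubElement(kl, _q("listOfLocalParameters"))
        etree.SubElement(
            lparams, _q("localParameter"), id="k", value=repr(r.rate_constant),
        )
    tree = etree.ElementTree(root)
    tree.write(
        str(path), xml_declaration=True, encoding="UTF-8", pretty_print=True
    )


def read_sbml(path: str | Path) -> ReactionNetwork:
    """Parse an SBML Level 3 document written by :func:`write_sbml`.

    Only the constructs the writer emits are interpreted; unknown SBML
    features are ignored.
    """
    tree = etree.parse(str(path))
    model = tree.getroot().find(_q("model"))
    if model is None:
        raise ValueError(f"{path}: no <model> element")
    species = []
    for el in model.findall(f"{_q('listOfSpecies')}/{_q('species')}"):
        species.append(
            Species(
                el.get("id"),
                el.get(_q("category", ANNOT_NS), "cell"),
                int(float(el.get("initialAmount", "0"))),
                el.get("name"),
            )
        )
    reactions = []
    for el in model.findall(f"{_q('listOfReactions')}/{_q('reaction')}"):
        reactants: list[str] = []
        for ref in el.findall(f"{_q('listOfReactants')}/{_q('speciesReference')}"):
            reactants.extend([ref.get("species")] * int(float(ref.get("stoichiometry", "1"))))
        products: list[str] = []
        for ref in el.findall(f"{_q('listOfProducts')}/{_q('speciesReference')}"):
            products.extend([ref.get("species")] * int(float(ref.get("stoichiometry", "1"))))
        k = None
        for lp in el.findall(
            f"{_q('kineticLaw')}/{_q('listOfLocalParameters')}/{_q('localParameter')}"
        ):
            if lp.get("id") == "k":
                k = float(lp.get("value"))
        if k is None:
            raise ValueError(f"reaction {el.get('id')!r}: no local parameter 'k'")
        reactions.append(
            Reaction(
                el.get("id"), reactants, products, k,
                el.get(_q("category", ANNOT_NS), "signaling"),
            )
        )
    return ReactionNetwork(species, reactions)
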