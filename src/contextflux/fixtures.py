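"""Programmatic test assets: a small two-pathway bacterial model and synthetic
transcriptomes.

The example network has two compartments (extracellular ``_e``, intracellular
``_c``) and seven chemical species — glucose, proline, glycine,
5-aminovalerate, acetate, CO2 and ATP — giving 14 metabolites. Sixteen
reactions wire them together: 7 exchanges, 7 transporters and 2 lumped
metabolic reactions. ATP (arbitrary units) can be generated two ways:

* glycolysis:            1 glc_c -> 1 atp_c + 1 ac_c + 0.9 co2_c
* Stickland fermentation: 1 pro_c + 1 gly_c -> 0.9 atp_c + 1 amv_c + 0.5 co2_c

Glycolysis yields more ATP per unit of substrate (1 per glucose versus 0.45
per amino acid) and touches fewer reactions, so it is the parsimonious route;
Stickland fermentation pairs proline (reduced to 5-aminovalerate) and glycine
in coupled redox reactions at lower yield, and its CO2 byproduct forces CO2
efflux whenever it runs. The boundary demand for extracellular ATP is the
objective. Coefficients are in arbitrary units, chosen so that pathway choice
under transcript weighting is decided by the weighted-cost ordering rather
than by substrate availability (see docs/methods.md).
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from cobra import Metabolite, Model, Reaction

from .weighting import TranscriptAbundanceTable

PROFILES = ("glycolysis_high", "stickland_high", "uniform")

#: genes whose products act on the glucose branch (enzyme + glucose transporter)
GLYCOLYSIS_GENES = ("g_glyc", "g_tglc")
#: Stickland enzyme plus the peptide-substrate and 5-aminovalerate transporters
STICKLAND_GENES = ("g_stck", "g_tpro", "g_tgly", "g_tamv")


@dataclass
class ExampleSpec:
    """Which branch of the example model is transcriptionally elevated."""

    profile: str = "uniform"
    high: float = 1000.0
    low: float = 10.0

    def __post_init__(self) -> None:
        if self.profile not in PROFILES:
            raise ValueError(f"unknown profile {self.profile!r}; expected {PROFILES}")
        if self.high <= 0 or self.low <= 0:
            raise ValueError("abundance magnitudes must be positive")


def _rxn(model, rxn_id, stoich, lb, ub, gene=None):
    rxn = Reaction(rxn_id, lower_bound=lb, upper_bound=ub)
    rxn.add_metabolites({model.metabolites.get_by_id(m): c for m, c in stoich.items()})
    if gene is not None:
        rxn.gene_reaction_rule = gene
    return rxn


def build_example_model() -> Model:
    """Construct the 16-reaction / 14-metabolite two-pathway example model."""
    model = Model("example_model")
    species = {
        "glc": "glucose",
        "pro": "proline",
        "gly": "glycine",
        "amv": "5-aminovalerate",
        "ac": "acetate",
        "co2": "carbon dioxide",
        "atp": "ATP",
    }
    mets = []
    for sid, name in species.items():
        mets.append(Metabolite(f"{sid}_e", name=f"{name} (extracellular)", compartment="e"))
        mets.append(Metabolite(f"{sid}_c", name=f"{name} (intracellular)", compartment="c"))
    model.add_metabolites(mets)

    reactions = []
    # 7 exchanges: substrates open in both directions ("complete media"),
    # the ATP exchange is the secretion-only demand serving as objective.
    for sid in species:
        if sid == "atp":
            reactions.append(_rxn(model, "EX_atp_e", {"atp_e": -1}, 0, 1000))
        else:
            reactions.append(_rxn(model, f"EX_{sid}_e", {f"{sid}_e": -1}, -1000, 1000))
    # 7 transporters, one per species, each with its own gene
    for sid, gene in [
        ("glc", "g_tglc"),
        ("pro", "g_tpro"),
        ("gly", "g_tgly"),
        ("amv", "g_tamv"),
        ("ac", "g_tac"),
        ("co2", "g_tco2"),
        ("atp", "g_tatp"),
    ]:
        reactions.append(
            _rxn(model, f"T_{sid.upper()}", {f"{sid}_e": -1, f"{sid}_c": 1}, -1000, 1000, gene)
        )
    # 2 lumped metabolic reactions
    reactions.append(
        _rxn(
            model,
            "GLYC",
            {"glc_c": -1, "atp_c": 1, "ac_c": 1, "co2_c": 0.9},
            0,
            1000,
            "g_glyc",
        )
    )
    reactions.append(
        _rxn(
            model,
            "STCK",
            {"pro_c": -1, "gly_c": -1, "atp_c": 0.9, "amv_c": 1, "co2_c": 0.5},
            0,
            1000,
            "g_stck",
        )
    )
    model.add_reactions(reactions)
    # ATP leaves the cell through its transporter and is drained by EX_atp_e,
    # whose flux is the ATP generation rate.
    model.objective = "EX_atp_e"
    return model


def simulate_transcriptome(model: Model, spec: ExampleSpec) -> TranscriptAbundanceTable:
    """Simulated transcript abundances for the example model.

    ``uniform`` assigns one identical abundance to every gene; the two
    pathway profiles assign ``spec.high`` to the elevated branch's enzyme and
    transporter genes and ``spec.low`` everywhere else.
    """
    genes = [g.id for g in model.genes]
    if not genes:
        raise ValueError("model has no genes to simulate transcription for")
    if spec.profile == "uniform":
        return {g: spec.high for g in genes}
    elevated = GLYCOLYSIS_GENES if spec.profile == "glycolysis_high" else STICKLAND_GENES
    return {g: (spec.high if g in elevated else spec.low) for g in genes}


def random_genre(n_metabolites: int, n_reactions: int, seed: int) -> Model:
    """Random flux-consistent model with a guaranteed source->objective path.

    A linear conversion chain runs from one open exchange through intracellular
    metabolites to a demand reaction (the objective), so FBA optimum > 0 by
    construction. Remaining reaction slots become off-path reactions that can
    never carry flux in a minimum-total-flux solution: dead-end producers
    (their product has no consumer) and backward chain edges (futile cycles
    that only add cost). This keeps the parsimonious optimum unique, which
    property tests rely on. GPR rules are random 1-2 gene AND/OR clauses.
    """
    if n_metabolites < 2:
        raise ValueError("need at least 2 metabolites")
    rng = random.Random(seed)

    # reserve up to a third of metabolites as dead-end products
    n_dead = min(n_metabolites // 3, max(0, n_reactions - n_metabolites - 1))
    n_chain = n_metabolites - n_dead - 1  # minus the extracellular source
    if n_chain < 1:
        n_chain, n_dead = n_metabolites - 1, 0

    model = Model(f"random_genre_{seed}")
    src = Metabolite("src_e", compartment="e")
    chain = [Metabolite(f"c{i}_c", compartment="c") for i in range(n_chain)]
    dead = [Metabolite(f"d{i}_c", compartment="c") for i in range(n_dead)]
    model.add_metabolites([src] + chain + dead)

    gene_pool = [f"gene_{i}" for i in range(max(2, (n_reactions * 2) // 3))]

    def rule() -> str:
        if rng.random() < 0.25:
            return ""  # gene-less reaction
        if rng.random() < 0.5:
            return rng.choice(gene_pool)
        op = rng.choice([" and ", " or "])
        return op.join(rng.sample(gene_pool, 2))

    reactions = [
        _rxn(model, "EX_src_e", {"src_e": -1}, -1000, 0),
        _rxn(model, "T_SRC", {"src_e": -1, "c0_c": 1}, 0, 1000, rule()),
    ]
    for i in range(n_chain - 1):
        reversible = rng.random() < 0.4
        reactions.append(
            _rxn(
                model,
                f"STEP_{i}",
                {f"c{i}_c": -1, f"c{i + 1}_c": 1},
                -1000 if reversible else 0,
                1000,
                rule(),
            )
        )
    reactions.append(
        _rxn(model, "DM_obj", {f"c{n_chain - 1}_c": -1}, 0, 1000, rule())
    )

    extra = n_reactions - len(reactions)
    for k in range(max(0, extra)):
        if dead and (k % 2 == 0 or n_chain < 2):
            j = rng.randrange(len(dead))
            i = rng.randrange(n_chain)
            stoich = {f"c{i}_c": -1, dead[j].id: 1}
            rxn_id = f"DEADEND_{k}"
        elif n_chain >= 2:
            j = rng.randrange(1, n_chain)
            i = rng.randrange(0, j)
            stoich = {f"c{j}_c": -1, f"c{i}_c": 1}  # backward edge: futile cycle
            rxn_id = f"BACK_{k}"
        else:
            stoich = {"c0_c": -1, "src_e": 1}  # re-export: futile with uptake
            rxn_id = f"BACK_{k}"
        reactions.append(_rxn(model, rxn_id, stoich, 0, 1000, rule()))

    model.add_reactions(reactions)
    model.objective = "DM_obj"
    if model.slim_optimize() <= 0:
        raise RuntimeError("random model construction failed to produce growth")
    return model
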