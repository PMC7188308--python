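"""Core transcriptome-guided parsimonious contextualization.

The pipeline constrains the cellular objective to a fraction f of its optimum,
splits reversible reactions into irreversible pairs, minimizes the
transcript-weighted total flux

    min sum_r rw_pruning(r) * v_r    s.t.  S v = 0,  0 <= v <= v_max,
                                           v_objective >= f * z*

and removes every reaction whose flux in that solution falls below the pruning
threshold, together with orphaned genes and metabolites. The surviving model
still reaches at least f * z* and is handed to the sampling module to explore
the remaining solution space under the inverse (sampling) weights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import pandas as pd
from cobra import Model, Reaction
from optlang.symbolics import Zero

from .weighting import (
    GPR_MODES,
    ReactionWeights,
    TranscriptAbundanceTable,
    assign_reaction_weights,
    compute_gene_weights,
    normalize_rpm,
)

logger = logging.getLogger(__name__)

FEASIBILITY_TOL = 1e-6
REVERSE_SUFFIX = "__rev"

OBJECTIVE_MODES = ("objective", "tasks")


@dataclass
class ContextSettings:
    """All tunable parameters of a contextualization run."""

    fraction: float = 0.8
    prune_threshold: float = 1e-6
    n_samples: int = 500
    gpr_mode: str = "max"
    weight_cap: Optional[float] = None
    protected_reactions: Sequence[str] = field(default_factory=tuple)
    tasks: Sequence[str] = field(default_factory=tuple)
    skip_sampling: bool = False
    objective_mode: str = "objective"
    sampling_fraction: Optional[float] = None  # defaults to `fraction`
    task_flux: Optional[float] = None  # defaults to `prune_threshold`
    seed: int = 42
    solver: str = "glpk"

    def __post_init__(self) -> None:
        if not 0 < self.fraction <= 1:
            raise ValueError(f"fraction must be in (0, 1], got {self.fraction}")
        if self.prune_threshold <= 0:
            raise ValueError("prune_threshold must be positive")
        if self.n_samples < 2:
            raise ValueError("n_samples must be at least 2")
        if self.gpr_mode not in GPR_MODES:
            raise ValueError(f"gpr_mode must be one of {GPR_MODES}")
        if self.objective_mode not in OBJECTIVE_MODES:
            raise ValueError(f"objective_mode must be one of {OBJECTIVE_MODES}")
        if self.sampling_fraction is not None and not 0 <= self.sampling_fraction <= 1:
            raise ValueError("sampling_fraction must be in [0, 1]")

    def effective_sampling_fraction(self) -> float:
        return self.fraction if self.sampling_fraction is None else self.sampling_fraction

    def effective_task_flux(self) -> float:
        return self.prune_threshold if self.task_flux is None else self.task_flux

    def to_dict(self) -> dict:
        return {
            "fraction": self.fraction,
            "prune_threshold": self.prune_threshold,
            "n_samples": self.n_samples,
            "gpr_mode": self.gpr_mode,
            "weight_cap": self.weight_cap,
            "protected_reactions": list(self.protected_reactions),
            "tasks": list(self.tasks),
            "skip_sampling": self.skip_sampling,
            "objective_mode": self.objective_mode,
            "sampling_fraction": self.effective_sampling_fraction(),
            "task_flux": self.effective_task_flux(),
            "seed": self.seed,
            "solver": self.solver,
        }


@dataclass
class IrreversibleModel:
    """A model in which every reaction carries non-negative flux.

    ``model`` holds the split copy (reversible parents replaced by a forward
    copy [0, ub] and a stoichiometry-negated reverse copy [0, -lb]);
    ``source`` is the unsplit, objective-constrained parent model; ``parent``
    maps split reaction ids back to parent ids.
    """

    model: Model
    source: Model
    parent: Dict[str, str]
    halves: Dict[str, List[str]]


@dataclass
class ContextResult:
    """Everything a contextualization run produced, plus full provenance."""

    pruned_model: Model
    retained_reactions: Set[str]
    pruned_reactions: Set[str]
    settings: ContextSettings
    weights: ReactionWeights
    objective_bounds: Tuple[Optional[float], Optional[float]]
    metrics: Dict[str, float]
    flux_samples: Optional["FluxSampleSet"] = None  # noqa: F821
    fva: Optional[pd.DataFrame] = None
    concordance: Optional["ConcordanceResult"] = None  # noqa: F821
    minimization_fluxes: Optional[pd.Series] = None


def _objective_reaction(model: Model) -> Reaction:
    """The unique reaction carrying the model's objective."""
    rxns = [r for r in model.reactions if r.objective_coefficient != 0]
    if not rxns:
        raise ValueError("model declares no objective reaction")
    if len(rxns) > 1:
        raise ValueError(
            f"expected a single objective reaction, found {[r.id for r in rxns]}"
        )
    return rxns[0]


def constrain_objective(model: Model, f: float) -> Tuple[Model, float]:
    """Install a lower bound f * z* on the objective reaction (in place).

    Solves FBA for the optimum z* first; the original upper bound is kept, so
    the objective may vary within [f * z*, z*] afterwards ("a 20% range of
    allowed variation" at the default f = 0.8).
    """
    if not 0 < f <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {f}")
    obj_rxn = _objective_reaction(model)
    z_star = model.slim_optimize()
    if z_star is None or pd.isna(z_star) or z_star <= 0:
        raise ValueError("objective cannot carry flux (infeasible model or z* <= 0)")
    obj_rxn.lower_bound = max(obj_rxn.lower_bound, f * z_star)
    return model, float(z_star)


def split_reversible(model: Model) -> IrreversibleModel:
    """Replace every reversible reaction by a forward/reverse pair.

    Reactions with lower_bound >= 0 are copied unchanged. A reversible parent
    with bounds (lb < 0, ub) becomes a forward copy with bounds
    (max(lb, 0), max(ub, 0)) and a reverse copy with negated stoichiometry and
    bounds (max(-ub, 0), -lb), so recombining forward - reverse reproduces the
    parent's feasible interval.
    """
    split = Model(f"{model.id}_irreversible")
    split.add_metabolites([m.copy() for m in model.metabolites])
    parent: Dict[str, str] = {}
    halves: Dict[str, List[str]] = {}
    new_reactions = []
    for rxn in model.reactions:
        stoich = {m.id: c for m, c in rxn.metabolites.items()}
        if rxn.lower_bound < 0:
            fwd = Reaction(rxn.id, lower_bound=max(rxn.lower_bound, 0.0),
                           upper_bound=max(rxn.upper_bound, 0.0))
            rev = Reaction(rxn.id + REVERSE_SUFFIX,
                           lower_bound=max(-rxn.upper_bound, 0.0),
                           upper_bound=-rxn.lower_bound)
            fwd.add_metabolites({split.metabolites.get_by_id(m): c for m, c in stoich.items()})
            rev.add_metabolites({split.metabolites.get_by_id(m): -c for m, c in stoich.items()})
            for half in (fwd, rev):
                half.gene_reaction_rule = rxn.gene_reaction_rule
            new_reactions.extend([fwd, rev])
            parent[fwd.id] = rxn.id
            parent[rev.id] = rxn.id
            halves[rxn.id] = [fwd.id, rev.id]
        else:
            copy = Reaction(rxn.id, lower_bound=rxn.lower_bound, upper_bound=rxn.upper_bound)
            copy.add_metabolites({split.metabolites.get_by_id(m): c for m, c in stoich.items()})
            copy.gene_reaction_rule = rxn.gene_reaction_rule
            new_reactions.append(copy)
            parent[copy.id] = rxn.id
            halves[rxn.id] = [copy.id]
    split.add_reactions(new_reactions)
    # carry the objective over (useful for LP-equivalence checks)
    try:
        obj = _objective_reaction(model)
        split.objective = obj.id
    except ValueError:
        pass
    return IrreversibleModel(model=split, source=model, parent=parent, halves=halves)


def minimize_weighted_flux(imodel: IrreversibleModel, weights: ReactionWeights) -> pd.Series:
    """Minimize the pruning-weighted total flux on the split model.

    Both halves of a split pair inherit their parent's pruning coefficient.
    Returns the optimal flux vector indexed by split reaction id.
    """
    model = imodel.model
    objective = model.problem.Objective(Zero, direction="min", sloppy=True)
    model.objective = objective
    coefficients = {}
    for rxn in model.reactions:
        w = weights.pruning[imodel.parent[rxn.id]]
        coefficients[rxn.forward_variable] = w
        coefficients[rxn.reverse_variable] = w
    model.objective.set_linear_coefficients(coefficients)
    solution = model.optimize()
    if solution.status != "optimal":
        raise RuntimeError(
            f"weighted flux minimization failed with solver status {solution.status!r}"
        )
    return solution.fluxes


def prune(
    imodel: IrreversibleModel,
    solution: pd.Series,
    threshold: float = 1e-6,
    protected: Iterable[str] = (),
) -> Model:
    """Remove reactions inactive in the weighted-minimum solution.

    A parent reaction is removed iff every split half carries |flux| below
    ``threshold`` and it is not protected. If exactly one half of a reversible
    pair survives, the merged reaction keeps only the surviving direction
    (bounds clipped at zero). Orphaned metabolites and genes are removed. The
    result must still attain the objective lower bound installed by
    :func:`constrain_objective`; anything else raises.
    """
    protected = set(protected)
    source = imodel.source
    pruned = source.copy()
    to_remove = []
    for rxn in source.reactions:
        half_ids = imodel.halves[rxn.id]
        fluxes = {h: float(solution[h]) for h in half_ids}
        if rxn.id in protected:
            continue
        if all(abs(v) < threshold for v in fluxes.values()):
            to_remove.append(rxn.id)
        elif len(half_ids) == 2:
            fwd_id, rev_id = half_ids
            target = pruned.reactions.get_by_id(rxn.id)
            if fluxes[rev_id] < threshold <= fluxes[fwd_id]:
                target.lower_bound = max(target.lower_bound, 0.0)
            elif fluxes[fwd_id] < threshold <= fluxes[rev_id]:
                target.upper_bound = min(target.upper_bound, 0.0)
    if to_remove:
        pruned.remove_reactions(
            [pruned.reactions.get_by_id(r) for r in to_remove], remove_orphans=True
        )
    if len(pruned.reactions) == 0:
        raise RuntimeError("pruning removed every reaction; threshold too aggressive")
    optimum = pruned.slim_optimize()
    if optimum is None or pd.isna(optimum):
        raise RuntimeError(
            "pruned model lost objective feasibility; threshold too aggressive"
        )
    return pruned


def _apply_task_constraints(model: Model, tasks: Sequence[str], min_flux: float) -> None:
    for task_id in tasks:
        rxn = model.reactions.get_by_id(task_id)
        rxn.lower_bound = max(rxn.lower_bound, min_flux)


def contextualize(
    model: Model,
    abundances: TranscriptAbundanceTable,
    settings: Optional[ContextSettings] = None,
) -> ContextResult:
    """Run the full pipeline: weights -> constrain -> minimize -> prune -> sample."""
    from . import analysis, sampling  # deferred to avoid import cycle

    settings = settings or ContextSettings()
    known = {r.id for r in model.reactions}
    for rxn_id in list(settings.protected_reactions) + list(settings.tasks):
        if rxn_id not in known:
            raise ValueError(f"reaction {rxn_id!r} not present in the model")

    rpm = normalize_rpm(abundances)
    gene_weights = compute_gene_weights(rpm, model)
    weights = assign_reaction_weights(
        gene_weights, model, mode=settings.gpr_mode, cap=settings.weight_cap
    )

    work = model.copy()
    work.solver = settings.solver
    if settings.objective_mode == "objective":
        _, z_star = constrain_objective(work, settings.fraction)
        objective_bounds: Tuple[Optional[float], Optional[float]] = (
            settings.fraction * z_star,
            z_star,
        )
    else:
        _apply_task_constraints(work, settings.tasks, settings.effective_task_flux())
        z_star = None
        objective_bounds = (None, None)

    imodel = split_reversible(work)
    min_fluxes = minimize_weighted_flux(imodel, weights)
    protected = set(settings.protected_reactions) | set(settings.tasks)
    pruned = prune(imodel, min_fluxes, settings.prune_threshold, protected)

    retained = {r.id for r in pruned.reactions}
    removed = known - retained
    metrics = {
        "n_reactions_original": len(model.reactions),
        "n_reactions_retained": len(retained),
        "fraction_reactions_removed": len(removed) / len(model.reactions),
        "fraction_metabolites_removed": 1 - len(pruned.metabolites) / max(1, len(model.metabolites)),
        "fraction_genes_removed": 1 - len(pruned.genes) / max(1, len(model.genes)),
    }
    logger.info(
        "pruned %d/%d reactions (%.1f%%)",
        len(removed),
        len(model.reactions),
        100 * metrics["fraction_reactions_removed"],
    )

    result = ContextResult(
        pruned_model=pruned,
        retained_reactions=retained,
        pruned_reactions=removed,
        settings=settings,
        weights=weights,
        objective_bounds=objective_bounds,
        metrics=metrics,
        minimization_fluxes=min_fluxes,
    )

    if not settings.skip_sampling:
        constrained, w_star = sampling.set_sampling_objective(
            pruned, weights, settings.effective_sampling_fraction()
        )
        result.fva = sampling.fva(constrained)
        result.flux_samples = sampling.gapsplit_sample(
            constrained, settings.n_samples, settings.seed, fva_ranges=result.fva
        )
        result.metrics["sampling_weight_optimum"] = w_star
        result.concordance = analysis.concordance(result.flux_samples, weights)
    return result
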