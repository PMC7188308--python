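"""Transcript abundances -> per-reaction linear coefficients.

Each model gene g receives a weight gw(g) = T_g / T_max in (0, 1], where T_g is
the reads-per-million normalized abundance of g and T_max the largest abundance
among genes that appear in the model. Per reaction these gene weights combine
(by default, the maximum over the GPR) into a *sampling* coefficient, and the
complementary *pruning* coefficient is

    rw_pruning(r) = (min gw + max gw) - rw_sampling(r)

so that highly transcribed reactions are cheap during the flux-minimization
(pruning) step and strongly promoted during the flux-maximization (sampling)
step. Reactions without genes receive the median gene weight, which neither
penalizes nor favors them.
"""

from __future__ import annotations

import ast
import logging
from dataclasses import dataclass, field
from statistics import median
from typing import Dict, Optional

import pandas as pd
from cobra import Model

logger = logging.getLogger(__name__)

#: gene identifier -> non-negative abundance (raw counts or normalized units)
TranscriptAbundanceTable = Dict[str, float]

RPM_TOTAL = 1e6

GPR_MODES = ("max", "pool", "gpr_aware")


@dataclass
class GeneWeights:
    """Per-gene transcription weights, gw = T_g / T_max, restricted to model genes."""

    weights: Dict[str, float]
    t_max: float

    @property
    def gw_min(self) -> float:
        return min(self.weights.values())

    @property
    def gw_max(self) -> float:
        return max(self.weights.values())


@dataclass
class ReactionWeights:
    """Paired pruning/sampling linear coefficients for every reaction."""

    sampling: Dict[str, float]
    pruning: Dict[str, float]
    gw_min: float
    gw_max: float
    gpr_mode: str = "max"
    cap: Optional[float] = None

    def to_frame(self) -> pd.DataFrame:
        """Exportable audit table (reaction id, sampling weight, pruning weight)."""
        ids = list(self.sampling)
        return pd.DataFrame(
            {
                "reaction_id": ids,
                "sampling_weight": [self.sampling[i] for i in ids],
                "pruning_weight": [self.pruning[i] for i in ids],
            }
        ).set_index("reaction_id")


def normalize_rpm(table: TranscriptAbundanceTable) -> TranscriptAbundanceTable:
    """Scale abundances to reads-per-million (output sums to 1e6).

    Raises
    ------
    ValueError
        If the table is empty, all-zero, or contains a negative abundance.
    """
    if not table:
        raise ValueError("abundance table is empty")
    for gene, value in table.items():
        if value < 0:
            raise ValueError(f"negative abundance for gene {gene!r}: {value}")
    total = float(sum(table.values()))
    if total <= 0:
        raise ValueError("cannot normalize an all-zero abundance table")
    scale = RPM_TOTAL / total
    if not all(
        value * scale == value * scale and value * scale != float("inf")
        for value in table.values()
    ):
        raise ValueError("abundance magnitudes overflow/underflow RPM normalization")
    return {gene: value * scale for gene, value in table.items()}


def compute_gene_weights(
    table: TranscriptAbundanceTable,
    model: Model,
    zero_floor: Optional[float] = None,
    missing_weight: Optional[float] = None,
) -> GeneWeights:
    """Restrict the table to model genes and form gw = T_g / T_max.

    T_max is taken over the genes present in both the table and the model, so
    the most transcribed *model* gene always has gw = 1 and uninformative
    transcripts do not skew the distribution.

    Zero-abundance genes would receive gw = 0, outside the required (0, 1]
    coefficient range; they are floored at the smallest positive observed gw
    (or ``zero_floor``). Model genes absent from the table default to the
    minimum observed gw (or ``missing_weight``): absence of transcript is
    treated as no evidence of cellular investment.
    """
    model_genes = {g.id for g in model.genes}
    if not model_genes:
        raise ValueError("model has no genes; cannot assign transcript weights")
    overlap = {g: float(table[g]) for g in model_genes if g in table}
    if not overlap:
        sample = sorted(model_genes)[:5]
        raise ValueError(
            "no overlap between abundance table and model genes "
            f"(model gene examples: {sample})"
        )
    t_max = max(overlap.values())
    if t_max <= 0:
        raise ValueError("all mapped model genes have zero abundance")
    weights = {g: v / t_max for g, v in overlap.items()}

    positive = [w for w in weights.values() if w > 0]
    floor = zero_floor if zero_floor is not None else min(positive)
    if floor <= 0:
        raise ValueError("zero-abundance floor must be positive")
    n_zero = 0
    for g, w in weights.items():
        if w <= 0:
            weights[g] = floor
            n_zero += 1
    if n_zero:
        logger.info("floored %d zero-abundance gene weights at %.3g", n_zero, floor)

    missing = model_genes - weights.keys()
    fill = missing_weight if missing_weight is not None else min(weights.values())
    for g in missing:
        weights[g] = fill
    if missing:
        logger.info(
            "%d model genes absent from the abundance table assigned weight %.3g",
            len(missing),
            fill,
        )
    return GeneWeights(weights=weights, t_max=t_max)


def _eval_gpr_weight(node: ast.expr, gw: Dict[str, float], default: float) -> float:
    """Recursively score a GPR AST: AND -> min of subclauses, OR -> max."""
    if isinstance(node, ast.Name):
        return gw.get(node.id, default)
    if isinstance(node, ast.BoolOp):
        values = [_eval_gpr_weight(v, gw, default) for v in node.values]
        return min(values) if isinstance(node.op, ast.And) else max(values)
    raise ValueError(f"unsupported GPR expression node: {ast.dump(node)}")


def assign_reaction_weights(
    gw: GeneWeights,
    model: Model,
    mode: str = "max",
    cap: Optional[float] = None,
) -> ReactionWeights:
    """Transfer gene weights onto reactions and build the paired distributions.

    Modes
    -----
    max (default)
        A reaction inherits the maximum gw among the genes of its GPR — the
        most invested-in gene product is assumed to carry the reaction.
    pool
        Gene weights of the GPR are summed and the pooled values re-normalized
        by the largest pooled value, crediting reactions backed by overall
        transcript investment across all contributing genes.
    gpr_aware
        AND-connected subclauses contribute their minimum weight (an enzyme
        complex is limited by its least transcribed member), OR-connected their
        maximum; nested clauses evaluate recursively. Penalizes reactions with
        discordant abundances among required gene products.

    Gene-less reactions receive the median of the gene-level gw distribution.
    If ``cap`` is given, reaction-level weights are bounded above by it before
    the pruning-weight inversion. For every reaction,
    ``pruning[r] + sampling[r] == gw_min + gw_max`` exactly.
    """
    if mode not in GPR_MODES:
        raise ValueError(f"unknown gpr mode {mode!r}; expected one of {GPR_MODES}")
    if cap is not None and cap <= 0:
        raise ValueError("weight cap must be positive")
    if len(model.reactions) == 0:
        raise ValueError("model has no reactions")

    gene_values = gw.weights
    gw_min, gw_max = gw.gw_min, gw.gw_max
    # median of the gene-level distribution, before any capping
    median_weight = float(median(sorted(gene_values.values())))

    raw: Dict[str, float] = {}
    if mode == "pool":
        pooled = {}
        for rxn in model.reactions:
            genes = [g.id for g in rxn.genes]
            if genes:
                pooled[rxn.id] = sum(gene_values.get(g, gw_min) for g in genes)
        pool_max = max(pooled.values()) if pooled else 1.0
        for rxn_id, value in pooled.items():
            raw[rxn_id] = value / pool_max

    sampling: Dict[str, float] = {}
    pruning: Dict[str, float] = {}
    for rxn in model.reactions:
        genes = [g.id for g in rxn.genes]
        if not genes:
            weight = median_weight
        elif mode == "max":
            weight = max(gene_values.get(g, gw_min) for g in genes)
        elif mode == "pool":
            weight = raw[rxn.id]
        else:  # gpr_aware
            weight = _eval_gpr_weight(rxn.gpr.body, gene_values, gw_min)
        if cap is not None:
            weight = min(weight, cap)
        sampling[rxn.id] = weight
        pruning[rxn.id] = (gw_min + gw_max) - weight

    return ReactionWeights(
        sampling=sampling,
        pruning=pruning,
        gw_min=gw_min,
        gw_max=gw_max,
        gpr_mode=mode,
        cap=cap,
    )
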