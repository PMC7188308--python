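"""Downstream metrics on contextualized models and their flux samples."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
import pandas as pd
from cobra import Model
from scipy import stats

from .sampling import FluxSampleSet
from .weighting import ReactionWeights

logger = logging.getLogger(__name__)


@dataclass
class ConcordanceResult:
    """Spearman correlation between sampling weights and median |flux|.

    A positive rho means the sampled flux magnitudes track the cellular
    investment implied by transcription; reactions far off the trend are
    candidates for strong post-transcriptional regulation. ``undefined`` is
    set when every median is identical and ranks carry no information.
    """

    rho: float
    p_value: float
    n_reactions: int
    undefined: bool = False


def concordance(samples: FluxSampleSet, weights: ReactionWeights) -> ConcordanceResult:
    """Correlate median absolute sampled flux with the sampling coefficients."""
    ids = [c for c in samples.matrix.columns if c in weights.sampling]
    if len(ids) < 3:
        raise ValueError(
            f"concordance needs at least 3 weighted reactions, got {len(ids)}"
        )
    medians = samples.matrix[ids].abs().median(axis=0).to_numpy()
    coefficients = np.array([weights.sampling[i] for i in ids])
    if np.allclose(medians, medians[0]) or np.allclose(coefficients, coefficients[0]):
        logger.warning(
            "median fluxes or sampling weights are constant; concordance undefined"
        )
        return ConcordanceResult(math.nan, math.nan, len(ids), undefined=True)
    rho, p_value = stats.spearmanr(medians, coefficients)
    return ConcordanceResult(float(rho), float(p_value), len(ids))


def doubling_time(objective_flux: float) -> float:
    """Doubling time in minutes from a growth-rate objective flux in 1/hr.

    Exponential growth at rate mu doubles biomass every ln(2)/mu hours.
    """
    if objective_flux <= 0:
        raise ValueError("objective flux must be positive to define a doubling time")
    return math.log(2) / objective_flux * 60.0


@dataclass
class EssentialityReport:
    """Single-gene knockout classification against a growth threshold."""

    status: Dict[str, str]
    wild_type: float
    threshold_fraction: float
    knockout_optimum: Dict[str, float] = field(default_factory=dict)

    @property
    def essential_genes(self) -> set:
        return {g for g, s in self.status.items() if s == "essential"}

    def to_frame(self) -> pd.DataFrame:
        genes = sorted(self.status)
        return pd.DataFrame(
            {
                "gene": genes,
                "status": [self.status[g] for g in genes],
                "knockout_optimum": [self.knockout_optimum.get(g, math.nan) for g in genes],
            }
        ).set_index("gene")


def gene_essentiality(model: Model, threshold_fraction: float = 0.01) -> EssentialityReport:
    """Classify each gene by knocking it out and re-optimizing.

    A gene is essential iff, with every reaction whose GPR evaluates false
    under the knockout closed to flux, the optimum falls below
    ``threshold_fraction`` of the wild-type optimum (infeasibility counts as
    zero growth). Bounds are restored between genes. Genes in no GPR are
    nonessential by definition.
    """
    if threshold_fraction < 0:
        raise ValueError("threshold_fraction must be non-negative")
    wild_type = model.slim_optimize()
    if wild_type is None or pd.isna(wild_type) or wild_type <= 0:
        raise ValueError("model must have a positive wild-type optimum")
    cutoff = threshold_fraction * wild_type
    status: Dict[str, str] = {}
    optima: Dict[str, float] = {}
    for gene in model.genes:
        if not gene.reactions:
            status[gene.id] = "nonessential"
            optima[gene.id] = float(wild_type)
            continue
        with model:
            gene.knock_out()
            optimum = model.slim_optimize()
        if optimum is None or pd.isna(optimum):
            optimum = 0.0  # infeasible knockout: no growth state exists
        optima[gene.id] = float(optimum)
        essential = optimum < cutoff if threshold_fraction > 0 else optimum <= 0
        status[gene.id] = "essential" if essential else "nonessential"
    return EssentialityReport(
        status=status,
        wild_type=float(wild_type),
        threshold_fraction=threshold_fraction,
        knockout_optimum=optima,
    )


def infer_growth_substrates(samples: FluxSampleSet, model: Model) -> pd.DataFrame:
    """Extracellular metabolites taken up (median exchange flux < 0) in sampling.

    Exchange reactions are the single-metabolite boundary reactions; by
    convention negative flux is uptake. Returns a frame indexed by metabolite
    id with the exchange reaction and its median sampled flux, sorted most
    consumed first.
    """
    records = []
    for rxn in model.reactions:
        if len(rxn.metabolites) != 1 or rxn.id not in samples.matrix.columns:
            continue
        med = float(samples.matrix[rxn.id].median())
        if med < 0:
            metabolite = next(iter(rxn.metabolites))
            records.append((metabolite.id, rxn.id, med))
    frame = pd.DataFrame(records, columns=["metabolite", "exchange", "median_flux"])
    return frame.sort_values("median_flux").set_index("metabolite")


def biomass_normalized_flux(
    samples: FluxSampleSet,
    biomass_id: str,
    overall_median_biomass: Optional[float] = None,
) -> FluxSampleSet:
    """Scale each sample so biomass flux is constant across conditions.

    Each row is multiplied by overall_median_biomass / (row biomass flux), so
    within-row flux ratios are preserved and the biomass column becomes the
    constant ``overall_median_biomass`` (defaulting to this sample set's own
    median). Rows with non-positive biomass flux are excluded with a warning.
    """
    if biomass_id not in samples.matrix.columns:
        raise KeyError(f"biomass reaction {biomass_id!r} not in sample columns")
    biomass = samples.matrix[biomass_id]
    if overall_median_biomass is None:
        overall_median_biomass = float(biomass.median())
    keep = biomass > 0
    if not keep.all():
        logger.warning(
            "excluding %d samples with non-positive biomass flux", int((~keep).sum())
        )
    scaled = samples.matrix.loc[keep].mul(
        overall_median_biomass / biomass[keep], axis=0
    )
    return FluxSampleSet(matrix=scaled, seed=samples.seed)
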