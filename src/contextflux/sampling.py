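"""Exploration of the pruned solution space: FVA plus gap-splitting sampling.

After pruning, coefficients are re-assigned with the *sampling* weights (large
for highly transcribed reactions) and the weighted total flux is maximized:

    w* = max sum_r rw_sampling(r) * v_r

posed on the non-negative forward/reverse decomposition of each reaction. The
constraint sum_r rw_sampling(r) * v_r >= f_sampling * w* is then installed so
the sampler explores near-optimal weighted-flux states instead of a single
degenerate optimum. Flux variability analysis establishes per-reaction ranges,
and the gap-splitting sampler repeatedly fixes the variable with the largest
unexplored fraction of its range at the midpoint of that gap, maximizing
coverage per sample in a deterministic, coverage-driven sweep.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from cobra import Model
from optlang.symbolics import Zero

logger = logging.getLogger(__name__)

SAMPLING_CONSTRAINT_ID = "sampling_weight_floor"
#: FVA widths below this are treated as fixed variables
ZERO_WIDTH_TOL = 1e-9
MAX_RETRIES = 10


@dataclass
class FluxSampleSet:
    """Feasible flux vectors (rows) over a fixed reaction ordering (columns)."""

    matrix: pd.DataFrame
    seed: int

    @property
    def n_samples(self) -> int:
        return len(self.matrix)

    def median_absolute_flux(self) -> pd.Series:
        return self.matrix.abs().median(axis=0)


def _weighted_flux_coefficients(model: Model, sampling_weights: Dict[str, float]):
    coefficients = {}
    for rxn in model.reactions:
        w = sampling_weights[rxn.id]
        coefficients[rxn.forward_variable] = w
        coefficients[rxn.reverse_variable] = w
    return coefficients


def set_sampling_objective(
    pruned: Model, weights, f_sampling: float
) -> Tuple[Model, float]:
    """Install the weighted-flux floor on a copy of the pruned model.

    Returns the constrained copy and the weighted optimum w*. With
    ``f_sampling = 0`` the constraint is vacuous and the polytope is just the
    objective-constrained pruned space.
    """
    work = pruned.copy()
    objective = work.problem.Objective(Zero, direction="max", sloppy=True)
    work.objective = objective
    coefficients = _weighted_flux_coefficients(work, weights.sampling)
    work.objective.set_linear_coefficients(coefficients)
    w_star = work.slim_optimize()
    if w_star is None or pd.isna(w_star):
        raise RuntimeError("weighted flux maximization failed (infeasible model)")
    if not np.isfinite(w_star):
        raise RuntimeError(
            "weighted flux maximization is unbounded; review reaction bounds"
        )
    constraint = work.problem.Constraint(
        Zero, lb=f_sampling * float(w_star), name=SAMPLING_CONSTRAINT_ID
    )
    work.add_cons_vars([constraint], sloppy=True)
    work.solver.update()
    constraint.set_linear_coefficients(coefficients)
    return work, float(w_star)


def fva(model: Model, reactions=None) -> pd.DataFrame:
    """Per-reaction flux minima/maxima under all installed constraints.

    Runs 2 LPs per reaction. A failed per-reaction LP is recorded as a missing
    range (NaN) with a warning; the run continues.
    """
    targets = list(model.reactions) if reactions is None else [
        model.reactions.get_by_id(r) for r in reactions
    ]
    records = {}
    for rxn in targets:
        bounds = []
        for direction in ("min", "max"):
            try:
                model.objective = model.problem.Objective(
                    rxn.flux_expression, direction=direction
                )
                value = model.slim_optimize()
                if value is None or pd.isna(value):
                    raise RuntimeError("solver returned no optimum")
                bounds.append(float(value))
            except Exception as exc:  # pragma: no cover - solver hiccups
                logger.warning("FVA failed for %s (%s): %s", rxn.id, direction, exc)
                bounds.append(np.nan)
        lo, hi = bounds
        if np.isfinite(lo) and np.isfinite(hi) and lo > hi:
            lo, hi = hi, lo  # solver tolerance crossover
        records[rxn.id] = (lo, hi)
    frame = pd.DataFrame.from_dict(records, orient="index", columns=["minimum", "maximum"])
    return frame.reindex([r.id for r in model.reactions])


def _largest_gap(values: np.ndarray, lo: float, hi: float) -> Tuple[float, float]:
    """Largest interval between adjacent sampled values (bounds as sentinels).

    Returns (gap width, gap midpoint)."""
    points = np.concatenate(([lo], np.clip(values, lo, hi), [hi]))
    points.sort()
    diffs = np.diff(points)
    k = int(np.argmax(diffs))
    return float(diffs[k]), float(points[k] + diffs[k] / 2)


def gapsplit_sample(
    model: Model,
    n: int,
    seed: int,
    fva_ranges: Optional[pd.DataFrame] = None,
    max_retries: int = MAX_RETRIES,
) -> FluxSampleSet:
    """Coverage-driven sampling of the constrained polytope.

    Each iteration scores every free variable by its largest normalized gap
    (largest unsampled interval divided by the FVA width), picks the variable
    with the largest gap (ties broken by lowest column index), temporarily
    fixes it at the midpoint of that gap and solves a feasibility LP for the
    remaining fluxes. Variables with zero FVA width are skipped. The procedure
    is deterministic; the seed is recorded for provenance.
    """
    if n < 2:
        raise ValueError("need at least 2 samples")
    if fva_ranges is None:
        fva_ranges = fva(model)
    ids = [r.id for r in model.reactions]
    lo = fva_ranges["minimum"].reindex(ids).to_numpy()
    hi = fva_ranges["maximum"].reindex(ids).to_numpy()
    if np.isnan(lo).any() or np.isnan(hi).any():
        raise ValueError("FVA ranges contain missing values; cannot sample")
    width = hi - lo
    free = np.where(width > ZERO_WIDTH_TOL)[0]
    if free.size == 0:
        raise ValueError("all variables have zero flux range; nothing to sample")

    feasibility = model.problem.Objective(Zero, direction="min", sloppy=True)
    model.objective = feasibility

    rows = []
    sampled = np.empty((0, len(ids)))
    for _ in range(n):
        best_idx, best_gap, best_mid = -1, -1.0, 0.0
        for j in free:
            gap, mid = _largest_gap(sampled[:, j], lo[j], hi[j])
            norm = gap / width[j]
            if norm > best_gap + 1e-12:
                best_idx, best_gap, best_mid = j, norm, mid
        target = model.reactions.get_by_id(ids[best_idx])
        flux_row = None
        for attempt in range(max_retries + 1):
            delta = 0.0 if attempt == 0 else (
                min(best_gap * width[best_idx] / 2, width[best_idx] * 1e-8 * 10 ** attempt)
            )
            with model:
                target.bounds = (
                    max(lo[best_idx], best_mid - delta),
                    min(hi[best_idx], best_mid + delta),
                )
                solution = model.optimize()
                if solution.status == "optimal":
                    flux_row = solution.fluxes.reindex(ids).to_numpy()
                    break
        if flux_row is None:
            raise RuntimeError(
                f"could not find a feasible point fixing {ids[best_idx]} "
                f"at {best_mid:.6g} after {max_retries} retries"
            )
        rows.append(flux_row)
        sampled = np.vstack([sampled, flux_row])

    matrix = pd.DataFrame(rows, columns=ids)
    matrix.index.name = "sample"
    return FluxSampleSet(matrix=matrix, seed=seed)


def max_normalized_gaps(samples: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Per-variable maximal normalized gap given accumulated samples.

    Exposed for coverage diagnostics: 1 - gap is the per-variable coverage.
    Zero-width variables report a gap of 0."""
    n_vars = samples.shape[1] if samples.ndim == 2 else len(lo)
    gaps = np.zeros(n_vars)
    for j in range(n_vars):
        w = hi[j] - lo[j]
        if w <= ZERO_WIDTH_TOL:
            continue
        gap, _ = _largest_gap(samples[:, j], lo[j], hi[j])
        gaps[j] = gap / w
    return gaps
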