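# Methods

## The model

contextflux extracts a context-specific metabolic model from a genome-scale
network reconstruction (GENRE) and a single transcript-abundance table, on the
premise that transcript levels are a signature of cellular *investment* rather
than a direct predictor of enzyme activity. The method therefore never turns
abundances into flux bounds or on/off calls; instead it biases a parsimonious
flux analysis so that divergence from the minimum-total-flux state is rewarded
exactly where the cell has invested transcription.

### Weighting

Abundances are normalized to reads-per-million and restricted to genes present
in the model; the ratio to the largest remaining abundance gives each gene a
weight gw = T_g / T_max in (0, 1] (the top model-mapped gene always scores 1,
so uninformative transcripts cannot skew the distribution). Per reaction the
gene weights combine into the *sampling* coefficient rw_s(r), and the paired
*pruning* coefficient is its reflection

    rw_p(r) = (min gw + max gw) − rw_s(r),

which makes pruning and sampling weights exactly complementary and order-
reversed: the more a reaction's genes are transcribed, the cheaper its flux is
during minimization and the more it is promoted during sampling.

GPR combination modes:

* **max** (default): a reaction scores the maximum gw over its genes — the
  most invested-in isozyme or subunit is assumed to carry the reaction.
* **pool**: gene weights of the GPR are summed, then re-normalized by the
  largest pooled value, crediting total transcript across contributors.
* **gpr_aware**: AND-clauses contribute their minimum member (a complex is
  limited by its least transcribed subunit), OR-clauses their maximum; nested
  clauses evaluate recursively. The AND=min / OR=max semantics are this
  package's design choice for penalizing discordant abundances within
  required complexes.

Gene-less reactions (exchanges, spontaneous reactions) receive the **median**
of the gene-level gw distribution, computed before any capping — neither
penalized nor favored. Zero-abundance genes are floored at the smallest
positive observed gw (configurable) to keep every coefficient strictly
positive; model genes absent from the table receive the minimum observed gw
("no evidence of investment"), and both events are logged with counts.

### Contextualization

1. Solve FBA for the optimum z\* and install the lower bound f·z\* on the
   objective reaction (default f = 0.8, leaving a 20% band of allowed
   variation). The written form is a lower bound, not an equality: the band
   is what lets transcription choose among near-optimal strategies.
2. Split every reversible reaction into non-negative forward/reverse copies;
   both halves inherit the parent's coefficients.
3. Minimize Σ rw_p(r)·v_r subject to mass balance, bounds and the objective
   floor (pure LP; no integer variables anywhere in the package).
4. Remove every unprotected reaction whose halves all carry < 1e-6 flux
   (threshold configurable), then orphaned metabolites and genes. If exactly
   one half of a reversible pair survives, the merged reaction keeps only the
   surviving direction — pruning fixes parsimonious directionality.
5. Re-weight the survivors with rw_s, maximize Σ rw_s(r)·v_r to get w\*, and
   constrain the sampling polytope by Σ rw_s(r)·v_r ≥ f_s·w\* (default
   f_s = f). Installing the maximization as a fractional floor rather than
   sampling at the single optimum is a deliberate choice: the optimum alone is
   a degenerate face, while the band describes the near-optimal weighted-flux
   states the transcriptome supports.
6. Run FVA (2 LPs per reaction) and the gap-splitting sampler (default 500
   samples), then report the Spearman concordance between median |flux| and
   rw_s across retained reactions.

### Gap-splitting sampler

Implemented from scratch as a deterministic coverage-driven procedure: each
iteration scores every free variable by its maximal normalized gap (largest
interval between adjacent previously sampled values, FVA bounds as sentinels,
divided by the FVA width), fixes the variable with the largest gap at that
gap's midpoint, and solves a zero-objective feasibility LP for the remaining
fluxes. Configuration choices labeled "standard" here: primary-target
splitting only (no secondary blocking), ties broken by lowest column index,
variables with FVA width ≤ 1e-9 excluded from gap accounting, up to 10
retries per sample with a geometrically widening interval around the midpoint
when a fix is numerically infeasible. Because the procedure and the LP solver
(GLPK) are deterministic, identical inputs reproduce the sample matrix
bit-for-bit; the seed argument is recorded in the provenance report.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| fraction f | 0.8 | – | objective floor f·z*; the 20% band balances growth optimality against transcriptome concordance |
| prune_threshold | 1e-6 | flux | below typical LP feasibility noise ceilings; reactions this inactive are pruned |
| n_samples | 500 | – | coverage saturates quickly under gap-splitting on pruned models |
| gpr_mode | max | – | see weighting modes above |
| weight_cap | none | – | optional ceiling on reaction weights to blunt single dominant transcripts |
| sampling_fraction f_s | = f | – | floor on the weighted flux total during sampling |
| task_flux | = prune_threshold | flux | lower bound for task reactions in tasks mode |

Model units follow the reconstruction (mmol/gDW/hr for metabolic fluxes, 1/hr
for biomass); the example model uses arbitrary units.

## Numerical choices and degenerate inputs

* Feasibility tolerances: mass-balance residuals of samples are asserted at
  1e-6; FVA min/max crossovers below solver noise are clamped.
* LP degeneracy: alternate optima of the weighted minimization can in
  principle change the pruned set. The pipeline prunes from the solver's
  returned basis under a fixed variable ordering (model reaction order) and a
  fixed solver (GLPK, named in the report), trading canonicalization cost for
  reproducibility: identical inputs give identical retained sets.
* Coefficient dynamic range: pruning weights are computed as
  (min gw + max gw) − rw_s; abundance ratios beyond ~12 orders of magnitude
  collapse this difference in double precision. RPM normalization refuses
  tables whose totals overflow or underflow.
* All-zero abundance tables, empty models, zero gene overlap, non-positive
  objective optima and an infinite pruning threshold are rejected with
  explicit errors rather than silently producing empty models.
* Tasks mode replaces the objective floor with lower bounds on each task
  reaction. With the default task_flux equal to the pruning threshold,
  downstream fluxes attenuated by stoichiometry (< 1 product per substrate)
  can fall below both the threshold and the solver's feasibility tolerance;
  for meaningful task-driven contextualization set task_flux well above the
  pruning threshold.
* Concordance is reported as undefined (NaN, flagged) when either the median
  fluxes or the weights are constant — notably under a uniform transcriptome.
  The p-value uses the standard large-sample approximation, uncorrected
  (a single test per run).

## The example model and synthetic data

The built-in fixture emulates a facultative fermenter choosing between two
energy strategies: a lumped glycolysis (1 glucose → 1 ATP + 1 acetate +
0.9 CO2) and a lumped Stickland fermentation (1 proline + 1 glycine →
0.9 ATP + 1 5-aminovalerate + 0.5 CO2), wired through 7 exchanges and 7
transporters across two compartments with an extracellular ATP drain as the
objective (16 reactions, 14 metabolites). The coefficients are in arbitrary
units and were chosen — before any tuning against tests — to satisfy the
qualitative structure the model must exhibit: glycolysis yields more ATP per
substrate unit and is the unweighted parsimony winner; Stickland fermentation
becomes the cheaper weighted route whenever its genes are elevated by a factor
≥ 2; CO2 efflux is stoichiometrically unavoidable during fermentation; and
within each contextualized route the elevated enzymes carry at least as much
flux as the byproduct chain, so weight–flux concordance is positive.

Simulated transcriptomes assign a high abundance (default 1000) to one
branch's enzyme and transporter genes and a low abundance (default 10)
elsewhere, or a single identical value (uniform). The random GENRE generator
chains one exchange through intracellular conversions to a demand objective
and pads with dead-end and futile-cycle reactions that cannot carry flux in
any minimum-total-flux solution, which keeps the parsimonious optimum unique
— deliberately so, because its purpose is property testing of the
maximum-parsimony equivalence, where solver-degenerate alternate optima would
make support comparisons meaningless.

What the synthetic assets do **not** emulate: realistic negative-binomial
abundance dispersion, multi-compartment eukaryote-scale networks, GPRs with
deep AND/OR nesting, thermodynamically infeasible loops spanning several
reactions, and genome-scale degeneracy of alternate optima. Passing tests on
these fixtures therefore validate the algorithmic contracts (selection,
pruning, feasibility, determinism, concordance sign), not biological accuracy
on real reconstructions.

Test and acceptance problem sizes: the 16-reaction example model with 500
samples, and 20 random GENREs of 12 metabolites × 20 reactions. These sizes
were chosen because every published qualitative behavior of the method is
already expressible at them; the pipeline itself is linear-programming
throughout and scales to genome-scale reconstructions (a 2583-reaction
bacterial model contextualizes in seconds to minutes depending on sample
count).

## Known limitations

* A single transcriptome per run; no differential expression, no
  multi-condition joint contextualization.
* The weighted maximization before sampling can include forward/reverse
  futile-pair flux in w\* for reversible reactions that survive pruning in
  both directions (pruning's direction-clipping makes this rare).
* Essentiality on the pruned model (the default, exposed flag for the full
  model) reports necessity *for the context-specific strategy*, not organism
  survival.
* No MILP-based alternatives (single-step pruning only), no hit-and-run
  samplers, no ordination/machine-learning statistics — flux tables are
  exported for external tools.
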