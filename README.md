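# contextflux

Transcriptome-guided parsimonious flux analysis for genome-scale metabolic
network reconstructions (GENREs).

Constraint-based models can reach an objective through vastly more flux states
than a cell would ever use. Parsimonious FBA narrows this by minimizing total
flux at near-optimal growth, but it is blind to condition: the same model
yields the same strategy in rich broth and inside a host. contextflux weights
the parsimony assumption with a transcriptome. Given a GENRE (SBML L3+FBC or
BiGG-style JSON) and a two-column gene→abundance table, it produces a pruned,
growth-capable, context-specific model plus flux samples, concordance
statistics, and downstream analyses (gene essentiality, growth-substrate
inference, doubling time). It is aimed at microbial systems biologists who
have expression data — including metatranscriptomes of single community
members — but cannot enumerate the growth medium.

## The method

Each model gene g gets a weight from its reads-per-million abundance,
gw = T_g / T_max ∈ (0, 1], with T_max the largest abundance among model genes.
Reactions inherit gene weights through their GPR rules (default: maximum over
the rule) giving the sampling coefficient rw_s(r); the pruning coefficient is
the reflection rw_p(r) = (min gw + max gw) − rw_s(r). The pipeline then solves
two LPs around a pruning step:

    min Σ_r rw_p(r)·v_r   s.t.  S·v = 0,  0 ≤ v ≤ v_max,  v_obj ≥ f·z*

on the irreversible (forward/reverse split) model with f = 0.8 by default;
reactions carrying < 1e-6 flux in the solution are removed together with
orphaned genes and metabolites. On the survivors the weighted total flux
w* = max Σ_r rw_s(r)·v_r is computed and the polytope constrained by
Σ rw_s(r)·v_r ≥ f_s·w*, then characterized by flux variability analysis and a
deterministic gap-splitting sampler (default 500 samples). Spearman
correlation between median |flux| and rw_s summarizes how concordant the
sampled states are with the transcriptome. Everything is plain linear
programming (GLPK by default, pluggable through cobra/optlang).

See `docs/methods.md` for assumptions, parameter rationale and limitations.

## Worked example

The package ships a programmatic 16-reaction, 14-metabolite example model of a
bacterium that can make ATP either by glycolysis (cheap: 1 glucose → 1 ATP)
or by Stickland fermentation (costlier: proline + glycine → 0.9 ATP, with
obligatory CO2 efflux). Running `python examples/01_contextualize_example_model.py`:

```
model: 16 reactions, 14 metabolites
FBA optimum (ATP demand): 1000.0

uniform           retained  9/16 reactions; active pathway: GLYC
                  pruned: EX_amv_e, EX_gly_e, EX_pro_e, STCK, T_AMV, T_GLY, T_PRO
glycolysis_high   retained  9/16 reactions; active pathway: GLYC
                  pruned: EX_amv_e, EX_gly_e, EX_pro_e, STCK, T_AMV, T_GLY, T_PRO
stickland_high    retained 11/16 reactions; active pathway: STCK
                  pruned: EX_ac_e, EX_glc_e, GLYC, T_AC, T_GLC
```

With uniform transcription the result equals unweighted parsimony (glycolysis
wins). When Stickland genes are elevated the pipeline deliberately accepts the
less parsimonious pathway, pruning glycolysis along with the glucose
transporter and exchange — note CO2 efflux is retained to keep the
fermentation mass-balanced. Sampling the Stickland model
(`examples/02_sampling_and_concordance.py`) prints

```
concordance: Spearman rho = 0.251 (p = 0.456, n = 11 reactions)

growth substrates (median uptake flux):
            exchange  median_flux
gly_e       EX_gly_e  -945.638021
pro_e       EX_pro_e  -945.638021
```

a positive weight–flux concordance, and proline/glycine (not glucose)
identified as growth substrates purely from exchange-flux signs.
`examples/03_essentiality_and_growth.py` shows context-dependent gene
essentiality: the Stickland enzyme gene is dispensable in the full network but
essential after Stickland-context pruning.

## Command line

```sh
contextflux fixtures --out assets/
contextflux run --model assets/example_model.xml \
    --abundances assets/transcriptome_stickland_high.tsv \
    --fraction 0.8 --threshold 1e-6 --samples 500 --out results/
contextflux essentiality --model results/pruned_model.xml
```

`run` writes the pruned model (SBML + JSON), the sample matrix and FVA ranges
as TSV, a reaction-weight audit table, and a `report.json` carrying every
setting needed to reproduce the run. Genome-scale inputs work the same way,
e.g. a BiGG model plus a mapped RNA-Seq count table; with all exchanges open
(±1000, "complete media") the pruned model's surviving exchanges predict the
growth substrates the transcriptome implies.

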