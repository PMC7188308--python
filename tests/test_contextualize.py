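import cobra
import pytest

from contextflux import (
    ContextSettings,
    assign_reaction_weights,
    compute_gene_weights,
    constrain_objective,
    contextualize,
    minimize_weighted_flux,
    normalize_rpm,
    prune,
    random_genre,
    split_reversible,
)
from conftest import GLYCOLYSIS_BRANCH, STICKLAND_BRANCH


def pfba_support(model, fraction=0.8, threshold=1e-6):
    """Independent oracle: support of cobra's parsimonious FBA solution."""
    solution = cobra.flux_analysis.pfba(model, fraction_of_optimum=fraction)
    return {r.id for r in model.reactions if abs(solution.fluxes[r.id]) > threshold}


class TestSettings:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"fraction": 0.0},
            {"fraction": 1.5},
            {"prune_threshold": 0.0},
            {"n_samples": 1},
            {"gpr_mode": "nope"},
            {"objective_mode": "biomass"},
            {"sampling_fraction": 1.2},
        ],
    )
    def test_invalid_settings_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ContextSettings(**kwargs)

    def test_sampling_fraction_defaults_to_objective_fraction(self):
        assert ContextSettings(fraction=0.7).effective_sampling_fraction() == 0.7
        assert ContextSettings(sampling_fraction=0.3).effective_sampling_fraction() == 0.3


class TestConstrainObjective:
    def test_installs_lower_bound_at_fraction_of_optimum(self, example_model):
        _, z_star = constrain_objective(example_model, 0.8)
        obj = example_model.reactions.EX_atp_e
        assert z_star == pytest.approx(1000.0)
        assert obj.lower_bound == pytest.approx(800.0)
        assert obj.upper_bound == pytest.approx(1000.0)

    def test_fraction_one_pins_objective_to_optimum(self, example_model):
        _, z_star = constrain_objective(example_model, 1.0)
        obj = example_model.reactions.EX_atp_e
        assert obj.lower_bound == pytest.approx(z_star)

    def test_closed_exchanges_raise(self, example_model):
        for rxn in example_model.reactions:
            if rxn.id.startswith("EX_") and rxn.id != "EX_atp_e":
                rxn.lower_bound = 0.0
        with pytest.raises(ValueError, match="objective cannot carry flux"):
            constrain_objective(example_model, 0.8)


class TestSplitReversible:
    def test_reversible_becomes_two_forward_reactions(self, example_model):
        imodel = split_reversible(example_model)
        fwd = imodel.model.reactions.get_by_id("T_GLC")
        rev = imodel.model.reactions.get_by_id("T_GLC__rev")
        assert fwd.bounds == (0.0, 1000.0)
        assert rev.bounds == (0.0, 1000.0)
        stoich = {m.id: c for m, c in fwd.metabolites.items()}
        rstoich = {m.id: c for m, c in rev.metabolites.items()}
        assert rstoich == {m: -c for m, c in stoich.items()}
        assert imodel.parent["T_GLC__rev"] == "T_GLC"

    def test_irreversible_copied_unchanged(self, example_model):
        imodel = split_reversible(example_model)
        assert imodel.model.reactions.get_by_id("GLYC").bounds == (0.0, 1000.0)
        assert "GLYC__rev" not in imodel.model.reactions
        assert all(r.lower_bound >= 0 for r in imodel.model.reactions)

    def test_backward_only_reaction_maps_to_reverse_copy(self, example_model):
        example_model.reactions.T_AC.bounds = (-1000.0, -10.0)
        imodel = split_reversible(example_model)
        assert imodel.model.reactions.get_by_id("T_AC").bounds == (0.0, 0.0)
        assert imodel.model.reactions.get_by_id("T_AC__rev").bounds == (10.0, 1000.0)

    def test_fba_optimum_preserved_by_splitting(self, example_model):
        # LP equivalence: the split model must reach the same optimum
        original = example_model.slim_optimize()
        imodel = split_reversible(example_model)
        assert imodel.model.slim_optimize() == pytest.approx(original, rel=1e-9)


def _weights_for(model, table):
    gw = compute_gene_weights(normalize_rpm(table), model)
    return assign_reaction_weights(gw, model)


class TestMinimizeAndPrune:
    def test_glycolysis_transcriptome_silences_stickland(
        self, example_model, glycolysis_table
    ):
        weights = _weights_for(example_model, glycolysis_table)
        constrain_objective(example_model, 0.8)
        imodel = split_reversible(example_model)
        fluxes = minimize_weighted_flux(imodel, weights)
        assert fluxes["STCK"] == pytest.approx(0.0, abs=1e-9)
        assert fluxes["GLYC"] > 1.0

    def test_stickland_transcriptome_reroutes_flux(self, example_model, stickland_table):
        weights = _weights_for(example_model, stickland_table)
        constrain_objective(example_model, 0.8)
        imodel = split_reversible(example_model)
        fluxes = minimize_weighted_flux(imodel, weights)
        assert fluxes["GLYC"] == pytest.approx(0.0, abs=1e-9)
        assert fluxes["STCK"] > 1.0
        # CO2 efflux stays active to keep the fermentation mass-balanced
        # (the transporter is written e->c, so efflux runs its reverse half)
        assert fluxes["T_CO2"] + fluxes["T_CO2__rev"] > 1.0

    def test_uniform_weights_reproduce_pfba_support(self, example_model, uniform_table):
        weights = _weights_for(example_model, uniform_table)
        support = pfba_support(example_model)
        constrain_objective(example_model, 0.8)
        imodel = split_reversible(example_model)
        fluxes = minimize_weighted_flux(imodel, weights)
        active = {
            parent
            for split_id, parent in imodel.parent.items()
            if abs(fluxes[split_id]) > 1e-6
        }
        assert active == support

    def test_protecting_everything_leaves_model_intact(
        self, example_model, stickland_table
    ):
        weights = _weights_for(example_model, stickland_table)
        constrain_objective(example_model, 0.8)
        imodel = split_reversible(example_model)
        fluxes = minimize_weighted_flux(imodel, weights)
        all_ids = {r.id for r in example_model.reactions}
        pruned = prune(imodel, fluxes, protected=all_ids)
        assert {r.id for r in pruned.reactions} == all_ids
        for rxn in pruned.reactions:
            assert rxn.bounds == example_model.reactions.get_by_id(rxn.id).bounds

    def test_infinite_threshold_prunes_everything_and_raises(
        self, example_model, uniform_table
    ):
        weights = _weights_for(example_model, uniform_table)
        constrain_objective(example_model, 0.8)
        imodel = split_reversible(example_model)
        fluxes = minimize_weighted_flux(imodel, weights)
        with pytest.raises(RuntimeError):
            prune(imodel, fluxes, threshold=float("inf"))

    def test_orphan_genes_and_metabolites_removed(self, example_model, stickland_table):
        weights = _weights_for(example_model, stickland_table)
        constrain_objective(example_model, 0.8)
        imodel = split_reversible(example_model)
        fluxes = minimize_weighted_flux(imodel, weights)
        pruned = prune(imodel, fluxes)
        gene_ids = {g.id for g in pruned.genes}
        met_ids = {m.id for m in pruned.metabolites}
        assert "g_glyc" not in gene_ids and "g_tglc" not in gene_ids
        assert "glc_e" not in met_ids and "glc_c" not in met_ids


class TestContextualize:
    def test_glycolysis_context_excludes_stickland_branch(self, glycolysis_result):
        assert STICKLAND_BRANCH.isdisjoint(glycolysis_result.retained_reactions)
        assert GLYCOLYSIS_BRANCH <= glycolysis_result.retained_reactions

    def test_retained_and_pruned_partition_the_reaction_set(
        self, example_model, glycolysis_result
    ):
        all_ids = {r.id for r in example_model.reactions}
        retained = glycolysis_result.retained_reactions
        removed = glycolysis_result.pruned_reactions
        assert retained | removed == all_ids
        assert retained & removed == set()

    def test_pruned_model_keeps_objective_band(self, stickland_result):
        low, high = stickland_result.objective_bounds
        assert low == pytest.approx(800.0)
        assert high == pytest.approx(1000.0)
        assert stickland_result.pruned_model.slim_optimize() >= low - 1e-6

    def test_uniform_transcriptome_matches_pfba_oracle(
        self, example_model, uniform_table
    ):
        result = contextualize(
            example_model, uniform_table, ContextSettings(skip_sampling=True)
        )
        assert result.retained_reactions == pfba_support(example_model)

    @pytest.mark.parametrize("seed", [0, 7, 19])
    def test_uniform_matches_pfba_on_random_models(self, seed):
        model = random_genre(n_metabolites=10, n_reactions=16, seed=seed)
        table = {g.id: 3.0 for g in model.genes}
        result = contextualize(model, table, ContextSettings(skip_sampling=True))
        assert result.retained_reactions == pfba_support(model)

    def test_enlarging_protection_never_shrinks_retained_set(
        self, example_model, stickland_table
    ):
        base = contextualize(
            example_model, stickland_table, ContextSettings(skip_sampling=True)
        )
        shielded = contextualize(
            example_model,
            stickland_table,
            ContextSettings(
                skip_sampling=True, protected_reactions=["GLYC", "T_GLC", "EX_glc_e"]
            ),
        )
        assert base.retained_reactions <= shielded.retained_reactions

    def test_same_inputs_give_identical_retained_set(self, example_model, stickland_table):
        settings = ContextSettings(skip_sampling=True)
        first = contextualize(example_model, stickland_table, settings)
        second = contextualize(example_model, stickland_table, settings)
        assert first.retained_reactions == second.retained_reactions

    def test_task_mode_forces_task_reaction_into_model(
        self, example_model, glycolysis_table
    ):
        # even under glycolysis-elevated transcription, requiring the
        # Stickland task keeps that pathway in the model
        result = contextualize(
            example_model,
            glycolysis_table,
            ContextSettings(skip_sampling=True, objective_mode="tasks", tasks=["STCK"]),
        )
        assert "STCK" in result.retained_reactions

    def test_unknown_protected_reaction_rejected(self, example_model, uniform_table):
        with pytest.raises(ValueError, match="not present"):
            contextualize(
                example_model,
                uniform_table,
                ContextSettings(skip_sampling=True, protected_reactions=["NOPE"]),
            )

    def test_zero_gene_overlap_propagates(self, example_model):
        with pytest.raises(ValueError, match="no overlap"):
            contextualize(
                example_model, {"alien": 10.0}, ContextSettings(skip_sampling=True)
            )

    def test_metrics_report_removed_fractions(self, stickland_result):
        metrics = stickland_result.metrics
        assert metrics["n_reactions_original"] == 16
        assert metrics["fraction_reactions_removed"] == pytest.approx(5 / 16)
        assert 0 < metrics["fraction_genes_removed"] < 1
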