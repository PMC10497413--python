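import pandas as pd
import pytest

from commflux import community_builder as cb
from commflux import drug_sim, lp_engine, model_core as mc, quality
from commflux import synthetic_data as syn

from _oracles import cobra_optimum


# ---------------------------------------------------------------------------
# pan-species models


def test_pan_model_is_reaction_union():
    s1 = syn.make_strain(syn.StrainSpec(species="Panner",
                                        substrates=("glc_D",), strain="a"))
    s2 = syn.make_strain(syn.StrainSpec(species="Panner",
                                        substrates=("glc_D",),
                                        drug_enzymes=("azoreductase",),
                                        strain="b"))
    pan = cb.build_pan_model([s1, s2], species="Panner")
    expected = (set(s1.reactions) | set(s2.reactions)) - {"BIO"}
    assert set(pan.reactions) == expected | {"biomassPan"}
    assert pan.objective_reaction == "biomassPan"
    assert "AZOR_e" in pan.reactions


def test_single_strain_pan_is_identity_up_to_biomass_rename():
    s1 = syn.make_strain(syn.StrainSpec(species="Solo",
                                        substrates=("glc_D",)))
    pan = cb.build_pan_model([s1])
    assert set(pan.reactions) == (set(s1.reactions) - {"BIO"}) \
        | {"biomassPan"}
    assert pan.reactions["biomassPan"].stoichiometry == \
        s1.reactions["BIO"].stoichiometry


def test_pan_growth_dominates_member_growth(western_diet):
    # the pan model is a constraint relaxation of each member
    s1 = syn.make_strain(syn.StrainSpec(species="Panner",
                                        substrates=("glc_D",), strain="a"))
    s2 = syn.make_strain(syn.StrainSpec(species="Panner",
                                        substrates=("glc_D", "rib"),
                                        strain="b"))
    pan = cb.build_pan_model([s1, s2], species="Panner")
    diet = syn.rich_diet()
    pan_growth = quality.growth_rate(pan, diet)
    for strain in (s1, s2):
        assert pan_growth >= quality.growth_rate(strain, diet) - 1e-9


def test_conflicting_stoichiometry_raises():
    s1 = syn.make_strain(syn.StrainSpec(species="Clash",
                                        substrates=("glc_D",), strain="a"))
    s2 = syn.make_strain(syn.StrainSpec(species="Clash",
                                        substrates=("glc_D",), strain="b"))
    s2.reactions["CAT_glc_D"].stoichiometry["pyr[c]"] = 3.0
    with pytest.raises(mc.ValidationError) as err:
        cb.build_pan_model([s1, s2], species="Clash")
    assert "CAT_glc_D" in str(err.value)


def test_shared_reaction_gprs_joined_by_or():
    s1 = syn.make_strain(syn.StrainSpec(species="Orly",
                                        substrates=("glc_D",), strain="a"))
    s2 = syn.make_strain(syn.StrainSpec(species="Orly",
                                        substrates=("glc_D",), strain="b"))
    s2.reactions["PREC_glc_D"].gpr = "other_gene"
    pan = cb.build_pan_model([s1, s2], species="Orly")
    gpr = pan.reactions["PREC_glc_D"].gpr
    assert "or" in gpr and "other_gene" in gpr


# ---------------------------------------------------------------------------
# taxon mapping


def test_map_taxa_coverage_and_unmapped():
    mapping, coverage = cb.map_taxa(["A", "B", "D"],
                                    {"A": 1, "B": 2, "C": 3})
    assert mapping == {"A": "A", "B": "B"}
    assert coverage == pytest.approx(2 / 3)


def test_map_taxa_normalizes_names():
    mapping, coverage = cb.map_taxa(
        ["escherichia_coli", "BACTEROIDES FRAGILIS"],
        {"Escherichia coli": 1, "Bacteroides fragilis": 2})
    assert coverage == 1.0
    assert mapping["escherichia_coli"] == "Escherichia coli"


def test_map_taxa_empty_sample_errors():
    with pytest.raises(mc.ValidationError):
        cb.map_taxa([], {"A": 1})


# ---------------------------------------------------------------------------
# abundance tables


def test_abundance_table_invariants():
    good = pd.DataFrame([[0.6, 0.4]], index=["s1"], columns=["A", "B"])
    table = cb.AbundanceTable(values=good)
    assert table.sample("s1") == {"A": 0.6, "B": 0.4}
    with pytest.raises(mc.ValidationError):
        cb.AbundanceTable(values=pd.DataFrame([[-0.1, 0.5]],
                                              index=["s1"],
                                              columns=["A", "B"]))
    with pytest.raises(mc.ValidationError):
        cb.AbundanceTable(values=pd.DataFrame([[0.9, 0.9]],
                                              index=["s1"],
                                              columns=["A", "B"]))


def test_abundance_tsv_roundtrip(tmp_path):
    df = pd.DataFrame([[0.6, 0.4], [0.1, 0.9]], index=["s1", "s2"],
                      columns=["A", "B"])
    table = cb.AbundanceTable(values=df)
    path = tmp_path / "abund.tsv"
    table.to_tsv(path)
    loaded = cb.AbundanceTable.from_tsv(path)
    pd.testing.assert_frame_equal(loaded.values, df)


# ---------------------------------------------------------------------------
# community assembly


def test_community_biomass_coefficients_are_normalized_abundances(levo_pair):
    a, b = levo_pair
    community = cb.assemble_community(
        {"Levoa prima": a, "Levob secunda": b},
        {"Levoa prima": 3.0, "Levob secunda": 1.0})
    stoich = community.model.reactions["communityBiomass"].stoichiometry
    assert stoich[community.members["Levoa prima"].biomass_metabolite] \
        == pytest.approx(-0.75)
    assert stoich[community.members["Levob secunda"].biomass_metabolite] \
        == pytest.approx(-0.25)
    assert sum(community.abundances.values()) == pytest.approx(1.0)


def test_community_has_diet_and_fecal_layer(azo_community):
    model = azo_community.model
    assert "DUt_glc_D" in model.reactions
    assert "UFEt_glc_D" in model.reactions
    assert "EX_glc_D[d]" in model.reactions
    assert "EX_glc_D[fe]" in model.reactions
    assert "EX_microbeBiomass[fe]" in model.reactions
    lb, ub = (model.reactions["communityBiomass"].lower_bound,
              model.reactions["communityBiomass"].upper_bound)
    assert (lb, ub) == (0.4, 1.0)


def test_every_member_reaction_coupled_exactly_once(azo_community):
    coupled = [rid for rid, _, _ in azo_community.model.couplings]
    assert len(coupled) == len(set(coupled))
    member = azo_community.members["Azoreducens toy"]
    prefix = member.prefix
    member_rxns = {rid for rid in azo_community.model.reactions
                   if rid.startswith(f"{prefix}_")}
    assert set(coupled) == member_rxns - {member.biomass_reaction}


def test_errors_on_missing_model_or_zero_abundance(toy_azo):
    with pytest.raises(mc.ValidationError):
        cb.assemble_community({"A": toy_azo}, {"A": 1.0, "ghost": 0.5})
    with pytest.raises(mc.ValidationError):
        cb.assemble_community({"A": toy_azo}, {"A": 0.0})


def test_single_species_community_growth_is_biomass_bounded(
        azo_community, western_diet):
    constrained = cb.apply_diet_to_community(azo_community, western_diet)
    sol = lp_engine.optimize(constrained.model, "communityBiomass", "max")
    # the species grows at 6.67/h under this diet, far above the community
    # biomass cap, so the community pins at the upper bound 1.0/day
    assert sol.ok
    assert sol.objective_value == pytest.approx(1.0, abs=1e-8)


def test_coupling_constraints_hold_at_optimum(levo_community, western_diet,
                                              drugs):
    constrained, model = drug_sim._open_precursor_and_oxygen(
        levo_community, drugs["dopa_decarboxylase"], western_diet,
        aerobic=True, supply=1000.0)
    sol = lp_engine.optimize(model, "EX_mtym[fe]", "max")
    assert sol.ok
    for rid, bio, factor in model.couplings:
        assert abs(sol.fluxes[rid]) <= factor * sol.fluxes[bio] + 1e-6


def test_zero_abundance_equals_species_removal(levo_pair, western_diet,
                                               drugs):
    a, b = levo_pair
    with_b = cb.assemble_community(
        {"Levoa prima": a, "Levob secunda": b},
        {"Levoa prima": 1.0, "Levob secunda": 0.0})
    only_a = cb.assemble_community({"Levoa prima": a}, {"Levoa prima": 1.0})
    assert set(with_b.members) == set(only_a.members) == {"Levoa prima"}
    for community in (with_b, only_a):
        val = drug_sim.conversion_potential(
            community, drugs["dopa_decarboxylase"], western_diet)
        assert val == pytest.approx(400.0, abs=1e-6)


def test_mass_closure_nothing_created_in_transport_layers(toy_azo):
    # with every member reaction closed and an empty diet, no metabolite
    # can appear in the fecal compartment
    community = cb.assemble_community({"Azoreducens toy": toy_azo},
                                      {"Azoreducens toy": 1.0},
                                      biomass_bounds=(0.0, 1.0))
    constrained = cb.apply_diet_to_community(
        community, mc.DietProfile(name="empty"))
    model = constrained.model
    member = constrained.members["Azoreducens toy"]
    for rid in model.reactions:
        if rid.startswith(f"{member.prefix}_"):
            model.reactions[rid].lower_bound = 0.0
            model.reactions[rid].upper_bound = 0.0
    problem = lp_engine.LinearProblem(model)
    for rid, rxn in model.reactions.items():
        if rid.startswith("EX_") and rid.endswith("[fe]"):
            sol = problem.optimize(rid, "max")
            assert sol.ok and sol.objective_value <= 1e-9, rid


def test_monotone_abundance_effect_on_two_step_fixture(levo_pair,
                                                       western_diet, drugs):
    a, b = levo_pair
    values = []
    for w in (0.1, 0.2, 0.4):
        community = cb.assemble_community(
            {"Levoa prima": a, "Levob secunda": b},
            {"Levoa prima": w, "Levob secunda": 1 - w})
        values.append(drug_sim.conversion_potential(
            community, drugs["dopa_decarboxylase"], western_diet,
            product="mtym"))
    assert values[0] <= values[1] + 1e-9 <= values[2] + 1e-9
    assert values[2] > values[0]


def test_community_optimum_matches_independent_solver(azo_community,
                                                      western_diet, drugs):
    constrained, model = drug_sim._open_precursor_and_oxygen(
        azo_community, drugs["azoreductase"], western_diet,
        aerobic=True, supply=1000.0)
    ours = lp_engine.optimize(model, "EX_5asa[fe]", "max").objective_value
    theirs = cobra_optimum(model, "EX_5asa[fe]", "max")
    assert ours == pytest.approx(theirs, abs=1e-5)
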