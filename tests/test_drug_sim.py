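import numpy as np
import pandas as pd
import pytest

from commflux import community_builder as cb
from commflux import drug_sim, lp_engine, model_core as mc
from commflux import synthetic_data as syn

from _oracles import cobra_optimum


# ---------------------------------------------------------------------------
# conversion potential


def test_single_species_conversion_is_coupling_bound(azo_community,
                                                     western_diet, drugs):
    # supply 1000 >> coupling cap 400 * v_bio(=1): the binding constraint is
    # the coupling on the azoreductase flux, giving exactly 400
    val = drug_sim.conversion_potential(azo_community, drugs["azoreductase"],
                                        western_diet)
    assert val == pytest.approx(400.0, abs=1e-6)
    # identify the binding constraint: relaxing the coupling factor moves
    # the optimum (to 500, where the diet's 1000 water units bind instead:
    # azoreduction consumes 2 H2O per drug), relaxing the supply does not
    relaxed = cb.assemble_community({"Azoreducens toy": syn.toy_azo()},
                                    {"Azoreducens toy": 1.0},
                                    coupling_factor=800.0)
    assert drug_sim.conversion_potential(
        relaxed, drugs["azoreductase"], western_diet) == \
        pytest.approx(500.0, abs=1e-6)
    assert drug_sim.conversion_potential(
        azo_community, drugs["azoreductase"], western_diet,
        supply=2000.0) == pytest.approx(400.0, abs=1e-6)


def test_two_step_pathway_requires_both_species(levo_pair, western_diet,
                                                drugs):
    a, b = levo_pair
    only_a = cb.assemble_community({"Levoa prima": a}, {"Levoa prima": 1.0})
    assert drug_sim.conversion_potential(
        only_a, drugs["dopa_decarboxylase"], western_diet,
        product="mtym") == 0.0
    both = cb.assemble_community(
        {"Levoa prima": a, "Levob secunda": b},
        {"Levoa prima": 0.5, "Levob secunda": 0.5})
    val = drug_sim.conversion_potential(
        both, drugs["dopa_decarboxylase"], western_diet, product="mtym")
    assert val > 0
    # merged-network LP oracle through an independent solver
    constrained, model = drug_sim._open_precursor_and_oxygen(
        both, drugs["dopa_decarboxylase"], western_diet, True, 1000.0)
    assert val == pytest.approx(cobra_optimum(model, "EX_mtym[fe]", "max"),
                                abs=1e-5)


def test_absent_precursor_returns_zero_not_error(toy_chain, western_diet,
                                                 drugs):
    community = cb.assemble_community({"Chain": toy_chain}, {"Chain": 1.0},
                                      biomass_bounds=(0.0, 1.0))
    assert drug_sim.conversion_potential(
        community, drugs["azoreductase"], western_diet) == 0.0


def test_supply_monotonicity_and_saturation(azo_community, western_diet,
                                            drugs):
    values = [drug_sim.conversion_potential(
        azo_community, drugs["azoreductase"], western_diet, supply=s)
        for s in (50.0, 100.0, 200.0, 600.0, 1000.0)]
    assert all(values[i] <= values[i + 1] + 1e-9
               for i in range(len(values) - 1))
    # saturates at the coupling cap
    assert values[-1] == pytest.approx(400.0, abs=1e-6)
    assert values[-2] == pytest.approx(400.0, abs=1e-6)


def test_linearity_below_all_caps(azo_community, western_diet, drugs):
    v1 = drug_sim.conversion_potential(
        azo_community, drugs["azoreductase"], western_diet, supply=50.0)
    v2 = drug_sim.conversion_potential(
        azo_community, drugs["azoreductase"], western_diet, supply=100.0)
    assert v2 == pytest.approx(2 * v1, rel=1e-6)


# ---------------------------------------------------------------------------
# conversion panels


def _carrier_cohort(n_samples=20, seed=5):
    pool = (
        syn.StrainSpec(species="Azoreducens toy", substrates=("glc_D",),
                       products=("ac",), drug_enzymes=("azoreductase",)),
        syn.StrainSpec(species="Neutra commensalis", substrates=("glc_D",)),
    )
    spec = syn.CohortSpec(n_samples=n_samples, species=pool,
                          prevalence={"Azoreducens toy": 0.5,
                                      "Neutra commensalis": 1.0},
                          planted_effects={}, null_metabolites=("gaba",),
                          seed=seed)
    return syn.make_cohort(spec)


def test_panel_recovers_planted_carrier_prevalence(western_diet, drugs):
    cohort = _carrier_cohort()
    from commflux.pipeline import build_sample_communities

    communities = build_sample_communities(cohort)
    panel = drug_sim.conversion_panel(
        communities, {"azoreductase": drugs["azoreductase"]}, western_diet)
    present = (cohort.abundances.values["Azoreducens toy"] > 0)
    capable = panel.capability["5asa"]
    assert (capable == present.loc[capable.index]).all()
    assert panel.summary().loc["5asa", "fraction_capable"] == \
        pytest.approx(present.mean())


def test_panel_zero_for_uncarried_drug(western_diet, drugs):
    cohort = _carrier_cohort(n_samples=4)
    from commflux.pipeline import build_sample_communities

    communities = build_sample_communities(cohort)
    panel = drug_sim.conversion_panel(
        communities, {"drugx_deaminase": drugs["drugx_deaminase"]},
        western_diet)
    assert (panel.fluxes["nh4"] == 0).all()


def test_panel_summary_of_constant_column():
    fluxes = pd.DataFrame({"p": [3.0, 3.0, 3.0]},
                          index=["s1", "s2", "s3"])
    panel = drug_sim.ConversionPanel(fluxes=fluxes)
    summary = panel.summary()
    assert summary.loc["p", "mean"] == pytest.approx(3.0)
    assert summary.loc["p", "sd"] == pytest.approx(0.0)


# ---------------------------------------------------------------------------
# drug yields


def test_drugx_yields_hit_elemental_ceilings():
    model = syn.make_strain(syn.StrainSpec(
        species="Deaminator", substrates=("glc_D",), anaerobe=False,
        drug_enzymes=("drugx_deaminase",)))
    # drugX is C7H7NO2: one nitrogen -> nh4 yield exactly 1 (N-bounded)
    assert drug_sim.drug_yield(model, "EX_drugX", "nh4") == \
        pytest.approx(1.0, abs=1e-8)
    # seven carbons, complete oxidation -> co2 yield exactly 7
    assert drug_sim.drug_yield(model, "EX_drugX", "co2") == \
        pytest.approx(7.0, abs=1e-8)
    assert drug_sim.drug_yield(model, "EX_drugX", "atp") > 0


def test_yields_never_exceed_atom_counts():
    model = syn.make_strain(syn.StrainSpec(
        species="Deaminator", substrates=("glc_D",), anaerobe=False,
        drug_enzymes=("drugx_deaminase",)))
    formula = syn.FORMULARY["drugX"]
    assert drug_sim.drug_yield(model, "EX_drugX", "co2") <= formula["C"]
    assert drug_sim.drug_yield(model, "EX_drugX", "pyr") * 3 \
        <= formula["C"] + 1e-9
    assert drug_sim.drug_yield(model, "EX_drugX", "nh4") <= formula["N"]


def test_zero_substrate_control_yields_zero_atp(toy_glycolysis):
    assert drug_sim.drug_yield(toy_glycolysis, "EX_glc_D", "atp",
                               control="none") == 0.0


def test_glucose_control_pyruvate_yield_is_two(toy_glycolysis):
    assert drug_sim.drug_yield(toy_glycolysis, "EX_glc_D", "pyr",
                               control="glucose") == \
        pytest.approx(2.0, abs=1e-8)


def test_absent_currency_yields_zero_with_no_error(toy_chain):
    assert drug_sim.drug_yield(toy_chain, "EX_glc_D", "nh4") == 0.0


# ---------------------------------------------------------------------------
# bottleneck species


def test_single_species_bottleneck_is_reported(azo_community, western_diet,
                                               drugs):
    found = drug_sim.bottleneck_species(azo_community, drugs["azoreductase"],
                                        western_diet)
    assert [species for species, _ in found] == ["Azoreducens toy"]


def test_two_step_bottleneck_is_first_step_species(levo_community,
                                                   western_diet, drugs):
    # first-step species at abundance 0.2 limits m-tyramine production
    found = drug_sim.bottleneck_species(
        levo_community, drugs["dopa_decarboxylase"], western_diet,
        product="mtym")
    species = [sp for sp, _ in found]
    assert "Levoa prima" in species
    assert "Levob secunda" not in species


def test_bottleneck_soundness_under_abundance_perturbation(levo_pair,
                                                           western_diet,
                                                           drugs):
    a, b = levo_pair

    def potential(w_a):
        community = cb.assemble_community(
            {"Levoa prima": a, "Levob secunda": b},
            {"Levoa prima": w_a, "Levob secunda": 1 - 0.2})
        return drug_sim.conversion_potential(
            community, drugs["dopa_decarboxylase"], western_diet,
            product="mtym")

    base = potential(0.2)
    bumped = potential(0.2 * 1.1)
    assert bumped > base + 1e-9


# ---------------------------------------------------------------------------
# net secretion


def test_net_secretion_equals_conversion_for_same_objective(azo_community,
                                                            western_diet,
                                                            drugs):
    # supply the precursor through the diet, then the same LP is solved
    diet = mc.DietProfile(name="WD+bsz",
                          uptakes=dict(western_diet.uptakes) |
                          {"EX_bsz": 1000.0, "EX_o2": 1000.0},
                          aerobic=True)
    secretion = drug_sim.net_secretion(azo_community, ["5asa"], diet)
    conv = drug_sim.conversion_potential(azo_community,
                                         drugs["azoreductase"],
                                         western_diet)
    assert secretion["5asa"] == pytest.approx(conv, abs=1e-6)


def test_net_secretion_zero_without_producer_or_diet(azo_community,
                                                     western_diet):
    out = drug_sim.net_secretion(azo_community, ["mtym", "lac_L"],
                                 western_diet)
    assert out["mtym"] == 0.0  # metabolite not in the community at all
    assert out["lac_L"] == 0.0


def test_batch_net_secretion_matches_sequential(azo_community, western_diet):
    mets = ["ac", "5asa", "pyr", "co2"]
    batch = drug_sim.net_secretion(azo_community, mets, western_diet)
    for mid in mets:
        single = drug_sim.net_secretion(azo_community, [mid], western_diet)
        assert batch[mid] == pytest.approx(single[mid], abs=1e-8)


# ---------------------------------------------------------------------------
# diet sensitivity


def _panel(values, samples=("s1", "s2", "s3", "s4")):
    return drug_sim.ConversionPanel(
        fluxes=pd.DataFrame(values, index=list(samples)))


def test_identical_panels_correlate_perfectly():
    a = _panel({"p": [1.0, 2.0, 3.0, 4.0]})
    r = drug_sim.diet_sensitivity(a, a)
    assert r["p"] == pytest.approx(1.0)


def test_scaling_preserves_correlation():
    a = _panel({"p": [1.0, 2.0, 3.0, 4.0]})
    b = _panel({"p": [2.0, 4.0, 6.0, 8.0]})
    assert drug_sim.diet_sensitivity(a, b)["p"] == pytest.approx(1.0)


def test_anticorrelated_columns():
    a = _panel({"p": [1.0, 2.0, 3.0, 4.0]})
    b = _panel({"p": [4.0, 3.0, 2.0, 1.0]})
    assert drug_sim.diet_sensitivity(a, b)["p"] == pytest.approx(-1.0)


def test_constant_column_flagged_undefined():
    a = _panel({"p": [1.0, 1.0, 1.0, 1.0]})
    b = _panel({"p": [1.0, 2.0, 3.0, 4.0]})
    assert np.isnan(drug_sim.diet_sensitivity(a, b)["p"])


def test_mismatched_panels_rejected():
    a = _panel({"p": [1.0, 2.0, 3.0, 4.0]})
    b = _panel({"q": [1.0, 2.0, 3.0, 4.0]})
    with pytest.raises(mc.ValidationError):
        drug_sim.diet_sensitivity(a, b)


# ---------------------------------------------------------------------------
# drug module I/O


def test_drug_module_json_roundtrip(tmp_path, drugs):
    path = tmp_path / "drugs.json"
    drug_sim.save_drug_modules(drugs, path)
    loaded = drug_sim.load_drug_modules(path)
    assert set(loaded) == set(drugs)
    assert loaded["azoreductase"].reactions == \
        drugs["azoreductase"].reactions
    assert loaded["azoreductase"].precursor == "bsz"


def test_drug_module_invariants():
    with pytest.raises(mc.ValidationError):
        drug_sim.DrugModule(id="bad", location="mitochondrion")
    with pytest.raises(mc.ValidationError):
        drug_sim.DrugModule(
            id="bad2",
            reactions={"R": {"stoichiometry": {"a[c]": -1.0,
                                               "b[c]": 1.0}}},
            enzyme_reactions=["R"], precursor="zzz", products=["b"])
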