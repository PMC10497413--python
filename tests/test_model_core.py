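import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from commflux import model_core as mc
from commflux import lp_engine, synthetic_data as syn


# ---------------------------------------------------------------------------
# formulas


@pytest.mark.parametrize("text, expected", [
    ("C6H12O6", {"C": 6, "H": 12, "O": 6}),
    ("H2O", {"H": 2, "O": 1}),
    ("C10H16N5O13", {"C": 10, "H": 16, "N": 5, "O": 13}),
    ("", {}),
])
def test_formula_parsing(text, expected):
    assert mc.parse_formula(text) == expected


def test_formula_rejects_unknown_elements_and_garbage():
    with pytest.raises(mc.ValidationError):
        mc.parse_formula("C6Qq2")
    with pytest.raises(mc.ValidationError):
        mc.parse_formula("2CH4")


@settings(max_examples=50, derandomize=True)
@given(st.dictionaries(st.sampled_from(["C", "H", "N", "O", "P", "S"]),
                       st.integers(1, 40), min_size=1, max_size=5))
def test_formula_roundtrip(counts):
    counts = {k: float(v) for k, v in counts.items()}
    assert mc.parse_formula(mc.format_formula(counts)) == counts


# ---------------------------------------------------------------------------
# balance checks


def _two_met_model():
    m = mc.StoichiometricModel(id="bal")
    m.add_metabolite(mc.Metabolite(id="A", compartment="c",
                                   formula={"C": 6, "H": 12, "O": 6},
                                   charge=0))
    m.add_metabolite(mc.Metabolite(id="B", compartment="c",
                                   formula={"C": 5, "H": 10, "O": 5},
                                   charge=-1))
    m.add_reaction(mc.Reaction(id="R", stoichiometry={"A[c]": -1.0,
                                                      "B[c]": 1.0},
                               lower_bound=0))
    m.add_reaction(mc.Reaction(id="EX_A", stoichiometry={"A[c]": -1.0},
                               kind="exchange"))
    m.add_reaction(mc.Reaction(id="DM_B", stoichiometry={"B[c]": -1.0},
                               lower_bound=0, kind="demand"))
    return m


def test_elemental_imbalance_arithmetic():
    m = _two_met_model()
    assert mc.elemental_balance(m, "R") == {"C": -1, "H": -2, "O": -1}


def test_charge_imbalance_and_boundary_exemption():
    m = _two_met_model()
    assert mc.charge_balance(m, "R") == -1
    assert mc.elemental_balance(m, "EX_A") == mc.EXEMPT
    assert mc.charge_balance(m, "DM_B") == mc.EXEMPT


def test_balanced_azoreductase_reaction(toy_azo):
    assert mc.elemental_balance(toy_azo, "AZOR_e") == {}
    assert mc.charge_balance(toy_azo, "AZOR_e") == 0


def test_missing_formula_marked_unknown_not_raised():
    spec = syn.StrainSpec(species="Mystia", substrates=("glc_D",),
                          defects=("missing_formula",))
    m = syn.make_strain(spec)
    assert mc.elemental_balance(m, "MYST") == mc.UNKNOWN_COMPOSITION
    assert "MYST" not in mc.imbalanced_reactions(m)


def test_synthetic_strains_are_balanced_by_construction(toy_azo,
                                                        toy_glycolysis):
    for model in (toy_azo, toy_glycolysis):
        assert mc.imbalanced_reactions(model) == []


# ---------------------------------------------------------------------------
# demand reactions


def test_add_demand_follows_id_convention(toy_azo):
    m = toy_azo.copy()
    rid = mc.add_demand(m, "atp", "c")
    assert rid == "DM_atp_c_"
    assert m.reactions[rid].stoichiometry == {"atp[c]": -1.0}
    assert (m.reactions[rid].lower_bound,
            m.reactions[rid].upper_bound) == (0.0, 1000.0)


def test_add_demand_is_idempotent(toy_azo):
    m = toy_azo.copy()
    rid = mc.add_demand(m, "nh4", "c")
    n = len(m.reactions)
    assert mc.add_demand(m, "nh4", "c") == rid
    assert len(m.reactions) == n
    with pytest.raises(mc.ValidationError):
        mc.add_demand(m, "not_a_metabolite")


def test_demand_respects_conservation_on_starved_medium(toy_azo):
    # maximising an ammonia demand on a nitrogen-free medium must give 0
    m = toy_azo.copy()
    rid = mc.add_demand(m, "nh4", "c")
    diet = mc.DietProfile(name="N-free",
                          uptakes={"EX_glc_D": 10.0, "EX_h2o": 1000.0,
                                   "EX_pi": 10.0})
    constrained = mc.apply_diet(m, diet)
    sol = lp_engine.optimize(constrained, rid, "max")
    assert sol.ok and abs(sol.objective_value) < 1e-9


# ---------------------------------------------------------------------------
# diets


def test_apply_diet_sets_only_listed_uptakes(toy_chain):
    diet = mc.DietProfile(name="glc", uptakes={"EX_glc_D": 10.0})
    constrained = mc.apply_diet(toy_chain, diet)
    assert constrained.reactions["EX_glc_D"].lower_bound == -10.0
    # the input model is untouched
    assert toy_chain.reactions["EX_glc_D"].lower_bound == -10.0
    assert constrained is not toy_chain


def test_apply_diet_unlimited_profile(toy_azo):
    um = syn.unlimited_medium(toy_azo)
    constrained = mc.apply_diet(toy_azo, um)
    for rxn in constrained.exchanges:
        assert rxn.lower_bound == -1000.0


def test_apply_diet_empty_closes_all_uptakes_and_growth(toy_azo):
    constrained = mc.apply_diet(toy_azo, mc.DietProfile(name="empty"))
    assert all(r.lower_bound == 0 for r in constrained.exchanges)
    sol = lp_engine.optimize(constrained, "BIO", "max")
    assert sol.ok and abs(sol.objective_value) < 1e-9


def test_apply_diet_is_idempotent(toy_azo, western_diet):
    once = mc.apply_diet(toy_azo, western_diet)
    twice = mc.apply_diet(once, western_diet)
    assert mc.models_equivalent(once, twice)


def test_apply_diet_skips_unknown_exchanges(toy_chain, caplog):
    diet = mc.DietProfile(name="odd", uptakes={"EX_glc_D": 5.0,
                                               "EX_unobtainium": 3.0})
    constrained = mc.apply_diet(toy_chain, diet)
    assert constrained.reactions["EX_glc_D"].lower_bound == -5.0
    assert "EX_unobtainium" not in constrained.reactions


def test_aerobic_flag_opens_oxygen(toy_azo):
    diet = mc.DietProfile(name="aero", uptakes={"EX_glc_D": 10.0},
                          aerobic=True)
    constrained = mc.apply_diet(toy_azo, diet)
    assert constrained.reactions["EX_o2"].lower_bound == -1000.0
    anaero = mc.apply_diet(toy_azo, diet, aerobic=False)
    assert anaero.reactions["EX_o2"].lower_bound == 0.0


def test_diet_tsv_roundtrip(tmp_path, western_diet):
    path = tmp_path / "wd.tsv"
    mc.save_diet(western_diet, path)
    loaded = mc.load_diet(path)
    assert loaded.uptakes == western_diet.uptakes


# ---------------------------------------------------------------------------
# GPR syntax


@pytest.mark.parametrize("gpr, ok", [
    ("(g1 and g2) or g3", True),
    ("g1", True),
    ("", True),
    ("g1 and or g2", False),
    ("(g1 and g2", False),
    ("and g1", False),
])
def test_gpr_grammar(gpr, ok):
    m = mc.StoichiometricModel(id="g")
    m.add_metabolite(mc.Metabolite(id="A", compartment="c"))
    m.add_reaction(mc.Reaction(id="R", stoichiometry={"A[c]": -1.0},
                               gpr=gpr, kind="sink", lower_bound=0))
    flagged = mc.gpr_syntax_check(m)
    assert (flagged == []) is ok


# ---------------------------------------------------------------------------
# load / save


def test_toy_chain_fixture_file(tmp_path, toy_chain):
    path = tmp_path / "chain.json"
    mc.save_model(toy_chain, path, "json")
    loaded = mc.load_model(path, "json")
    assert len(loaded.reactions) == 4
    assert len(loaded.metabolites) == 3
    assert loaded.objective_reaction == "BIO"


@pytest.mark.parametrize("dialect", ["json", "sbml"])
def test_save_load_roundtrip(tmp_path, toy_azo, dialect):
    path = tmp_path / f"azo.{dialect}"
    mc.save_model(toy_azo, path, dialect)
    loaded = mc.load_model(path, dialect)
    assert mc.models_equivalent(toy_azo, loaded)


def test_cross_dialect_equivalence(tmp_path, toy_glycolysis):
    pj, ps = tmp_path / "m.json", tmp_path / "m.xml"
    mc.save_model(toy_glycolysis, pj, "json")
    mc.save_model(toy_glycolysis, ps, "sbml")
    assert mc.models_equivalent(mc.load_model(pj, "json"),
                                mc.load_model(ps, "sbml"))


def test_gpr_survives_roundtrip(tmp_path, toy_azo):
    path = tmp_path / "azo.json"
    mc.save_model(toy_azo, path, "json")
    loaded = mc.load_model(path, "json")
    tag = "Azoreducens_toy"
    assert loaded.reactions["BIO"].gpr == \
        f"({tag}_b1 and {tag}_b2) or {tag}_b3"


def test_undeclared_metabolite_is_a_validation_error(tmp_path):
    import json

    data = {"id": "bad", "metabolites": [
        {"id": "A", "compartment": "c"}],
        "reactions": [{"id": "R", "stoichiometry": {"A[c]": -1,
                                                    "ghost[c]": 1}}]}
    path = tmp_path / "bad.json"
    path.write_text(json.dumps(data))
    with pytest.raises(mc.ValidationError):
        mc.load_model(path, "json")


def test_unparseable_file_is_a_format_error(tmp_path):
    path = tmp_path / "junk.json"
    path.write_text("{not json")
    with pytest.raises(mc.FormatError):
        mc.load_model(path, "json")
    path2 = tmp_path / "junk.xml"
    path2.write_text("<sbml but broken")
    with pytest.raises(mc.FormatError):
        mc.load_model(path2, "sbml")


def test_duplicate_ids_rejected():
    m = mc.StoichiometricModel(id="dup")
    m.add_metabolite(mc.Metabolite(id="A", compartment="c"))
    with pytest.raises(mc.ValidationError):
        m.add_metabolite(mc.Metabolite(id="A", compartment="c"))
    m.add_reaction(mc.Reaction(id="R", stoichiometry={"A[c]": -1.0},
                               kind="sink", lower_bound=0))
    with pytest.raises(mc.ValidationError):
        m.add_reaction(mc.Reaction(id="R", stoichiometry={"A[c]": -1.0},
                                   kind="sink", lower_bound=0))


def test_reaction_invariants():
    with pytest.raises(mc.ValidationError):
        mc.Reaction(id="R", stoichiometry={"A[c]": -1.0}, lower_bound=5,
                    upper_bound=1)
    with pytest.raises(mc.ValidationError):
        mc.Reaction(id="EX", stoichiometry={"A[c]": -1.0, "B[c]": 1.0},
                    kind="exchange")
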