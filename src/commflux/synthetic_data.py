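"""Synthetic reconstructions, drug modules, cohorts and trait datasets.

Every input the pipeline consumes can be generated here with known ground
truth: small strain reconstructions with plantable capabilities (growth
substrates, fermentation products, drug enzymes) and plantable defects
(dead ends, futile cycles, missing formulas), drug-module definitions,
cohorts with planted species–metabolite effects, and trait datasets with a
controlled sign-flip rate.

The toy biochemistry uses a closed C/H/N/O element alphabet with synthetic
formulas chosen so that every constructed reaction is exactly elementally
balanced: substrates are CnH2nOn "sugar units" interconvertible with the
CH2O precursor ``prec``, energy metabolism runs on an abstract ATP/ADP/Pi
cycle, and any hydrogen/oxygen remainder of a template reaction is closed
with h2/h2o. Formulas are synthetic stand-ins, not real chemistry; what they
guarantee is that conservation laws hold by construction.

All generators are pure functions of (spec, seed): repeated calls are
byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .community_builder import AbundanceTable
from .drug_sim import DrugModule
from .model_core import (
    DEFAULT_BOUND,
    DietProfile,
    Metabolite,
    Reaction,
    StoichiometricModel,
    ValidationError,
    gpr_genes,
    infer_kind,
    met_key,
)

# synthetic formulary (closed C/H/N/O alphabet; see module docstring)
FORMULARY: dict[str, dict[str, float]] = {
    "glc_D": {"C": 6, "H": 12, "O": 6},
    "fru": {"C": 6, "H": 12, "O": 6},
    "rib": {"C": 5, "H": 10, "O": 5},
    "ac": {"C": 2, "H": 4, "O": 2},
    "lac_L": {"C": 3, "H": 6, "O": 3},
    "prec": {"C": 1, "H": 2, "O": 1},
    "pyr": {"C": 3, "H": 4, "O": 3},
    "co2": {"C": 1, "O": 2},
    "h2o": {"H": 2, "O": 1},
    "o2": {"O": 2},
    "h2": {"H": 2},
    "nh4": {"H": 4, "N": 1},
    "pi": {"H": 3, "O": 4},
    "atp": {"C": 10, "H": 16, "N": 5, "O": 13},
    "adp": {"C": 10, "H": 15, "N": 5, "O": 10},
    "biomass": {"C": 6, "H": 16, "N": 1, "O": 6},
    "bsz": {"C": 17, "H": 15, "N": 3, "O": 6},
    "5asa": {"C": 7, "H": 7, "N": 1, "O": 3},
    "aba": {"C": 10, "H": 12, "N": 2, "O": 3},
    "levodopa": {"C": 9, "H": 11, "N": 1, "O": 4},
    "dopamine": {"C": 8, "H": 11, "N": 1, "O": 2},
    "mtym": {"C": 8, "H": 11, "N": 1, "O": 1},
    "drugX": {"C": 7, "H": 7, "N": 1, "O": 2},
    "s7": {"C": 4, "H": 6, "O": 4},
    "s8": {"C": 4, "H": 6, "O": 4},
    "dde": {"C": 1, "H": 2, "O": 1},
    "etoh": {"C": 2, "H": 6, "O": 1},
    "but": {"C": 4, "H": 8, "O": 2},
}

#: substrates usable by make_strain: id -> number of CH2O precursor units
SUBSTRATE_POOL = {"glc_D": 6, "fru": 6, "rib": 5, "ac": 2, "lac_L": 3}
#: fermentation products expressible from the precursor (id -> CH2O units)
PRODUCT_POOL = {"ac": 2, "lac_L": 3, "pyr": 3, "etoh": 2, "but": 4}


def _balance_with_h2o_h2(stoich: dict[str, float]) -> dict[str, float]:
    """Close the H/O remainder of a draft reaction with h2o/h2 (cytosolic).

    C and N must already balance (asserted); the returned stoichiometry is
    exactly elementally balanced.
    """
    totals: dict[str, float] = {}
    for key, coeff in stoich.items():
        mid = key.split("[")[0]
        for el, n in FORMULARY[mid].items():
            totals[el] = totals.get(el, 0.0) + coeff * n
    if abs(totals.get("C", 0)) > 1e-9 or abs(totals.get("N", 0)) > 1e-9:
        raise ValidationError(f"template cannot balance C/N: {totals}")
    out = dict(stoich)
    x_h2o = -totals.get("O", 0.0)
    x_h2 = -(totals.get("H", 0.0) + 2 * x_h2o) / 2
    for mid, x in (("h2o", x_h2o), ("h2", x_h2)):
        if abs(x) > 1e-9:
            key = met_key(mid, "c")
            out[key] = out.get(key, 0.0) + x
            if abs(out[key]) < 1e-9:
                del out[key]
    return out


# ---------------------------------------------------------------------------
# strain specifications


@dataclass(frozen=True)
class StrainSpec:
    """Recipe for a synthetic strain reconstruction."""

    species: str
    substrates: tuple[str, ...] = ("glc_D",)
    products: tuple[str, ...] = ()
    drug_enzymes: tuple[str, ...] = ()
    anaerobe: bool = True
    defects: tuple[str, ...] = ()
    strain: str = ""

    def __post_init__(self) -> None:
        if not self.substrates:
            raise ValidationError("a strain needs at least one substrate")
        for s in self.substrates:
            if s not in SUBSTRATE_POOL:
                raise ValidationError(f"unknown substrate {s!r}")
        for p in self.products:
            if p not in PRODUCT_POOL:
                raise ValidationError(f"unknown fermentation product {p!r}")
        for d in self.defects:
            if d not in ("dead_end", "futile_cycle", "missing_formula"):
                raise ValidationError(f"unknown defect {d!r}")


def _sanitize(label: str) -> str:
    import re

    return re.sub(r"\W+", "_", label.strip())


class _Builder:
    """Incremental strain construction with id-deduplicated parts."""

    def __init__(self, model_id: str):
        self.model = StoichiometricModel(id=model_id)

    def met(self, mid: str, comp: str,
            formula: dict | None = "lookup") -> str:
        key = met_key(mid, comp)
        if key not in self.model.metabolites:
            if formula == "lookup":
                formula = dict(FORMULARY[mid]) if mid in FORMULARY else None
            self.model.add_metabolite(Metabolite(
                id=mid, compartment=comp, name=mid,
                formula=formula, charge=0))
        return key

    def rxn(self, rid: str, stoich: dict[str, float], lb: float, ub: float,
            gpr: str = "", kind: str | None = None,
            subsystem: str = "") -> None:
        if rid in self.model.reactions:
            if self.model.reactions[rid].stoichiometry != stoich:
                raise ValidationError(
                    f"conflicting definitions for reaction {rid}")
            return
        if kind is None:
            kind = infer_kind(rid, stoich, self.model.metabolites)
        self.model.add_reaction(Reaction(
            id=rid, stoichiometry=stoich, lower_bound=lb, upper_bound=ub,
            gpr=gpr, kind=kind, subsystem=subsystem))
        self.model.genes |= gpr_genes(gpr)

    def exchangeable(self, mid: str) -> None:
        """Extracellular + cytosolic metabolite, transport and exchange."""
        self.met(mid, "e")
        self.met(mid, "c")
        self.rxn(f"{mid}t",
                 {met_key(mid, "e"): -1.0, met_key(mid, "c"): 1.0},
                 -DEFAULT_BOUND, DEFAULT_BOUND, kind="transport")
        self.rxn(f"EX_{mid}", {met_key(mid, "e"): -1.0},
                 -DEFAULT_BOUND, DEFAULT_BOUND, kind="exchange")


def make_strain(spec: StrainSpec, seed: int = 0,
                modules: dict[str, DrugModule] | None = None
                ) -> StoichiometricModel:
    """Build a strain reconstruction from a spec.

    The model grows on each listed substrate (and on no absent substrate),
    secretes each listed fermentation product, carries complete reaction
    sets for the listed drug enzymes, and is mass/charge balanced by
    construction except where defects are planted.
    """
    del seed  # construction is fully deterministic; kept for API symmetry
    modules = modules if modules is not None else standard_drug_modules()
    tag = _sanitize(spec.species)
    b = _Builder(tag if not spec.strain else f"{tag}_{spec.strain}")
    model = b.model
    model.taxonomy = {"species": spec.species,
                      "strain": spec.strain or "type"}

    for mid in ("h2o", "o2", "co2", "h2", "nh4", "pi", "pyr"):
        b.exchangeable(mid)
    for mid in ("atp", "adp", "prec", "biomass"):
        b.met(mid, "c")
    # maintenance ATP hydrolysis keeps the ATP/ADP pool recyclable
    b.rxn("ATPM", _balance_with_h2o_h2(
        {met_key("atp", "c"): -1.0, met_key("adp", "c"): 1.0,
         met_key("pi", "c"): 1.0}), 0.0, DEFAULT_BOUND)

    for sub in spec.substrates:
        b.exchangeable(sub)
        n_prec = SUBSTRATE_POOL[sub]
        gene = f"{tag}_{sub}_g"
        b.rxn(f"PREC_{sub}", {met_key(sub, "c"): -1.0,
                              met_key("prec", "c"): float(n_prec)},
              0.0, DEFAULT_BOUND, gpr=gene)
        carbons = FORMULARY[sub]["C"]
        n_pyr, n_co2 = divmod(int(carbons), 3)
        # 2 ATP per substrate: glycolysis-style substrate-level phosphorylation
        draft = {met_key(sub, "c"): -1.0, met_key("adp", "c"): -2.0,
                 met_key("pi", "c"): -2.0, met_key("atp", "c"): 2.0}
        if n_pyr:
            draft[met_key("pyr", "c")] = float(n_pyr)
        if n_co2:
            draft[met_key("co2", "c")] = float(n_co2)
        b.rxn(f"CAT_{sub}", _balance_with_h2o_h2(draft), 0.0, DEFAULT_BOUND,
              gpr=gene)

    for prod in spec.products:
        b.exchangeable(prod)
        n_prec = PRODUCT_POOL[prod]
        draft = {met_key("prec", "c"): -float(n_prec),
                 met_key(prod, "c"): 1.0}
        b.rxn(f"PROD_{prod}", _balance_with_h2o_h2(draft), 0.0,
              DEFAULT_BOUND, gpr=f"{tag}_{prod}_g")

    # biomass: 6 precursor units + nitrogen + 1 ATP equivalent
    b.rxn("BIO", _balance_with_h2o_h2(
        {met_key("prec", "c"): -6.0, met_key("nh4", "c"): -1.0,
         met_key("atp", "c"): -1.0, met_key("biomass", "c"): 1.0,
         met_key("adp", "c"): 1.0, met_key("pi", "c"): 1.0}),
        0.0, DEFAULT_BOUND,
        gpr=f"({tag}_b1 and {tag}_b2) or {tag}_b3")
    b.rxn("DM_biomass_c_", {met_key("biomass", "c"): -1.0}, 0.0,
          DEFAULT_BOUND, kind="demand")
    model.objective_reaction = "BIO"

    for enzyme_id in spec.drug_enzymes:
        module = modules[enzyme_id]
        _install_module(b, module, anaerobe=spec.anaerobe)

    _install_defects(b, spec.defects)
    model.validate()
    return model


def _install_module(b: _Builder, module: DrugModule, anaerobe: bool) -> None:
    for mid, formula in module.metabolites.items():
        FORMULARY.setdefault(mid, dict(formula) if formula else formula)
    for rid, spec_ in module.reactions.items():
        stoich = dict(spec_["stoichiometry"])
        if anaerobe and rid in module.enzyme_reactions:
            for key, coeff in stoich.items():
                if key.split("[")[0] == "o2" and coeff < 0:
                    raise ValidationError(
                        f"anaerobe cannot carry oxygen-consuming enzyme "
                        f"reaction {rid} ({module.id})")
        for key in stoich:
            mid, comp = key.split("[")[0], key.split("[")[1].rstrip("]")
            formula = module.metabolites.get(mid, "lookup")
            if isinstance(formula, dict):
                formula = dict(formula)
            b.met(mid, comp, formula=formula)
        gpr = " or ".join(module.genes)
        b.rxn(rid, stoich, float(spec_.get("lower_bound", 0.0)),
              float(spec_.get("upper_bound", DEFAULT_BOUND)),
              gpr=gpr if rid in module.enzyme_reactions else "",
              subsystem="drug metabolism")


def _install_defects(b: _Builder, defects) -> None:
    if "dead_end" in defects:
        b.met("dde", "c")
        b.rxn("DEADEND", {met_key("prec", "c"): -1.0,
                          met_key("dde", "c"): 1.0}, 0.0, DEFAULT_BOUND)
    if "futile_cycle" in defects:
        b.met("s7", "c")
        b.met("s8", "c")
        # an uncosted ATP-generating isomerisation loop: each step is
        # elementally balanced, the cycle is thermodynamically implausible
        b.rxn("FC1", {met_key("s7", "c"): -1.0, met_key("adp", "c"): -1.0,
                      met_key("pi", "c"): -1.0, met_key("s8", "c"): 1.0,
                      met_key("atp", "c"): 1.0, met_key("h2o", "c"): 1.0},
              0.0, DEFAULT_BOUND)
        b.rxn("FC2", {met_key("s8", "c"): -1.0, met_key("s7", "c"): 1.0},
              0.0, DEFAULT_BOUND)
    if "missing_formula" in defects:
        b.met("mystery", "c", formula=None)
        b.rxn("MYST", {met_key("prec", "c"): -1.0,
                       met_key("mystery", "c"): 1.0}, 0.0, DEFAULT_BOUND)


# ---------------------------------------------------------------------------
# drug modules


def standard_drug_modules() -> dict[str, DrugModule]:
    """Hand-written synthetic drug modules.

    Azoreductase (extracellular, balsalazide-like prodrug activation to a
    5-ASA analog), a two-step levodopa chain (decarboxylase to dopamine,
    then dehydroxylase to an m-tyramine analog, carried by different
    species), and an oxidative deaminase whose substrate can serve as a
    carbon/nitrogen/energy source.
    """
    modules = {}
    modules["azoreductase"] = DrugModule(
        id="azoreductase", name="azoreductase (synthetic)", genes=["azoR"],
        metabolites={m: dict(FORMULARY[m]) for m in ("bsz", "5asa", "aba")},
        reactions={
            "AZOR_e": {"stoichiometry": {
                "bsz[e]": -1.0, "h2o[e]": -2.0,
                "5asa[e]": 1.0, "aba[e]": 1.0, "o2[e]": 1.0}},
            "EX_bsz": {"stoichiometry": {"bsz[e]": -1.0},
                       "lower_bound": -DEFAULT_BOUND},
            "EX_5asa": {"stoichiometry": {"5asa[e]": -1.0}},
            "EX_aba": {"stoichiometry": {"aba[e]": -1.0}},
        },
        enzyme_reactions=["AZOR_e"], precursor="bsz",
        products=["5asa", "aba"], location="extracellular")
    modules["dopa_decarboxylase"] = DrugModule(
        id="dopa_decarboxylase", name="tyrosine/DOPA decarboxylase "
        "(synthetic)", genes=["tdcA"],
        metabolites={m: dict(FORMULARY[m])
                     for m in ("levodopa", "dopamine")},
        reactions={
            "LDOPAt": {"stoichiometry": {"levodopa[e]": -1.0,
                                         "levodopa[c]": 1.0},
                       "lower_bound": -DEFAULT_BOUND},
            "DOPADC": {"stoichiometry": {"levodopa[c]": -1.0,
                                         "dopamine[c]": 1.0,
                                         "co2[c]": 1.0}},
            "DOPAt": {"stoichiometry": {"dopamine[e]": -1.0,
                                        "dopamine[c]": 1.0},
                      "lower_bound": -DEFAULT_BOUND},
            "EX_levodopa": {"stoichiometry": {"levodopa[e]": -1.0},
                            "lower_bound": -DEFAULT_BOUND},
            "EX_dopamine": {"stoichiometry": {"dopamine[e]": -1.0},
                            "lower_bound": -DEFAULT_BOUND},
        },
        enzyme_reactions=["DOPADC"], precursor="levodopa",
        products=["dopamine"], location="cytosol")
    modules["dopamine_dehydroxylase"] = DrugModule(
        id="dopamine_dehydroxylase",
        name="dopamine dehydroxylase (synthetic)", genes=["dadh"],
        metabolites={m: dict(FORMULARY[m]) for m in ("dopamine", "mtym")},
        reactions={
            "DOPAt": {"stoichiometry": {"dopamine[e]": -1.0,
                                        "dopamine[c]": 1.0},
                      "lower_bound": -DEFAULT_BOUND},
            "DOPADH": {"stoichiometry": {"dopamine[c]": -2.0,
                                         "mtym[c]": 2.0, "o2[c]": 1.0}},
            "MTYMt": {"stoichiometry": {"mtym[e]": -1.0, "mtym[c]": 1.0},
                      "lower_bound": -DEFAULT_BOUND},
            "EX_dopamine": {"stoichiometry": {"dopamine[e]": -1.0},
                            "lower_bound": -DEFAULT_BOUND},
            "EX_mtym": {"stoichiometry": {"mtym[e]": -1.0}},
        },
        enzyme_reactions=["DOPADH"], precursor="dopamine",
        products=["mtym"], location="cytosol")
    modules["drugx_deaminase"] = DrugModule(
        id="drugx_deaminase", name="oxidative drug deaminase (synthetic)",
        genes=["dxda"],
        metabolites={"drugX": dict(FORMULARY["drugX"])},
        reactions={
            "DRUGXt": {"stoichiometry": {"drugX[e]": -1.0, "drugX[c]": 1.0},
                       "lower_bound": -DEFAULT_BOUND},
            "DRUGXCAT": {"stoichiometry": {
                "drugX[c]": -1.0, "o2[c]": -5.5, "adp[c]": -1.0,
                "pi[c]": -1.0, "co2[c]": 7.0, "nh4[c]": 1.0,
                "atp[c]": 1.0, "h2[c]": 2.5}},
            "EX_drugX": {"stoichiometry": {"drugX[e]": -1.0},
                         "lower_bound": -DEFAULT_BOUND},
        },
        enzyme_reactions=["DRUGXCAT"], precursor="drugX",
        products=["nh4"], location="cytosol")
    return modules


def make_drug_modules(n: int, seed: int = 0) -> dict[str, DrugModule]:
    """Generate ``n`` synthetic decarboxylase-style drug modules.

    Modules 0 and 1 always form a two-step chain (precursor -> intermediate
    by enzyme A, intermediate -> product by enzyme B), emulating two-step
    pathways carried by different species. Every enzymatic reaction is
    elementally balanced by construction (product = precursor - CO2).
    """
    if n < 2:
        raise ValidationError("need n >= 2 (the two-step chain takes two)")
    rng = np.random.default_rng(seed)
    modules: dict[str, DrugModule] = {}

    def formula(c: int, h: int, o: int, n_at: int) -> dict[str, float]:
        return {k: float(v)
                for k, v in (("C", c), ("H", h), ("O", o), ("N", n_at))
                if v > 0}

    def decarb_module(idx: int, prec_id: str, prod_id: str,
                      prec_f: dict, prod_f: dict) -> DrugModule:
        for mid, f in ((prec_id, prec_f), (prod_id, prod_f)):
            FORMULARY.setdefault(mid, dict(f))
        rid = f"SDC{idx}"
        return DrugModule(
            id=f"syn_enz{idx}", name=f"synthetic decarboxylase {idx}",
            genes=[f"sde{idx}"],
            metabolites={prec_id: prec_f, prod_id: prod_f},
            reactions={
                f"{prec_id}t": {"stoichiometry": {f"{prec_id}[e]": -1.0,
                                                  f"{prec_id}[c]": 1.0},
                                "lower_bound": -DEFAULT_BOUND},
                rid: {"stoichiometry": {f"{prec_id}[c]": -1.0,
                                        f"{prod_id}[c]": 1.0,
                                        "co2[c]": 1.0}},
                f"{prod_id}t": {"stoichiometry": {f"{prod_id}[e]": -1.0,
                                                  f"{prod_id}[c]": 1.0},
                                "lower_bound": -DEFAULT_BOUND},
                f"EX_{prec_id}": {"stoichiometry": {f"{prec_id}[e]": -1.0},
                                  "lower_bound": -DEFAULT_BOUND},
                f"EX_{prod_id}": {"stoichiometry": {f"{prod_id}[e]": -1.0},
                                  "lower_bound": -DEFAULT_BOUND},
            },
            enzyme_reactions=[rid], precursor=prec_id, products=[prod_id],
            location="cytosol")

    for idx in range(n):
        c = int(rng.integers(6, 12))
        h = 2 * int(rng.integers(4, c + 2))
        o = int(rng.integers(5, 8))
        n_at = int(rng.integers(0, 3))
        if idx == 0:
            p = formula(c, h, o, n_at)
            q = formula(c - 1, h, o - 2, n_at)
            r = formula(c - 2, h, o - 4, n_at)
            modules["syn_enz0"] = decarb_module(0, "sd0p", "sd0q", p, q)
            modules["syn_enz1"] = decarb_module(1, "sd0q", "sd0r", q, r)
        elif idx == 1:
            continue  # consumed by the chain above
        else:
            p = formula(c, h, o, n_at)
            q = formula(c - 1, h, o - 2, n_at)
            modules[f"syn_enz{idx}"] = decarb_module(
                idx, f"sd{idx}p", f"sd{idx}q", p, q)
    return modules


# ---------------------------------------------------------------------------
# named toy fixtures


def toy_chain() -> StoichiometricModel:
    """Minimal linear chain: glucose uptake -> transport -> biomass.

    EX_glc_D (lb -10), GLCt, BIO (2 glc[c] -> biomass[c], objective) and
    the biomass drain; at the glucose cap the maximal growth flux is 5.0.
    """
    m = StoichiometricModel(id="TOY_CHAIN")
    m.add_metabolite(Metabolite(id="glc_D", compartment="e",
                                formula=dict(FORMULARY["glc_D"]), charge=0))
    m.add_metabolite(Metabolite(id="glc_D", compartment="c",
                                formula=dict(FORMULARY["glc_D"]), charge=0))
    m.add_metabolite(Metabolite(id="biomass", compartment="c",
                                formula={"C": 12, "H": 24, "O": 12},
                                charge=0))
    m.add_reaction(Reaction(id="EX_glc_D",
                            stoichiometry={"glc_D[e]": -1.0},
                            lower_bound=-10.0, upper_bound=DEFAULT_BOUND,
                            kind="exchange"))
    m.add_reaction(Reaction(id="GLCt",
                            stoichiometry={"glc_D[e]": -1.0,
                                           "glc_D[c]": 1.0},
                            lower_bound=0.0, upper_bound=DEFAULT_BOUND,
                            kind="transport"))
    m.add_reaction(Reaction(id="BIO",
                            stoichiometry={"glc_D[c]": -2.0,
                                           "biomass[c]": 1.0},
                            lower_bound=0.0, upper_bound=DEFAULT_BOUND,
                            kind="internal"))
    m.add_reaction(Reaction(id="DM_biomass_c_",
                            stoichiometry={"biomass[c]": -1.0},
                            lower_bound=0.0, upper_bound=DEFAULT_BOUND,
                            kind="demand"))
    m.objective_reaction = "BIO"
    m.validate()
    return m


def toy_azo() -> StoichiometricModel:
    """Glucose-growing strain carrying the extracellular azoreductase."""
    return make_strain(StrainSpec(species="Azoreducens toy",
                                  substrates=("glc_D",), products=("ac",),
                                  drug_enzymes=("azoreductase",)))


def toy_levo_pair() -> tuple[StoichiometricModel, StoichiometricModel]:
    """Two strains splitting the two-step levodopa pathway.

    Strain A decarboxylates levodopa to dopamine; strain B dehydroxylates
    dopamine to the m-tyramine analog. Only together can a community turn
    levodopa into m-tyramine.
    """
    a = make_strain(StrainSpec(species="Levoa prima", substrates=("glc_D",),
                               drug_enzymes=("dopa_decarboxylase",)))
    b = make_strain(StrainSpec(species="Levob secunda", substrates=("glc_D",),
                               drug_enzymes=("dopamine_dehydroxylase",)))
    return a, b


def toy_futile() -> StoichiometricModel:
    """Glucose strain with a planted uncosted ATP-generating cycle."""
    return make_strain(StrainSpec(species="Futilis demo",
                                  substrates=("glc_D",),
                                  defects=("futile_cycle",)))


def toy_glycolysis() -> StoichiometricModel:
    """Clean glucose strain: 1 ATP per glucose through CAT_glc_D."""
    return make_strain(StrainSpec(species="Glycolytica demo",
                                  substrates=("glc_D",), products=("pyr",)))


# ---------------------------------------------------------------------------
# diets


def western_diet() -> DietProfile:
    """Carbon/nitrogen/phosphate-limited reference diet (anaerobic)."""
    return DietProfile(name="WD", uptakes={
        "EX_glc_D": 10.0, "EX_nh4": 10.0, "EX_pi": 10.0, "EX_h2o": 1000.0})


def rich_diet() -> DietProfile:
    """Strict superset of the Western diet (extra carbon sources)."""
    base = western_diet()
    uptakes = dict(base.uptakes)
    uptakes.update({"EX_fru": 10.0, "EX_rib": 10.0, "EX_ac": 10.0})
    return DietProfile(name="rich", uptakes=uptakes)


def unlimited_medium(model: StoichiometricModel) -> DietProfile:
    """Every exchange of the model opened at 1000 (aerobic)."""
    return DietProfile(name="UM", uptakes={
        r.id: DEFAULT_BOUND for r in model.exchanges}, aerobic=True)


def complex_medium(model: StoichiometricModel) -> DietProfile:
    """All exchanges at 10 (water unlimited); oxygen left to the caller."""
    uptakes = {r.id: 10.0 for r in model.exchanges}
    for rid in ("EX_h2o", "EX_h2o[d]"):
        if rid in uptakes:
            uptakes[rid] = 1000.0
    return DietProfile(name="complex", uptakes=uptakes)


# ---------------------------------------------------------------------------
# cohorts


def default_species_pool() -> tuple[StrainSpec, ...]:
    return (
        StrainSpec(species="Lactis planta", substrates=("glc_D",),
                   products=("lac_L",)),
        StrainSpec(species="Acetix planta", substrates=("glc_D",),
                   products=("ac",)),
        StrainSpec(species="Ethana planta", substrates=("glc_D", "fru"),
                   products=("etoh",)),
        StrainSpec(species="Neutra commensalis", substrates=("glc_D",)),
        StrainSpec(species="Ribosa commensalis", substrates=("rib",)),
        StrainSpec(species="Fructia commensalis", substrates=("fru",)),
    )


DEFAULT_PLANTED_EFFECTS = {
    ("Lactis planta", "lac_L"): 2.0,
    ("Acetix planta", "ac"): 2.0,
    ("Ethana planta", "etoh"): 2.0,
}


@dataclass
class CohortSpec:
    """Recipe for a synthetic cohort with planted ground truth."""

    n_samples: int = 20
    species: tuple[StrainSpec, ...] = field(
        default_factory=default_species_pool)
    prevalence: dict[str, float] | float = 0.5
    lognormal_mu: float = 0.0
    lognormal_sigma: float = 1.0
    planted_effects: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_PLANTED_EFFECTS))
    baseline_concentration: float = 10.0
    noise_sd: float = 1.0
    detection_limit: float = 0.05
    null_metabolites: tuple[str, ...] = ("gaba", "met_L")
    seed: int = 0

    def prevalence_of(self, species: str) -> float:
        if isinstance(self.prevalence, dict):
            return self.prevalence.get(species, 0.5)
        return float(self.prevalence)


@dataclass
class Cohort:
    models: dict[str, StoichiometricModel]
    abundances: AbundanceTable
    metadata: pd.DataFrame  # sample, age, sex, BMI, group
    concentrations: pd.DataFrame  # samples x metabolites
    ledger: dict


def make_cohort(spec: CohortSpec) -> Cohort:
    """Sample a cohort: presence, abundances, covariates, fecal metabolome.

    Fecal concentrations are baseline + sum(planted effect x presence) +
    Gaussian noise, censored at the detection limit. The ledger records
    every planted effect so recovery can be scored exactly.
    """
    rng = np.random.default_rng(spec.seed)
    species_names = [s.species for s in spec.species]
    models = {s.species: make_strain(s) for s in spec.species}
    prev = np.array([spec.prevalence_of(sp) for sp in species_names])

    presence = rng.random((spec.n_samples, len(species_names))) < prev
    anchor = int(np.argmax(prev))
    presence[~presence.any(axis=1), anchor] = True  # no empty microbiomes

    raw = np.exp(rng.normal(spec.lognormal_mu, spec.lognormal_sigma,
                            presence.shape)) * presence
    values = raw / raw.sum(axis=1, keepdims=True)
    samples = [f"S{i:04d}" for i in range(spec.n_samples)]
    abundances = AbundanceTable(values=pd.DataFrame(
        values, index=samples, columns=species_names))

    metadata = pd.DataFrame({
        "sample": samples,
        "age": np.clip(rng.normal(55, 10, spec.n_samples), 20, 90),
        "sex": rng.integers(0, 2, spec.n_samples),
        "BMI": np.clip(rng.normal(23, 3, spec.n_samples), 15, 40),
        "group": rng.integers(0, 2, spec.n_samples),
    }).set_index("sample")

    mets = sorted({m for _, m in spec.planted_effects}
                  | set(spec.null_metabolites))
    conc = pd.DataFrame(
        spec.baseline_concentration
        + rng.normal(0, spec.noise_sd, (spec.n_samples, len(mets))),
        index=samples, columns=mets)
    for (sp, met), effect in spec.planted_effects.items():
        conc[met] += effect * presence[:, species_names.index(sp)]
    conc = conc.clip(lower=spec.detection_limit)

    ledger = {
        "seed": spec.seed,
        "planted_effects": {f"{sp}::{met}": eff
                            for (sp, met), eff in
                            spec.planted_effects.items()},
        "prevalence": dict(zip(species_names, prev.tolist())),
        "detection_limit": spec.detection_limit,
    }
    return Cohort(models=models, abundances=abundances, metadata=metadata,
                  concentrations=conc, ledger=ledger)


# ---------------------------------------------------------------------------
# trait datasets


DEFAULT_TRAIT_TARGETS = ("glc_D", "fru", "rib", "ac", "lac_L", "pyr",
                         "etoh", "h2")


def make_trait_dataset(models: dict[str, StoichiometricModel],
                       flip_rate: float, seed: int = 0,
                       targets=DEFAULT_TRAIT_TARGETS,
                       kinds=("uptake", "secretion")):
    """Trait dataset derived from the models' own computed capabilities.

    Ground-truth signs come from FBA-based prediction on unlimited medium;
    a seeded Bernoulli(flip_rate) fraction of signs is then inverted. The
    returned ledger lists every flipped record, so flips partition exactly
    into the false positives/negatives they must create.
    """
    from .validation_harness import (
        NEGATIVE,
        POSITIVE,
        TraitRecord,
        predict_trait,
        record_label,
    )

    if not 0 <= flip_rate <= 1:
        raise ValidationError("flip_rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    records: list[TraitRecord] = []
    flipped: list[str] = []
    for organism in sorted(models):
        model = models[organism]
        for kind in kinds:
            for target in targets:
                truth = predict_trait(model, TraitRecord(
                    organism=organism, resolution="species", kind=kind,
                    target=target, sign=POSITIVE))
                sign = truth
                if rng.random() < flip_rate:
                    sign = NEGATIVE if truth == POSITIVE else POSITIVE
                record = TraitRecord(organism=organism, resolution="species",
                                     kind=kind, target=target, sign=sign)
                records.append(record)
                if sign != truth:
                    flipped.append(record_label(record))
    return records, {"flip_rate": flip_rate, "seed": seed,
                     "flipped": flipped}
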