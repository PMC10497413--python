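"""Drug metabolism simulation.

Strain-level drug yields, community-level conversion potentials, net fecal
secretion, diet sensitivity and shadow-price bottleneck species. The
simulation protocol for conversion potentials follows the community
convention: the respective precursor drug and oxygen are supplied at a de
facto unlimited uptake rate of 1000 mmol/gDW/h on top of the diet, and the
fecal secretion of the drug's metabolic end product is maximised by FBA.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import lp_engine
from .community_builder import (
    CommunityModel,
    apply_diet_to_community,
    diet_exchange_id,
    fecal_exchange_id,
)
from .model_core import (
    DEFAULT_BOUND,
    DietProfile,
    StoichiometricModel,
    ValidationError,
    add_demand,
    apply_diet,
    met_key,
)

logger = logging.getLogger(__name__)

#: qualitative capability threshold, mmol/person/day
EPS_CAPABILITY = 1e-6


# ---------------------------------------------------------------------------
# drug modules


@dataclass
class DrugModule:
    """One drug-metabolizing enzyme and the reactions it brings along.

    ``reactions`` maps reaction ids to dicts with ``stoichiometry`` (keyed
    by ``met[comp]``), optional bounds and an optional ``kind``;
    ``metabolites`` declares formulas for any metabolite the module
    introduces. ``enzyme_reactions`` names the enzymatic reaction(s) proper
    (as opposed to accompanying transports/exchanges); their presence and
    flux capability define whether a model "carries" the enzyme.
    """

    id: str
    name: str = ""
    genes: list[str] = field(default_factory=list)
    metabolites: dict[str, dict] = field(default_factory=dict)
    reactions: dict[str, dict] = field(default_factory=dict)
    enzyme_reactions: list[str] = field(default_factory=list)
    precursor: str = ""
    products: list[str] = field(default_factory=list)
    location: str = "cytosol"

    def __post_init__(self) -> None:
        if self.location not in ("cytosol", "extracellular"):
            raise ValidationError(
                f"drug module {self.id}: unknown location {self.location!r}")
        mentioned = set()
        for rid in self.enzyme_reactions:
            if rid not in self.reactions:
                raise ValidationError(
                    f"drug module {self.id}: enzyme reaction {rid} undefined")
            for key in self.reactions[rid]["stoichiometry"]:
                mentioned.add(key.split("[")[0])
        for met in [self.precursor, *self.products]:
            if met and met not in mentioned:
                raise ValidationError(
                    f"drug module {self.id}: {met} does not appear in the "
                    f"enzymatic reactions")

    @property
    def product(self) -> str:
        """The primary metabolic end product."""
        return self.products[0]


def load_drug_modules(path) -> dict[str, DrugModule]:
    with open(path) as fh:
        data = json.load(fh)
    modules = {}
    for entry in data["modules"] if isinstance(data, dict) else data:
        module = DrugModule(**entry)
        modules[module.id] = module
    return modules


def save_drug_modules(modules: dict[str, DrugModule], path) -> None:
    from dataclasses import asdict

    with open(path, "w") as fh:
        json.dump({"modules": [asdict(m) for m in modules.values()]}, fh,
                  indent=1)
        fh.write("\n")


# ---------------------------------------------------------------------------
# community-level simulation


def _open_precursor_and_oxygen(community: CommunityModel, drug: DrugModule,
                               diet: DietProfile, aerobic: bool,
                               supply: float):
    """Diet-constrained community with precursor (and oxygen) opened."""
    constrained = apply_diet_to_community(community, diet)
    model = constrained.model
    prec_ex = diet_exchange_id(drug.precursor)
    if prec_ex not in model.reactions:
        return None, None
    model.reactions[prec_ex].lower_bound = -supply
    if aerobic:
        o2 = diet_exchange_id("o2")
        if o2 in model.reactions:
            model.reactions[o2].lower_bound = -DEFAULT_BOUND
    return constrained, model


def conversion_potential(community: CommunityModel, drug: DrugModule,
                         diet: DietProfile, product: str | None = None,
                         aerobic: bool = True,
                         supply: float = DEFAULT_BOUND) -> float:
    """Maximal fecal secretion flux of a drug's end product.

    Returns 0 when no member carries the precursor or the product (the
    community has "no carrier" for the drug) or when the community is not
    viable under the diet.
    """
    product = product or drug.product
    constrained, model = _open_precursor_and_oxygen(
        community, drug, diet, aerobic, supply)
    if model is None:
        logger.debug("community %s: no carrier for precursor %s",
                    community.sample_id, drug.precursor)
        return 0.0
    prod_ex = fecal_exchange_id(product)
    if prod_ex not in model.reactions:
        logger.debug("community %s: product %s not secretable",
                    community.sample_id, product)
        return 0.0
    sol = lp_engine.optimize(model, prod_ex, "max")
    if not sol.ok:
        return 0.0
    return max(0.0, sol.objective_value)


@dataclass
class ConversionPanel:
    """Samples x drug-products matrix of maximal fecal secretion fluxes."""

    fluxes: pd.DataFrame  # index = samples, columns = products
    eps: float = EPS_CAPABILITY

    @property
    def capability(self) -> pd.DataFrame:
        return self.fluxes > self.eps

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "mean": self.fluxes.mean(axis=0),
            "sd": self.fluxes.std(axis=0, ddof=1),
            "fraction_capable": self.capability.mean(axis=0),
        })


def conversion_panel(communities: dict[str, CommunityModel],
                     drugs: dict[str, DrugModule],
                     diet: DietProfile, aerobic: bool = True,
                     eps: float = EPS_CAPABILITY) -> ConversionPanel:
    """Conversion potential of every community for every drug product."""
    records = {}
    for sample_id, community in communities.items():
        row = {}
        for drug in drugs.values():
            for product in drug.products:
                row[product] = conversion_potential(
                    community, drug, diet, product=product, aerobic=aerobic)
        records[sample_id] = row
    fluxes = pd.DataFrame.from_dict(records, orient="index").sort_index()
    return ConversionPanel(fluxes=fluxes, eps=eps)


def bottleneck_species(community: CommunityModel, drug: DrugModule,
                       diet: DietProfile, product: str | None = None,
                       aerobic: bool = True, tol: float = 1e-6
                       ) -> list[tuple[str, float]]:
    """Species whose biomass limits the drug conversion optimum.

    Returns (species, shadow price of the species biomass metabolite) for
    every member whose |shadow price| exceeds ``tol``, sorted by magnitude.
    A nonzero price means the conversion optimum responds to that species'
    biomass availability — the species is a bottleneck.
    """
    product = product or drug.product
    constrained, model = _open_precursor_and_oxygen(
        community, drug, diet, aerobic, DEFAULT_BOUND)
    if model is None:
        return []
    prod_ex = fecal_exchange_id(product)
    if prod_ex not in model.reactions:
        return []
    base = lp_engine.optimize(model, prod_ex, "max")
    if not base.ok:
        return []
    out = []
    for species, member in community.members.items():
        sp = lp_engine.shadow_price(model, prod_ex, "max",
                                    member.biomass_metabolite)
        if abs(sp.value) > tol:
            out.append((species, float(sp.value)))
    out.sort(key=lambda pair: -abs(pair[1]))
    return out


def net_secretion(community: CommunityModel, metabolite_ids,
                  diet: DietProfile, aerobic: bool | None = None
                  ) -> dict[str, float]:
    """Maximal net fecal secretion of each metabolite under the diet."""
    constrained = apply_diet_to_community(community, diet, aerobic=aerobic)
    problem = lp_engine.LinearProblem(constrained.model)
    out = {}
    for mid in metabolite_ids:
        rid = fecal_exchange_id(mid)
        if rid not in constrained.model.reactions:
            out[mid] = 0.0
            continue
        sol = problem.optimize(rid, "max")
        out[mid] = max(0.0, sol.objective_value) if sol.ok else 0.0
    return out


def diet_sensitivity(panel_a: ConversionPanel, panel_b: ConversionPanel
                     ) -> pd.Series:
    """Per-drug Pearson correlation between two conversion panels.

    Columns that are constant in either panel have an undefined correlation
    and are reported as NaN.
    """
    a, b = panel_a.fluxes, panel_b.fluxes
    if list(a.index) != list(b.index) or set(a.columns) != set(b.columns):
        raise ValidationError("panels must share samples and drug products")
    out = {}
    for col in a.columns:
        x, y = a[col].to_numpy(float), b[col].to_numpy(float)
        if np.std(x) == 0 or np.std(y) == 0:
            out[col] = np.nan
        else:
            out[col] = float(np.corrcoef(x, y)[0, 1])
    return pd.Series(out, name="pearson_r")


# ---------------------------------------------------------------------------
# strain-level drug yields


def drug_yield(model: StoichiometricModel, drug_exchange: str,
               currency: str = "atp", control: str | None = None,
               uptake: float = 1.0, aerobic: bool = True) -> float:
    """Yield of a currency metabolite from 1 mmol of drug per gDW per h.

    The model is constrained to only allow the uptake of water, phosphate
    and oxygen; the drug (or, for ``control='glucose'``, glucose) is then
    supplied at ``uptake``; ``control='none'`` supplies no substrate at all.
    The demand for the currency metabolite (atp | nh4 | co2 | pyr) is
    maximised; the flux per mmol of substrate is returned.
    """
    base = DietProfile(
        name="mineral",
        uptakes={"EX_h2o": DEFAULT_BOUND, "EX_pi": DEFAULT_BOUND},
        aerobic=aerobic)
    constrained = apply_diet(model, base)
    if control == "glucose":
        sub_ex = "EX_glc_D"
    elif control == "none":
        sub_ex = None
    else:
        sub_ex = drug_exchange
    if sub_ex is not None:
        if sub_ex not in constrained.reactions:
            return 0.0
        constrained.reactions[sub_ex].lower_bound = -abs(uptake)
    if currency == "atp":
        from .quality import ensure_atp_demand

        demand = ensure_atp_demand(constrained)
        if demand is None:
            return 0.0
    else:
        key = met_key(currency, "c")
        if key not in constrained.metabolites:
            logger.info("model %s: currency %s absent", model.id, currency)
            return 0.0
        demand = add_demand(constrained, currency, "c")
    sol = lp_engine.optimize(constrained, demand, "max")
    if not sol.ok:
        return 0.0
    return max(0.0, sol.objective_value) / abs(uptake)
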