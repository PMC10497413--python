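"""Pan-species models and personalized, abundance-weighted community models.

A community model places every member species' reactions (id-prefixed) next
to a shared lumen compartment ``[u]``, a diet compartment ``[d]`` and a fecal
compartment ``[fe]``. Metabolites enter through diet exchanges ``EX_<met>[d]``
and diet transports ``DUt_<met>`` and leave through fecal transports
``UFEt_<met>`` and fecal exchanges ``EX_<met>[fe]``. Each member reaction j is
coupled to its species' biomass reaction, ``|v_j| <= u_cpl * v_biomass``, so
that no species can sustain flux without growing. The community biomass
reaction consumes abundance-weighted species biomass metabolites
(``<species>_biomass[c]``) and produces ``microbeBiomass[u]``; its flux is
bounded (default [0.4, 1.0] per day), which anchors community fluxes on a
per-day scale.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import pandas as pd

from .model_core import (
    DEFAULT_BOUND,
    DietProfile,
    Metabolite,
    Reaction,
    StoichiometricModel,
    ValidationError,
    apply_diet,
    met_key,
)

logger = logging.getLogger(__name__)

#: default coupling factor (mgPipe convention)
DEFAULT_COUPLING_FACTOR = 400.0
#: default community biomass flux bounds, per day
DEFAULT_BIOMASS_BOUNDS = (0.4, 1.0)

LUMEN, DIET, FECAL = "u", "d", "fe"


def diet_exchange_id(met_id: str) -> str:
    return f"EX_{met_id}[{DIET}]"


def fecal_exchange_id(met_id: str) -> str:
    return f"EX_{met_id}[{FECAL}]"


# ---------------------------------------------------------------------------
# abundances


@dataclass
class AbundanceTable:
    """Relative abundances, samples x species (a thin DataFrame wrapper)."""

    values: pd.DataFrame  # index = samples, columns = species

    def __post_init__(self) -> None:
        if (self.values.values < 0).any():
            raise ValidationError("abundances must be non-negative")
        sums = self.values.sum(axis=1)
        if ((sums <= 0) | (sums > 1 + 1e-6)).any():
            bad = sums[(sums <= 0) | (sums > 1 + 1e-6)].index.tolist()
            raise ValidationError(
                f"per-sample abundance sums outside (0, 1]: {bad}")

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)

    @property
    def species(self) -> list[str]:
        return list(self.values.columns)

    def sample(self, sample_id: str) -> dict[str, float]:
        """Nonzero species abundances of one sample."""
        row = self.values.loc[sample_id]
        return {sp: float(a) for sp, a in row.items() if a > 0}

    def prevalence(self) -> pd.Series:
        """Fraction of samples in which each species is present (>0)."""
        return (self.values > 0).mean(axis=0)

    @classmethod
    def from_tsv(cls, path) -> "AbundanceTable":
        # on disk: rows = species, columns = samples
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(values=df.T)

    def to_tsv(self, path) -> None:
        self.values.T.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# pan-species models


def build_pan_model(strain_models, species: str | None = None
                    ) -> StoichiometricModel:
    """Union of strain reconstructions with one representative biomass.

    Reaction set is the union over strains (bounds widened to the per-id
    union interval, GPRs of shared reactions joined by OR); the biomass of
    the strain with the most reactions (ties broken by lexicographically
    first model id) is adopted and renamed ``biomassPan``.
    """
    strains = list(strain_models)
    if not strains:
        raise ValidationError("build_pan_model needs at least one strain")
    species = species or strains[0].taxonomy.get("species", strains[0].id)
    donor = sorted(strains, key=lambda m: (-len(m.reactions), m.id))[0]
    pan_id = "pan" + re.sub(r"\W+", "_", species)
    pan = StoichiometricModel(id=pan_id, taxonomy={"species": species})
    conflicts = []
    biomass_ids = {m.objective_reaction for m in strains
                   if m.objective_reaction}
    for strain in strains:
        for key, met in strain.metabolites.items():
            if key not in pan.metabolites:
                pan.add_metabolite(
                    Metabolite(id=met.id, compartment=met.compartment,
                               name=met.name,
                               formula=dict(met.formula)
                               if met.formula is not None else None,
                               charge=met.charge))
        for rid, rxn in strain.reactions.items():
            if rid in biomass_ids:
                continue  # biomass handled separately
            if rid not in pan.reactions:
                pan.add_reaction(rxn.copy())
                continue
            existing = pan.reactions[rid]
            if existing.stoichiometry != rxn.stoichiometry:
                conflicts.append(rid)
                continue
            existing.lower_bound = min(existing.lower_bound, rxn.lower_bound)
            existing.upper_bound = max(existing.upper_bound, rxn.upper_bound)
            if rxn.gpr and rxn.gpr != existing.gpr:
                if existing.gpr:
                    existing.gpr = f"({existing.gpr}) or ({rxn.gpr})"
                else:
                    existing.gpr = rxn.gpr
        pan.genes |= strain.genes
    if conflicts:
        raise ValidationError(
            f"conflicting reaction definitions across strains: "
            f"{sorted(set(conflicts))}")
    if donor.objective_reaction is None:
        raise ValidationError(f"strain {donor.id} has no biomass objective")
    biomass = donor.reactions[donor.objective_reaction].copy()
    biomass.id = "biomassPan"
    pan.reactions["biomassPan"] = biomass
    pan.objective_reaction = "biomassPan"
    pan.validate()
    return pan


# ---------------------------------------------------------------------------
# taxon mapping


def _normalize_name(name: str) -> str:
    return re.sub(r"[\s_\-]+", "_", name.strip().lower())


def map_taxa(sample_species, registry) -> tuple[dict[str, str], float]:
    """Map sample species names onto a model registry.

    Exact-name matching first, then normalized (case / separator
    insensitive). Returns (mapping, coverage); unmapped names are simply
    absent from the mapping.
    """
    names = list(sample_species)
    if not names:
        raise ValidationError("empty species list: coverage undefined")
    keys = list(registry)
    normalized = {_normalize_name(k): k for k in keys}
    mapping: dict[str, str] = {}
    for name in names:
        if name in registry:
            mapping[name] = name
        elif _normalize_name(name) in normalized:
            mapping[name] = normalized[_normalize_name(name)]
    return mapping, len(mapping) / len(names)


# ---------------------------------------------------------------------------
# community assembly


@dataclass
class CommunityMember:
    species: str
    abundance: float  # normalized, sums to 1 across members
    prefix: str
    biomass_reaction: str  # prefixed reaction id
    biomass_metabolite: str  # prefixed metabolite key, e.g. "Ecoli_biomass[c]"


@dataclass
class CommunityModel:
    """A personalized community model plus its member bookkeeping."""

    sample_id: str
    model: StoichiometricModel
    members: dict[str, CommunityMember] = field(default_factory=dict)
    coupling_factor: float = DEFAULT_COUPLING_FACTOR
    biomass_bounds: tuple[float, float] = DEFAULT_BIOMASS_BOUNDS

    @property
    def abundances(self) -> dict[str, float]:
        return {sp: m.abundance for sp, m in self.members.items()}


def _species_prefix(species: str) -> str:
    return re.sub(r"\W+", "_", species.strip())


def _biomass_metabolite_key(model: StoichiometricModel) -> str:
    """The biomass metabolite produced by the model's objective reaction."""
    if model.objective_reaction is None:
        raise ValidationError(f"model {model.id} has no biomass objective")
    rxn = model.reactions[model.objective_reaction]
    products = [k for k, v in rxn.stoichiometry.items() if v > 0]
    for key in products:
        if "biomass" in key.lower():
            return key
    if len(products) == 1:
        return products[0]
    raise ValidationError(
        f"cannot identify biomass metabolite of {model.id} "
        f"(objective {model.objective_reaction})")


def assemble_community(models: dict[str, StoichiometricModel],
                       abundances: dict[str, float],
                       coupling_factor: float = DEFAULT_COUPLING_FACTOR,
                       biomass_bounds: tuple[float, float] =
                       DEFAULT_BIOMASS_BOUNDS,
                       abundance_cutoff: float = 0.0,
                       sample_id: str = "community") -> CommunityModel:
    """Assemble an abundance-weighted community model.

    Every species with abundance above ``abundance_cutoff`` is included;
    abundances are renormalized to sum to one. Member extracellular
    metabolites are rewired to the shared lumen; member exchanges are
    replaced by the diet/fecal transport layer.
    """
    kept = {sp: a for sp, a in abundances.items() if a > abundance_cutoff}
    if not kept:
        raise ValidationError("zero total abundance: no community members")
    missing = [sp for sp in kept if sp not in models]
    if missing:
        raise ValidationError(f"species without a model: {missing}")
    if any(a <= 0 for a in kept.values()):
        raise ValidationError("member abundances must be positive")
    total = sum(kept.values())
    norm = {sp: a / total for sp, a in kept.items()}

    cm = StoichiometricModel(id=f"community_{sample_id}")
    members: dict[str, CommunityMember] = {}
    couplings: list[tuple[str, str, float]] = []
    lumen_mets: set[str] = set()

    def ensure_lumen(met: Metabolite) -> str:
        key = met_key(met.id, LUMEN)
        if key not in cm.metabolites:
            cm.add_metabolite(Metabolite(
                id=met.id, compartment=LUMEN, name=met.name,
                formula=dict(met.formula) if met.formula is not None
                else None, charge=met.charge))
            lumen_mets.add(met.id)
        return key

    for species in sorted(norm):
        member_model = models[species]
        prefix = _species_prefix(species)
        bio_rid = member_model.objective_reaction
        if bio_rid is None:
            raise ValidationError(f"member {species} has no biomass objective")
        bio_met = _biomass_metabolite_key(member_model)

        remap: dict[str, str] = {}
        for key, met in member_model.metabolites.items():
            if met.compartment == "e":
                remap[key] = ensure_lumen(met)
            else:
                new_id = f"{prefix}_{met.id}"
                new_key = met_key(new_id, met.compartment)
                if new_key not in cm.metabolites:
                    cm.add_metabolite(Metabolite(
                        id=new_id, compartment=met.compartment, name=met.name,
                        formula=dict(met.formula) if met.formula is not None
                        else None, charge=met.charge))
                remap[key] = new_key

        for rid, rxn in member_model.reactions.items():
            if rxn.kind == "exchange":
                continue  # replaced by the diet/fecal layer
            if rxn.kind in ("demand", "sink") \
                    and bio_met in rxn.stoichiometry:
                continue  # biomass flows only into the community biomass
            new_rid = f"{prefix}_{rid}"
            cm.add_reaction(Reaction(
                id=new_rid,
                stoichiometry={remap[k]: v
                               for k, v in rxn.stoichiometry.items()},
                lower_bound=rxn.lower_bound, upper_bound=rxn.upper_bound,
                gpr=rxn.gpr, subsystem=rxn.subsystem, kind=rxn.kind))
            if rid != bio_rid:
                couplings.append((new_rid, f"{prefix}_{bio_rid}",
                                  coupling_factor))
        cm.genes |= {f"{prefix}_{g}" for g in member_model.genes}
        members[species] = CommunityMember(
            species=species, abundance=norm[species], prefix=prefix,
            biomass_reaction=f"{prefix}_{bio_rid}",
            biomass_metabolite=remap[bio_met])

    # diet / fecal transport layer for every lumen metabolite
    for mid in sorted(lumen_mets):
        lumen = met_key(mid, LUMEN)
        met = cm.metabolites[lumen]
        for comp in (DIET, FECAL):
            cm.add_metabolite(Metabolite(
                id=mid, compartment=comp, name=met.name,
                formula=dict(met.formula) if met.formula is not None
                else None, charge=met.charge))
        cm.add_reaction(Reaction(
            id=f"DUt_{mid}",
            stoichiometry={met_key(mid, DIET): -1.0, lumen: 1.0},
            lower_bound=0.0, upper_bound=DEFAULT_BOUND, kind="transport"))
        cm.add_reaction(Reaction(
            id=f"UFEt_{mid}",
            stoichiometry={lumen: -1.0, met_key(mid, FECAL): 1.0},
            lower_bound=0.0, upper_bound=DEFAULT_BOUND, kind="transport"))
        cm.add_reaction(Reaction(
            id=diet_exchange_id(mid),
            stoichiometry={met_key(mid, DIET): -1.0},
            lower_bound=-DEFAULT_BOUND, upper_bound=DEFAULT_BOUND,
            kind="exchange"))
        cm.add_reaction(Reaction(
            id=fecal_exchange_id(mid),
            stoichiometry={met_key(mid, FECAL): -1.0},
            lower_bound=0.0, upper_bound=DEFAULT_BOUND, kind="exchange"))

    # community biomass: abundance-weighted species biomass -> microbeBiomass
    cm.add_metabolite(Metabolite(id="microbeBiomass", compartment=LUMEN,
                                 name="community biomass proxy"))
    stoich = {m.biomass_metabolite: -m.abundance for m in members.values()}
    stoich[met_key("microbeBiomass", LUMEN)] = 1.0
    cm.add_reaction(Reaction(
        id="communityBiomass", stoichiometry=stoich,
        lower_bound=biomass_bounds[0], upper_bound=biomass_bounds[1],
        kind="internal"))
    cm.add_metabolite(Metabolite(id="microbeBiomass", compartment=FECAL,
                                 name="community biomass proxy"))
    cm.add_reaction(Reaction(
        id="UFEt_microbeBiomass",
        stoichiometry={met_key("microbeBiomass", LUMEN): -1.0,
                       met_key("microbeBiomass", FECAL): 1.0},
        lower_bound=0.0, upper_bound=DEFAULT_BOUND, kind="transport"))
    cm.add_reaction(Reaction(
        id=fecal_exchange_id("microbeBiomass"),
        stoichiometry={met_key("microbeBiomass", FECAL): -1.0},
        lower_bound=0.0, upper_bound=DEFAULT_BOUND, kind="exchange"))

    cm.objective_reaction = "communityBiomass"
    cm.couplings = couplings
    cm.validate()
    return CommunityModel(sample_id=sample_id, model=cm, members=members,
                          coupling_factor=coupling_factor,
                          biomass_bounds=tuple(biomass_bounds))


def apply_diet_to_community(community: CommunityModel, diet: DietProfile,
                            aerobic: bool | None = None) -> CommunityModel:
    """Apply a diet to a community's ``[d]`` exchanges (new copy).

    Exchange ids from strain-level diet files (``EX_glc_D``) are translated
    to their diet-compartment counterparts (``EX_glc_D[d]``).
    """
    translated = {}
    for rid, mag in diet.uptakes.items():
        if rid in community.model.reactions:
            translated[rid] = mag
        else:
            candidate = f"{rid}[{DIET}]"
            translated[candidate] = mag
    tdiet = DietProfile(name=diet.name, uptakes=translated,
                        aerobic=diet.aerobic)
    model = apply_diet(community.model, tdiet, aerobic=aerobic)
    return CommunityModel(sample_id=community.sample_id, model=model,
                          members=dict(community.members),
                          coupling_factor=community.coupling_factor,
                          biomass_bounds=community.biomass_bounds)
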