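"""End-to-end orchestration: simulate -> qc -> community -> drugsim ->
validate -> concordance, with a hashed artifact manifest for idempotent
reruns.

This module also hosts the end-to-end cohort analyses that tie the other
modules together: per-sample community assembly, community net secretion of
planted metabolites, and in-vivo vs in-silico sign concordance.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import association_stats as stats
from . import drug_sim, quality, validation_harness
from .community_builder import CommunityModel, assemble_community
from .model_core import save_diet, save_model
from .synthetic_data import (
    Cohort,
    CohortSpec,
    complex_medium,
    make_cohort,
    make_trait_dataset,
    rich_diet,
    standard_drug_modules,
    unlimited_medium,
    western_diet,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# cohort-level analyses


def build_sample_communities(cohort: Cohort, coupling_factor: float = 400.0,
                             biomass_bounds=(0.4, 1.0)
                             ) -> dict[str, CommunityModel]:
    """One personalized community model per cohort sample (nonzero members)."""
    out = {}
    for sample in cohort.abundances.samples:
        abund = cohort.abundances.sample(sample)
        out[sample] = assemble_community(
            cohort.models, abund, coupling_factor=coupling_factor,
            biomass_bounds=biomass_bounds, sample_id=sample)
    return out


def cohort_net_secretion(cohort: Cohort, metabolites, diet=None,
                         communities: dict[str, CommunityModel] | None = None
                         ) -> pd.DataFrame:
    """Samples x metabolites maximal community net fecal secretion."""
    diet = diet or western_diet()
    communities = communities or build_sample_communities(cohort)
    rows = {}
    for sample, community in communities.items():
        rows[sample] = drug_sim.net_secretion(community, metabolites, diet)
    return pd.DataFrame.from_dict(rows, orient="index").loc[
        cohort.abundances.samples]


def cohort_associations(cohort: Cohort, responses: pd.DataFrame, side: str,
                        lo: float = 0.1, hi: float = 0.9
                        ) -> list[stats.AssociationResult]:
    """Presence-effect OLS for every filtered species x response column."""
    covariates = cohort.metadata[["age", "sex", "BMI", "group"]]
    species = stats.presence_filter(cohort.abundances, lo, hi)
    presence = (cohort.abundances.values > 0).astype(float)
    results = []
    for sp in species:
        for met in responses.columns:
            results.append(stats.fit_presence_effect(
                responses[met].to_numpy(), presence[sp].to_numpy(),
                covariates=covariates, species=sp, metabolite=met,
                side=side))
    return results


def cohort_sign_concordance(cohort: Cohort, metabolites=None,
                            alpha: float = 0.05, diet=None,
                            min_detect_fraction: float = 0.5
                            ) -> pd.DataFrame:
    """End-to-end in-vivo vs in-silico sign concordance for a cohort."""
    detect = stats.metabolite_inclusion(
        cohort.concentrations, cohort.ledger["detection_limit"],
        min_detect_fraction)
    metabolites = [m for m in (metabolites or detect) if m in detect]
    in_vivo = cohort_associations(
        cohort, cohort.concentrations[metabolites], side="in_vivo")
    secretion = cohort_net_secretion(cohort, metabolites, diet=diet)
    in_silico = cohort_associations(cohort, secretion, side="in_silico")
    return stats.sign_concordance(in_vivo, in_silico, alpha=alpha)


def planted_effect_recovery(cohort: Cohort, alpha: float = 0.05,
                            diet=None) -> float:
    """Fraction of planted species->metabolite effects recovered end to end.

    A planted effect counts as recovered when the in-vivo OLS detects it
    (p < alpha) with the planted sign AND the in-silico (community net
    secretion) effect carries the same sign.
    """
    pairs = [(key.split("::")[0], key.split("::")[1], eff)
             for key, eff in cohort.ledger["planted_effects"].items()]
    mets = sorted({met for _, met, _ in pairs})
    in_vivo = {(r.species, r.metabolite): r for r in cohort_associations(
        cohort, cohort.concentrations[mets], side="in_vivo")}
    secretion = cohort_net_secretion(cohort, mets, diet=diet)
    in_silico = {(r.species, r.metabolite): r for r in cohort_associations(
        cohort, secretion, side="in_silico")}
    hits = 0
    for sp, met, eff in pairs:
        vivo = in_vivo.get((sp, met))
        silico = in_silico.get((sp, met))
        if vivo is None or silico is None:
            continue
        if (vivo.p_value < alpha
                and np.sign(vivo.effect) == np.sign(eff)
                and np.sign(silico.effect) == np.sign(eff)):
            hits += 1
    return hits / len(pairs) if pairs else float("nan")


# ---------------------------------------------------------------------------
# pipeline with manifest


@dataclass
class RunConfig:
    out_dir: str
    seed: int = 0
    n_samples: int = 20
    coupling_factor: float = 400.0
    biomass_bounds: tuple[float, float] = (0.4, 1.0)
    eps: float = 1e-6
    atp_threshold: float = 500.0
    trait_flip_rate: float = 0.1
    alpha: float = 0.05

    def to_dict(self) -> dict:
        from dataclasses import asdict

        return asdict(self)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = json.load(fh)
        data["biomass_bounds"] = tuple(data.get("biomass_bounds", (0.4, 1.0)))
        return cls(**data)


def _hash_obj(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()


def _hash_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


class _Manifest:
    def __init__(self, path):
        self.path = path
        self.data = {}
        if os.path.exists(path):
            with open(path) as fh:
                self.data = json.load(fh)

    def up_to_date(self, stage: str, input_hash: str) -> bool:
        entry = self.data.get(stage)
        if not entry or entry["input_hash"] != input_hash:
            return False
        for out, digest in entry["outputs"].items():
            if not os.path.exists(out):
                return False
            if _hash_file(out) != digest:
                raise PipelineError(
                    f"stage {stage}: stale hash for output {out} "
                    f"(file was modified outside the pipeline)")
        return True

    def record(self, stage: str, input_hash: str, outputs) -> None:
        self.data[stage] = {
            "input_hash": input_hash,
            "outputs": {out: _hash_file(out) for out in outputs}}
        with open(self.path, "w") as fh:
            json.dump(self.data, fh, indent=1)


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages in dependency order; return the artifact manifest.

    Rerunning with the same config and intact outputs skips every stage.
    Any stage failure aborts with the stage name.
    """
    os.makedirs(config.out_dir, exist_ok=True)
    manifest = _Manifest(os.path.join(config.out_dir, "manifest.json"))
    config_hash = _hash_obj(config.to_dict())
    drugs = standard_drug_modules()

    spec = CohortSpec(n_samples=config.n_samples, seed=config.seed,
                      species=_demo_species_pool())
    cohort = make_cohort(spec)
    stages_run = []

    def stage(name, input_hash, builder):
        if manifest.up_to_date(name, input_hash):
            logger.info("stage %s up to date", name)
            return
        try:
            outputs = builder()
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage {name} failed: {exc}") from exc
        manifest.record(name, input_hash, outputs)
        stages_run.append(name)

    out = lambda *parts: os.path.join(config.out_dir, *parts)  # noqa: E731

    # 1 — simulate
    def simulate():
        os.makedirs(out("models"), exist_ok=True)
        outputs = []
        for species, model in cohort.models.items():
            path = out("models", f"{model.id}.json")
            save_model(model, path, dialect="json")
            outputs.append(path)
        cohort.abundances.to_tsv(out("abundances.tsv"))
        cohort.metadata.to_csv(out("metadata.tsv"), sep="\t")
        cohort.concentrations.to_csv(out("concentrations.tsv"), sep="\t")
        with open(out("ground_truth.json"), "w") as fh:
            json.dump(cohort.ledger, fh, indent=1)
        save_diet(western_diet(), out("diet_WD.tsv"))
        save_diet(rich_diet(), out("diet_rich.tsv"))
        drug_sim.save_drug_modules(drugs, out("drug_modules.json"))
        return outputs + [out("abundances.tsv"), out("metadata.tsv"),
                          out("concentrations.tsv"), out("ground_truth.json"),
                          out("diet_WD.tsv"), out("diet_rich.tsv"),
                          out("drug_modules.json")]

    stage("simulate", config_hash, simulate)

    # 2 — qc
    def qc():
        rows = []
        for species, model in cohort.models.items():
            diets = {"complex": complex_medium(model),
                     "WD": western_diet(), "UM": unlimited_medium(model)}
            report = quality.run_qc(model, diets,
                                    atp_threshold=config.atp_threshold)
            rows.append({"model": model.id,
                         "growth_complex_anaerobic":
                         report.anaerobic_growth_complex,
                         "growth_WD": report.growth_WD,
                         "growth_UM": report.growth_UM,
                         "atp_WD_aerobic": report.atp_WD_aerobic,
                         "atp_WD_anaerobic": report.atp_WD_anaerobic,
                         "futile": report.futile_aerobic
                         or report.futile_anaerobic,
                         "n_imbalanced": report.n_imbalanced_reactions,
                         "n_bad_gpr": report.n_bad_gpr,
                         "stoich_consistent":
                         report.stoich_consistent_fraction,
                         "flux_consistent": report.flux_consistent_fraction,
                         "passed": report.passed})
        pd.DataFrame(rows).to_csv(out("qc_summary.tsv"), sep="\t",
                                  index=False)
        return [out("qc_summary.tsv")]

    stage("qc", config_hash, qc)

    communities = build_sample_communities(
        cohort, coupling_factor=config.coupling_factor,
        biomass_bounds=config.biomass_bounds)

    # 3 — community
    def community():
        rows = [{"sample": s, "n_members": len(c.members),
                 "abundance_sum": sum(c.abundances.values())}
                for s, c in communities.items()]
        pd.DataFrame(rows).to_csv(out("communities.tsv"), sep="\t",
                                  index=False)
        first = next(iter(communities.values()))
        save_model(first.model, out("community_example.json"),
                   dialect="json")
        return [out("communities.tsv"), out("community_example.json")]

    stage("community", config_hash, community)

    # 4 — drugsim
    def drugsim():
        panel = drug_sim.conversion_panel(communities, drugs, western_diet())
        panel.fluxes.to_csv(out("conversion_panel.tsv"), sep="\t")
        panel.summary().to_csv(out("conversion_summary.tsv"), sep="\t")
        return [out("conversion_panel.tsv"), out("conversion_summary.tsv")]

    stage("drugsim", config_hash, drugsim)

    # 5 — validate
    def validate():
        records, ledger = make_trait_dataset(
            cohort.models, flip_rate=config.trait_flip_rate,
            seed=config.seed)
        validation_harness.save_traits(records, out("traits.tsv"))
        summary = validation_harness.evaluate(cohort.models, records)
        with open(out("validation_summary.json"), "w") as fh:
            json.dump(summary.to_dict() | {"n_flipped":
                                           len(ledger["flipped"])},
                      fh, indent=1)
        return [out("traits.tsv"), out("validation_summary.json")]

    stage("validate", config_hash, validate)

    # 6 — concordance
    def concordance():
        table = cohort_sign_concordance(cohort, alpha=config.alpha)
        table.to_csv(out("concordance.tsv"), sep="\t", index=False)
        return [out("concordance.tsv")]

    stage("concordance", config_hash, concordance)

    return {"stages_run": stages_run, "manifest": manifest.data,
            "out_dir": config.out_dir}


def load_cohort_dir(path) -> Cohort:
    """Load a cohort from a directory written by the simulate stage."""
    from .model_core import load_model

    models = {}
    models_dir = os.path.join(path, "models")
    for name in sorted(os.listdir(models_dir)):
        if name.endswith(".json"):
            model = load_model(os.path.join(models_dir, name), "json")
            models[model.taxonomy.get("species", model.id)] = model
    from .community_builder import AbundanceTable

    abundances = AbundanceTable.from_tsv(os.path.join(path,
                                                      "abundances.tsv"))
    metadata = pd.read_csv(os.path.join(path, "metadata.tsv"), sep="\t",
                           index_col=0)
    concentrations = pd.read_csv(os.path.join(path, "concentrations.tsv"),
                                 sep="\t", index_col=0)
    with open(os.path.join(path, "ground_truth.json")) as fh:
        ledger = json.load(fh)
    return Cohort(models=models, abundances=abundances, metadata=metadata,
                  concentrations=concentrations, ledger=ledger)


def _demo_species_pool():
    """Cohort species pool for the demo pipeline (drug carriers included)."""
    from .synthetic_data import StrainSpec

    return (
        StrainSpec(species="Lactis planta", substrates=("glc_D",),
                   products=("lac_L",)),
        StrainSpec(species="Acetix planta", substrates=("glc_D",),
                   products=("ac",), drug_enzymes=("azoreductase",)),
        StrainSpec(species="Ethana planta", substrates=("glc_D", "fru"),
                   products=("etoh",)),
        StrainSpec(species="Levoa prima", substrates=("glc_D",),
                   drug_enzymes=("dopa_decarboxylase",)),
        StrainSpec(species="Levob secunda", substrates=("glc_D",),
                   drug_enzymes=("dopamine_dehydroxylase",)),
        StrainSpec(species="Neutra commensalis", substrates=("glc_D",)),
    )
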