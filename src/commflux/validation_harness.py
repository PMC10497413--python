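"""FBA-based prediction of experimental trait data and confusion scoring.

A trait record states that an organism has (positive) or lacks (negative)
a capability: uptake or secretion of a metabolite, activity of an enzyme
(a set of reactions), or a drug transformation. The corresponding model
capability is computed by FBA on unlimited medium — minimising the exchange
for uptake, maximising it for secretion, and checking whether any mapped
reaction can carry nonzero flux for enzymes — and scored against the record
into a TP/TN/FP/FN confusion summary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from . import lp_engine
from .model_core import (
    DEFAULT_BOUND,
    DietProfile,
    StoichiometricModel,
    apply_diet,
)

logger = logging.getLogger(__name__)

POSITIVE, NEGATIVE = "positive", "negative"
TRAIT_KINDS = ("uptake", "secretion", "enzyme", "drug_transformation")


@dataclass(frozen=True)
class TraitRecord:
    organism: str
    resolution: str  # strain | species
    kind: str
    target: str | tuple[str, ...]  # metabolite id, reaction ids, or drug id
    sign: str  # positive | negative

    def __post_init__(self) -> None:
        if self.kind not in TRAIT_KINDS:
            raise ValueError(f"unknown trait kind {self.kind!r}")
        if self.sign not in (POSITIVE, NEGATIVE):
            raise ValueError(f"sign must be positive/negative, "
                             f"got {self.sign!r}")
        if self.kind == "enzyme" and not self.target:
            raise ValueError("enzyme records need a non-empty reaction set")


def record_label(record: TraitRecord) -> str:
    target = record.target if isinstance(record.target, str) \
        else "|".join(record.target)
    return f"{record.organism}:{record.kind}:{target}"


# -- TSV serialisation (organism, resolution, kind, target, sign) -----------


def load_traits(path) -> list[TraitRecord]:
    df = pd.read_csv(path, sep="\t", comment="#")
    records = []
    for row in df.itertuples():
        target = str(row.target)
        if row.kind == "enzyme" and "|" in target:
            target = tuple(target.split("|"))
        elif row.kind == "enzyme":
            target = (target,)
        records.append(TraitRecord(
            organism=str(row.organism), resolution=str(row.resolution),
            kind=str(row.kind), target=target, sign=str(row.sign)))
    return records


def save_traits(records, path) -> None:
    rows = []
    for r in records:
        target = r.target if isinstance(r.target, str) else "|".join(r.target)
        rows.append((r.organism, r.resolution, r.kind, target, r.sign))
    pd.DataFrame(rows, columns=["organism", "resolution", "kind", "target",
                                "sign"]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# prediction


def unlimited_medium(model: StoichiometricModel) -> DietProfile:
    """All exchanges open at the de facto unlimited rate (validation diet)."""
    return DietProfile(
        name="unlimited",
        uptakes={r.id: DEFAULT_BOUND for r in model.exchanges},
        aerobic=True)


def _exchange_for(model: StoichiometricModel, met_id: str) -> str | None:
    for rid in (f"EX_{met_id}", f"EX_{met_id}(e)", f"EX_{met_id}[e]",
                f"EX_{met_id}_e"):
        if rid in model.reactions:
            return rid
    return None


def _can_carry_flux(model, problem: lp_engine.LinearProblem, rid: str,
                    eps: float) -> bool:
    hi = problem.optimize(rid, "max")
    if hi.ok and hi.objective_value >= eps:
        return True
    lo = problem.optimize(rid, "min")
    return lo.ok and lo.objective_value <= -eps


def predict_trait(model: StoichiometricModel, record: TraitRecord,
                  drugs=None, eps: float = lp_engine.EPS_ACTIVITY,
                  medium: DietProfile | None = None) -> str:
    """Predict the sign of one trait record for one model.

    An absent target metabolite or reaction predicts negative (the
    capability is not captured), never an error.
    """
    constrained = apply_diet(model, medium or unlimited_medium(model))
    if record.kind in ("uptake", "secretion"):
        rid = _exchange_for(constrained, record.target)
        if rid is None:
            return NEGATIVE
        if record.kind == "uptake":
            sol = lp_engine.optimize(constrained, rid, "min")
            capable = sol.ok and sol.objective_value < -eps
        else:
            sol = lp_engine.optimize(constrained, rid, "max")
            capable = sol.ok and sol.objective_value > eps
        return POSITIVE if capable else NEGATIVE
    # enzyme / drug_transformation: at least one mapped reaction present
    # in the model and able to carry nonzero flux
    if record.kind == "enzyme":
        rxn_ids = record.target if not isinstance(record.target, str) \
            else (record.target,)
    else:
        if drugs is None or record.target not in drugs:
            raise ValueError(
                f"drug_transformation record {record.target!r} needs a drug "
                f"module registry")
        rxn_ids = drugs[record.target].enzyme_reactions
    present = [rid for rid in rxn_ids if rid in constrained.reactions]
    if not present:
        return NEGATIVE
    problem = lp_engine.LinearProblem(constrained)
    for rid in present:
        if _can_carry_flux(constrained, problem, rid, eps):
            return POSITIVE
    return NEGATIVE


# ---------------------------------------------------------------------------
# scoring


@dataclass
class ConfusionSummary:
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0
    skipped: list[str] = field(default_factory=list)
    per_model: pd.DataFrame | None = None

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def accuracy(self) -> float | None:
        return (self.tp + self.tn) / self.total if self.total else None

    @property
    def sensitivity(self) -> float | None:
        pos = self.tp + self.fn
        return self.tp / pos if pos else None

    @property
    def specificity(self) -> float | None:
        neg = self.tn + self.fp
        return self.tn / neg if neg else None

    def to_dict(self) -> dict:
        return {"tp": self.tp, "tn": self.tn, "fp": self.fp, "fn": self.fn,
                "n_skipped": len(self.skipped), "accuracy": self.accuracy,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity}


def _resolve(registry: dict, organism: str):
    """Model(s) for an organism: exact key, else None (skipped)."""
    entry = registry.get(organism)
    if entry is None:
        return None
    return entry if isinstance(entry, (list, tuple)) else [entry]


def evaluate(registry: dict, dataset, drugs=None,
             eps: float = lp_engine.EPS_ACTIVITY) -> ConfusionSummary:
    """Score a trait dataset against a model registry.

    Registry values may be a single model (strain or pan-species) or a list
    of strain models; species-level records against a list use
    any-strain-positive aggregation. Unresolvable organisms are skipped and
    listed, so tp+tn+fp+fn+len(skipped) == len(dataset) always.
    """
    summary = ConfusionSummary()
    per_model: dict[tuple[str, str], list[int]] = {}
    for record in dataset:
        models = _resolve(registry, record.organism)
        if models is None:
            summary.skipped.append(record_label(record))
            continue
        predicted = POSITIVE if any(
            predict_trait(m, record, drugs=drugs, eps=eps) == POSITIVE
            for m in models) else NEGATIVE
        correct = predicted == record.sign
        if record.sign == POSITIVE:
            if correct:
                summary.tp += 1
            else:
                summary.fn += 1
        else:
            if correct:
                summary.tn += 1
            else:
                summary.fp += 1
        cell = per_model.setdefault((record.organism, record.kind), [0, 0])
        cell[0] += int(correct)
        cell[1] += 1
    rows = [(org, kind, c, t, c / t)
            for (org, kind), (c, t) in sorted(per_model.items())]
    summary.per_model = pd.DataFrame(
        rows, columns=["organism", "kind", "correct", "total", "accuracy"])
    return summary


def per_model_accuracy(summary: ConfusionSummary) -> dict[str, float]:
    """Overall per-organism accuracy from a summary's per-model table."""
    if summary.per_model is None or summary.per_model.empty:
        return {}
    grouped = summary.per_model.groupby("organism")[["correct", "total"]].sum()
    return (grouped["correct"] / grouped["total"]).to_dict()


def per_model_accuracy_delta(summary_a: ConfusionSummary,
                             summary_b: ConfusionSummary
                             ) -> dict[str, float]:
    """Paired per-organism accuracy differences (a - b).

    The aligned differences feed a nonparametric sign-rank test (performed
    by the caller with a standard statistics package).
    """
    acc_a = per_model_accuracy(summary_a)
    acc_b = per_model_accuracy(summary_b)
    common = sorted(set(acc_a) & set(acc_b))
    if not common:
        logger.warning("per_model_accuracy_delta: disjoint model sets")
    return {org: acc_a[org] - acc_b[org] for org in common}
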