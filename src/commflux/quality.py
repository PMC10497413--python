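"""Reconstruction quality control.

Stoichiometric and flux consistency subsets, ATP-realism (futile cycle)
diagnostics, growth tests and trait-agreement checks, aggregated into a
:class:`QCReport`. A reconstruction is considered healthy when it grows
anaerobically on a complex medium, is mass/charge balanced, produces
realistic amounts of ATP (no futile cycles) and captures the organism's
known metabolic traits.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from . import lp_engine
from .model_core import (
    DEFAULT_BOUND,
    DietProfile,
    Reaction,
    StoichiometricModel,
    add_demand,
    gpr_syntax_check,
    imbalanced_reactions,
    met_key,
)

logger = logging.getLogger(__name__)

#: ATP flux (mmol/gDW/h) above which production is considered
#: thermodynamically implausible (futile cycling)
FUTILE_ATP_THRESHOLD = 500.0

ATP_DEMAND_ID = "DM_atp_c_"


def ensure_atp_demand(model: StoichiometricModel) -> str | None:
    """Install the ATP demand ``DM_atp_c_`` if absent; return its id.

    Formulated as an ATP hydrolysis (atp + h2o -> adp + pi) when the
    partners exist — the convention used by the gut-microbial reconstruction
    resources, and the only formulation under which futile cycles in a
    mass-balanced network show up as unbounded ATP production. Falls back to
    a plain sink otherwise. Returns None when the model has no cytosolic ATP.
    """
    if ATP_DEMAND_ID in model.reactions:
        return ATP_DEMAND_ID
    atp = met_key("atp", "c")
    if atp not in model.metabolites:
        return None
    partners = [met_key(m, "c") for m in ("h2o", "adp", "pi")]
    if all(p in model.metabolites for p in partners):
        h2o, adp, pi = partners
        model.add_reaction(Reaction(
            id=ATP_DEMAND_ID,
            stoichiometry={atp: -1.0, h2o: -1.0, adp: 1.0, pi: 1.0},
            lower_bound=0.0, upper_bound=DEFAULT_BOUND, kind="internal"))
        return ATP_DEMAND_ID
    return add_demand(model, "atp", "c")


# ---------------------------------------------------------------------------
# stoichiometric consistency


def _mass_feasible(model: StoichiometricModel, subset) -> bool:
    """Does a strictly positive conserved mass vector exist for ``subset``?"""
    subset = sorted(subset)
    if not subset:
        return True
    mets = sorted({k for rid in subset
                   for k in model.reactions[rid].stoichiometry})
    midx = {k: i for i, k in enumerate(mets)}
    rows, cols, data = [], [], []
    for i, rid in enumerate(subset):
        for key, coeff in model.reactions[rid].stoichiometry.items():
            rows.append(i)
            cols.append(midx[key])
            data.append(coeff)
    A = sparse.csr_matrix((data, (rows, cols)),
                          shape=(len(subset), len(mets)))
    res = linprog(np.zeros(len(mets)), A_eq=A, b_eq=np.zeros(len(subset)),
                  bounds=[(1, None)] * len(mets), method="highs")
    return res.status == 0


#: upper bound on relative molecular masses in the consistency search
_MASS_UB = 1e4


def stoich_consistent_set(model: StoichiometricModel,
                          tol: float = 1e-6) -> set[str]:
    """Maximum internal-reaction subset admitting positive molecular masses.

    A reaction subset R is stoichiometrically consistent when a strictly
    positive mass vector m over its participating metabolites satisfies
    S_R' m = 0. Exchange/demand/sink reactions are excluded by definition
    (mass imbalanced by construction).

    The maximum-cardinality subset is found exactly by a small big-M MILP
    (binary inclusion indicator per internal reaction, masses in
    [1, _MASS_UB]), which HiGHS solves instantly at the model sizes this
    package targets; greedy LP pruning can strand reactions that merely
    share a metabolite with an inconsistent one. Masses are relative, so
    the [1, _MASS_UB] box only excludes pathological >1e4 mass ratios.
    """
    from scipy.optimize import LinearConstraint, milp

    internal = sorted(r.id for r in model.internal_reactions())
    if not internal:
        return set()
    mets = sorted({k for rid in internal
                   for k in model.reactions[rid].stoichiometry})
    midx = {k: i for i, k in enumerate(mets)}
    n_m, n_r = len(mets), len(internal)
    # variables: [m (n_m) in [1, UB], y (n_r) binary]
    constraints = []
    for i, rid in enumerate(internal):
        row = np.zeros(n_m + n_r)
        for key, coeff in model.reactions[rid].stoichiometry.items():
            row[midx[key]] = coeff
        big_m = (np.abs(row[:n_m]).sum()) * _MASS_UB + 1.0
        # y_i = 1  =>  S_i' m = 0
        upper = row.copy()
        upper[n_m + i] = big_m
        constraints.append(LinearConstraint(upper, -np.inf, big_m))
        lower = row.copy()
        lower[n_m + i] = -big_m
        constraints.append(LinearConstraint(lower, -big_m, np.inf))
    c = np.concatenate([np.zeros(n_m), -np.ones(n_r)])
    integrality = np.concatenate([np.zeros(n_m), np.ones(n_r)])
    from scipy.optimize import Bounds

    bounds = Bounds(np.concatenate([np.ones(n_m), np.zeros(n_r)]),
                    np.concatenate([np.full(n_m, _MASS_UB), np.ones(n_r)]))
    res = milp(c, constraints=constraints, integrality=integrality,
               bounds=bounds)
    if res.status != 0:
        raise lp_engine.LPError(
            f"stoichiometric consistency MILP status {res.status}")
    chosen = {internal[i] for i in range(n_r)
              if res.x[n_m + i] > 0.5}
    # certify: the indicator solution must itself admit positive masses
    assert _mass_feasible(model, chosen)
    return chosen


# ---------------------------------------------------------------------------
# flux consistency


def flux_consistent_set(model: StoichiometricModel,
                        eps: float = lp_engine.EPS_ACTIVITY) -> set[str]:
    """Reactions that can carry |flux| >= eps under the model's constraints.

    A FASTCC-style sweep: one block LP maximises the number of reactions
    simultaneously active in the forward direction, then the remaining
    candidates are checked one by one by per-reaction maximisation and
    (for reversibles) minimisation.
    """
    problem = lp_engine.LinearProblem(model)
    n = len(problem.rxn_ids)
    consistent: set[str] = set()
    # block LP: variables [v (n), z (n)], maximise sum z, z_j <= v_j,
    # z in [0, eps]
    S_ext = sparse.hstack(
        [problem.S, sparse.csr_matrix((len(problem.met_keys), n))]).tocsr()
    blocks = [sparse.hstack([-sparse.eye(n), sparse.eye(n)]).tocsr()]
    b_ub = [np.zeros(n)]
    if problem.A_ub is not None:
        blocks.append(sparse.hstack(
            [problem.A_ub,
             sparse.csr_matrix((problem.A_ub.shape[0], n))]).tocsr())
        b_ub.append(problem.b_ub)
    A_ub = sparse.vstack(blocks).tocsr()
    c = np.concatenate([np.zeros(n), -np.ones(n)])
    bounds = np.column_stack([
        np.concatenate([problem.lb, np.zeros(n)]),
        np.concatenate([problem.ub, np.full(n, eps)])])
    res = linprog(c, A_eq=S_ext, b_eq=np.zeros(len(problem.met_keys)),
                  A_ub=A_ub, b_ub=np.concatenate(b_ub), bounds=bounds,
                  method="highs")
    if res.status == 0:
        v = res.x[:n]
        for j, rid in enumerate(problem.rxn_ids):
            if abs(v[j]) >= eps * (1 - 1e-6):
                consistent.add(rid)
    # stragglers: per-reaction checks
    for rid in problem.rxn_ids:
        if rid in consistent:
            continue
        hi = problem.optimize(rid, "max")
        if hi.ok and hi.objective_value >= eps * (1 - 1e-6):
            consistent.add(rid)
            continue
        if model.reactions[rid].lower_bound < 0:
            lo = problem.optimize(rid, "min")
            if lo.ok and lo.objective_value <= -eps * (1 - 1e-6):
                consistent.add(rid)
    return consistent


def consistency_fraction(model: StoichiometricModel,
                         eps: float = lp_engine.EPS_ACTIVITY) -> float:
    """Fraction of internal reactions both flux and stoich consistent."""
    internal = {r.id for r in model.internal_reactions()}
    if not internal:
        return 1.0
    good = stoich_consistent_set(model) & flux_consistent_set(model, eps)
    return len(good & internal) / len(internal)


# ---------------------------------------------------------------------------
# ATP realism and growth


def atp_production(model: StoichiometricModel, diet: DietProfile,
                   aerobic: bool = False,
                   threshold: float = FUTILE_ATP_THRESHOLD
                   ) -> tuple[float, bool]:
    """Maximal ATP demand flux under a diet, with a futile-cycle flag.

    ATP production far above what the diet can plausibly fund (default
    threshold 500 mmol/gDW/h) indicates a thermodynamically implausible
    futile cycle.
    """
    work = model.copy()
    demand = ensure_atp_demand(work)
    if demand is None:
        return 0.0, False
    constrained_diet = DietProfile(name=diet.name, uptakes=dict(diet.uptakes),
                                   aerobic=aerobic)
    from .model_core import apply_diet

    constrained = apply_diet(work, constrained_diet)
    sol = lp_engine.optimize(constrained, demand, "max")
    flux = max(0.0, sol.objective_value) if sol.ok else 0.0
    return flux, flux > threshold


def growth_rate(model: StoichiometricModel, diet: DietProfile,
                aerobic: bool | None = None) -> float:
    """FBA maximum of the biomass objective under a diet (0 when no growth)."""
    if model.objective_reaction is None:
        return 0.0
    from .model_core import apply_diet

    constrained = apply_diet(model, diet, aerobic=aerobic)
    sol = lp_engine.optimize(constrained, model.objective_reaction, "max")
    if not sol.ok:
        return 0.0
    return max(0.0, sol.objective_value)


# ---------------------------------------------------------------------------
# aggregate report


@dataclass
class QCReport:
    model_id: str
    anaerobic_growth_complex: float = 0.0
    growth_WD: float = 0.0
    growth_UM: float = 0.0
    atp_WD_aerobic: float = 0.0
    atp_WD_anaerobic: float = 0.0
    futile_aerobic: bool = False
    futile_anaerobic: bool = False
    n_imbalanced_reactions: int = 0
    n_bad_gpr: int = 0
    stoich_consistent_fraction: float = 1.0
    flux_consistent_fraction: float = 1.0
    trait_agreement: dict[str, str] = field(default_factory=dict)

    @property
    def passed(self) -> bool:
        return (self.anaerobic_growth_complex > 1e-6
                and not self.futile_aerobic and not self.futile_anaerobic
                and self.n_imbalanced_reactions == 0
                and self.n_bad_gpr == 0
                and all(v == "agree" for v in self.trait_agreement.values()))

    def to_json(self, path=None) -> str:
        from dataclasses import asdict

        text = json.dumps(asdict(self) | {"passed": self.passed}, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def run_qc(model: StoichiometricModel, diets: dict[str, DietProfile],
           traits=None, drugs=None,
           atp_threshold: float = FUTILE_ATP_THRESHOLD) -> QCReport:
    """Aggregate quality control for one reconstruction.

    ``diets`` should provide 'complex', 'WD' and 'UM' profiles; ``traits``
    is an optional collection of trait records for this organism, scored by
    FBA-based prediction (agree/disagree per finding).
    """
    internal = {r.id for r in model.internal_reactions()}
    stoich = stoich_consistent_set(model)
    fluxc = flux_consistent_set(model)
    report = QCReport(model_id=model.id)
    if "complex" in diets:
        report.anaerobic_growth_complex = growth_rate(
            model, diets["complex"], aerobic=False)
    if "WD" in diets:
        report.growth_WD = growth_rate(model, diets["WD"])
        report.atp_WD_aerobic, report.futile_aerobic = atp_production(
            model, diets["WD"], aerobic=True, threshold=atp_threshold)
        report.atp_WD_anaerobic, report.futile_anaerobic = atp_production(
            model, diets["WD"], aerobic=False, threshold=atp_threshold)
    if "UM" in diets:
        report.growth_UM = growth_rate(model, diets["UM"])
    report.n_imbalanced_reactions = len(imbalanced_reactions(model))
    report.n_bad_gpr = len(gpr_syntax_check(model))
    if internal:
        report.stoich_consistent_fraction = \
            len(stoich & internal) / len(internal)
        report.flux_consistent_fraction = \
            len(fluxc & internal) / len(internal)
    if traits:
        from .validation_harness import predict_trait, record_label

        for record in traits:
            predicted = predict_trait(model, record, drugs=drugs)
            report.trait_agreement[record_label(record)] = (
                "agree" if predicted == record.sign else "disagree")
    return report
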