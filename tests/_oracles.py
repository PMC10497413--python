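"""Independent oracles for the test suite.

These deliberately avoid the package's own LP path: FBA/FVA oracles run
through cobrapy with the GLPK backend (a different solver and model
construction), stoichiometric consistency is checked by exhaustive subset
enumeration, shadow prices by explicit supply-reaction finite differences,
and Fisher p-values by direct hypergeometric enumeration.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.optimize import linprog

from commflux.model_core import (
    Metabolite,
    Reaction,
    StoichiometricModel,
    to_cobra,
)


def cobra_model(model: StoichiometricModel):
    cm = to_cobra(model)
    cm.solver = "glpk"
    for rid, bio, factor in model.couplings:
        rxn = cm.reactions.get_by_id(rid)
        b = cm.reactions.get_by_id(bio)
        cm.add_cons_vars(cm.problem.Constraint(
            rxn.flux_expression - factor * b.flux_expression,
            ub=0, name=f"cpl_u_{rid}"))
        cm.add_cons_vars(cm.problem.Constraint(
            -rxn.flux_expression - factor * b.flux_expression,
            ub=0, name=f"cpl_l_{rid}"))
    return cm


def cobra_optimum(model: StoichiometricModel, objective: str,
                  sense: str = "max"):
    """FBA optimum through cobra+GLPK; None if infeasible."""
    cm = cobra_model(model)
    cm.objective = objective
    cm.objective_direction = sense
    value = cm.slim_optimize(error_value=None)
    return value


def cobra_fva(model: StoichiometricModel, reaction_ids):
    """Per-reaction min/max through cobra+GLPK (no objective constraint)."""
    out = {}
    cm = cobra_model(model)
    for rid in reaction_ids:
        cm.objective = rid
        cm.objective_direction = "min"
        lo = cm.slim_optimize(error_value=None)
        cm.objective_direction = "max"
        hi = cm.slim_optimize(error_value=None)
        out[rid] = (lo, hi)
    return out


def brute_force_stoich_consistent(model: StoichiometricModel,
                                  max_reactions: int = 8) -> set[str]:
    """Largest internal subset with strictly positive conserved masses.

    Exhaustive top-down enumeration with a feasibility LP (m >= 1 for every
    participating metabolite, S_R' m = 0) per subset. Only usable for tiny
    fixtures.
    """
    internal = sorted(r.id for r in model.internal_reactions())
    assert len(internal) <= max_reactions, "oracle limited to tiny fixtures"

    def feasible(subset) -> bool:
        if not subset:
            return True
        mets = sorted({k for rid in subset
                       for k in model.reactions[rid].stoichiometry})
        midx = {k: i for i, k in enumerate(mets)}
        A = np.zeros((len(subset), len(mets)))
        for i, rid in enumerate(subset):
            for key, coeff in model.reactions[rid].stoichiometry.items():
                A[i, midx[key]] = coeff
        res = linprog(np.zeros(len(mets)), A_eq=A,
                      b_eq=np.zeros(len(subset)),
                      bounds=[(1, None)] * len(mets), method="highs")
        return res.status == 0

    for size in range(len(internal), -1, -1):
        hits = [set(sub) for sub in itertools.combinations(internal, size)
                if feasible(sub)]
        if hits:
            # the maximal consistent subset is the union of all maximum-
            # cardinality consistent subsets on these fixtures
            out = set()
            for h in hits:
                out |= h
            if feasible(sorted(out)):
                return out
            return hits[0]
    return set()


def finite_difference_shadow_price(model: StoichiometricModel,
                                   objective: str, sense: str,
                                   metabolite: str,
                                   eps: float = 1e-4):
    """Supply-reaction finite difference: add a fixed eps inflow and re-solve.

    Returns (value, two_sided) where two_sided is False when the left and
    right derivatives disagree (degenerate optimum).
    """
    from commflux import lp_engine

    base = lp_engine.optimize(model, objective, sense)
    assert base.ok
    z0 = base.objective_value

    def perturbed(rate: float):
        work = model.copy()
        work.add_reaction(Reaction(
            id="__FD_SUPPLY__", stoichiometry={metabolite: 1.0},
            lower_bound=rate, upper_bound=rate, kind="sink"))
        sol = lp_engine.optimize(work, objective, sense)
        return sol.objective_value if sol.ok else None

    z_plus = perturbed(eps)
    z_minus = perturbed(-eps)
    right = None if z_plus is None else (z_plus - z0) / eps
    left = None if z_minus is None else (z0 - z_minus) / eps
    if right is None or left is None or abs(right - left) > 1e-5:
        return (right if right is not None else left), False
    return right, True


def fisher_two_sided(table) -> float:
    """Two-sided Fisher p by hypergeometric enumeration."""
    from scipy.stats import hypergeom

    (a, b), (c, d) = table
    n = a + b + c + d
    row1, col1 = a + b, a + c
    rv = hypergeom(n, row1, col1)
    support = range(max(0, row1 + col1 - n), min(row1, col1) + 1)
    p_obs = rv.pmf(a)
    return float(sum(rv.pmf(k) for k in support
                     if rv.pmf(k) <= p_obs * (1 + 1e-9)))


def random_model(seed: int, max_reactions: int = 15) -> StoichiometricModel:
    """A small random metabolic network (always includes exchanges)."""
    rng = np.random.default_rng(seed)
    n_mets = int(rng.integers(3, 7))
    n_internal = int(rng.integers(2, max_reactions - 3))
    model = StoichiometricModel(id=f"random_{seed}")
    mets = []
    for i in range(n_mets):
        for comp in ("c",):
            m = Metabolite(id=f"m{i}", compartment=comp)
            model.add_metabolite(m)
            mets.append(m.key)
    for j in range(n_internal):
        k = int(rng.integers(2, min(4, n_mets) + 1))
        chosen = rng.choice(n_mets, size=k, replace=False)
        stoich = {}
        for idx, mi in enumerate(chosen):
            coeff = float(rng.choice([-2.0, -1.0, 1.0, 2.0]))
            if idx == 0:
                coeff = -abs(coeff)
            elif idx == len(chosen) - 1:
                coeff = abs(coeff)
            stoich[mets[mi]] = coeff
        lb = -1000.0 if rng.random() < 0.4 else 0.0
        model.add_reaction(Reaction(
            id=f"R{j}", stoichiometry=stoich, lower_bound=lb,
            upper_bound=1000.0, kind="internal"))
    n_ex = int(rng.integers(1, n_mets + 1))
    for mi in rng.choice(n_mets, size=n_ex, replace=False):
        mid = mets[mi].split("[")[0]
        model.add_reaction(Reaction(
            id=f"EX_{mid}", stoichiometry={mets[mi]: -1.0},
            lower_bound=-1000.0 if rng.random() < 0.7 else 0.0,
            upper_bound=1000.0, kind="exchange"))
    model.validate()
    return model
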