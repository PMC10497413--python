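"""Linear-programming backbone: FBA, FVA and shadow prices.

All solves go through :func:`scipy.optimize.linprog` (HiGHS) behind the
narrow :class:`LinearProblem` interface: steady-state mass balance
``S v = 0`` as equality rows, flux bounds per reaction, and optional
community coupling constraints ``|v_j| <= u * v_biomass`` as inequality
rows. Only objective values are contractual — individual fluxes of a
returned solution may be one of several alternate optima.

Shadow-price sign convention: the reported value is
``d(optimal objective) / d(epsilon)`` where ``epsilon`` units of the
metabolite are supplied to the network for free. A positive value for a
maximisation therefore means "more of this metabolite would raise the
optimum" — the limiting-metabolite reading used throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .model_core import StoichiometricModel

#: primal feasibility tolerance
TOL_FEAS = 1e-9
#: primal-dual objective gap tolerance
TOL_GAP = 1e-8
#: activity threshold for FVA / consistency checks
EPS_ACTIVITY = 1e-6

OPTIMAL = "optimal"
INFEASIBLE = "infeasible"
UNBOUNDED = "unbounded"

_STATUS = {0: OPTIMAL, 2: INFEASIBLE, 3: UNBOUNDED}


class LPError(RuntimeError):
    """A base problem required to be solvable was not."""


@dataclass
class FluxSolution:
    status: str
    objective_value: float | None
    fluxes: dict[str, float] = field(default_factory=dict)
    metabolite_duals: dict[str, float] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return self.status == OPTIMAL


class LinearProblem:
    """FBA problem matrices for one model, reusable across objectives."""

    def __init__(self, model: StoichiometricModel):
        self.model = model
        S, met_keys, rxn_ids = model.stoichiometric_matrix()
        self.S = S
        self.met_keys = met_keys
        self.rxn_ids = rxn_ids
        self.midx = {k: i for i, k in enumerate(met_keys)}
        self.ridx = {k: j for j, k in enumerate(rxn_ids)}
        self.lb = np.array([model.reactions[r].lower_bound for r in rxn_ids])
        self.ub = np.array([model.reactions[r].upper_bound for r in rxn_ids])
        self.b = np.zeros(len(met_keys))
        if model.couplings:
            rows, cols, data = [], [], []
            for i, (rid, bio, factor) in enumerate(model.couplings):
                j, jb = self.ridx[rid], self.ridx[bio]
                # v_j - factor * v_bio <= 0
                rows += [2 * i, 2 * i]
                cols += [j, jb]
                data += [1.0, -factor]
                # -v_j - factor * v_bio <= 0
                rows += [2 * i + 1, 2 * i + 1]
                cols += [j, jb]
                data += [-1.0, -factor]
            self.A_ub = sparse.csr_matrix(
                (data, (rows, cols)),
                shape=(2 * len(model.couplings), len(rxn_ids)))
            self.b_ub = np.zeros(2 * len(model.couplings))
        else:
            self.A_ub = None
            self.b_ub = None

    # -- core solve ---------------------------------------------------------

    def solve(self, c: np.ndarray, b: np.ndarray | None = None,
              lb: np.ndarray | None = None, ub: np.ndarray | None = None):
        """Minimise ``c @ v``; return the raw scipy result."""
        lo = self.lb if lb is None else lb
        hi = self.ub if ub is None else ub
        res = linprog(
            c, A_eq=self.S, b_eq=self.b if b is None else b,
            A_ub=self.A_ub, b_ub=self.b_ub,
            bounds=np.column_stack([lo, hi]), method="highs")
        return res

    def optimize(self, objective_reaction: str, sense: str = "max",
                 b: np.ndarray | None = None,
                 lb: np.ndarray | None = None,
                 ub: np.ndarray | None = None) -> FluxSolution:
        if objective_reaction not in self.ridx:
            raise KeyError(f"objective reaction {objective_reaction!r} "
                           f"not in model {self.model.id}")
        if sense not in ("max", "min"):
            raise ValueError(f"sense must be max or min, got {sense!r}")
        sign = -1.0 if sense == "max" else 1.0
        c = np.zeros(len(self.rxn_ids))
        c[self.ridx[objective_reaction]] = sign
        res = self.solve(c, b=b, lb=lb, ub=ub)
        status = _STATUS.get(res.status, INFEASIBLE)
        if status != OPTIMAL:
            return FluxSolution(status=status, objective_value=None)
        fluxes = dict(zip(self.rxn_ids, res.x))
        # normalise duals so a positive dual means free supply of the
        # metabolite raises a maximisation objective (see module docstring)
        marg = res.eqlin.marginals
        duals = dict(zip(self.met_keys, marg if sense == "max" else -marg))
        return FluxSolution(status=OPTIMAL,
                            objective_value=sign * res.fun,
                            fluxes=fluxes, metabolite_duals=duals)


def optimize(model: StoichiometricModel,
             objective_reaction: str | None = None,
             sense: str = "max") -> FluxSolution:
    """FBA: optimise one reaction flux subject to S v = 0 and bounds."""
    if objective_reaction is None:
        objective_reaction = model.objective_reaction
    if objective_reaction is None:
        raise ValueError(f"model {model.id} has no objective reaction")
    return LinearProblem(model).optimize(objective_reaction, sense)


def fva(model: StoichiometricModel,
        reaction_ids=None,
        fraction_of_optimum: float = 1.0,
        objective_reaction: str | None = None) -> dict[str, tuple[float, float]]:
    """Flux variability analysis.

    The (maximisation) objective is first solved and constrained to at least
    ``fraction_of_optimum`` of its optimum, then each listed reaction is
    minimised and maximised. With ``fraction_of_optimum=0`` the objective
    constraint is omitted (unconstrained per-reaction ranges).
    """
    if not 0 <= fraction_of_optimum <= 1:
        raise ValueError("fraction_of_optimum must lie in [0, 1]")
    problem = LinearProblem(model)
    if reaction_ids is None:
        reaction_ids = list(model.reactions)
    lb, ub = problem.lb.copy(), problem.ub.copy()
    if fraction_of_optimum > 0:
        obj = objective_reaction or model.objective_reaction
        if obj is None:
            raise ValueError("fraction_of_optimum > 0 requires an objective")
        base = problem.optimize(obj, "max")
        if not base.ok:
            raise LPError(f"base FBA problem is {base.status}")
        j = problem.ridx[obj]
        lb[j] = max(lb[j], fraction_of_optimum * base.objective_value)
    out: dict[str, tuple[float, float]] = {}
    n = len(problem.rxn_ids)
    for rid in reaction_ids:
        j = problem.ridx[rid]
        c = np.zeros(n)
        c[j] = 1.0
        lo_res = problem.solve(c, lb=lb, ub=ub)
        c[j] = -1.0
        hi_res = problem.solve(c, lb=lb, ub=ub)
        if lo_res.status != 0 or hi_res.status != 0:
            raise LPError(f"FVA subproblem for {rid} not optimal")
        out[rid] = (lo_res.fun, -hi_res.fun)
    return out


@dataclass
class ShadowPrice:
    metabolite: str
    value: float
    degenerate: bool = False


def shadow_price(model: StoichiometricModel, objective_reaction: str,
                 sense: str, metabolite: str,
                 eps: float = 1e-3, tol: float = 1e-6) -> ShadowPrice:
    """Shadow price of a metabolite with finite-difference verified sign.

    Returns the solver dual (sign-normalised per the module docstring) and
    flags the value as degenerate when the left and right finite-difference
    re-solves disagree beyond ``tol`` — the dual is then one subgradient of
    a kinked optimum rather than a two-sided derivative.
    """
    problem = LinearProblem(model)
    if metabolite not in problem.midx:
        raise KeyError(f"metabolite {metabolite!r} not in model {model.id}")
    base = problem.optimize(objective_reaction, sense)
    if not base.ok:
        raise LPError(f"base problem is {base.status}")
    dual = base.metabolite_duals[metabolite]
    i = problem.midx[metabolite]
    z0 = base.objective_value

    def perturbed(supply: float) -> float | None:
        # free supply of `supply` units: mass-balance RHS becomes -supply
        b = problem.b.copy()
        b[i] = -supply
        res = problem.optimize(objective_reaction, sense, b=b)
        return res.objective_value if res.ok else None

    z_plus = perturbed(eps)
    z_minus = perturbed(-eps)
    fd_right = None if z_plus is None else (z_plus - z0) / eps
    fd_left = None if z_minus is None else (z0 - z_minus) / eps
    degenerate = False
    if fd_right is None or fd_left is None:
        degenerate = True
    elif abs(fd_right - fd_left) > tol:
        degenerate = True
    return ShadowPrice(metabolite=metabolite, value=dual,
                       degenerate=degenerate)


def check_duality_gap(model: StoichiometricModel, objective_reaction: str,
                      sense: str = "max") -> float:
    """|primal - dual| objective gap of one solve (strong-duality check)."""
    problem = LinearProblem(model)
    sign = -1.0 if sense == "max" else 1.0
    c = np.zeros(len(problem.rxn_ids))
    c[problem.ridx[objective_reaction]] = sign
    res = problem.solve(c)
    if res.status != 0:
        raise LPError(f"solve status {res.status}")
    # dual objective recomputed from marginals: y'b + bound terms
    y = res.eqlin.marginals
    lo_marg = res.lower.marginals
    hi_marg = res.upper.marginals
    dual_obj = float(
        y @ problem.b
        + lo_marg @ np.where(np.isfinite(problem.lb), problem.lb, 0.0)
        + hi_marg @ np.where(np.isfinite(problem.ub), problem.ub, 0.0))
    if problem.b_ub is not None:
        dual_obj += float(res.ineqlin.marginals @ problem.b_ub)
    return abs(res.fun - dual_obj)
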