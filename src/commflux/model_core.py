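"""Domain types and structural operations for stoichiometric models.

The in-memory representation follows the VMH-style conventions used by the
gut-microbial reconstruction community: metabolites carry a flat namespace id
plus a compartment tag (``glc_D`` in ``e`` is written ``glc_D[e]``), reactions
carry plain string ids (``EX_glc_D``, ``DM_atp_c_``), and flux bounds are in
mmol/gDW/h with a default magnitude of 1000 ("de facto unlimited").

Two on-disk dialects are supported: SBML Level 3 (read/written through
cobrapy) and a JSON dialect mirroring the in-memory schema one-to-one
(documented in ``docs/json_schema.md``).
"""

from __future__ import annotations

import json
import logging
import math
import re
from dataclasses import dataclass, field, replace

import pandas as pd

logger = logging.getLogger(__name__)

#: default bound magnitude, mmol/gDW/h
DEFAULT_BOUND = 1000.0

VALID_ELEMENTS = {
    "H", "He", "Li", "Be", "B", "C", "N", "O", "F", "Ne", "Na", "Mg", "Al",
    "Si", "P", "S", "Cl", "Ar", "K", "Ca", "Mn", "Fe", "Co", "Ni", "Cu",
    "Zn", "Se", "Mo", "I", "R", "X",  # R/X: generic moieties used by VMH
}

REACTION_KINDS = ("internal", "exchange", "demand", "sink", "transport")

#: marker returned by balance checks for boundary reactions, which are mass
#: and charge imbalanced by definition
EXEMPT = "exempt"
#: marker for reactions with at least one formula-free metabolite
UNKNOWN_COMPOSITION = "unknown composition"


class ValidationError(ValueError):
    """A model or file violates a structural invariant."""


class FormatError(ValueError):
    """A file cannot be parsed under the requested dialect."""


# ---------------------------------------------------------------------------
# formulas


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*\.?\d*)")


def parse_formula(formula: str) -> dict[str, float]:
    """Parse a Hill-notation formula string into an element->count map."""
    if formula is None or formula == "":
        return {}
    counts: dict[str, float] = {}
    pos = 0
    for match in _FORMULA_TOKEN.finditer(formula):
        if match.start() != pos:
            raise ValidationError(f"cannot parse formula {formula!r}")
        pos = match.end()
        element, num = match.groups()
        if element not in VALID_ELEMENTS:
            raise ValidationError(
                f"unknown element {element!r} in formula {formula!r}")
        n = float(num) if num else 1.0
        counts[element] = counts.get(element, 0.0) + n
    if pos != len(formula):
        raise ValidationError(f"cannot parse formula {formula!r}")
    return {el: n for el, n in counts.items() if n != 0}


def format_formula(counts: dict[str, float] | None) -> str:
    """Render an element map as a Hill-notation string (C, H, then others)."""
    if not counts:
        return ""
    def fmt(n: float) -> str:
        if n == 1:
            return ""
        if float(n).is_integer():
            return str(int(n))
        return str(n)
    order = [el for el in ("C", "H") if el in counts]
    order += sorted(el for el in counts if el not in ("C", "H"))
    return "".join(f"{el}{fmt(counts[el])}" for el in order)


# ---------------------------------------------------------------------------
# domain types


@dataclass
class Metabolite:
    """One metabolite in one compartment.

    ``formula`` is an element->count map (``None`` means unknown composition,
    an empty dict means a massless pseudo-metabolite such as biomass proxies
    whose formula was deliberately not assigned).
    """

    id: str
    compartment: str
    name: str = ""
    formula: dict[str, float] | None = None
    charge: int | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("metabolite id must be non-empty")
        if self.formula is not None:
            for el in self.formula:
                if el not in VALID_ELEMENTS:
                    raise ValidationError(
                        f"unknown element {el!r} for metabolite {self.id}")

    @property
    def key(self) -> str:
        return f"{self.id}[{self.compartment}]"


def met_key(met_id: str, compartment: str) -> str:
    return f"{met_id}[{compartment}]"


def split_key(key: str) -> tuple[str, str]:
    """Split ``glc_D[e]`` into (``glc_D``, ``e``)."""
    m = re.fullmatch(r"(.+)\[([^\[\]]+)\]", key)
    if not m:
        raise ValidationError(f"not a metabolite key: {key!r}")
    return m.group(1), m.group(2)


@dataclass
class Reaction:
    """A (possibly boundary) reaction.

    ``stoichiometry`` maps metabolite keys (``met[comp]``) to signed
    coefficients; negative coefficients are substrates.
    """

    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    gpr: str = ""
    subsystem: str = ""
    kind: str = "internal"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("reaction id must be non-empty")
        if self.lower_bound > self.upper_bound:
            raise ValidationError(
                f"{self.id}: lower bound {self.lower_bound} exceeds upper "
                f"bound {self.upper_bound}")
        if self.kind not in REACTION_KINDS:
            raise ValidationError(f"{self.id}: unknown kind {self.kind!r}")
        if any(c == 0 for c in self.stoichiometry.values()):
            raise ValidationError(f"{self.id}: zero stoichiometric coefficient")
        if self.kind in ("exchange", "demand", "sink") \
                and len(self.stoichiometry) != 1:
            raise ValidationError(
                f"{self.id}: boundary reactions reference exactly one "
                f"metabolite")

    @property
    def is_boundary(self) -> bool:
        return self.kind in ("exchange", "demand", "sink")

    def copy(self) -> "Reaction":
        return replace(self, stoichiometry=dict(self.stoichiometry))


def infer_kind(rxn_id: str, stoichiometry: dict[str, float],
               metabolites: dict[str, "Metabolite"] | None = None) -> str:
    """Classify a reaction from its id prefix and stoichiometry shape."""
    if len(stoichiometry) == 1:
        if rxn_id.startswith("EX_"):
            return "exchange"
        if rxn_id.startswith("DM_"):
            return "demand"
        if rxn_id.startswith(("sink_", "SK_")):
            return "sink"
        return "exchange"
    if metabolites is not None and len(stoichiometry) > 1:
        comps = {metabolites[k].compartment for k in stoichiometry
                 if k in metabolites}
        if len(comps) > 1:
            return "transport"
    return "internal"


@dataclass
class StoichiometricModel:
    """A genome-scale (or toy) metabolic model.

    Metabolites are keyed by ``id[compartment]``; reactions by id. The
    stoichiometric matrix S (rows = metabolites, columns = reactions) is
    materialised on demand by :meth:`stoichiometric_matrix`.

    ``couplings`` (used by community models) lists
    ``(reaction_id, biomass_reaction_id, factor)`` triples enforcing
    ``|v_j| <= factor * v_biomass`` in every LP solved on the model.
    """

    id: str
    metabolites: dict[str, Metabolite] = field(default_factory=dict)
    reactions: dict[str, Reaction] = field(default_factory=dict)
    genes: set[str] = field(default_factory=set)
    objective_reaction: str | None = None
    taxonomy: dict[str, str] = field(default_factory=dict)
    couplings: list[tuple[str, str, float]] = field(default_factory=list)

    # -- construction helpers ------------------------------------------------

    def add_metabolite(self, met: Metabolite) -> Metabolite:
        if met.key in self.metabolites:
            raise ValidationError(f"duplicate metabolite {met.key}")
        self.metabolites[met.key] = met
        return met

    def add_reaction(self, rxn: Reaction) -> Reaction:
        if rxn.id in self.reactions:
            raise ValidationError(f"duplicate reaction {rxn.id}")
        for key in rxn.stoichiometry:
            if key not in self.metabolites:
                raise ValidationError(
                    f"reaction {rxn.id} references undeclared metabolite "
                    f"{key}")
        self.reactions[rxn.id] = rxn
        return rxn

    @property
    def compartments(self) -> set[str]:
        return {m.compartment for m in self.metabolites.values()}

    @property
    def exchanges(self) -> list[Reaction]:
        return [r for r in self.reactions.values() if r.kind == "exchange"]

    def internal_reactions(self) -> list[Reaction]:
        """Reactions subject to mass/charge conservation (non-boundary)."""
        return [r for r in self.reactions.values() if not r.is_boundary]

    def validate(self) -> None:
        for rxn in self.reactions.values():
            for key in rxn.stoichiometry:
                if key not in self.metabolites:
                    raise ValidationError(
                        f"reaction {rxn.id} references undeclared metabolite "
                        f"{key}")
        if self.objective_reaction is not None \
                and self.objective_reaction not in self.reactions:
            raise ValidationError(
                f"objective reaction {self.objective_reaction!r} not in model")
        for rid, bio, factor in self.couplings:
            if rid not in self.reactions or bio not in self.reactions:
                raise ValidationError(f"coupling references unknown reaction "
                                      f"({rid}, {bio})")
            if factor <= 0:
                raise ValidationError("coupling factor must be positive")

    def copy(self, new_id: str | None = None) -> "StoichiometricModel":
        return StoichiometricModel(
            id=new_id or self.id,
            metabolites={k: replace(m, formula=dict(m.formula)
                                    if m.formula is not None else None)
                         for k, m in self.metabolites.items()},
            reactions={k: r.copy() for k, r in self.reactions.items()},
            genes=set(self.genes),
            objective_reaction=self.objective_reaction,
            taxonomy=dict(self.taxonomy),
            couplings=list(self.couplings),
        )

    def stoichiometric_matrix(self):
        """Return (S, metabolite_keys, reaction_ids) with S sparse CSR."""
        import numpy as np
        from scipy import sparse

        met_keys = list(self.metabolites)
        rxn_ids = list(self.reactions)
        midx = {k: i for i, k in enumerate(met_keys)}
        rows, cols, data = [], [], []
        for j, rid in enumerate(rxn_ids):
            for key, coeff in self.reactions[rid].stoichiometry.items():
                rows.append(midx[key])
                cols.append(j)
                data.append(coeff)
        S = sparse.csr_matrix(
            (np.asarray(data, dtype=float), (rows, cols)),
            shape=(len(met_keys), len(rxn_ids)))
        return S, met_keys, rxn_ids


@dataclass
class DietProfile:
    """Named uptake-bound profile applied to exchange reactions.

    ``uptakes`` maps exchange reaction ids to non-negative uptake magnitudes
    (mmol/gDW/h); applying the profile sets the exchange lower bound to the
    negated magnitude. ``aerobic`` opens the oxygen exchange (at the listed
    magnitude, or ``DEFAULT_BOUND`` if oxygen is not listed).
    """

    name: str
    uptakes: dict[str, float] = field(default_factory=dict)
    aerobic: bool = False

    def __post_init__(self) -> None:
        for rid, mag in self.uptakes.items():
            if mag < 0:
                raise ValidationError(
                    f"diet {self.name}: negative uptake for {rid}")
            if not rid.startswith("EX_"):
                raise ValidationError(
                    f"diet {self.name}: {rid!r} is not an exchange id")


OXYGEN_EXCHANGE_IDS = ("EX_o2", "EX_o2[d]", "EX_o2(e)", "EX_o2_e")


def _oxygen_exchange(model: StoichiometricModel) -> str | None:
    for rid in OXYGEN_EXCHANGE_IDS:
        if rid in model.reactions:
            return rid
    return None


def apply_diet(model: StoichiometricModel, diet: DietProfile,
               aerobic: bool | None = None) -> StoichiometricModel:
    """Return a copy of ``model`` constrained to ``diet``.

    All exchange lower bounds are first closed (set to 0), then each listed
    exchange is opened to ``-uptake``. Secretion (upper) bounds are left
    untouched. Exchanges named by the diet but absent from the model are
    skipped with a logged count. ``aerobic`` overrides the profile flag.
    """
    out = model.copy()
    for rxn in out.reactions.values():
        if rxn.kind == "exchange":
            rxn.lower_bound = 0.0
    skipped = 0
    for rid, mag in diet.uptakes.items():
        rxn = out.reactions.get(rid)
        if rxn is None or rxn.kind != "exchange":
            skipped += 1
            continue
        rxn.lower_bound = -abs(mag)
    if skipped:
        logger.info("diet %s: %d exchange ids absent from model %s (skipped)",
                    diet.name, skipped, model.id)
    use_oxygen = diet.aerobic if aerobic is None else aerobic
    o2 = _oxygen_exchange(out)
    if o2 is not None:
        if use_oxygen:
            mag = diet.uptakes.get(o2, DEFAULT_BOUND)
            out.reactions[o2].lower_bound = -abs(mag)
        else:
            out.reactions[o2].lower_bound = 0.0
    return out


def load_diet(path) -> DietProfile:
    """Read a diet TSV (``exchange_id<TAB>uptake_mmol_per_gDW_h``)."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["exchange_id", "uptake"])
    uptakes = {str(r.exchange_id): float(r.uptake) for r in df.itertuples()}
    import os
    name = os.path.splitext(os.path.basename(str(path)))[0]
    aerobic = any(rid in uptakes for rid in OXYGEN_EXCHANGE_IDS)
    return DietProfile(name=name, uptakes=uptakes, aerobic=aerobic)


def save_diet(diet: DietProfile, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# diet profile: {diet.name}\n")
        for rid, mag in diet.uptakes.items():
            fh.write(f"{rid}\t{mag}\n")


# ---------------------------------------------------------------------------
# balance checks


def elemental_balance(model: StoichiometricModel, reaction_id: str):
    """Per-element signed imbalance of a reaction.

    Returns an element->imbalance map (empty map == balanced), or the marker
    :data:`EXEMPT` for exchange/demand/sink reactions (mass imbalanced by
    definition) or :data:`UNKNOWN_COMPOSITION` when a participating
    metabolite has no formula.
    """
    rxn = model.reactions[reaction_id]
    if rxn.is_boundary:
        return EXEMPT
    imbalance: dict[str, float] = {}
    for key, coeff in rxn.stoichiometry.items():
        met = model.metabolites[key]
        if met.formula is None:
            return UNKNOWN_COMPOSITION
        for el, n in met.formula.items():
            imbalance[el] = imbalance.get(el, 0.0) + coeff * n
    return {el: v for el, v in imbalance.items() if abs(v) > 1e-9}


def charge_balance(model: StoichiometricModel, reaction_id: str):
    """Signed charge imbalance of a reaction (same markers as elemental)."""
    rxn = model.reactions[reaction_id]
    if rxn.is_boundary:
        return EXEMPT
    total = 0.0
    for key, coeff in rxn.stoichiometry.items():
        met = model.metabolites[key]
        charge = met.charge
        if charge is None:
            logger.warning("metabolite %s has no charge; assuming 0", key)
            charge = 0
        total += coeff * charge
    return 0 if abs(total) < 1e-9 else total


def imbalanced_reactions(model: StoichiometricModel) -> list[str]:
    """Internal/transport reactions with a mass or charge imbalance."""
    bad = []
    for rid in model.reactions:
        eb = elemental_balance(model, rid)
        if eb in (EXEMPT, UNKNOWN_COMPOSITION):
            continue
        cb = charge_balance(model, rid)
        if eb or (cb != EXEMPT and cb != 0):
            bad.append(rid)
    return bad


# ---------------------------------------------------------------------------
# demand reactions


def add_demand(model: StoichiometricModel, metabolite_id: str,
               compartment: str = "c") -> str:
    """Add a sink-style demand ``DM_<met>_<comp>_`` for a metabolite.

    Idempotent: returns the existing reaction id if already present.
    """
    key = met_key(metabolite_id, compartment)
    if key not in model.metabolites:
        raise ValidationError(f"unknown metabolite {key}")
    rid = f"DM_{metabolite_id}_{compartment}_"
    if rid in model.reactions:
        return rid
    model.add_reaction(Reaction(
        id=rid, stoichiometry={key: -1.0}, lower_bound=0.0,
        upper_bound=DEFAULT_BOUND, kind="demand"))
    return rid


# ---------------------------------------------------------------------------
# GPR syntax


_GPR_TOKEN = re.compile(r"\s*(\(|\)|and\b|or\b|[A-Za-z0-9_.\-]+)\s*",
                        re.IGNORECASE)


def _parse_gpr(expr: str) -> bool:
    """Recursive-descent check of a boolean gene expression. True if valid."""
    tokens: list[str] = []
    pos = 0
    while pos < len(expr):
        m = _GPR_TOKEN.match(expr, pos)
        if not m or m.end() == pos:
            return False
        tokens.append(m.group(1))
        pos = m.end()

    idx = 0

    def peek():
        return tokens[idx] if idx < len(tokens) else None

    def term() -> bool:
        nonlocal idx
        tok = peek()
        if tok == "(":
            idx += 1
            if not disjunction():
                return False
            if peek() != ")":
                return False
            idx += 1
            return True
        if tok is None or tok in (")",) or tok.lower() in ("and", "or"):
            return False
        idx += 1
        return True

    def conjunction() -> bool:
        nonlocal idx
        if not term():
            return False
        while peek() is not None and peek().lower() == "and":
            idx += 1
            if not term():
                return False
        return True

    def disjunction() -> bool:
        nonlocal idx
        if not conjunction():
            return False
        while peek() is not None and peek().lower() == "or":
            idx += 1
            if not conjunction():
                return False
        return True

    ok = disjunction()
    return ok and idx == len(tokens)


def gpr_genes(gpr: str) -> set[str]:
    """All gene ids mentioned in a GPR string."""
    if not gpr:
        return set()
    return {t for t in re.findall(r"[A-Za-z0-9_.\-]+", gpr)
            if t.lower() not in ("and", "or")}


def gpr_syntax_check(model: StoichiometricModel) -> list[str]:
    """Reaction ids whose GPR fails the boolean grammar (empty GPR is valid)."""
    bad = []
    for rid, rxn in model.reactions.items():
        if rxn.gpr and not _parse_gpr(rxn.gpr):
            bad.append(rid)
    return bad


# ---------------------------------------------------------------------------
# I/O: JSON dialect


_JSON_SCHEMA_VERSION = 1


def _model_to_dict(model: StoichiometricModel) -> dict:
    return {
        "schema_version": _JSON_SCHEMA_VERSION,
        "id": model.id,
        "objective_reaction": model.objective_reaction,
        "taxonomy": model.taxonomy,
        "genes": sorted(model.genes),
        "metabolites": [
            {"id": m.id, "compartment": m.compartment, "name": m.name,
             "formula": m.formula, "charge": m.charge}
            for m in model.metabolites.values()
        ],
        "reactions": [
            {"id": r.id, "stoichiometry": r.stoichiometry,
             "lower_bound": r.lower_bound, "upper_bound": r.upper_bound,
             "gpr": r.gpr, "subsystem": r.subsystem, "kind": r.kind}
            for r in model.reactions.values()
        ],
        "couplings": [list(c) for c in model.couplings],
    }


def _model_from_dict(data: dict) -> StoichiometricModel:
    try:
        model = StoichiometricModel(
            id=data["id"],
            objective_reaction=data.get("objective_reaction"),
            taxonomy=dict(data.get("taxonomy") or {}),
            genes=set(data.get("genes") or ()),
        )
        for m in data["metabolites"]:
            model.add_metabolite(Metabolite(
                id=m["id"], compartment=m["compartment"],
                name=m.get("name", ""), formula=m.get("formula"),
                charge=m.get("charge")))
        for r in data["reactions"]:
            kind = r.get("kind") or infer_kind(r["id"], r["stoichiometry"],
                                               model.metabolites)
            model.add_reaction(Reaction(
                id=r["id"], stoichiometry=dict(r["stoichiometry"]),
                lower_bound=float(r.get("lower_bound", -DEFAULT_BOUND)),
                upper_bound=float(r.get("upper_bound", DEFAULT_BOUND)),
                gpr=r.get("gpr", ""), subsystem=r.get("subsystem", ""),
                kind=kind))
        model.couplings = [tuple(c) for c in data.get("couplings") or []]
    except KeyError as exc:
        raise FormatError(f"missing field {exc} in JSON model") from exc
    model.validate()
    return model


# ---------------------------------------------------------------------------
# I/O: SBML through cobrapy


def to_cobra(model: StoichiometricModel):
    """Convert to a :class:`cobra.Model` (metabolite ids become id_comp)."""
    import cobra

    cm = cobra.Model(model.id)
    cmets = {}
    for key, met in model.metabolites.items():
        c = cobra.Metabolite(
            id=f"{met.id}_{met.compartment}", name=met.name or met.id,
            compartment=met.compartment)
        if met.formula is not None:
            c.formula = format_formula(met.formula)
        if met.charge is not None:
            c.charge = met.charge
        cmets[key] = c
    cm.add_metabolites(list(cmets.values()))
    crxns = []
    for rxn in model.reactions.values():
        cr = cobra.Reaction(rxn.id, lower_bound=rxn.lower_bound,
                            upper_bound=rxn.upper_bound)
        cr.subsystem = rxn.subsystem
        crxns.append(cr)
    cm.add_reactions(crxns)
    for rxn in model.reactions.values():
        cr = cm.reactions.get_by_id(rxn.id)
        cr.add_metabolites({cmets[k]: v for k, v in rxn.stoichiometry.items()})
        if rxn.gpr:
            cr.gene_reaction_rule = rxn.gpr
    if model.objective_reaction is not None:
        cm.objective = model.objective_reaction
    return cm


def from_cobra(cm) -> StoichiometricModel:
    """Convert a :class:`cobra.Model` into a :class:`StoichiometricModel`."""
    model = StoichiometricModel(id=cm.id or "model")
    for cmet in cm.metabolites:
        comp = cmet.compartment or "c"
        base = cmet.id
        suffix = f"_{comp}"
        if base.endswith(suffix):
            base = base[: -len(suffix)]
        formula = None
        if cmet.formula:
            formula = parse_formula(cmet.formula)
        elif cmet.formula == "":
            formula = {}
        model.add_metabolite(Metabolite(
            id=base, compartment=comp,
            name="" if cmet.name == base else (cmet.name or ""),
            formula=formula, charge=cmet.charge))
    key_of = {}
    for cmet in cm.metabolites:
        comp = cmet.compartment or "c"
        base = cmet.id
        if base.endswith(f"_{comp}"):
            base = base[: -len(f"_{comp}")]
        key_of[cmet.id] = met_key(base, comp)
    objective_ids = [r.id for r in cm.reactions
                     if r.objective_coefficient not in (0, None)]
    for cr in cm.reactions:
        stoich = {key_of[m.id]: float(v) for m, v in cr.metabolites.items()}
        model.add_reaction(Reaction(
            id=cr.id, stoichiometry=stoich,
            lower_bound=float(cr.lower_bound),
            upper_bound=float(cr.upper_bound),
            gpr=cr.gene_reaction_rule or "",
            subsystem=cr.subsystem or "",
            kind=infer_kind(cr.id, stoich, model.metabolites)))
        model.genes |= gpr_genes(cr.gene_reaction_rule or "")
    if objective_ids:
        model.objective_reaction = objective_ids[0]
    model.validate()
    return model


# ---------------------------------------------------------------------------
# load / save


def load_model(path, dialect: str = "json") -> StoichiometricModel:
    """Load a model from ``path`` under the named dialect (sbml|json)."""
    if dialect == "json":
        try:
            with open(path) as fh:
                data = json.load(fh)
        except json.JSONDecodeError as exc:
            raise FormatError(f"{path}: not valid JSON ({exc})") from exc
        return _model_from_dict(data)
    if dialect == "sbml":
        import cobra.io

        try:
            cm = cobra.io.read_sbml_model(str(path))
        except Exception as exc:  # libsbml raises various error types
            raise FormatError(f"{path}: SBML parse failure ({exc})") from exc
        return from_cobra(cm)
    raise ValueError(f"unknown dialect {dialect!r}")


def save_model(model: StoichiometricModel, path, dialect: str = "json") -> None:
    model.validate()
    if dialect == "json":
        with open(path, "w") as fh:
            json.dump(_model_to_dict(model), fh, indent=1, sort_keys=False)
            fh.write("\n")
        return
    if dialect == "sbml":
        import cobra.io

        cobra.io.write_sbml_model(to_cobra(model), str(path))
        return
    raise ValueError(f"unknown dialect {dialect!r}")


def models_equivalent(a: StoichiometricModel, b: StoichiometricModel,
                      check_objective: bool = True) -> bool:
    """Structural equality: metabolites, reactions, bounds, GPRs, objective."""
    if set(a.metabolites) != set(b.metabolites):
        return False
    for key, ma in a.metabolites.items():
        mb = b.metabolites[key]
        if (ma.formula or {}) != (mb.formula or {}):
            return False
        if (ma.charge or 0) != (mb.charge or 0):
            return False
    if set(a.reactions) != set(b.reactions):
        return False
    for rid, ra in a.reactions.items():
        rb = b.reactions[rid]
        if ra.stoichiometry != rb.stoichiometry:
            return False
        if not (math.isclose(ra.lower_bound, rb.lower_bound, abs_tol=1e-9)
                and math.isclose(ra.upper_bound, rb.upper_bound,
                                 abs_tol=1e-9)):
            return False
        if ra.gpr != rb.gpr:
            return False
    if check_objective and a.objective_reaction != b.objective_reaction:
        return False
    return True
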