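"""Species–metabolite association sign concordance.

For each species present in 10–90% of microbiomes, the effect of species
presence (binary predictor) on each fecal metabolite concentration is
estimated by multivariable OLS adjusting for age, sex, BMI and study group —
once against measured concentrations (in vivo) and once against community
net secretion fluxes (in silico). Per metabolite, the agreement in effect
signs between the two sides is tabulated over species with in-vivo p < 0.05,
tested by Fisher's exact test, and corrected across metabolites by
Benjamini–Hochberg FDR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .community_builder import AbundanceTable

DEFAULT_COVARIATES = ("age", "sex", "BMI", "group")


@dataclass
class AssociationResult:
    species: str
    metabolite: str
    side: str  # in_vivo | in_silico
    effect: float
    p_value: float
    n: int


def presence_filter(abundances: AbundanceTable, lo: float = 0.1,
                    hi: float = 0.9) -> list[str]:
    """Species whose presence prevalence lies in the closed band [lo, hi]."""
    if not 0 <= lo < hi <= 1:
        raise ValueError("need 0 <= lo < hi <= 1")
    prev = abundances.prevalence()
    return [sp for sp in abundances.species if lo <= prev[sp] <= hi]


def fit_presence_effect(y, presence, covariates=None,
                        species: str = "", metabolite: str = "",
                        side: str = "in_vivo") -> AssociationResult:
    """OLS of a response on species presence, adjusting for covariates.

    ``y`` is the per-sample response (concentration or flux), ``presence``
    a binary per-sample vector, ``covariates`` an optional DataFrame
    (columns named). The presence coefficient and its two-sided t-test
    p-value are returned.
    """
    import statsmodels.api as sm

    y = np.asarray(y, dtype=float)
    presence = np.asarray(presence, dtype=float)
    if presence.std() == 0:
        raise ValueError("constant presence vector (apply presence_filter)")
    cols = {"presence": presence}
    if covariates is not None:
        cov = pd.DataFrame(covariates)
        for name in cov.columns:
            cols[str(name)] = np.asarray(cov[name], dtype=float)
    X = pd.DataFrame(cols)
    n, k = X.shape
    if n <= k + 1:
        raise ValueError(f"n={n} too small for {k} predictors")
    design = sm.add_constant(X)
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        for name in X.columns:
            reduced = design.drop(columns=[name])
            if np.linalg.matrix_rank(reduced.to_numpy()) == rank:
                raise ValueError(f"collinear covariate: {name}")
        raise ValueError("collinear design matrix")
    fit = sm.OLS(y, design).fit()
    return AssociationResult(
        species=species, metabolite=metabolite, side=side,
        effect=float(fit.params["presence"]),
        p_value=float(fit.pvalues["presence"]), n=n)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted q-values."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _results_frame(results) -> pd.DataFrame:
    if isinstance(results, pd.DataFrame):
        return results
    return pd.DataFrame([{
        "species": r.species, "metabolite": r.metabolite,
        "effect": r.effect, "p_value": r.p_value} for r in results])


def sign_concordance(in_vivo, in_silico, alpha: float = 0.05) -> pd.DataFrame:
    """Sign agreement between in-vivo and in-silico association statistics.

    Restricted to species–metabolite pairs with in-vivo p < alpha. Per
    metabolite: the 2x2 table of (in-vivo sign x in-silico sign), the
    agreement fraction, a two-sided Fisher exact p, a BH-FDR q across
    metabolites, and a flag for consistently inverse metabolites (all signs
    opposite — the net-uptake signature).
    """
    vivo = _results_frame(in_vivo)
    silico = _results_frame(in_silico)
    merged = vivo.merge(silico, on=["species", "metabolite"],
                        suffixes=("_vivo", "_silico"))
    merged = merged[merged["p_value_vivo"] < alpha]
    rows = []
    for met, grp in merged.groupby("metabolite"):
        sv = grp["effect_vivo"] > 0
        ss = grp["effect_silico"] > 0
        table = np.array([
            [int((sv & ss).sum()), int((sv & ~ss).sum())],
            [int((~sv & ss).sum()), int((~sv & ~ss).sum())]])
        n = int(table.sum())
        agree = int(table[0, 0] + table[1, 1])
        fisher_p = float(stats.fisher_exact(table,
                                            alternative="two-sided")[1])
        rows.append({
            "metabolite": met, "n_species": n, "n_agree": agree,
            "n_disagree": n - agree,
            "agreement": agree / n if n else np.nan,
            "pp": int(table[0, 0]), "pn": int(table[0, 1]),
            "np": int(table[1, 0]), "nn": int(table[1, 1]),
            "fisher_p": fisher_p,
            "consistently_inverse": bool(n > 0 and agree == 0)})
    out = pd.DataFrame(rows)
    if not out.empty:
        out["fdr_q"] = bh_fdr(out["fisher_p"])
        out = out.sort_values("metabolite").reset_index(drop=True)
    return out


def metabolite_inclusion(concentrations: pd.DataFrame, detection_limit: float,
                         min_fraction: float = 0.5) -> list[str]:
    """Metabolites quantified above the detection limit in >min_fraction of
    samples (inclusion rule for the concordance analysis)."""
    above = (concentrations > detection_limit).mean(axis=0)
    return [m for m in concentrations.columns if above[m] > min_fraction]
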