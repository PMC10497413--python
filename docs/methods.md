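# Methods

This note documents the models, conventions and numerical choices behind
`commflux`, in the spirit of the methods documentation of the established
constraint-based modeling toolchains.

## Stoichiometric models and conventions

A model is a set of metabolites (flat namespace id + compartment tag,
written `glc_D[e]`) and reactions (plain string ids) with flux bounds in
mmol/gDW/h. Wherever a bound is unspecified the magnitude is 1000 — the
"de facto unlimited" convention of the gut-microbial reconstruction
ecosystem. Exchange reactions `EX_<met>` remove one extracellular
metabolite; negative flux is uptake, positive is secretion. Demand
reactions `DM_<met>_<comp>_` are irreversible single-metabolite sinks;
`add_demand` follows that id convention exactly and is idempotent.

One deliberate exception: the ATP demand used by the ATP-realism test
(`DM_atp_c_`) is formulated as an ATP hydrolysis
(`atp + h2o -> adp + pi`) whenever the partner metabolites exist. A plain
sink cannot expose futile cycles in a mass-balanced network, because ADP
is never regenerated and the sink's maximal flux is zero regardless of any
internal loop; the hydrolysis form is also how the reference reconstruction
resources formulate their ATP demand. `add_demand` itself stays a plain
sink for all metabolites.

Formulas are element→count maps parsed from Hill notation; a missing
formula yields an "unknown composition" marker from the balance checks
rather than an exception, and missing charges default to 0 with a warning.
Exchange, demand and sink reactions are exempt from mass/charge balance by
definition and are never flagged.

Two on-disk dialects are supported: SBML Level 3 (through cobrapy, with
flux bounds as fbc parameters) and a JSON dialect that mirrors the
in-memory schema one-to-one (`docs/json_schema.md`). Round-tripping either
dialect preserves metabolites, formulas, charges, reactions, bounds, GPRs
and the objective.

Diet profiles are named maps from exchange id to a non-negative uptake
magnitude. Applying a diet closes every exchange lower bound, then opens
the listed ones to `-magnitude`; secretion bounds are untouched; the
`aerobic` flag controls the oxygen exchange (opened at the listed
magnitude or 1000). Exchanges named by a diet but absent from a model are
counted and logged, not errors — diets are shared across heterogeneous
model collections.

## LP engine

All solves run through HiGHS (`scipy.optimize.linprog`) behind a single
`LinearProblem` wrapper that carries `S v = 0` as equality rows, flux
bounds, and (for communities) coupling inequalities. Tolerances:
feasibility 1e-9, primal–dual gap 1e-8, activity threshold 1e-6 — well
inside double precision for coefficient magnitudes of 1–1000. Only
objective values are contractual; a returned flux vector may be one of
several alternate optima, and the tests assert individual fluxes only
where FVA proves uniqueness.

**Shadow prices.** The reported value is the derivative of the optimal
objective with respect to free supply of the metabolite: positive for a
maximisation means "more of this metabolite raises the optimum". Solvers
disagree on dual sign conventions, so the sign is pinned by this
finite-difference semantics and every `shadow_price` call verifies its
dual against left and right re-solves (±1e-3 supply); when the two
one-sided derivatives disagree beyond 1e-6 the value is flagged degenerate
— it is then a subgradient at a kinked optimum, still reported but not a
two-sided derivative.

**FVA** first solves the objective, constrains it to
`fraction_of_optimum × optimum` (as a tightened lower bound on the
objective reaction), then minimises and maximises each requested reaction.
`fraction_of_optimum = 0` omits the objective constraint entirely.

## Quality control

**Stoichiometric consistency.** A subset of internal reactions is
consistent when a strictly positive molecular-mass vector `m` satisfies
`S_R' m = 0` over its participating metabolites. The maximum-cardinality
subset is found exactly by a small big-M MILP (binary inclusion indicator
per reaction, masses bounded to [1, 1e4]; masses are relative, so the box
only excludes mass ratios beyond 1e4). An LP-relaxation pruning heuristic
was tried first and rejected: removing every reaction that touches a
zero-mass metabolite also removes innocent neighbours of an inconsistent
reaction and cannot guarantee maximality. At the model sizes this package
targets the MILP solves in milliseconds. The maximum subset need not be
unique; the test suite therefore checks cardinality plus a positive-mass
feasibility certificate against an exhaustive-enumeration oracle.

**Flux consistency.** A reaction is flux consistent when some steady-state
flux distribution gives it |v| ≥ 1e-6. A FASTCC-style block LP first finds
the reactions that can be active simultaneously in the forward direction;
the remaining candidates are settled by per-reaction maximisation and (for
reversibles) minimisation. The per-reaction step makes the result exact;
the block LP is purely a speedup.

**ATP realism.** `atp_production` maximises the hydrolysis demand under a
diet. Fluxes above a threshold (default 500 mmol/gDW/h, configurable) flag
a thermodynamically implausible futile cycle; the reference observation is
models hitting the 1000 bound on complex medium. The threshold is a policy
knob — no published cutoff exists — and the default sits between the
highest legitimate diet-limited yield in the synthetic fixtures (20) and
the bound (1000).

**Consistency fraction** is |flux-consistent ∩ stoich-consistent| over the
internal (non-boundary) reactions, the quantity used to compare
reconstruction resources. A model without internal reactions reports 1.0.

## Community models

Per member species, all non-exchange reactions are copied with a species
prefix; extracellular metabolites map to the shared lumen `[u]`; member
exchanges are dropped in favour of a community-level transport layer: for
every lumen metabolite, `DUt_<met>` ([d]→[u]), `UFEt_<met>` ([u]→[fe]),
`EX_<met>[d]` and `EX_<met>[fe]`. Member demands/sinks that drain the
biomass metabolite are removed so biomass can only flow into the community
biomass reaction, which consumes each species' biomass metabolite
(`<species>_biomass[c]`) at its normalized abundance and produces
`microbeBiomass[u]`, exported via `EX_microbeBiomass[fe]`.

Coupling follows the published community-modeling convention: every member
reaction j obeys `|v_j| ≤ u_cpl · v_biomass,species` with u_cpl = 400, and
the community biomass flux is bounded to [0.4, 1.0] per day. Community
fluxes are interpreted directly as mmol/person/day through those per-day
bounds; no additional fecal-mass scaling is applied (an assumption — the
exact rescaling used by the upstream pipelines is not specified in this
package's sources).

Pan-species models take the union of strain reactions (bounds widened to
the per-id union interval, GPRs of shared reactions joined by OR) and
adopt the biomass of the strain with the most reactions (ties:
lexicographically first id), renamed `biomassPan`. Identical ids with
conflicting stoichiometry abort with the offender list. No abundance floor
is applied when assembling communities ("all species with nonzero
abundance"); a cutoff parameter exists for performance and defaults to 0.

## Drug simulation

`conversion_potential` applies the diet, opens the precursor's diet
exchange and oxygen at 1000 mmol/gDW/h, and maximises the product's fecal
exchange. Missing precursor or product in the community returns 0 ("no
carrier"), never an error. The qualitative capability threshold is 1e-6
mmol/person/day. `bottleneck_species` reports members whose biomass
metabolite has |shadow price| > 1e-6 at that optimum; because the
community biomass reaction *consumes* biomass metabolites, a bottleneck
shows up with a negative price (free biomass substitutes for production
and relaxes nothing downstream), and its 10% abundance increase strictly
raises the conversion optimum — the property the tests verify directly.

`drug_yield` constrains a strain to take up only water, phosphate and
oxygen, supplies the drug (or glucose as control) at exactly 1 mmol/gDW/h,
and maximises the demand of the currency metabolite (ATP via the
hydrolysis demand; ammonia, CO2 and pyruvate via plain sinks added on
demand). With no substrate the ATP yield is exactly 0; since all synthetic
chemistry is elementally balanced, carbon-proxy yields can never exceed
the drug's carbon count nor ammonia its nitrogen count.

## Validation harness

Trait prediction runs on unlimited medium (all exchanges open at 1000):
uptake = minimise the exchange (capable iff min < −1e-6), secretion =
maximise (capable iff max > 1e-6), enzyme and drug-transformation records
= at least one mapped reaction present and able to carry |flux| ≥ 1e-6. An
absent target predicts negative — the model does not capture the
capability. Species-level records are evaluated against a pan model when
one is registered, else against all registered strains with
any-strain-positive aggregation. Scoring is deterministic and closed:
TP+TN+FP+FN plus skipped (unresolvable organism) equals the dataset size.
Undefined ratios (empty positive or negative class) are `None`, never
silent NaN.

## Association statistics

The in-vivo side fits ordinary least squares of each fecal metabolite
concentration on species presence (binary), adjusting for age, sex, BMI
and study group; the spline machinery some epidemiological analyses use
for age belongs to a different analysis arm and is deliberately not
replicated here. The in-silico side runs the same regression on community
net secretion fluxes. Species enter only if present in 10–90% of samples
(closed bounds); metabolites only if above the detection limit in more
than half the samples. Sign concordance per metabolite is tabulated over
species with in-vivo p < 0.05; significance by two-sided Fisher's exact
test (summing all tables with probability ≤ observed); FDR by
Benjamini–Hochberg across metabolites. A metabolite whose significant
signs all disagree is flagged "consistently inverse" — the signature of
net microbial uptake. The Fisher p-values are reported without any
correction for species–species or metabolite–metabolite dependence.

## Synthetic data generator

The generator emulates the inputs of a community drug-metabolism study at
desk scale: strain reconstructions, drug modules, cohorts and trait data.
Its chemistry uses a closed C/H/N/O alphabet with synthetic formulas:
substrates are `CnH2nOn` sugars interconvertible with a `CH2O` precursor
unit, catabolism yields 2 ATP per substrate (glycolysis-style), biomass
consumes 6 precursor units + ammonia + 1 ATP, and any hydrogen/oxygen
remainder of a template reaction is closed with `h2`/`h2o`, so every
constructed reaction is exactly elementally balanced. The formulas are
stand-ins, not real chemistry; what they guarantee is that conservation
laws (and hence yield ceilings and balance checks) hold by construction.
Plantable defects break specific QC checks on purpose: a dead-end
reaction (flux inconsistency), an uncosted ATP-generating isomerisation
loop whose steps are individually mass-balanced (a genuine futile cycle),
and a formula-free metabolite (unknown composition).

Drug modules mirror known microbial transformations in shape: an
*extracellular* azoreductase that activates a balsalazide-like prodrug
(extracellular so the enzymatic step is the only coupled reaction on the
drug path — its water co-substrate enters through the uncoupled diet
transport layer), a two-step levodopa chain split across two species
(decarboxylase, then dehydroxylase), and an oxidative deaminase whose
substrate serves as carbon/nitrogen/energy source. Generated module sets
(`make_drug_modules`) are decarboxylase-style with product = precursor −
CO2, always including one two-step chain.

Cohorts: species presence is Bernoulli per-species prevalence (default
0.5; microbiomes drawn empty get the most prevalent species forced
present); abundances are log-normal (μ=0, σ=1 — the typical metagenomic
shape) renormalized to sum exactly to 1 per sample; covariates age ~
N(55, 10), sex ~ Bernoulli(0.5), BMI ~ N(23, 3), group ~ Bernoulli(0.5);
fecal concentrations are baseline 10 + Σ planted effect × presence +
N(0, 1) noise, censored at a detection limit of 0.05. Default planted
effects are +2.0 on three fermentation products, each carried by exactly
one species, so the effect is realized on both the in-vivo side
(concentrations) and the in-silico side (only the carrier's presence
creates secretion capability). Trait datasets take each model's own
FBA-predicted signs and invert a Bernoulli(flip_rate) subset, recording
every flip — evaluation accuracy then equals 1 − (realized flip fraction)
exactly, and tracks 1 − flip_rate within binomial error.

All generators are pure functions of (spec, seed).

### What the generator does not emulate

Real reconstruction namespaces and real biochemistry; genome sequences;
taxonomic structure of real resources; host compartments; realistic drug
doses or pharmacokinetics; correlated species co-occurrence;
compositionality artifacts of relative-abundance data beyond the
renormalization itself; measurement error models beyond additive Gaussian
noise with left-censoring. Passing tests therefore demonstrate that the
algorithms are correct on networks whose ground truth is known — not that
predictions on real reconstructions are accurate.

## Problem sizes and determinism

The shipped analyses run at deliberately small scale: strains of ~25–40
reactions, communities of up to ~6 species (a few hundred reactions),
cohorts of 12–200 samples, 10-seed replications. The full test suite runs
in under a minute on one CPU; the acceptance script in well under a
minute for the deterministic checks and a few minutes end to end. All
stochastic steps consume an explicit seed; LP solves are deterministic for
fixed inputs, and only objective values (never alternate-optimal flux
vectors) are asserted anywhere.

## Known limitations

- The periplasm compartment is representable but no placement logic
  exists; synthetic strains use cytosol/extracellular only.
- The community flux unit rests on the per-day biomass bounds; absolute
  mmol/person/day values are only as meaningful as that convention.
- The MILP consistency search is exact but intended for small networks;
  genome-scale models would need the iterative heuristics of the large
  reconstruction toolboxes.
- `per_model_accuracy_delta` prepares paired per-model accuracies; the
  sign-rank test itself is left to standard statistics packages.
- No MILP/QP variants of FBA (parsimonious FBA, loopless FBA) are
  provided.
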