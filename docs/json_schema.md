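# JSON model dialect

The JSON dialect mirrors the in-memory model schema one-to-one and
round-trips losslessly against the SBML writer/reader. One model per file,
a single top-level object:

```json
{
 "schema_version": 1,
 "id": "Azoreducens_toy",
 "objective_reaction": "BIO",
 "taxonomy": {"species": "Azoreducens toy", "strain": "type"},
 "genes": ["azoR", "Azoreducens_toy_b1"],
 "metabolites": [
  {"id": "glc_D", "compartment": "e", "name": "glc_D",
   "formula": {"C": 6, "H": 12, "O": 6}, "charge": 0}
 ],
 "reactions": [
  {"id": "EX_glc_D", "stoichiometry": {"glc_D[e]": -1.0},
   "lower_bound": -1000.0, "upper_bound": 1000.0,
   "gpr": "", "subsystem": "", "kind": "exchange"}
 ],
 "couplings": [["Azo_AZOR_e", "Azo_BIO", 400.0]]
}
```

Field notes:

- `metabolites[].formula`: element→count map, `null` for unknown
  composition. `charge`: integer, `null` allowed (treated as 0 with a
  warning by the balance checks).
- `reactions[].stoichiometry`: keys are metabolite keys
  `<id>[<compartment>]`; values are signed coefficients (negatives =
  substrates). Bounds default to ±1000 when omitted.
- `reactions[].kind`: one of `internal | exchange | demand | sink |
  transport`. When omitted it is inferred from the id prefix (`EX_`,
  `DM_`, `sink_`/`SK_`) and the stoichiometry shape (single-metabolite
  reactions are boundary; multi-compartment reactions are transports).
- `couplings`: optional list of `[reaction_id, biomass_reaction_id,
  factor]` triples enforcing `|v_reaction| <= factor * v_biomass` in every
  LP solved on the model; used by community models, empty for strains.
- Every metabolite referenced by a reaction must be declared; duplicate
  ids are rejected; `objective_reaction` may be `null`.
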