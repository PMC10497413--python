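"""FBA and shadow prices on a minimal glucose-to-biomass chain.

Builds the three-metabolite toy chain (glucose uptake capped at 10
mmol/gDW/h, two glucose per biomass unit), maximises growth, and asks which
metabolite limits the optimum.
"""

from commflux import lp_engine
from commflux.synthetic_data import toy_chain

model = toy_chain()
sol = lp_engine.optimize(model, "BIO", "max")
print(f"maximal growth flux: {sol.objective_value:.3f} /h")
# 5.000: the 10 mmol/gDW/h glucose cap splits two-to-one into biomass

sp = lp_engine.shadow_price(model, "BIO", "max", "glc_D[c]")
print(f"shadow price of cytosolic glucose: {sp.value:+.3f} "
      f"(degenerate: {sp.degenerate})")
# +0.500: one extra unit of internal glucose would buy half a biomass unit —
# glucose is the limiting metabolite

intervals = lp_engine.fva(model, fraction_of_optimum=1.0,
                          objective_reaction="BIO")
print("flux ranges at the optimum (all pinned — a single linear route):")
for rid, (lo, hi) in intervals.items():
    print(f"  {rid:15s} [{lo:7.3f}, {hi:7.3f}]")
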