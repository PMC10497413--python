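"""Community drug-conversion potential and bottleneck species.

Assembles a two-species community splitting the two-step levodopa pathway
(species A decarboxylates levodopa to dopamine, species B dehydroxylates
dopamine onward), computes the conversion potential of the final product,
and identifies the bottleneck species by shadow-price analysis.
"""

from commflux import drug_sim
from commflux.community_builder import assemble_community
from commflux.synthetic_data import (
    standard_drug_modules,
    toy_levo_pair,
    western_diet,
)

a, b = toy_levo_pair()
drugs = standard_drug_modules()
diet = western_diet()

community = assemble_community(
    {"Levoa prima": a, "Levob secunda": b},
    {"Levoa prima": 0.2, "Levob secunda": 0.8})

for product in ("dopamine", "mtym"):
    val = drug_sim.conversion_potential(
        community, drugs["dopa_decarboxylase"], diet, product=product)
    print(f"max fecal secretion of {product}: {val:.1f} mmol/person/day")
# dopamine 80.0 and mtym 80.0: both capped by the first-step species, whose
# reactions may carry at most 400 x (abundance 0.2) x (community biomass 1)

bottlenecks = drug_sim.bottleneck_species(
    community, drugs["dopa_decarboxylase"], diet, product="mtym")
for species, price in bottlenecks:
    print(f"bottleneck: {species} (biomass shadow price {price:+.1f})")
# only the low-abundance first-step species appears: the second step is
# limited by the species carrying out the first step

only_a = assemble_community({"Levoa prima": a}, {"Levoa prima": 1.0})
val = drug_sim.conversion_potential(
    only_a, drugs["dopa_decarboxylase"], diet, product="mtym")
print(f"without the second species the final product is unreachable: {val}")
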