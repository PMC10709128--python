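"""The shortest reactional distance, on one enzyme's neighborhood.

Builds the worked-example pathway (an enzyme converting a substrate into a
product, with further reactions extending one and two steps away) and
queries the SRD of the enzyme against every metabolite, plus the two
non-numeric outcomes.
"""

from srdkit import build_graph, srd
from srdkit.synth import toy_enzyme_neighborhood

g = build_graph(toy_enzyme_neighborhood())
enzyme = "hsa:100"

print("SRD from the enzyme to each metabolite (reaction steps):")
for met, role in [
    ("C00001", "its substrate"),
    ("C00002", "its product"),
    ("C00010", "one reaction before the substrate"),
    ("C00011", "one reaction past the product"),
    ("C00012", "one reaction past the product"),
    ("C00021", "two reactions out"),
]:
    print(f"  {met} ({role}): SRD = {srd(g, enzyme, met)}")

# absence and disconnection are answers, not errors
print(f"  unknown gene hsa:999 vs C00001: SRD = {srd(g, 'hsa:999', 'C00001')}")
print()
print("0 means the metabolite is a direct reactant of the gene's reaction;")
print("each additional reaction step adds 1; NA means not in this graph.")
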