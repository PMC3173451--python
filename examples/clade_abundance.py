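"""Assign environmental sequences to reference clades and estimate abundance.

Builds a tree of reference taxa plus an environmental pool, assigns each
environmental leaf to the order of its nearest reference clade, and runs the
rare-clade abundance arithmetic, including the packaged scaffold
sampling-site table for the oceanic mitochondria-affiliated clade (OMAC).
"""

from mitoscreen import (
    assign_to_reference_clades,
    clade_fractions,
    get_backend,
    overall_abundance,
    packaged_omac_site_table,
    rare_clade_fraction,
    root_with_outgroup,
)
from mitoscreen.screen import category_from_tag
from mitoscreen.simulate import SimConfig, simulate_dataset
from mitoscreen.trees import ENVIRONMENTAL

dataset = simulate_dataset(SimConfig(rng_seed=2, env_pool_size=300))
marker = "RPS2"
ref = dataset.reference_dataset(marker)
env = dataset.environmental_dataset(marker)
aln = {**ref.alignment, **env.alignment}
cats = {i: category_from_tag(t) for i, t in ref.members.items()}
cats.update({i: ENVIRONMENTAL for i in env.members})
tree = get_backend("nj-jc20")(aln, cats)
rooted = root_with_outgroup(tree, [i for i, c in cats.items()
                                   if c.kind == "outgroup"])

fractions = clade_fractions(assign_to_reference_clades(rooted))
for order, pct in sorted(fractions.items(), key=lambda kv: -kv[1]):
    print(f"  {order:<18} {pct:5.1f}%")
print("Percentages are shares of the assigned environmental sequences; the")
print("dominant clade mirrors the simulated SAR11-like profile.")

sites = packaged_omac_site_table()
pct = rare_clade_fraction(len(sites), 566)
print(f"\nOMAC: {len(sites)} of 566 environmental COX1 homologs -> {pct}%")
print(f"Sargasso Sea scaffolds: "
      f"{int(sites.sample_location.str.contains('Sargasso').sum())} of {len(sites)}")
print(f"overall abundance at a 32.5% alphaproteobacterial cell fraction: "
      f"{overall_abundance(pct):.2f}% of all cells")
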