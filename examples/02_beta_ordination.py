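"""Weighted UniFrac, PCoA and PERMANOVA across a three-site gradient.

Builds a synthetic three-site survey with strong site structure,
computes phylogenetic distances on the rarefied table, ordinates them,
and tests the site and habitat factors with a one-factor PERMANOVA
(999 label permutations).
"""

from rhizonet import adonis, pcoa, rarefy, weighted_unifrac
from rhizonet.synthetic import SyntheticConfig, generate_dataset, generate_tree

fungal, _, metadata, _ = generate_dataset(
    SyntheticConfig(n_fungal_otus=120, n_bacterial_otus=80, seed=2)
)
rarefied = rarefy(fungal, seed=2).drop_empty_otus()
tree = generate_tree(rarefied.otu_ids, seed=2)

dm = weighted_unifrac(rarefied, tree)
ordination = pcoa(dm, dimensions=2)
print("PCoA variance explained:",
      [round(p, 3) for p in ordination.proportion_explained[:2]])

for factor in ("site", "habitat"):
    res = adonis(dm, metadata, factor, n_permutations=999, seed=2)
    print(res)
print(
    "\nR2 is the fraction of squared UniFrac distance explained by the "
    "factor; p comes from permuting sample labels."
)
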