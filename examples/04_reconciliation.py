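"""Reconciliation-based accuracy criteria on a toy gene family.

The minimum-duplication count (minimised over gene-tree rootings) and the
average number of implied losses per branch both measure how parsimonious
the duplication/loss history of a gene tree is: all else equal, more
accurate gene trees need fewer events.
"""

from filterbench import Phylotree, SpeciesMap, losses_per_branch, min_duplications

species_tree = Phylotree.parse("((human,mouse),frog);")
mapping = {"h1": "human", "m1": "mouse", "f1": "frog",
           "h2": "human", "m2": "mouse"}
smap = SpeciesMap(mapping, species_tree)

# one ancient duplication, both copies resolved congruently vs a tree that
# wrongly clusters the copies by species (forcing a duplication per species)
congruent = Phylotree.parse("(((h1,m1),(h2,m2)),f1);")
by_species = Phylotree.parse("(((h1,h2),(m1,m2)),f1);")

for label, tree in (("copies resolved congruently", congruent),
                    ("copies clustered by species ", by_species)):
    dups = min_duplications(tree, smap)
    lpb = losses_per_branch(tree, smap)
    print(f"{label}: {dups} duplication(s), "
          f"{lpb:.3f} losses per branch")
print("(the species-clustered tree needs an extra duplication: parsimony "
      "flags it as the worse gene tree)")
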