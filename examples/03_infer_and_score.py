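"""Infer trees from a simulated alignment and score them against truth.

Builds WAG maximum-likelihood pairwise distances, then a neighbor-joining
tree and a variance-weighted least-squares tree (NNI search), and reports
the fraction of wrong splits of each; bootstrap supports are attached to
the NJ tree.  An error of 0 means the inferred topology is exact.
"""

from filterbench import SimConfig, evolve, fraction_wrong_splits, splits_of
from filterbench.inference import (bootstrap_support, nj_tree,
                                   pairwise_distances, wls_nni_tree)

family = evolve(SimConfig(seed=3))
aln = family.true_alignment

dm = pairwise_distances(aln)
nj = nj_tree(dm)
wls = wls_nni_tree(dm, start=nj)

print(f"NJ  fraction wrong splits: {fraction_wrong_splits(nj, family.true_tree):.3f}")
print(f"WLS fraction wrong splits: {fraction_wrong_splits(wls, family.true_tree):.3f}")


def builder(a):
    return nj_tree(pairwise_distances(a))


with_support = bootstrap_support(aln, builder, n_reps=25, seed=0)
sups = sorted(splits_of(with_support).supports.values())
print(f"bootstrap supports (25 reps), lowest five: "
      f"{[round(s, 2) for s in sups[:5]]}")
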