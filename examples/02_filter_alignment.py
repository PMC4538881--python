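"""Run every built-in column filter on one simulated alignment.

Prints, per filter, the fraction of columns removed and the sum-of-pairs
precision/recall of the filtered alignment against the simulated truth:
filtering can only keep precision at 1 here (the input IS the truth), so
the interesting number is how much recall each filter gives up.
"""

from filterbench import (SimConfig, evolve, apply_mask, make_filter,
                         sop_precision, sop_recall, GBLOCKS_RELAXED)
from filterbench.core import EmptyAlignmentError

family = evolve(SimConfig(seed=2))
aln = family.true_alignment

settings = [
    ("unfiltered", {}),
    ("random 30%", {}),
    ("maxgap 30%", {}),
    ("gblocks-like default", {}),
    ("gblocks-like relaxed", {}),
    ("gappyout", {}),
    ("entropy w=3 c=0.9", {}),
]
filters = [
    make_filter("unfiltered"),
    make_filter("random", {"fraction": 0.3}, seed=0),
    make_filter("maxgap", {"fraction": 0.3}),
    make_filter("gblockslike"),
    make_filter("gblockslike", GBLOCKS_RELAXED),
    make_filter("gappyout"),
    make_filter("entropy", {"window": 3, "cutoff": 0.9}),
]

print(f"{'filter':24s} {'removed':>8s} {'precision':>10s} {'recall':>8s}")
for (label, _), fn in zip(settings, filters):
    mask = fn(aln)
    try:
        trimmed = apply_mask(aln, mask)
    except EmptyAlignmentError:
        print(f"{label:24s} {mask.fraction_removed:8.1%}  (everything removed)")
        continue
    p = sop_precision(trimmed, aln)
    r = sop_recall(trimmed, aln)
    print(f"{label:24s} {mask.fraction_removed:8.1%} {p:10.3f} {r:8.3f}")
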