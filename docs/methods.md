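# Methods

`filterbench` measures whether removing alignment columns before tree
inference helps or hurts single-gene phylogenies. Everything runs on
synthetic families with known truth, so every statistic the package
reports can be checked against ground truth or an independent brute-force
computation. This note records the models, conventions and numerical
choices, and what the synthetic data does and does not emulate.

## The assessment tests

**Species-tree discordance.** A gene family of orthologs must, by
definition, follow the species tree. A tree inferred from a (filtered)
alignment is scored by its fraction of wrong splits against the reference
topology: |splits(inferred) \ splits(reference)| / (n − 3), where the
reference is fully resolved. For binary inferred trees this equals the
normalized Robinson–Foulds distance. The normalization is one-sided by
choice: an unresolved inferred branch asserts nothing and therefore counts
as *not wrong* here; loss of resolution is surfaced separately by the
support decomposition (below). This choice is deliberate and documented —
both conventions appear in the literature.

**Enriched variant.** The reference topology is trusted only for a small
core of taxa. The full (enriched) set is aligned, filtered and used for
inference; the inferred tree is then pruned back to the core. Pruning
merges paths into single branches: a merged branch carries the *sum* of
the merged lengths and the *maximum* of the merged supports — a
conservative stand-in for the support of the merged branch. On synthetic
data the core is a uniformly random subset of leaves and the reference is
the true tree restricted to it.

**Support decomposition.** Given a support threshold t, the pruned tree's
splits with support ≥ t are resolved: true positives if present in the
reference, false positives otherwise; reference splits missing from the
resolved set are false negatives. TP + FN = n − 3 always; TP is
nonincreasing and FN nondecreasing in t. Default thresholds: 0.75, 0.9,
0.95, 0.99. Support sources: column-bootstrap split frequencies, or a
branch-length surrogate (branches ≥ a PAM threshold count as resolved —
the boundary is inclusive).

**Reconciliation criteria.** For families with paralogs, LCA
reconciliation against a rooted binary species tree gives (a) the minimum
duplication count over all rootings of the gene tree (a node is a
duplication if its species-LCA equals the species-LCA of one of its
children) and (b) the average number of implied losses per gene-tree
branch at a fixed rooting: for an edge from u to child c, the species-tree
edges strictly between M(u) and M(c) each imply a loss, plus one loss on
the side of a duplication whose copy is absent. Both are topology-only. A
single-rooting mode mirrors pipelines that root once during
reconciliation; the default minimizes over rootings. The exact
loss-counting variant used by production reconciliation pipelines is not
published in detail; the standard LCA-implied count above is adopted.
Multifurcating gene trees are rejected — inference here always returns
binary trees, and resolving polytomies is out of scope.

**Alignment accuracy.** Sum-of-pairs precision is the mean over sequence
pairs of (correctly aligned residue pairs in the test) / (aligned residue
pairs in the test); recall divides by the true alignment's pairs instead.
A pair for which the test alignment asserts nothing contributes fD = 1 to
precision (no assertions, no false assertions) and is flagged so that
averages can exclude it. Column filtering removes residues from the rows,
so filtered alignments carry per-residue provenance (the index of each
residue in the full sequence) through `apply_mask`; identity of residue
pairs is always judged in original-sequence coordinates. The true-column
measure is all-or-nothing on full residue-index columns.

## The simulator

Each family: a birth–death tree on `n_taxa = 30` extant tips with
birth/death ratio 10 (absolute rates are irrelevant after rescaling; λ = 1,
μ = 0.1, conditioned on the tip count via the general sampling approach of
dendropy), rescaled so the maximum root-to-leaf path is exactly
`depth_pam = 250` PAM (100 PAM is the lighter control setting). Root
sequence length is a rounded Gamma(k = 2.78, θ = 133.81) draw (minimum 1,
mean ≈ 372); rounding vs flooring is unspecified upstream — rounding is
adopted. Residues start at WAG equilibrium.

Substitutions follow WAG with the generator normalized to 0.01 expected
substitutions per site per PAM; end states along a branch of d PAM are
sampled exactly from P(Q·0.01d) via a cached spectral decomposition
(validated against `scipy.linalg.expm` and detailed balance). Because end
states are sampled analytically, substitution *events* are not itemized in
the event log; calibration is instead verified empirically (observed
identity on a 100-PAM branch matches the closed form; ML re-estimation
recovers the simulated distance).

Indels are a Poisson process at `indel_rate = 1e-4` events per site per
PAM, with the total rate tracking the *current* sequence length after
every event. Insertions and deletions are equiprobable (the combined rate
is what is specified). Lengths are Zipf(1.821) draws truncated to ≤ 50 by
rejection (renormalized sampling would be equivalent here; rejection is
adopted and tested by a χ² fit). Insertions place new residues (drawn from
equilibrium) at a uniform position, carry no parental homology, and keep
substituting for the rest of the branch; insertions into previous
insertions are allowed. Deletions start at a uniform site and truncate at
the sequence end (the realized length is logged). Homology is threaded
through a global column order, so the true alignment is exact by
construction; stripping its gaps reproduces the emitted sequences
byte-for-byte. The event log records every indel with branch, time and
position, and per-branch site·PAM exposure is accumulated exactly from the
process trajectory — total events / total exposure is an unbiased rate
estimate used by the fidelity checks.

All randomness flows from one seeded generator per family; campaign
family seeds are `campaign_seed + index`.

**What the generator does not emulate:** rate heterogeneity across sites,
domain structure, compositional drift, nucleotide data, alignment-length
biases of real ortholog sets. Passing tests show the *machinery* is
correct and reproduce the direction of the filtering effects at the
stated simulation conditions; they do not certify effect sizes on real
data.

## Filters

All filters are pure functions of (alignment, parameters, seed) returning
a boolean keep-mask; removal counts use round-half-away-from-zero.

- **random(fraction)** — drops exactly round(fraction·ncols) columns,
  uniformly without replacement.
- **maxgap(fraction)** — drops the round(fraction·ncols) columns with the
  highest gap fraction; ties prefer dropping the rightmost column.
- **gblockslike** — the six-step block filter: classify columns
  (nonconserved / conserved / highly conserved), remove long nonconserved
  runs (> 8), trim blocks to highly conserved flanks, drop blocks < 15,
  remove disallowed gap columns plus adjacent nonconserved stretches, drop
  blocks < 10. The published prose omits the numeric class boundaries; the
  original tool's conventions are adopted and exposed as parameters:
  conserved = majority residue in > N/2 sequences (floor(N/2)+1), highly
  conserved = ≥ 0.85·N, and gap policies "none" (any gap disqualifies),
  "with half" (> 50% gaps disqualifies), "all". The relaxed preset
  (flank = 9 sequences, runs ≤ 10, min block 5, "with half") presumes
  ~30-sequence alignments; with fewer than 9 sequences it is degenerate by
  construction.
- **gappyout** — candidate thresholds are the distinct column gap
  fractions; the proportion-removed curve over sorted thresholds is
  nonincreasing and the threshold at its largest discrete drop is chosen,
  ties resolving to the smaller threshold (removes more, matching the
  method's intent); columns strictly above it are dropped. This follows
  the published description, not the tool's internal refinements.
- **entropy(window, cutoff)** — per-column Shannon entropy of non-gap
  residues normalized by log(alphabet size); gap-only columns score 1.
  Smoothing is a centered moving average of odd width, truncated at the
  edges; columns with smoothed score strictly above the cutoff drop.
- **external adapter** — writes FASTA, runs any trimming tool, and maps
  its output back to columns either from a kept-index report or by
  in-order exact matching of trimmed columns.

These "-like" variants are faithful to the published *descriptions*; they
are not byte-level reimplementations of the binaries.

## Inference

Amino-acid pairwise distances are ML under WAG on the pairwise shared
(both non-gap) sites: the log-likelihood Σ C_ab log P_ab(d) is maximized
by a bracketed scalar search on [1e-8, 1000] PAM (coarse log-grid, then
golden-section to ~1e-6 relative width), vectorized over all pairs.
Saturated pairs cap at 1000 PAM with a warning; identical sequences get
distance 0. Nucleotide alignments use the Jukes–Cantor correction.
Variances for weighting use v ∝ d² with a small floor (1e-4 PAM) — the
exact variance model of the original weighted least-squares implementation
is not published; this standard proportional-error form is adopted and
parameterized.

Topologies come from neighbor joining (scikit-bio; negative branch
lengths clamped to zero), optionally refined by variance-weighted
least-squares NNI search: branch lengths by nonnegative weighted least
squares on the path matrix, deterministic edge sweep, first-improvement
acceptance, re-sweeping until a pass makes no change. The search never
returns a worse loss than its start tree and matches an exhaustive
105-topology scan on ≥ 95% of perturbed-additive 6-taxon inputs (tested).

Built-in branch support is the column-bootstrap split frequency (the
approximate-Bayesian supports of external ML tools live behind the
adapter; campaign reports name their support source). The branch-length
surrogate (thresholds 0.1 / 1 / 2 / 5 PAM) is provided for
support-measure robustness checks.

## Campaigns and aggregation

Per family × filter setting the campaign records fraction removed,
fraction wrong splits, optional TP/FP/FN per threshold, and alignment
precision/recall. A family in which *any* filter empties the alignment
(or any stage fails) is excluded from the aggregates of *all* settings —
strict intersection, so every comparison stays paired. Summaries report
mean ± SEM over families, the two-sided paired Wilcoxon p versus the
mandatory unfiltered control (zero differences dropped; all-zero
differences give p = 1) with significance at α = 0.01 and *no*
multiple-testing correction (stated in the output docs), the fraction of
families improved/unchanged/worsened, and %-removed vs error curve points
(linear interpolation between grid points is the intended rendering).
Campaign state is file-based per family, so interrupted campaigns resume
idempotently; regenerating a summary from the stored record table is
deterministic.

## Problem sizes

The shipped checks use desk-scale sizes chosen to exercise the full
pipeline: 25 realigned families for the alignment-accuracy level, 100
families for indel-rate recovery, 10,000 draws for the length law, 200
families for the random-removal campaign, 100 trials for the 6-taxon
search oracle, and all 1,065 gene-tree topologies with ≤ 7 leaves for the
reconciliation oracle.

## Aligner

The realignment step uses mafft G-INS-i (`--globalpair --maxiterate
1000`) by default: simulated families are homologous over their whole
length, the setting mafft documents that mode for. Any other aligner can
be plugged in as a `seqs -> Alignment` callable. Note that aligner
families differ systematically in their precision/recall trade-off at
high divergence: conservative phylogeny-aware aligners leave uncertain
regions unaligned and so score higher sum-of-pairs precision (and lower
recall) than aligners that place every residue; results of
alignment-accuracy comparisons must be read relative to the aligner used.

## Known limitations

- Amino-acid simulation only; the nucleotide pathway is limited to
  Jukes–Cantor distances on externally provided alignments.
- No site-rate heterogeneity in the simulator or the distance model.
- LCA reconciliation assumes a correct, binary species tree and rejects
  multifurcating gene trees.
- Bootstrap support on distance trees is a pragmatic built-in; it is not
  numerically comparable to approximate-Bayesian ML supports.
- The WLS+NNI search is exact only in the sense of the tested 6-taxon
  oracle; larger trees get a local optimum.
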