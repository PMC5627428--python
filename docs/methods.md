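# Methods

This note documents the models, conventions and numerical choices behind
famkit, in the order a family analysis uses them.

## Trees, I/O and the species map (`treecore`)

All trees are rooted; the unrooted reading exists only inside
Robinson–Foulds computations. Parsing is delegated to dendropy and
converted to a lightweight node structure. Conventions, chosen to match
the output of the Bayesian/reconciliation programs whose files this
package consumes (BEAST, \*BEAST, ALE, TreeAnnotator):

- quoted labels supported; underscores literal (never blanks);
- `[...]` comments dropped;
- a numeric internal-node label is read as a support value when no
  explicit support exists;
- unary internal nodes are suppressed on read, branch lengths summed;
- an absent branch length means "no information" and is never treated
  as 0; zero lengths are permitted on input (the simulator rejects them,
  see below).

Posterior samples are newick lists (one tree per line) or NEXUS trees
blocks with an optional Translate table. Burn-in is a *fraction of trees*
(files carry trees, not generation stamps): the first ⌊b·N⌋ trees are
excluded, and the remainder must share one leaf set.

The gene-leaf → species rule is deliberately configurable (table TSV,
delimiter field, or single-group regex) because upstream databases do not
agree on an identifier scheme; unmapped leaves either raise or are pruned
(`on_unmapped`).

## Species overlap and splitting (`orthosplit`)

For each internal node, child species sets are computed bottom-up; the
overlap set contains species occurring in ≥ 2 children (this is also the
multifurcation rule — species in at least two children — chosen over
resolving multifurcations to binary, which would make events depend on an
arbitrary resolution order). Overlap score = |overlap| / |union|. A node
is a duplication when score > threshold, *strictly*; at the default
threshold 0.0 this is equivalent to "any non-empty overlap".

A *paralog-generating* node additionally has |overlap| ≥ `min_common`
(default 2). The default ignores species-specific duplications — nodes
overlapping in a single species — which reflect recent lineage-specific
expansion; flagging them would fragment families into many tiny sets and
pack no additional cross-species signal. `min_common=1` reduces exactly
to plain SO duplication detection.

Splitting dissolves each flagged node: its child subtrees become
independent trees and the forest partitions the leaf set. Flags are
detected once on the whole tree; because a node's SO events depend only on
its descendants, dissolving an ancestor cannot create or remove a flag
inside a released piece, so a single pass equals iterated re-scanning.
Note the piece count: a dissolved *root* yields its children only (k
chained root dissolutions give k+1 pieces), while a dissolved internal
node yields its children *plus* the residual tree around it.

`graft_orthologs` is the inverse: a re-estimated ortholog tree replaces
the child of its original split node whose leaf set matches exactly,
keeping the backbone's attachment branch length. Leaf-set mismatches are
errors, never coerced.

## Duplication-aware family nRF (`treedist`)

RF is computed on the unrooted interpretation (standard definition; the
root's artificial split is merged), with max RF = |B₁| + |B₂| — the
normalization that reduces to 2(n−3) for binary trees. Pairs sharing
fewer than 4 leaves have no non-trivial splits and are *skipped*, excluded
from averages but counted in the report; RF below 4 common leaves is
degenerate and reporting 0.0 silently would bias means toward agreement.

The family-level statistic runs: extract ortholog sets (min_common = 2) →
decompose each ortholog tree at every remaining SO duplication
(threshold 0.0) into single-copy subtrees, leaves relabelled to species →
nRF of each subtree against the species tree restricted to common
species → mean per ortholog tree over non-skipped subtrees → unweighted
mean of the per-ortholog means. The unweighted mean makes each ortholog
tree count once regardless of how many subtrees it shattered into; the
pooled mean over all subtrees is reported alongside as a secondary
figure. When every subtree is skipped the overall mean is undefined and
flagged, not zero.

## LCA reconciliation (`reconcile`)

M(v) is the species-tree LCA of the images of v's children (leaves map to
their species). v is a duplication iff M(v) equals a child's image.
Losses use the classic depth convention, implemented site-by-site: walking
the species path M(v) → M(c), every path node where the lineage is
committed to one daughter charges one loss to each off-path daughter
branch (all path nodes for a duplication, all but M(v) for a speciation).
For a binary species tree this totals depth(M(c)) − depth(M(v)) − [v is a
speciation]; at a multifurcating species node every off-path daughter is
charged, the natural generalization. Duplications are attributed to the
branch above M(v).

Species present in the species tree but entirely absent from the family
are reported as a separate "absent species" list rather than converted
into path losses: whole-genome absence of a family member cannot be
dated onto a branch by LCA mapping alone (it needs an assumption of
presence at the family root), so the two kinds of evidence are not mixed.

SO and LCA duplication sets differ by design (LCA is more inclusive); the
guaranteed relation, covered by tests, is that every SO duplication is
also an LCA duplication — shared species force M(v) = M(child).

## MCC summarization (`treesample`)

Clades are *rooted* leaf sets (TreeAnnotator semantics, matching rooted
BEAST samples), counted over post-burn-in trees. The MCC tree is the
sampled tree maximizing Σ log(clade frequency) — always a member of the
sample, never a consensus construction; ties break to the earliest sample
index. Supports are clade frequencies. Mean clade heights (mean MRCA
height over the trees containing the clade) are annotated only when every
sampled tree is ultrametric (relative tolerance 1e-6); the default
burn-in in the CLI is 0.1.

## Simulator (`famsim`)

A linear birth–death–transfer process per gene lineage in species-tree
time, root → tips. Waiting times are Exp(λ_d + λ_l + λ_t) per lineage;
a duplication splits the lineage in place, a loss terminates it, a
transfer copies it onto a branch drawn uniformly among branches
co-existing at that moment, donor excluded (uniform recipients, not
rate-weighted flows — sufficient for generating test fixtures and stated
here explicitly). At species nodes every surviving lineage enters both
daughters. Root copies (default 1) start at the species root itself; no
stem branch is modelled. Transfers require an ultrametric tree (absolute
tolerance 1e-6 on tip times) because co-existence is a statement about
absolute time; branch lengths must be strictly positive. Rates are per
lineage per unit branch time.

The default fixture is a balanced ultrametric 8-species tree of height 1
(splits at times 0, 0.35/0.45, and shallower; total length 4.15), small
enough for exhaustive checking yet deep enough that duplications land on
both internal and pendant branches.

Ground truth: every event is logged with time, species branch, gene node
id and (for transfers) recipient; the full tree retains extinct lineages;
node ids survive pruning, so an internal node of the observable tree can
be traced to the event that created it. What the simulator does *not*
emulate: sequence evolution (no alignments anywhere in the package),
among-family rate variation, and incomplete lineage sorting — so passing
recovery tests demonstrates correctness of the detectors under the DL(T)
model, not robustness to coalescent discordance or inference error in the
input trees.

Moment check: with pure duplication, E[N(t)] = N₀·e^{λ_d t} along a
branch and the expected duplication count is Σ_branches N₀(e^{λ_d L} − 1),
computed by forward recursion; the simulated mean over 2000 replicates is
required to sit within 3 standard errors.

## Detection performance metrics

On simulated families (λ_d = 0.1, λ_l = 0.05, λ_t = 0, 500 replicates, the
stock 8-species tree), paralog-generating-node detection is scored as:

- **precision** over flagged nodes: a flagged node must be a true logged
  duplication (the suite requires zero false positives);
- **recall** over the detector's *target class*: duplications on internal
  species branches, i.e. those whose copies can reach two or more species.
  A `min_common=2` detector is by construction blind to species-specific
  duplications (the single-species overlap it deliberately ignores), so
  they are excluded from the denominator; within the target class the
  only misses come from losses erasing one copy's descendants. Recall
  over *all* logged duplications is reported alongside for transparency
  (roughly the fraction of tree length on internal branches, ~0.4 on the
  stock tree).

## Problem sizes and determinism

Exhaustive checks enumerate all binary unrooted topologies on 5 and 6
leaves (15 and 105; all ordered pairs) and all rooted shapes up to 7
leaves over 4 species (11 464 trees). Simulation-based checks use 100
(null pipeline), 500 (duplication recovery) and 2000 (moments)
replicates. All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; replicate i of a batch is seeded with
`[seed, i]`, making every figure bit-reproducible.

## Known limitations

- The splitter is the SO/paralog-generating criterion; strict
  topology-based reconciliation is available for event inference
  (`reconcile`) but is not used as the primary splitter.
- No branch-length-aware distances (weighted RF, KC); no
  duplication-penalized TreeKO variants.
- No transfer-aware reconciliation: transfers exist in the simulator's
  event vocabulary, but LCA reconciliation interprets a transferred
  family as duplications/losses, as any DL model must.
- MCC node heights are summarized only for fully ultrametric samples; no
  HPD intervals.
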