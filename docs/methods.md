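# Methods

## Stratigraphic congruence

All stratigraphic quantities derive from first appearance data (FADs) in
Ma, larger = older; last appearances are carried for range reporting but
never enter any congruence statistic. A node's minimum age is the oldest
FAD among its tip descendants, so ages never decrease toward the root and
the root carries the oldest FAD overall. The ghost lineage on a branch is
`age(parent) − age(child)` ≥ 0; their sum is the minimum implied gap
(MIG). Gmin = oldest − youngest FAD is the minimum of MIG over all
topologies (the pectinate tree with taxa nested youngest-inward attains
it; the test suite verifies the identity by brute force over every rooted
binary topology on up to six taxa). Gmax = Σ(oldest − FAD) over non-oldest
taxa is attained when the oldest taxon is maximally nested. The gap excess
ratio is GER = 1 − (MIG − Gmin)/(Gmax − Gmin), undefined when all FADs
coincide (raised as an explicit error, never returned as NaN).

GER is invariant to adding a constant to all FADs and to rescaling them by
a positive factor, and to child order and tip relabelling; these are
property-tested. Polytomies are hard: each child is dated against the
polytomous parent. The soft alternative (`resolve_polytomy_min_mig`)
replaces each polytomy by the pectinate resolution of its children ordered
by descending subtree age, oldest outermost. For any one polytomy this is
provably optimal — the connecting ghost lineages telescope to (oldest
child age − youngest child age), a lower bound for every resolution — and
the suite confirms it against exhaustive enumeration of all resolutions
for up to five children. Age ties are broken by the lexicographically
smallest descendant tip label so output is deterministic.

`compare_topologies` prunes each hypothesis to its own intersection with
the occurrence table (and an optional scope), computes Gmin/Gmax on each
tree's surviving taxa, and reports per-row taxon counts so rows with
different coverage are not compared naively. Published maximum-age
constraints on clades are realized implicitly: a clade's age is the oldest
FAD of its members, so constraining a clade by a taxon is the same as
including that taxon as a tip.

## Parsimony scoring

Character lengths use generalized (Sankoff) dynamic programming with unit
step costs for unordered characters and |i − j| for ordered ones; the
recursion handles polytomies natively. A tip costs 0 for any state in its
state set: polymorphic cells are scored any-of (the common morphological
default; the all-of alternative used by some programs can differ by a few
steps on the same data, a known divergence risk), and missing (`?`) and
gap (`-`) cells cost 0 everywhere. The gap symbol is treated as missing
throughout, the conventional reading for morphological matrices. For
ordered characters the DP state space is the full integer range between
the observed minimum and maximum, since optimal internal states can be
intermediate; for unordered characters observed states suffice.

Per-character extremes: minimum conceivable steps `m` is, for unordered
characters, one less than the smallest set of states hitting every scored
cell (exact search over state subsets in increasing size), and for ordered
characters the width of the narrowest state interval hitting every cell.
The maximum `g` is the character's length on the star tree, evaluated
exactly by minimizing over root states. A character with g = m cannot show
homoplasy on any tree and is flagged uninformative.

Ensemble indices follow the standard definitions (CI = Σm/Σs,
RI = (Σg−Σs)/(Σg−Σm), HI = 1−CI, RC = CI·RI). Uninformative characters
always realize s = m = g and are excluded from the RI sums (they
contribute 0/0); they are *included* in CI/HI by default, with a flag to
exclude them — published CI and HI values are frequently reported under
different inclusion rules, and printed pairs that violate HI = 1 − CI are
a recognized symptom, so both conventions are exposed. A
`reported_length` argument substitutes a published total length for Σs,
allowing indices to be recomputed exactly as printed alongside a published
tree length without rescoring the (possibly unavailable) optimal trees.

An unambiguous synapomorphy of a clade is a character whose every
minimum-cost reconstruction places a change on the clade's subtending
branch. Membership is decided exactly: with down-vectors A[v][s] (subtree
cost given v = s) and out-vectors Out[v][s] (cost of everything outside
v's subtree including the branch to its parent), the branch carries a
change in some optimal reconstruction-free labelling iff constraining its
endpoints equal leaves the optimum unchanged; if the constrained optimum
is strictly larger, the change is unavoidable. Note that without an
outgroup the root state itself can be ambiguous, in which case a
two-state split across the root can legitimately fail the test — scoring
matrices should include the outgroup used to root the tree.

## Ancestral areas

Tips are restricted to a single continent-level area (by convention, where
the taxon's oldest material was recovered) and represented as indicator
distributions over the closed-world area set. Internal distributions are
computed tip to base; the default rule is the equal-weight arithmetic mean
of the children (1/k per child at a k-furcation). This is the unique rule
that arises from enumerating equiprobable child-area scenarios with the
elementary multiplication and addition rules, and on binary trees it
produces dyadic probabilities k/2^d — consistent with printed values such
as 75% and 62.5%. The rule sits behind a single function; a
normalized-product alternative (with mean fallback when child supports are
disjoint) is exposed for sensitivity reporting. No dispersal matrix,
adjacency, or rate model is assumed, and fossil and extant tips are
treated identically. Focal clades resolve to the MRCA of their tip sets;
on consensus trees the MRCA may contain extra tips, which triggers a
warning rather than an error because strict monophyly checks are brittle
there.

## Synthetic data

`simulate_tree` draws Yule (pure-birth) topologies: starting from two
lineages, a uniformly chosen extant tip is bifurcated until the requested
tip count. Every generator derives a fresh `numpy` Generator from
(seed, salt) per call, so identical configs are bit-reproducible and no
global state is touched.

`simulate_fads` steers expected congruence. At `congruence = 1` it builds
an assignment whose GER is exactly 1 on any topology: ages strictly
decrease along one root-to-tip spine and all tips of each off-spine
subtree tie at their attachment age, so ghost lineages telescope to Gmin.
The ties are essential, not cosmetic: a balanced four-tip tree with four
distinct FADs provably cannot attain GER = 1 (brute-forced in the suite).
At `congruence = 0` one "donor" tip per lowest internal node carries the
oldest age, forcing every internal node to the oldest age, which makes
MIG = Gmax exactly. In between, a continuous dose (1 − c)·|donors| of
promotions toward the oldest age (the fractional remainder promoting one
donor partway) moves MIG smoothly between the extremes; a promotion is
skipped if it would leave fewer than two tips younger than the oldest age
(where GER is undefined). Under this design the rank correlation between
the knob and recovered GER across 200 sixteen-tip trees is ≈ 0.81–0.83.

`simulate_characters` evolves unordered k-state characters by a symmetric
change process: each branch carries a Poisson number of events with total
expectation `change_rate` per character, each event moving to a uniformly
chosen different state. True change counts are recorded so tests can
assert parsimony length ≤ true changes. Missing data and one-extra-state
polymorphisms are injected per cell at configurable probabilities.
`simulate_tip_areas` draws a root area and switches per branch with fixed
probability. Defaults (16 tips, 100 characters, 3 states, 2 expected
changes per character, two areas, 10% switch probability, root age 100 Ma)
are sized like a small morphological dataset.

What the generators do *not* emulate: fossilized-birth-death sampling,
preservation biases, correlated characters, ordered-character evolution,
or geographically structured diversification. Passing tests therefore
demonstrate correctness of the statistics and the recoverability of
controlled structure, not realism of any particular empirical dataset.

The packaged marine-turtle example encodes four published arrangements of
americhelydian lineages and a 13-taxon occurrence table. Each record
carries a provenance flag: `published` where a published statement fixes the
value, `illustrative` for stand-ins consistent with the fossil record
(anchored to published relative statements such as the ~30 Myr gap between
the oldest protostegid and the oldest non-protostegid total-group sea
turtle). The fixture demonstrates and tests the machinery; it is not an
authoritative occurrence compilation.

## Numerical and I/O choices

Ages and steps are floats; MIG equals the sum of its per-branch
decomposition to 1e-9. Newick/NEXUS parsing is delegated to dendropy and
converted into this package's light tree/matrix types with added
validation (unique non-empty tip labels, unary-node collapse, ragged-row
detection). Branch lengths in input trees are ignored: every age here
derives from occurrence data. `?` expands to the observed state universe
of its character ({0} if no taxon is scored, keeping cells non-empty);
character indices are 1-based in every user-facing API ("ch. 203" style);
taxon matching normalizes whitespace to underscores. Ordered characters
are supplied as a sidecar list of indices rather than parsed from
ASSUMPTIONS blocks, whose dialects vary too much to interpret reliably.
Problem sizes in the test suite (exhaustive enumeration up to six tips,
four states, five-child polytomies; 10,000 randomized DP instances; 1,000
congruence-extreme cases; 200-seed recovery runs) were chosen so exact
brute-force oracles remain feasible while covering every code path.

## Known limitations

No tree search, branch support, or Bayesian inference — trees are inputs.
Only unordered and linearly ordered characters (no arbitrary step
matrices). Only the GER among congruence indices (no SCI/RCI/MSM*), and
no randomization significance test for it, though `permute_fads_null`
supplies the permutation machinery. Area estimation is the averaging rule
only — no DEC/DIVA-style model — and the report surfaces all candidate
nodes rather than adjudicating which node a published figure meant when
clade boundaries are ambiguous.
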