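# Methods

## The fabric representation

netweave draws a network on a fixed square grid: every node is a horizontal
line segment occupying its own row, every drawable edge copy a vertical
segment occupying its own column, with a small square at each edge endpoint
and an arrowhead at the target row of a directed edge. A layout is therefore
nothing more than two bijections — node → row (1..n) and link copy → column
(1..E) — and can be persisted losslessly as two plain-text order files.
Because row pitch equals column pitch, the slopes of the fabric's upper and
lower boundaries are directly interpretable: a lower boundary at 45° means
every new column consumes a new row (each edge introduces a new node); a
flat stretch means edges are landing on already-visited nodes.

## Default layout

Node rows come from a breadth-first traversal in which neighbors are
visited in decreasing-degree order:

1. the highest-degree unplaced node seeds the next free row (so components
   are entered in order of their maximum-degree node, and degree-0 nodes
   sink to the bottom);
2. each placed row, in order, appends its still-unplaced neighbors sorted
   by decreasing degree;
3. when the walk runs past the last placed row, the next seed is taken.

All edges are treated as undirected; duplicate relations between the same
endpoints count once toward degree; a self-loop counts one. Every tie is
broken by byte-wise lexicographic node-name order, applied uniformly at
seeding and at neighbor expansion. The implementation is validated against
an independently written queue-based oracle on random graphs.

Edge columns are then assigned by scanning rows top to bottom and filling
each node's *zone* — the contiguous block of columns it owns:

* **standard mode**: a node owns every link whose upper (smaller-row)
  endpoint it is; width E = e.
* **shadow mode**: every link is first duplicated with a `shdw`-prefixed
  relation; the real copy stays with the upper endpoint, the shadow copy
  goes to the lower endpoint, so each zone holds the node's complete
  incidence inventory and the width doubles. The real copy always lands in
  a strictly smaller column than its shadow.

Within a zone, copies are bucketed by distal (far-endpoint) row, buckets in
increasing row so shorter links come first; within a bucket, relation
labels order copies lexicographically, a real copy precedes its shadow, and
for a directed pair sharing a relation the downward link precedes the
upward one. Self-loops are a boundary case the ordering rules do not fix on
their own: we place them in the first bucket of their zone (one column in
standard mode; real then shadow copies adjacent in shadow mode). In shadow
mode the single bucket-by-distal-row rule automatically puts a zone's
shadow block (upward links) left of its real block; only the per-link
real-before-shadow relation is fundamental — the within-zone arrangement is
this package's convention, and pixel parity with other tools is not a goal.

With link groups active, each zone is first partitioned by the group of
each copy's *base* relation (matching an ordered list of suffix tags;
shadow prefixes are ignored so a copy pair stays together), and all the
ordering above applies within each group.

## Connectivity layout

Every linked node pair gets a similarity coefficient computed once from the
static network, direction and duplicate relations collapsed:
cosine, |N_j ∩ N_m| / √(|N_j||N_m|) on 0/1 connectivity vectors, or
Jaccard, |N_j ∩ N_m| / |N_j ∪ N_m| on distinct-neighbor sets. Both are
symmetric and lie in [0, 1]; a node is in its own neighbor set only when
self-looped.

Placement grows a list P from the front F (unplaced nodes adjacent to P).
Pure greedy — always take the best front coefficient — abandons a richly
interconnected run whenever a marginally better edge appears elsewhere, so
the walk is made sticky by an ordered chain of the r most recently used
placed nodes and a threshold fraction t ∈ [0, 1]: if the best front edge
overall has coefficient S_b (from placed node A) but some chain node C
reaches the front with S_d > S_b·t, C's candidate is placed instead. A
chain win moves C to the chain head and inserts the new node behind it; a
global win empties the chain and restarts it as [A, new]; the chain is then
trimmed to r. At t = 1 the chain can never win and the layout reduces to
greedy placement (asserted against an independent greedy oracle).

Decisions where the procedure is underdetermined, resolved once here:
seeds (initial and per component) are the highest-degree unplaced node with
lexicographic ties, consistent with the default layout; after a global win
the freshly emptied chain receives A in slot 1; equal-coefficient front
candidates resolve to the smallest node name, equal chain candidates to the
most recently used chain member; coefficients are static (not recomputed
during placement); one coefficient is shared by all parallel relations of a
pair. Defaults r = 20, t = 0.9 make stickiness visible on clustered
networks while still letting clearly better front edges win; both are
exposed on the CLI. Edge columns reuse the standard column assignment — a
layout is just the two orderings, and only the node order differs.

## Subset views

A selection is seeds + their neighbors + every link copy incident on at
least one seed (both copies in shadow mode); neighbor–neighbor links
touching no seed are excluded. Compression renumbers the selected rows and
columns densely while preserving relative order, so the subset is an
order-isomorphic window onto the full layout; zone ownership is inherited,
never recomputed. With duplicate dropping active (shadow layouts), each
link keeps exactly the copy residing in a seed node's zone — the real copy
for a seed's downward links, the shadow copy for its upward links, the real
one when both endpoints are seeds. This reading of "discard the leftmost
true and rightmost shadow copies" keeps every seed's inventory intact while
halving duplication; it is recorded here because other interpretations are
defensible. One level of subset nesting is supported.

## Rendering

Scenes are resolution-independent draw lists (O(n + E) primitives) built on
the square grid; SVG output is byte-deterministic (fixed float formatting,
one XML element per primitive), and PNG output is drawn at 2× and
downsampled with a Lanczos filter for antialiasing — essential because the
fabric is many tightly spaced parallel lines. The 32-color cycle is
generated programmatically: 32 evenly spaced hues, a light high-lightness
variant for node lines keyed by row and a dark low-lightness variant for
edge lines keyed by column, the dark variant always lower in luminance so
edges float in front of nodes. The specific color values are this package's
own. Zone shading alternates pale blue `#E6EEF8` and pale pink `#FAE6EE`.
Glyph proportions: endpoint squares 0.5 cell, arrowheads 0.6 cell, labels
0.8 cell anchored at the zone's right terminus. Node segments are padded
0.45 cell per side so single-column extents remain visible; lone nodes get
a one-cell stub left of column 1; self-loops a short vertical tick with one
endpoint square. There is no tile cache: a raster call above a 64-megapixel
budget fails with a clear message rather than thrash.

## Synthetic data

The generators emulate the two qualitative extremes the fabric makes
visible, at the sizes used throughout the shape analysis:

* `er_gnm(n, m, seed)` — uniform G(n, m) via networkx, relation `ee`,
  zero-padded node names so lexicographic and numeric order coincide.
  At n = m = 10^4 (mean degree 2) roughly 13–14% of nodes are isolated and
  the default layout's lower boundary runs just under the 45° limit
  (measured ≈ 41°).
* `ba_graph(n, m_per_step, seed)` — preferential attachment where vertex i
  joins min(m_per_step, i−1) distinct earlier vertices with probability
  proportional to degree + 1 (the +1 keeps isolated early vertices
  reachable; the exact kernel is a package decision — only seed-internal
  determinism and the closed-form edge count Σ min(m, i−1) are
  contractual). At n = 2000, m = 6 this yields exactly 11,979 edges and the
  characteristic sawtooth of shrinking edge wedges (zone width vs row:
  Spearman ρ < −0.5 on every tested seed).

These graphs have none of real interactomes' relation multiplicity,
directionality or annotation structure; passing on them demonstrates the
layout algebra (bijections, zone structure, order isomorphisms) and the
shape phenomenology, not biological fidelity. Canonical 3–5-node fixtures
(path, star, triangle, triangle+pendant, two components, multi-relation
pair) carry the exact hand-worked expectations.

One note on the sawtooth statistic: a *negative* zone-width/row rank
correlation is not by itself diagnostic of scale-freeness — sparse G(n, m)
layouts show a comparable trend, because late rows own few forward links
under any breadth-first order. The distinctive scale-free signature in the
fabric is the heavy-tailed wedge-size distribution (asserted separately via
maximum-degree dominance over density-matched G(n, m) graphs); the
correlation test asserts only the decay trend.

## Numerical and format choices

* Rows and columns are 1-based everywhere, in files and API.
* SIF lines containing a tab split on tabs only; otherwise on whitespace
  runs (tolerant fallback for hand-written fixtures). Two-field lines are
  errors with line numbers; single tokens declare lone nodes.
* Undirected duplicate orientation canonicalizes to the lexicographically
  smaller endpoint first — a convention, chosen once.
* Directedness is declared per relation label at import; default
  undirected.
* Order files are UTF-8, LF newlines, link keys `source (relation) target`
  with the shadow prefix visible; reading enforces bijectivity and
  completeness with errors naming the offender.
* All tie-breaks are byte-wise ordinal string comparisons; nothing in the
  pipeline consults a random source except the two seeded generators.

## Known limitations

* Interactive navigation (magnifier, overview, touring), tile-cached
  rendering and session formats are out of scope; the artifact is a
  library + batch CLI.
* The front scan in the connectivity layout is O(|P|·|F|) per step in the
  worst case; it is meant for the desk-scale networks the tests use, not
  for 10^6-edge inputs.
* Link keys are ambiguous if node names themselves contain ` (relation) `
  patterns; keys are matched exactly against the network so round trips
  are safe, but hand-edited order files must use the canonical spelling.
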