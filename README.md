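# netweave

Fabric-style visualization layouts for large biological networks.

Conventional node-link diagrams of interactomes, regulatory networks and
association networks collapse into hairballs beyond a few hundred edges.
netweave implements the alternative fabric representation: every node is a
**horizontal line** in its own row, every edge a **vertical line** in its
own column, on a fixed square grid. A layout is then just two bijections —
node → row (1..n), edge copy → column (1..E) — which makes large networks
scannable as a linear catalogue, makes node connectivity visible as compact
*edge wedges*, and makes the fabric's outline (e.g. the slope of its lower
boundary) an honest readout of global network structure.

The package is a library plus a thin batch CLI, aimed at computational
biologists who want reproducible, scriptable network figures and at anyone
studying vertex-ordering methods. It provides:

* **Default layout** — breadth-first traversal from the most connected
  component, neighbors visited in decreasing-degree order, all ties broken
  lexicographically; edge columns filled per-node-zone, shortest links
  first.
* **Connectivity layout** — orders nodes by neighborhood similarity
  (cosine or Jaccard on 0/1 connectivity vectors) using a sticky-chain
  walk with chain size r and threshold t, producing long runs of
  similarly-wired nodes.
* **Shadow links** — every edge duplicated (relation prefixed `shdw`) so
  each endpoint's zone carries its complete incidence inventory; the
  fabric's width doubles.
* **Link groups** — ordered relation-suffix tags that partition each zone
  into side-by-side sub-wedges, for comparing conditions edge-by-edge.
* **Subset views** — first-neighbor selections compressed into a
  sub-layout that preserves all relative row/column order.
* **Plain-text persistence** — SIF import (Cytoscape simple interaction
  format, with node-attribute files), and node/link order files that round
  trip any layout exactly, so externally computed orderings (cluster
  assignments, etc.) can drive the fabric.
* **Deterministic rendering** — SVG (byte-identical across runs) and
  antialiased PNG, with the 32-color repeating cycle, endpoint squares,
  arrowheads, node labels and optional blue/pink zone shading.
* **Seeded generators** — Erdős–Rényi G(n, m) and Barabási–Albert
  preferential-attachment networks plus canonical hand-checkable fixtures,
  so everything is testable offline.

## Worked example

Generate a 200-node scale-free network, lay it out with shadow links, and
render it:

```
$ netweave gen --kind ba --nodes 200 --m-per-step 2 --seed 7 -o ba.sif
INFO netweave: wrote ba.sif: 200 nodes, 397 links
$ netweave layout ba.sif --shadows -o ba
INFO netweave: loaded ba.sif: 200 nodes, 397 links
INFO netweave: layout default: 200 rows, 794 columns in 0.006s
INFO netweave: wrote ba.noa and ba.eda
$ netweave render ba.sif --node-order ba.noa --link-order ba.eda \
      --shadows --shading -o ba.svg
INFO netweave: rendered ba.svg (217858 bytes) in 0.010s
$ head -4 ba.noa ba.eda
==> ba.noa <==
Row
n002 = 1
n005 = 2
n003 = 3

==> ba.eda <==
Column
n002 (ee) n005 = 1
n002 (ee) n003 = 2
n002 (ee) n017 = 3
```

Reading the numbers: the 397 imported links become 794 columns because
shadow mode duplicates every edge; node `n002` (the highest-degree hub)
takes row 1, and its zone opens at column 1 with its shortest link (to the
row-2 node `n005`) first. The same pipeline is available in-process:

```python
import netweave as nw

net = nw.ba_graph(200, 2, seed=7)
order = nw.assign_rows(net)                      # node -> row
cols = nw.assign_columns(nw.expand_shadows(net), order, mode="shadow")
svg = nw.render_svg(nw.build_scene(net, order, cols))
```

For the similarity-driven ordering use
`netweave layout net.sif --layout connectivity --measure jaccard
--chain-size 20 --threshold 0.9`, and `netweave subset` to extract a
compressed first-neighbor view around chosen nodes.

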