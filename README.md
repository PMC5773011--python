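# musclenet

Whole-body musculoskeletal network analysis for systems biologists and
clinicians interested in how focal muscle injury propagates through the
body and how the muscular system maps onto the motor cortex.

The body is modelled as a **hypergraph**: bones are nodes and each
muscle is a hyperedge joining every bone it attaches to, summarized by
a bones × muscles incidence matrix `C` (`C[i,j] = 1` iff bone *i* is an
attachment of muscle *j*).  On top of that structure the package
implements:

* a physically embedded **spring–mass model** — bones are unit point
  masses, a degree-*k* muscle is a clique of *k(k−1)/2* damped springs
  of strength 1/(k−1) — in which perturbing a muscle means clamping its
  bones at a displacement *d* in a fourth spatial dimension; the
  **impact score** is the total distance moved by all nodes (time-summed
  under the dynamics `m r̈ = Σ S û (x − ‖l‖) − β ṙ`, or at equilibrium);
* degree-preserving **null hypergraph ensembles** (local triad
  rewiring, category rewiring, free rewiring, fully random) and the
  **impact deviation** z = (impact − null mean)/null std per degree
  class;
* Louvain-like **modularity communities** of muscles at resolution γ
  with consensus over stochastic runs, compared to the motor-homunculus
  partition by the z-Rand score;
* a one-dimensional **muscle coordinate** from classical MDS on
  shortest-path distances of the binarized muscle-centric network;
* **robust weighted regressions** (bisquare IRLS) linking impact
  deviations to published injury recovery times and motor-strip
  activation volumes, which ship as packaged tables.

A seeded synthetic-body generator with the same statistical structure
(modal hyperedge degree 2 with a heavy tail, spatially localized
attachments, contiguous body-axis categories, fixed boundary bones)
makes every stage testable without any downloads.

## Worked example

A five-bone chain with three muscles — `ma` spans bones b1–b3
(degree 3), `mb` and `mc` span two bones each; the chain ends are
fixed in space:

```python
import musclenet as mn

lib = mn.fixture_library()
h, emb = lib["chain"]["hypergraph"], lib["chain"]["embedding"]

table = mn.impact_all(h, emb, "steady_state_4d")
print(table.to_string(index=False))
```

```
muscle  degree   impact            mode
    ma       3 3.500000 steady_state_4d
    mb       2 2.500000 steady_state_4d
    mc       2 2.992913 steady_state_4d
```

Perturbing the degree-3 muscle moves the network most: its three
clamped bones contribute 3 length units and the free neighbour another
0.5.  Ranking the other muscles by how far the perturbation of `ma`
moves their bones:

```python
print(mn.most_impacted(h, emb, ["ma"]).to_string(index=False))
```

```
muscle  displacement
    mb          0.75
    mc          0.25
```

The muscle sharing a bone with the perturbed one (`mb`) is displaced
three times as much as the distant one — the "focal injury has distant
effects, decaying with topological distance" picture in miniature.

The full pipeline (impact → nulls → deviations → communities →
ordering → regressions) runs from one YAML config:

```sh
musclenet run-all --config config.yaml     # or: musclenet simulate-data ...
```

with stage caching, provenance hashes and a machine-readable
`report.json` of all regression results.

## Real data

Loaders accept the documented CSV dialects (edge list `muscle,bone
[,side]` or labelled 0/1 matrix; coordinates `bone,x,y,z,fixed[,mass]`;
categories `muscle,category_id`), so supplementary spreadsheet exports
of the published whole-body network parse directly; place them under
`data/real/` to activate the published-network checks in the test
suite.  The published injury-recovery, activation-volume and
homunculus-category tables are bundled as package data
(`musclenet.stats.load_recovery_table()` etc.).

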