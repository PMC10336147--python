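# nanoirr

Irregularity topological indices of molecular graphs, with exact closed
forms and graph generators for the pentagon–heptagon nanotube families
HAC5C7[p,q] and HAC5C6C7[p,q].

## What this is for

A topological index is a single number computed from a molecular graph
(atoms = vertices, bonds = edges), used in QSPR/QSAR studies as a structure
descriptor. *Irregularity* indices measure a graph's departure from
regularity: they are edge-additive sums whose per-edge term vanishes when
the two endpoint weights are equal. The classical weight is the vertex
degree d_u; the *neighborhood* versions replace d_u by the neighborhood
degree sum δ_u = Σ_{v∼u} d_v.

The package serves people who compute such descriptors for nanostructures:
it evaluates the 11 standard irregularity forms under either weighting

| name | per-edge contribution | prefactor |
|------|----------------------|-----------|
| AL   | \|x − y\|            | 1 |
| IRL  | \|ln x − ln y\|      | 1 |
| IRRT | \|x − y\|            | 1/2 |
| IRF  | (x − y)²             | 1 |
| IRA  | (x^−½ − y^−½)²       | 1 |
| IRDIF| \|x/y − y/x\|        | 1 |
| IRLF | \|x − y\|/√(xy)      | 1 |
| LA   | \|x − y\|/(x + y)    | 2 |
| IRDI | ln(1 + \|x − y\|)    | 1 |
| IRGA | ln[(x + y)/(2√(xy))] | 1 |
| IRB  | (√x − √y)²           | 1 |

on arbitrary graphs (edge list or GraphML input) or directly on *edge
partitions* — the multiset of endpoint-weight pairs with frequencies, which
is a sufficient statistic for every edge-additive index.

For the two nanotube families the neighborhood partitions have class
frequencies affine in the parameters (a·pq + b·p), so every index is an
exact linear function of p, independent of q. The package re-derives all
22 closed-form coefficients symbolically (rationals, surds and logarithms
kept exact; floated only for display), generates the nanotube graphs
themselves, cross-checks graph values against the closed forms, and audits
the coefficients against their commonly reported values — flagging two
genuine errata and one statement/derivation conflict in the reference
tabulation (run `nanoirr verify`).

## Worked example

Generate the HAC5C7 tube with p = 2 heptagons per row and q = 2 periods,
validate it, and compute its neighborhood indices:

```
$ nanoirr generate --family hac5c7 -p 2 -q 2 -o tube.edgelist
$ nanoirr compute --input tube.edgelist
graph,p,q,weighting,index,value
tube.edgelist,,,neighborhood,AL,20
tube.edgelist,,,neighborhood,IRL,2.7410920083035042
tube.edgelist,,,neighborhood,IRRT,10
tube.edgelist,,,neighborhood,IRF,32
...
```

AL = 20 and IRF = 32 are the closed forms 10p and 16p at p = 2: the graph
has 30 bulk edges whose endpoints both have δ = 9 (contributing nothing)
and a boundary whose weight classes (9,8), (9,7), (8,8), (8,6), (7,6)
scale with p alone — which is why the same command with `-q 5` prints the
identical values.

Reproduce the published comparison grid and the coefficient audit:

```
$ nanoirr grid --family hac5c7 --pmax 6 -o grid.csv   # 2 decimals on stdout,
                                                      # full precision in CSV
$ nanoirr verify --family both
...
  IRGA   computed 0.03789440918  (exact: 2*log(17*sqrt(2)/24) + ...)  reported 1.26918503  -> erratum
...
audit complete: 2 erratum/errata, 1 statement/derivation conflict(s)
```

The library mirrors the CLI: `build_hac5c7(p, q)`,
`evaluate_all(graph, "neighborhood")`, `derive_all("HAC5C7")`,
`errata_report(family)`, `run_grid(family, pairs)`.

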