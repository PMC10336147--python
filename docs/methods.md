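# Methods

## Indices and weightings

All 11 indices are edge-additive irregularity measures: for a weighting
w (vertex degree, or neighborhood degree sum δ_u = Σ_{v∼u} d_v),

    I(G) = prefactor · Σ_{uv ∈ E} c(w_u, w_v),

with c symmetric, non-negative, and c(x, x) = 0 (for IRGA this is the
AM–GM inequality). The prefactor is 1 except IRRT (1/2) and LA (2),
modelled separately so IRRT = AL/2 holds identically. Because c depends
only on the unordered endpoint-weight pair, the *edge partition* — the
map (w_hi, w_lo) → frequency — is a sufficient statistic, and the engine
evaluates either a graph (via its partition) or a partition directly.
Terms are accumulated over partition entries sorted by (w_hi, w_lo)
descending, a fixed order that makes graph-route and partition-route
evaluation bitwise identical.

Numerics: weights are exact integers; contributions are computed in double
precision, so each term carries only the rounding of elementary
operations (≲1e-15 relative). No rounded intermediate constants are used
anywhere — the reference derivations being audited did use them, which is
exactly what the audit tolerance absorbs. Weight 0 (an isolated vertex's
neighborhood weight) is accepted by the graph layer but rejected with a
named domain error by the log/ratio/root forms (IRL, IRA, IRDIF, IRLF,
IRGA, IRB); it can never occur for an actual edge endpoint. `evaluate_all`
records per-index domain errors (value NaN) and computes the remaining
indices.

## Closed forms

Both nanotube families have neighborhood partitions with frequencies
affine in the parameters, a·pq + b·p. The closed form of an index is
therefore C_pq·pq + C_p·p with C_pq = pref·Σ a_i c(pair_i) and
C_p = pref·Σ b_i c(pair_i). All the pq-dependence sits in the bulk (9,9)
class, whose contribution vanishes, so C_pq = 0 for every form: each
index equals C_p·p, independent of q. Coefficients are derived in sympy
with exact rationals, surds and logarithms (e.g. HAC5C7 IRDIF = 697/252,
IRDI = ln 432) and floated only at report time. This is what lets the
audit separate genuine tabulation errors from rounding noise: true
agreement sits at 1e-6…1e-4, the two errata at 1.2 and 2.8.

The audit verdict per coefficient: `match` within 1e-3 of the reported
headline value; otherwise `statement_conflict` if the reported
derivation's own result (stored alongside, where it differs from the
headline) matches; otherwise `erratum`. Across the 22 coefficients this
yields exactly two errata (HAC5C7 IRGA: computed ≈ 0.0378944 vs reported
1.26918503; HAC5C6C7 IRDI: computed 10 ln 2 + 4 ln 3 ≈ 11.32592 vs
reported 8.553331516, whose derivation stops one 4p·ln 2 term short) and
one conflict (HAC5C6C7 IRL: headline 9 vs derivation 2.505525927; the
exact value ln(49/4) corroborates the derivation). The audit flags the
conflict without guessing beyond that.

## Generator construction and its contract

No adjacency algorithm accompanies the published drawings of these
tubes, so the generators are *contract-driven*: the authoritative
specification is the invariant set — vertex/edge counts, degree multiset,
the neighborhood partition table, connectivity, and p-fold
circumferential symmetry — and any adjacency realizing it produces
identical descriptor values, because every index is a function of the
partition alone. The realization used: all non-(9,9) classes live on a
boundary rim of p pentagonal motifs (six vertices per column, two of
degree 2, contributing per column exactly 2×(9,8), 1×(9,7), 1×(8,8),
2×(8,6), 2×(7,6)); the body is a 3-regular, p-rotation-symmetric graph (a
cycle with a long-chord perfect matching) whose vertices all have δ = 9.
HAC5C7 gets one rim, HAC5C6C7 two. The construction is open axially and
periodic circumferentially (shifting the column origin is a graph
automorphism, exposed as `column_rotation`). **No planar face structure
is claimed**: the builder realizes the partition contract, not a
particular embedding of the pentagon/heptagon tiling. Parameters p, q < 2
are rejected rather than special-cased; grid rows at p = q = 1 are served
by the closed forms.

Two documented inconsistencies in the reference tabulation shape the
generators:

* **HAC5C7 vertex count.** The commonly quoted 8pq + p is incompatible
  with the family's own partition table: the table's δ-endpoint counts
  force exactly (8pq−5p, 2p, p, 2p) vertices with δ = (9, 8, 7, 6),
  i.e. |V| = 8pq with 2p degree-2 vertices, and any extra vertex would
  have to be isolated. The generator follows the table (which generates
  every reported numerical value) and builds 8pq vertices.
* **HAC5C6C7 partition.** The published table is not the neighborhood
  partition of *any* simple graph when 3 ∤ p: all weights lie in
  {6,7,8,9}; a δ = 9 vertex must then have degree 3 with all-degree-3
  neighbors (every alternative creates a (9,6) or (9,7) class the table
  lacks), so 3 must divide the δ = 9 endpoint count 24pq − 14p — i.e.
  3 | p; and at p = 3 an exhaustive vertex-type accounting (including the
  degree-4 types the table's classes would admit) has no non-negative
  solution either. The generator realizes the nearest realizable family:
  the published table with boundary class (8,7): 2p replaced by
  (9,7): 2p — same edge total 12pq + 7p, 8pq + 6p vertices, two
  HAC5C7-style rims. Closed forms and comparison grids follow the
  *published* table; `validate_structure` reports the published-partition
  mismatch explicitly, and the grid's graph provenance documents that for
  this family it reflects the realized variant.

`validate_structure` never raises: every invariant becomes a pass/fail
entry with expected vs actual values.

## Grids and printed-cell matching

`run_grid` reproduces the published comparison layout (rows [k,k],
k = 1…6) with full-precision values; rounding to 2 decimals happens only
at presentation, and CSV output carries 17 significant digits. The
reference grids round inconsistently (round-half-up in some cells,
truncation in others, e.g. an IRB cell printed "3.2"), so reproduction is
checked at each cell's own printed precision: a computed value matches if
it rounds to the cell, truncates to it, or lies within 0.01. Under that
rule every cell of both grids reproduces except three HAC5C7 cells that
are plain typos (IRL at [5,5] and [6,6], IRLF at [4,4], each off by
0.02–0.05 from the coefficient including the reference's own), plus the
columns tabulated from the two erroneous coefficients (HAC5C7 IRGA,
HAC5C6C7 IRDI) and the corrupted HAC5C6C7 IRL [2,2] cell ("65.04"),
which are excluded outright.

## Problem sizes and test design

Everything here is exact or O(|E|), so the default suite runs full scope
in seconds: generators are exercised on (p,q) ∈ {2..5}² (plus p = 6
spot-checks), grids to p = q = 6, and graph-vs-partition equivalence is
checked against an independent naive edge-loop oracle over all 1253
graphs on ≤ 7 vertices (the networkx atlas) under both weightings.
Property-based tests (hypothesis, derandomized) cover the handshake and
first-Zagreb identities, partition totals, frequency-scaling linearity
and relabeling invariance on seeded random graphs. Tests of the
generators assert the realizable contracts above; the published-value
test module additionally asserts the two irreconcilable published claims
verbatim, so their failures document the inconsistencies rather than hide
them.

## Limitations

* The generators realize partitions, not embeddings: they are the right
  object for descriptor computation and closed-form validation, but not a
  source of 3D coordinates or face lists (out of scope, as are chemical
  file formats and bond orders).
* The errata audit is specific to the two families' reference values
  packaged in `nanoirr.reference`; it does not generalize to other
  tabulations.
* Degree-based (non-neighborhood) closed forms for the families are not
  tabulated — the engine computes them from graphs, but no reference
  exists to audit against.
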