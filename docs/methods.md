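# Methods

## Model and procedure

The pipeline evaluates one system (not a set of competing alternatives)
against a two-level framework of dimensions and criteria, in four stages.

**1. Influence aggregation (DEMATEL).** Each of `K` experts fills a square
matrix of direct-influence ratings on an integer scale `0..scale_max`
(default 0–4, the convention of this model family: 0 = no influence, 4 =
very high influence; the scale is configurable). The element-wise mean `A`
is normalized by

```
s = max(max_i Σ_j a_ij , max_j Σ_i a_ij),    D = A / s
```

which keeps the spectral radius of `D` below 1 for any matrix with slack in
at least one row or column sum; a row-sum-only variant is available
(`normalize_direct(..., variant="row")`) since both appear in practice. The
total influence is the closed form of the Neumann series,
`T = D(I − D)⁻¹`, computed as a linear solve; the computation refuses
matrices whose spectral radius is within 1e−9 of 1. Conservation
`Σ(r − c) = 0` holds to machine precision because `Σr` and `Σc` are both
the grand total of `T`.

A consensus diagnostic (mean relative deviation of experts from the panel
average over off-diagonal cells, in percent) is reported for awareness but
never gates the pipeline.

**2. Weights (DANP).** The dimension-level matrix `T_D` takes block means
of `T`. The unweighted supermatrix normalizes each (row-criterion ×
column-dimension) block of `T` to sum 1 and transposes; each dimension
block of a column then sums to 1, so full columns sum to the number of
dimensions — only after scaling block `(g,h)` by the row-normalized
`T_D[h,g]` does the matrix become column-stochastic (checked at 1e−9).
The influential weights are the common column of the limit under matrix
powers. Powers are multiplied out until successive iterates differ by less
than 1e−9 in max norm (cap 10,000); if the iterates cycle instead — toy
chains such as a two-criterion swap are periodic — the cycle is detected
against a short history window and the limit is the Cesàro average over one
period, the standard limit for periodic column-stochastic chains. No
teleportation damping is introduced: reducible supermatrices (criteria
receiving zero influence) are legitimate inputs and resolve through the
same power/Cesàro procedure. The stationary vector is cross-checked in the
tests against an independent eigendecomposition oracle; the implementation
itself never calls an eigensolver for the limit.

**3. Gap scoring (modified VIKOR).** Group scores are plain means over
valid questionnaires (no respondent weighting). Gaps are measured against a
fixed aspiration scale, default `f* = 10`, `f⁻ = 0` — the only scale
consistent with every printed gap of the packaged fixture (`gap = (10 −
f)/10` reproduces all 52 checkable cells) — and configurable for other
instruments. Aggregation weights are renormalized to sum exactly 1 before
every weighted mean. This matters with published 3-decimal weight tables:
the funding dimension's printed local weights sum to 1.001, and its printed
expert performance 4.746 is reproducible only under renormalization (4.751
otherwise). All arithmetic is carried at full precision; half-up rounding
to 3 decimals (the print convention of decision tables; Python's builtin
`round` is banker's rounding and would print 4.9815 as 4.981) is applied
only in the report layout. Questionnaires with missing cells are rejected
by default; `on_missing="drop"` discards them, mirroring how such surveys
handle invalid returns.

**4. Improvement synthesis.** Dimensions are ranked by gap (descending;
ties keep framework display order and are flagged joint, with equality at
1e−9). Within each dimension the influence source is the criterion with the
largest net relation computed on the dimension's *own* sub-block of `T` — a
self-contained sub-map, matching how per-dimension sources are discussed in
this literature; a whole-map alternative is behind `sub_map="whole"`. The
report marks the degenerate case where the largest-gap criterion is itself
the source. The report is a pure function of the gap report and influence
structure: identical inputs give identical output.

## Packaged fixture

The fixture carries the published 5×20 framework, the printed local and
dimension weights, and both groups' criterion performances. The raw
influence questionnaires behind the weights live in an appendix that is not
part of the available text, so the weights are inputs, not outputs: the
pipeline reproduces every downstream aggregate from them (all criterion
gaps, dimension performances/gaps, totals 4.982/0.502 and 6.196/0.380,
within ±0.001 after rounding) but cannot re-derive the weights themselves.
Two printed cells differ from recomputation by exactly 0.001 (a user
criterion gap of 0.361 where the half-up rounding of 0.3615 gives 0.362,
and a user dimension performance of 6.200 where renormalized weights give
6.199); both sit inside the fixture tolerance. Published weights are
accepted as internally consistent at 0.0015, the slack of 3-decimal
rounding.

## Synthetic data generator

The generator emulates the study design: 10 influence questionnaires over
the 5×20 framework, and performance surveys from an expert group (n = 10)
and a user group (n = 315) on the 0–10 instrument. Influence responses are
an integer ground-truth matrix with independent ±1 jitter per off-diagonal
cell (probability `jitter_p`, default 0.25, direction uniform), clipped to
the scale; performance scores are normal draws per criterion clipped to the
bounds, with per-criterion means drawn uniformly from [4, 7] — the
mid-range band the published evaluation sits in — and sd 1.5, a plausible
spread for a 0–10 satisfaction item. A planted dominant-source dimension
(maximal outgoing, minimal incoming ratings) gives a known causal ground
truth for rank-recovery checks. All randomness flows from one seed through
one `numpy.random.default_rng` stream; outputs are byte-identical across
runs.

What the generator does *not* model: inter-expert correlation or response
styles, item non-response patterns, ordinal discreteness of real
satisfaction items, and clipping bias at the scale ends (jitter on a truth
value of 0 or 4 is asymmetric after clipping, so panel averages are
unbiased only for interior truth values; recovery tests use interior
values). Passing tests therefore show the pipeline recovers parameters
under clean, independent noise — not that any real panel satisfies these
assumptions.

## Problem sizes and tolerances

Oracle suites run at the study's natural size (20 criteria): 200 random
matrices up to n = 25 for the Neumann-series equivalence (1e−8), 100
random column-stochastic 20×20 chains against the eigenvector oracle
(1e−7), 100 randomized instances for the gap identities (level
consistency, monotonicity, affine invariance, at 1e−9), and 100 generator
seeds for planted-source rank recovery (with single-respondent performance
groups, since only the influence side is exercised). Mean-recovery checks
use the 3·sd/√n Monte-Carlo band. The full suite completes in a few
seconds on one CPU.

## Known limitations

- The additive weighted-mean aggregation assumes criterion independence in
  preference; non-additive aggregation is out of scope.
- Classical VIKOR compromise indices (S/R/Q, the v parameter) and
  multi-alternative ranking are deliberately absent: the aspiration-gap
  form evaluates one system.
- INRM output is coordinates and edge lists only; no plotting.
- Pre-test screening implements the 7.5/5 importance thresholds as a total
  function on [0, 10] (the upper band inclusive, deletion strictly below
  5); the multi-round expert discussion the resurvey band feeds is a human
  process outside the package.
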