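# Methods

## Fatty-acid model

Fatty acids are represented by `(carbons, double_bonds, omega)` parsed from
`C:Dn-x` shorthand. Input accepts the typographic dialects that appear in
the literature (`n−3` with a Unicode minus, `n-3`, `(n-3)`,
case-insensitive); output is always canonical ASCII `C:Dn-x`. Only
methylene-interrupted PUFA are representable: the carboxyl-referenced
double-bond positions are `{C − (ω + 3i) : i = 0 … D−1}`, and a shorthand
whose proximal bond would fall at Δ < 2 is rejected as geometrically
impossible. Conjugated or odd-spaced isomers are out of scope — every acid
in the packaged pathway follows the 3-carbon spacing rule, and anything
violating it should be flagged, not silently accepted.

Conversion classification is purely structural: Δk if the product has the
same chain length, one extra bond, and its position set is the substrate's
plus `{k}`; elongation/β-oxidation if the chain changes by ±2 carbons with
the bond count and n-x series conserved (the series, being
methyl-referenced, is invariant under both). Pairs that differ by more than
one step return the value `"not-single-step"` rather than raising, so
pathway searches can skip them cheaply; a series mismatch between two
unsaturated acids is an error because no single enzymatic step explains it.

The packaged pathway graph carries, per series (n-3 and n-6): the Δ6 route
(Δ6 – elongation – Δ5) and the Δ8 route (elongation – Δ8 – Δ5) to EPA/ARA,
two downstream elongations to the C24 intermediate, the Sprecher terminus
(Δ6 desaturation then partial β-oxidation back to C22), and the direct Δ4
edge. Every edge label is re-derived by the classifier on insertion, so the
graph cannot encode an inconsistent step. Carboxyl (Δ) numbering is the
internal convention since activities are named Δ4/Δ5/Δ6/Δ8; ω numbering is
derived on demand.

## Assay quantification

The primitive observable is a GC peak area (arbitrary units, non-negative).
A single step's conversion is `product/(product+substrate) × 100`; division
happens before scaling so the result is exactly within [0, 100], and a 0/0
pair raises (undefined) rather than reporting ND — ND is reserved for a
peak at or below the configurable `detection_floor` (default 0; the
threshold behind published "ND" entries is never stated, so it is a
parameter).

For chained assays (an elongase feeding a desaturase), `chain_conversions`
walks the pathway graph breadth-first from the exogenous substrate. Each
outgoing edge of a detected node yields one result; undetected products
yield ND and are not expanded. The product term of an edge is the product's
own area **plus its downstream derivatives** reached by the walk, while the
substrate term is the substrate's remaining peak. This is the only reading
under which each step's conversion equals the fraction of the arriving pool
the step turned over (e.g. areas 700/200/100 along
22:5n-3 → 24:5n-3 → 24:6n-3 give 30.0% elongation, not 22.2%), and it
matches the practice of summing a product with its further-converted
derivatives. Downstream products are never added back into upstream
substrate pools. β-oxidation edges are skipped by default because the yeast
host lacks the peroxisomal step (24:6n-3 accumulates); pass
`include_beta_oxidation=True` to traverse them.

The normalisation ratio is `conv_24:5n-3 / conv_control`, rounded half-up
to 2 decimals; an ND numerator gives 0.00 by definition, while an ND or
zero control with a measurable numerator is an error (the ratio is
undefined, not zero). Conversions are rounded half-up to 1 decimal only at
report formatting; internal values keep full precision. Control assays are
separate records (separate cultures), never derived from the C24 assay's
peak table. For the packaged 15-enzyme table the printed ratios are
reproduced from the printed 1-dp conversion columns; whether the original
ratios were computed before or after rounding the conversions is
indistinguishable (all 15 rows agree under both readings).

Input TSVs carry either raw areas (long format) or pre-computed conversions
(wide format); the dialect is sniffed from the header (`peak_area` vs
`conv_*` columns) and logged.

## Motif scanning

The Δ4-signature query is the column-wise consensus of aligned seed
sequences: a column with one shared residue and no gaps emits it; anything
else emits the wildcard `X`. Gap columns become `X` rather than being
dropped so the query length — and hence the Y-anchor arithmetic — stays
stable. The YXXN anchor is located as the first emitted `Y` with an `N`
three positions later; its absence is a derivation error prompting a wider
window. The default query is the published 20-residue Δ4 consensus
`PPLLIPVFYNFNIMXTMISR` with the Y anchor at offset 8 (so the anchor N is at
offset 11); "positions 1 and +4" of the YXXN domain are read 1-based within
the domain. The seed alignments behind it named two further key residues
whose identity is not recoverable from the consensus alone, so only the Y/N
anchors are hard requirements; additional anchors can be imposed by editing
the query.

Scanning is exhaustive windowed comparison (a deliberate replacement for
similarity search against live databases, which is out of scope): every
window within `max_mismatches` over the non-wildcard positions is reported,
wildcards excluded from both the mismatch count and the identity
denominator, non-standard residues (B, Z, J, U, O, `*`) never matching. The
default ceiling is 6 of the 19 scored positions (~68% identity floor) —
a configurable choice, since no similarity threshold is published; the
anchors are mandatory regardless of the ceiling. A candidate's verdict
comes from its best hit (fewest mismatches, then leftmost): putative-Δ4
iff the hit is within the ceiling *and* the anchors are intact. Nucleotide
input is rejected rather than translated.

## Phylogenetics

Distances: p-distance under pairwise gap deletion, optionally
Poisson-corrected (`−ln(1−p)`), the conventional protein default for
distance trees; the model is a flag because the original workflow's exact
correction is undocumented. A pair with no shared ungapped column, or with
p = 1 under the correction, raises with the pair named.

Neighbor joining follows Saitou–Nei: minimise
`Q(i,j) = (m−2)·d(i,j) − R_i − R_j`, with ties broken by the lowest
(row, column) pair in current label order so runs are bit-reproducible.
Limb lengths use the standard formulas; a negative limb is clamped to zero
with the deficit moved to its sister so the pair still spans `d(i,j)`. The
result is unrooted (stored rooted at the final trifurcation). On additive
input NJ is exact: the tests require topology recovery (Robinson–Foulds 0)
and path-length agreement to 1e-9 on random trees, with an independent NJ
implementation (dendropy) as cross-check.

Bootstrap: resample columns with replacement (same length), recompute
distances and NJ, count internal bipartitions, and report each
point-estimate bipartition's support as an integer percentage of usable
replicates. A replicate that leaves some pair with no comparable columns is
skipped, counted, and reported. One seeded generator drives all replicates
sequentially, so supports depend only on (alignment, model, iterations,
seed). The published tree's printed supports are not reproduced here —
that would need the original public sequence set — so bootstrap behaviour
is validated on synthetic two-clade alignments instead, where the central
bipartition's support is predictable.

Newick I/O is written in-package so supports survive round-trips exactly:
numeric internal labels parse as supports, branch lengths print with 12
significant digits, and parse errors carry a character offset. A minimal
leaf-outgroup rerooting utility is included; likelihood/Bayesian inference
and model selection are out of scope. Alignments are consumed, not
computed (alignment construction belongs to external tools).

## Synthetic data

`simulate_assay` allocates substrate area sequentially along a route: a
step with fraction `f` moves `f` of the area arriving at its substrate
onward, so the noiseless per-step conversion is exactly `100·f` and total
area is conserved. Noise is multiplicative lognormal per peak,
parameterised by coefficient of variation (chromatographic areas are
positive with roughly proportional error), with `σ² = ln(1+CV²)` and unit
mean. The default C24 assay route is
22:5n-3 → (elongation) → 24:5n-3 → (Δ6) → 24:6n-3; defaults are CV 5% and
step fractions drawn in [0.05, 0.6] by the callers, spanning the conversion
range seen in real assays (≈1–42%). What the simulator does *not* emulate:
detector response factors, co-eluting peaks, and substrate-uptake
differences — so recovery tests validate the estimator arithmetic, not GC
practice.

`simulate_family` evolves a uniform-residue root sequence (signature
embedded at a recorded offset, wildcards filled randomly) along a random
bifurcating tree (coalescent-style joins, exponential branch lengths scaled
to a root-to-leaf height in substitutions/site; defaults: 20 taxa, height
0.15, rate 1.0, 350 residues). Substitutions are Poisson per branch with
uniform replacement — no substitution matrix, a stated simplification
adequate for exercising distance/NJ and motif machinery, not for realistic
protein evolution. The designated fraction of taxa (rounded to an exact
count) forms a true clade whose Y/N anchor columns are shielded from random
substitution; every other taxon receives one forced disruptive anchor
substitution. Truth labels are therefore exact by construction.
`suggested_max_mismatches` sets the scan ceiling to the expected non-anchor
mismatch load plus a four-sigma Poisson margin, capped at the scored
length.

`two_clade_alignment` builds the bootstrap test case directly: a fraction
of columns fixed-divergent between two clades (default 50% of 200 columns),
plus 3% per-taxon noise so within-clade distances are positive; every
divergent column supports the central bipartition, which should bootstrap
near 100%.

Problem sizes used by the test suite and the acceptance script — 500 random
trees of 4–12 taxa, 100 bootstrap replicates on 8×200 alignments, 200
simulated assays, families of 10–50 taxa — are chosen so the full suite
runs in seconds while keeping the stochastic checks' expected margins wide
(e.g. median recovery error ≈0.8 pp against a 2 pp bound).

## Command-line interface

All subcommands are deterministic functions of (inputs, options, seed);
the default seed is a fixed constant (20170620) rather than entropy, so
unflagged runs are reproducible, and every TSV/JSON report header echoes
the version, seed, and effective options. Newick output files are kept free
of comment lines so downstream parsers accept them; the seed travels in the
companion supports TSV. Exit codes: 0 success, 2 usage/input error,
1 internal error; logs go to stderr only.
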