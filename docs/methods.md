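# Methods

This note documents the models, algorithms and design choices behind
`orthoquery`, in the order the pipeline applies them, together with the
assumptions each stage makes and what the simulated-data tests do and do
not demonstrate.

## Inputs and the header convention

Proteome FASTA headers in genome-portal bulk dumps are compact and
pipe-delimited: a source tag, a short species code, a numeric protein id
that is unique only *within* a species, and optionally an ortholog-group
ordinal. Two positional conventions occur in practice — `tag|species|
protein|group` and `tag|species|group|protein` — so the field order is a
named preset (`species_protein_group`, the default, and
`species_group_protein`), not a hard-coded rule. Parsing is lenient:
headers without a pipe keep their raw text as the only label. Sequences
are uppercased on read (identity counting must be case-insensitive), one
trailing `*` stop marker is stripped, and ambiguity codes (X/B/Z) plus
selenocysteine (U) are retained. Duplicate headers within one file are kept
and logged, with occurrence suffixes on internal keys so no record is
silently overwritten.

## Ortholog-group tables

Upstream inference output is one wide row per group with one column per
species; cells hold comma-separated member ids, optional `:score`
confidence suffixes, and a `*` placeholder where a species has no member.
The parser fans each cell out to one tidy row per member
(`group_id, species_code, protein_id, member_score`) and enforces two
invariants: member triples are unique, and group membership partitions the
proteins (a protein in two groups is a validation error naming the
duplicates). Separators and the placeholder token are a registered
*dialect*, so upstream format drift is configuration, not code. Scores are
parsed when present but nothing downstream requires them. Species column
names are taken verbatim — they must match proteome file stems for
sequence resolution.

## Pairwise alignment

Global alignment is Needleman–Wunsch with affine gaps in the three-state
(match / gap-up / gap-left) formulation. A gap run of length *L* costs
`gap_open + (L−1)·gap_extend` with defaults 10 and 1; the substitution
matrix is BLOSUM62 (U and O score as X). The invariant
`gap_extend ≤ gap_open` lets the left-gap state be filled with an exact
running-max scan (re-opening inside a run can never beat extending), which
keeps the fill vectorised per row. Traceback tie-breaks are fixed —
diagonal, then up (gap in the second sequence), then left — so alignments
are identical across platforms and runs. The engine is checked two
independent ways in the tests: exhaustive enumeration of all alignments on
short pairs, and score agreement with an established pairwise aligner on
longer random pairs.

## Progressive multiple alignment

No attempt is made to reproduce any particular MSA engine bit-for-bit; the
downstream contract (PIM and tree) depends on alignment quality, not engine
identity. The scheme is the classic one: pairwise p-distances
(`1 − identity/100` from optimal pairwise alignments) feed a
neighbor-joining guide tree; profiles are merged bottom-up in guide-tree
order by the same affine-gap dynamic programming, scoring a column pair as
the mean of all residue–residue substitution scores between the two columns
(pairs involving a gap contribute zero). Columns that become all-gap after
a merge are removed, output rows are returned in input order, and
de-gapping any output row reproduces its input sequence exactly. A single
input sequence yields a degenerate one-row alignment with a warning.

## Percent identity matrix

For rows *i, j* the reported identity is
`100 · (# columns where both rows carry the identical residue) /
(# columns where both rows carry any residue)`. Excluding gap columns from
the denominator makes identical sequences score exactly 100 regardless of
gaps induced by other rows, which is what the heatmap's diagonal promises.
Because the denominator convention is genuinely ambiguous in the wild, two
alternatives are selectable (`shorter` ungapped length, full `alignment`
length); the co-residue rule is the default. Row pairs with no co-residue
columns report 0 with a warning. Values are written at one decimal place.

## Distances, neighbor joining, midpoint rooting

Distances are plain p-distances `d = 1 − PIM/100` (a Poisson-style
`−ln(1−p)` correction is available but off by default, since the simple
transform is the conventional reading and keeps distances bounded).
The tree is canonical Saitou–Nei neighbor joining: join the pair minimizing
the Q-criterion, branch lengths from the two-point formulas, negative
lengths clamped to zero with the deficit moved to the sibling edge so the
joined pair's total is conserved. Q-ties break on the lowest (row, column)
index pair, making the output bitwise reproducible. The unrooted result has
a trifurcating top node; two taxa are the trivial single-edge case.

Midpoint rooting works on the unrooted adjacency (pass-through degree-2
nodes contracted): find the two most distant leaves by double depth-first
search, walk the diameter path to its midpoint, and insert the root there —
on the node itself if the midpoint lands exactly on one. Ties in the
diameter search break on leaf names. Total branch length is conserved by
construction. On additive matrices neighbor joining provably recovers the
generating topology and path lengths, and the tests exercise exactly that
oracle (random trees → tip-to-tip distances → NJ → compare).

Newick output rounds branch lengths to 6 significant digits; parsing and
serialization ride on scikit-bio's tree container, wrapped so malformed
input raises one package error type.

## Built-in inference stand-in

The reciprocal-best-hit stage exists so the whole pipeline runs with no
upstream binary; it is *not* a re-implementation of any production
orthology tool's scoring or in-paralog rules, and the group-file parser
remains the fidelity path for real upstream output. Every protein's best
global-alignment hit per other species is recorded with score normalized
by the query's self-score (length-robust, bounded by 1); edges survive if
reciprocal and both scores ≥ `min_score` (default 0.05, deliberately
permissive for exploratory screening); groups are connected components,
singletons dropped, ids ordinal by smallest member. The all-vs-all step is
quadratic and intended for desk-scale inputs only.

## Query matching cascade

Group membership lookup for a query protein is undefined in general — the
query may be unannotated, or from a species with no public proteome — so
matching proceeds exact-sequence → header `(species, protein id)` → best
alignment identity ≥ threshold (default 90%). Exact matches always win;
the alignment fallback is what places a query from an unsequenced species.
When several queries hit several groups the result is the union,
deduplicated, with per-query match modes recorded in the manifest. The
query sequence itself always appears as an alignment row (unless
byte-identical to a member, in which case that member already represents
it); unmatched queries join the alignment only when explicitly requested.

## Synthetic data generator

The generator replaces bulk proteome downloads plus an upstream inference
run. Protein families evolve down a known species tree: per branch, each
site is replaced with a uniformly chosen *different* residue with
probability equal to the branch length (realized divergence is therefore
binomial around the branch length, which the tests verify within three
standard errors), after an optional per-site single-residue indel step
(rate split evenly between insertion and deletion, applied before
substitutions, all positions drawn from one seeded stream). Defaults are a
balanced 8-species tree with 0.05 expected substitutions per site per
branch, 3 single-copy families of 120 residues, indel rate 0.01 and a
fixed seed: long enough for sister species to be statistically separable,
small enough that the full suite runs in seconds. A uniform replacement
model was chosen over empirical amino-acid rate matrices deliberately:
ground-truth bookkeeping matters more than realism here.

What passing these tests shows: the machinery is internally consistent,
deterministic, and recovers known truth when the signal is present. What
it does not show: behavior on real proteomes with paralogs, domain
shuffling, heterogeneous rates, or fragmentary gene models — none of which
the generator emulates. The nearest-neighbour property (highest-PIM partner
= least-diverged relative) is a statistical expectation, not a theorem: at
120 sites and low divergence an occasional member of a random replicate can
rank a non-sister first.

## Outputs and determinism

All artifacts are plain text (tidy TSV, square TSV at one decimal, aligned
FASTA, Newick); heatmap images (png via matplotlib, html as a value table)
are optional so headless environments never fail on a graphics stack. The
manifest records parameters, match modes, dropped members, and a digest per
artifact, and is written last. Re-running with identical inputs and
parameters yields byte-identical TSV/FASTA/Newick outputs; this is asserted
end-to-end in the tests.

## Problem sizes

The test suite and the acceptance script run on simulated inputs sized for
interactive iteration: 200 brute-force alignment pairs (length ≤ 5), 100
random trees each for the NJ, rooting and round-trip properties (2–14
leaves), and the 8-species / 3-family / 120-residue end-to-end study.
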