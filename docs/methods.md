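# Methods

This note documents the models and algorithms inside `elemtrace`, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the design choices made where the design was genuinely open.

## Query validation

A query is one DNA record over {A,C,G,T,N}. "Under 3 kb" is read literally:
2999 bases are accepted, 3000 rejected. At most 10% N is allowed. The
nonrepetitive requirement is surfaced, not enforced: a DUST-like score
(triplet-count statistic over 64-base windows, cutoff 2.0) flags
low-complexity queries with a warning, because a repetitive query degrades
the search statistics but does not invalidate the machinery. IUPAC
ambiguity codes on input are collapsed to N; soft-masking (lowercase) is
ignored and everything is uppercased, since the workflow defines no masking
policy. N never counts as a match anywhere downstream.

## Homology search

**Seeding.** A discontiguous 21-column template with 12 sampled positions
{0,1,3,4,6,7,9,10,12,13,15,16} (a coding-style pattern) is indexed over
both strands of each genome; a seed is any query/subject window pair
agreeing at all 12 sampled positions. Sampled words containing N are
skipped. Seeding is complete — no heuristic dropping — so the expected
spurious seed count against random sequence is exactly
`W_q · W_s · 2 · 4^-12`, which the tests verify.

**Extension.** From each seed start an affine-gap extension runs in both
directions with X-drop pruning: a cell is abandoned once it trails the
running best by more than `xdrop`. Scores: match +2, mismatch −3, gap open
−5, gap extend −2 (a gap of length L costs `open + L·ext`). The X-drop
default is 100 raw-score units, chosen so that an extension can bridge
moderate indels — a 17-nt deletion costs 5 + 34 = 39, and a drop-off below
that would split any hit spanning it into two — while still terminating
after ~55 columns of random sequence. Seeds whose start pair lies on an
already-reported alignment path are skipped; with a high-identity homolog
this collapses hundreds of redundant seeds into one extension. HSPs scoring
below 28 (a 14-nt exact match) are not reported. Overlapping HSPs are not
chained or merged; ranking decides.

**Statistics.** λ solves `Σ p_i p_j e^{λ s_ij} = 1` for uniform base
frequencies (bisection), and K comes from the standard Karlin–Altschul
series over the score random walk, truncated at 1e−6. For +2/−3 this gives
λ = 0.6337, K = 0.408, matching the published ungapped values for this
scheme. `E = m·n·2^{−bits}` uses raw sequence lengths — no edge-effect or
effective-length correction — and the ungapped (λ, K) are applied to gapped
scores as well; both are deliberate simplifications, so E-values here are
conservative relative to NCBI's and parity is not claimed. The null
calibration (best ungapped score of random 500×500 pairs) is tested against
the implied Poisson rate.

**Filtering and orthologs.** A hit is retained iff `E ≤ 1e−5`, query
coverage `≥ 0.3` and identity `≥ 0%` (no identity floor by default; the
flag exists because the upstream workflow exposes one without stating a
default). Per genome the policy is `best` (default), `all`, or `top_k`;
ranking is bit score, then E-value, then subject start, then contig name.
Minus-strand hits store forward-strand subject coordinates and the
extracted homolog is reverse-complemented, so all alignment rows read in
query orientation. Internally coordinates are 0-based half-open; the hit
log is 1-based inclusive with start > end signalling the minus strand,
following BLAST tabular convention.

## Progressive alignment

Guide distances are `1 − shared/min(n_i, n_j)` over 6-mer multisets;
sequences shorter than k get maximal distance with a warning. The guide
tree is UPGMA (average linkage, ties to the smallest index pair, children
ordered by smallest leaf index). Profiles align by global DP over columns:
the score of pairing two columns is the expected substitution score over
their base frequencies (gaps and N excluded from the frequencies; an
all-gap profile column scores 0), with the same affine gap costs as the
search and terminal gap runs charged half the open cost. One progressive
pass, no iterative refinement — a fidelity gap relative to
refinement-based aligners, acceptable here because the synthetic benchmark
is aligned and evaluated by the same code path. On sequence pairs the DP
provably matches a brute-force global alignment oracle, which the tests
exercise up to length 50.

## MSA to variation graph

Columns are partitioned into maximal runs with identical
row-presence-and-base pattern: the column key is (set of non-gap rows,
partition of those rows by base equality). Within one run every row is
either present throughout or gapped throughout, and two rows in different
base-classes differ at every column, so each class spells one distinct
gapless segment. This is the coarsest split for which every segment is a
literal substring of each traversing row, which yields the respell
guarantee: concatenating any path's segments reproduces that row's
ungapped sequence exactly (fuzz-tested). Segment ids are 1-based in
left-to-right discovery order, so the graph is a DAG topologically ordered
by column position. Output is GFA 1.0 with H/S/L/P records only, "+"
orientations and "0M" overlaps; paths are emitted for every row including
the query. All-N columns are ordinary characters, not gaps.

## Phylogeny

Distances are Jukes–Cantor, `d = −(3/4)·ln(1 − 4p/3)`, with p computed
over columns where both rows carry a real base; saturated (p ≥ 0.75) or
zero-overlap pairs are capped at d = 5.0 with a warning. Topology is
canonical neighbor joining (Q criterion, ties to the smallest index pair);
negative branch lengths are clamped to zero with the deficit moved to the
sister edge. The tree is stored rooted at the final trifurcation, which is
only a representation — the likelihood is invariant under re-rooting
(pulley principle, tested to 1e−8).

The substitution model is GTR+Γ: exchangeabilities (AC, AG, AT, CG, CT,
GT; GT = 1) default to all ones, base frequencies are empirical from the
alignment (gaps/N excluded, floored at one pseudo-count), Γ shape α
defaults to 1.0 with 4 mean-of-quantile-bin categories normalized to mean
1 (Yang's discretization; verified against numeric quadrature).
Exchangeabilities and α are config-exposed but not optimized — this keeps
the stage deterministic and cheap, and model-parameter optimization is an
extension point, not a goal. `P(t) = e^{Qt}` is computed by
eigendecomposition of the reversible Q in the π-symmetrized basis; the
rate matrix is scaled so branch lengths are expected substitutions per
site.

The likelihood is Felsenstein pruning over compressed column patterns with
per-node scaling; gaps and N are missing data (partial vector of ones).
Branch lengths are polished by cyclic per-edge bounded scalar maximization
on [1e−8, 10] until the gain per cycle drops below 1e−3 (max 20 cycles);
the log-likelihood never decreases. This NJ + branch-length-polish scheme
deliberately replaces a full ML topology search (SPR etc.), which is out of
scope; bootstrap supports therefore summarize NJ replicate topologies.
The nonparametric bootstrap resamples columns with replacement
(default 100 replicates, seeded), rebuilds an NJ tree per replicate, and
annotates each internal edge of the best tree with the percentage of
replicates containing the same leaf-label bipartition (canonical side: the
one not containing the alphabetically first leaf; the query counts like
any leaf). Four files are written: best tree, support-annotated tree, one
replicate tree per line, and a run-info text file.

## Conservation

The per-column score is `(modal real-base count / n_rows) · (non-gap rows
/ n_rows)`, with the modal factor set to 1 when at most one row
contributes a real base (a lone base is scored by coverage alone). The
score is in [0, 1], permutation-invariant, and monotone in agreement with
the modal base. Elements are maximal conserved-state runs of the Viterbi
path of a two-state HMM: Gaussian emissions with means 0.5 (neutral) and
0.9 (conserved), shared σ = 0.15, symmetric switch probability 0.01,
uniform start, ties toward neutral. These emission means suit best-hit
alignments of a conserved element, where background columns score near
0.4–0.6 and conserved columns near 1; they are config-exposed. This module
is intentionally *not* a phylo-HMM: emissions ignore the tree, so the
scores are descriptive column statistics, not substitution-rate tests, and
no numeric parity with phastCons/phyloP is claimed. Elements are reported
in alignment columns (BED, 0-based half-open) and can be projected to
query coordinates by skipping query-gap columns.

## Synthetic data

The generator evolves the query along a user tree: site rate categories
are drawn once at the root from the discrete Γ, each edge substitutes
sites via `P(t·rate)`, and leaves in the deletion clade have the deletion
span excised afterwards. Elements are then written over random windows of
i.i.d. uniform background (total genome length = `background_length`,
default 10 kb; multiple non-overlapping copies supported), with the true
insertion coordinates returned for assertions. Randomness uses one named
substream per purpose/genome derived from the single seed, so the whole
fixture is reproducible bit for bit.

The default demo mirrors the published benchmark shape: a 766-nt query, 18
genomes on a shallow vertebrate-style tree (root-to-tip ≲ 0.1
substitutions/site so every ortholog passes the default thresholds), a
4-leaf snake clade (boa, python, cobra, viper) carrying a 17-nt deletion at
query position 380. The deletion start is otherwise arbitrary — roughly
mid-element, as in the real enhancer. The reported benchmark itself used 18
genomes (one figure caption says 16 species; the demo follows the 18 stated
in the text).

What the generator does **not** emulate: repeats and low-complexity
isochores (background is i.i.d. uniform, making the spurious-seed rate
analytically predictable), indels other than the scripted clade deletion
(so MSA gap structure is fully attributable), rearrangements, and
duplication families beyond the `copies` parameter. Passing the synthetic
benchmark therefore demonstrates the machinery end to end with known
truth, not robustness to repeat-rich real genomes.

## Problem sizes and numerics

The shipped demo and test sizes — 766-nt query, 18 × 10 kb genomes, 100
bootstrap replicates, 5000-column branch-length recovery, ≤ 14-column
exhaustive Viterbi checks, ≤ 8-taxon NJ property sweeps — are chosen so the
full suite runs in well under a minute each while keeping every statistical
check adequately powered; they are the package's own defaults, and all are
parameters. Numerical tie-breaks are fixed everywhere (smallest index pair
in UPGMA/NJ, neutral state in Viterbi, match state in alignment traceback)
so identical inputs give byte-identical outputs. Known limitations worth
restating: E-values are conservative approximations; the MSA is a single
progressive pass; tree topology comes from NJ, not ML search; and the
conservation caller is phylogeny-free.
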