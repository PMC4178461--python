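# Methods

## Model

`ampliswarm` treats dereplicated amplicons as points of an abstract
amplicon-space in which neighbors differ by one edit (substitution,
insertion, or deletion). An OTU is a contiguous occupied region of that
space; the method assumes distinct biological clusters are separated by
empty regions. Clustering is agglomerative single linkage at a local
threshold *d*: the partition produced by the growth phase equals the
connected components of the graph whose edges join amplicon pairs with at
most *d* differences. This gives two structural guarantees that the test
suite checks on every clustering: every member of an OTU has a neighbor
within *d* inside the OTU (contiguity), and amplicons in different OTUs are
more than *d* apart (separation).

The number of differences between two amplicons is defined as the count of
mismatch plus indel columns in one optimal global alignment under the
transformed penalty system (below). It is **not** in general the
Levenshtein distance: the penalty-optimal alignment may trade one gap shape
for another, and the counted value may exceed the unit-cost edit distance.

## Pairwise alignment and the penalty transformation

The default similarity scheme is match +5, mismatch −4, gap opening −12,
gap extension −4 (a gap of length L scores open + L·extend). For
sequences of lengths m and n every global alignment satisfies

    2·S  =  match·(m + n) − P₂ ,

where P₂ charges 2·(match − mismatch) per mismatch column, 2·|open| per
gap, and match + 2·|extend| per gap column. Maximizing S is therefore
strictly equivalent to minimizing P₂, and the two systems admit identical
sets of optimal alignments — a property the tests verify set-wise by
exhaustive co-optimal enumeration. On the half scale the default penalties
are mismatch 9, gap opening 12, and gap extension 6.5, reported as 7
(round half up); optimality is always decided on the fraction-free doubled
scale (18 / 24 / 13), so the rounding never changes which alignments are
optimal. The reported `penalty_score` of an alignment is its half-scale
decomposition (9·X + Σ per gap (12 + 7·L)).

The aligner is a three-state affine Gotoh minimization over the full
dynamic-programming matrix (no banding, no 8-bit saturation); the
one-byte capacity (28 differences at the default penalties) is kept as an
analytic function. Backtracking is deterministic: from the terminal cell,
ties prefer the diagonal move, then a gap in the second sequence, then a
gap in the first; inside a gap, closing is preferred over extending.
Co-optimal alignments can contain different numbers of gap columns, so the
counted difference on adversarial inputs is a property of this pinned
tie-break, not of the sequences alone.

## k-mer parity prefilter

Each sequence is summarized by a 4ᵏ-bit occurrence-parity vector (k = 5 by
default; bit index encodes the k-mer with A=0, C=1, G=2, T=3, two bits per
base, big-endian). One edit changes the parity of at most 2k k-mers, so
two sequences within d edits differ in at most 2dk bits; pairs beyond that
Hamming distance, or differing in length by more than d, are skipped
without alignment. The filter is lossless (false positives only), and
⌈Hamming/2k⌉ is a valid lower bound on the **edit** distance. Sequences
shorter than k get the all-zero vector and fall through to the length and
alignment checks.

## Growth phase and the generation filter

Seeds are taken in pool order; dereplication sorts by decreasing abundance,
so the most abundant amplicon seeds the first OTU (a speed heuristic — the
partition does not depend on it). The seed pass aligns the seed against
every remaining amplicon, capturing those within d (generation 1) and
recording exact seed distances. Each generation-g subseed is then compared
only to candidates that may lie within (g+1)·d of the seed, after the
length/k-mer candidate filter at threshold d.

Because the counted difference is not a metric (see above), exceeding
(g+1)·d in *counted* seed distance does not prove a candidate is out of
reach of a subseed. Exclusions are therefore certified with the k-mer
parity lower bound on the true edit distance: a candidate is skipped only
when that bound exceeds (g+1)·d, while a counted distance within the bound
is accepted immediately. This keeps the generation filter lossless, which
is what makes the partition exactly equal to the single-linkage components
and hence input-order independent — both verified against brute-force
oracles in the tests.

Capture ties (two same-generation subseeds reaching one candidate) go to
the earlier subseed in capture order; this affects the capture tree and the
radius statistic, never membership. The OTU radius is the maximum over
members of the cumulated edge differences along the capture path from the
seed (the alternative reading — exact seed-to-member distance — is also
stored per member). A `threads` parameter is accepted for interface
compatibility; the implementation is sequential and results are identical
by contract for any thread count.

## Breaking phase

The capture tree of each OTU is searched for chains: members with at least
`peak_min_abundance` copies (default 100) are peaks; for every peak pair
the unique tree path from the primary (more abundant) to the secondary peak
is walked, and the interior member of minimum abundance defines the valley.
A valley is breakable when its minimum is strictly below the secondary
peak's abundance (plateaus do not count) and the ratio secondary/minimum is
at least `valley_ratio` (default 50). The stated ratio direction is the
one for which a threshold of 50 is meaningful. The cut removes the tree
edge between the valley minimum and its neighbor on the primary side, so
the valley amplicon stays with the component it ascends toward; each
component is re-rooted at its most abundant member, seed distances are
recomputed by exact alignment, and the search recurses until no breakable
valley remains — which makes a single refinement pass idempotent. OTUs
whose peaks are all below the threshold are left untouched, not discarded.

## Synthetic communities

The generator emulates a dereplicated amplicon survey at desk scale.
Defaults: 20 species, 150-nt random templates kept ≥ 13 differences apart
by rejection sampling, species abundances log-normal (μ = 4, σ = 1;
median ≈ 55 copies, occasional thousands — a few abundant species and many
rare ones) or even (100 copies each), and per-copy errors drawn from
Poisson(λ = 0.3) capped at 3 edits, with substitution:insertion:deletion
weights 80:10:10. The cap, together with the template floor, guarantees a
*designed d window* [3, 6] (more generally [max_edits,
min_inter − 2·max_edits − 1]) in which every species cloud is one connected
component and no two clouds touch, so the full pipeline must recover the
species partition exactly (ARI = 1) for every d in the window — the
structural form of the d-insensitivity property. The chained-community
fixture plants two peaks (1,000 and 500 copies) joined by an abundance-2
bridge of single-substitution steps, giving a valley ratio of 250.

What the generator does **not** model: sequencing-chemistry error
profiles, chimeras, length heterogeneity beyond small indels, and real
inter-species sequence structure. Passing tests therefore demonstrate the
algorithmic guarantees (exact single linkage, order invariance, lossless
filtering, valley rule), not field accuracy on real reads.

## Evaluation metrics

Recall, precision, and the adjusted Rand index are all computed from one
pair-count contingency table over unique amplicons (not read copies):
recall is the fraction of same-species pairs co-clustered, precision the
fraction of co-clustered pairs sharing a species, and the ARI the
Hubert–Arabie chance-corrected form. Degenerate cases are defined as 1.0
(no same-species pairs for recall, no co-clustered pairs for precision,
zero ARI denominator), which the field's reference implementations also
use.

## Numerical and scale choices

Alignment scores use 32-bit integers (amplicon-scale sequences stay far
from overflow); the inner loop is JIT-compiled. Test problem sizes are
chosen for exhaustiveness per amplicon rather than volume: oracle
comparisons run on 50 random pools of up to 200 amplicons (lengths
80–120 nt) at d ∈ {1, 2, 3}, order invariance on 100 shuffles of a
50-amplicon pool, and filter losslessness on the full single-edit
neighborhood of a 20-nt sequence. Score-system equivalence is checked
set-wise (all co-optimal alignments) exhaustively over two-letter
sequences to length 6 — the dynamic program only consults pairwise base
equality, so two letters realize the relevant match/mismatch patterns —
plus random four-letter pairs, with the traceback enumerator itself
validated against full brute-force enumeration at short lengths, and the
optimal-score identity checked on 500 longer random pairs.

## Known limitations

- Difference counts on inputs with many co-optimal gap placements depend
  on the pinned backtracking tie-break and may differ from other
  implementations of the same scoring scheme.
- The breaking phase operates on the capture tree produced by growth, not
  on a recomputed minimum spanning tree of all pairwise distances; cut
  placement and break scheduling (best ratio first, then deeper valley,
  then capture order) are implementation policy.
- The chain breaker runs in-process on `ClusteringResult` objects; a
  standalone re-loader for saved OTU lists plus capture-edge sidecar files
  is not provided.
- No SIMD batching, multi-byte score fallback, or true multi-threading;
  the implementation targets correctness at desk scale.
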