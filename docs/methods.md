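# Methods

## Sketching model

A genome is reduced to the set of its canonical k-mers (the numerically
smaller of each k-mer's 2-bit code and that of its reverse complement;
A=0, C=1, G=2, T=3, big-endian over positions) that pass a *substring
subspace* filter: the k-mer is kept iff the code of its central length-`l`
substring — offset `⌊(k−l)/2⌋`, a fixed convention of this package —
belongs to a retained set drawn once per study. The retained set is the
first `4^(l−r)` entries of a seeded permutation of `range(4^l)`, so exactly
a fraction `4^−r` of substring space (and, for random sequence, of k-mer
space) is sampled. Reduction is in factors of 4 so the retained count stays
a power of four.

The permutation is produced by numpy's PCG64 `Generator.permutation`
(a Fisher–Yates shuffle over 64-bit streams), which is documented and
platform-independent; the `.shuf` container records `(k, l, r, seed)`, a
magic string and a format version, making sampling decisions portable and
reproducible bit-for-bit. Because the filter is a membership test on the
k-mer itself rather than on a hash image, sketch union/intersection/
subtraction are exact set operations on genome k-mer space — there is no
hash-collision bias, and subtracting a reference sketch from an
individual's sketch leaves exactly the individual's differential k-mers.

Defaults: `k=21, l=11, r=2, seed=42`. `k=21` is the common sketching
compromise between specificity (random 21-mer collisions are negligible for
genomes below ~10 Mb) and mutation sensitivity; `l=11` keeps the enumerated
substring space (4 million codes) small while leaving headroom for `r` up
to 10; `r=2` (1/16 sampling) keeps desk-scale sketches in the tens of
thousands of k-mers.

### Multiplicity filter

All records of a file are pooled as one genome. K-mers must appear at least
`min_multiplicity` times: default 1 for FASTA (assemblies), 2 for FASTQ, so
that k-mers created by isolated sequencing errors — which are overwhelmingly
singletons at reasonable coverage — are suppressed in raw-read sketches.
Windows containing non-ACGT characters are skipped entirely (determinism
over sensitivity; no random base assignment).

## Distance estimation

With sketches S(A), S(B), the Jaccard index J = |∩|/|∪| is computed
exactly, and converted to a per-site divergence estimate by

    D = −(1/k) · ln( 2J / (1 + J) ),

the inverse of the Poisson k-mer-survival model: if substitutions hit sites
independently at rate D, a k-mer survives in both genomes with probability
≈ e^(−kD), which maps the expected shared fraction to J. The formula
diverges as J → 0, so D is reported as `min(formula, d_max)` with
`d_max = 1.0` by default. Capping everywhere (not only at J = 0) keeps D
monotone non-increasing in J — important because sketches of unrelated
genomes can produce arbitrarily small positive J. The cap is configurable;
1.0 is far beyond any distance at which the estimator is meaningful
(the model saturates near D ≈ 0.25–0.3 for k = 21).

Matrices are written as square relaxed PHYLIP: a count line, then one row
per taxon (name, whitespace, all n distances at 6 decimals). Names of any
length are allowed but must not contain whitespace. Fixed 6-decimal output
makes artifacts diffable and byte-reproducible.

## Tree construction

`nj` is the classical agglomerative algorithm: join the pair minimizing
`Q(i,j) = (n−2)·d(i,j) − R_i − R_j`, with limb lengths from the standard
split formula. Numerical policies:

- Negative limb lengths are clamped to zero with the deficit transferred to
  the sister limb (total pair depth preserved); final edges are clamped at 0.
- Ties in Q are broken by the lowest (row, column) index pair — this makes
  the output deterministic and is the contract that lets `dnj` match `nj`
  exactly.
- The final three clusters join at a trifurcating root: NJ trees are
  unrooted, and rooting is left to consumers.

`dnj` accelerates pair selection: rows are scanned in increasing distance
order and abandoned as soon as the bound `(n−2)·d(i,j) − R_i − max(R)`
exceeds the best Q found, which skips most Q evaluations. Only pairs that
provably cannot attain the minimum are pruned, and Q is evaluated with the
same floating-point expression as the full scan, so the selected pair — and
hence the topology, branch lengths and serialized Newick — is identical to
`nj`'s on every input, not just on matrices with unique minima. This
implementation targets topology equivalence, not the internals or the
asymptotics of published accelerated-NJ codes (the per-iteration row sort
here is O(n² log n)).

Newick output quotes names containing structural characters or whitespace
(single quotes, internal quotes doubled) and prints branch lengths at 6
decimals; repeated runs are byte-identical. The parser reports the string
position of syntax errors and rejects duplicate leaf names.

## Topology comparison

Each internal edge of the unrooted interpretation induces a bipartition of
the leaf set; splits are stored as the side not containing the
lexicographically smallest leaf, so rootings and child orderings do not
affect equality, and a binary root's duplicate edge collapses naturally.
Trivial splits are excluded. The normalized Robinson–Foulds distance is

    nRF = |splits(T1) Δ splits(T2)| / (|splits(T1)| + |splits(T2)|),

which reduces to RF / 2(n−3) for two fully resolved trees and handles
multifurcating trees gracefully (the alternative — normalizing by the
maximum possible RF — coincides on resolved trees). Two trees with no
internal edges at all are topologically identical and score 0. Branch
lengths are ignored.

## Pipelines

- **routine**: sketch all inputs → pairwise matrix (PHYLIP) → NJ/DNJ tree
  (Newick + ASCII rendering). Artifact-for-artifact identical to composing
  the individual operations.
- **reference subtraction**: additionally sketches a representative
  reference and subtracts it from every individual's sketch before the
  distance stage. Within a species, genomes share almost all k-mers; after
  sketch-level downsampling the informative differential k-mers are a tiny
  minority, and distances computed on full sketches are dominated by the
  shared backbone. Subtraction removes the backbone exactly, so distances
  reflect only differential k-mers. An individual whose remainder is empty
  is reported by name as an error.
- **placement**: each query is sketched and ranked against a local
  directory of sketches (a `SketchDatabase`; all members must share one
  parameter tuple); the top `N` neighbors per query (default 10, ties
  broken by name) are deduplicated by name and a routine-stage tree is
  built over queries plus neighbors. A TSV retrieval table
  (query, rank, neighbor, distance) is written alongside.
- **quick** dispatches one of the three from a single validated config and
  keeps all intermediates under one output directory; re-runs overwrite
  deterministically.

Every pipeline writes a `run.log` with input counts, sketch sizes and stage
timings.

## Synthetic data

The simulation module generates: uniform random genomes; substitution-only
mutants (each site independently replaced with probability `p` by a
uniformly chosen different base, so the expected mismatch fraction is
exactly `p`); genomes evolved along a tree by applying an independent
substitution process per edge with probability equal to the branch length
(probabilities are deliberately *not* compounded into rates — at the small
per-edge values used, the difference is second-order); and uniformly placed
single-end reads from both strands with i.i.d. per-base errors and constant
quality strings. All generators are deterministic per seed and write a JSON
manifest of their parameters.

What this emulates — and does not. The generator reproduces the one
mechanism the distance model inverts: independent point substitutions. It
produces no indels, rearrangements, repeats, compositional bias, coverage
bias or realistic quality profiles. Tests passing on these fixtures
demonstrate the correctness of the sketching/distance/tree machinery and
the self-consistency of the estimator with its own model; they do not
certify accuracy on real genomes, where repeat content and structural
variation violate the model's assumptions.

## Verification problem sizes

The test suite checks, among others: exhaustive encode/canonicalize
identities over all 4^5 5-mers; sketch equality with a string-scan oracle on
100 random genomes (r=0); recovery of simulated substitution rates
p ∈ {0.01, 0.05} from 1 Mb genomes at r ∈ {0, 2} (median of 10 replicates
within 15% relative error); NJ consistency on 100 random additive matrices
(n ≤ 10, path lengths to 1e−9); `dnj` ≡ `nj` Newick equality on 200 random
matrices (n = 4–32); end-to-end topology recovery for 8 genomes of 200 kb
evolved along a known tree (edges 0.02–0.05); and round trips of all four
file formats. These sizes were chosen as the smallest at which the checked
statistics are comfortably separated from their failure modes.

## Known limitations

- The distance estimator saturates for divergences beyond ≈ ln(2)/k and is
  then reported at the cap; trees over very distant genomes degrade to
  star-like shapes.
- Sketch containers are JSON for transparency, trading file size and parse
  speed; they are not compatible with any external sketching tool's format.
- `dnj` matches `nj` exactly but is engineered for identical output, not
  for large-n performance.
- FASTQ multiplicity is counted pooled across all reads of a file;
  per-read counting is not offered.
- Amino-acid alphabets, paired-end semantics and remote databases are out
  of scope.
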