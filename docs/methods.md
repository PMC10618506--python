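# Methods

## The funnel

The package evaluates alignment-free genome encodings by how well they
reproduce alignment-based distances, in three stages that progressively
narrow the field (hence "funnel"):

1. **Matrix stage.** Every encoding maps each genome to a fixed-length
   descriptor; pairwise Euclidean distances give a matrix per encoding.
   Every reference alignment gives a Jukes–Cantor matrix. All matrices are
   min-max normalized so that methods producing numerically large or small
   distances are compared on shape, not scale. Encodings are ranked per
   reference by the Euclidean norm of the matrix difference, counting each
   unordered pair of taxa once (strict upper triangle); a full-matrix mode
   is available via `matrix_euclidean(..., full=True)`.
2. **Tree stage.** Each matrix is turned into a neighbor-joining tree and
   each (encoding, reference) pair is scored with nine tree-comparison
   metrics.
3. **Shortlist.** Per metric, the mean over all (encoding, reference)
   cells is the "overall average"; an encoding is shortlisted when its
   value is below the overall average for at least 5 of the 9 metrics.
   The majority threshold is configurable (`FunnelConfig.shortlist_majority`).

Normalization is applied symmetrically to encoded and reference matrices;
references enter as files (aligned FASTA or matrix CSV) or in-memory
objects — no aligner is ever invoked by the package.

## Encodings: conventions and defaults

Constants for the six per-base maps, listed in the `encoders` module
docstring, are the standard values from the genomic signal-processing
literature. Choices the literature leaves open are fixed as follows:

- **CGR corners** A=(0,0), C=(0,1), G=(1,1), T=(1,0), start at (½, ½)
  (Jeffrey's convention). The trajectory is treated as the complex series
  x + iy; its DFT power spectrum drops the DC term by default (`keep_dc`
  retains it), since DC encodes composition already captured by count-based
  schemes and otherwise dominates every moment.
- **Dinucleotides** are placed at angles 2πj/16, j being the rank in
  lexicographic order AA, AC, …, TT; the signal is the (cos θ, sin θ) pair
  per overlapping dinucleotide.
- **I Ching hexagrams**: each base contributes two binary lines (A=00,
  C=01, G=10, T=11), so a codon is a 6-bit hexagram index 0–63. Note this
  coincides numerically with the triplet scheme's lexicographic codon rank;
  both schemes are kept because they are distinct methods in the field with
  independently varying conventions.
- **Triplet reading frame**: non-overlapping codons from position 1; a
  trailing partial codon is dropped.
- **Inter-nucleotide distance**: at position i, the offset j − i to the
  nearest j > i with the same base and j ≡ i (mod k); 0 if none. The
  stride default is k = 1 (the classical definition).
- **Entropy windows**: Shannon entropy in bits (log₂) over base
  frequencies in a sliding window of width w = 12 by default — wide enough
  for a non-trivial 4-symbol distribution, narrow enough to remain local.
- **Stacking enthalpies**: the unified nearest-neighbor ΔH table
  (SantaLucia 1998, kcal/mol), extended to all 16 dinucleotides via
  reverse-complement symmetry; kept as a single named constant.
- **k-mer schemes** default to k = 3 (64 k-mers), balancing resolution
  against sparsity at the 10³–10⁴-site scale the tests use. k-mer counts
  are L1-normalized to frequencies so sequence length cancels. The k-mer
  natural vector uses 1-based slot positions and defines D₂ = 0 for k-mers
  occurring at most once.
- **Moment vectors** default to J = 4 (mean, σ, skewness, kurtosis) per
  channel — the lowest order that captures asymmetry and tail weight;
  standardized moments of a constant channel are defined as 0.
- **Ambiguity policy**: IUPAC codes other than N become N on input (with a
  logged count). Per-position maps assign N the mean of the four base
  values; windowed schemes (pairs, codons, k-mers, entropy windows) drop
  any window containing an N.

### Spectral schemes and the descriptor choice

The published forms of the Fourier-power-spectrum and CGR-DFT methods
compare power spectra directly, even-scaled to a common length when
sequences differ in length. The funnel's generic reduction — moment vectors
— is also available for them, but four moments of a heavy-tailed power
spectrum retain very little of the between-genome signal: on synthetic JC
data the moment-reduced CGR spectrum correlates with the alignment
reference at Spearman ρ ≈ 0.08, versus ρ ≈ 0.9 for the even-scaled
spectrum. `descriptor_batch(..., m=...)` therefore exposes the spectral
descriptor, and the replication sweep (`ranking_sweep`) uses it for `fps`
and `cgrdft` with m = longest sequence length − 1 (no free parameter);
all other schemes go through moments.

## Distances

Jukes–Cantor distances use pairwise deletion: sites where either sequence
carries a gap or N are excluded per pair (mirroring the common default in
alignment software). p ≥ 3/4 is reported as a saturation error naming the
pair rather than silently truncated. Min-max normalization takes its
extremes over off-diagonal entries only — including the zero diagonal
would pin the minimum at 0 and distort matrices whose smallest true
distance is positive — and a matrix with constant off-diagonal entries is
rejected as degenerate.

## Trees

Neighbor joining is the classic Studier–Keppler formulation. Two
determinism guarantees: ties in the Q criterion are broken by the
lexicographically smallest pair of subtree labels, and negative
branch-length estimates are clamped to zero with the total deficit logged
(clamping, rather than redistributing, because the downstream metrics are
topology-dominated). Rooted views for the rooted metrics come from
midpoint rooting — the root at half the tree diameter, ties broken by the
lexicographically smallest leaf pair — chosen because it needs no outgroup
and is the common default in tree viewers.

## Tree metrics

Unrooted metrics (RF, matching pair, quartet, path difference, cophenetic
L2) are computed on unrooted views (a degree-two root is suppressed);
rooted metrics (triples, matching cluster, nodal splitted, MAST) consume
rooted views, midpoint-rooting unrooted input. Conventions follow the
TreeCmp family: RF is half the symmetric difference of nontrivial splits;
the matching metrics solve a minimum-weight assignment (Hungarian
algorithm) over splits/clusters with symmetric-difference-style costs,
padding unmatched items against the empty set; MAST distance is
n − |maximum agreement subtree|, computed exactly by dynamic programming
over rooted node pairs with a max-weight child matching at multifurcations;
nodal splitted is the L2 norm over ordered leaf pairs of the edge count
from a leaf to the pair's LCA. Quartet and triple topologies are derived
from path-length matrices and LCA depths respectively, treating ties as
unresolved (star).

All algorithms are exact and written for desk scale (up to a few hundred
taxa; the quartet metric enumerates all C(n, 4) subsets). Every metric is
tested against an independent brute-force oracle on random small trees:
split enumeration, ancestor-chain MRCA logic, path-disjointness quartets,
subset-search MAST, exhaustive assignment matchings. Where a closed-form
combinatorial maximum exists (quartet C(n,4), triples C(n,3), RF n−3,
MAST n) a normalized value in [0, 1] is reported; the other metrics report
no normalizer.

## Synthetic data

The simulator emulates the structure of curated virus-genome sets: n
related sequences of equal length L, evolved along a known tree under
JC69 — along a branch of length t each site substitutes with probability
p(t) = (3/4)(1 − e^(−4t/3)) to a uniformly chosen different base. Defaults
(n = 10, L = 3000, scale 0.1 expected substitutions/site) give divergence
in the range where JC correction matters but saturation is rare. Tree
models: Yule topology with i.i.d. Exponential(scale) branch lengths
(default), or a Kingman coalescent (ultrametric). One numpy generator
stream drives topology, root sequence and substitutions, so a seed replays
bit for bit.

What the simulator deliberately omits: indels (so the truth alignment is
the sequence set itself — isolating encoding behaviour from alignment
error), rate heterogeneity across sites, unequal base frequencies,
recombination, and genome-scale composition structure (coding vs
non-coding). Passing tests therefore demonstrate correctness of the
machinery and the recoverability of JC-generated structure; they do not by
themselves establish how the encodings rank on real viral genomes, where
composition bias and indel-driven alignment error matter.

## Problem sizes in the shipped experiments

The test suite and acceptance script size their experiments for a single
CPU: oracle sweeps use 200 tree pairs with 4–8 taxa; NJ consistency uses
100 trees with 5–12 taxa; the Monte-Carlo JC check uses one 100 000-site
branch; the replication sweep uses 20 datasets of 8–16 taxa and 3000–5000
sites. In that sweep the k-mer family, the CGR spectrum and the Fourier
power spectrum populate the top of the ranking against the JC reference,
with the k-mer natural vector and the CGR spectrum in the top half of the
seventeen encodings in a clear majority of replicates — the same
qualitative picture the funnel is designed to surface on real data.

## Known limitations

- The quartet metric is O(n⁴); beyond a few hundred taxa it dominates
  runtime.
- The funnel's shortlist rule (majority of metrics under the overall
  average) is one reasonable operationalization of "consistently better
  than average"; alternatives (mean rank, count thresholds) can be built
  from the long-format report.
- JC69 is both the simulator and the reference-distance model, which is
  exactly what makes ground truth exact — but it means the synthetic
  experiments cannot detect model misspecification effects present in real
  data.
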