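# Methods

This note documents the algorithms, parameter defaults, and numerical
choices behind `strucphy`, plus the design of the synthetic fixture
generators used throughout the test suite.

## 1. Chain model and size filter

A structure file is decomposed with gemmi into one record per polymer
chain: the deposited one-letter sequence (FASTA if supplied, else the
SEQRES-derived entity sequence, else the resolved residues), the resolved
sequence, and one Cα coordinate per resolved residue (first model, first
alternate location; non-standard residues with tabulated parents map to
the parent code, e.g. MSE → M; unknowns become `X`).

*Chain size* is the deposited-sequence length — the size of the protein,
not of the crystallographically resolved part. The inclusion filter keeps
chains of size ≥ 50 aa: shorter chains are mostly peptides and tags whose
"fold" carries little phylogenetic signal.

## 2. Sequence comparison

Two measures, for two jobs:

* **Clustering identity** — semi-global alignment (free terminal gaps;
  match +1, mismatch −1, gap open −2, extend −1, via Biopython's
  `PairwiseAligner`). Identity = identical columns / internal (non-terminal-gap)
  columns, with the denominator floored at the shorter sequence length.
  The floor matters: with free end gaps and ±1 scoring, two unrelated
  sequences maximise their score with a tiny coincidentally matching
  overlap, which would otherwise report identity ≈ 1 and merge unrelated
  clusters. The coverage-aware denominator (as in centroid-linkage
  clustering tools) removes that failure mode without affecting
  near-full-length matches.
* **Annotation statistics** — Smith–Waterman local alignment under
  BLOSUM62 (gap open 11, extend 1). Identity% and similarity% (positive
  BLOSUM62 pairs, i.e. BLAST "positives") are fractions of local-alignment
  columns. Bit score = (λ·S − ln K)/ln 2 with the published gapped
  constants λ = 0.267, K = 0.041; E-value = m·n·2^(−bits) over the product
  search space (a `search_space` parameter allows database-scale
  extrapolation). A pair with no positive-scoring local alignment is
  recorded as NO_SIMILARITY (−1 in every field).

Both measures canonicalise the argument order internally, so they are
exactly symmetric (bit-for-bit), which the determinism guarantees below
rely on.

## 3. Secondary-structure assignment (Cα only)

A P-SEA-style geometric assignment from Cα distances alone:

| element | candidate criterion (Å)                         | min run | tail extension |
|---------|--------------------------------------------------|---------|----------------|
| helix   | d(i,i+3) ∈ [4.5, 6.0] and d(i,i+4) ∈ [5.7, 7.0] | 5       | +4 residues    |
| strand  | d(i,i+2) ∈ [6.2, 7.2] and d(i,i+3) ∈ [9.3, 10.8]| 3       | +3 residues    |

Runs of candidate positions are turned into elements (helix takes
precedence on overlap); each element gets an axis by SVD line fit through
a 4-residue smoothed trace, with endpoints and midpoint derived from the
projection of the terminal residues onto the axis.

## 4. Structural alignment and Qscore

The aligner is Cα-only and proceeds seed → refine → score:

1. **Seeds.** Every same-kind SSE pair whose axis lengths are compatible
   generates a rigid transform by Kabsch fit of the four axis endpoints,
   keeping pairs within 30° axis angle and 5 Å midpoint separation after
   a coarse compatibility screen. These are *always* supplemented by
   gapless sliding-window seeds (Kabsch over a 15-residue window at up to
   80 strided diagonal offsets): coordinate noise truncates detected SSE
   boundaries, and endpoint-based seeds can then land one helix-turn out
   of register — a local optimum the refinement cannot escape. Duplicate
   transforms (‖ΔR‖_F < 0.05, |Δt| < 0.5 Å) are merged, seeds are ranked
   by a cKDTree count of residues brought within the distance cutoff, and
   at most `max_seeds` are refined, stopping early at Qscore ≥ 0.999.
2. **Refinement.** Given a transform: a Needleman–Wunsch pass with score
   1/(1 + (d/r0)²) and zero gap penalty produces a sequential
   correspondence; pairs farther than `d_cut` = 5 Å are dropped; Kabsch
   refits the transform; repeat until the correspondence set repeats or
   `max_iter` = 50. The best iterate by Qscore is kept.
3. **Acceptance.** A result is structural similarity only if it has
   ≥ `min_aligned` = 10 aligned pairs **and** ≥ `sse_anchor_min` = 3 of
   them fall inside detected SSEs of *both* chains. The anchor criterion
   exists because a zero-gap-penalty DP accumulates scattered coincidental
   pairs between any two chains; without it a 60-residue helix vs a
   60-residue coil scores Q ≈ 0.14 and the NO_SIMILARITY sentinel would
   never fire. Chains with zero detectable SSEs always report
   NO_SIMILARITY — consistent with an SSE-matching engine.

**Qscore** = N_align² / ((1 + (RMSD/R0)²) · N1 · N2) with R0 = 3 Å, where
N1, N2 are the *resolved* residue counts of the two chains (the quantities
the aligner can actually superpose). It is 1 exactly when two identical
structures fully align at RMSD 0.

Determinism and symmetry: chains are compared in canonical lexicographic
id order and the result is re-oriented afterwards, so `align(a, b)` and
`align(b, a)` are bit-for-bit mirror images. Kabsch uses
`scipy.spatial.transform.Rotation.align_vectors`, which returns a proper
rotation (det +1) even for degenerate point sets; the test suite checks it
against a brute-force rigid-fit minimiser to 1e-6.

## 5. Clustering, vetting, confidence

Greedy centroid-linkage clustering at 90% identity: chains in decreasing
size order (ties lexicographic), each joining the first centroid at
identity ≥ threshold, else founding a new cluster. Cluster ids are
5-digit ordinals in founding order. Per-member confidence: low iff
|size − cluster median| > population SD of member sizes (zero SD means any
deviation flags low).

Centroid vetting runs the structural self-check (≥ 1 SSE and self-Qscore
≥ 0.99) on each centroid; a failing centroid is replaced by the largest
passing member, and clusters with no passing member are removed, with
every action logged to `vetting.tsv`.

## 6. Distances, trees, serialisation

Distance = 1 − Qscore; NO_SIMILARITY maps to the maximal distance 1.0.
Distance matrices are validated (symmetry, zero diagonal, [0, 1]) before
use.

Neighbour joining is hand-implemented (Saitou–Nei) because its edge
semantics are pinned: ties in the Q-criterion break toward the smallest
(i, j) index pair (strict `<` with a 1e-15 guard), negative branch-length
estimates are clamped to 0, the unrooted tree is represented with a
trifurcating root (a single halved edge for 2 taxa). NJ reconstructs
additive matrices exactly; the tests verify this against randomly
generated trees and cross-check against dendropy's NJ.

NEXUS output is a TAXA block plus a DISTANCES block with
`FORMAT TRIANGLE=BOTH DIAGONAL` (full square matrix, 9 decimals); Newick
uses 6-decimal branch lengths; both share a `[A-Za-z0-9_]` label
sanitiser.

## 7. Pipeline and persistence

The build funnel: read/split → size filter → cluster → confidence flags →
vet centroids → all-pairs centroid scores (Qscore, RMSD, n_aligned plus
the local-sequence statistics, with fixed roundings: Qscore 6 dp, RMSD
4 dp, percentages 2 dp, E-value 6 significant digits). The database is a
plain directory — `chains.tsv`, `clusters.tsv`, `scores.tsv`,
`vetting.tsv`, `meta.json`, `chains/*.pdb` — so it is inspectable and
diff-able; rebuilding from the same input is byte-identical (verified in
the tests), because every stage is deterministic and every table is
written in a canonical order.

Query modes: `neighbours` (hits at Qscore ≥ 0.1 — below that, structural
similarity enters its twilight zone — ranked by Qscore, id tie-break,
top 50) and `clusters` (per-member superposition against the centroid).
Annotations (SCOP/CATH/description) are joined from a user-supplied local
TSV keyed by `member_id`; absent annotations render as `N/A`.

## 8. Synthetic fixture generators

Ideal-geometry Cα builders: α-helix (rise 1.5 Å, twist 100°, radius
2.3 Å), β-strand (rise 3.3 Å with ±0.94 Å zig-zag, step exactly 3.8 Å),
and coil (smoothed self-avoiding random walk with 3.8 Å steps). Chains
are concatenations of such segments; `perturb_chain` adds iid Gaussian
coordinate noise, `mutate_seq` substitutes residues at a given rate.

The `family-set` preset (27 chains) plants a known ground truth: two
~100-residue founders of opposite SSE class (helix-only and strand-only),
each with 7 near-identical copies (2% mutation, 0.2 Å noise — one
cluster) and 5 diverged relatives (50% mutation, 0.2 Å noise — separate
clusters, same fold), plus one 60-residue coil singleton that fails
centroid vetting. The 0.2 Å noise level is deliberate: the strand
detection windows are only ~1 Å wide, and above ~0.4 Å noise strand
assignment becomes unreliable — the generator stays in the regime where
the ground truth is actually recoverable. Opposite SSE classes guarantee
the two families fall below the 0.1 Qscore cutoff (measured cross-family
maximum ≈ 0.06), so neighbourhood queries have an exact expected answer.

Realism limits: fixtures are Cα traces with ideal local geometry, no side
chains, no chain breaks, single-model, single-conformer; sequence and
structure divergence are independent knobs rather than co-evolved.

## 9. Parameter defaults

| parameter | default | rationale |
|---|---|---|
| `min_length` | 50 aa | peptide/tag exclusion threshold on deposited size |
| `identity` | 0.90 | redundancy-removal threshold (point mutants, re-depositions) |
| `r0` | 3.0 Å | Qscore distance scale; ~tight superposition RMSD |
| `d_cut` | 5.0 Å | pair rejection during refinement; ~1.3 Cα steps |
| `min_aligned` | 10 | fewer pairs cannot define a rigid transform meaningfully |
| `sse_anchor_min` | 3 | minimum SSE-anchored pairs for structural similarity |
| `max_iter` | 50 | refinement always converges far earlier in practice |
| `max_seeds` | 100 | cost cap; agreement ranking makes later seeds redundant |
| `window` | 15 res | sliding-window seed size; ~1 SSE length |
| `seed_angle_tol` / `seed_dist_tol` | 30° / 5 Å | SSE-pair compatibility screen |
| `early_stop_q` | 0.999 | stop refining seeds once essentially perfect |
| neighbour cutoff | Qscore 0.1 | structural twilight-zone boundary |
| neighbour list | top 50 | reporting cap |

## 10. Problem sizes and cost

Intended working scale per query: tens of thousands of chains for
clustering, hundreds–thousands of vetted centroids for all-pairs scoring
(O(n²) alignments; the 27-chain demo builds in ~35 s on one CPU, 66
centroid pairs). Alignment cost per pair is O(seeds · iter · n1·n2) for
the DP, with n ≈ 100–500 residues typical. NJ is O(n³) in the number of
taxa, negligible at neighbourhood sizes (≤ 51).

## 11. Known limitations

* The aligner is rigid-body and sequential: no flexible/multi-domain
  alignment, no non-sequential (circularly permuted) correspondences.
* SSE assignment from Cα geometry alone is noise-sensitive near its
  window boundaries; heavily distorted strands can drop below
  detectability and push genuinely similar pairs to NO_SIMILARITY.
* Karlin–Altschul constants are fixed (BLOSUM62 11/1); E-values for other
  scoring schemes would need their own λ, K.
* Greedy clustering is order-deterministic but not globally optimal;
  borderline chains can join the first rather than the best centroid
  (`best_hit=True` trades speed for the latter).
* Qscore normalises by resolved residue counts; chains with large
  unresolved regions score higher than a deposited-length normalisation
  would give.
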