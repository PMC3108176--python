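# Methods

`barcodegap` implements the standard distance-based DNA-barcoding workflow
for protein-coding animal barcodes (the 5′ ~652 bp COI fragment), together
with a sequence simulator that generates libraries with a controlled
divergence structure. This note records the models, conventions and design
choices behind each stage.

## Quality control and alignment

A barcode record passes QC when its length is **strictly greater** than
`min_length` (default 500 bp) and its best reading frame under the
vertebrate mitochondrial code (NCBI table 2, configurable) contains no
internal stop codons. The best frame is the one of {0, 1, 2} minimizing
internal stops, ties resolved to the lowest index. Two conventions matter
for fragments: the terminal, possibly partial codon is never counted
(barcodes routinely end mid-codon), and a codon containing any IUPAC
ambiguity code is never counted as a stop.

Because QC-passed sequences of one coding region are indel-free, no aligner
is used: each sequence is trimmed to its first complete codon and placed on
a shared codon grid ("frame anchoring"). With `min_coverage = 1.0`
(default) the comparison window is the strict intersection of all rows, so
every pairwise comparison uses identical columns; lowering it (floor 0.5)
keeps columns covered by at least that fraction of records and pads shorter
rows at the 3′ end with `-`, a character deliberately distinct from IUPAC
`N`. Frame anchoring aligns phase, not absolute gene position: it assumes
all inputs come from the same amplicon window, which holds for standard
barcode libraries and for everything the simulator emits. A consensus
window of 652 bp is an emergent property of full-length inputs, not an
enforced constant.

## K2P distances

Distances use the Kimura two-parameter model. For a sequence pair, sites
where either row carries a pad or ambiguity code are excluded (pairwise
deletion — the common default in distance software; the alternative,
complete deletion, shifts third-decimal values on real data). With P and Q
the transition and transversion proportions over the compared sites,

    d = −(1/2)·ln(1 − 2P − Q) − (1/4)·ln(1 − 2Q)

in substitutions per site; reports multiply by 100 and print three decimals.
Pairs for which a logarithm argument is non-positive (saturation) raise an
error identifying the pair rather than clamping — fish COI divergences top
out near 40%, far from saturation, so a saturated pair indicates bad input.
A pair with zero comparable sites is likewise a hard error.

## Rank partition and gap statistics

Every unordered pair falls in exactly one category by lowest shared rank:
S (conspecific), G (congeneric), F (confamilial across genera), O (same
order), C (same class); cross-class pairs are out of scope and raise.
Summary rows report taxa (distinct taxa at the category's rank contributing
≥ 1 pair — the counting rule is stated in output metadata because printed
survey tables leave it ambiguous), comparisons, mean, median, min, max and
SE. The SE treats pairwise distances as independent, which they are not;
this mirrors the conventional survey-table presentation and should not be
read as a defensible variance. The TSV writer suppresses the median above
the family rank, matching the usual printed convention; the value is still
computed and present in JSON.

Boxplot statistics use Tukey hinges (the SPSS convention: halves include
the median when n is odd; hinge depth (⌊(n+1)/2⌋+1)/2), whiskers at the
most extreme observations within 1.5×IQR of the hinges, mild outliers
between 1.5 and 3×IQR beyond a hinge, extreme outliers past 3×IQR. At
least 5 values are required. Alternative quantile definitions shift hinges
on small samples; the choice is fixed and tested.

Mann-Whitney U uses midranks for ties; the p-value is exact when the
smaller sample has ≤ 8 observations and no ties are present, otherwise a
normal approximation with tie-corrected variance and continuity correction
(the p-values come from `scipy.stats.mannwhitneyu`; U and the standardized
z are computed in-module). Two-sided p-values are reported for S vs G,
G vs F and S vs F.

Overlap reports compare a lower category's maximum with an upper category's
minimum and list every pair on the wrong side of the other distribution's
extreme; per-family reports are produced only for families with ≥ 2 genera,
where within-family S/G/F comparisons exist.

## Neighbor joining and tree diagnostics

The tree builder is the classic Saitou–Nei agglomeration with the standard
two-point branch-length formulas and a final trifurcation, i.e. an unrooted
tree. Determinism: ties in the Q criterion resolve to the lexicographically
smallest pair of node creation indices, and the Q search runs over the
upper triangle only (floating-point evaluation order makes the full Q
matrix asymmetric in the last ulp). Negative branch lengths are clamped to
zero with the deficit shifted to the sibling edge (split across both
siblings at the final trifurcation); raw estimates are retained as node
metadata. For additive matrices the implementation recovers the generating
topology and reproduces path lengths to ≤ 1e−10 (property-tested), and its
splits match an independent NJ implementation on perturbed matrices.

Species monophyly is a pure bipartition question: a species with ≥ 2
individuals is monophyletic iff some edge of the unrooted tree isolates
exactly its leaf set. Singletons are vacuously monophyletic and are
reported separately, outside the denominator. Family cohesion is
operationalized as the **largest family-pure edge-defined cluster**: a
family is cohesive when that cluster holds all its specimens, strays are
the members outside it, and the specimen-level cohesion fraction is the
share of all specimens inside their family's largest pure cluster. Other
formalizations of "expected division of families" exist; the rule used is
recorded in report metadata.

Introgression flags target the classic mitochondrial pattern: individuals
of one species carrying another species' haplotypes. A species pair is
screened when its minimum between-species K2P distance falls below the
intraspecific threshold (default 2.0%) — haplotype sharing, orders of
magnitude below normal congeneric divergence. The recipient (nested) side
is identified by distance asymmetry: its sub-threshold individuals are
simultaneously diverged beyond the threshold from their own remaining
conspecifics, whereas the donor's individuals remain close to theirs. The
tree arbitrates only when distance cannot orient the pair (full
mitochondrial capture, where one species lies entirely within the threshold
of the other): the host is then the species whose smallest edge-defined
cluster encloses the other's leaves. One flag per species pair, listing
the nested individuals. After full capture the two species' haplotypes may
interleave in the tree, in which case the host/nested orientation is not
identifiable from mitochondrial data at all; the flag still names the pair,
with a deterministic but arbitrary orientation. Distance-first detection is deliberately robust to
the neighbor-joining placement of a captured haplotype, which may attach
inside the donor's cluster or as its immediate sister depending on
within-species noise; both placements are the same biological signal.

## Identification and cryptic flags

Identification is nearest-species matching with an explicit threshold t
(default 2.0%, always echoed in results): each reference species is
represented by its minimum distance to the query; `match` when exactly one
species lies within t, `ambiguous` when several do, `novel_candidate` when
none does. A distance exactly at t counts as within (documented tie rule).
The 2.0% default sits above typical fish COI intraspecific maxima (~2%)
and far below the >10% congeneric regime, and every report states the value
used. Cryptic-species flags list species whose maximum intraspecific
distance exceeds a (stricter, default 1.0%) threshold, with the offending
pair.

## Simulator

The generator draws an approximately ultrametric taxonomy tree and evolves
sequences along it. Rank split heights are half the configured expected
pairwise divergence, jittered ±20% (relative) per node to avoid exactly
ultrametric ties; a child's height is capped at 0.9× its parent's.
Default depths — intraspecific 0.003, congeneric 0.16, confamilial 0.20,
interfamily 0.25 substitutions/site — reproduce the divergence regime of
published fish COI surveys (intraspecific means ~0.3%, congeneric means in
the mid-teens, family/order means in the 20–25% band). Default taxon
counts (12 families × 2 genera × 3 species × 3 individuals = 216
sequences, 652 bp) emulate a ~100-species coastal survey at a size where
the full pipeline, including the O(n³) tree build, runs in seconds.

Substitutions follow the two-rate Markov process matching the K2P model:
per-site substitution rate normalized to 1, transition target chosen with
probability κ/(κ+2) (default κ = 4, a typical fish mtDNA transition bias),
each transversion 1/(κ+2). Branches are realized by a Poisson draw of
event counts and sequential application, which is exact for this
uniform-total-rate process. Two realism features sit on top and are **not**
part of the distance model: third codon positions evolve at 5× the rate of
first/second positions (rates renormalized to mean 1), and proposed
substitutions creating an in-frame stop are redrawn among the remaining
targets (suppressed if none is viable), so every emitted sequence passes QC
by construction. Both can be disabled (`third_position_rate=1.0`,
`enforce_orf=False`). Parameter-recovery experiments run with both
disabled: site-rate heterogeneity biases pooled K2P estimates downward
(Jensen's inequality; ~6% relative at d = 0.15), so a recovery check under
the mismatched pooled estimator would measure that bias, not estimator
correctness.

Introgression injection replaces chosen recipient individuals' sequences
with fresh draws from the donor's intraspecific lineage: a random donor
individual's haplotype evolved onward by half the intraspecific depth.
Drawing from a crown haplotype (rather than the species ancestor) makes the
introgressed lineage nest *inside* the donor cluster, the pattern seen in
real mitochondrial capture. Cryptic species are created at tree level: the
species' root is placed at `cryptic_depth` (default 0.03) with two shallow
subclusters. The truth record (generating tree, taxonomy, event lists) is
sufficient to score every downstream flag exactly. Everything is
deterministic under a seed, to the byte, in all written outputs.

What the simulator does not model: coalescent population structure within
species, indels, sequencing error, contamination, missing data, rate
variation across lineages, and codon-usage structure beyond the stop-codon
constraint. Passing tests on simulated data therefore demonstrate the
pipeline's correctness under the stated generative model, not robustness to
every artifact of real libraries; the real-data checks in
`tests/test_acceptance.py` exist for that purpose and require the fetched
survey dataset.

## Numerical conventions and degenerate inputs

- Distances are kept in substitutions/site internally; percent only at
  reporting boundaries (TSV: 3 decimals; JSON: full precision).
- A single-pair category uses the SE = 0 convention.
- Analysis of n = 2 records produces distance/summary output but skips the
  tree stage with a warning (NJ needs n ≥ 3).
- `qc_filter` is idempotent; rerunning the pipeline on identical inputs is
  bit-identical (no hidden state, no wall-clock in reports).
- Seeds fix everything: the simulator consumes a single `numpy` Generator
  in a fixed traversal order.
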