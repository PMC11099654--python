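# Methods

This note documents the models, algorithms and parameter choices
behind `structmsa`, in enough detail to reproduce or question them.

## Sequence identity and clustering

Pairwise sequence identity (SI) is computed from a global alignment
(BLOSUM62, affine gaps: open −10, extend −0.5) as the number of
identically aligned residue pairs divided by the length of the
*shorter* sequence, so a fragment contained in a longer sequence
scores 1.0.  Clustering is greedy and representative-based: sequences
are visited longest-first (ties broken by id) and join the first
cluster whose representative they match at or above the threshold.
This is the classic CD-HIT-style scheme without its k-mer prefilter —
every comparison runs the full alignment, trading speed for exactness
and determinism at the scales this package targets (tens to hundreds
of sequences).  Consequences: cluster memberships are reproducible
bit-for-bit, and the threshold-monotonicity of cluster counts holds
exactly.

Subset creation reuses the same clustering at a low threshold
(default 0.3).  Clusters at or above `min_subset_size` (default 2)
become subsets.  Smaller clusters are either returned as orphans or,
with collation (the pipeline default), pooled first-fit-decreasing
into extra subsets capped at the median regular-subset size; a
trailing pool too small to align merges into its neighbour.  Collation
is the default because pooled sequences then pass through the
structure-aware subset aligner, which is considerably more robust at
low SI than inserting each orphan by profile alignment alone.

## Structure acquisition and validation

Each sequence is routed to at most one structure source: a
user-provided file matched by normalised id (file stem, case-folded),
else an accession-keyed model database (requires a UniProt accession
in the FASTA header), else a sequence-based predictor for chains
shorter than 400 residues (the bound is strict: length ≤ 399).  Live
fetchers for the two web services exist behind the same provider
interface but the test suite exercises only the local-directory
provider; acquisition is best-effort, and any provider failure demotes
the sequence to *structureless* rather than aborting.

Every fetched structure is validated by deriving the chain's
one-letter sequence from residue names (first chain with CA atoms
unless a chain id is given; highest-occupancy altloc; non-standard
residues map to their parent amino acid, unknowns to X) and globally
aligning it to the input sequence with identity scoring.  The
alignment defines the resolved-position mask; below 95% identity over
resolved positions the file is rejected as a mismatch.  Structures
whose unresolved fraction exceeds `max_unresolved_fraction` (default
0.25 — deliberately conservative, configurable) are excluded from the
run entirely, since a mostly-missing backbone would poison the
structural scoring.

## Secondary structure

Three-state strings (H/E/C) come either from classic DSSP output
(8→3 collapse: H,G,I→H; E,B→E; everything else, including the
polyproline code, →C) or from a built-in CA-geometry assignment in the
spirit of P-SEA, which needs nothing beyond the CA trace that every
predicted model has:

- helix flag at i: |CA(i)−CA(i+3)| ∈ 5.5±0.5 Å and |CA(i)−CA(i+4)| ∈
  6.4±0.6 Å; runs of ≥5 flags label positions i…i+4 of the run H.
- strand flag at i: |CA(i)−CA(i+2)| ∈ 6.7±0.6 Å and the backbone angle
  at CA(i) between its neighbours in [120°, 155°]; runs of ≥3 flags
  label positions i−1…i+2 E (the flag already validates geometry at
  i−1).  The 155° cap matters: real strands zigzag near 123°, whereas
  near-straight stretches of loop would otherwise satisfy the distance
  window and acquire spurious E labels that measurably perturb
  downstream alignment registers.
- everything else, and all unresolved positions, is C.

On ideal geometry the assignment recovers all interior block positions;
block termini (positions missing window partners) may relax to C,
which is why conserved-block detection downstream uses a fractional
threshold rather than unanimity.

## The structure-aware aligner

All alignments in the package reduce to one primitive: global
Needleman–Wunsch/Gotoh over a precomputed position-score matrix with
affine gaps and a fixed tie-break order (diagonal, then gap in the
first profile, then the second), JIT-compiled with numba.  Everything
is therefore deterministic.

**Pairwise.** Position scores combine three channels:
`w_seq`·BLOSUM62/4 (w_seq = 1), `w_ss`·δ(ss_a = ss_b) (w_ss = 2), and
— once a superposition exists — a TM-score-like proximity term
`w_d / (1 + (d/d0)²)` with w_d = 4, d0 = 5 Å, where d is the CA–CA
distance after superposition (unresolved positions contribute the
first two channels only).  Gap open −8, extend −0.5.  The procedure
alternates Kabsch superposition on the currently aligned CA pairs with
realignment, until the pair set is stable or 10 rounds.  Because a
wrong initial register biases the superposition toward itself (the
classic local-optimum trap of iterative structure alignment), the
refinement is multi-start: the sequence/SS seed plus gapless
threadings at offsets −16…16 in steps of 4, keeping the best-scoring
converged result.  d0 is fixed rather than length-dependent — a
documented simplification appropriate for single-domain chains.

**Subsets.** Pairwise scores (normalised by the shorter length) define
an average-linkage guide tree; profiles are merged bottom-up.  Profile
column pairs score the *mean* over cross-profile non-gap residue pairs
of the sequence term, plus the SS-agreement term, plus a structural
proximity term between per-column CA centroids with all members
expressed in the first member's frame.  The centroid term carries a
higher weight (`w_d_profile` = 8) than the per-residue pairwise term:
the centroid average has far lower variance than a single residue
pair, and it must be able to outvote occasional per-row artefacts
(e.g. an SS label bleeding one residue past a block boundary).
A two-member subset is exactly the pairwise alignment.

## Merging and the shape-preservation contract

Subset alignments are merged progressively, largest first (ties by
first row id), by a profile-profile dynamic program over whole
columns: the only permitted edit is inserting a full-height gap
column, so restricting the merged alignment to one input's rows and
deleting the columns that are all-gap in that restriction reproduces
the input exactly.  Orphans, then structureless sequences, are
inserted individually (in id order) under the same contract.

Merge scoring has two modes.  Without secondary structure or
coordinates it is the plain mean BLOSUM62/4 over non-gap residue
pairs.  When the pipeline supplies SS strings and common-frame
coordinates, the scoring adds an H/E-agreement bonus (coil–coil
agreement is excluded: C is the default state and carries no register
information) and the centroid proximity term, and subtracts a
`match_offset` evidence baseline (3.0; gap open −4, extend −0.5).
The offset encodes the central commitment of a structure-informed
merge: two columns are stacked only when sequence, secondary structure
or spatial proximity actually supports their homology; dissimilar loop
columns stay staggered as parallel gap runs.  This is also what makes
the merge step inflate gap counts in loops — the behaviour the squeeze
step exists to clean up.  Without the offset the arithmetic of affine
gap costs makes matching weakly similar columns always cheaper than
parallel gaps, merges come out gap-minimal, loops get forced into
unsupported columns, and there is nothing left to squeeze.

## Squeeze

A column is *conserved* when, for helix or strand, the fraction of
structure-bearing non-gap rows in that state reaches
`squeeze_threshold` (default 0.8, at least 2 rows); maximal conserved
runs of ≥ `min_block` (default 2) columns are blocks.  Each inter-block
loop region is re-packed: per-row residue segments are re-aligned by a
sequence-only progressive profile alignment (gap open −4, extend −0.5,
segments added longest-first), and the region is replaced only if this
makes it narrower.  Rows without secondary structure are passive in
annotation but re-packed like all others.  Guarantees, all tested:
block columns are copied bit-for-bit, residues never cross block
boundaries, every row's degapped sequence is unchanged, total gap
count never increases, and the operation is idempotent.

## Column Score

Columns are compared as sets of (row, residue-position) pairs over the
sequences shared between query and reference, so repeated amino-acid
types cannot create false matches and query column order is
irrelevant.  Reference columns that are all-gap over shared rows are
excluded from the denominator m.  Region masks (e.g. conserved blocks
vs loops) are defined over reference columns and may be supplied as
ranges or derived from the conserved-column annotation.  The
production implementation is asserted exactly equal to a brute-force
restatement (every reference column against every query column) on
randomised instances.

## The synthetic family generator

The generator emulates the target use case: a family with a conserved
fold and low SI.  An ancestor is sampled over an architecture of
helix/strand blocks and loops; descendants evolve along a balanced
binary tree (optionally star-shaped, optionally partitioned into
clades with a separate root-to-clade divergence).  Substitutions are
uniform over the 19 alternative residues — adequate for controlling
identity, not a phylogenetic model (no rate matrix, no Γ rates).
Indels live exclusively in loops (geometric lengths, default rate 0.05
per site per branch, extension 0.4).  The per-branch substitution
probability is calibrated by bisection until the realised mean
pairwise identity (measured on the true alignment) is within ±0.05 of
the target; substitution and indel randomness use separate streams
with unconditional draws, so the indel history — and hence every
sequence length — is invariant across the bisection, making the
calibration monotone.  Homology bookkeeping uses a global column
ledger: insertions allocate fresh columns immediately after their
anchor, so the emitted true alignment is exact by construction.

Geometry: all family members share ideal block coordinates laid out
along one axis (α-helix: rise 1.5 Å, 100°/residue, radius 2.3 Å;
strand: 3.8 Å zigzag), while loops are per-sequence biased random
walks bridging the blocks at 3.8 Å steps.  The default βαβ-repeat
architecture varies block lengths across units (E 6/7/8, H 9/11/9):
exactly identical repeat units would make the inter-unit register
structurally ambiguous — unit-shifted superpositions score almost as
well — which is a pathology of a too-symmetric test bed rather than of
real repeat proteins, whose units also differ.

What the generator does *not* emulate — and hence what passing tests
do not establish about real data: side chains and hydrogen-bond
physics (the SS assignment sees ideal CA geometry), model/experimental
coordinate error (block coordinates are identical across members, so
superposition is unrealistically clean), compensating substitutions,
domain rearrangements, and any realistic evolutionary rate structure.
Results on these fixtures bound the engine's algorithmic correctness,
not its accuracy on PDB-derived families.

## Pipeline mechanics

Every stage writes its outputs and a manifest (SHA-256 of each input
file plus the stage's parameters); a stage is skipped on re-run iff
its manifest matches and its outputs exist, giving file-level
checkpoint/resume.  Subset alignments are independent jobs; with
`n_jobs > 1` they run in a thread pool and results are collected in
subset order, so concurrent and sequential runs are byte-identical.
The run report accounts for every input sequence with exactly one fate
(dropped-redundant, excluded-unresolved, subset_NNN, orphan,
structureless).  An `ExternalAligner`-style adapter was considered and
deliberately left out of this release: the built-in engine covers the
package's scope, and the per-stage file layout (`subset_NNN.txt`,
`subset_NNN.aln.fasta`) is already the interface an external tool
would plug into.

## Problem sizes

Defaults throughout target desk scale: the acceptance script and the
end-to-end tests use families of 24 sequences (~80–130 residues) in 3
clades at ~30% mean identity, five seeds; the whole test suite runs in
about a minute on one CPU.  The O(n²) exact clustering and the
multi-start pairwise engine are the costs that grow fastest with
family size; both are deliberate correctness-over-speed choices at
this scale.
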