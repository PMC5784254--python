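# Methods

`gpcrmine` implements a desk-scale pipeline for finding **GPCR-bigrams** —
proteins that couple a seven-transmembrane (7TM) receptor region to a
catalytic accessory domain — and for characterising the receptor-kinase
(GPCR-PIPK) family in particular: its LRxGI linker motif and the placement
of its kinase domains relative to the classical PIPK types I–III. Because
no public accessions accompany the family inventory the package mirrors,
every stage is developed and validated against synthetic proteomes with
planted, fully recorded ground truth. This note documents the models, the
defaults and why they are set where they are, what the generator does and
does not emulate, and the open design choices.

## Transmembrane topology

TM segments are called from the Kyte–Doolittle hydropathy scale with a
centered sliding-window mean (window 19 residues), thresholded at 1.6 KD
units; maximal above-threshold runs separated by fewer than 4 positions are
merged, and runs shorter than 15 positions are dropped. These are the
classical Kyte–Doolittle settings for membrane-spanning helices; they are
exposed as `TMParams`. Positions whose window does not fit in the sequence
carry no score; ambiguous residues (B, Z, X, U…) contribute 0 KD so no
real-world FASTA dialect raises.

Orientation uses the positive-inside rule: loops alternate between the two
membrane faces, the summed K+R count of each face is compared, and the N
terminus is assigned to the *less* positive face. Equal counts yield
`undetermined`. The canonical receptor signature is 7 TM helices with an
extracellular N terminus; the candidate filter used by the pipeline is the
wider 5–9 TM band (`is_gpcr_candidate`, lenient mode), with a strict mode
that additionally demands the canonical 7TM/N-out topology. Whether an
N-terminal signal peptide should count toward the TM total is genuinely
open; signal peptides are therefore detected by a dedicated heuristic (a
6–17 residue hydrophobic stretch, mean KD > 2.0 over a 7-window, starting
within the first 30 residues — too short to be a TM helix) and reported as
separate evidence rather than as a TM segment. A switch on
`build_topology` can instead fold a short first helix into the signal slot.

A single in-house hydropathy predictor stands where production inventories
would combine several external topology predictors; the package exposes
strict/lenient candidate modes instead of a consensus rule.

## Domain profiles

Accessory domains (PIPK, TKL, INPP, AC, PDE, DEP, AP, FYVE) and the decoy
families (transporter, channel) are modelled as per-column log-odds
profiles built from seed alignments shipped with the package. Columns with
more than 50% gaps are dropped; retained columns are Laplace-smoothed
(pseudocount 1.0 against a uniform background) and scored in bits:

    score(col, aa) = log2( ((count + pc·bg) / (n + pc)) / bg )

Scanning sums per-column scores over every window and reports
non-overlapping above-threshold hits greedily by score, ties broken by the
smaller start — determinism over elegance. The packaged default threshold
is 0.35 of a profile's maximum achievable score: far above the best window
of any composition-preserving shuffle (empirically negative for these
profiles) and far below a faithful domain instance (≈ 0.6–0.7 of max).
`calibrate_threshold` offers the empirical alternative: the (1 − FPR)
quantile of best-window scores over Fisher–Yates shuffles of a background
set, bit-reproducible per seed.

The shipped seed alignments are **synthetic fixtures** (30 rows each,
generated by `scripts/make_seed_alignments.py`), not curated family
alignments; importing real seed alignments is a supported extension, since
`build_profile` accepts any aligned FASTA. The kinase profile embeds the
three invariant catalytic anchors — DLGKS, MDYSL, and the activation-loop
dilysine KK — as near-invariant columns, and records the activation-loop
offset used by the type I/II signature check.

No insert/delete-state profile HMM is attempted: windows are gapless. This
is adequate for the benchmark (planted domains are contiguous) and keeps
the scan equivalent to an exhaustive window oracle, which the tests assert.

## Architecture grammar

Per protein, the classifier applies a fixed decision order:

1. decoy profile hit (transporter/channel) → `NON_GPCR_TM`
   (or `SOLUBLE` with no TM segments);
2. TM count outside 5–9 → `SOLUBLE` / `NON_GPCR_TM`, except that a
   catalytic hit together with linker-motif evidence on a partial topology
   yields `AMBIGUOUS_TRUNCATED` (probably a truncated gene model);
3. a **receptor block** with a downstream catalytic hit → the matching
   bigram class (`GPCR_PIPK`, `GPCR_TKL`, `GPCR_INPP`, `GPCR_AC`,
   `GPCR_PDE`); a DEP hit C-terminal of a TKL hit sets `has_dep`;
4. signal peptide plus an AP hit N-terminal of a C-terminal receptor block
   → `AP_GPCR` (the mirror-image architecture);
5. a passing topology with no catalytic evidence → `GPCR_PLAIN`.

A receptor block is the largest run of consecutive TM segments whose
connecting loops are shorter than 120 residues, accepted when the run has
5–9 segments. Adjacency prevents calling a "7TM" scattered across a
2000-residue multi-pass protein; accepting 5–9 rather than exactly 7
matches the candidate band and keeps a single borderline helix call from
flipping the class — the canonical case remains 7. Contradictory
overlapping catalytic hits are resolved by score, then earlier start.

PIPK typing: a receptor block preceding the kinase domain defines type IV.
Soluble kinases are typed from a packaged YAML signature table — a
FYVE-like accessory marks type III; types I and II are separated by the
dipeptide at the kinase profile's activation-loop position (KK vs RK).
The I–III signatures are **provisional configuration**: the true
type-defining domain compositions vary by annotation source, so the table
is data, not code.

Fragment reconstitution pairs a record carrying a receptor block plus the
linker motif (no kinase) with a same-species record carrying a kinase
domain (no receptor block), requiring a sequence overlap of ≥ 5 residues
(the generator can duplicate 0–10 residues across the split, so both
overlap regimes are testable) or motif adjacency (motif near the first
fragment's C terminus, kinase near the second's N terminus). Best overlap
wins; exact ties are all reported, flagged `unresolved`.

## Conservation and the LRxGI motif

Column conservation is the frequency of the majority physico-chemical
class among non-gap symbols (partition shipped as
`data/residue_classes.tsv`: acidic DE, basic KRH, hydrophobic AVLIMFWC,
polar STNQY, neutral GP); an all-gap column scores 0. This is a documented
substitute for alignment-annotation conservation scores whose exact
algorithms are not reproducible here; it is tested against its own
definition. The profile is smoothed with a centered 50-position moving
average whose window truncates at the edges, so the smoothed series keeps
the raw length and stays in [0, 1]. Note that a truncated centered mean
does *not* preserve the global mean of a non-constant series (edge columns
receive less total weight); constancy is preserved exactly and that is
what the tests assert.

The motif model is an anchored 13-column position weight matrix:
literal LR at the head, a 9-column spacer, literal GI at the tail.
Extraction from a linker alignment picks the 13-column window maximising
summed conservation subject to the anchor columns' consensus spelling
LR…GI, and builds the PWM with pseudocount 0.5. Scanning requires the
literal anchors (mismatch budget 0 by default — the dimers are essentially
invariant in the family) *and* a PWM score at least 0.35 of the model
maximum. The fraction is deliberately just above what the anchors alone
can contribute (≈ 0.33 of max), so every reported hit carries positive
spacer evidence; a chance LR…GI in background sequence scores far below.
The spacer frequency table is an artifact default — only the anchors are
constrained by the motif's definition — and lives in
`data/lrxgi_spacer_frequencies.tsv`.

## Alignment and phylogeny

Pairwise and profile–profile alignment is a Gotoh affine-gap global DP
(gap of length L costs open + (L−1)·extend; defaults BLOSUM62, open 10,
extend 0.5) with deterministic tie-breaking (match over gap-in-second over
gap-in-first). Progressive alignment merges profiles leaf-to-root along a
3-mer-distance/UPGMA guide tree and preserves the input row order.
Alignment columns with more than 25% gaps are trimmed before distances
(strictly-more-than: a 4-row column with exactly one gap is retained).

Distances are pairwise maximum-likelihood under the WAG empirical
substitution model (rate matrix normalised to one expected substitution
per site; eigendecomposition cached; distance found by bounded scalar
optimisation, capped at 10 substitutions/site against saturation).
Discrete 4-category gamma rate heterogeneity is implemented but off by
default — pairwise ML with gamma is several times slower and changes
nothing about clade recovery on the benchmark. Trees are built by
neighbor joining with lowest-index tie-breaking and negative branch
lengths clamped to zero; NJ is exact on additive matrices, which the tests
assert, and a full maximum-likelihood tree search is deliberately out of
scope — at this scale the quantity of interest is planted-clade recovery.
Column bootstrap (default 100 replicates at desk scale; 500 is the
conventional full-size setting) resamples columns with replacement,
reruns distances + NJ, and reports the percentage of replicates containing
each internal bipartition; values annotate the Newick output as internal
node labels. Only kinase-domain subsequences (profile-hit spans) enter the
tree, never full-length proteins.

## The synthetic benchmark

`generate_proteome` plants architectures whose statistics match what the
pipeline assumes, without encoding the detectors themselves:

- **Helices** (21 residues) are drawn from {I,L,V,F,A,M} with
  KD-proportional weights; **loops** from hydrophilic residues with
  cytoplasmic loops carrying K/R and outside loops D/E, so the
  positive-inside rule has signal. Separability is enforced at sampling
  time: a helix is resampled until its mean KD ≥ 3.45 *and* every
  13-residue stretch stays ≥ 3.3; a loop until its mean lies in
  [−1.45, −1.0] and no 6-residue stretch falls below −2.0. The window-scale
  floors make every helix-edge detector window provably exceed the 1.6
  threshold, so helix recovery is structural rather than statistical.
- **Domains** are per-column samples from the same seed-profile
  frequencies the scanner uses (≈ 80% consensus), with the kinase anchors
  planted literally and a per-type set of eight signature residues that
  gives the four PIPK types genuine divergence structure for the tree.
- **The motif** is literal LR + a spacer sampled from the packaged
  frequency table + literal GI, planted between the last TM helix and the
  kinase domain.
- **Decoys**: 11-TM transporters and 3-TM channels with their own
  signature domains, soluble kinases of types I–III (type III with a
  FYVE-like accessory), and hydropathy-neutral background proteins
  (uniform composition, 120–400 residues).

The packaged preset (`pinf_like_specs`) mirrors the reference census of
one well-studied oomycete proteome: 44 bigrams — 12 GPCR-PIPK, 17
GPCR-TKL (8 with DEP), 7 GPCR-INPP, 4 GPCR-AC, 3 GPCR-PDE, 1 AP-GPCR —
mixed with exactly 200 decoys (50 transporters, 50 channels, 40 soluble
kinases, 60 background). All randomness flows through one
`numpy.random.default_rng(seed)`; identical seeds give byte-identical
FASTA and truth.

`divergent_pipk_family` serves the conservation study specifically: the
clean preset is same-species-like, so its kinase domains are nearly as
conserved as the linker and the smoothed profile would peak inside the
kinase domain. Real conservation profiles come from families that
diverged across taxa; the builder emulates that regime (40% of helix
positions from small/polar residues, kinase emission mixed 70% with a
uniform background, anchors and motif intact, fixed region lengths so the
rows align trivially), and there the 50-column smoothed profile peaks at
the linker, up to the half-window resolution of the smoother.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: realistic amino-acid composition and
low-complexity regions; homology *between* families (each profile is an
independent random consensus, so cross-family discrimination is easier
than for, say, the kinase superfamily); alignment difficulty of real
divergent families (the scan thresholds assume near-species-level
conservation; detecting remote homologues needs profile HMMs and iterative
search, which are out of scope); gene structure, nucleotide sequence, and
assembly artifacts beyond the simple two-fragment split.

`simulate_family` evolves sequences along a given tree by Markov
substitution under WAG (root drawn from the equilibrium frequencies),
with optional site-tracked indels so the leaf-to-leaf residue homology map
is exact — that map is the oracle for the progressive-alignment accuracy
test.

## Problem sizes

The defaults are chosen so the whole battery runs on one CPU in minutes:
the benchmark preset has 244 proteins (~100 k residues); the kinase tree
covers 52 domains with 100 bootstrap replicates (~1 min); distance
recovery is checked at simulated divergence 0.3 substitutions/site over
20 replicates of length 2000; the clade-support check uses a 12-taxon
type-structured family of length 300.

## Known limitations

- Single-predictor topology: no consensus over multiple predictors, no
  HMM topology grammar; re-entrant loops and amphipathic helices would
  confound the hydropathy scanner.
- Gapless profile scanning: a real domain split by a long insertion would
  score as two partial windows, not one hit.
- The type I–III signature table is provisional configuration.
- The AP-GPCR orientation call can come out `undetermined` or
  `intracellular` when the N-terminal protease region happens to carry
  many K/R; classification does not depend on orientation in lenient mode.
- NJ + pairwise-ML distances is not a full ML tree search; branch support
  below ~50 on short alignments should not be over-read.
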