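# Methods

This note documents the models, rules and numerical choices behind
`scaffoldmine`, the parameters that matter, and what the synthetic test
fixtures do and do not establish.

## Domain detection

One profile-HMM per domain label is built from a multiple alignment of the
label's training sequences (alignment is delegated to a pluggable backend;
`mafft` when available, a gap-padding fallback for already-columnar motif
sets). Detection thresholds (`domT`) are *per-domain bit scores*, not
e-values: bit scores are independent of database size, so a threshold
calibrated once remains meaningful for any scan. Calibration sets each
profile's threshold to the minimum best-domain score over its own training
members, which guarantees recall 1.0 when the calibration set is rescanned.
Because HMMER bit scores carry a target-length correction, the same domain
embedded in a longer protein can score ~1–2 bits below its standalone
calibration score; thresholds are therefore floors, not margins, and
borderline domains in unusually long proteins can be missed.

Scanning disables the acceleration prefilters (`F1=F2=F3=1`, no bias
filter) so that short or unusual profiles behave like full-length ones;
hits below threshold are dropped, and overlapping retained hits (overlap
> 50 % of the shorter hit) are resolved in favour of the higher bit score,
ties alphabetically — a determinism-driven choice, since nothing in the
domain grammar tolerates overlapping assignments. ACP and bACP are
interchangeable for everything downstream (both are carrier domains), so
the pair is treated as one role via a label-equivalence table rather than
by forcing the profiles to separate them.

Cross-validation is stratified by label with a fixed seed and
label-order-independent fold assignment; held-out sequences are classified
by the highest-scoring profile, and per-label precision/recall/F1 equal the
values recomputed from the pooled confusion matrix (asserted in tests).

## Module grammar

Segmentation closes a module after the carrier domain plus any immediately
trailing E/TE/TD. This boundary is inferred from the observation that every
common arrangement ends in a carrier (possibly followed by
epimerization/release domains); it is a convention, not chemistry.
Classification first consults an editable pattern table (first-match
semantics; the shipped table carries the 20 most common arrangements) and
falls back to compositional rules: a module with a substrate-selecting
domain (A/AT) and a carrier and a derivable modification profile is
*normal*; trans-AT modules, carrier-less fragments and incomplete reduction
arrangements (reductive domains present but no KR — `ketone*`) are
*special*; everything else is *non-functional*. Modules whose domains span
two adjacent same-strand genes are merged only when the combined
arrangement matches a known pattern, since cross-gene modules are common in
real clusters but arbitrary merges would corrupt the grammar.

Methyltransferase position carries signal: a cMT anywhere among the
reductive domains or directly after the AT is an α-methylation in cis; a
cMT squeezed between the reductive domains and the carrier is the trans-AT
arrangement and flags the module as trans-AT even when no docking domain
was detected. An oMT acting on a lone-KR module O-methylates the
β-hydroxyl (methoxy); an oMT without reduction domains has no general rule
and is ignored, as is the rare NRPS cMT. A doubly α-methylated
methylmalonyl unit cannot be dehydrated, so its β-state is capped at
ketone/hydroxyl.

## Block ordering

Blocks are maximal same-strand adjacent module runs, split after any
internal terminal module. Ordering scores every admissible ordered block
pair by the best Smith–Waterman local alignment (match +1, mismatch −1,
gap open −2 applied to the first gapped symbol, extension −1, over the
domain-label alphabet with one symbol per label and no carrier equivalence)
of the pair's concatenated domain string against a reference database of
single-block clusters. Admissibility: loading blocks only first, terminal
blocks only last, two terminal blocks never joined. The best pair is merged
and the matrix recomputed with the merged block (greedy with recompute —
the level of search the reference description pins down). Ties are broken
by (1) fewer unmatched concatenation symbols — local alignment does not
charge trailing symbols, so without this a pair that skips a block can tie
the correct pair — then (2) genomic-order preservation, then (3) block
ids; pure determinism choices. With more than 10 blocks (configurable) the
genomic order is returned unchanged.

## Substrate specificity

Alignment columns are one-hot encoded with the gap symbol as a first-class
category, so every row sums to the column count and gaps remain
informative. Training labels with fewer than 10 members are dropped (too
few for a stable class). Hyperparameters come from an exhaustive grid
(depth × max-features × trees × min-split × bootstrap × criterion ×
min-leaf = 4·5·3·3·2·2·3 = 2160 configurations) selected by mean micro-F1
over seeded stratified 10-fold CV. Two published details are normalised to
the scikit-learn API: `max_features="auto"` maps to `"sqrt"` (its meaning
for classifiers before the alias was removed) and a min-samples-split of 1
maps to 2 (a 1-sample split is a no-op). No class weighting is applied —
the gap between micro and macro averages is reported rather than hidden.

At predict time a new sequence is projected into the training column space
by global pairwise alignment against the first training row's ungapped
sequence (match 2, mismatch −1, open −5, extend −1); columns the new
sequence would insert are dropped. This is one of several defensible
mappings; it is exact for near-full-length domain hits and degrades
gracefully for truncated ones.

## Scaffold assembly

A PK building block is a β-carbon and an α-carbon; an NRP block is the
peptide-bond nitrogen (β) and the α-carbon. Blocks condense head-to-tail:
the junction into an NRP block is an amide (carbonyl contributed by the
upstream block's carboxyl), the junction into a PK block *is* that block's
β-carbon. Because chain extension bonds the new α-carbon to the carbonyl
inherited from the previous unit, a module's reductive domains chemically
modify the *previous* building block's carbon; in the emitted linear chain
that carbon is the β-atom written directly upstream of the module's own
α-carbon, so the implementation writes each module's reduction state to its
own unit's β-slot — same molecule, index-shift-free bookkeeping. Loading
modules contribute no β-carbon; TE caps the chain as the free acid, TD as
the terminal alcohol (macrolactonization is deliberately not attempted, so
products are linear). L residues are written as (S) (`[C@@H]` in the
N-side-chain-carbonyl neighbor order), epimerized residues as D; PK
β-hydroxyl stereocenters are left unset. Imino and aryl acids (proline,
pipecolate, 2,3-dihydroxybenzoate, dehydroaminobutyrate) use full unit
templates in the chemistry table instead of a side chain on a standard α —
aryl-acid templates are topological approximations adequate for
similarity-based screening, not curated natural-product chemistry.
Special modules without a substrate prediction (trans-AT) insert an
unsubstituted malonyl-like unit, the most common trans-AT substrate;
`ketone*` modules emit a ketone block (the reduction cannot proceed without
KR). All fragments are canonicalized, so assembly is deterministic and
idempotent.

## PSM prediction

Substructure counts use SMARTS patterns for the seven PSM classes with
matches deduplicated by atom set, so ring automorphisms count once. Count
models are ordinary least squares: the published evaluation is an R² on
counts, which is a regression criterion, so a linear model is the family
that matches the printed metric (the alternative reading, classification,
is incompatible with it). A model's `cv_r2` is the pooled out-of-fold R²
over seeded 5-fold CV; the baseline is the always-zero predictor on the
identical folds (closed form: necessarily ≤ 0 for non-negative targets
with any positive value), and a model is retained only if it beats the
baseline. Predictions are rounded to the nearest integer and clipped at
zero; absent feature domains count 0. Feature domains are the positive
Pearson correlates intersected with a curated allow-list (shipped as data).
Only glycoside *counts* are predicted — sugar identity is out of scope.

## Screening

Libraries are deduplicated by canonical SMILES; Morgan fingerprints use
radius 3 and 2048 bits (an in-memory index; a relational backend is a
deployment detail behind the same interface). The multi-fragment MCS score
sorts fragments by descending heavy-atom count, finds the MCS of the
current fragment against the current target (connected MCS, atoms by
element, bonds by order), enumerates up to 20 placements of it, deletes
each placement from the target, and recurses with the next fragment; the
best branch wins and a skip branch guards against pathological fragments.
The final score is the arithmetic mean of the matched-atoms+bonds fraction
on the query side and on the target side — the reading of "dividing each
matching atom and bond in the predicted molecule and the target molecule by
the total number of atoms and bonds" that keeps the score symmetric in
effort; a query-side-only normalization is available as a switch. The
score is 1 exactly when the fragments tile the target.

The PSM score is `1 − Bray–Curtis dissimilarity` of the two count vectors:
the dissimilarity form is the standard definition, and the similarity
orientation is fixed by the stated contract that identical PSM vectors
score 1. Two all-zero vectors score 1 (identical emptiness). The mixed
score is the weighted sum of the three components; the weight grid search
evaluates every (a, b, c) on a 0–1 grid in steps of 0.1 (1331 configs,
minus the all-zero one) by Top-10 fraction of true products, reporting the
lexicographically smallest of tied optima. Ranks are 1-based competition
ranks (ties share the best rank).

## Pipeline

Input records are GenBank (CDS translations used directly), protein FASTA,
or DNA FASTA (genes called through a subprocess contract, `prodigal` by
default; protein input bypasses gene calling entirely). Domain-bearing
genes within a 10 kb window (configurable — the boundary rule of the
original system is not published, and 10 kb is a conventional intergenic
cutoff for cluster co-membership) form one cluster; minus-strand gene runs
are traversed in translation order. Cluster type (PKS/NRPS/Mixed) derives
from functional modules only. One seed propagates to every stochastic
component, making end-to-end runs reproducible.

## Synthetic fixtures: what they show

The fixture generator plants motif-style domain families (60–80 aa
consensus, members at 4 point mutations), a three-gene NRPS cluster whose
A-domains carry a 15-residue substrate signature, a shuffled-gene genome
variant (terminal gene first, middle gene on the minus strand), a
32-compound screening library containing the true Gly-Ala-Val product, and
Pfam/PSM count tables with planted linear slopes (β = 0.8 and 1.5, noise
σ = 0.3, 60 clusters; the recovery check uses n = 200). The genome embeds
the un-mutated family consensus, which outscores every calibration member
by a wide margin — so planted domains clear the calibrated thresholds by
construction.

Passing these fixtures demonstrates that the machinery is internally
correct — segmentation partitions, thresholds filter, ordering recovers a
planted permutation when the truth is in the reference set, separable
substrate signal is learned, assembly produces the intended molecule, and
the true product outranks decoys. It does *not* demonstrate real-data
performance: real domain families are diverse and overlapping, real
substrate signal is weak and confounded by phylogeny, real libraries are
three orders of magnitude larger, and real clusters contain tailoring
genes the grammar ignores. Reproducing the published classifier benchmark
requires the curated AT/A-domain training collections (see README); the
harness for it (`substrates.reproduce_benchmark`) is part of the package.

## Problem sizes

Test and acceptance runs use toy sizes chosen to exercise every code path:
8 domain families × 6 members, 36 substrate training sequences, 3-module
clusters, k ≤ 4 block permutations, a 32-compound library, and n = 200 for
regression recovery. These are the package's own fixture dimensions; all
scale linearly upward in the obvious way.
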