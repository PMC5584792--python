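# Methods

This note documents the models and procedures implemented in `riboregulon`,
the parameters that matter, the synthetic data the tests run on, and the
design choices made where the problem admitted more than one reasonable
answer.

## Aptamer detection with a profile HMM

The detector is a classic profile hidden Markov model over DNA
(match/insert/delete states, Durbin-style layout: begin = M0, M1..ML,
end; I0..IL; D1..DL). It is estimated from a seed alignment of aptamer
sequences: columns whose gap fraction is at most `gap_threshold` (default
0.5) become match states; emission probabilities use additive smoothing,
(count + c) / (total + 4c), and transitions are tallied from each row's
state path with the same smoothing (c defaults to 0.5, a mild Jeffreys-like
pseudocount appropriate for small seed alignments). States at the model's
right edge have no delete successor and renormalise over two outgoing edges.
Scores are log-odds in bits against an i.i.d. background; `N` and all other
ambiguity codes score 0 (background odds), so runs of ambiguous sequence
carry no evidence — a hit whose matched interval is entirely ambiguous is
discarded.

Two alignment modes exist. `viterbi_score` is global (the whole input
traverses the model) and is the form checked against exhaustive path
enumeration in the tests. Genome scanning is *glocal*: the model must be
traversed in full but flanking window sequence is free (scores as
background). Glocal scoring makes a window's score independent of where the
motif sits inside it, which in turn makes merging well behaved: any window
fully containing a motif scores the same, so dense and sparse window tilings
yield identical merged hits. Windows default to twice the model length with
a step of half the model length, guaranteeing every full-length motif is
contained in at least one window. Overlapping above-threshold windows merge
into a single hit that keeps the maximum score and the maximising window's
matched interval; merging ignores strand because aptamer helices are
partially self-complementary, so a strong hit typically casts a weaker
shadow on the opposite strand at the same locus.

No published bit-score cutoff exists for this detector, so the threshold is
calibrated: the empirical (1 − FPR) quantile of glocal scores over
background windows sampled at the genome's GC content (default FPR 1e-4 per
window, 20,000 windows). The calibration refuses to resolve quantiles finer
than its sample size.

Candidate hits are checked against the comparative-analysis consensus
secondary structure. The hit is aligned to the model by global Viterbi; each
consensus base pair whose two columns are both realised by match states
counts as canonical if the mapped nucleotides form a Watson–Crick or GU
pair. The compatibility fraction is canonical/evaluated (default pass
threshold 0.7); when no pair has both partners matched the result is
flagged indeterminate rather than failed. This filter is a deliberately
lightweight structural check — it does not fold the sequence
thermodynamically and does not replace a covariance-model search.

## Regulon assignment

A riboswitch regulates downstream, same-strand sequence. Each hit is
assigned to the nearest gene on its own strand whose strand-aware start lies
at or downstream of the hit start, within `max_upstream` bases of the hit
end. The default of 500 nt covers bacterial 5'UTR leader lengths; hits
overlapping a gene's annotated start are assigned to that gene at distance
zero, since annotated start codons are imprecise. If the assigned gene is
the first gene of an operon (by the operon table's stated order, which is
trusted over coordinates), the whole operon is the target. Strain
de-duplication keeps one genome per species, choosing the lexicographically
smallest genome identifier for determinism.

## Function catalogue and phylogenomic profile

The catalogue ships as an editable TSV. Lysine biosynthesis comprises the
DAP-pathway genes lysC, asd, dapA, dapB, dapD, dapH, ddh, dapF and lysA.
Genes that co-occur in the printed operons but are functionally unrelated —
amino hydrolase/amidohydrolase, aminotransferase, alanine racemase (alr),
acetyltransferase, cyclic beta 1-2 glucan synthetase, pspF3 — are
deliberately classed "other", including the aminotransferase recurring in
Thermotogales operons despite its pathway adjacency. The spelling variant
"lyC" resolves to lysC through the synonym map. lysP and gabP share COG0833
and one profile column labelled lysP/gabP, reflecting their interchangeable
annotation. Name lookup is case-insensitive with whitespace/dash
normalisation; products containing "hypothetical protein" (or names starting
"hypothetical") form their own class; everything else is "other".

The phylogenomic profile is a species × catalogue-gene matrix with cell
states riboswitch_and_gene / gene_only / absent. An operon-level assignment
marks every catalogued gene the operon contains. iTOL export writes one
DATASET_BINARY file per class (circles for biosynthesis, squares for
transporters, stars for catabolic genes) encoding 1 = filled (riboswitch and
gene), 0 = outline (gene only), −1 = absent.

## Distances, neighbor joining, bootstrap

Alignment columns with more than 20% gaps are trimmed (the boundary is
inclusive: exactly 20% survives). Families concatenate into a super-gene
alignment only when every family contains every taxon. Distances use
pairwise gap deletion. Three estimators are available: p-distance, Poisson
correction −ln(1 − p) (capped at 10 substitutions/site when p ≥ 0.99, with
a warning), and the default `jtt_ml`: a one-dimensional maximum-likelihood
branch time per pair under the Jones–Taylor–Thornton rate matrix normalised
to one expected substitution per site per unit time. The JTT generator is
eigendecomposed once through its symmetrised form, so each likelihood
evaluation is two small matrix products; optimisation is bounded scalar
minimisation on [1e-6, 10]. Gamma rate variation is not modelled.

Neighbor joining follows Saitou–Nei agglomeration. Ties in the Q criterion
are broken by the lexicographic order of cluster names (each cluster named
by its smallest member taxon), making the output deterministic and invariant
to input taxon order. Negative branch-length estimates are clamped to zero
with a warning. The returned tree is unrooted (final three-way join).
Bootstrap support resamples alignment columns with replacement, rebuilds the
tree per replicate, and scores each internal edge of the full-data tree by
the fraction of replicates containing the same bipartition; the Newick
writer prints supports above a display threshold (default 0.5) as internal
node labels.

## Transfer and duplication detection

Gene trees are unrooted, so "the smallest clade containing a leaf" is read
off the tree's bipartitions: for every well-supported internal split, both
sides are candidate clades. A leaf whose smallest supported containing side
(with at least one other member) consists entirely of a single taxonomic
group different from the leaf's own is called a transfer recipient from that
group, with the split's support attached. The donor rank defaults to phylum
for cross-phylum calls and order for within-phylum analyses. Because
incongruence is symmetric, the donor-clade leaf a recipient attaches to can
be flagged reciprocally; consumers interested only in planted-event recovery
match on the recipient.

For taxa contributing two gene copies, each copy's smallest supported
containing side is classified ignoring the taxon's own copies. One copy
clading concordantly with the taxon's own group while the other clades with
a single foreign group is the duplication-followed-by-divergence signature;
the foreign-clading copy is named in the event. Gene-tree/species-tree
concordance is summarised as shared and conflicting non-trivial
bipartitions on the common leaf set (Robinson–Foulds-style symmetric
difference); external corroboration services are out of scope, with a
nearest-neighbour patristic-distance report as a lightweight stand-in.

No formal incongruence criterion is published for this analysis; the
smallest-supported-foreign-clade rule operationalises the case descriptions
(single foreign leaf inside a supported clade; second gene copy clading with
a foreign order). The bootstrap threshold of 0.5 mirrors the display
threshold and is configurable.

## Transporter annotation

"Similarity" is interpreted as BLAST's *positives*: the percentage of
aligned columns (gap columns included) whose substitution score is positive;
identity is reported alongside for transparency. "Coverage" is query
coverage: the aligned query span over the query length. Alignment is
affine-gap local alignment under BLOSUM62 (gap open 11, extend 1; a gap of
length k costs open + (k−1)·extend). E-values use the ungapped
Karlin–Altschul formula E = K·m·n·exp(−λS) with λ = 0.3176, K = 0.134 for
BLOSUM62, applied to gapped scores without finite-size correction — adequate
for thresholding, documented as approximate. The decision rule is a strict
conjunction: best-hit thresholds (E ≤ 1e-5, similarity ≥ 50%, coverage
≥ 30%, boundaries inclusive, best hit chosen by lowest E then highest
similarity then highest coverage), a catalogued domain motif (consensus
string matched within a mismatch budget; the packaged catalogue is a
synthetic family motif, editable TSV), and at least one predicted
transmembrane segment.

The transmembrane predictor is a Kyte–Doolittle sliding-window heuristic:
19-residue windows with mean hydropathy above 1.6 are collected into maximal
runs, runs closer than 5 window positions merge, and each run is one
segment. It is a stand-in for a full transmembrane-topology HMM; counts on
real proteins may differ from dedicated predictors and should be treated as
supporting evidence, not topology.

## Synthetic data: what it emulates, what it does not

The generator produces the statistical structure the pipeline assumes,
nothing more. Genomic background is i.i.d. at a configurable GC content —
no repeats, codon structure or compositional heterogeneity — because the
detector is aptamer-local. Genes are annotated intervals grouped into
same-strand operons; one aptamer motif is planted per operon on the operon
strand, its 3' end a configurable distance (default 20–150 nt) upstream of
the first gene's strand-aware start. Motifs derive from the packaged seed
alignment's consensus with per-position identity (default 0.9).

Protein families evolve site-independently along a known species tree under
a 20-state Jukes–Cantor process (uniform exchangeabilities): along a branch
of length b the probability a site differs from its parent is
(19/20)(1 − exp(−(20/19)·b·r)), r being the configured substitution rate
(default 0.2/site/unit branch). Horizontal transfer is modelled as sequence
replacement: the recipient is re-drawn from a randomly chosen donor-clade
leaf's parent sequence, evolved along half that leaf's terminal branch —
i.e. transfer from an extant lineage *within* the donor clade, which is both
the biological picture and what makes the recipient nest inside the donor
clade rather than attach ambiguously at its base. Duplications add a second,
faster-evolving copy (rate factor 3), optionally re-drawn from a donor clade
to create the duplication-followed-by-divergence scenario. Marker families
default to 150–200 aligned positions (ribosomal-protein scale); single-gene
transfer simulations use 450 positions (transporter-protein scale). There
are no indels, no rate heterogeneity across sites and no alignment error,
so passing tests demonstrate the correctness of the algorithms under their
model assumptions — not robustness to misalignment or compositional bias in
real genomes.

Transporter proteins alternate hydrophobic segments (default 21 residues
from {I,L,V,F}) with polar linkers (25 residues, mean hydropathy < 0) and
carry a fixed 20-residue family motif in the N-terminal linker. All three
generators are deterministic given the seed.

## Numerical choices and degenerate inputs

Emission/transition distributions are validated to sum to 1 within 1e-9.
Viterbi ties resolve by the fixed candidate order match > insert > delete;
NJ ties lexicographically, as above. Empty sequences, empty alignments,
alignments with zero match columns, windows smaller than the model,
quantiles finer than the calibration sample, operons referencing unknown
genes, unannotated gene-tree leaves and fewer than four shared leaves in
tree comparison all raise typed errors naming the violated constraint.
Saturated Poisson distances cap at 10 with a warning; the structure filter
reports indeterminate rather than failing when no consensus pair is
evaluable.

## Problem sizes

The test suite and acceptance script run at fixed sizes chosen to exercise
the statistics meaningfully on a single CPU: 50 genomes of 6 kb with 50
planted motifs for detector recall/FPR; 20,000 background windows for
calibration; 200 random additive matrices (4–8 taxa) for NJ exactness; 20
marker families × 12 taxa × 100 bootstrap replicates for species-tree
recovery; 50 + 50 seeded simulations for transfer recovery and false-call
rates; 100 random peptide pairs for the local-alignment oracle.

## Known limitations

The detector is a profile HMM, not a covariance model: it captures sequence
conservation and checks structure only through the pairing-compatibility
filter. E-values are ungapped-theory approximations. Maximum-likelihood
*tree search* is not implemented (distances are ML, topology is NJ).
Operon boundaries are taken from the input tables, not predicted. The
transfer detector calls incongruence, not direction or timing; reciprocal
calls at the attachment point are expected and left to the consumer to
interpret.
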