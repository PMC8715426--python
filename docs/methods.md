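# Methods

`viropan` reconstructs, at desk scale, the comparative-genomics workflow used
for pan-genome analyses of nucleocytoplasmic large DNA viruses (NCLDVs):
protein-cluster construction from whole proteomes, exhaustive ORF
classification against external reference collections, a maximum-likelihood
phylogeny from cluster presence/absence, bipartite gene-sharing networks with
Jaccard profiles, and a forward simulator of genome-content evolution that
gives every stage a ground truth to be tested against.

## Similarity search

All-vs-all protein comparison uses exact Smith–Waterman local alignment under
affine gap costs (BLOSUM62, gap open 11, gap extend 1; a gap of length k
costs `open + k·extend`), with a deterministic traceback (ties prefer
diagonal, then up, then left).  E-values follow the Karlin–Altschul
convention `E = K·m·n·exp(−λS)` with the standard gapped BLOSUM62/11/1
parameters fixed at λ = 0.267, K = 0.041 and `n` the total residue count of
the searched collection.  These are not composition-adjusted statistics; they
are adequate for relative ranking and thresholding at the data sizes this
package targets.  An edge enters the similarity graph when the E-value is at
or below the cutoff (default 1e−5) in both query directions; the edge weight
is `min(−log10 E, 200)`.  The dynamic-programming kernels are JIT-compiled
and exact; no heuristic seeding, masking or composition statistics are used,
so the implementation is sized for thousands, not millions, of ORFs.  A
tabular-hit ingest (12-column, outfmt-6-like) is provided for plugging in an
external search tool on larger data.

## Markov clustering

The graph is clustered with canonical MCL: self-loops set to each node's
maximum incident weight, column-stochastic normalisation, then repeated
expansion (matrix squaring), inflation (element-wise power, default 1.5, then
renormalisation) and pruning of entries below 1e−5, until the flow matrix
changes by less than 1e−6 or 200 iterations elapse (non-convergence returns
the current partition with a warning).  Attractors (positive return flow)
define clusters; attractors flowing into one another form one attractor
system; every other node joins the system from which it receives the most
flow, ties resolved lexicographically.  Protein clusters have at least two
members; nodes in size-1 groups and isolated nodes are singletons.  This is
plain MCL, not the full OrthoMCL procedure: there is no reciprocal-best-hit
ortholog weighting, inter-species normalisation or percent-match filter.

## Profile construction and cluster merging

Each cluster gets a position-specific residue-frequency profile from a star
multiple alignment: the centre is the member with the highest summed pairwise
alignment score (ties: longer sequence, then smaller id), all other members
are globally aligned to it, and the centre's positions define the columns
(insertions relative to the centre are discarded).  Columns with occupancy
below 0.5 are dropped; counts receive a +0.05 uniform pseudocount, and
log-odds are taken against Robinson–Robinson background frequencies.

Profiles are compared by local alignment over columns, scoring a column pair
by the symmetrised dot product of one profile's frequencies with the other's
log-odds (column gap open 3.0, extend 0.3 — set so that identical profiles
align end to end).  The match probability is 1 minus the empirical p-value
of the raw score against column-shuffled profile pairs (default 1000 shuffles,
seeded per pair in an order-independent way; fewer than 100 shuffles is
rejected as too coarse).  This is a deliberately simple, seeded stand-in for
the calibrated probabilities of HMM–HMM search tools — a semantic substitute,
not a reimplementation — and by construction its false-positive rate at the
0.95 threshold is at most 5 % for unrelated profiles.

Two clusters merge when their profiles overlap over more than 50 % of the
shorter profile's length *and* the probability exceeds 0.95, both strictly;
qualifying links close transitively (union–find).  Merging only coarsens the
partition: the clustered ORF set and the singletons are untouched.  One merge
round is run by default; the pipeline iterates to a fixed point if asked.
The 50 % is measured against the shorter profile — a conservative reading,
since the alternative (longer profile) merges strictly less.

## ORF classification and gene-set statistics

Every ORF receives exactly one of four categories from two booleans: cluster
membership, and external homology.  For clustered ORFs, external homology is
decided at cluster level — one member with a qualifying best hit (highest bit
score per taxon collection, E ≤ 1e−5, ties by E-value then subject id) marks
the whole cluster.  Per-genome category proportions sum to one.  Cluster
sharing records count genomes and virus family/group labels per cluster; the
core gene set holds clusters found in strictly more than `core_family_min`
(default 6) families, universal clusters occur in every genome, and
family-restricted clusters occur in at least two families with no external
hits at all.  Reference collections never include the analysed genome set
itself.

## Gene-content phylogeny

The binary genomes × clusters incidence matrix is analysed under a two-state
general time-reversible model with free stationary frequencies (π0, π1) and
rate normalisation β = 1/(2π0π1), so branch lengths are expected events per
character:

    P00(t) = π0 + π1·e^(−βt)   P01(t) = π1·(1 − e^(−βt))
    P10(t) = π0·(1 − e^(−βt))  P11(t) = π1 + π0·e^(−βt)

Likelihoods use Felsenstein pruning over compressed site patterns.  Because
all-absent clusters can never be observed, the likelihood is conditioned on
variable characters (Lewis-type ascertainment correction): each pattern
probability is divided by 1 − P(all absent) − P(all present).  All-present
columns are retained in the matrix but flagged in the output; they carry no
split information either way.

Search starts from neighbour joining on Jaccard distances (own deterministic
NJ, lexicographic tie-breaks — exact on additive distances) and hill-climbs
with nearest-neighbour interchanges.  Branch lengths are optimised
per-branch by a coarse log-grid scan followed by bounded Brent refinement;
the grid matters, because with the ascertainment term the single-branch
likelihood can be multimodal and plain Brent coordinate ascent can stall far
below the optimum.  π1 is re-estimated by bounded maximisation between NNI
rounds.  Because the surface retains local optima across topologies, the
search runs from the NJ tree plus two seeded NNI-perturbed restarts and keeps
the best result; searches are deterministic given the seed.  Supports come
from a standard nonparametric bootstrap over matrix columns (replicates
re-searched from the ML topology), which is conservative relative to
approximation-based ultrafast bootstraps; branches are marked when support
exceeds 0.95.

### Known limitation: loss-dominated characters

When the generating process is strongly loss-dominated (families present at
the root and only ever lost — Dollo-like characters), reversible-model ML
systematically misplaces very short internal edges even with hundreds of
characters, while parsimony resolves them; we verified the same behaviour in
an independent ML implementation (R/phangorn) on identical matrices, so this
is a property of the model class, not of this implementation.  Gene-content
trees from such data should be read with that caveat.  The recovery
experiments below therefore use a mixed regime in which de-novo gains provide
clade-marking characters.

## Synthetic genome-content evolution

The simulator draws a birth–death tree conditioned on the tip count (crown
start, stop at the n-th birth; optionally rescaled to a target height, and
optionally re-drawn until every internal edge exceeds a set fraction of the
height so that all splits are identifiable).  The two youngest tips have
zero-length branches by construction of the stopping rule; they are twin
genomes, which downstream stages must (and do) handle.  Along each branch of
length t, in a documented draw order from one seeded generator: each family
survives with probability e^(−μt); survivors gain Poisson(δt) duplicate
copies; Poisson(νt) new families arise de novo; Poisson(λL·t) lateral
transfers each copy one family drawn uniformly from those present elsewhere
in the already-simulated state (an extant-pool approximation of
contemporaneous donors).  The event log is complete — replaying it
reproduces the incidence and copy-number tables exactly.

Sequences evolve by per-site Poisson substitution with uniform residue
frequencies; a substitution replaces the residue with one of the other 19
uniformly, so the probability a site is unchanged over a path of length T is
1/20 + (19/20)·e^(−(20/19)·rate·T) — the closed form the calibration tests
check.  Duplicates and transferred copies diverge from the midpoint of the
branch on which they arise; transfers restart from the family's ancestral
sequence.  There are no indels, no codon structure, no rate heterogeneity
and no genomic coordinates (the terminal-region bias of real NCLDV genome
rearrangements is not modelled), so passing tests demonstrate pipeline
correctness on graded similarity — not performance on real divergent
proteomes.  Virus family/group labels are assigned by cutting the true tree
into k clades, giving family-level statistics a ground truth.

### Presets and study conditions

* `small` — 10 genomes, 2 family groups, 60 root families, tree height 1;
  μ = 0.3, δ = 0.15, ν = 2, λL = 0.5 per unit length, substitution rate
  0.15/site (moderate divergence: clustering should be essentially exact).
* `plasticity` — as `small` with δ = 1.5, λL = 2: duplication bursts and
  frequent transfer for copy-number profiling.
* `reduction` — as `small` plus a loss burst deleting 16 % (rounded down) of
  one leaf's families, echoing laboratory genome-reduction experiments in
  which a giant-virus genome shrank by 16 % under subculture.
* tree-recovery condition — 10 taxa, unit height, every internal edge ≥ 5 %
  of the height, 250 root families with μ = 0.2 plus de-novo gains at ν = 60
  (≥ 400 observable characters); chosen so characters are variable but
  unsaturated and every split earns clade-marking gains.  Under this
  condition the ML tree matches the generating topology in 10/10 fixed-seed
  replicates and mean bootstrap support of true branches is ≈ 0.93; on other
  seed batches recovery is 8–10/10, the misses being one-NNI errors on the
  shortest edges (see the limitation above).

## Numerical and determinism choices

Branch lengths are bounded to [1e−8, 50]; the branch-length grid spans
1e−8–10 on a log scale; optimisation tolerances are 1e−7 (branch lengths) and
1e−5 (π1).  Newick serialisation orders children canonically (smallest
descendant tip first), so equal trees serialise identically.  All pipeline
randomness (profile nulls, bootstrap, search restarts) derives from the
single configured seed; two runs with the same config and seed produce
byte-identical cluster tables, classification tables and trees.  Problem
sizes in the shipped experiments (10 genomes, ~500 ORFs, ~60 families;
400-character tree recovery; 100 bootstrap replicates; 200–1000 profile-null
shuffles) were chosen so the whole validation suite runs comfortably on a
single CPU.
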