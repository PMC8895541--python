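# Methods

This note documents the models, algorithms, numerical choices and synthetic
data behind `phyloquartet`. The package re-implements, as a tested library,
the analytical chain used in phylogenomic studies of groups such as
cladobranch sea slugs: tiered supermatrix curation, screening for violations
of the stationary/reversible/homogeneous (SRH) model conditions, and
quartet-based dissection of phylogenetic versus confounding signal
(Four-cluster Likelihood Mapping with permutation baselines, Quartet
Sampling branch scores, and approximately-unbiased placement tests).

## Substitution models and likelihoods

Sequences are amino acids over the 20 canonical residues plus one MISSING
state, to which alignment gaps (`-`), `?`, `X` and all non-canonical
letters are mapped. A substitution model is a symmetric exchangeability
matrix S, stationary frequencies pi, and optionally a discrete-gamma
distribution of site rates (k equiprobable categories with mean-per-quantile
rates; k = 4 by default, the field convention). The rate matrix
Q = S·diag(pi) is rescaled to mean rate 1, so branch lengths are expected
substitutions per site. Transition probabilities use the symmetric
eigendecomposition of diag(sqrt(pi))·Q·diag(1/sqrt(pi)), which is exact and
numerically stable for reversible Q; an independent `expm` route exists for
cross-checks. The package ships Poisson(+F) and a PAML-format
*synthetic* empirical-style matrix (`data/empirical_synthetic.paml`,
generated deterministically, not a published matrix); any user-supplied
PAML file (LG, WAG, ...) loads the same way. Which single matrix best
stands in for per-partition model selection is a user decision.

Likelihoods use Felsenstein pruning with per-node rescaling and site-pattern
compression. MISSING residues contribute all-ones partial likelihoods
(total ambiguity), so a fully-MISSING column has likelihood exactly 1.
A brute-force oracle sums explicitly over all internal-node (and
MISSING-tip) state assignments for trees of up to six leaves; it exists
solely as an independent check of the pruning engine and agrees with it to
below 1e-8 log-likelihood units on randomized instances.

### Branch-length optimization

Branch lengths are optimized by cyclic bounded scalar (Brent-type)
minimization on [1e-8, 10], stopping when a full sweep improves the total
log-likelihood by less than a tolerance (1e-6 by default for quartets;
stages that only need log-likelihood differences of order 0.1 or larger use
1e-4). An update is accepted only if it does not lower the likelihood, so
the trajectory is monotone.

For quartets a dedicated kernel exploits two structural facts: (i) with
four taxa, sites enter the likelihood only through their (a,b) and (c,d)
residue pairs, of which there are at most 400 each; and (ii) through the
eigendecomposition every per-edge likelihood reduces to
lik_p(t) = sum_e T[e,p]·exp(lambda_e·r_c·t) with T fixed during that edge's
line search, making each Brent evaluation a single weighted exponential
sum. The five lengths are initialized from pairwise maximum-likelihood
distances via the four-point decomposition, which starts the search near
the optimum and avoids the long, nearly flat coordinate-descent ridges that
otherwise arise on signal-free (permuted) data. Stages that compare
log-likelihoods at the O(0.1)-and-above scale (FcLM, Quartet Sampling)
evaluate in single precision; rounding there is orders of magnitude below
the quantities of interest.

On general trees, per-edge optimization reuses cached conditional
likelihood vectors: processing edges in postorder keeps every cached vector
current, so a sweep costs one traversal plus one outside-partial walk per
edge.

## Curation

* **Assembly ranking** picks, per species, the assembly with the largest
  cumulative length of ortholog-assigned transcripts; ties break by the
  number of assigned genes, then lexicographic id.
* **Coverage filters**: species with *less than* 60% of the ortholog set
  recovered are excluded (a species at exactly the threshold is kept);
  genes present in *at least* 50% of species are kept. Both thresholds are
  configuration values defaulting to these protocol values.
* **Outlier sequences** (misassigned or misaligned rows) are flagged by
  their mean BLOSUM62 similarity to the column-majority consensus: a robust
  z-score (median/MAD, consistency constant 1.4826) below -3.5 flags a row.
  The cutoff is configurable; the criteria of the original outlier script
  are not published, so this scoring is this package's own design.
* **Ambiguous-site masking** is a seedable Monte-Carlo sliding-window
  procedure in the spirit of Aliscore (whose exact settings are likewise
  not published): for every sequence pair, BLOSUM62 window scores (window 6)
  over shared columns are compared against the maximum window score of 100
  residue shuffles of that pair; a column survives if any covering window in
  any pair beats the null, and gap-only columns are always removed. On a
  perfectly conserved alignment nothing is masked; iid-random blocks are
  masked almost completely.
* **Concatenation** fills species absent from a gene with MISSING across
  that gene's columns and emits contiguous partitions. Internal coordinates
  are 0-based half-open; partition files on disk are 1-based inclusive
  (`MODEL, name = start-end`).
* **Tiers**: unreduced = all genes; intermediate = genes where every
  user-defined group retains at least one present member; strict = genes
  present in every species. Strict ⊆ intermediate ⊆ unreduced by
  construction, and the strict tier has zero missing rows per partition.
  Group representation is applied after any SRH-based taxon removal,
  matching the protocol ordering.

## SRH screening (Bowker tests)

For each taxon pair the 20x20 divergence table counts residue pairs over
columns where both taxa have data. Bowker's matched-pairs statistic
S = sum_{i<j} (n_ij - n_ji)^2 / (n_ij + n_ji) is referred to a chi-squared
distribution with df equal to the number of off-diagonal pairs with nonzero
paired sums — counting only occupied pairs avoids df inflation in sparse
amino-acid tables. Pairs with df = 0 (e.g. identical rows) are untestable
and excluded from the percent-violating denominator. Offender ranking
orders taxa by their share of violating pairs (ties by label); the choice of
how many offenders to drop is left to the user, since the original
exclusion rule ("strongly violated") is qualitative.

Calibration: on stationary, homogeneous pairs the test holds its nominal
size when the divergence table is reasonably occupied. The calibration
fixture uses pairwise distance 1.0 at 5,000 sites, giving expected
off-diagonal cell counts above 5; at much smaller divergences the sparse
table makes the chi-squared approximation conservative, which is a known
property of the test, not an implementation artifact.

## Four-cluster Likelihood Mapping

Quartets are drawn one taxon per user-defined group (group 4 = outgroup),
exhaustively if the product of group sizes is at most the cap, else as a
seeded uniform subsample of distinct combinations. Only columns where all
four taxa are non-MISSING are used; quartets with fewer than `min_sites`
(default 50) usable columns are recorded as uninformative — missing data
thus acts through quartet availability, which the permutation design then
probes. Each quartet's three topologies are optimized and the likelihood
weights w_k = exp(lnL_k - max)/sum are mapped into the classic 7-region
simplex: corner k if w_k >= 2/3, else the edge of the top two weights if
the minimum weight < 1/6, else center (the 2/3 and 1/6 boundaries
approximate the classic likelihood-mapping figure and are configurable).
Summaries report both the 7-region counts and the 3-region "basin"
percentages in which every informative quartet is assigned to its
maximum-weight corner.

Permutation schemes (all operating within partitions, preserving the gene
block structure):

* **I** — permute each taxon row's non-MISSING residues within each
  partition: destroys columnar co-variation, preserves the missingness mask
  and every per-taxon-per-gene residue multiset (hence any compositional
  heterogeneity).
* **II** — shuffle all non-MISSING residues of a partition across all
  cells: additionally homogenizes composition, so no SRH violation remains.
* **III** — scheme II plus re-randomization of which (taxon, gene) blocks
  are missing, preserving the per-partition count of absent taxa.

Net support per corner is max(0, original% - permuted%): support that
survives permutation cannot be phylogenetic and is subtracted as
confounding. The permuted baseline may pool several independent
permutation replicates (fresh permutation, fresh draw) for a stabler
estimate; with small group sizes (say 2 per group, 16 quartets) a single
permutation's corner distribution is dominated by sampling noise, so
pooled replicates are the default design for corner-uniformity checks.
Two caveats, documented on purpose: quartets drawn from the same permuted
matrix share taxa and are therefore positively correlated, and scheme I
preserves each row's realized composition, so the finite-sample
compositional fingerprint of the original matrix persists across all
replicates. Both effects make permuted corner percentages noisier than a
multinomial count would suggest.

## Quartet Sampling

Around every internal branch the tree induces four taxon sets; N quartets
(default 100) are drawn one taxon per set. A quartet is resolved when its
best topology beats the runner-up by at least delta (default 2.0
log-likelihood units), else uncertain; quartets with insufficient shared
sites are uncertain. Scores: QC = 1 + sum_t p_t log3 p_t over resolved
frequencies, signed negative unless the concordant topology is the unique
most frequent (ties count as non-concordant — conservative);
QD = 1 - |d1 - d2|/(d1 + d2), defined as 1 when d1 + d2 = 0 so that
overwhelming concordance without discordance scores QD = 1; QI =
resolved/N; per-taxon QF = fraction of that taxon's resolved quartets that
were concordant. Branch annotations ("QC/QD/QI", 2 decimals, NA where
unscored) round-trip through newick.

## AU placement tests

Candidate placements of a focal taxon are produced by pruning it and
regrafting at the midpoint of named edges (edges are addressed by the
sorted taxa of either side of their bipartition on the pruned backbone).
Branch lengths are re-optimized per candidate topology by default; a flag
allows a fixed-lengths fast mode. Per-site log-likelihoods feed a
multiscale RELL bootstrap (default scales 0.5..1.4, B = 10,000): at scale r,
B resamples of ceil(r·n) site indices are drawn, winners are tallied
(exact ties split uniformly at random via an infinitesimal jitter), and
BP_k(r) is probit-transformed with a 1/(2B) continuity correction and
fitted by weighted least squares (binomial variance through the
normal-quantile delta method) to z(r) = d·sqrt(r) + c/sqrt(r). The AU
p-value is 1 - Phi(d - c). Topologies with BP strictly inside (0,1) at
fewer than two scales get a clamped p-value (0 or 1) and a degenerate-fit
flag.

## Synthetic data

The simulator generates exactly the pathologies the pipeline is built to
detect, with known truth:

* **Sequence evolution** along a tree (root from pi, children via sampled
  transitions, per-site gamma categories). Heterogeneity specs rebuild the
  model with shifted frequencies pi' on every branch whose descendant
  leaves all lie in the affected set, producing SRH violations.
* **Missingness** operates at whole-gene-per-species granularity — the way
  ortholog absence manifests in real supermatrices — and returns the
  realized presence matrix as ground truth. Group-correlated patterns are
  supported.
* **Outliers** replace rows either with sequences simulated off-tree (a
  two-step walk from a stationary draw at distance 2.0 — misassignment) or
  with residue shuffles of the row itself (alignment error).
* **Four-group fixtures** place four groups on ((G1,G2),(G3,G4)) with a
  central internal branch b; a fraction rho of genes is simulated under the
  alternative quartet topologies (gene-tree discordance modelled as a
  topology mixture, sufficient to exercise the QC/QD semantics). Group
  rakes use per-gene terminal lengths drawn from a configurable range;
  star fixtures (b absent) serve as no-signal nulls.

Randomness discipline: every entry point takes a seed; multi-gene
generators spawn one independent substream per gene
(`SeedSequence.spawn`), so per-gene output does not depend on how many
other genes are drawn. All pipeline stages derive their streams from the
single run seed, making full runs bit-reproducible.

What the simulator does *not* emulate: indels and alignment error (columns
are always homologous), codon structure, among-gene rate variation beyond
the topology mixture, site-specific selective constraints, and realistic
missingness structure beyond gene-level presence probabilities. Passing
tests therefore demonstrate correctness of the statistical machinery under
the stated generating processes, not performance on real transcriptomes.

## Validation-study problem sizes

The self-contained validation studies (test suite and worked examples) run
at reduced scale chosen to keep each study's Monte-Carlo error well inside
its decision margin: oracle agreement on ~100 random 4-6-leaf instances;
Bowker calibration on 500 pairs of 5,000 sites; FcLM signal recovery on a
2-taxa-per-group, 50-gene x 500-site fixture with the scheme-I baseline
pooled over 24 permutation replicates; the confounding-signal null on a
5-taxa-per-group star fixture with 16 genes x 200 sites; Quartet Sampling
at N = 100, delta = 2 on 12-taxon fixtures; AU calibration on 200
replicates of a 12-taxon, 300-site fixture with B = 1,500. The QS mixture
fixtures deliberately combine a gene-level topology mixture with gene-level
missingness: with group-exchangeable rakes and complete matrices every
sampled quartet would see the same pooled signal and per-branch outcomes
would be all-or-nothing, whereas partial gene coverage gives each sampled
quartet its own gene subset and thereby the draw-level outcome variance
that mixed support scores describe.

## Known limitations

* Single evaluation model across partitions (real analyses select models
  per partition); supplying any PAML matrix mitigates but does not remove
  this simplification.
* The AU fit follows the classic two-parameter signed-distance/curvature
  form; no model-averaging or third-order corrections.
* Scheme III redistributes residues over the new present cells and so
  preserves per-partition residue multisets only up to rounding when
  per-site gaps exist inside present blocks (gene-level missingness, the
  generator's granularity, is preserved exactly).
* Bowker tests at low divergence are conservative (sparse tables); the
  package reports df so users can judge occupancy.
* Quartet drawing treats groups as fixed and ignores within-group
  phylogenetic structure, as in the original four-cluster design.
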