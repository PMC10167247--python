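# Methods

`nfatevo` quantifies four facets of a gene family's evolution across a set
of species — duplication, chromosomal rearrangement, alternative splicing
and selective pressure — and the correlation structure among them. This
note records the models, the defaults and the numerical choices, and what
the synthetic-data layer does and does not establish.

## Duplication from gene trees

An internal node of a rooted gene-family tree is labeled a **duplication**
when the species sets of at least two of its child subtrees intersect
(the species-overlap criterion); all other internal nodes are speciations.
For a multifurcating node any one overlapping pair of children suffices.
The **duplication ratio** is the number of duplication nodes divided by
the number of internal nodes. Because the duplication/speciation labels
exist only at internal nodes, the internal-node count is the default
denominator; `node_total="all"` divides by every node including leaves
for users who prefer the alternative reading. The ratio is invariant to
leaf order and branch-length rescaling, and on loss-free simulations the
labeling is exact: a duplication with two surviving descendant lineages
always produces overlapping child species sets, and a speciation never
does. With losses this breaks down asymmetrically — a duplication that
lost one side is invisible — so recall on lossy data is *measured*, never
asserted.

Leaf labels follow the `SPECIES|GENEID` convention (delimiter
configurable); an explicit gene-to-species map can be supplied instead.

Tree congruence utilities: the unrooted Robinson–Foulds distance (via
dendropy's bipartition machinery) and a permutation incongruence-length-
difference (ILD) test on Fitch parsimony lengths. Two search modes exist
for the ILD: scoring on one fixed topology (fast; note that parsimony
lengths are then additive over characters, so the ILD statistic is
identically zero — useful only as a degenerate baseline) and exhaustive
minimization over all unrooted binary topologies, precompiled and
feasible to 9 taxa. The permutation p-value uses the add-one rule
p = (1 + #{permuted ≥ observed}) / (n_perm + 1). Fitch scoring is
restricted to binary trees; multifurcating inputs are rejected rather
than scored by a heuristic generalization.

## Chromosome dispersion and breakpoints

The **chromosome ratio** of a family in a taxon is the number of
family-bearing chromosomes over the karyotype size. It is computed per
species and averaged (unweighted) over the taxon's species; a pooled
variant (summed counts over summed karyotype sizes) is available because
the per-taxon wording is genuinely ambiguous. Chromosome identity is
nominal — renaming chromosomes or permuting table rows changes nothing.

An **evolutionary breakpoint (EBP)** is a reference-order gene adjacency
that is no longer an adjacency in the target species, after both orders
are restricted to their shared gene set. Adjacencies are *unordered*
pairs — gene directionality is deliberately ignored — so reversing an
entire target order produces zero breakpoints, and the count is symmetric
in reference and target. **Synteny blocks** are obtained by cutting the
restricted reference at every broken adjacency; because pairwise
adjacency chains force contiguity, each block is a maximal run contiguous
(forward or reversed) in the target, blocks tile the shared genes, and
#blocks = #EBPs + 1.

The neighborhood window defaults to 5 genes each side of the anchor
(typical of published synteny diagrams for this family, which show about
4–6 neighbors); windows truncate at chromosome ends without padding. If
an ortholog group appears twice in a window the copy closest to the
anchor is kept, which keeps restriction-to-shared-genes well defined.
Ordinal positions are 0-based internally. A BED importer (0-based
half-open, strand in column 6) is provided; strand is parsed and carried
but never consulted by the EBP logic.

## Selection: pairwise dN/dS

Two estimators operate on in-frame pairwise codon alignments (gapped or
ambiguous codon columns dropped whole; in-frame stops are errors).

**Counting (NG86).** Synonymous site fractions per codon position are the
share of non-stop single-nucleotide changes that preserve the amino acid,
so synonymous + nonsynonymous sites = 3 per codon and site totals equal
the nucleotide length. Multi-hit codon pairs are pathway-averaged over
all orderings of the changes, excluding pathways that visit a stop codon
(under the standard code at least one stop-free pathway always exists,
verified exhaustively over all 61×61 pairs). Proportions receive the
Jukes–Cantor correction d = −(3/4)·ln(1 − 4p/3); a proportion ≥ 3/4 is
flagged saturated and dS = 0 flags omega undefined rather than dividing.
With transition bias (κ ≠ 1) NG86 is mildly biased; recovery tests hold
it to 15% rather than pretending otherwise.

**Maximum likelihood (GY94-style).** A reversible 61-state codon model:
single-nucleotide exchanges only, transitions scaled by κ, nonsynonymous
changes by ω, stop codons inaccessible, rate matrix normalized to one
expected substitution per codon per unit branch length. Codon frequencies
are uniform by default; F1x4/F3x4 empirical options exist (with add-one
smoothing) but the bundled simulator is deliberately uniform so that
recovery tests stay identifiable. The pairwise likelihood is
lnL = Σ log π(a)·P(a→b; t), evaluated through the symmetrized spectral
decomposition of the generator (the model is time reversible, so the
value is symmetric in sequence order; a matrix-exponential oracle agrees
to 1e−6).

Optimization is bounded L-BFGS-B in log-parameter space, t ∈ [1e−6, 50],
ω ∈ [1e−4, 99], from the fixed start grid t ∈ {0.1, 1.0} × ω ∈ {0.3, 3.0}
for determinism. κ is estimated jointly by default (start 2.0, bounds
[0.01, 100]): fixing κ at an arbitrary value biases ω̂ when the data carry
transition bias, and the published workflow this mirrors also treats κ as
a free nuisance parameter. The null model refits the same nuisance
parameters with ω pinned at 1, so the LRT statistic 2ΔlnL (clipped at 0)
is referred to χ²(1); no 50:50 boundary mixture is applied because ω = 1
is interior to the parameter space. Identical sequences yield t̂ at its
lower bound with ω flagged unidentifiable; non-convergence of every start
is flagged, never silent. Reported dN, dS and site counts use the
model-based flux decomposition (synonymous share of substitution flux at
the MLE, mutational opportunity at ω = 1), which keeps dN/dS ≡ ω̂ and
S + N equal to the nucleotide length.

**Classification.** With p the LRT p-value and α the threshold: p ≥ α →
neutral; otherwise ω > 1 positive, ω < 1 purifying; undefined ω →
inconclusive. Per-family summaries report the mean and SEM of the defined
pairwise ω̂ values and pool pairwise LRT p-values by Fisher's method
(−2Σln p against χ²(2k)); `combine="none"` leaves the p-values raw, since
no pooling rule is canonical for this summary.

## Splicing and the correlation layer

The **splicing ratio** of a group is the number of alternative-splicing
isoforms over the total transcript count. The numerator counts, for each
gene with ≥ 2 isoforms, the isoforms beyond the first (`numerator="all"`
counts all isoforms of such genes instead — the phrase "alternative
splicing isoforms" supports either reading). The isoform table is assumed
already deduplicated across tissues; transcript-level filtering is
upstream of this package.

Correlations are plain Pearson r with the t-transform p-value (n−2 df)
and the OLS line; R² = r². The standard report computes duplication ratio
~ divergence time, duplication ratio ~ chromosome ratio, and mean ω ~
chromosome ratio, each on the complete cases of its column pair.

**Dunnett many-to-one comparisons** adjust each group-vs-control t
statistic (pooled variance, N−k df) against a seeded Monte Carlo sample
of the null max-|t| distribution, p = (1 + #{max ≥ |t|})/(n_mc + 1), with
n_mc = 1e5 by default. Monte Carlo was chosen over multivariate-t
quadrature to keep the dependency surface small and the determinism
contract exact; the accuracy is controlled by n_mc and the implementation
is cross-checked in the tests against an independent multivariate-t
implementation. With a single comparison it reduces to the two-sample
t-test within Monte Carlo error.

**Bootstrap partial correlations** residualize response and predictor
against the remaining predictors (with intercept) and correlate the
residuals; with one predictor this is exactly Pearson r. Uncertainty
comes from case resampling: percentile CIs and the sign-based two-sided
p = 2·min(P(r* ≥ 0), P(r* ≤ 0)).

## Synthetic data: what it emulates, and what it does not

Every generator is a pure function of its arguments including the seed
(one `numpy` Generator per call, no global state).

* **Species trees** are pure birth (Yule): lineages split at a constant
  rate and all tips are extended to the present, so trees are exactly
  ultrametric. Extinction is omitted on purpose — the species tree plays
  the role of a fixed, externally dated scaffold, and extinct lineages
  would add nothing testable.
* **Gene families** evolve inside the species tree by birth–death:
  duplication and loss at constant per-lineage rates along branches,
  speciation copying every lineage into each descendant branch. Recorded
  truth counts only duplications with ≥ 2 surviving descendant lineages,
  i.e. the tree-visible events reconciliation could ever recover. With
  loss = 0 the expected event count has a closed form (Σ over edges of
  e^{λs}(e^{λL} − 1)) used as an independent check, and the gene-leaf
  count satisfies an exact per-replicate identity. Total extinction
  triggers seeded retries and then a hard failure.
* **Codon pairs** draw each ancestral codon uniformly from the 61 sense
  codons and evolve two descendants independently for t/2 under the same
  GY94-style generator the estimator fits (built separately in the
  simulator and the estimator modules, so recovery tests do not pass
  trivially through a shared matrix).
* **Gene orders** apply explicit inversion/translocation/swap operations
  to a reference order and record the broken adjacencies as planted
  truth. A helper draws k interior, pairwise non-adjacent inversions,
  each of which breaks exactly two adjacencies.
* **Ratio pairs** are y = a·x + b + ε with x uniform on [0, 1].

What passing these tests does *not* show: real gene families violate the
constant-rate birth–death assumption (bursts, hemiplasy, incomplete
sampling), real codon evolution has non-uniform frequencies, rate
variation among sites and alignments with error, and real synteny data
carry assembly artifacts and one-to-many orthology that the duplicate-
resolution rule only approximates. The simulators establish correctness
of the machinery, not robustness to those violations.

## The demo study and problem sizes

`make_demo` writes a 15-species study (5 taxa of 3 species) with 5
families; each taxon's divergence time is the mean pairwise MRCA age of
its species on the simulated tree. Planted conditions: duplication rates 0.1–0.7 per lineage per
unit time (an increasing gradient across families), family ω of
0.2/0.5/1.0/1.4/2.0 with t = 0.5, κ = 2 over 400 codons and three taxon
pairs per family, 0–3 planted neighborhood inversions per taxon, 0–2
extra family-bearing chromosomes per taxon, and a splicing propensity
rising along the taxon order. These sizes keep the full pipeline under a
minute while leaving every planted signal recoverable; the calibration
tests use larger, purpose-chosen sizes (2000 codons × 50 replicates per
grid cell for ω recovery, 200 replicates for LRT size, 500 null runs for
the Dunnett family-wise error, exhaustive enumeration to 6 leaves / 7
genes for the combinatorial oracles).

## Known limitations

* The species-overlap criterion overcounts duplications under incomplete
  lineage sorting and undercounts under loss; it is a topology-only
  criterion with no rate model.
* Pairwise ML assumes one ω per pair (no site or branch variation) and
  the χ²(1) reference is asymptotic; at short alignments the LRT is
  mildly conservative.
* The ILD test is defined between data partitions; applying it to
  topologies from two inference methods is not supported — compare
  topologies with the RF distance instead.
* EBP counts from windowed neighborhoods can miss breakpoints that fall
  outside the window after large rearrangements; the survey reports the
  shared-gene count per comparison so such truncation is visible.
* The chromosome ratio treats karyotype size as known and exact;
  scaffold-level assemblies violate this upstream of the package.
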