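# Methods

`phylodiscord` implements a workflow for diagnosing discordant genetic
signal among closely related taxa sampled for a biparental nuclear
marker (ITS-like) and a uniparental plastid marker (cpDNA-like). This
note documents the models and procedures, the parameters that matter,
what the synthetic-data generator does and does not emulate, and the
numerical and design choices behind the implementation.

## Intra-individual polymorphism (IPS) and additivity (APS)

Direct sequencing of a multi-copy marker such as ITS superimposes the
ribotypes present in an individual; double peaks are coded with IUPAC
ambiguity symbols. A column is an **intra-individual polymorphic site
(IPS)** for an accession when that accession carries a 2-, 3- or 4-base
ambiguity code there. `N` is treated as a failed base call (missing),
not as polymorphism. An IPS is **additive (APS)** when *every*
constituent base of the code also occurs as an unambiguous state in at
least one *other* scoped accession at the *same column*: the accession
then looks like the superposition of two variants that segregate in the
sample — the signature expected when hybridization combines parental
ribotypes and concerted evolution has not yet homogenized them.
"Same column, different accession" is the only reading of additivity
under which the presence of both parental variants is testable, and it
is the one implemented. The analysis scope defaults to the ingroup
accessions; the scope is exposed because published counts of this kind
are sometimes computed over all accessions instead.

Splitting a dataset on APS yields an APS-free alignment (scoped
sequences with zero APS plus all out-of-scope sequences, so outgroups
are never dropped) and an APS-bearing alignment; the APS-free set is
the one suitable for tree building, concatenation and species-tree
work.

## Parsimony engine

Tree length is Fitch small parsimony with leaf state sets equal to the
IUPAC base sets; gap (`-`) and `?` are the full set {A,C,G,T} ("gaps
treated as missing"). The Fitch pass is vectorized over unique column
patterns and roots at a trivalent node, which is equivalent to rooting
on an edge, so lengths are rooting-invariant; this is asserted against
an exhaustive enumeration of internal-state assignments in the tests.

Per-site bounds: the minimum steps `m_i` is the minimum number of
states hitting every observed base set at the site (brute force over
the 15 subsets of {A,C,G,T}) minus one; the maximum `g_i` is
`n_eff − max state cover` (attained on a star tree), where a sequence
covers a state if its base set contains it. CI = Σm/Σs and
RI = (Σg−Σs)/(Σg−Σm) are summed over variable sites, with sites where
`g = m` contributing only to the length.

Site classification follows common practice: ambiguity codes
contribute to no state count, a column is variable iff ≥ 2 distinct
unambiguous states occur and informative iff ≥ 2 states are each borne
by ≥ 2 sequences. Because programs differ in how ambiguity codes enter
these counts, an alternative rule (`ambiguity="resolve"`: variable iff
the base sets cannot be resolved to one state) is exposed.

The MP search is random-addition stepwise insertion followed by
subtree-pruning-regrafting (SPR) hill climbing with restarts; an
NNI-radius restriction of the SPR neighborhood is available for fast
bootstrap replicates. This approximates tree-bisection-reconnection
searches: on the data sizes this package targets, restarts recover the
same optima, which is checked against exhaustive enumeration for ≤ 7
taxa (heuristic mode can never report a length below the global
optimum it is compared to). Exhaustive search is the default at ≤ 7
taxa. All equally parsimonious topologies found are retained; strict
consensus uses dendropy. Bootstrap support resamples columns with
replacement, runs one fast search per replicate, and reports the
percentage of replicates containing each split.

### ILD / partition-homogeneity test

`D = L(A∪B) − [L(A) + L(B)]` with lengths from MP searches; replicates
reassign columns at random to pseudo-partitions of the original sizes,
and `p = (1 + #{D_rep ≥ D_obs})/(n_reps + 1)` (add-one convention).
Since the combined length is permutation-invariant, a replicate is at
least as extreme iff its partition-length sum is ≤ the observed sum.
For ≤ 8 taxa the implementation precomputes Fitch steps for every
topology × column pattern, reducing each replicate to two
matrix-vector products; this is what makes simulation-based
calibration of the test cheap.

Calibration caveat: on weakly divergent congruent partitions the
separate-partition optimum already attains the permutation maximum
(`D_obs = 0`), so the p-value is 1 by construction — the statistic is
degenerate, not miscalibrated. Approximate uniformity of the null
p-value is a property of regimes with appreciable homoplasy; the
calibration simulations therefore use 6 taxa at 1.2
substitutions/site branch length and 2 × 200 sites.

## Supporting-position split spectra

For a bipartition into functional ingroup and functional outgroup,
every column is classified as **symmetric** (two states overall, each
side fixed for a different one), **asymmetric** for side S (S fixed,
other side shows ≥ 2 states none equal to S's), or **noisy** for side S
(S fixed for a state that also occurs opposite — convergence, chance
similarity, or an autapomorphic column). Ambiguity codes and gaps are
missing for the fixation tests; a side must have ≥ 1 resolved
character to count as fixed, and columns with an unresolved side are
skipped. A constant column is noisy for both sides under these
definitions — the implemented convention is asserted explicitly in the
tests. The headline "supporting positions" count for a split is
symmetric + asymmetric, excluding noisy positions, since noisy columns
represent convergence rather than support.

## Statistical-parsimony haplotype network

Sequences are collapsed to haplotypes (exact identity by default; a
missing-compatible policy is available) and connected
agglomeratively: at step lengths j = 1 … limit, components whose
minimum inter-component haplotype distance is j are joined, inserting
j−1 inferred (unsampled) intermediate nodes per new path. All equally
short alternative connections at the same j are retained, producing
the loops characteristic of such networks; node ids are assigned in
input order, so construction is deterministic. Components not joinable
within the limit stay disconnected. The probability-of-parsimony (95%)
connection limit of the original statistical-parsimony method is not
computed; the limit is a required parameter (30 steps in the workflow
this package reproduces). Haplotype distances treat gaps as missing by
default, with a fifth-state option, because network programs differ on
this point and the haplotype count can depend on it.

## Likelihoods and topology tests

Per-site log-likelihoods use Felsenstein pruning with IUPAC leaf
vectors (1 for each compatible base; all ones for gap/missing).
Models are the GTR family (JC69, K80, HKY85, SYM, TVM, GTR) via
symmetric-form eigendecomposition, scaled to one expected substitution
per site. Among-site rate variation uses a discrete gamma with
mean-of-slice category rates (4 categories by default) and an optional
invariant-sites proportion mixed as a two-component site mixture.
Empirical base frequencies are used for HKY/TVM/GTR; equal frequencies
for JC/K80/SYM. Branch lengths are optimized coordinate-wise with
bounded scalar minimization, iterated until the relative
log-likelihood change is below tolerance; the total log-likelihood is
nondecreasing across sweeps. Two-taxon optimization reproduces the
analytic JC and K80 distances to 1e-6, which is the accuracy level the
tests enforce.

Constrained topologies (e.g. enforced monophyly of a taxon) come from
the parsimony search under clade constraints and are then
branch-length optimized; the machinery mirrors the common practice of
comparing a best tree with constraint-satisfying alternatives.

Topology tests resample estimated per-site log-likelihoods (RELL)
without re-optimization. **WKH** (weighted Kishino–Hasegawa): the
log-likelihood difference of each tree to the best tree is
standardized by its bootstrap standard deviation and referred to the
centred bootstrap distribution, two-sided. **WSH** (weighted
Shimodaira–Hasegawa): each tree's statistic is the maximum
standardized difference over all rivals, with the null taken as the
centred maximum across bootstrap replicates. Degenerate zero-variance
comparisons return p = 1 with a warning. The approximately-unbiased
test (multiscale bootstrap) is out of scope. On two trees, WKH reduces
to a z-test of the mean site difference, which the tests verify.

## Multispecies coalescent and the hybridization test

The species tree is rooted and ultrametric with node heights in
expected substitutions per site and a population-size parameter θ on
every branch, including the root stem (which extends indefinitely). θ
is the *mean within-branch pairwise coalescence time* in
substitutions/site — the convention of dmv-style annotations produced
by Bayesian species-tree software — so a lineage pair coalesces at
rate 1/(θ·h) and k lineages at rate k(k−1)/(2θh), where h is the locus'
heredity scalar (2 for a biparental nuclear marker, 1 for a maternally
inherited plastid marker). Consequently E[pairwise TMRCA] = θh and
E[TMRCA of n samples] = 2θh(1 − 1/n), the closed forms the simulator
is validated against (within 2% at 10,000 replicates). Gene trees are
simulated by running an exponential race within each branch and
passing surviving lineages to the ancestral branch. Hybridization is
modelled as a gene-flow pulse: looking backward, each lineage in the
recipient species moves to the donor at the event time with
probability γ — the simplest mechanism the minimum-distance test is
sensitive to; a full network model is out of scope. Every simulated
gene tree satisfies the no-migration MSC constraint (no cross-species
coalescence below the species divergence) when no pulse is configured,
and this is asserted over replicates.

Sequences evolve site-independently along the gene tree with branch
durations scaled by the locus' relative mutation rate μ_rel; per-site
rates are drawn from the model's discrete-gamma categories (rate 0
with probability p_inv).

The **posterior-predictive hybridization test** consumes a posterior
sample of annotated species trees (Newick list or NEXUS; bracketed
`theta`/`dmv` metadata), applies burn-in and thinning, simulates one
replicate dataset per retained tree, and computes for every species
pair `p = #{simulated minimum inter-species distance ≤ observed}/n_sim`
— a plain proportion without add-one correction, matching the
published tool's p-value resolution. Distances are uncorrected
p-distances with pairwise deletion; IUPAC codes compare by base-set
disjointness (overlap = match), which is conservative for a
minimum-distance statistic. Small p flags pairs whose sequences are
closer than incomplete lineage sorting alone can explain.

Because the minimum distance lives on a lattice (multiples of 1/L) and
ties count toward p, the test is conservative: under a no-migration
truth the realized type-I rate sits at or slightly below the nominal
α = 0.05. The calibration check therefore brackets the rate with a
binomial band across replicate studies rather than across individual
pair-tests. Power against a recent γ = 0.5 pulse at moderate θ exceeds
50% of replicate studies in the configuration tested (two species
diverged 0.02 subs/site, θ = 0.002, pulse at 0.001, 3 samples per
species, 500 sites).

## Synthetic-data generator

The generator emulates the study design the pipeline targets: a small
ingroup species tree from a pure-birth (random-join, exponential
waiting time) process with per-branch θ drawn uniformly from a range;
one divergent outgroup species attached above the root; two loci with
the nuclear/plastid contrast — by default an ITS-like locus (SYM+G,
653 sites, relative rate 1.016, heredity 2) and a cpDNA-like locus
(TVM+I+G with AT-rich frequencies, 960 sites, relative rate 0.385,
heredity 1); configurable hybridization pulses; and intra-individual
ribotype mixing. For the nuclear locus each individual carries two
gene copies; the reported sequence writes differing sites as IUPAC
codes unless homogenization (probability `c` per differing site,
collapsing to one parent chosen uniformly) erases them — `c = 0` gives
fully additive patterns, `c = 1` fully homogenized contigs. Defaults:
5 ingroup species, 4 samples per species (outgroup capped at 2),
θ ∈ [0.002, 0.006], birth rate 80 per substitution/site, outgroup stem
0.08, c = 0.5.

A pseudo-posterior stands in for a Bayesian species-tree sample:
copies of the truth with mean-one multiplicative lognormal noise on
the height scale (a single factor per sample, preserving
ultrametricity) and on each branch's θ independently.

What the generator does **not** emulate: indels (alignments are
gapless; gap handling is tested on hand-built fixtures), PCR and
sequencing error, recombination within loci, within-species population
structure and geography, and PCR-mediated ribotype bias. Passing tests
therefore demonstrate correctness of the algorithms under the MSC +
pulse + mixing model, not robustness to alignment error or
recombination in real data.

Everything is deterministic under the scenario seed (byte-identical
output bundles); the pipeline derives one RNG stream per stage from
the master seed and the stage name, so toggling stages does not shift
another stage's randomness.

## Numerical choices and degenerate inputs

- Coordinates are 0-based half-open everywhere; NEXUS 1-based
  inclusive CHARSET ranges are converted on read. `U` normalizes to
  `T`.
- p-distance with zero comparable positions raises an error; inside
  the all-pairs distance matrix such pairs are NaN and are skipped by
  the minimum-distance scan.
- CI is undefined (error) when no steps are observed; RI is defined as
  1 when its denominator vanishes on otherwise valid data.
- Branch lengths are bounded to [1e-9, 10] during optimization;
  transition matrices are clipped at 0 and row-renormalized against
  rounding.
- Ties in the MP search are retained (all equal-length topologies,
  deduplicated by canonical split sets); equal-length alternative
  connections in the haplotype network are all kept.
- The problem sizes used by the test-suite and acceptance-script
  simulations (hundreds of sites, 4–7 species, tens to hundreds of
  replicates) are the package's chosen verification scale; the closed
  forms and oracles they are checked against are size-independent.

## Known limitations

- The MP search is exact only to 7 taxa; beyond that it is a heuristic
  and, as for any heuristic search, reported lengths are upper bounds.
- The haplotype network omits the statistical (95% probability)
  connection limit; the fixed step limit is a required parameter.
- The AU topology test is not implemented (WKH/WSH only).
- The hybridization test's p-values are conservative on tied minimum
  distances (see above) and share the published method's sensitivity
  limits: pulses immediately after speciation, or loci with effective
  population sizes shrunk by concerted evolution, are hard to detect.
- Likelihood optimization is per-branch coordinate ascent on a fixed
  topology; there is no simultaneous model-parameter estimation or ML
  topology search.
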