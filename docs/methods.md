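# Methods

`bkit` re-implements, as a verifiable library, the analytical core of a
genome study of a severely bottlenecked mammal population: diversity
quantification from multi-sample variant calls, read-depth detection of
segmental duplications, two-population demographic inference from the joint
allele-frequency spectrum, branch-specific dN/dS scanning on a fixed
5-taxon tree, and similarity-graph clustering of genes into families.
Every stage is exercised against synthetic data whose generating process is
known, so each claim in the test suite is a statement about planted truth.

## Synthetic data

The cohort generator draws genotypes from a coalescent simulation (msprime)
under five parametric demographies (constant size; split with migration;
ancestral bottleneck then split; split, bottleneck, recovery; growth, split,
independent bottlenecks).  Sizes are ratios of the diploid ancestral size,
times are in generations, and the mutation rate can be given per generation
or per year (converted with the generation time, default 3 years; the
default rate 0.3e-8/year follows the usual cross-species divergence
calculation).  Ancestral alleles are known exactly, per-sample depth is
Poisson.  The coalescent backend is deliberately confined to fixture
generation and test oracles; the inference engine below never uses it.

Depth tracks are per-position read-start counts, Poisson (or
negative-binomial with variance mu + a*mu^2) with mean
`mean_depth * CN / 2`, zero in assembly gaps.  Codon alignments evolve by a
Goldman–Yang-style jump process (single-nucleotide codon changes, kappa for
transitions, branch-specific omega on nonsynonymous changes, stop codons
unreachable), recording every realised substitution per branch.  Bit-score
graphs plant family structure directly in Hscore units by fixing self
scores at 100.

What the generators do *not* emulate: sequencing error and genotyping
uncertainty, alignment error, indels and structural variation other than
planted gains, GC-coverage bias, and real repeat families.  Passing tests
therefore demonstrate correctness of the algorithms under their stated
models, not robustness to upstream artefacts.

## Diversity measures

Variant positions are 1-based (VCF), intervals 0-based half-open (BED); a
position `pos` is masked iff some interval satisfies `start < pos <= end`.
The depth filter keeps sites with every sample in [5, 30] reads
(inclusive, AND across samples).  Windowed statistics tile each scaffold
from position 0 with fixed windows (50 kbp for density, 100 kbp for the
heterozygosity classification), dropping scaffolds shorter than one window
and the trailing partial window.  A 100-kbp window is heterozygous iff it
holds strictly more than 40 heterozygous SNVs; the homozygous percentage is
reported both over classified windows and over the whole genome length,
since short excluded scaffolds make the two denominators differ.

ROH detection follows PLINK semantics: windows of 20 consecutive SNVs, a
window "hits" when it contains at most 1 heterozygote, a SNV is in ROH
state when more than 5 % of windows overlapping it hit, and maximal
ROH-state runs are kept if they span at least 10 kbp with at least one SNV
per 50 kbp.  The 5 % proportion and 1-het allowance are PLINK defaults,
adopted because only the three main flags are specified for this analysis.

Tandem-repeat records are labelled microsatellite (monomer < 5 bp), complex
(monomer > 4 bp, GC within [20, 80] %, array > 100 bp, entropy > 1.76,
copy-number variation > 4 bp, imperfect array) and large (array >= 1 kbp,
subgrouped at 1/3/10 kbp); complex and large are deliberately not mutually
exclusive.

## Read-depth segmental duplications

Repeat and gap masks are combined with a k-mer over-representation mask
(36-bp k-mers sampled every 31 bp; sampled k-mers with 3 or more exact
forward-strand occurrences in the assembly are masked) and padded by 36 bp
on each flank.  Scaffolds under 10 kbp and listed sex scaffolds are
excluded.  Windows hold exactly 1000 unmasked positions (genomic spans may
be longer); read depth is the sum of read starts over a window's unmasked
positions.

Control regions are found by iterative symmetric trimming: windows more
than 3 sd from the current mean are discarded until the set stabilises (or
the mean moves < 1e-6).  The trimming severity is configurable since the
original tool's exact convergence rule is not published.  Copy number is
`CN = 2 * RD / mean(control RD)`; on uniform-coverage genomes the control
mean CN centres at 2 (the calibration the acceptance script reproduces).

Calling rule: per sample, thresholds are taken from the control-window CN
distribution (hard = mean + 3 sd, soft = mean + 2 sd).  A candidate block
is a maximal run of consecutive windows above the hard threshold, where two
runs separated by a single window that still clears the soft threshold are
bridged (one such dip per block).  Blocks need at least five windows, a
genomic span of at least 10 kbp, and no member CN above 100; gaps are
subtracted from reported intervals.  The alternative reading — maximal runs
above the *soft* threshold with at most one sub-hard member — was
implemented first and rejected: with the tight control sd of clean data,
~8 % of ordinary windows exceed the soft cutoff, noise windows attach to
every true run and the allowance is exhausted, collapsing sensitivity (0.64
measured against planted truth vs 1.0 for the bridging reading).

Cross-sample sharing is base-pair-level interval intersection; gene overlap
requires at least 60 % of the gene span inside shared duplications.

## Joint-AFS demographic inference

The observed spectrum X is the (n1+1) x (n2+1) matrix of derived-count
tallies with the fixed corners (0,0) and (n1,n2) masked.  Sites with
missing calls are hypergeometrically projected down when enough alleles are
called, otherwise dropped.

The expectation engine is a discrete Wright–Fisher frequency-grid chain.
The density of segregating sites over derived-allele count 0..G (grid
default 100; 4x the larger sample size minimum) evolves by:

* **drift** — the binomial transition of the grid, applied per step with
  mixture weight `alpha = G dt / nu`, matching the diffusion drift rate of
  a population of relative size nu;
* **mutation influx** — a calibrated low-count profile: the solution `c` of
  `(I - B^T) eta = c` for the target `eta_i = 1/i`, truncated to counts
  1–5.  The truncation matters: the full solution also carries small
  positive entries next to the fixation boundary that merely balance the
  chain's absorption flux, and injecting them acts like new mutations
  arising at frequency ~1, visibly corrupting fixed-in-one-population
  cells.  With the truncated profile the stationary spectrum is within
  ~0.6 % of theta/i at grid 200;
* **migration** — a deterministic frequency map `x1' = x1 + m dt (x2 - x1)`
  applied by linear remapping, operator-split into chunks short enough that
  the shift stays below half a grid cell;
* **size changes and splits** — piecewise-constant epochs; at a split both
  daughter populations inherit the ancestral frequency (diagonal joint
  density).

Epochs without migration compose the per-step affine map by binary
doubling, so severe bottlenecks cost O(log steps) matrix products rather
than O(steps).  Projection from grid to sample counts is hypergeometric
(subsampling consistency of the SFS), which keeps the neutral limit exact.
Validation against coalescent branch-length expectations shows interior
cells agreeing to ~1–3 %, with worst-case ~5–9 % on a few cells dominated
by young post-split mutations.

The composite likelihood treats unmasked cells as independent Poisson
counts; theta is profiled analytically (`theta_hat = sum X / sum M`).
Fitting is multi-start Nelder–Mead in log-parameter space (bottleneck onset
times as logit fractions of the split time, keeping epoch ordering feasible
by construction), with a longer polishing run from the best coarse
optimum.  For the ISB model two informed starts are available, mapping
fitted BIM and SBR optima into ISB space; ISB approximately nests BIM, so
the warm start guarantees it is never ranked below an artefact of
optimisation.  Model comparison uses LL ranking plus chi-square LRTs for
explicitly declared nested pairs; uncertainty comes from a 1-Mb block
bootstrap (blocks, not sites, to respect linkage).

**Identifiability.**  At n = 8 + 6 haploids the ISB likelihood has exact
ridges: fitting the engine's own noise-free expectation recovers the
bottleneck parameters while (growth size, growth duration, split time) move
far along a ridge at numerically identical LL, and each bottleneck's size
and duration trade off at fixed severity tau_b/nu_b (the drift the
bottleneck accumulates).  Parameter-recovery experiments therefore assert
the identifiable severities, not the raw (nu_b, tau_b) decomposition.

## Branch dN/dS

Ancestral sequences come from Fitch parsimony per nucleotide column
(bottom-up sets, top-down assignment keeping the parent state where
possible; remaining ties broken by fixed base order A<C<G<T and the tie
fraction reported).  Substitutions are attributed per branch by
Nei–Gojobori (1986) counting between parent and child: per-codon
synonymous-site fractions by neighbour enumeration (stop neighbours
excluded from the fraction, so N + S = 3 per codon), multi-step codon
differences averaged over all minimal stop-free pathways, Jukes–Cantor
correction optional.  Site totals are taken from the child sequence.
Reconstructed stop codons (rare parsimony artefacts) exclude that codon
column from that branch's counts.

Aggregate rates use supergene concatenation; uncertainty is a codon-column
bootstrap (default B = 500 at full scale).  The per-gene foreground test
contrasts omega on the cheetah branch against the pooled background
branches with the difference statistic T = omega_fg − omega_bg;
p = (1 + #{T* <= 0})/(B + 1) over codon-bootstrap replicates.  A bootstrap
(rather than a branch-label permutation) is used because branch lengths
make per-column attributions non-exchangeable across branches.  Branches
with Sd = 0 receive a recorded 0.5 pseudocount on the synonymous count
rather than an infinite ratio.  Calibration measured over 200 null
replicates puts the empirical size near 0.03–0.05 at alpha = 0.05.

This counting machinery deliberately replaces likelihood codon models: it
is exactly reproducible, fast enough for resampling-based inference, and
its behaviour is fully auditable against enumeration oracles.  Numerical
agreement with ML codon-model estimates on real data is out of scope.

## Gene families

Edges require more than 1/3 of both genes aligned; the weight is
Hscore = 100 * sc(G1,G2) / max(sc(G1,G1), sc(G2,G2)) clamped to [0, 100]
(the x100 scaling makes the quoted 0–100 range and the >5 threshold
coherent).  Genes without self hits fall back to their maximum observed
score (flagged).  Clustering is greedy average-linkage over the filtered
graph: the pair of clusters with the highest average cross Hscore (absent
edges count 0) merges, refusing merges with average <= 5, merged edge
density <= 1/3, size > 500, or involving a cluster that already contains an
outgroup-species gene.  Ties break on the lexicographically smallest merged
member set, making the result independent of input order.  Sharing
summaries report both exclusive (species set equals the combination) and
inclusive counts.

## Problem sizes and seeds

All experiments are seeded and deterministic.  The test suite uses
desk-scale problem sizes chosen to keep each experiment's Monte-Carlo noise
well inside its asserted margin: 5-Mb genomes at 10x for the duplication
caller, 60-Mb cohorts (= 5e4 segregating sites) for demographic recovery,
grid 60 for fitting and 200 for neutral-limit checks, 300-codon alignments
for test calibration and 1500–2000 codons for power and bootstrap
experiments.

## Known limitations

* The AFS engine's few-percent bias on young-mutation boundary cells is
  visible in Pearson residuals on large simulated datasets; it is small
  relative to the 25 % recovery tolerances used here but would matter for
  fine-grained real-data model comparison.
* Composite likelihood ignores linkage, so LL differences of a few units
  between near-equivalent demographic models are not meaningful on a single
  realisation; rankings are asserted across seeds.
* Fitch parsimony under-counts substitutions on long branches and cannot
  separate the outgroup branch from its sibling at the root; both effects
  are shared by all branch-rate comparisons reported.
* The gene-family oracle scales are small (tens of genes); the greedy
  clustering is O(n^3)-ish and not tuned for proteome-scale graphs.
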