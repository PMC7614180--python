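# Methods

This note documents the models, estimators and numerical choices behind
`stockid`, what the synthetic-data generator does and does not emulate, and
the design decisions taken where the problem was genuinely open.

## Genotype container and filtering

Genotypes are diploid ALT-allele dosages {0, 1, 2, missing} over biallelic
SNPs; multi-allelic records must be split upstream and are skipped on VCF
import. Site filters retain loci with call quality QUAL ≥ `qual_min`
(loci without a QUAL pass only when the threshold is 0), number of samples
with data NS ≥ `ns_min`, and pooled minor allele frequency ≥ `maf_min`
computed over all non-missing calls ignoring population labels. The three
filters commute, and the default pipeline applies QUAL ≥ 20, NS ≥ 30,
MAF ≥ 0.05 — the thresholds typical of low-coverage cohort filtering.

## Weir–Cockerham F_ST

Per site and population pair, the moment estimator's variance components
are computed from sample sizes n_i, ALT frequencies p_i and observed
heterozygote proportions h_i (two-population case):

    nbar = (n1+n2)/2,  n_c = (n1+n2) − (n1²+n2²)/(n1+n2)
    pbar = (n1 p1 + n2 p2)/(n1+n2),  hbar = (n1 h1 + n2 h2)/(n1+n2)
    s² = [n1(p1−pbar)² + n2(p2−pbar)²]/nbar

    a = (nbar/n_c)(s² − [pbar(1−pbar) − s²/2 − hbar/4]/(nbar−1))
    b = (nbar/(nbar−1))(pbar(1−pbar) − s²/2 − (2nbar−1)/(4nbar)·hbar)
    c = hbar/2

θ = a/(a+b+c), undefined when a+b+c = 0 (monomorphic across the pair) or
when either population has fewer than two genotyped individuals at the
locus. Multi-locus θ is **ratio of sums** Σa/Σ(a+b+c) over defined loci,
the standard convention; it is not the mean of per-locus ratios. Negative
per-locus components are kept so the ratio stays unbiased; excluded
monomorphic loci contribute zero to both sums, so their exclusion is
inconsequential. Missingness is handled pairwise-complete per locus; no
imputation enters estimation. The test suite checks the components against
an independently written brute-force transcription of the general-r
formulas to 1e-12 on random instances.

## Synthetic cohorts

**Model.** Ancestral ALT frequencies are uniform on a configurable MAF
interval (default [0.1, 0.5]). Per-population frequencies follow the
Balding–Nichols model, p_k ~ Beta(p(1−F)/F, (1−p)(1−F)/F), on a two-level
star tree: populations in a designated subgroup first share a branch with
drift F_shared, then drift independently along terminal branches F_k;
genotypes are Binomial(2, p_k) (Hardy–Weinberg within populations).

**Drift calibration.** For a pair with drifts F_i, F_j the expected
pairwise θ is taken as (F_i+F_j)/2 — exact in expectation for equal drifts,
and verified empirically by Monte-Carlo rather than assumed: 200-replicate
means over a drift grid {0.05, 0.13, 0.2, 0.45} at 118 loci recover F
within ±0.015. Per-population drifts are least-squares fitted (logit
parameterisation, bounded (1e-5, 0.95)) so the expected matrix matches a
target pairwise F_ST matrix. A two-level tree is required because a
single-level star cannot reproduce a pattern in which one population is
uniformly farther from all others while two populations are mutually close;
with the sister pair sharing a branch the fit reaches max residual < 0.01
on the default four-stock target.

**Outlier loci and hotspots.** Outlier loci receive drift multiplied by
`outlier_drift_scale` (both tree levels; configurations where scaled drift
would reach 1 are rejected); `floor(outlier_chrom_fraction × n_outliers)`
of them are placed on one hotspot chromosome, the rest cycle over the other
chromosomes — flooring and round-robin placement keep locus metadata
deterministic. The default genome-like scenario uses scale 100 over
background drifts fitted to a genome-wide F_ST of 0.0007–0.0046, which
puts the *designed panel's* pairwise θ in the 0.1–0.45 range of the
motivating study.

**Assessment cohorts and label error.** A row-stochastic mixing matrix
gives P(true origin | traditional label). Individuals carry a traditional
label drawn from configured label margins (default: even split); the true
origin is drawn from the label's mixing row and genotypes from the origin's
*realised* baseline frequencies — so baseline and assessment cohorts are
consistent draws from the same populations. Technical replicates are
duplicated individuals (id suffix `-rep`, a seeded random subset) with
identical genotypes before degradation.

**Degradation.** Each call is set missing with `missing_rate`; surviving
calls move to one of the other two dosages with equal probability under
`genotype_error_rate` — the simplest exchangeable corruption.

**What is not emulated.** Sequencing reads, per-individual coverage
variation, genotype likelihoods, linkage (simulated loci are exchangeable
given the tree, so LD pruning on simulated data is exercised via planted
duplicated/correlated columns in tests), and selection. Passing tests on
synthetic data therefore demonstrate correctness of the estimators and the
pipeline logic under the stated generative model, not robustness to
coverage artefacts or real LD structure.

## Panel design

Per population pair, the k loci with largest defined θ are selected
(default k = 100), ties broken by ascending genome order, stable;
duplicates across pairs are merged recording all contributing pairs, the
best rank and the best θ. LD pruning runs sliding windows (default 50 loci,
step 5) over the candidates in genome order; within a window, while any
surviving pair has genotype r² > `r2_max` (default 0.5), the largest-r²
pair is resolved by removing its lower-θ member (tie: the later locus).
r² uses pairwise-complete samples; constant columns have r² ≡ 0. The
pruning parameters are not dictated by any convention — 0.5/50/5 are common
practice and explicit for reproducibility; pruning is idempotent. Ranking
within pruning uses each locus's best θ across contributing pairs, which
preserves the most discriminative loci. Whether LD should be computed
baseline-wide or within populations is open; baseline-wide is used.

## Population structure

**PCA** mean-imputes missing dosages per locus, centres (optionally
scales), and fixes signs so each axis's largest-magnitude loading is
positive.

**Cluster search.** For each k, seeded k-means (10 restarts) on the PC
scores is scored by BIC(k) = n·ln(WSS/n) + k·ln(n) (the cited clustering
function does not specify its criterion; this is the standard WSS form).
By default *all* principal axes are retained at this stage: with only a few
informative axes kept, any ~e^{ln n/n} fractional WSS reduction pays for
an extra cluster and the BIC curve decreases indefinitely, whereas with the
unstructured axes included the curve attains its minimum at the true K on
well-separated data.

**Admixture model.** Individual-by-locus genotypes are modelled as two
binomial draws with ALT probability Σ_k q_ik p_kl; the log-likelihood skips
missing entries. EM updates Q and P in closed form and is monotone; P is
clamped to [1e-6, 1−1e-6] to keep the likelihood finite; Q rows are
initialised Dirichlet(1), P from pooled frequencies with seeded Gaussian
jitter (sd 0.05). Single fits default to convergence (tol 1e-3, max 300
iterations). This is a deliberate maximum-likelihood replacement for
Bayesian MCMC admixture inference with correlated allele frequencies: same
model family, deterministic per seed, desk-scale. Absolute log-likelihoods
are **not** comparable to posterior model likelihoods — only plateau and
ΔK patterns are.

**Replicate protocol and model choice.** `replicate_likelihood_table` runs
n_runs seeded fits per K and aligns the replicate Q matrices to the best
run by greedy column-permutation on correlations. Unlike single fits, the
protocol runs every fit for a *fixed* iteration budget (default 50, no
convergence stop), mirroring the fixed-sweep design of replicate MCMC runs.
This choice is load-bearing: run to convergence, the ML likelihood gains
roughly half the added parameter count (≈(L+n)/2 log-units) for every
K beyond the true one, so a likelihood "plateau" never occurs; at a common
finite budget the spurious gains are truncated (noise-fitting converges
slowly) while the true-structure gains are realised, and the replicate
spread reflects multimodality plus unfinished hill-climbing. The plateau
criterion — the smallest K whose mean lnL gain to K+1 falls below the
replicate standard deviation at K — then typically (not always: the gain
and the sd are the same order, so the selection remains seed-sensitive)
selects the simulated K on strongly structured data. Evanno's
ΔK(K) = |mean lnL(K+1) − 2·mean lnL(K) + mean lnL(K−1)| / sd lnL(K) is
computed at interior K and flagged undefined where the sd is zero; on
hierarchically structured data it peaks at K = 2 (the deepest split), and
re-running after removing the most divergent population exposes the next
split, supporting the iterative-subsetting workflow.

## Assignment

**Bayesian predictive (Rannala–Mountain).** For each candidate population
with baseline ALT/total allele counts (x, n) at a locus, the probability of
a query genotype is the Dirichlet(½,½)-multinomial predictive, with alleles
drawn sequentially (counts updating) and a factor 2 for heterozygotes:
P(g=2) = (x+½)(x+1+½)/[(n+1)(n+2)], etc. Per-population log-likelihoods
sum over non-missing loci; the posterior uses a uniform prior over
populations. Leave-one-out removes the query's own alleles from its
population's counts first. The prior α = 1/J per allele (J = 2) is
configurable. No exclusion test is applied — UNASSIGNED arises only from
method disagreement.

**DAPC.** PCA is fitted on the baseline (mean-imputed, centred); linear
discriminant analysis with shared within-class covariance runs on the
retained PCs (≤ K−1 discriminant axes); queries are projected using the
baseline's imputation means and rotations and scored with Gaussian
posteriors. A singular within-class covariance falls back to a ridge
(shrinkage) solver, logged.

**Monte-Carlo resampled classifier.** The third engine retrains the same
PCA+LDA classifier on stratified resamples of the baseline (default 30
resamples at 50%) and takes a majority vote; scores are vote fractions.
The resample draw uses one global permutation of sample positions, so all
three engines are equivariant under renaming populations. Exact posterior
ties resolve to the lexicographically smallest population name, logged.

**Consensus and cross-validation.** The consensus label exists iff all
three argmax labels coincide; otherwise UNASSIGNED — the consensus set is
exactly the intersection of per-method agreement. Self-assignment runs
stratified 50% train/test splits (default 90 iterations) with the DAPC
engine and averages row-normalised confusion matrices; a split missing a
population is resampled (logged), and a population absent from a test split
contributes its identity row.

## Evaluation

Assignment rate = assigned / total; agreement rate = (consensus equals
traditional label) / assigned, with the full-cohort denominator also
reported; per-label rates use each traditional label's individuals as
denominator (recorded in the report metadata, since conventions vary).
A replicate pair counts as concordant iff both members have equal consensus
labels; a doubly-UNASSIGNED pair counts only when explicitly enabled
(default strict). Human-readable percentages round half-up to one decimal;
machine output is unrounded.

## Problem sizes and determinism

All defaults are desk-scale: the bundled study scenario uses 118 panel
loci, 103 baseline and 240+28 assessment individuals; the acceptance script
uses 200 simulation replicates per drift target, 90 cross-validation
iterations, and 80 admixture fits, completing in seconds to minutes. Every
stochastic step takes a seed; derived seeds come from `SeedSequence` spawns
(kept below 2³¹), and identical configuration plus seed reproduces outputs
bit-for-bit.

## Known limitations

Genotype-likelihood-aware estimation for low-coverage data is out of scope;
the admixture analogue cannot reproduce posterior model-likelihood values;
cluster-number selection by the likelihood-plateau criterion is
intrinsically noisy (see above) and should be read alongside the BIC curve
and ΔK; the Bayesian engine assumes loci are independent given ancestry
(panel LD pruning mitigates this); and simulated cohorts carry no intra-
chromosomal LD beyond planted correlations.
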