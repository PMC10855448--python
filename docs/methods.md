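# Methods

## Data model

A dataset is a rectangular Ct matrix (samples × genes) with per-sample
metadata: a donor label and a tissue-source group (e.g. BMSC, ASC, hAMSC).
Ct is treated throughout as log2 expression with amplification efficiency
fixed at 2 (100 %): one cycle = one doubling, and geNorm's "relative
quantity" transform 2^(Ctmin−Ct) is implemented implicitly through Ct
differences, which is also the convention of Ct-based web tools.  Ct values
must be non-negative and below a configurable ceiling (default 40 cycles,
warning above 35 — ordinary qPCR practice; the bundled study values are all
≤ 21, so the defaults never trigger on them).  Missing cells are allowed at
I/O level and counted, but any stability computation touching one fails
loudly; nothing is imputed.  Analysis conditions are by-group slices of one
matrix; slicing preserves gene order and sample order.

## Stability statistics

All four statistics are "lower = more stable".

**Comparative ΔCt.**  For gene j: the mean over partner genes k of the
sample SD of (Ct_j − Ct_k), SDs with divisor n−1.  Pairwise differences
cancel any per-sample global offset (loading/efficiency), so the statistic
is invariant to such offsets.

**geNorm.**  The full-panel M-value of gene j is identical to the ΔCt
statistic (the algebraic identity SD(Ct_j − Ct_k) = SD of the log2
expression ratio is exact and is asserted to 1e-12 in the tests).  geNorm
additionally excludes the worst gene (highest M) iteratively, recomputing M
each round, until two genes remain — the best pair.  Exact ties on the
maximal M remove the later gene in input order (deterministic, logged).
The table reports both full-panel M values and the stepwise M at each
gene's exclusion (the value conventionally printed, shared by the final
pair).  Genes with full-panel M ≥ 1.5 are flagged by the conventional
instability threshold.

*Limitation (deliberate):* stepwise exclusion is a greedy procedure.  It is
not a global optimizer: the pair it retains does not always minimize the
pairwise variation over all gene pairs.  On iid-random 5-gene × 12-sample
matrices the greedy pair differs from the exhaustive minimum in roughly 10 %
of draws (a concrete counterexample lives in the test suite), and the
disagreement persists on study-like correlated panels.  The greedy procedure
is retained because it *is* geNorm; the exhaustive pair is easy to obtain
separately if wanted.

**BestKeeper.**  Per-gene SD of raw Ct about the arithmetic mean with
divisor n, plus the CV (%) and the Pearson correlation of each gene against
the BestKeeper index, the per-sample geometric mean of all candidate Cts.
The ranking key is the SD alone; the correlation is descriptive (its role in
published rankings is unclear, so it is reported but never ranked on).  The
original 2004 descriptor is a mean absolute deviation; the divisor-n SD used
here follows the convention of the Ct-based re-implementations this package
mirrors, and the divisor is a keyword for callers who want n−1.  Because raw
Cts are used, BestKeeper is *not* invariant to per-sample offsets — the
designed contrast with geNorm/ΔCt, asserted on generated data.

**NormFinder.**  The Andersen et al. (2004) variance decomposition.  With
k genes, per-sample residuals z_ig = Ct_ig − mean_g(Ct_ig) remove the sample
loading.  Per group: residual variances s²_ig (divisor n−1) are
bias-corrected for the centering leak, σ̂²_ig = k/(k−2) · (s²_ig − S_g/k²)
with S_g = k/(k−1) · Σ_i s²_ig, clipped at zero; inter-group differences
d_ig (gene's group mean of z minus its grand mean over groups) are shrunk by
their sampling variance, d̃_ig = d_ig · γ̂²/(γ̂² + σ̂²_ig/n_g), where
γ̂² = max(0, Σ d²_ig/((G−1)(k−1)) − mean(σ̂²_ig/n_g)).  Stability is
ρ_i = mean over groups of (|d̃_ig| + SE(d̃_ig)).  Single-group slices use the
ungrouped reduction ρ_i = σ̂_i.  Dispatch: single-source conditions run
ungrouped, multi-source conditions grouped with group = tissue source.  With
k = 2 the bias correction is undefined; the uncorrected s² is used and a
warning issued (a warning is also issued below 3 genes, where the method is
not recommended).  Note a structural property the tests document: a strongly
group-shifted gene leaks −shift/k into every other gene's d via the sample
mean, so the *relative* ordering of the remaining near-stable genes becomes
noise-dominated at small n.  Exact numeric agreement with published
NormFinder columns is not claimed (web re-implementations differ from the
original applets); the consensus step is exact.

## Consensus ranking

Within each method, genes are ranked 1..n by ascending stability; exact
value ties are broken by input order and recorded.  geNorm's best pair both
receive rank 1 and the next gene rank 3 (rank 2 skipped), the remaining
genes following in reverse exclusion order — the only convention under which
published consensus values of the form (2,1,1,1) → 1.19 reproduce.  The
consensus score is the geometric mean of the four ranks, reported rounded
half-even to 2 decimals; final order is ascending, ties by input order.  The
consensus is invariant to the order the methods are supplied in and bounded
by the min and max rank.

`consensus_from_reported_values` rebuilds the consensus from a printed
method-value table alone (gene, value) lists per method, with the geNorm
entry starting at the joint best pair.  One published row (the BMSC/hAMSC
block) hides a higher-precision BestKeeper tie — the printed 2-decimal
values imply a different rank order than the printed row order — and is
therefore excluded from the golden expectations rather than guessed.

## Normalizer impact

Relative expression: q = 2^−(Ct_target − Ct_normalizer) per sample.  Ratio
matrices put the *column* sample over the *row* sample (r_ab = q_a/q_b),
flagged `up` above 2, `down` below 0.5; antisymmetry r_ab·r_ba = 1 holds by
construction.  The artifact (apparent-modulation) matrix is the cell-wise
quotient of worst-normalizer ratios over best-normalizer ratios; cells
outside [0.5, 2] are flagged — the normalizer choice alone moved the
apparent ratio more than two-fold.  A ±c-cycle group shift on the normalizer
produces exactly 2^c-fold modulation in cross-group cells, which the tests
exploit on noiseless data.  "Best" and "worst" default to the consensus
ranking's first and last gene for the condition, overridable by name.

Group comparisons run on the linear q scale: per-group means, fold change of
means (reported ≥ 1), a Shapiro–Wilk normality gate at α = 0.01, then an
unpaired t-test (two groups) or a one-way repeated-measures ANOVA with
Tukey's post-hoc test (three groups).  The repeated-measures pairing treats
donor position within group as the repeated factor, mirroring the stated
published procedure; since donors are different people across sources the
design is biologically unpaired, so `paired=False` switches to an ordinary
one-way ANOVA — the default follows the stated procedure and the discrepancy
is documented here.  When the normality gate fails, the parametric test is
still run and the gate result reported (no nonparametric fallback was
specified; q values are log-normal, so the gate fails often for
high-variance targets — a caveat, not an error).  A pair is called
significant only when p < 0.05 *and* fold change > 2.  No multiplicity
correction beyond Tukey is applied.

## Expression overview

PCA: per-gene (column) centering, no scaling, via SVD; percent variance per
component reported to 1 decimal.  A constant matrix yields all-zero scores
and 0 % components.  Clustering: 1 − Pearson correlation distance, average
linkage (scipy), on sample profiles (or gene profiles with `axis="genes"`).
Zero-variance profiles are rejected by name, since their correlation is
undefined.  Leaf ordering places the subtree with the lower merge height
first at every node ("tighter cluster first"); a singleton leaf has height 0
and therefore precedes any true cluster — a convention choice, stated here
because the alternative (clusters before singletons) is equally defensible.

## Synthetic data generator

Ct_ig = base_g + shift_g(group_i) + donor_ig + sample_i + ε_ig, all terms
Gaussian on the Ct scale (log-normal expression noise, the standard qPCR
error structure), drawn from an explicit per-dataset seed; no global RNG
state.  The donor effect is drawn once per (donor, gene) and held constant,
creating donor-specific fingerprints; the sample term is a global per-sample
offset that moves BestKeeper but cancels in geNorm/ΔCt — the knob behind the
invariance tests.  Default design: 3 groups × 4 donors.

The study-calibrated fixture uses the published per-source mean Cts of the
five candidates (ACTB, EF1A, GAPDH, RPLP0, TBP) as base + shift exactly, and
donor_sd = 0.25 / noise_sd = 0.15 cycles so the implied group SEM over four
donors (≈ 0.15) sits mid-range of the published per-group SEMs (0.07–0.33).
Two targets: an ICAM1-like gene dominated by donor variation
(donor_sd = 1.5), and an IL8-like gene with a −9-cycle hAMSC shift
(≈ 512-fold upregulation) plus a −2-cycle ASC shift.  What the generator
does *not* emulate: amplification-efficiency deviations from 2, technical
replicates, missing data patterns, and inter-gene regulatory correlation
beyond the shared sample offset — so passing recovery tests demonstrates
correct statistics under the declared model, not robustness to those
real-data features.

## Problem sizes and statistical power of the recovery tests

Monte-Carlo tests use the study's 12-sample design where the claim is about
that design, and larger single-group designs (40 samples) where the claim is
about estimator correctness, because at n = 12 the pairwise-SD estimates
behind geNorm/ΔCt have standard errors comparable to the M-value gaps
between near-tied candidates: a perfectly stable gene competing against
0.29-cycle-SD candidates is expected to win each method only ~85–95 % of the
time per seed.  The ensemble means, by contrast, recover the generating
parameters tightly (NormFinder's ungrouped values average 0.092/0.188/0.385
against true SDs 0.1/0.2/0.4 over 100 seeds).  Consequently, on the
3×4-design extreme-recovery ensemble (one perfectly stable gene, one
+1.5-cycle-shifted gene, three SEM-calibrated fillers) the consensus
identifies both extremes simultaneously in 189 of 200 seeds (94.5 %): the
shifted gene is essentially always last; the residual misses are the stable
gene edged out of rank 1 by a filler, driven by NormFinder's leakage noise
and pairwise-SD sampling error at n = 12.  This is reported as measured — it
is a property of small-n reference-gene selection worth knowing, not a
defect to calibrate away.

## Pipeline and reproducibility

`run_pipeline` executes stability + consensus for every expressible
condition, the impact analysis on the pooled condition (best/worst from its
consensus), and the group-mean overview, writing CSV/JSON plus a summary
with every tie resolution and warning; identical config + input give
byte-identical JSON.  The CLI (`refstab simulate|stability|rank|impact|
overview|run`) is a thin layer over these functions with exit codes
0/1/2 = ok/user error/internal error.
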