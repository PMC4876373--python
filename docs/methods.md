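# Methods

This note documents the statistical models behind `admixnet`, the choices
made where the design was genuinely open, and what the bundled simulator
does and does not establish about real data.

## Data model

The unit of analysis is an *ancestry component*: a latent population
cluster with an allele-frequency vector over M biallelic markers (the
ADMIXTURE `.P` layout) and an effective total allele count
n_k = 2 Σ_i q_ik derived from the `.Q` proportions.  Effective counts are
generally non-integral and are used as real numbers everywhere; rounding
(half away from zero) happens only at TreeMix export, whose file format
needs integer counts.  Markers are treated as independent throughout —
the assumption under which every statistic here is defined; linked markers
would require block-resampling standard errors, which this package
deliberately does not implement.

## f3 admixture statistics

Per marker, with sampled frequencies p̂_X, p̂_A, p̂_B and target allele
count n_X:

    f3_m = (p̂_X − p̂_A)(p̂_X − p̂_B) − ĥ_X / n_X,
    ĥ_X = n_X p̂_X (1 − p̂_X) / (n_X − 1).

The correction removes the upward bias Var(p̂_X) = p_X(1−p_X)/n_X; the
estimator is exactly unbiased under independent binomial sampling (the
test suite checks this against a Monte-Carlo oracle and, for small counts,
against exact enumeration over the binomial supports).  Because f3_m is a
polynomial in three independent binomial proportions, its variance has an
exact finite closed form built from binomial factorial moments
(E[X(X−1)…(X−r+1)] = n(n−1)…(n−r+1)p^r, valid for real n); `f3_variance`
implements it and the suite verifies it within 2% of a 6×10^5-replicate
Monte-Carlo oracle over a 5×5×5 frequency grid at counts 10/50/200.

**Where the variance is evaluated.**  The variance formula takes
frequencies as inputs, and the choice of *which* frequencies matters
enormously.  Evaluating it at each population's own sampled frequency
makes the per-marker denominator strongly correlated with the numerator;
under a global null this biases every marker z-score negative (simulated
mean combined Z ≈ −4.4 instead of 0), so the test would reject a true
null essentially always.  `f3_test` therefore evaluates the variance at
the count-weighted pooled frequency
p̄ = (n_X p̂_X + n_A p̂_A + n_B p̂_B)/(n_X + n_A + n_B), the maximum
likelihood estimate of the common frequency under the no-differentiation
null — the same device a score test uses.  Simulation shows this restores
the nominal level (≈4.7% rejections at the one-sided 5% level) without
hurting power: truly admixed targets still yield combined z-scores in the
−30…−250 range in the demo conditions.

Marker z-scores are combined with equal (Stouffer) weights,
Z = Σ_m z_m/√M over the M usable markers, and tested one-sided against
the negative tail (p = Φ(Z)), since only negative f3 is evidence of
admixture.  Markers whose pooled frequency is 0 or 1 carry no information
(zero variance) and are dropped and counted.  The exhaustive scan
evaluates every target/parent-pair configuration — K·C(K−1, 2) of them,
2,907 at K = 19 — and applies Bonferroni correction at α/n_configs.

## f4-ratio mixture proportions

For admixed X with parental proxies B (proportion α) and C (proportion
1 − α), sibling A of B, and outgroup O:

    r_m = [(p_A − p_O)(p_X − p_C)] / [(p_A − p_O)(p_B − p_C)]    (full)
        = (p_X − p_C) / (p_B − p_C)                               (simplified)

The two agree at every marker where p_A ≠ p_O; the full form is the
classical f4-ratio and the simplified form drops the common factor.  Each
r_m is a ratio of dependent, asymptotically normal quantities and hence
Cauchy-like with no finite mean or variance, so the pipeline reports the
sample **median** (the Cauchy location) and **IQR** (twice the scale).
`compare_mean_vs_median` quantifies the alternative estimators by
replicate simulation: the per-marker mean's replicate spread does not
shrink as markers are added, while the median's shrinks like 1/√M.

Numerical conventions, fixed because quartile definitions vary: medians
use the midpoint rule for even M; quartiles use linear interpolation;
markers with |denominator| ≤ 1e−12 (frequencies are O(1), so absolute ≈
relative) are dropped and counted, never imputed.  Percentages are kept
at full precision internally; display rounds the B-side to one decimal
and takes the complement after rounding, so printed pairs sum to 100.0
exactly (0.412 → 41.2 / 58.8).

**Known limitation.**  The median of r_m is not exactly α when the
denominator is noisy: correlated noise (p̂_C appears in numerator and
denominator) shifts the median by roughly (1 − 2α)·V/D², with V the
sampling variance of a frequency and D the typical B–C frequency
difference.  At continental-scale proxy divergence (pairwise F_ST ≈ 0.1)
and effective counts of a few hundred alleles the shift is ≲0.015; with
weakly diverged proxies (F_ST ≈ 0.05) it can reach ~0.03 at α = 0.3.
Choose proxies as diverged from each other as the history allows.

## F_ST, split decomposition, Q-residual

Pairwise distances are Hudson-type ratio-of-averages F_ST: per pair,
Σ_m[(p_j − p_k)² − p_j(1−p_j)/(n_j−1) − p_k(1−p_k)/(n_k−1)] over
Σ_m[p_j(1−p_k) + p_k(1−p_j)], clamped to [0, 1]; the corrections are
omitted in frequencies-only mode.  A matrix computed elsewhere (e.g. the
one ADMIXTURE reports) can be supplied instead as a PHYLIP square matrix;
asymmetric inputs are symmetrized by averaging with a warning above 1e−6.

Split decomposition follows Bandelt–Dress: a bipartition A|B is a d-split
iff its isolation index

    α(A|B) = ½ min_{i,i'∈A; j,j'∈B} [max(d_ij + d_i'j', d_ij' + d_i'j,
                                         d_ii' + d_jj') − d_ii' − d_jj']

is positive (pairs may repeat, which handles singleton sides).  The
implementation is incremental — each added taxon extends the current
d-splits both ways plus its own trivial split, which bounds the candidate
set — and is verified set-equal (weights within 1e−9) to brute-force
enumeration of all 2^(K−1) − 1 bipartitions on random metrics up to K = 8.
For additive metrics the weighted splits reconstruct the input distances
exactly (conservation), and the system is written as NEXUS Taxa + Splits
blocks for network viewers.

The Q-residual score is reconstructed from the cited methodology rather
than copied from any program binary: distances are scaled so the mean
off-diagonal entry is 1 (making the score scale-free), each quartet
contributes (s1 − s2)² where s1 ≥ s2 ≥ s3 are its three pairwise-sum
pairings, and the score is the mean over all C(K, 4) quartets.  Additive
metrics score exactly 0 by the four-point condition.  Because the exact
normalization used by other implementations cannot be confirmed, absolute
scores are comparable only within this package; the *ranking* produced by
the leave-one-out procedure is the meaningful output.  Leave-one-out
re-normalizes each (K−1)-taxon submatrix before scoring (the score is
defined on the analyzed taxon set), ranks ascending — the lowest score
marks the ancestry contributing most to non-tree-likeness — and breaks
ties lexicographically (scores ≤ 1e−12 are treated as exact zeros for
ranking so that additive inputs tie cleanly).

## Synthetic demography

The simulator exists to give every stage a ground truth.  Frequencies
evolve on a rooted tree whose branch lengths are drift parameters
c ∈ [0, 1): the child frequency is Balding–Nichols,
Beta(p(1−c)/c, (1−p)(1−c)/c), with mean p and variance c·p(1−p), so c
plays the role of per-branch F_ST.  Any mean-preserving law would do; the
drift step is isolated in one function if another law is wanted.  Root
frequencies are Uniform(0.05, 0.95) by default, keeping ratio denominators
away from boundary degeneracies; fixed frequencies (0 or 1) stay fixed.
Admixture events create a *new* leaf as α·p_a + (1−α)·p_b plus optional
post-admixture drift, leaving the ground-truth parents observable.
Finite-sample noise is added separately by binomial resampling at the
effective allele counts.  A single integer seed drives one generator
stream, so all outputs are bit-reproducible.

The bundled fixture has eight tree ancestries (an outgroup, an African
clade, a West-Eurasian clade; per-branch drift 0.012–0.08) plus one
admixed leaf with α = 0.412 and post-drift 0.005 — an East-African-style
admixture between a Nilo-Saharan-like and an Arabian-like source.
Default study conditions elsewhere: effective counts of 200 alleles per
ancestry (≈100 diploids, the order of per-ancestry effective sample sizes
that ADMIXTURE runs on a few thousand individuals yield), 20,000 markers
for recovery experiments (enough that the median's sampling error is well
below the ±0.03 recovery tolerance while keeping the suite fast; the
statistics are per-marker, so nothing but precision changes at higher M),
and recovery demographies with proxy divergence ≈0.12 — the
continental-scale regime the method is used in (see the limitation above).

What the simulator does *not* emulate: linkage disequilibrium between
markers (real markers are correlated; combined z-scores on real data are
therefore anti-conservative unless markers are thinned), ascertainment
bias of genotyping arrays, estimation error in the ancestry decomposition
itself (ADMIXTURE's P and Q are treated as data), and multi-way or
continuous gene flow.  Passing tests show the statistics behave as derived
under their own assumptions — not that those assumptions hold for any
particular data set.

## Numerical and interface choices

- Ancestry labels: ADMIXTURE emits none, so readers require a sidecar
  label list or auto-name columns Anc1…AncK; supplying labels explicitly
  is strongly recommended to avoid silent column misassignment.
- TreeMix export rounds each of the two allele counts independently (half
  away from zero), so a line's total can differ from round(n_k) by one.
- TreeMix output trees are tallied on topology only; bracketed
  migration-edge annotations are stripped before parsing, since subtree
  frequencies, not edges, are what gets tallied.
- Split weights below 1e−10 are treated as zero (numerical guard for the
  isolation-index minimum).
- Significance flags, drop counts and marker totals are reported in every
  result object and logged by the CLI at stage granularity, so silently
  dropped markers are auditable.
- Reports are tab-separated with `#` header comments; display rounding
  (one decimal for percentages) lives in the reporting layer only.
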