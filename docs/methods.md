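# Methods

## Effect sizes

All pairwise evidence starts from partial correlations.  The default is
full order: from the gene–gene correlation matrix R, the precision matrix
Ω = R⁻¹ gives r_ij·rest = −ω_ij/√(ω_ii ω_jj), the correlation of genes i
and j after regressing both on every other gene (the two are equal — the
test suite checks the residual-regression identity to 1e-8).  A
first-order variant conditions each pair on its single strongest
confounder k (the gene maximising |r_ik·r_jk|), for data whose sample
count cannot support conditioning on all genes.  When the correlation
matrix's condition number exceeds 1e8, a ridge (1−λ)R + λI with λ = 0.05
is applied before inversion; with shrinkage disabled the same situation is
an error, never a silent repair.

Significance tests carry the conditioning count g in their degrees of
freedom: the t-test uses t = r√((n−2−g)/(1−r²)) with df = n−2−g, the
z-test arctanh(r)·√(n−3−g).  For a marginal correlation (g = 0) these
reduce to the textbook forms.  |r| = 1 returns p = 0 with a degenerate
flag rather than raising, so pipelines on constructed data keep running.

## Combining across datasets

**FTCCT.**  Each dataset's r_k is mapped to z_k = arctanh(r_k), with
sampling variance 1/(N_k−3−g).  Using 1/(N_k−3) — correct only for
marginal correlations — would understate the variance of full-order
partials and inflate the type-I error (about 0.077 instead of 0.05 at
n = 100, g = 18).  Between-dataset variance τ² is the DerSimonian–Laird
moment estimate from Cochran's Q, truncated at zero; random-effects
weights w_k = 1/(var_k + τ²) give z̄ and its standard error 1/√(Σw), and
r̄ = tanh(z̄).  The default significance test is the z-statistic z̄/se;
a t-test with effective sample size n_eff = 3 + 1/se² is selectable
(`AnalysisConfig.significance_test`), since with a single study the
t-form is the natural test of a correlation with its own n, while for a
combined coefficient the z-form follows directly from the weighting — the
two agree closely whenever Σw is large.  All tests are two-sided: the
sign of a regulatory effect is not known a priori.

Correlations are clipped to |r| ≤ 1 − 1e-15 before arctanh; FICPT's
per-dataset p-values are floored at 1e-300 before the log.  Both bounds
are plain finite-arithmetic guards.

**FICPT.**  Per-dataset two-sided t-test p-values (df = N_k−2−g) are
combined as S = −2Σ ln p_k against χ² with 2Z degrees of freedom — the
standard reference distribution for Fisher's method over Z independent
p-values.  At Z = 1 the χ²₂ survival function recovers the input p-value
exactly, which the tests assert.

**Ranking scores.**  ROC evaluation ranks pairs by a per-method score:
|r̄| for FTCCT, |r| for the relevance network, and S itself for FICPT.
At Z = 24 a strong pair's combined p-value underflows double precision,
which would tie all top pairs at p = 0; S is a monotone transform of the
combined p wherever the latter is representable, so the ranking is the
same where both exist and well-defined everywhere.

**Calibration behaviour.**  FICPT's type-I error is exact under the null
(measured 0.0500 over 11 400 null pairs).  FTCCT's z-test is mildly
conservative at small Z (≈ 0.036 at Z = 5): τ² is truncated at zero, so
estimation noise in Q can only inflate the standard error.  This is a
known property of DerSimonian–Laird random effects, not corrected for.

## Baselines

The relevance network scores each pair by |partial correlation| with the
per-pair t-test.  CLR standardises each MI value against its row's
off-diagonal background (negatives clipped at zero) and combines the two
directions as √(z_ij² + z_ji²); a constant row contributes z = 0.  ARACNe
applies the data-processing inequality to every gene triple, removing
(i,j) when MI_ij < min(MI_ik, MI_jk)·(1−ε), with ε = 0 (strict) by
default.  MRNET selects regulators per target greedily by relevance minus
mean redundancy with the already-selected set, stopping at a non-positive
score; the undirected score is the larger of the two directions.  These
are re-implementations following the published algorithm descriptions
with their most common default settings; numerical parity with the
original binaries is not claimed.  Mutual information defaults to the
bivariate-normal closed form MI = −½ ln(1−r²); an equal-width-bin plug-in
estimator is available.

Copula concatenation replaces each gene's profile within each dataset by
rank/(N_k+1) (average ranks for ties) and concatenates columns, giving a
pooled dataset of ΣN_k samples on a common (0,1) scale.

## Synthetic data

The generator emulates a SynTReN-style transcriptional simulator:
exact parity with that tool is not claimed, only its documented
characteristics.

*Topology.*  Preferential attachment over genes in a fixed order —
each new gene takes one parent drawn proportionally to degree+1, then the
remaining edge budget adds extra parents with the same bias — yields a
scale-free directed acyclic graph with exactly the requested gene and
edge counts (default 15 and 17).  Edges activate with probability 0.7,
otherwise repress.  The DAG restriction keeps the steady state
closed-form; cyclic feedback is out of scope.

*Expression.*  Root genes draw Uniform(0.1, 1).  A regulated gene
multiplies Hill activations h(x) = x²/(0.5² + x²) of its activators and
complements 1−h(x) of its repressors, receives additive Gaussian
biological noise σ_bio (clipped at zero), and every measurement is
finally multiplied by exp(N(0, σ_tech)) technical noise.  Samples are
independent steady-state draws.  Within an ensemble, dataset k scales
both noise levels by independent Uniform(1−η, 1+η) factors, emulating
studies of varying quality.

*Noise defaults as calibration constants.*  σ_bio = 0.15, σ_tech = 1.0,
η = 0.3 were fixed once so that the single-dataset relevance network
reaches a median AUC near 0.73 on the default topology at n = 1000 — the
anchor the benchmark levels are defined against — and live in
`SimulationDefaults`, not in the algorithm code.  Two regimes are worth
knowing about when changing them: biological noise propagates from parent
to child (the parent's noisy value is what the child responds to), so it
adds shared signal and *raises* detectability, while multiplicative
log-normal technical noise corrupts measurements after the fact, breaks
the conditioning that blocks indirect paths, and is what makes the
problem hard.  Large η lets near-noise-free datasets dominate the
z-average and inflates the combined AUC.

*What the generator does not emulate.*  Real microarray compendia differ
by platform, normalisation pipeline and population, not only by noise
level; expression is not at steady state; regulatory kinetics vary per
edge.  Passing benchmarks here shows the combiners behave correctly under
heterogeneous independent noise with a known nonlinear truth — not that
the same AUC levels will be reached on any real cohort.

*Determinism.*  All randomness flows from one master seed through numpy
`SeedSequence` spawning into PCG64 generators; an ensemble is bit-for-bit
reproducible from one integer, and the CLI manifest records it.

## Evaluation

Correlation-style inferrers are undirected, so AUC, tIDR/tIRR, motif
TPR/TNR and edge TPR are computed against the undirected skeleton of the
directed truth; motif *typing* (chain, collider, fork, feed-forward
triangle over gene triples) uses the directions.  AUC ties receive the
average rank.  tIDR = |T ∩ M \ ∪I_k|/|T| and tIRR = |T ∩ ∪I_k \ M|/|T|
share the denominator |T| (true skeleton edges), making the two rates
directly comparable and their sum at most 1; M and I_k are the pair sets
with p below the hard threshold α = 1e-12.

Motif reconstruction rates for types with two true pairs and one absent
pair (chain, collider, fork) average (TPR + TNR)/2 per motif per ensemble
member, so an empty inference scores exactly 0.5; the triangle has no
absent pair and scores its recovered fraction, and a type absent from the
truth reports rate 0 by convention.  Edge colours bin the mean recovery
rate of each true edge over the ensemble: red [0, 0.25], green
(0.25, 0.5], blue (0.5, 0.75], black (0.75, 1] — a rate of exactly 0.75
is blue.  Leaf edges point into terminal genes with exactly one parent;
in-hub edges point into genes with more than two parents (in-degree ≥ 3,
reading "more than two" literally).

CAT curves compare ranked gene lists around a master gene (ascending
p-value; ties by descending |effect|, then gene id).  Meta mode reports
|top_n(a) ∩ top_n(b)|/n; individual mode averages each list's top-n
overlap with a reference list.  Lists shorter than n_max truncate the
curve with a warning rather than failing.  Method-vs-method AUC samples
are compared with the two-sided Wilcoxon rank-sum test.

## Benchmark problem sizes

The shipped benchmark protocol uses 20 replicate default ensembles
(20 × 24 × 1000-sample datasets); the null-calibration check uses twelve
5-dataset ensembles of 20 independent genes at n = 100 (2280 pairs).
Both complete in seconds on one CPU because every per-dataset step is a
15×15 or 20×20 matrix operation.

## Known limitations

Fit scores s_k attached to inferred networks are carried but unused by
the combiners.  The Bayesian-network baseline is deliberately absent: its
posterior scores are not p-values, and converting them for threshold-based
comparisons would bias the discovery-rate benchmarks.  Cyclic networks,
time-course simulation, kernel MI estimators and raw microarray formats
(CEL/SOFT) are out of scope.  The conditioning order actually appropriate
for small-n real cohorts is dataset-dependent; both full and first order
are exposed on `AnalysisConfig`.
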