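# Methods

## Problem setting

Spontaneous reporting systems (SRS) such as FAERS collect case reports,
each listing the drugs a patient took and the adverse drug events (ADEs)
observed. Screening for drug–drug-interaction (DDI) ADE signals means
asking, for every (drug1, drug2, ADE) combination, whether reports
mentioning both drugs carry the ADE more often than the two drugs'
separate effects predict. Two obstacles dominate: confounding by the
thousands of comedications that travel with any given pair, and the
false-positive burden of screening hundreds of thousands of
combinations. `ddimix` implements a detector that addresses both — a
propensity-score-adjusted expected frequency feeding an empirical-Bayes
three-component mixture with a local-FDR readout (PS-3CMM) — plus the
Ω shrinkage measure and the proportional reporting ratio (PRR) as
comparators, and a labeled simulation benchmark.

## Data model

For one combination, reports cross-classify into a 2×2×2 table with
cells a..h (exposure to drug1 × exposure to drug2 × ADE) and reporting
rates r00 = a/(a+b), r10 = c/(c+d), r01 = e/(e+f), r11 = g/(g+h). The
observed frequency is N = g; every statistic below is a comparison of N
to some expected frequency E computed under "no interaction". Rates with
zero denominators are NaN, never zero; downstream statistics either
raise a typed error or propagate NaN so a skipped combination is visible
rather than silently mis-scored. Drug pairs are unordered and
canonicalized lexicographically; pairs enter the analysis when their
co-occurrence count exceeds `min_pair_freq` (default 50, strict
inequality).

## Ω shrinkage (comparator)

The additive-odds baseline sets O_xy = r_xy/(1−r_xy), floors the
single-drug odds at the background odds (a drug may not look protective
relative to background), and predicts
E = (1 − 1/(O10 + O01 − O00 + 1))·(g+h). With a Gamma(α, α) prior on the
relative risk λ and N ~ Poisson(λE), the posterior is
Gamma(N+α, rate E+α), giving Ω = log2((N+α)/(E+α)) and Ω025 = log2 of
the exact 2.5% posterior quantile (no normal approximation). α defaults
to 0.5; Ω025 > 0 flags a signal, and Ω025 is the ranking score.

## PRR (reference)

The pair is treated as a "new drug": PRR_D1D2 = [g/(g+h)] /
[(a+c+e)/(a+b+c+d+e+f)], with the analogous single-drug ratios and
log-normal 95% CI lower bounds (z = 1.96). The signal rule is
PRR025_D1D2 > max(PRR025_D1, PRR025_D2). Zero cells raise an error
naming the degenerate term; an optional continuity flag adds 0.5 to
every cell but is off by default because the uncorrected estimator is
the reference definition.

## PS-adjusted expected frequency

Per combination, a logistic outcome model is fit by maximum likelihood:

    logit P(ADE) = β0 + β1·D1 + β2·D2 + β3·D1·D2 + β4·PS1 + β5·PS2,

where PS1, PS2 are each drug's propensity score. Dropping the
interaction term gives the no-DDI prediction, summed over the g+h
doubly exposed reports at their own propensity scores:

    E = Σ_i invlogit(β̂0 + β̂1 + β̂2 + β̂4·PS1_i + β̂5·PS2_i).

Without PS terms this collapses to the multiplicative-odds baseline
E = invlogit(β̂0+β̂1+β̂2)·(g+h).

On report-level data the propensity scores come from covariance PCA of
the binary comedication matrix (column-centered, unscaled — rare drugs
genuinely carry less variance and unit scaling would inflate them; sign
fixed by making each loading's largest-magnitude entry positive),
retaining the minimal K components reaching the explained-variance
threshold (default 0.70), followed by a logistic regression of exposure
on the PC scores. Each focal drug's own indicator column is removed
before computing its basis, since a drug trivially predicts its own
exposure. In simulation mode the generating PS values are used directly
— the study design simulates propensity scores, not comedication lists.

All logistic fits share one Newton/IRLS routine: relative
log-likelihood tolerance 1e-8, at most 100 iterations, step-halving,
intercept warm start, and an optional small ridge (off by default) as a
quasi-separation guard. Rank-deficient designs and single-class
outcomes raise a typed error; in the pipeline the combination is
flagged and skipped, never imputed. The fitter was verified against
statsmodels to 1e-6 on shared designs and exists chiefly because the
benchmark performs thousands of fits at n = 100 000, where per-fit
overhead dominates wall time.

## Three-component mixture and adjusted FDR

Across combinations the relative risk λ is modelled as

    λ ~ P1·I(λ=0) + P2·Gamma(α2, α2) + P3·Gamma(α3, β3),

with α2 = β2 (background mean exactly 1), α3 > β3 (signal mean above
1), and N | λ ~ Poisson(λE). Each gamma component marginalizes to a
negative binomial F(k; α, β, E). Because the bulk of combinations have
N = 0, fitting uses the zero-truncated conditional likelihood over
combinations with N > 0; its free parameters are (α2, α3, β3, ρ) with
ρ = P3/P2. The local ("adjusted") FDR of a combination is the posterior
probability of the background component,
F(k;α2,α2,E) / (F(k;α2,α2,E) + ρ·F(k;α3,β3,E)), computed with the
PS-adjusted E. The zero-inflated full likelihood (extra mass p1 at
λ = 0) is also implemented; the conditional model is the default
because it avoids carrying the enormous N = 0 stratum and leaves the
local FDR unchanged.

Numerical choices: all pmf evaluation is in log space via log-gamma
functions, with the β-dependent terms written as −α·log1p(E/β) so that
large shape/rate pairs cancel without catastrophic rounding (naively,
α·[log β − log(E+β)] at α ~ 1e300 amplifies rounding error by ~1e290
and can fabricate positive log-likelihoods); P(N>0) uses expm1.
Optimization runs in log-parameters (log α2, log β3, log(α3−β3),
log ρ), which makes the constraints α2 > 0, α3 > β3 > 0, ρ > 0 hold by
construction, inside a generous box (shapes/rates in [1e-5, 1e5], ρ in
[1e-8, 1e4]) that exists purely to keep L-BFGS-B out of the
numerically meaningless corners. Five deterministic starts (one
moment-based: α2 from the dispersion of N/E near 1, ρ from the
fraction with N/E > 2, the signal gamma from the moments of that
fraction; four fixed) and the best likelihood wins, making the fit
deterministic and permutation-invariant. Combinations with N = 0 are
excluded from the fit and assigned FDR 1 for ranking — without a
single report the posterior cannot favour the signal component — and
combinations whose outcome fit failed keep FDR NaN and rank jointly
worst.

One property worth recording: the local FDR is strictly decreasing in
k only when the components are ordered in likelihood ratio (e.g.
α3 ≥ α2). When the fitted signal shape is small (α3 < 1, as in sparse
real-data fits), the heavy-tailed signal component also explains very
small counts, so the FDR can rise over the first few counts before
decreasing — this is correct posterior behaviour, not a defect, and the
tests assert monotonicity only where the mathematics implies it.

Identifiability: at a few thousand combinations the conditional
likelihood has a pronounced ridge trading ρ against the signal-gamma
shape; single-fit estimates of α3 and ρ scatter widely (tens of
percent) even though the fitted likelihood exceeds the generating
parameters' likelihood, while α2 is tightly determined. The recovery
test therefore checks that the *median* estimate across 20 simulated
datasets lands within 15% of each generating value — the criterion an
asymptotically unbiased MLE can meet at that sample size — and the
FDR values implied by ridge-equivalent parameter sets agree far more
tightly than the parameters themselves.

## Simulation design

Each simulated pair is an independent cohort. Per report:
PS1, PS2 ~ Beta(1, 6) i.i.d. (mean exposure 1/7 ≈ 0.143, mimicking
moderately common drugs); D1 ~ Bernoulli(PS1), D2 ~ Bernoulli(PS2);
Y from the logistic outcome model above with the generating βs. True
signals draw β3 ~ U[0.1, 1], negative controls β3 ~ U[−1, −0.1];
β0 ~ U[−6, −5] throughout (baseline ADE rate 0.25–0.67%, the rarity
regime of real SRS outcomes). Situation (a) draws β1, β2 ~ U[−0.8, 0.8]
with no confounding (β4 = β5 = 0); situation (b) makes every true
signal NPIRR (β1 ~ U[0.1, 2], β2 ~ U[−2, 0.1]); situation (c) adds
confounding through the propensity scores (signals β4, β5 ~ U[−2, 1],
negatives U[−1, 1]). The β2 upper end of 0.1 in situation (b) is used
as specified by the design even though it admits a marginally positive
effect. PS1 and PS2 are independent per report (the minimal assumption;
a Gaussian-copula correlation hook is available but defaults to 0).

Per-pair random streams come from `SeedSequence(seed, spawn_key=(i,))`,
so pair i is bit-identical regardless of the total pair count and
studies are prefix-stable and parallelizable.

What the generator does *not* emulate: report duplication, missing
demographics, drug-name noise, correlated comedication structure, or
reporting biases of real SRS data. Passing benchmarks therefore show
that the detectors behave as designed under the stated generative
model, not that real-data performance is guaranteed.

## Benchmark and problem sizes

The benchmark chain is simulate → per-pair scoring (Ω025; outcome-model
fit with true PS → adjusted E) → pooled conditional mixture fit →
adjusted FDR → AUC against the labels, with AUC computed as the midrank
Mann-Whitney statistic (ties at 1/2; missing scores jointly worst). The
full-scale design is 10 000 signals + 10 000 negatives at 100 000
reports per pair; the package's desk scale — used by the test suite and
`scripts/acceptance.py` — keeps the full 100 000 reports per pair (so
per-pair sampling noise matches the full design) and reduces the study
to 1000 signals + 1000 negatives, which runs in a few minutes per
situation on one CPU and estimates AUC with a standard error of about
0.01.

## Known limitations

- Real-data ingestion is a generic report-table reader; FAERS quarterly
  files, drug-name normalization and MedDRA coding are out of scope.
- The conditional mixture fit needs at least 4 combinations with N > 0
  and behaves best with hundreds; tiny studies can land on the ρ–α3
  ridge.
- PS estimation from comedications recomputes a PCA per focal drug
  (own-column exclusion); for very large drug universes this is the
  dominant cost of report-level scoring.
- The PRR reference requires strictly positive cells unless the
  continuity flag is set.
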