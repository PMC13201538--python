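# Methods

This note documents the models, numerical choices and known limitations
of the package, in the order the pipeline runs them.

## Respirometry

A sealed 7.2 L chamber with one fish logs dissolved O2 [mg L⁻¹] and
temperature [°C] each minute; one fish-free chamber per run measures
background (microbial) respiration. Processing: discard the first
30 min (acclimation), fit OLS to O2 over the next 120 min, subtract the
control's slope for the same window, multiply by the net water volume
(chamber minus fish volume at tissue density 1000 kg m⁻³, so 1 g
displaces 1 mL), and convert to J h⁻¹ via 1.429 g O2 per litre of gas
and 20.1 J per mL O2. Records with regression r² < 0.8 are flagged as
failing quality control and excluded from downstream fits.

Order of corrections: the control slope is subtracted **before** the
volume multiplication. Background respiration occurs throughout the
water, so the correction is volumetric; subtracting afterwards would mix
units. The analysis window is anchored to sealing time; longer runs are
truncated, never extended. The chamber temperature entering later models
is the arithmetic mean over the analysis window. Sign convention: raw
slopes keep their sign (depletion negative); whole-organism consumption
is reported positive.

The control window is matched per-run, not per-chamber; a correction
computed over mismatched windows is flagged non-comparable rather than
rejected. Body mass is a required input — no length–mass relation is
imposed on real data (the synthetic generator uses one, below).

## Scaling models

All rates are analysed on the natural-log scale as linear regressions on
ln mass, Arrhenius temperature x = (T − T0)/(k·T·T0) (k = 8.618×10⁻⁵
eV K⁻¹, T0 = 283.15 K) and the source factor. The candidate set is every
subset of {mass, temperature, source} terms and their interactions that
respects marginality (an interaction requires all its lower-order
terms): 19 models for three predictors. Marginality is enforced because
non-hierarchical models make main-effect estimates uninterpretable and
the optimum models of interest are hierarchical.

AICc counts the residual variance as a parameter (q = p + 1 for p
regression coefficients): AICc = −2ℓ + 2q + 2q(q+1)/(n−q−1), with ℓ the
Gaussian log-likelihood at the MLE variance. Selection takes the minimum
AICc; exact ties go to fewer parameters, then lexicographic term order,
so the choice is independent of candidate ordering. Candidates with too
many parameters for the sample (n ≤ q + 1) are dropped from the
comparison. The reference source level is "cold" when present (the
unheated regime is the natural control). Predictions are exp of the
linear predictor with no retransformation correction — conditional
medians under log-normal errors; a smearing correction would change
predicted feeding rates by a common factor and thus shift efficiency
intercepts only.

The source factor's levels are data: the pooled cold/warm analysis and
the three-stream variant run through identical code paths
(`source_mode` in the pipeline config).

## Feeding and efficiency

Feeding rate is F = Nₑ/t over a ~24 h trial with 20 prey offered. Prey
depletion is ignored, exactly as that definition implies, so F
understates the instantaneous rate when most prey are eaten; the
synthetic generator therefore saturates eaten counts at the number
offered, and this bias is inherited knowingly. Zero-eaten trials have no
log rate and are excluded from fitting with a logged count. Per-prey
mean individual mass and caloric content are user configuration — they
are site- and season-specific; the defaults in `RunConfig` (Radix
5 mg at 18 J mg⁻¹ dry, Simulium 1.5 mg at 22 J mg⁻¹) are plausible
placeholders, not measurements, and should be overridden for real data.

Efficiency per fish: y = ω·F_J/I_J with ω the logistic assimilation
efficiency (intercept e^2.266 at T0* = 293.15 K, activation energy
0.164 eV). Both ω and the predicted F are evaluated at the temperature
of that fish's metabolic measurement, tying the whole ratio to one
thermal state. F comes from the AICc-selected feeding model even when
that model omits mass; mass then enters y only through I. The identity
ln y = ln ω + ln F_J − ln I_J holds to machine precision per record and
is tested.

## Differentiation statistics

Weir–Cockerham θ uses the standard per-allele variance components a
(among populations), b (among individuals within populations) and c
(within individuals), summed over alleles within a locus and combined
across loci as a ratio of sums (not a mean of per-locus ratios).
Negative estimates are retained: they are the unbiased estimator's
behaviour near zero differentiation. Loci fixed for the same allele in
both populations of a comparison are excluded and listed. Missing
genotypes are dropped locus-wise, never imputed. Correctness is pinned
by an independent oracle — a nested random-effects ANOVA on the 0/1
allele-indicator array — which must agree to 1e-12 on toy tables.

Jost's D_EST per locus is (H_T − H_S)/(1 − H_S) · r/(r−1) with
Nei–Chesser bias-corrected H_S and H_T (harmonic-mean sample size,
unweighted frequency means). The multi-locus summary applies the same
formula to the across-locus means of H_T and H_S. A harmonic mean of
per-locus D values is undefined when weak differentiation produces
negative estimates — routine at this study's scale — so the averaged-
heterozygosity combination is used and documented as approximate.

Bootstrap intervals resample individuals with replacement within
populations (loci optionally, behind a flag); individual-level
resampling preserves the two-allele linkage within individuals.
Resampling individuals inflates apparent between-population differences,
so the bootstrap distribution of θ sits above the point estimate near
zero; a BC-percentile (z₀) correction degenerates there (the correction
diverges when almost no replicate falls below the estimate). The
interval is therefore the 5%/95% percentile bounds shifted down by the
bootstrap bias (mean of replicates minus the estimate), which behaves
continuously through zero and yields the expected slightly-negative
lower bounds for weakly differentiated pairs.

The exact genic test runs, per locus, a Metropolis chain over
populations × alleles count tables with fixed margins whose stationary
law is the multiple hypergeometric; the p-value is the chain frequency
of tables no more probable than the observed one (a 1e-9 log-tolerance
absorbs float ties), with a standard error from per-batch estimates.
Defaults follow common practice: 10,000 dememorisation steps, 100
batches of 5,000 iterations. Monomorphic loci are skipped and the
Fisher-combination degrees of freedom (2 per usable locus) shrink
accordingly; a zero p-estimate from a finite chain is floored at
1/(total iterations) before taking logs.

## Clustering

Genotypes are encoded as per-allele dosage columns (0/1/2), missing
entries mean-imputed (keeping the PCA defined and matching de-facto
practice for this kind of analysis), centred but not scaled, and
decomposed by SVD. Axis signs are fixed by making each axis's largest-
magnitude loading positive, so results are bit-reproducible.

DAPC is linear discriminant analysis on the leading PCs with
proportional priors; posteriors follow the Gaussian equal-covariance
rule. The retained-PC count is chosen by the a-score (reassignment
success minus its permutation expectation) and/or hold-out
cross-validation accuracy over a grid, keeping the larger optimum; ties
within a criterion go to the smallest count. Cross-validation removes a
random 1/8 of each prior group (at least one member, never leaving a
group untrainable), trains on the rest and scores the held-out fish.

Every accuracy should be read against the proportional-assignment null
Σ(nᵢ/N)². Note that this null describes *random proportional* guessing;
a discriminant classifier trained on no-structure data is not that —
with unequal groups its proportional priors pull predictions toward the
majority class, and its held-out accuracy on null data measurably
exceeds Σ(nᵢ/N)². The package therefore verifies the null analytically
and by direct simulation of proportional assignment, and verifies the
overfitting control through the a-score contrast between structured and
null data.

Blind k-means runs a repeat of random starts per k (restarting any
start that produces an empty cluster), keeps the lowest-WSS partition,
and scores k by BIC = n·ln(WSS/n) + k·ln(n); repeat stability is the
fraction of starts reproducing the best partition exactly. This WSS-BIC
trades off correctly in the regime these data occupy — tens of
individuals against tens of PC dimensions, where splitting noise barely
reduces total WSS. In low-dimensional small-n toys the same formula
over-splits (the sample WSS reduction from splitting a Gaussian blob
exceeds ln n); the k-selection tests therefore run at genotype scale.

## Synthetic data generator

The generator emulates the study conditions end to end: 86 fish (44
cold-origin, 21 + 21 warm-origin), fork lengths uniform on 65–180 mm
with mass from the standard cubic condition relation W[g] = 0.01·L[cm]³,
dealt into runs of 9–10 chambers with cold/warm counts balanced within
one fish, and run temperatures uniform on 4.6–19.7 °C.

Generating models default to the study-scale fits: ln metabolic rate =
−1.098 + 0.7986·ln M + 0.3693·x with Gaussian residual SD back-solved so
the regression r² equals 0.67 given the realised design spread
(sd = √(var(signal)·(1−r²)/r²)). The printed intercept is physically
consistent only with mass in grams (in mg it implies chamber-depleting
oxygen consumption), so the generator applies the coefficients to
ln(mass [g]); slope recovery is unit-invariant. Rates in the upper
residual tail are capped at what the chamber can support (O2 never
driven below 0.5 mg L⁻¹ over the trace) so every trace remains
measurable — a truncation affecting a percent or two of fish. O2 traces
are linear declines (generating rate over net volume, plus a shared
background slope realised alone in the control) with Gaussian
measurement noise.

Feeding trials are binomial thinnings of the 20 offered prey with
capture probability F·t/20 capped at 1, where the mean rate F [ind h⁻¹]
is linear in Arrhenius temperature with a warm offset and a
temperature × warm interaction (per-taxon defaults from the study-scale
fits, read on the natural scale of F — on the log scale those printed
coefficients would imply rates inconsistent with 20 offered prey).
Tests assert recovery of the generating *structure* (interaction signs,
coefficient recovery), not printed values, for feeding.

Genotypes follow the Balding–Nichols model: per locus, 2–10 alleles with
Dirichlet(1) ancestral frequencies; each population draws its
frequencies from Dirichlet(p·(1−F)/F) at target F_ST (default 0.02,
study-like weak divergence); individuals draw two alleles independently.
One locus can be forced monomorphic to exercise the fixed-locus
exclusion path. Default genotype sample sizes are 24/15/8 per stream,
the genotyped subset sizes.

What the generator does *not* emulate: prey depletion dynamics,
non-linear O2 traces (stress, hypoxia responses), genotyping error,
null alleles, linkage, or within-run temperature drift. Passing tests
therefore demonstrate the statistical machinery, not robustness to those
field realities.

All randomness flows from one mandatory seed through numpy's PCG64
(`default_rng`); sub-streams are split with `SeedSequence` so stages are
independently reproducible. Determinism holds across platforms for a
fixed numpy version.

## Scale of the shipped simulations

Tests and examples run scaled-down stochastic settings chosen for desk
use — e.g. 120–500 bootstrap replicates, chains of a few thousand steps,
200 cross-validation repeats, 500-replicate recovery simulations —
while library defaults keep the full-scale values (10,000 bootstrap
replicates; 10,000/100/5,000 chain settings). The full-scale pipeline
run completes in roughly ten minutes on one CPU, most of it in the
bootstrap.

## Known limitations

- Static (closed-chamber) respirometry only; no intermittent-flow
  protocols, and routine field rates are neither basal nor maximal.
- No functional-response (prey-density-dependent) feeding models.
- No mixed-effects or run-level random effects in the scaling models.
- The multi-locus D_EST combination is an approximation (above).
- The exact-test chain is a plain Metropolis sampler; p-values carry
  Monte-Carlo error reported via batch standard errors.
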