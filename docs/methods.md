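# Methods

This note documents the models, numerical choices and limitations of the
`cpet_entropy` pipeline: what each stage computes, which parameters matter,
what the synthetic cohort does and does not emulate, and where design
choices were genuinely open.

## Data model

A breath-by-breath CPET table holds one row per breath: elapsed seconds,
V̇O₂/V̇CO₂ (L/min), V̇E (L/min), HR (bpm), RR (breaths/min), VT (L/breath)
and ergometer work rate (W). Time is stored in seconds everywhere; the
work-rate filter converts to minutes at its use site. Removed or missing
values are kept as NaN gaps rather than dropped rows, because the 30-s-gap
exclusion rule is defined on elapsed time between surviving observations —
dropping rows would silently destroy that information. HR is whatever the
table provides: metabolic carts assign the instantaneous HR to each breath,
which is why repeated HR values are expected and are emulated by the
generator.

## Cleaning

Three rules run in a fixed order, each on the survivors of the previous:

1. **Work-rate ramp filter.** A breath is removed (whole row — a breath is
   one observation event) when WR_t < S·c_t − 1, where
   S = (WR₉₅ − WR₅)/(c₉₅ − c₅) is the slope through the participant's own
   work-rate and time percentiles and c is time in minutes. The printed
   form is typographically ambiguous; the default reads the −1 as a 1 W
   offset after the product, and `eq1_variant="subtract_inside"` selects
   the alternative S·(c_t − 1). Two properties of the default form are
   worth knowing. First, on a proportional ramp WR = α·t the percentile
   slope equals α exactly and nothing is flagged. Second, the rule is a
   line through the *origin*: any recorded unloaded lead-in shifts the
   whole subsequent ramp below the line by more than 1 W and every breath
   gets flagged. The rule therefore presumes exports whose work-rate
   channel ramps from t = 0, and the generator honors that. Degenerate
   percentiles (constant work rate) skip the rule with a warning.
2. **Absolute bounds.** V̇O₂/V̇CO₂ < 0.2 L/min, HR outside 50–230 bpm, RR
   outside 8–75, VT outside 0.1–3.5 L. Inequalities are strict as printed:
   boundary values are kept.
3. **Moving-window rule.** μ_t and σ_t are the mean and *population* SD
   (divisor exactly 15) of the 15-breath window centered on t; b_t is an
   extreme point iff |b_t − μ_t| > 3σ_t. Windows index over surviving
   breaths (ordinal, not wall clock), positions within 7 of either end are
   not evaluated (no partial windows, since the divisor is fixed at 15),
   σ_t = 0 windows flag nothing, and the rule runs a single pass — it is
   deliberately not iterated to a fixed point.

After cleaning, a participant is excluded when any metric has ≥ 30
consecutive seconds without data, counting the spans from test start to
the first observation and from the last observation to the recorded test
duration. The gap is measured *after* cleaning, since cleaning creates the
gaps the rule guards against. Every removal is accounted per rule × metric
and the report satisfies removals + survivors = original present count.

## Stationarity

Ramp protocols make every metric trend upward, violating the constant-mean
assumption SampEn needs. Each signal is first-differenced
(x̃_t = x_t − x_{t−1}), standardized to zero mean and unit sample SD
(divisor n − 1), and screened with the ADF unit-root test: constant-only
regression (differencing has already removed the trend), lag order by AIC
up to ⌊12·(n/100)^0.25⌋, α = 0.05. Signals shorter than 20 return a
conservative p = 1. Differenced-then-constant signals (e.g. noiseless
ramps; detected at relative SD < 1e-10) are flagged non-analyzable.

Verdicts are corrected with Holm–Šidák over the *widest* family — every
(participant × metric × segment) test in one run — which is the most
conservative choice the unspecified family admits. Signals that fail the
corrected check are excluded from entropy analysis rather than analyzed
anyway; stationarity is treated as a precondition, and exclusion is the
conservative action. The step-down form: sort p ascending, adjusted
p₍ᵢ₎ = maxⱼ≤ᵢ [1 − (1 − p₍ⱼ₎)^(m−j+1)] capped at 1, reject the prefix with
adjusted p < α.

## Sample Entropy

SampEn(x, m, r) = −log(A^m(r)/B^m(r)) with Chebyshev template distance and
an inclusive match condition (≤ r). Both template lengths use start
indices 1…N−m (the last (m+1)-template ends exactly at x_N) and share the
normalization Z(N, m) = (N−m)(N−m−1); self-matches are excluded. This
follows the defining summation limits used here and differs from textbook
variants with N−m−1 templates — comparisons with other software should
expect small systematic offsets at short N. r is in SD units of the
already-standardized signal, so no rescaling happens inside the routine.

Two implementations exist: an O(N²) brute-force enumeration (the oracle,
kept deliberately naive) and a production version that builds the pairwise
distance matrix incrementally over the embedding lag. They agree bitwise
on match counts — the production version reorganizes the computation but
performs the identical float comparisons. Zero A-matches yield an
undefined result (+∞ sentinel, `defined=False`); undefined rows are
excluded from the Bayesian stage rather than imputed.

**(m, r) selection.** Per metric, over m ∈ {1, 2, 3} and
r ∈ {0.05, …, 0.50}, the objective is the median across participants of
the delta-method relative error of SampEn — treating the conditional match
probability CP = A/B as a binomial proportion over the B matching
m-template pairs, var(−log CP) ≈ (1 − CP)/(CP·B_count) — plus a penalty
λ·r (λ = 0.2 for V̇O₂/V̇CO₂/V̇E/RR/VT, 0.006 for HR, whose redundant
repeated values need a weaker pull toward small r). Grid points with an
infinite median (mostly-undefined results at small r) or no long-enough
signal are dropped; ties break toward smaller m, then smaller r. This
surrogate is this package's own documented criterion — it is *not* a
reimplementation of any external optimizer, and selected values need not
match any particular study's.

## Segmentation and summaries

The midpoint (total test time / 2) splits each test: breaths strictly
before it are pre-midpoint, breaths at or after it are post-midpoint. Age
groups: males are "older" from 13.0 years, females from 12.0 (boundary
ages fall on the older side — "younger than 13" makes [13, ∞) the older
group). Sensitivity schemes: a female cutoff at 11, and exclusion bands
dropping males aged [12.5, 13.5) and females [11, 12). V̇O₂ peak is the
maximum 20-s rolling mean stepping every 5 s through the final 120 s,
windows half-open [start, start + 20); peak RER uses the same scheme and
only flags (never drops) sub-maximal tests.

## Bayesian comparison

Per group cell, SampEn observations follow a Student-t likelihood
y ~ t(μ, σ, ν) with μ ~ N(2, 1), σ ~ Uniform(0.05, 0.50),
ν ~ LogNormal(1, 1). The heavy-tailed likelihood absorbs outlying entropy
values; the σ support and μ prior reflect the range of SampEn seen in
healthy pediatric cohorts. ν carries no group subscript and is shared
within each fit; the cells of one comparison family are fit *jointly* so
the Δ statistics subtract paired draws from a single posterior.

Sampling uses an affine-invariant ensemble sampler (emcee): 32 walkers,
2000 warm-up steps, then thinning by 24 to retain 4000 draws, diagnosed as
4 chains × 1000 via R̂ and bulk ESS (arviz); the reference fit gives
R̂ ≈ 1.001 and ESS > 1500. A fit with R̂ > 1.05 is flagged unconverged,
never silently accepted. Per-cell seeds derive from the run seed plus a
CRC of the cell key, so reruns are bit-for-bit reproducible.

Δ statistics, each with P(Δ ≥ 0|y) = mean of the indicator over draws
(ties count as ≥, exactly as defined; identical draw vectors give p = 1,
a documented degenerate case):

* midpoint: Δ = μ_post − μ_pre (raw nats);
* age: Δ = (μ_older − μ_younger)/μ_older × 100;
* sex: Δ = (μ_male − μ_female)/μ_female × 100.

p < 0.05 or p > 0.95 declares a credible direction. Cells with fewer than
5 defined SampEn values are reported but not classified. Note that for two
cells whose data actually come from the same distribution, p is
approximately uniform on (0, 1) — it is a direction probability, not a
concentration statistic, and no amount of data drives it to 0.5 under the
null.

## Synthetic cohort

The generator emulates the study design the pipeline targets: four
sex × age cells (default 40/45/40/45), durations uniform on 8–12 min,
per-test breath counts drawn from N(304.6, 68.3) and realized by scaling a
linear 20→50 breaths/min RR profile whose integral sets the breath times.
Each metric is a linear ramp (gas-exchange amplitudes scaled per cell to
mirror the spread of V̇O₂ peak across sexes and ages) plus a damped
accumulation (mean-reversion 0.98) of an innovation process. Because the
differenced signal is then essentially the innovation sequence, complexity
is controlled directly: iid Gaussian innovations give high SampEn
(~2.2 nats at m = 2, r = 0.2), AR(1) innovations progressively less. The
default post-midpoint process for V̇O₂/V̇CO₂/V̇E/HR is AR(1) with
φ = 0.7; RR and VT stay iid in both halves.

Group-wise complexity modifiers are multiplicative on SampEn: a modifier κ
is translated to an effective AR coefficient through an empirically
calibrated SampEn-vs-φ curve (quartic fit at m = 2, r = 0.2, N = 300),
clipped at φ = 0 since iid is this family's complexity ceiling. Defaults:
females ×1.15 on all metrics, younger participants ×1.10 on V̇O₂ and V̇E.
HR repeats the previous breath's value with probability 0.3 pre / 0.5
post, emulating per-breath HR assignment; this injects sex-independent
redundancy that lowers HR SampEn (most strongly post-midpoint) and
partially masks group contrasts in HR — which is why directional tests
lean on the gas-exchange metrics for the sex comparison.

Artifact injection writes its ground truth: out-of-range values per metric
at a configurable per-breath rate, isolated in-range spikes far off the
local moving-window level, ≥ 30-s null gaps, and pedaling lapses (work
rate dropped to 0) for the ramp filter. What the generator does *not*
emulate: gas-exchange kinetics (no V̇O₂ slow component, no plateau),
breath-timing irregularity beyond the smooth RR ramp, measurement drift or
calibration error, or any coupling between metrics. Passing tests
therefore demonstrate that the pipeline recovers known structure from
data with the study's size, trend, artifact and complexity profile — not
that the physiological conclusions transfer to real cohorts.

Noise scales (per-breath innovation SD: V̇O₂/V̇CO₂ 0.018 L/min, V̇E 0.55,
HR 0.8, RR 0.5, VT 0.02) are the implementer's choices — no within-test
variance figures were available to calibrate against — set so that
breath-to-breath variability is visible against the ramp while false
removals by the cleaning rules stay well under 2%.

## Problem sizes and determinism

Default analyses run the full 170-participant design; the numbered
analysis scripts default to 12 per cell as a quick-look size, and the test
suite uses 2–5 per cell for structural checks plus full-size cohorts for
the directional acceptance checks. Every stochastic stage draws from seeds
derived from a single run seed; rerunning any entry point with the same
configuration reproduces its outputs exactly.

## Known limitations

* The percentile-line work-rate filter cannot cope with recorded unloaded
  phases (see above); real exports with warm-up segments need upstream
  trimming.
* SampEn index conventions differ from some published implementations
  (see above); absolute values are comparable only within this pipeline.
* The (m, r) selection surrogate optimizes estimator precision, not any
  physiological criterion; with very short signals it prefers larger r.
* HR complexity contrasts are attenuated by value repetition, by design;
  treat HR results as more conservative than the gas-exchange metrics.
* The ensemble sampler's walkers interact, so the 4-chain diagnostics are
  a pragmatic grouping, not independent restarts; R̂ is interpreted
  accordingly.
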