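# Methods

This note documents the models, estimators and numerical choices behind the
package, in the order data flows through the pipeline.

## Stimulus construction

An oddball sequence is a frozen train of `n` tone pips (default 653) at two
frequencies A and B, 100 ms long with a 300-ms inter-stimulus interval
(400-ms onset-to-onset period, times stored as integer ms).  The deviant
count is `round(p_deviant * n)` with ties rounded half away from zero
(65 deviants for p = 0.1, n = 653).  Deviant positions are drawn by a
stratified-gap scheme: inter-deviant gaps come from a shuffled multiset of
pair-sums spanning the feasible range `[2, 2*floor(n/n_dev) - 2]`
symmetrically around the mean gap, so the distribution of the number of
standards preceding each deviant is as flat as the integer constraints
allow.  Gap 1 is forbidden — no two deviants are adjacent — which keeps
post-deviant position analyses well defined.  The counterbalanced partner
sequence swaps the A/B labels at identical deviant positions, so each
frequency serves as standard and deviant equally often.  Equal-probability
sequences are a seeded shuffle of exactly n/2 A's and n/2 B's.

The light schedule marks every k-th tone (1-based multiples of k; k = 5 by
default, so tone 5 is the first lit tone and `floor(n/5) = 130` tones are
lit).  Each pulse lasts 250 ms starting 100 ms before tone onset; since the
pulse is shorter than the 400-ms period it can never touch two tone
onsets.  Sound level (65 dB SPL) and the 0.39-octave tone separation are
carried as metadata only.

## Synthetic spike trains

The generator emulates a *homogeneous* population of putative excitatory
units: every neuron shares one rate table (heterogeneity is available as a
log-normal per-neuron rate jitter, off by default).  Homogeneity makes the
population mean equal to the per-neuron expectation, so the table directly
fixes what the analyses should recover.  Per tone, the spike count in the
50-ms response window is Poisson with mean `rate x 0.05 s`, spontaneous
counts fill the 50-ms pre-tone window the same way, and spike times are
uniform within their window — the analyses consume only counts, so PSTH
shape realism is deliberately out of scope.  Because the light pulse begins
100 ms before tone onset, the pre-tone window of a lit tone uses the
light-on spontaneous rate.

### Rate tables

The flat tables embed the population effect sizes of optogenetic
suppression.  Writing a and b for the light-on/off rate multipliers of the
standard and deviant conditions and c for the relative change of the SSA
index, the standard/deviant rate ratio x = S/D must satisfy

```
(b - a x)/(b + a x) = (1 + c)(1 - x)/(1 + x)
  =>  a(c-1) x^2 + (b-a)(1+c) x + b(1-c) = 0
```

For the PV table (a = 2.02, b = 1.56, c = -0.41) this is
`0.8282 x^2 + 0.7314 x - 0.6396 = 0`, giving x = 0.542; with the deviant
rate fixed at 10 Hz that yields standard 5.42 -> 10.95 Hz, deviant
10 -> 15.6 Hz, spontaneous 2 -> 5.7 Hz (+185%/+102%/+56%, SSA -41%).  The
SOM table solves `0.3225 x^2 + 0.5075 x - 0.25 = 0` (x = 0.394): standard
3.94 -> 5.08 Hz, deviant unchanged, spontaneous 2 -> 2.92 Hz
(+46%/+29%/0%, SSA -25%).  The control table has identical on/off columns.
Equal-probability rates are not constrained by the same derivation; they
are set between the standard and deviant rates with on/off changes of +41%
(PV) and +17% (SOM), the population changes reported for the equal
stimulus.

### Flat vs dynamic mode

The probability-condition effect sizes and the within-sequence time
courses come from the same recordings, but coupling them in one generator
would contaminate the mean-rate targets, so the generator has two modes.
*Flat* mode has no time-course structure and is used for all mean-rate
recoveries.  *Dynamic* mode multiplies the standard rate by a post-deviant
gain (T1 1.60, T2 1.26, T3 = T4 = 1.00 — the transient release from
adaptation after a deviant) and by an onset-adaptation gain
`1 + (2 - 1) exp(-j / (20/3))` for the j-th standard, so the response
starts at twice its steady state and decays to ~5% residual elevation by
the 20th standard, the time course over which adaptation develops at
sequence onset.

What the generator does *not* emulate: per-neuron effect-size dispersion
(unreported for this paradigm), cross-neuron correlations, burst
structure, and any light effect on tones other than the lit one.  Passing
recovery tests therefore shows estimator correctness under the stated
statistical structure, not robustness to real-data heterogeneity.

## Spike analyses

All windows are half-open `[start, start + len)`; a boundary spike belongs
to the later window.  Putative excitatory units use 50-ms evoked and
spontaneous windows; identified interneurons would use 100 ms via the
`window_ms` arguments.  A "tone response" unit is a (neuron, tone) pair:
the deviant response of tone A comes from the sequence where A is rare.

Inclusion requires (i) light-off deviant-evoked counts above the paired
spontaneous counts (one-sided Wilcoxon signed-rank, p < 0.05), (ii) an
overall rate above 0.02 Hz in each oddball sequence, and (iii) a tuning
test — evoked counts above the pooled out-of-band counts (one-sided
rank-sum).  In synthetic sessions the out-of-band pool is the pre-tone
counts, since out-of-band tones would be generated at the spontaneous
rate.  SSA analyses additionally require criterion (i) for both tones.

Normalization divides every condition of a unit by that unit's reference:
the maximum 5-ms-bin PSTH rate of the light-off deviant response (default)
or its mean rate.  Population percent changes are computed on population
means of normalized rates, `(mean_on - mean_off)/mean_off * 100`, not as
means of per-neuron ratios: the two coincide in expectation for the
homogeneous generator, and the former is stable for low-rate neurons.  The
population SSA index is the mean of per-neuron indices computed from raw
rates, separately for light-on and light-off trials.

Post-event time courses label each standard by its position relative to
the nearest preceding deviant (T1..T4, T-1 for the standard just before a
deviant) or relative to the light pulses.  Standards that follow a lit
standard are excluded from the deviant-position analysis, and tones that
follow a deviant from the light-position analysis, so the two effects do
not contaminate each other.  Rates are pooled over qualifying tones and
neurons, then normalized by the light-off rate at the reference position
(T4, or T3 for the light analysis); neurons with no deviant spikes are
excluded.  Matched subsets use greedy nearest-neighbour pairing with a
caliper (half the larger group SD) followed by trimming of the most
discrepant pairs until subset means and SDs agree within 5% of the pooled
mean absolute statistic; ties in strong/weak tone pooling go to tone A.

Group comparisons follow the experimental decision tree: Student's t-test
when both samples have n >= 30; otherwise each sample is checked for
normality with the Kolmogorov-Smirnov test in its estimated-moments
(Lilliefors) form, and if any sample fails, a rank test is used —
signed-rank when paired, rank-sum otherwise.  Bonferroni correction
multiplies p by the number of comparisons, capped at 1.  Two identical
constant samples short-circuit to p = 1 in the rank branch.

## LFP and CSD

The synthetic laminar session has 32 channels at 25-µm spacing.  Each tone
evokes a separable voltage deflection — a Gaussian bump across depth times
a difference-of-exponentials time course (3-ms rise, 15-ms decay, 5-ms
onset latency) — whose second spatial derivative is a single negative
basin (sink) flanked by sources.  The Gaussian SD is half the configured
band width plus half a channel, which makes the discrete second difference
negative exactly on the configured granular band.  The standard-tone sink
amplitude is the deviant amplitude divided by r = 1.5974, so the granular
CSD SSA index `(r-1)/(r+1)` is 0.23 by construction; additive white
Gaussian noise (default 1.5 µV, ~5% of the 30-µV LFP peak) completes the
session.

CSD is the second-order central finite difference across channels,
`(V[i-1] - 2 V[i] + V[i+1]) / dz^2`; edge channels are dropped rather than
padded (padding would invent data).  Sink localization takes the
trial-averaged deviant CSD, finds the most negative trough within 0-50 ms
("deepest" in the sense of sink strength — layers are assigned both above
and below it), and extends the band while the channel's window-mean CSD
stays below 2 standard errors of the pre-onset baseline (the factor is
configurable; with a noise-free profile the threshold degenerates to
strict negativity).  Layer amplitude is the per-channel RMS over the first
50 ms, averaged across the layer's channels and normalized by the deviant
light-off value.  Because trial averaging leaves more residual noise power
in the rare deviant condition than in the common standard, the windowed
power is debiased by subtracting the baseline-window power before the
square root; without this the recovered CSD SSA index overshoots its
configured value whenever noise is non-negligible.  The CSD SSA index
applies the spiking formula to the amplitudes, pooled over tones by
default (tone-separated indices are available).

## Rate-network models

Both models follow `tau dN/dt = -N + (k - r) S(total input)` with tau =
10 ms, k = 15, r = 1.  `S` clamps its argument between population limits
(E: -1..1.75, PV: -0.5..4, SOM: 0..3) and is linear in between.
Inhibitory rates reach the excitatory population through saturating output
transfers: a logistic `1/(1 + exp(-0.3 (r - 9)))` for PV and `tanh(r/3)`
for SOM.  Thalamic drive is `g(t) r(t)` with
`dg/dt = (g0 - g)/3000 - g r/80` (ms) and `r(t)` a 50-ms gate carrying a
decaying exponential (amplitude 3, 40-ms time constant) from each tone
onset; under a held gate of 3 the conductance settles at the closed-form
fixed point 0.00881.  In a four-tone train (400-ms period, matching the
experimental stimulus; the model literature leaves the model ISI open) the
first response stands in for the deviant and the fourth for the standard.

The pairwise model couples one excitatory and one inhibitory population
with (j_EI, j_IE) = (0.2, -1.0) for the PV variant and (0.05, -0.39) for
SOM; the inhibitory input transfer uses the variant's clamp limits (the
pairwise limits are otherwise unspecified, so the coupled model's
per-population limits are reused and exposed in the parameters).  The
inhibitory term enters as `j_IE * S_inh(I)` — weight applied to the
transformed rate — because the transfers are parameterised in rate units
(theta = 9 against k = 15) and the coupled model's coupling term
`sum_k j_ki S_k(N_k)` uses the same order; the alternative reading
`S_inh(j_IE * I)` would evaluate the logistic deep in its tail for any
plausible activity.  Optogenetic suppression is a unitary negative input
pulse to the inhibitory population, 250 ms starting 100 ms before the
probed tone.  The coupled model adds the E-PV-SOM weight matrix
(E->SOM 0.25, SOM->E -0.25, E->PV 0.4, PV->E -1, SOM->PV -0.1, all others
zero) and pulse amplitudes j_ext,PV = 1.5, j_ext,SOM = 1.

The tone input to SOM is delayed 7 ms in the pairwise model (SOMs lack
direct thalamic input).  In the coupled model this delay is *not* applied
by default: with delayed drive the SOM population is still in the linear
part of its tanh during the deviant's rising phase, so suppressing SOM
boosts the deviant peak as much as the standard — contradicting the
defining dissociation in which the deviant response is untouched.  With
synchronous drive, SOM saturates before the excitatory peak and the
dissociation emerges cleanly (SOM suppression: deviant change ~0, standard
clearly up; PV suppression: both up within a factor of two).  The delay
remains a parameter for users who want the literal variant.

Each run starts from the no-input fixed point obtained by a 2-s numerical
relaxation.  Integration uses explicit Heun (second-order trapezoidal)
stepping at dt = 0.1 ms, with end-of-step inputs evaluated as left limits
so the half-open gate and pulse edges are integrated exactly; plain Euler
leaves ~0.3% step-halving error at the input discontinuities, Heun with
left-limit sampling is below 0.01%.  A blow-up guard aborts if any
activity exceeds 1e6.  Summaries subtract the pre-stimulus baseline and
divide by the light-off first-tone (deviant) peak, which is therefore 1 by
construction; the deviant is probed with light on tone 1 and the standard
with light on tone 4 in separate runs (which tone carried the light in the
original figure is ambiguous; both placements are supported).

## Problem sizes and tolerances

Recovery tests run at study scale — 160 (PV), 114 (SOM) or 148 (dynamic)
neurons, 4 repetitions of the 653-tone pair — and compare recovered
statistics to the table-implied values within 3 Monte-Carlo standard
errors: delta-method SEs over units for percent changes of population
means, Poisson-count SEs for pooled rate ratios.  Statistical error
control is checked against the nominal 5% level with binomial 3-SE bands
(10^4 null simulations for the t branch).  Deterministic contracts (SSA
identities, model normalization, CSD stencils) are asserted exactly or to
float precision.

## Known limitations

* The generator's homogeneous population cannot probe estimator behaviour
  under realistic rate and effect-size heterogeneity.
* Spike times are uniform within windows, so latency- or shape-based
  analyses (beyond the 5-ms-bin peak used for normalization) are not
  meaningful on synthetic data.
* The CSD module implements the standard second-difference estimator only;
  spline-based iCSD variants are out of scope.
* Model parameters are fixed constants of the circuit description, not
  fitted; the dissociation
  results are qualitative circuit demonstrations, not quantitative fits to
  recorded firing rates.
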