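# Methods

## Input model

The unit of raw data is a footfall event: one limb's ground-contact
interval (foot-on, foot-off), in seconds within a source video. A trial is
a cyclic sequence of such events from one individual; trials carry the
video frame rate when known. All analyses depend only on time differences,
so the pipeline is invariant to translating a trial's clock (videos start
at arbitrary times). Limb codes are LH/LF/RH/RF, case-insensitive on read,
canonical uppercase on write. Same-limb contacts must be disjoint;
duplicate foot-on times are rejected as double-digitized rows.

## Stride parameters

Strides are delimited by successive LH foot-on events; the LH contact is
the phase reference (φ_LH = 0). Each other limb is attributed its first
foot-on at or after the stride start and before the next LH contact;
cycles in which some limb has no foot-on (occlusion, non-steady movement)
are excluded and counted, never interpolated. Phase is
((on − t₀) mod T)/T with T the stride duration. A limb's stance for duty
factor purposes is its attributed contact's full on→off span even when the
foot-off falls beyond the stride's end: under steady locomotion this
equals the within-stride stance carried over from the previous cycle, and
it avoids an arbitrary windowing rule. Consequences: DF ∈ (0, 1] for
well-digitized steady data, but a contact longer than the stride reports
DF > 1 rather than being silently truncated.

Trial means average phases on the unit circle (vector mean of angles
2πφ, mapped back to [0, 1)) and every scalar parameter arithmetically.
Circular averaging matters for limbs whose phase straddles the wrap point
— a fore limb near φ ≈ 0.94/0.0 in a trot — where the arithmetic mean is
badly biased; when the two means differ by more than 0.005 the difference
is logged (INFO level). Phases are reported in [0, 1) with no forced
wrap, so a near-trot fore phase reports as ≈0.94–0.99 or ≈0.0 and
downstream comparisons are circular. Note the circular mean of n > 2
values is not identical to the arithmetic mean even far from the wrap
(the difference is O(dispersion²), ~10⁻⁴ for SD 0.05); only the
two-point mean is exactly the arc midpoint.

## Gait classification

The forelimb lag is the circular mean of the two hind→ipsilateral-fore
foot-on offsets, φ_LF − φ_LH and φ_RF − φ_RH. Ideal values: 0.5 trot,
0 pace, 0.25 lateral-sequence singlefoot, 0.75 diagonal-sequence
singlefoot. The eight-pattern scheme bins the lag into circular windows
of width 0.125 centered at k/8 (couplet patterns at the odd eighths); the
four-pattern scheme uses width 0.25 at quarters. Bins are half-open
[center − w/2, center + w/2) with boundary values going to the higher
bin — a deterministic tie-break; the published windows are approximate
anyway. The two schemes are computed independently from the lag: a couplet
bin straddles a four-way boundary, so the four-way label is not a function
of the eight-way label (their centers always agree to within 0.125, which
is the property tested).

Walking vs running is the kinematic definition: DF ≥ 0.5 walking
(inclusive at exactly 0.5), DF < 0.5 running. Strides whose hind lag
(φ_RH) falls outside 0.5 ± 0.125 circularly are flagged asymmetrical;
labels are still emitted with the flag so unusual strides remain visible
rather than suppressed.

## Support timeline and aerial phases

Limb i occupies the circular interval [φᵢ, φᵢ + DFᵢ) mod 1 of the stride.
Breakpoints at every foot-on/off phase partition the cycle into intervals
of constant support set, computed exactly (no sampling); adjacent
intervals with equal support are merged across the wrap seam. Interval
lengths reproduce each limb's DF exactly, which doubles as an internal
consistency check. Zero-support intervals are aerial phases; their total
length is the aerial fraction. The support profile reports stride
fractions by configuration, with two-limb supports subtyped diagonal,
lateral (ipsilateral), fore-pair and hind-pair.

The simplified criterion predicts an aerial phase when the mean DF is
less than the greatest phase gap between two consecutive ipsilateral
footfalls: (1 − φ_LF) for the left pair and (φ_RF − φ_RH) for the right,
both mod 1. This mean-value shortcut and the exact timeline agree on ideal
trots (aerial ⇔ DF < 0.5) but can disagree near the crossover when phases
deviate from the ideal — e.g. at the observed hippo means the left gap is
0.54 but a fore footfall intervenes before the next LH contact, so the
exact computation finds no airborne interval at DF 0.5. Both results are
reported side by side; neither is treated as primary.

## Half-cosine loading model

Vertical force over one stance is idealised as half a cosine cycle,
F(t) = F_peak·sin(πt/T_stance). If a limb supports a fraction s of body
weight averaged over the whole stride, impulse balance gives a
stance-average force of s/DF body weights and a peak of
F_peak = s·(π/2)/DF. The default share for a single forelimb is s = 0.30
(forelimb pair carrying 60% of body weight, the usual anterior bias of
quadrupedal mammals); at DF 0.37 this yields 1.27 body weights. The share
is a parameter, not a constant, because real fore/hind splits vary; an
impulse-conservation test integrates the profile numerically and recovers
the stride impulse to 1e-9. The model ignores impact transients, double
humps and horizontal forces — it is a scaling estimate, not kinetics.

## Trend statistics

Regressions operate on trial means (one point per trial), not pooled
strides, to avoid pseudo-replication from multi-stride trials. The linear
fit is ordinary least squares with the slope's two-sided t-test. The
power fit y = a·xᵇ is nonlinear least squares on the linear scale,
initialised from the log–log OLS fit; the log–log fit is retained as a
cross-check because the two estimators differ under noise (log-scale
fitting down-weights large responses), and R² is always reported on the
linear scale. A degenerate constant response returns slope 0 and R² = 0.

The Wilcoxon matched-pairs signed-rank test ranks |differences| with
average ranks for ties. Zero differences are dropped before ranking by
default (classic treatment; with paired duty factors recorded at 2
decimals and a median difference of ~0.01, exact ties do occur), or
included in the ranking and then discarded (Pratt) as an option. Up to 20
nonzero pairs the exact two-tailed p is computed by tie-aware dynamic
programming over all sign assignments (doubled ranks are integers, so the
full null distribution is built by convolution — equivalent to 2ⁿ
enumeration); beyond that, a normal approximation with continuity
correction and the exact variance Σrᵢ²/4.

The DF histogram uses fixed-width bins tiling [0, 1] (default width 0.05),
with index-based binning and an epsilon so cluster edges such as 0.75 land
in the correct bin despite binary rounding of 0.05. The detected empty
range is the longest run of empty bins strictly between occupied bins —
a descriptive statistic, not a test for multimodality.

## Synthetic generator

`generate_trial` lays strides on an exact grid of duration 1/SF. The
reference limb's footfalls sit on the grid; the other limbs' foot-ons are
placed at (template phase + trial offset + per-stride Gaussian jitter) ×
duration, foot-offs at DF (+ jitter) × duration later. Keeping the
reference limb unjittered is deliberate: phases are measured *relative*
to LH, so a jittered reference would inflate recovered phase SDs by √2
over the nominal jitter SD and make stride durations noisy; with the grid
fixed, zero-jitter trials round-trip exactly (phases, DF, SF to 1e-9) and
jittered trials recover the nominal SD. Jitter is truncated (±0.33
stride) and foot-offs clipped below the next same-limb foot-on so limb
event streams stay valid. A limb whose template phase sits on the stride
wrap (the fore limb at phase ≈ 0 in a trot) occasionally jitters across
the stride boundary; the affected cycle is then excluded by segmentation,
which slightly censors that limb's recovered dispersion — visible in the
study emulation as a few percent of strides lost.

Frame-rate quantization rounds every time to the nearest frame
(1/frame_rate); a collapsed contact is restored to one frame. A 30 Hz
video of a 1 s stride perturbs DF by at most 2 frames/stride (≤ 0.067),
the worst case verified by exhaustive scan.

`generate_study` emulates the survey conditions the analysis targets, and
its defaults are fixed, not tuning knobs: 46 trials of 32 individuals;
trial-mean DF drawn from uniform clusters (0.36, 0.58) with weight 0.41
and (0.75, 0.94) otherwise (the low-cluster weight makes the expected
number of running trials, DF < 0.5, equal 12); SF = −4.14·DF + 3.89 plus
Gaussian noise whose SD (≈0.433) is derived analytically from the mixture
variance so the linear fit recovers R² ≈ 0.763 in expectation, floored at
0.15 Hz; per-trial limb-phase offsets Gaussian around the hippo trot
means (LF −0.04, RH +0.01, RF −0.06 from ideal) with SDs 0.050/0.051/
0.040; per-stride phase and DF jitter SD 0.02; forelimb DFs 0.01 above
hindlimb DFs (the observed median fore−hind difference). Stride counts
per trial are drawn from geometrically decaying weights over 1–8 (ratio
found by bisection) so the expected total is 169 strides — a uniform draw
over 1–8 would give ~207. Stance durations follow DF/SF rather than an
independent stance model, so DF is exactly consistent by construction;
the steep stance-vs-DF power law then *emerges* from the linear SF–DF
link rather than being injected. Event times are exact by default
(`frame_rate=None`); quantization can be layered on.

What the generator does not emulate: asymmetrical (canter/gallop) gaits,
within-trial drift or acceleration, panning/zoom digitization error
structure, observer bias, or correlations between trials of the same
individual. Passing the emulation tests therefore shows the pipeline is
correct and well-behaved under the survey's statistical structure, not
that every property of field video data is captured.

## Numerical choices

- Circular statistics via scipy's circmean/circstd on [0, 1).
- Classification bin boundaries go to the higher bin; walking is
  inclusive at DF = 0.5.
- Support intervals use interval arithmetic with midpoint membership
  tests; equality of adjacent support sets triggers merging.
- Exact signed-rank p-values use integer DP over doubled ranks; the
  normal branch applies a 0.5 continuity correction toward the mean.
- Degenerate inputs: fewer than two reference footfalls → zero strides
  (not an error); empty stride list → error for trial means; constant
  regressor → error; all-zero paired differences → p = 1 with a warning.

## Problem sizes

Tests exercise the pipeline at the survey's own scale (46 trials,
~170 strides), 10,000-stride Monte Carlo runs for jitter recovery, and
1,000 random configurations for the aerial-detection cross-check; the
whole suite runs in a few seconds.

## Known limitations

- No velocity-related parameters (speed, stride length): footfall timings
  alone carry no spatial scale.
- Asymmetrical gaits are flagged but not parameterised (no lead-limb or
  gathered/extended suspension analysis).
- The simplified aerial criterion is reported alongside the exact one;
  near DF ≈ 0.5 they genuinely disagree and users must choose per
  question.
- The loading model is a stride-averaged idealisation; it should not be
  read as measured kinetics.
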