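# Methods

## Forward model

The synthetic generator emulates a frequency-tagging experiment: two gratings
flicker at f1 = 5 Hz and f2 = 7 Hz, shown alone or together (a plaid), with the
plaid presented either monocularly (superimposed, same eye) or dichoptically (one
component per eye).  Trials last 6 s with a 3-s intertrial interval; epochs span
1.5 s before onset to 1.5 s after offset.  Each participant's tagged response is

```
s(t) = Σ_i A_i · g_i(t) · T(t) · sin(2π f_i t + φ_i)
```

with components at f_i, their second harmonics 2·f_i (fraction `harmonic_gain` of
the fundamental) and, in plaid conditions, a sum intermodulation term at
f1 + f2 = 12 Hz (fraction `im_gain` of the participant amplitude).  The divisive
gain is

```
g_i(t) = 1 / (1 + w(t) · m_i),    w(t) = w0 + (w_inf − w0) · (1 − e^(−t/τ))
```

where `m_i` is the competing component's drive (1 in plaids, 0 alone).  The true
suppression in dB is therefore `20·log10(1 + w(t))` — the latent quantity the
pipeline estimates.  A single exponential with one time constant per mask type is
the minimal model for a suppressive weight that strengthens over the first seconds
of stimulation; the asymptote differs between monocular and dichoptic masks
because interocular suppression need not equal within-eye suppression.

`T(t) = 1 + a·e^(−t/τ_T)` is a multiplicative onset transient (default a = 0.5,
τ_T = 0.2 s) applied identically to all components, so it cancels exactly in the
suppression ratio — mirroring how onset transients behave in the ratio of measured
courses.  Broadband noise is Gaussian `1/f^β` (β = 1) with per-sample SD 1 µV
during stimulation and variance multiplied by `iti_noise_multiplier` (default 2)
outside it, emulating movement-related activity between trials.  Artifact trials
(probability `artifact_rate`) are replaced by broadband segments with 10× the
participant's response amplitude.  Participant heterogeneity enters through
response amplitudes drawn from N(4, 1.5²) µV (floored at 0.5 µV) and random
response phases.

What the generator deliberately does **not** model: realistic electrode forward
models and scalp topography (a single virtual occipital channel, optionally
replicated with independent noise, stands in for the electrode montage),
eye-specific optics, saccades/blinks beyond the generic artifact trials, trial-to-
trial phase jitter of the tagged response, and any participant-level variation in
the suppression parameters themselves.  Passing tests on these data therefore
demonstrate the correctness and calibration of the *analysis*, not that real EEG
satisfies the model; in particular between-participant variance here is
measurement noise only, so simulated effect sizes are much larger than empirical
ones.

## Estimator

Amplitude at a tagged frequency is the modulus of the exact-frequency projection
`(2/N)·Σ s[n]·e^(−i2πfn/fs)` over a rectangular 1-s window stepped every 10 ms
(studies below use 20 ms).  Both tagging frequencies are integer Hz, so a 1-s
window holds an exact number of cycles and on-bin estimates are leakage-free; no
taper is used for the same reason.  Windows are centered, and edge windows that
would extend past the epoch are dropped, not padded.  Trials are coherently
averaged (pointwise mean, attenuating non-phase-locked noise by ~1/√K) before the
sliding transform.  A fixed-phase variant multiplies each window by a sine of the
frequency and phase estimated once from the whole trial; for phase-locked signals
it equals the modulus course and provides a cross-check that is linear in the
signal.

Trial QC treats each trial's full-stimulation-period coefficient at each tagged
frequency as a (real, imag) pair and computes Mahalanobis distances with the
plain within-condition sample mean and covariance.  The default excludes a trial
whose distance exceeds 3 at *any* analysed frequency — more sensitive to
single-frequency artifacts than a joint 4-D distance, which is available behind
`joint=True`.  A singular covariance is ridge-regularized with a warning; the
all-identical degenerate case yields zero distances and no exclusions.

The suppression ratio applies an amplitude floor (10⁻³ µV) to numerator and
denominator before `20·log10`, keeping noise-free simulations finite.  dB uses the
amplitude (20·log10) convention throughout, and the ratio is computed as a
difference of logs so that swapping the roles of the two courses negates the
result exactly in floating point.  Pooling across frequencies and mask types is
the arithmetic mean of dB values.  The windowed effect size is a paired Cohen's
*d* of late-window minus early-window participant means (defaults 0–1 s vs
3–4 s); a pooled-SD flavor is available.  The intermodulation index is the
proportional increase of the plaid's 12 Hz amplitude over the mean of the two
alone-condition 12 Hz courses (which contain only noise at 12 Hz).

### Temporal resolution of the estimate

The sliding window reports the *window-averaged* gain, not the instantaneous one.
For a constant gain this does not matter at all — the blur is identical in
numerator and denominator and cancels exactly (verified to ~10⁻¹³ dB by the
blur-cancellation diagnostic, including windows straddling onset).  For a
time-varying weight (τ = 1.5 s) the estimate deviates from the instantaneous
suppression by up to ~0.15 dB in the first second (window blur plus a second-order
effect: a gain-modulated component is no longer perfectly orthogonal to the
competing bin 2 Hz away) and converges below 0.05 dB once the weight settles.
These bounds are asserted by the noise-free ground-truth tests.  Exponential fits
to a whole course are insensitive to this local bias, which is why parameter
recovery is accurate.

## Statistics

The increasing-suppression test forms, at every window center t with both
t ± 0.5 s on the grid, the paired t statistic (df = N−1) across participants of
`ratio_dB(t + lag/2) − ratio_dB(t − lag/2)` with lag 1 s, one-sided for an
increase.  Clusters are maximal runs of temporally adjacent supra-threshold
points (cluster-forming α = 0.05, the field's convention), scored by summed t.
The null flips the sign of each participant's entire difference series at random
— the exchangeable null for a one-sample design with symmetric noise (the group
randomization scheme has no analogue for one sample) — and records the maximum
cluster sum per permutation; a cluster is significant if its sum exceeds the 95th
percentile of 1000 permutations.  Zero-variance differences map to a ±∞ sentinel
that counts as supra-threshold, the documented degenerate-input behavior.
Analysis is restricted to window centers fully inside the stimulation period, so
windows mixing stimulation with intertrial noise never enter the test.

The group comparison uses pointwise pooled-variance two-sample t (two-sided,
df = N−2), the same clustering, and a null that randomizes group membership with
group sizes preserved, scoring maximum |summed t|.  Group splits are by score
median (ties assigned to the low group) or by diagnosis labels verbatim;
participants with missing values are dropped with a warning.

Cubic smoothing-spline fits (scipy `make_smoothing_spline`, GCV-chosen penalty)
are provided for display only; smoothed courses carry a flag and every
statistical entry point rejects them.

## Validation studies and problem sizes

The study drivers (`ssvepdyn.studies`) choose desk-scale sizes: simulations run
at 500 Hz (type-I study: 250 Hz) rather than the generator's 1 kHz default, since
all modelled components sit far below Nyquist either way and every estimate is
sample-rate-invariant; the type-I study uses 20 participants × 8 trials/condition
× 200 datasets with 500 permutations, and the recovery study the full N = 40 with
48 trials/condition over 20 seeds.  Expected behavior: family-wise false-positive
rates near the nominal 5% for both tests; near-certain detection of a 1.5 dB
asymptote with τ = 1.5 s; recovered τ within 30% (a small downward bias is
expected because `20·log10(1 + w(t))` is slightly more saturating than a pure
exponential) and recovered asymptote within 0.2 dB.

## Known limitations

- The trend test's sign-flip null assumes symmetric lagged-difference
  distributions; Gaussian stationary noise satisfies this, strongly skewed real
  artifacts might not.
- Per-frequency QC with the exclude-if-any rule roughly doubles the per-trial
  false-positive rate relative to a single frequency (~2% at threshold 3).
- The estimator's first-second bias (see above) means very fast dynamics
  (τ ≪ window length) cannot be resolved; only the product of blur and dynamics
  is identifiable there.
- Native EEG formats are out of scope; data enter through the epochs container or
  delimited text.
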