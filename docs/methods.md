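# Methods

`cortimuscle` implements a corticomuscular-coupling analysis for
synchronized functional near-infrared spectroscopy (fNIRS) and surface
electromyography (sEMG) recordings, together with a forward simulator that
makes every stage testable by parameter recovery.  This note documents the
models, the defaults and why they were chosen, and what the validation
does and does not demonstrate.

## Recording model and time bookkeeping

A session is one block design (30 s rest, 330 s task, 10 s rest by
default) with two synchronized modalities on a shared clock:

* dual-wavelength (740/850 nm) light intensities at 10 Hz over 63
  channels with 3 cm source–detector separation; eight regions of
  interest (left/right PFC, PMC, SMA, M1) are fixed channel sets
  (30 labelled channels in total);
* raw sEMG at 2000 Hz from eight upper-limb muscles (left/right upper
  trapezius, medial deltoid, biceps brachii, triceps brachii) plus a
  maximal-voluntary-contraction (MVC) trial per muscle.

All windows are given in seconds, converted to sample indices by rounding
half-up, and treated as half-open `[start, end)` so boundary samples are
never double counted.  Cross-modal alignment requires the start-time
offset to be a whole number of 10 Hz samples; fractional offsets are an
error rather than a silent resample, since the synchronization contract
of the acquisition hardware is not observable downstream.

## fNIRS chain

1. **Optical density**: `dOD(t) = −ln(I(t)/Ī)` per channel and
   wavelength, with `Ī` the whole-record mean (robust to initial
   transients).  This makes concentrations below relative to the record
   mean — an arbitrary per-channel constant that every downstream
   statistic (band-passed correlations, coherence, phases, block-average
   differences) is invariant to.
2. **Motion artifacts**: a sample is flagged when the max-minus-min
   excursion within a 0.5 s sliding window exceeds 20× the robust SD
   (1.4826·MAD) of the channel's first differences, or 5 OD absolute;
   flags are dilated by 1 s per side.  The threshold is applied to the
   *first-difference* scale because hemodynamic signals at 10 Hz change
   by only a few percent of their SD per sample: a spike of 10 trace-SDs
   is ~300 first-difference SDs and is caught, while clean oscillations
   sit near 7 and are not.
3. **Spline correction**: within each flagged run, a smoothing-spline fit
   (p = 0.99 in the csaps convention, mapped to penalty
   `lam = (1−p)/p·dt³`) is subtracted and the residual re-anchored to the
   mean of the adjacent clean second (one-sided at record edges).  A
   trailing level shift — restoring continuity after a baseline step — is
   applied only when the across-gap discrepancy between local
   linear-trend extrapolations exceeds five robust SDs of same-lag level
   differences across the record.  Making the shift conditional avoids
   injecting spurious baseline shifts after spike-only artifacts, where
   anchor noise would otherwise propagate through the rest of the record.
4. **Band-pass**: zero-phase (forward–backward) Butterworth of order 3,
   0.01–0.1 Hz.  Zero phase is mandatory because instantaneous phases are
   compared across modalities later.  Measured contracts: 0.05 Hz passes
   at gain 0.999, a 1 Hz cardiac tone is attenuated by ~64 dB (single
   direction ~32 dB), group delay is zero.  Filtering is applied with
   reflective padding of three time constants of the 0.01 Hz edge;
   records shorter than ~300 s raise a warning because edge transients
   then reach the analysis window.
5. **Modified Beer–Lambert inversion**: per channel and sample, solve

       dOD(λᵢ) = [ε_HbO₂(λᵢ)·ΔHbO₂ + ε_HbR(λᵢ)·ΔHbR] · d · DPF(λᵢ)

   for (ΔHbO₂, ΔHbR) in µM.  Extinction coefficients ship as a versioned
   constants table (740 nm: 0.4383/1.1589; 850 nm: 1.0697/0.7861, all
   ×10⁻³ cm⁻¹µM⁻¹, from the standard compiled absorption spectra);
   DPF defaults to 6.0 at both wavelengths and is overridable.  Channels
   with nonpositive samples or intensity coefficient of variation above
   50% are pruned before inversion and excluded from ROI means.
6. **Block-averaged response**: amplitude = mean ΔHbO₂ over
   [onset+10 s, onset+100 s) minus mean over [onset−5 s, onset), per
   channel, then averaged over each ROI's channels.  Note that the
   0.01 Hz high-pass edge largely removes a 330 s task plateau
   (fundamental ≈ 0.003 Hz), so pipeline amplitudes are attenuated
   relative to the generative boxcar; the block-averaging operation
   itself is validated on constructed hemoglobin series, where a 0.5 µM
   boxcar is recovered exactly.
7. **Functional connectivity**: Pearson correlation of band-limited
   ΔHbO₂ between channels over the task interval (the FC window is
   configurable; the full task window is the default), aggregated to ROI
   level by averaging Fisher z = atanh(r) over all cross-region channel
   pairs and back-transforming.  Undefined cells (zero-variance or pruned
   channels) propagate as flagged missing values, never as zeros.

## sEMG chain

Zero-phase second-order Butterworth band-pass 10–400 Hz, full-wave
rectification, RMS over **non-overlapping** 100 ms windows (the envelope
is then natively 10 Hz and lands on the hemodynamic grid without
resampling), and normalization to percent of the MVC reference — the peak
of a 0.5 s moving average of the MVC trial's RMS envelope.  The MVC
protocol detail (0.5 s smoothing of a short maximal trial) is a declared
convention.  Because the broadband carrier spans the filter's own band
edges, band-passing shrinks absolute envelope estimates by roughly 7%;
the factor is common to task and MVC trials and cancels exactly in %MVC.

## Coupling statistics

Both statistics are computed per contralateral (muscle, ROI) pair — left
muscles against right hemisphere ROIs and vice versa, 32 pairs for 8
muscles × 8 ROIs — on the window 30–90 s after task onset (600 samples at
10 Hz), then averaged across subjects.

**Phase synchronization index.**  With θ_x, θ_y the Hilbert-transform
phases of the band-limited signals and θ_xy = nθ_x − mθ_y (n = m = 1),

    PSI = sqrt( ⟨cos θ_xy⟩² + ⟨sin θ_xy⟩² )  ∈ [0, 1].

Both inputs are band-limited to 0.01–0.1 Hz before the analytic signal —
the envelope is re-filtered with the hemodynamic band-pass, since that is
the only band the two 10 Hz series share.  The analytic signal is
computed on the full record and the window extracted afterwards, so
filter and Hilbert edge effects never touch the interior window.
Band-limited signals have strongly autocorrelated phases: two
*independent* such signals over 60 s have a PSI null centred near 0.33.
Significance judgements must therefore use a process-matched Monte-Carlo
null (provided), not the i.i.d.-phase null √(−ln α / N).

**Magnitude-squared coherence.**

    C_xy(f) = |P_xy(f)|² / (P_xx(f)·P_yy(f)) ∈ [0, 1]

with Welch-averaged spectra over Hanning-tapered, 50%-overlapped
segments of 100 samples, each segment demeaned.  Inputs are the demeaned
but otherwise unfiltered 10 Hz pair (pre-filtering to the band would only
rescale both numerator and denominator where the response is nonzero,
and single-channel filtering cannot change coherence).  The scalar
reported per pair is the unweighted mean over grid frequencies inside
0.01–0.1 Hz with DC excluded.  At 10 Hz a 100-sample segment gives
0.1 Hz resolution, so this band average rests on the single 0.1 Hz bin;
the pipeline therefore also reports a longer-segment diagnostic estimate
(300 samples, three in-band bins) alongside the headline value.  A known
consequence of the coarse headline resolution is a small negative bias at
the band-edge bin (the band-pass response varies across the bin), visible
in the recovery experiment below.

**Group statistics.**  Shapiro–Wilk normality screening, then two-tailed
independent or paired t-tests per outcome at α = 0.05, uncorrected for
multiplicity (Benjamini–Hochberg adjustment available behind a flag, with
a warning).  Non-normal outcomes are still t-tested, with the normality
p-values carried in the output.

## Synthetic-data generator

No public dataset exists for this acquisition design, so the simulator is
the package's reference instrument.  Its defaults define the simulated
study conditions:

| parameter | default | meaning |
|---|---|---|
| latent_sd | 0.1 µM | in-band (0.01–0.1 Hz, flat-spectrum) hemodynamic oscillation shared across channels |
| inter_channel_correlation r* | 0.6 | target pairwise in-band correlation between channels |
| Mayer / respiration / cardiac | 0.05 / 0.05 / 0.1 µM | sinusoidal nuisances at 0.1 / 0.3 / 1.0 Hz, per-subject random phase |
| white_sd | 0.02 µM | broadband channel noise |
| drift_slope | 5·10⁻⁴ µM/s | linear baseline drift scale |
| task_response_amplitude | 0.2 µM | boxcar convolved with a gamma kernel (peak ~4 s) |
| env_baseline / env_latent_sd / env_noise_sd | 0.5 / 0.05 / 0.05 mV | muscle envelope: baseline + g·(latent) + band-limited noise |
| mvc_multiple | 4× | MVC plateau over task envelope mean, 3 s trial |
| carrier | 10–400 Hz unit-RMS noise at 2000 Hz | amplitude-modulated by the envelope |

HbR is generated as −1/3 of HbO₂ plus small independent noise (HbO₂ is
the analysed chromophore; a richer HbR model would add nothing
testable).  Envelope positivity is enforced by a softplus clip with the
analytic coherence computed pre-clip and a warning once more than 1% of
samples would go negative.  Intensities and EMG are stored at single
precision, mirroring ADC resolution and keeping the text files lossless.

Under the additive construction, the coherence between the latent and
the envelope is `γ²(f) = g²S_s/(g²S_s + S_n)`, flat across the band.
The *measured* pair (ROI-mean ΔHbO₂ vs envelope) is further diluted by
the per-channel in-band noise implied by r* < 1; `theoretical_coherence`
implements the full closed form and `gain_for_band_coherence` inverts it,
so recovery experiments can set the analytic target of the measured pair
exactly.  The controlled recovery scenarios switch off the nuisance
lines, drift and task response: the 0.1 Hz Mayer line falls on the single
in-band bin of the headline estimator and is an fNIRS-only component not
represented in the closed form, so leaving it on would make the analytic
target wrong rather than merely noisy.  The default (fully contaminated)
scenario is used for the end-to-end cohort run.

Coupling gain is parameterized per muscle: all ROIs share one latent, so
one muscle's envelope necessarily has the same analytic coherence with
every ROI (up to per-ROI dilution); per-(muscle, ROI) targets that differ
within a muscle would require a per-ROI latent decomposition that the
validation does not need.

## What the validation shows (and does not)

The recovery experiments (see `cortimuscle.recovery`, asserted in
`tests/test_acceptance.py` and reported by `scripts/acceptance.py`):

* Beer–Lambert forward/inverse is exact to machine precision
  (< 10⁻⁹ µM over 63 × 3700 samples).
* Both filters meet their pass/stop/zero-phase contracts.
* Spline motion correction at least halves the RMSE against the
  artifact-free truth on ≥ 90% of 50 spike/step traces (median residual
  ~10% of the uncorrected error).
* A phase-locked narrowband pair reaches PSI ≥ 0.99; independent
  band-limited pairs fall below the 95th percentile of a 10⁴-rep
  process-matched null ~95% of the time.
* With the gain set for an analytic band coherence of 0.8, the median
  full-pipeline estimate over 50 seeded 600 s sessions lands within
  ±0.10 (typically ~0.77; the shortfall is the band-edge bin bias noted
  above), and the RMSE shrinks when records lengthen to 3000 s.
* ROI-level FC recovers a designed r* = 0.6 (mean ≈ 0.60 over 200 runs),
  and z-space aggregation matches brute-force enumeration.
* Block averaging recovers an injected 0.5 µM boxcar exactly without
  noise and within 3 SE over 200 noisy runs.
* The t-test battery is calibrated: type-I rate within the binomial CI
  of 0.05 over 1000 null runs, and empirical power for a 1 SD shift at
  n = 15 vs 25 matches the closed-form noncentral-t power.
* The full CLI chain on a 2 × 5-subject cohort with built-in coherence
  contrast 0.8 vs 0.2 produces 32 pairs per subject and flags the
  contrast (all 32 pair means ordered correctly; ≥ 75% individually
  significant at n = 5/5).

What passing these tests does **not** show: the simulator's nuisances
are stationary sinusoids and its artifacts are idealized spikes/steps,
so real head motion, scalp-coupling changes, superficial hemodynamics
(no short-separation channels are modelled or regressed), non-stationary
muscle fatigue and electrode artifacts are all outside the validated
regime.  Recovery of the coupling statistics on synthetic data bounds
estimator behaviour, not the physiological interpretability of PSI or
coherence in patients.

## Numerical and design choices

* Filter families/orders, Beer–Lambert constants, spline parameters and
  the MVC protocol are declared conventions where the acquisition
  convention is not observable; all are overridable parameters.
* Sample-index conversion is round-half-up; all intervals half-open.
* Coherence needs ≥ 2 Welch segments (single-segment coherence is
  identically 1 and rejected); undefined spectra bins (zero power)
  propagate as NaN.
* Fisher transform clips |r| ≥ 1 to ±(1−10⁻⁷) with a warning.
* Group-level SD over a single subject is reported as flagged missing,
  never 0.
* All Monte-Carlo experiments take explicit seeds; simulation streams
  (latent, optics, EMG, MVC) are independent substreams of the scenario
  seed, so identical scenarios are bit-reproducible.

## Problem sizes

Validation sizes were chosen to estimate each quantity to well inside
its tolerance on a single CPU: 50 traces (motion correction), 10⁴-rep
PSI null with 100 probes, 50 seeds × 600 s / 3000 s sessions
(coherence), 200 repetitions (FC, block averaging), 1000 repetitions
(test calibration), and a 10-subject end-to-end cohort at the full
370 s / 63-channel / 2000 Hz acquisition regime.
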