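# Methods

This note records the models, parameter choices and numerical conventions
behind `glomdyn`, and the known limitations of each.

## Scientific setting

Olfactory sensory neurons expressing the same receptor converge onto single
glomeruli of the olfactory bulb, where their glutamatergic output drives
mitral/tufted (MT) cells. Odor responses in this input layer are strongly
coupled to the respiration cycle: each inhalation draws odorant across the
epithelium and evokes a transient burst of transmitter release. `glomdyn`
analyses fluorescence time series from glomerular regions of interest
(ROIs) — a glutamate sensor reporting presynaptic input, optionally paired
with a red calcium indicator reporting postsynaptic activity — and asks how
the input signal is structured in time: its latency and kinetics relative to
inhalation, its polarity (excitation vs. suppression), its adaptation across
repeated sniffs, its locking to the sniff rhythm, and how population
activity patterns evolve over an odor presentation.

## Forward model (synthetic data generator)

The generator is first-class, tested code; every analysis can be validated
against its known ground truth.

A glomerulus–odor pair is a linear time-invariant drive plus noise:

    dF/F(t) = coupling * sum_i gain_i * h(t - t_i - L)
              + (tonic_amp + suppression_amp) * box(t) + noise

- `t_i` are inhalation onset times during the odor; `gain_i` is the
  per-inhalation response gain (constant for sustained responses, a
  geometric decay `0.55^i` for adapting ones, a ramp from 0.2 to 1 for
  facilitating ones).
- `h` is a unit-peak difference of exponentials with rise and decay time
  constants. A sensor kernel *adds* its own rise/decay constants to the
  glomerular ones and its latency offset to `L`. This additive composition
  is a deliberate simplification of true kernel convolution: it keeps the
  closed-form peak time t* = (τr·τd/(τd−τr))·ln(τd/τr) valid for the
  effective constants, which makes every kinetic analysis checkable against
  an analytic oracle.
- The fast glutamate kernel is (τr 10 ms, τd 20 ms, offset 0 ms); the slow
  calcium kernel is (τr 20 ms, τd 200 ms, offset 113 ms). The 113-ms offset
  is the designed presynaptic-to-postsynaptic latency difference that the
  dual-channel analysis must recover.
- `coupling` ∈ [0, 1] scales the sniff-locked (phasic) component;
  `tonic_amp` adds a smoothed boxcar spanning the odor; `suppression_amp`
  ≤ 0 produces suppressive and (with a phasic component) biphasic
  responses. Noise is i.i.d. Gaussian, independent between channels.
- Default dataset conditions: 150-Hz sampling, peak ΔF/F drawn from
  U(0.3, 1.0), onset latency U(113, 253) ms, rise τ U(30, 60) ms, decay τ
  U(100, 200) ms, noise SD 0.02, raw-F baseline 100 so that the ΔF/F step
  of the pipeline is exercised rather than bypassed.

Respiration is simulated per breath: a negative half-sine inhalation limb
over the first 35% of the period (trough at 17.5%), then a smaller positive
exhalation bump (0.6 relative amplitude). "Artificial" mode uses fixed-rate
breaths (default 0.25–2 Hz); "awake" mode draws breath periods from a
lognormal distribution (σ_log = 0.2) truncated to [0.15, 1] s around a
4.4-Hz mean rate.

Determinism: one root seed; every trace, channel and noise stream gets a
CRC-derived substream of `numpy`'s PCG64 generator, so datasets are
reproducible element-for-element and independent of iteration order.

## Analysis conventions

- **ΔF/F** uses the mean over a pre-odor window (default the second before
  the second preceding odor onset, i.e. [onset−2 s, onset−1 s]) as F0;
  degenerate (non-positive or zero-variance) baselines raise rather than
  propagate NaNs.
- **Resampling** to the 150-Hz analysis rate is shape-preserving monotone
  cubic (PCHIP) interpolation: it passes through every original sample and
  cannot overshoot a step, unlike an unconstrained cubic spline.
- **Low-pass filtering** is a zero-phase Gaussian with
  σ_t = √(ln 2)/(2π·f_c), which places the half-power (−3 dB, gain 1/√2)
  point exactly at the cutoff frequency f_c; edges use reflection padding.
- **Inhalation detection** finds flow troughs by prominence (default 1×
  the MAD-based robust SD — a pure oscillation has trough prominence of
  roughly twice its robust SD, so the detector cannot reject its own ideal
  input) and places the onset at the steepest negative slope between the
  preceding exhalation peak and the trough. Events closer than 200 ms to
  the previously retained one are dropped greedily from the left.
- **Inhalation-triggered averages (ITA)** use a [0, 4) s window for slow
  artificial sniffing and a [−0.3, +0.4) s window (baseline [−0.3, −0.1])
  for awake breathing. Onset latency is the first sustained (≥20 ms)
  crossing of 3× the baseline SD, with sub-sample half-height crossings by
  linear interpolation for FWHM.
- **Decay fits** are a single exponential A·exp(−(t−t_peak)/τ)+C from the
  ITA peak to the window end, initialised from the observed 1/e crossing.
- **Response classification** z-scores each ROI against the SD of its
  concatenated pre-odor baselines across all odors, after filtering: a 2-Hz
  low-pass branch scored as 0.95× the maximum z during the odor
  (excitation), and a 0.5-Hz branch scored as the 15th percentile of z over
  [onset, offset+0.5 s] (suppression). Crossing ±7 SD yields
  excitatory / suppressive / biphasic / none labels.
- **Lifetime sparseness** S = (1 − (Σr/N)²/Σ(r²/N))/(1 − 1/N) over an ROI's
  odor tuning vector; 1 for one-hot, 0 for uniform tuning.
- **Adaptation index** (T2 − T1)/Tmax from per-inhalation peak amplitudes
  (T1 first, T2 second-to-last inhalation window, Tmax the presentation
  maximum): −1 is complete adaptation, positive values are facilitation.
- **Sniff coherence** is Welch magnitude-squared coherence (Hann window,
  2-s segments, 50% overlap) between the trace and a rectangular pulse
  train (50-ms pulses) at the sniff frequency, read at the nearest bin.
- **Pattern decorrelation** correlates the across-ROI population vector of
  five 387-ms bin means (skipping the first 65 ms of the odor) against the
  first bin, using all ROIs without response thresholding.
- **Dual-channel concordance** reports the joint label table, directional
  percentages (a pair counts as excited if excitatory or biphasic), a 1-dof
  equal-expectation χ² for two response tallies, Spearman ρ and
  median/quartile differences of latencies and peak times (calcium minus
  glutamate), and Pearson r of adaptation indices.

## Problem sizes

The bundled acceptance script and test suite use desk-scale simulations
chosen to estimate each quantity stably: 10–12 glomeruli × 2–8 odors for
classification (48 pairs for accuracy, 200 pure-noise pairs for the
false-positive rate), 12 noiseless pairs for kernel-offset recovery, 8-ROI
populations for decorrelation, and 60-s awake respiration records. All are
generated at run time from the seed; no data files ship with the package.

## Limitations

- **Decay-τ bias.** Fitting a single exponential from the peak of a
  difference-of-exponentials transient is intrinsically upward-biased,
  because the rising exponential has not fully decayed at the peak. The
  bias grows with the rise/decay ratio of the effective constants (about
  1% at a ratio of 0.05, about 4% at 0.10, about 19% at 0.29). Recovery
  guarantees are therefore stated for fast-rise transients (ratio ≲ 0.1);
  reported τ values for slower-rising responses should be read as upper
  bounds on the true decay constant.
- **Cyclic-ITA latency at fast sniffing.** When the sniff period is shorter
  than the response duration, the previous transient's tail contaminates
  the pre-onset portion of the triggered average and can pin the detected
  onset to the window start. Latency measurements should use slow
  artificial inhalation (or isolated inhalations); at awake sniff rates the
  ITA characterises waveform shape and amplitude, not absolute latency.
- **Additive kernels.** Sensor kinetics add to glomerular kinetics rather
  than convolving with them; relative comparisons between channels are
  faithful, but absolute effective time constants are not those a full
  convolution model would produce.
- **Edge troughs.** Prominence-based peak finding cannot detect a trough
  lying on the first or last sample of a record; detection is specified for
  interior troughs only.
- **Linear drive.** The forward model is linear in the per-inhalation
  gains; saturation, paired-pulse interactions shorter than one sniff, and
  slow drifts are out of scope.
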