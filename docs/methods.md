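# Methods

This note documents the models, parameters, and numerical choices behind the
package, including the points where the procedure was genuinely open and a
choice had to be made.

## Preprocessing

**ΔF/F.** The baseline image is the per-pixel minimum-intensity projection
over all frames; `ΔF/F(t,y,x) = 100·(F − F_min)/F_min` (percent everywhere in
this package, so the 0.5 %, 1 % and 50 % thresholds below apply literally).
A minimum projection stays valid for cultures that are active most of the
time, at the cost of a noise-dependent offset (see *Closed-loop testing*).
Pixels whose minimum is ≤ 0 have no defined baseline and raise an error that
reports the affected pixel count.

**ROI means.** A pixel belongs to a circular ROI iff its center lies within
the disc, radius inclusive. Traces are mean ΔF/F over the member pixels,
rows ordered by ROI id.

**Smoothing.** Centered four-frame moving mean. At the trace edges the
window shrinks to the available samples (no padding), so no synthetic values
enter the threshold logic. For the even default window the extra sample
sits on the right: frame *t* averages frames `[t−1, t+2]`.

**Windowed-percentile baseline.** Before duration/AUC measurement the trace
is flattened: consecutive non-overlapping windows of `round(15 s × fs)`
frames (134 at 8.91 Hz; round-half-away-from-zero), the 1st percentile of
each window anchored at the window center, piecewise-linear interpolation
between anchors with constant extrapolation beyond the first/last, and the
resulting baseline subtracted. The windowing step and interpolation scheme
of the original routine are not published; non-overlapping windows with
linear interpolation were chosen for reproducibility and monotone behavior
(a spline can overshoot between anchors). Known consequence: under a
baseline sloping at rate *m*, the centered anchor leaves a constant residual
offset of at most `m × window`; the tests pin this bound. Recordings
shorter than one window fall back to a single global percentile shift, with
a logged notice.

## Transient detection

Peaks are strict local maxima on the smoothed trace (a flat plateau reports
its first frame) with value > 0.5 %ΔF/F. The height-vs-prominence reading
of the 0.5 % criterion is ambiguous; height is the default and a
`peak_criterion="prominence"` switch provides the alternative. Amplitude is
measured on the smoothed (pre-baseline-adjusted) trace as peak value minus
the minimum over the preceding inter-event interval (from frame 0 for the
first event), matching the stated order of operations; boundaries, AUC and
decay are measured on the baseline-adjusted trace.

Exclusion rules, applied per peak:

* **refractory** — the peak follows its predecessor by < 2 s;
* **elevated baseline** — amplitude < 50 % of the peak's absolute ΔF/F,
  where "absolute" is read as the peak's trace value over the
  minimum-projection baseline.

Excluded peaks stay in the event list — by default they count toward
frequency and inter-event intervals (`count_flagged_in_frequency=False`
switches this, since the original counting rule is implied but not stated) —
but never carry amplitude, duration, AUC or decay values.

Event start is the last upward crossing of 0.5 % before the peak (first
frame at/above threshold); the end scan tracks the running minimum after the
peak and stops at the first frame at/below 0.5 %, or at the running-minimum
frame if the trace first rises > 1 % above that minimum — the rise signals
the next event, so the trough is the natural boundary. Intervals are
half-open `[start, end)` in 0-based frames; `duration = (end − start)/fs`;
no sub-frame interpolation except in the half-decay time, which
interpolates the crossing of (peak value − amplitude/2). Events whose
boundaries run into the trace edges are marked `no_clear_bounds` and carry
no duration/AUC. AUC is `numpy.trapezoid` over the event samples scaled by
`1/fs` (%·s).

## Network synchrony

Active intervals are full-width-at-half-maximum spans around peaks with
prominence ≥ 0.5 % (scipy's standard prominence definition). The
half-maximum reference is ambiguous between half-prominence and half of the
absolute height; half-prominence — the standard width convention consistent
with a prominence-gated peak set — is the default, with
`fwhm_reference="half_height"` as the alternative. Interpolated crossings
are rounded outward so a neuron is active for every frame its half-height
span touches; overlapping intervals of one neuron merge.

The coactive fraction is the frame-wise count of distinct active neurons
over the roster size — no temporal smoothing. Network events are maximal
runs with fraction **strictly** above 0.20 (frames at exactly 20 % do not
count), kept if ≥ 2.5 s. Participation is the percentage of neurons whose
active intervals overlap the event at all. The interval-based detector is
proven equivalent, event for event, to a brute-force per-frame scan on
random instances in the test suite.

## Synthetic activity generator

The generator emulates the statistical structure of the three genotype
regimes — it defines the conditions under which the pipeline is verified,
not a fit to any published rates (none are reported numerically; the presets
reproduce the qualitative orderings: knockout > double mutant > wild type in
event frequency, size, duration, and network recruitment).

Model, per FOV (defaults 40 neurons, 300 s, 8.91 Hz):

* **Solo bursts** per neuron: homogeneous Poisson at `burst_rate_per_min`;
  spike count `1 + Poisson(mean − 1)`; spikes packed 80 ms apart (sub-frame),
  so a burst renders as one transient whose amplitude grows with spike count
  — the single mechanism that makes high-rate regimes also larger and longer
  (duration at a fixed absolute threshold grows like `τ_d·ln(A/θ)`).
* **Network events** per FOV: independent Poisson at `network_rate_per_min`;
  each neuron recruited with `participation_prob`; recruits fire an extended
  volley (≥ 8 spikes, 0.4 s apart, onset jittered ±0.1 s) whose smoothed
  trace forms a multi-second plateau, so recruited neurons stay above half
  maximum together for > 2.5 s.
* **Rendering**: each spike adds `a·(e^{−t/τ_d} − e^{−t/τ_r})` normalized to
  peak `amplitude_per_spike_pct` (2 %); kernels sum linearly. Defaults
  τ_rise = 0.1 s, τ_decay = 0.8 s — plausible red-indicator kinetics, not a
  published measurement; both configurable. Kernel tails are truncated at
  30·τ_decay (below double precision of the peak).
* **Nuisances**: white Gaussian noise per frame and a 60 s-period sinusoidal
  drift with an independent random phase per neuron (slow baseline wander is
  a per-cell nuisance; a field-coherent drift would manufacture artificial
  network synchrony that no motion-corrected recording shows).

Preset table (rates per neuron; network rate per FOV):

| preset | bursts·min⁻¹ | spikes/burst | network·min⁻¹ | participation | noise SD | drift |
|--------|-------------:|-------------:|--------------:|--------------:|---------:|------:|
| WT     | 0.8          | 2.0          | 0.4           | 0.30          | 0.2 %    | 0.2 % |
| KO_HET | 1.6          | 3.5          | 0.8           | 0.50          | 0.2 %    | 0.2 % |
| KO     | 2.8          | 5.0          | 1.5           | 0.75          | 0.2 %    | 0.2 % |

Noise and drift are acquisition properties, identical across genotypes.
Their level is pinned by the detection rule itself: a fixed absolute 0.5 %
threshold is only workable when the smoothed-noise floor sits well below it.
With the four-frame mean, raw noise SD σ gives a smoothed floor of σ/2;
at σ = 0.5 % the threshold is 2σ of the smoothed noise and white-noise
excursions alone produce ~40 spurious supra-threshold maxima per 300 s trace
(~0.73 F1 against isolated 5 % events), while at σ = 0.2 % the threshold is
5σ and recovery F1 exceeds 0.99. The presets therefore use σ = 0.2 %, the
regime implicit in recordings analyzed with this threshold. The recovery
benchmark reports F1 at both noise levels.

What the generator does **not** emulate: indicator saturation and Hill
binding, photobleaching, motion artifacts, correlated (non-white) noise,
neuropil contamination, and cell-to-cell kinetic variability. Passing
tests therefore demonstrate correctness of the analysis rules under the
stated statistical structure, not robustness to those real-data effects.

## Closed-loop testing

The toy movie renderer places ROIs on a grid with a quadratic radial falloff
inside each disc; the falloff cancels in the ΔF/F ratio, so with zero shot
noise preprocessing recovers input traces to machine precision (each trace
must touch its own baseline at least once, which sparse schedules guarantee).
Under per-frame shot noise the minimum projection is biased low by roughly
2.9 σ (the expected minimum of ~2700 Gaussians), which surfaces as a small
positive DC offset in raw recovered ΔF/F — an intrinsic property of a
minimum-projection baseline, present in real recordings too, and removed by
the windowed-percentile stage. Closed-loop fidelity under noise is therefore
assessed on baseline-adjusted traces against the per-pixel noise floor
(`100·σ_shot/baseline` in ΔF/F percent); ROI averaging keeps the residual
well under it.

## Determinism and sizes

Every stochastic component is a pure function of its arguments and an
integer seed (`numpy.random.default_rng`); pipelines re-run byte-identically,
and tables are written with a fixed float format to keep files stable.
Verification sizes — 20 seeds per preset for the regime orderings, 10 seeds
for recovery benchmarks, 100 random instances for the brute-force
equivalence, 200 seeds for the Poisson rate checks — were chosen so each
check's sampling error is far below the effect it measures; the whole suite
runs in well under a minute.
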