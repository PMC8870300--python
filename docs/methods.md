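# Methods

## Detector model

Excitation is a 40 MHz pulse train (period T = 25 ns). Per pulse, the number
of photons a pixel emits follows one of two models:

- `binomial` (default): at most one photon, with probability equal to the
  emission rate. This is the single-emitter regime — one fluorophore cannot
  emit twice per excitation — and it is the model under which "saturating
  emission" (probability 1) yields exactly one photon per pulse.
- `poisson`: Poisson-distributed photon number with the emission rate as its
  mean. This is the ensemble regime of a real pixel integrating many dye
  molecules, and the only regime in which several photons can compete inside
  one dead-time window.

Each photon's arrival time is t₀ + Exp(τ) + N(0, σ_IRF), wrapped modulo T.
The IRF is a Gaussian of σ = 0.2 ns centred at t₀ = 1 ns into the micro-time
window; placing the pulse at t₀ > 0 keeps negatively jittered arrivals from
wrapping to ≈T, which would otherwise bias the mean arrival time upward by
several tenths of a nanosecond.

The detector is non-paralyzable: a photon is recorded only if it arrives
after the dead interval opened by the previous recorded photon has expired.
Two re-arming modes model the two generations of electronics:

- *multi-stop* (rapid systems, dead time ≈ 2 ns): the detector re-arms the
  instant the dead time elapses, so several photons per excitation period can
  be recorded.
- *start–stop* (classic systems, dead time ≈ 50 ns): one conversion per sync
  period; the detector re-arms at the first excitation pulse after the dead
  interval ends.

Under multi-photon (Poisson) flux the classic start–stop detector records
the first photon of each armed cycle, giving the recorded density
f(t)·e^(−λF(t)) — the textbook pileup skew: the apparent lifetime of a
τ = 3 ns decay falls monotonically (≈3.0 → 2.3 ns) as the emission rate
rises from 0.01 to 1.0 photons/pulse. Two properties of this phenomenon are
worth making explicit because they constrain the simulator design:

- Single-photon-per-pulse emission cannot produce pileup shortening under
  any dead-time semantics. With at most one photon per pulse there is no
  within-window competition; the only selection effect is the loss of
  *early* photons in the partially blocked cycle at the dead-time boundary,
  which biases the apparent lifetime *upward* (≈ +27% at saturation,
  50 ns dead time, absolute re-arming). The pileup demonstrations therefore
  use the Poisson model.
- With absolute (non-sync-gated) re-arming the upward boundary bias and the
  downward first-photon bias nearly cancel, which is why the start–stop
  mode exists as an explicit switch rather than being approximated.

The rapid detector stays accurate across the same emission range in the
single-photon model (bias < 0.5%). Under extreme Poisson overdrive
(1.0 photons/pulse mean) even a 2 ns dead window clips the trailing photon
of sub-2 ns pairs and biases the estimate by ≈5%; at the sustained
~20–30 Mcps operating range of rapid acquisitions the bias is ≤3%.

## Fast lifetime estimation

The per-pixel lifetime is the photon-weighted mean micro-time at bin centres
(250 bins of 0.1 ns), corrected for period truncation by inverting the exact
wrapped-decay mean

    m(τ) = t₀ + τ − T · e^(t₀/τ) / (e^(T/τ) − 1)

by bisection (monotone in τ; means at or beyond the uniform-decay limit
return ∞ as "not resolvable"). At t₀ = 0 this reduces to the classic
truncated-exponential mean τ − T/(e^(T/τ) − 1). Recovery is unbiased to
within shot noise for τ/T ≤ 0.4. Pixels with fewer than `min_photons = 20`
counts (a floor tracking protocols typically leave unstated) carry an undefined
lifetime, encoded as NaN in memory and in the float32 TIFF channel — 0 is
avoided because τ̂ = 0 is a meaningful estimate — and documented in the JSON
sidecar. Which estimator a real vendor export uses (fast FLIM vs fitted τ)
is not fixed by the file format, so the estimator is pluggable
(`correct_truncation`, `irf_centroid_ns` arguments).

## Phasor analysis

First harmonic only, ω = 2π·(repetition rate). Discrete sums run over bin
centres, which is unbiased to ~10⁻⁵ at 0.1 ns bins. For phasor geometry
tests the simulator is run without IRF blur (σ = 0, t₀ = 0): an IRF rotates
and shrinks the phasor by e^(−ω²σ²/2)·e^(−iωt₀), and the package does not
implement reference-decay calibration. Gates are circles with configurable
centre/radius; the published gate geometry is unstated, so gate placement is
part of the run configuration, and only relative population shifts are
meaningful.

## Synthetic scenes

The generator emulates: free 2-D Brownian motion (per-axis step variance
2DΔt) for gel-embedded controls; confined motion inside the cell for
intracellular spots (wall crossings are rejected and redrawn, a
reflecting-wall surrogate that preserves in-region step statistics);
compartment-dependent monoexponential lifetimes (extracellular 2.0 ns,
cytoplasm 3.0 ns, nucleus 3.8 ns by default, step or k-frame ramp at
crossings); Gaussian PSFs (σ = 1 px) sampled at pixel centres; and uniform
background emission at the local compartment lifetime.

Key default choices, made once:

- *Control diffusion coefficient*: not reported for the gel experiments; the
  21 px jump limit only bounds the displacement scale. Default
  D = 2 px²/frame (per-frame rms step ≈ 2.8 px), comfortably inside the
  limit.
- *Spot brightness*: intracellular spots are endosomal clusters of many
  nanoparticles, while gel controls are single particles. Defaults encode
  this as 4000 vs 200 detected-scale photons/spot/frame. This ratio is not
  cosmetic: the classification rule compares a trajectory's smoothed
  lifetime *range* (≈2–2.6 σ of its per-frame noise for 10–30-frame tracks)
  to the mean control |Δτ| (≈1.13 σ of *control* noise). The comparison is
  scale-free in photon noise, so a track whose per-frame noise matches the
  controls' will typically exceed the threshold no matter how bright both
  are; the rule separates classes only when the analysed tracks are
  substantially quieter than the controls that set the threshold, i.e.
  brighter by roughly an order of magnitude. This is also why a control
  movie classified against its own threshold reports most tracks *above*
  threshold — expected behaviour, not a defect.
- *Control lifetime*: 3.0 ns, matching the cytoplasmic value — the same dye
  in a comparable environment.
- Coordinates are 0-based with pixel centres at integer positions,
  row-major; movies are frame-major, with per-pixel micro-time histograms
  (uint16) optionally collapsed to the two-channel representation.

What the generator does *not* emulate: 3-D/vectorial PSFs, photobleaching,
multiexponential decays, detector afterpulsing, stage drift, spot merging in
dense endosomes, or vendor file formats. Passing tests therefore demonstrate
correctness of the analysis chain under these idealized conditions, not
robustness to every artefact of real acquisitions.

## Tracking

The commercial trackers these experiments rely on are closed software; their
user-facing parameters are mapped onto standard operations with the same
semantics: difference-of-Gaussians band-pass (0.75–1 px band, background
scale 4× the upper band edge), local maxima above a robust MAD-based floor,
2-D Gaussian least-squares refinement (sub-pixel accuracy ≈0.05–0.1 px at
2000-photon spots), a fitted-width acceptance window of 0.85–1.5 px, and a
brightness floor. The customary dim-particle removal window (750–1500
integrated counts) is applied as a lower cut at 750; the upper value is
stored for provenance but not applied — whether it was meant as a keep-band
is ambiguous. Linking solves, per consecutive frame pair, the
globally optimal one-to-one assignment (Hungarian algorithm) on squared
displacement among pairs within the jump limit; no gap closing, merging or
splitting. Ties are resolved deterministically by sorting detections in
(y, x) order, which also makes linking invariant to input ordering.

## Trajectory classification

Per-frame trajectory lifetimes are the intensity-weighted mean of
defined-lifetime pixels within a 3 px radius of the sub-pixel position —
the 3 px neighbourhood limit is interpreted as the lifetime-sampling
radius rather than an additional linking constraint (the jump limit already
governs linking); a single-pixel read-out remains selectable via radius 0.
Undefined frames are skipped, never interpolated.
Smoothing is a centred 3-frame moving median; incomplete end windows pass
through unchanged. The threshold is the arithmetic mean of frame-to-frame
|Δτ| pooled over control tracks' *raw* series (the source controls appear
unsmoothed). Classification is strict: a track is above threshold iff
range(smoothed) > threshold. The shipped default threshold 0.39 ns is the
published control-derived value; synthetic pipelines recompute their own.
The boundary report assigns each track the zone of its median position
(boundary band vs interior, band width 3 px around membrane and nuclear
interfaces) and summarizes enrichment as an odds ratio, flagging complete
separation explicitly; no significance test is attached beyond the
permutation behaviour exercised in the tests.

## Problem sizes

Test and demonstration runs use 64×64 to 96×96 px frames, 15–30 frames,
6–20 particles and 10⁵–10⁷ excitation pulses per quantity — sizes chosen so
the full suite completes in a few minutes while keeping shot-noise margins
(standard errors several times smaller than the tolerances asserted).
Detector-throughput measurements use ≥1.2×10⁶ pulses (sampling error
< 0.1%).

## Known limitations

- The pileup magnitude under Poisson overdrive depends on the pair-loss
  model (the trailing photon of a sub-dead-time pair is dropped); real
  detectors may instead merge such pairs into one distorted pulse.
- Confined motion is not exact specular reflection; step statistics near
  walls are approximate.
- Phasor analysis has no IRF calibration; quantitative phasor positions
  require IRF-free histograms or external calibration.
- The lifetime-range rule's specificity depends on the control-to-sample
  noise ratio (see *Synthetic scenes*); with equally noisy controls and
  samples it degenerates to flagging nearly everything.
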