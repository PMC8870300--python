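# flimtrack

Simulation and analysis of rapid fluorescence-lifetime-imaging (FLIM) movies
of nanoparticle uptake in live cells.

Classic time-correlated single-photon counting (TCSPC) electronics pause for
~50 ns after every recorded photon. To avoid pileup — the skew of the decay
toward early arrival times when photons compete inside one dead-time window —
operators attenuate detection to below 10% of the laser repetition rate, which
makes frame times far too long to follow vesicle-scale transport. Hybrid
detectors with single-nanosecond dead times ("rapid FLIM") remove that
ceiling: at a 40 MHz repetition rate the sustainable count rate rises from
4 Mcps to ~40 Mcps, enough to acquire 120+ unbinned 512×512 lifetime frames in
under ten minutes and to track single nanoparticle spots frame by frame.

`flimtrack` implements the full analysis chain for such experiments, plus a
photon-level simulator that makes every stage testable without microscope
data:

- **Detector simulation** — pulse-by-pulse photon emission (single-emitter
  Bernoulli or ensemble Poisson), exponential decay with Gaussian IRF jitter
  wrapped into the pulse period, and a non-paralyzable dead-time model with
  either multi-stop (rapid) or start–stop (classic) re-arming.
- **Fast lifetime imaging** — per-pixel photon-weighted mean arrival time
  with an exact period-truncation correction, solving
  m(τ) = t₀ + τ − T·e^(t₀/τ)/(e^(T/τ) − 1) for τ; output is the two-channel
  (intensity, lifetime) image representation.
- **Phasor analysis** — first-harmonic transform
  G = ∫I(t)cos(ωt)dt / ∫I(t)dt, S = ∫I(t)sin(ωt)dt / ∫I(t)dt with
  ω = 2πf; monoexponential decays fall on the universal semicircle at
  G = 1/(1+(ωτ)²), S = ωτ·G; circular gates give population fractions per
  timepoint.
- **Tracking** — band-pass preprocessing, sub-pixel Gaussian spot fitting
  with size/brightness acceptance windows, and per-frame-pair optimal
  assignment linking under a hard maximum-jump constraint (21 px for gel
  controls, 5 px for caged intracellular motion).
- **Trajectory classification** — per-frame lifetimes sampled in a 3 px
  radius around each track position, 3-frame moving-median smoothing, and a
  threshold on the trajectory lifetime range taken from the mean
  frame-to-frame |Δτ| of agarose-embedded control particles (typically a
  few tenths of a nanosecond). Tracks whose smoothed range exceeds the
  threshold
  flag a changing molecular environment, and are reported against cell
  boundary masks (membrane / nuclear) with an enrichment odds ratio.

## Worked example

Measure the noise floor on a simulated agarose control, then classify the
trajectories of a simulated cell movie against it:

```python
from flimtrack.pipeline import agarose_run_config, cell_run_config, run_pipeline

control = run_pipeline(agarose_run_config(seed=1), "runs/control",
                       threshold_mode="self")
print(f"control threshold: {control['threshold_ns']:.3f} ns "
      f"from {control['n_control_deltas']} deltas")

cell = run_pipeline(cell_run_config(seed=2), "runs/cell",
                    threshold_ns=control["threshold_ns"])
print(f"cell tracks: {cell['n_tracks']}  "
      f"above: {cell['labels']['above_threshold']}  "
      f"below: {cell['labels']['below_threshold']}")
print(f"boundary odds ratio: {cell['odds_ratio_boundary']}")
```

prints

```
control threshold: 0.412 ns from 171 deltas
cell tracks: 10  above: 6  below: 4
boundary odds ratio: inf
```

The control threshold (0.412 ns here) is the mean frame-to-frame |Δτ| pooled
over all control trajectories — pure photon noise, since the gel-embedded
particles have a constant true lifetime. In the cell movie, the six tracks
whose smoothed lifetime range exceeds that threshold are exactly the spots
shuttling across the nuclear boundary (a +0.8 ns lifetime step in the
simulated ground truth); the infinite odds ratio means every above-threshold
track sits in a boundary band and every below-threshold track in the
compartment interior — the boundary-localization pattern the method is
designed to expose.

Each run directory contains the config (`config.yaml`), ground truth
(`ground_truth.csv`), the two-channel lifetime TIFF plus JSON sidecar, the
phasor cloud (`phasor.csv`), track tables (`tracks.csv`,
`classified_tracks.csv`), a `summary.json` and a checksummed
`manifest.json`. The same stages are exposed on the command line
(`flimtrack run-all --preset cell --seed 2 -o runs/cell`, plus `simulate`,
`flim`, `phasor`, `track`, `classify` for entering the pipeline at any
boundary with real data).

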