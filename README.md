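# tcpalm

Quantitative analysis of transient RNA polymerase II clustering in live-cell
super-resolution data, and of the transcriptional output those clusters gate.

Live-cell PALM with photo-convertible tags (Dendra2) detects single molecules
sparsely over time, so a sub-diffraction protein cluster is visible not as a
bright spot in one frame but as a transient surge in the *rate* of
single-molecule detections inside a region of interest.  This package
implements the analysis chain built on that idea, for people who work with
localization tables, MS2/MCP nascent-RNA imaging, or stochastic models of
transcription:

- **Photophysics simulation** (`tcpalm.photophysics`) — exact Gillespie
  simulation of the Dendra2 state model (activation `k_on = 0.0067 s⁻¹`,
  blinking `k_dark = 9.6 s⁻¹`, recovery `k_rev = 2.33 s⁻¹`, bleaching
  `k_bleach = 3 s⁻¹`), 60 ms camera binning with half-frame sensitivity and
  single-count collapsing, plus generators for spatial localization fields and
  mRNA-locus image stacks.
- **tcPALM event detection** (`tcpalm.events`) — cumulant (running-sum)
  traces, penalized piecewise-linear change-point segmentation to find the
  slope onset and plateau of each clustering event, and the derived metrics:
  apparent lifetime τ_cluster, burst size, clustering strength
  (tan α = size/lifetime), event frequency, and pre-existing vs de novo
  classification.
- **Molecular counting** (`tcpalm.counting`) — photophysical rate estimation
  from single-molecule traces by dwell-moment inversion, and cluster size
  estimation by simulation matching: the observed cumulant is compared with
  ensembles of simulated cumulants over candidate molecule numbers N and the
  minimum mean absolute deviation wins.
- **pcPALM** (`tcpalm.pcpalm`) — edge-corrected radial pair correlation and
  its decomposition into a single-molecule blinking term (Gaussian of width
  √2·σ_loc) and a genuine protein-clustering term.
- **Nascent-mRNA quantification** (`tcpalm.mrna`) — maximum-intensity
  projection, 3×3-window locus intensities with background subtraction, and
  counts as intensity ratios against the single-mRNA unit brightness.
- **Cluster-gated transcription model** (`tcpalm.transcription`) — clusters
  arrive at ~0.2 min⁻¹; while one is present, productive Pol II load every
  2.5 s (Poisson) and elongate at ~3.1 kbp/min through an MS2 cassette
  3.4 kb from the TSS; the cluster lifetime τ(t) is a Gaussian pulse
  (basal 6.9 s, peak 24 s at 12.5 min after stimulation).  The package
  simulates mean nascent-mRNA courses, fits free kinetic parameters to
  observed courses, measures the input→output peak lag, and simulates
  reversible CDK9-block (DRB-type) interventions.

## Worked example

```python
import numpy as np
from tcpalm import (ClusterScenario, DENDRA2, detect_events,
                    simulate_cluster_trace)

# a cluster of 100 Pol II molecules present from t = 200 s to 210 s,
# observed for 1000 s at 60 ms frames
trace = simulate_cluster_trace(ClusterScenario(100, 200.0, 210.0, 1000.0),
                               DENDRA2, seed=7)
event = detect_events(trace)[0]
print(f"onset {event.t_onset:.1f} s, lifetime {event.lifetime:.1f} s, "
      f"burst {event.burst_size} detections, "
      f"strength {event.strength:.2f} /s")
```

prints

```
onset 199.7 s, lifetime 11.3 s, burst 42 detections, strength 3.72 /s
```

— the detector reads the 10-second cluster off the cumulant trace: onset at
the assembly time of 200 s (after dead-time correction for the wait until the
first photo-conversion), an apparent lifetime near 10 s, and ~42 collapsed
detections produced by the handful of molecules that photo-convert during so
short a window.

The transcription model end of the chain:

```python
from tcpalm import (GeneGeometry, KineticParams, LifetimeProfile,
                    NascentCourse, lifetime_input, peak_lag,
                    simulate_nascent_course)

profile = LifetimeProfile()            # basal 6.9 s, peak 24 s at 12.5 min
course = simulate_nascent_course(profile, GeneGeometry(), KineticParams(),
                                 horizon_min=40, n_runs=50000, seed=1)
inp = NascentCourse(t_min=course.t_min,
                    mean=lifetime_input(course.t_min, profile))
print(f"peak lag {peak_lag(inp, course, method='vertex'):.2f} min")
```

prints `peak lag 2.09 min`: the mean mRNA output peaks about two minutes
after the cluster-lifetime input, the elongation delay to and through the
MS2 cassette.

A `tcpalm` command-line tool exposes the same stages
(`simulate`, `fixtures`, `tcpalm`, `count`, `pcpalm`, `model`, `quant`) for
reproducible runs from CSV/TIFF/YAML inputs; every subcommand takes `--seed`
and writes its artifacts plus a provenance log.

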