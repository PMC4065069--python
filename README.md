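# cawave

Analysis of stimulus-evoked intercellular calcium waves and oscillations in
fluorescence time-lapse recordings of brain-slice networks, plus
quantification of downstream nuclear transcription-factor activation
(NF-κB) from two-channel immunofluorescence images.

The package is aimed at slice electrophysiology / imaging labs that deliver
patterned electrical stimulation (theta-burst stimulation, TBS: here 8
trains of 8 pulses at 200 Hz, trains every 2 s — 64 stimuli in 14.04 s) to
an organotypic hippocampal culture while imaging a calcium indicator at
1 frame/s, and want population-level readouts for thousands of cells:

* **Segmentation** — threshold + distance-map watershed detection of cells
  or nuclei, with size/radius/separation criteria.
* **Traces** — per-cell ΔF/F₀ = (F − F₀)/F₀ with F₀ the mean over the 20
  pre-stimulus baseline frames; 9-point moving-average smoothing; responder
  filter (excluded if the trace maximum precedes stimulation or the
  excursion max − mean < 0.25).
* **Oscillations** — major-peak detection (minimum width 5 s at half
  prominence), peak-count classes 1..8 / >8, and per-class oscillation
  frequency `f = 1000 / mean(inter-peak interval in s)` in mHz.
* **Wave kinetics** — apparent propagation velocity from ordinary least
  squares of time-to-first-peak *t₁* on distance *d* (overall and split at
  a 150 µm breakpoint; `v = 1/slope`), and exponential amplitude decay
  `A(d) = A₀ · exp(−(d − 100 µm)/λ)` fitted on log amplitude over
  100–500 µm.
* **NF-κB** — per-nucleus mean marker intensity over nuclei segmented on
  the counterstain channel; per-region two-sided Student's t tests between
  control and stimulated groups with the image as the unit of analysis.
* **Synthetic data** — a generator producing movies, traces and
  immunofluorescence images with full ground truth, so every stage is
  validated by parameter recovery without any external data.

## Worked example

```python
from cawave.simgen import trace_mode_config, simulate_traces
from cawave.pipeline import analyze_trace_matrix

cfg = trace_mode_config(n_cells=5000, seed=1)   # standard study conditions
sim = simulate_traces(cfg)
res = analyze_trace_matrix(
    sim.raw, cfg.frame_interval, cfg.protocol,
    distances=sim.truth["distance_um"].to_numpy(),
)
v = res.velocity
print(f"velocity overall/proximal/distal: "
      f"{v.v_overall:.2f}/{v.v_proximal:.2f}/{v.v_distal:.2f} um/s")
print(f"amplitude decay length: {res.amplitude_decay.decay_length:.0f} um")
s = res.class_summary.set_index("peak_class")
for k in (3, 4, 8):
    print(f"class {k}: n={int(s.loc[k,'n_cells'])}, "
          f"{s.loc[k,'mean_frequency_mhz']:.1f} mHz")
```

prints

```
velocity overall/proximal/distal: 5.63/4.50/6.01 um/s
amplitude decay length: 150 um
class 3: n=831, 16.3 mHz
class 4: n=656, 21.4 mHz
class 8: n=99, 32.8 mHz
```

The wave crosses the proximal 150 µm at ~4.5 µm/s and speeds up to
~6 µm/s beyond it; the single-line fit over 0–500 µm reads ~5.6 µm/s.
First-peak amplitude decays with a ~150 µm length constant beyond the
100 µm plateau. Cells showing 3 calcium peaks oscillate at ~16–17 mHz and
8-peak cells at ~33 mHz — the detected frequency of the 3-peak class sits
slightly below the configured 17 mHz because the first-to-second interval
carries the amplitude-dependent refractory delay.

The same analysis runs image-based: `simulate` + `analyze` via the CLI

```
cawave simulate --n-cells 300 --seed 1 --out-dir sim    # renders movie.tiff
cawave analyze --config pipeline.yaml                   # full report bundle
cawave nfkb --effect-region CA1 --effect-size 1.5       # IF experiment
cawave recover --n-seeds 3                              # recovery table
```

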