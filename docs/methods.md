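# Methods

This note documents the generative model behind `cawave.simgen`, the
analysis procedures, the parameter defaults and the numerical choices made
where the design was genuinely open. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## The experiment being modelled

A monopolar electrode delivers theta-burst stimulation (TBS) to the
dentate-gyrus molecular layer of an organotypic hippocampal slice loaded
with a calcium indicator, while a confocal microscope records one frame per
second for 330 s (20 s baseline, stimulation onset at t = 20 s). The
stimulus is 8 trains of 8 pulses; each train lasts 40 ms (200 Hz within a
train) and trains start every 2 s, so the stimulus spans
(8 − 1) × 2 + 0.04 = 14.04 s. Train spacing is interpreted start-to-start:
it is the only reading under which the printed protocol parameters compose
to the printed total duration, and the package regression-locks this
convention in its tests.

The evoked response has a characteristic spatial structure: a calcium wave
sweeps radially outward, cells report a first ΔF/F₀ peak with a latency
that grows with distance from the electrode, first-peak amplitude decays
roughly exponentially beyond ~100 µm, and cells then oscillate — the
number and frequency of subsequent peaks increasing with distance.
Thirty minutes later, activation of the transcription factor NF-κB is read
out as nuclear immunofluorescence in the CA1, CA3 and dentate gyrus fields
and compared between stimulated and control slices.

## Synthetic-data generator

The generator emulates this structure with known ground truth so that every
analysis stage can be validated by parameter recovery. It does **not**
model the underlying biophysics (no calcium-induced calcium release, store
dynamics, gap-junction or ATP signalling), nor photobleaching, focus drift
or an optical PSF; passing tests therefore demonstrate correctness of the
*analysis* under the assumed response structure, not robustness to every
artefact of real recordings.

### Cell placement

Distance to the electrode is drawn uniformly between `r_range`
(10–500 µm in trace mode) with a uniform angle inside the field. Distance-
uniform placement mimics the banded, layered organisation of hippocampal
cell bodies rather than a uniform 2-D sheet, and gives every distance bin
equal statistical weight in the distance-resolved fits. In movie mode the
electrode sits at the centre of a 512 × 512 px field (2 µm/px) and a
16 µm minimum separation is enforced (bounded rejection sampling): a
centred electrode is used because annulus capacity grows linearly with
distance, so the separation constraint never depletes proximal annuli and
the configured distance distribution is preserved.

### First-peak latency and amplitude

Time-to-first-peak follows the piecewise-linear law

    t₁(d) = d / v_prox                          d ≤ 150 µm
    t₁(d) = 150/v_prox + (d − 150)/v_dist       d > 150 µm

with defaults v_prox = 4.5 µm/s and v_dist = 6.0 µm/s, plus Gaussian
jitter (SD 1 s). The apparent latency is generated directly from this law
(rather than as arrival time + rise time) so the regression stage has a
well-defined ground truth; the transient's rise time shapes the waveform
only. With these defaults a single least-squares line over 0–500 µm reads
~5.6 µm/s and all first peaks inside 500 µm occur within 120 s of onset.

First-peak amplitude is

    A(d) = A₀ · exp(−max(0, d − 100 µm) / λ)

with A₀ = 10 ΔF/F₀ and λ = 150 µm, times lognormal jitter (σ = 0.5 inside
the 100 µm plateau, emulating the wide proximal scatter; σ = 0.1 beyond
it). λ is not constrained by any published value and is exposed as a
configuration knob. A₀ sets the overall ΔF/F₀ scale, which is likewise
unreported; it is chosen so that the *dimmest* first peaks at 500 µm
(~0.7 ΔF/F₀ before jitter) still clear the 0.25-excursion responder
criterion after smoothing even for cells with many peaks (whose trace mean
is high). This self-consistency matters: in a real population the
criterion itself defines who counts as a responder, so the generator must
not label cells "responders" that its own inclusion rule would reject —
otherwise recovered class fractions are biased by distance-dependent
attrition.

### Oscillation structure

Each responder draws a peak-count class from the marginal mixture
(defaults: p₁ = .10, p₂ = .13, p₃ = .18, p₄ = .14, p₅ = .11, p₆ = .09,
p₇ = .07, p₈ = .023, p₍₎₈₎ = .157 — the 3-peak class is the mode, over
half of cells show ≥ 4 peaks). Class base frequencies are 13, 17, 22, 26,
29, 30, 33 mHz for k = 2..8 and 40 mHz for >8; base periods are their
reciprocals. A cell's own frequency is drawn from a normal around its
class value (SD 2.5 mHz) truncated from below at the smallest frequency
whose full train still fits in the 310 s post-onset window given the
cell's latency (a cell that cannot fit its drawn count at a feasible
frequency drops one peak and retries). The between-cell SD is deliberately
smaller than the ~7–8 mHz spread a real population shows: a large SD is
incompatible with the finite window — slow draws in high-count classes
could not complete their trains and would be silently reclassified,
biasing both the mixture and the class means. The observed population
spread also folds in distance trends and the refractory effect below, so
it is not a clean generator input.

Within a cell, consecutive intervals get Gaussian jitter (SD 2 s, clipped
at 6 s). The first-to-second interval additionally carries a refractory
delay proportional to first-peak amplitude (1 s per ΔF/F₀ unit), so
strongly stimulated proximal cells wait tens of seconds longer before
their second peak. Because the per-cell frequency estimate uses *all*
consecutive intervals by default (an `exclude_first_interval` flag is
provided), detected class means sit slightly below the configured base
frequencies — about 16.3 mHz for the 3-peak class against a 17 mHz base —
which is the expected signature of the refractory delay, not an estimator
defect.

### Waveform and rendering

A transient rises linearly over 6 s and decays exponentially with
τ = 15 s (a configurable ~1% of cells within 60 µm decay linearly
instead). Later peaks have amplitude 0.5 × the first (floor 0.3 ΔF/F₀,
5% lognormal jitter). Evoked fluorescence is clipped to zero before
stimulation onset (stimulus causality), and traces are returned as
raw fluorescence `F₀,cell × (1 + ΔF/F₀)` with the per-cell baseline drawn
from N(1500, 150²) intensity units.

Movie rendering paints each cell as a disk (radius 5–8 µm) at its centroid
over a background of 200 intensity units, adds Gaussian read noise
(SD 40) and stores uint16 frames; a multi-page TIFF writer is provided.
All randomness derives from one seed through per-cell substreams, so
outputs are bit-identical across runs and independent of cell order.

### Immunofluorescence images

`simulate_if_images` renders nucleus/marker channel pairs per region
(CA1, CA3, DG) and condition: ~40 elliptical nuclei per 256 × 256 image,
nucleus channel at 3000 over background 100, per-nucleus marker intensity
N(1000, 150²) plus a per-image offset N(0, 50²) and pixel noise (SD 50).
A multiplicative effect applies to the stimulated group in named regions
only, giving a programmed ground-truth effect size.

## Analysis procedures and numerical choices

* **Reference image.** Calcium movies are segmented on the temporal mean
  of the *baseline* frames: baseline brightness is activity-independent,
  so the histogram stays cleanly bimodal and responders and non-responders
  are detected alike. (A whole-movie mean boosts responding cells by their
  integrated activity, which drags an automatic threshold above the dimmest
  quiescent cells.) Nuclei are segmented directly on the counterstain
  channel.
* **Thresholding.** "auto" is Otsu's method; a numeric threshold is a
  fraction of the image dynamic range. Binarisation is followed by hole
  filling.
* **Watershed seeds.** Regional maxima of the Euclidean distance map with
  1 px h-maxima suppression; each maximum plateau contributes its deepest
  pixel (ties broken by lowest (row, col) for determinism); seed pairs
  closer than `min_separation` merge keeping the deeper seed. Objects
  failing `min_area` (20 µm²) or `min_radius` (2 µm) are dropped and the
  remainder relabelled contiguously from 1.
* **Smoothing edges.** The 9-point moving average uses shrinking windows
  at the trace ends (mean over in-range samples), keeping output length
  equal to input length and leaving constant traces unchanged.
* **Responder filter.** Applied to the smoothed trace; "peak before
  stimulation" means before the onset frame (a flag allows the stimulus
  *end* frame instead). Whether a real pipeline would apply the 0.25
  excursion rule to raw or smoothed data is ambiguous; smoothed is chosen
  for consistency with the peak analysis.
* **Peak detection.** Local maxima with prominence ≥ 0.1 ΔF/F₀ (an
  assumed floor, configurable) and width at half prominence ≥ 5 s. A peak
  whose decay runs into the recording end is judged by its rising flank
  (left-sided prominence; mirrored left half-width), because both its
  prominence and width are right-truncated; a monotonic rise at the very
  end is never counted. Peak time is the frame of the local maximum
  converted to seconds since onset.
* **Frequency.** 1000 / mean(consecutive inter-peak intervals, s), all
  intervals included by default (see refractory note above); undefined for
  fewer than two peaks.
* **Velocity.** Ordinary least squares of time on distance (not distance
  on time), overall and per segment with the breakpoint *fixed* at 150 µm;
  an optional grid-search breakpoint estimator exists but is off by
  default. Velocity is the reciprocal slope. Distal fast responders
  (synaptically driven outliers) are not trimmed; the generator's default
  fraction for them is 0.
* **Amplitude decay.** OLS on log amplitude over 100–500 µm; non-positive
  amplitudes are excluded with a warning; a non-negative slope reports
  "no decay" with infinite λ.
* **NF-κB comparison.** Equal-variance two-sided Student's t test on
  per-image region means (Welch and per-nucleus pooling available via
  flags). No background subtraction or cross-slice normalisation is
  applied.

## Problem sizes used in the tests

Population statistics are computed on 5,000-cell trace-mode simulations
(the full image pipeline is exercised on 300-cell rendered movies, and
segmentation recovery on ten 150-cell movies); these sizes give binomial
95% intervals of about ±1 percentage point on the 18% class fraction and
sub-0.5 mHz standard errors on class frequencies, which is ample for the
stated tolerances.

## Known limitations

* The generator's amplitude scale, decay length, refractory coefficient,
  between-cell frequency SD and noise levels are plausible but largely
  unconstrained by published values; recovery tests validate the analysis
  under these conditions, not the values themselves.
* Oscillation regularity is modelled as a jittered comb; real trains can
  drift in period, which would bias the interval-mean frequency estimator
  low relative to an instantaneous-rate estimator.
* The watershed assumes roughly convex, similar-scale objects; heavily
  overlapping or elongated cells would need shape-aware seeding.
* The NF-κB stage assumes registered, same-size channel pairs and
  region-pure images; region assignment from polygons on montages is not
  implemented.
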