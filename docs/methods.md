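# Methods

This note documents the models, numerical choices and limitations of
the `fibwave` analysis chain and its synthetic ground-truth
generator.

## Electrode geometry

Recordings are assumed to come from a rectangular lattice of unipolar
contact electrodes.  The default array (`default_mapping_grid`) is a
16×16 lattice at 2.5 mm spacing with seven corner sites masked,
giving 249 active electrodes — the electrode count and spacing of the
reference mapping hardware; the physical arrangement of that array is
not publicly specified, so the layout is configurable via mask files
and each atrium is treated as an independent grid carrying a region
label.  The neighbor relation is the 8-neighborhood: four orthogonal
links at `spacing` and four oblique links at `spacing·√2`.  The
periphery is the set of active electrodes with fewer than eight
active neighbors, which on a full rectangle reduces to the outer
ring.

Activation times are kept in milliseconds as floating point; at the
1,039 Hz hardware sampling rate the native resolution is
1/1.039 ≈ 0.962 ms per sample.

## Conduction block and the 12/17 ms limits

Block between adjacent electrodes is declared when the apparent
velocity `distance / Δt` falls below `v_block` (default 20 cm/s).
The limit returned by `max_at_difference` is the largest *whole
millisecond* delay not violating the threshold,
`⌊distance / v_block⌋`: at 2.5 mm and 20 cm/s the floors of 12.5 and
17.68 ms reproduce exactly the printed 12 ms (orthogonal) and 17 ms
(oblique) limits.  The floor rule makes the operation non-increasing
in `v_block` and non-decreasing in spacing.

## Activation-time detection

The detector marks the steepest negative slope of each unipolar
electrogram.  Implementation:

1. first difference of the signal, scaled to mV/ms, smoothed with a
   centered moving average of `smooth_ms` (default 2 ms, matched to
   the deflection width) so that sample-to-sample noise does not
   dominate the slope estimate;
2. candidates at local minima below `−k·1.4826·MAD` of the channel's
   derivative (`k = 4`); MAD-based thresholding is amplitude
   invariant, and a small absolute epsilon keeps flat channels empty;
3. non-maximum suppression within a refractory period (default
   40 ms, below any plausible atrial refractory period) keeping the
   steeper candidate;
4. sub-sample refinement by parabolic interpolation of the derivative
   minimum.  This step matters: without it, plane fits on planar
   waves inherit a staircase bias from the sample grid and median
   speed errors reach ~8% at 80–120 cm/s; with it they fall below
   0.5%.
5. an optional periodicity prior (off by default) iteratively
   re-scores candidates by slope magnitude × a Gaussian likelihood
   around the channel's running cycle-length estimate.  On compound
   AF episodes with per-cycle random block lines the per-electrode
   timing is genuinely aperiodic and the prior is not discriminative,
   which is why it is not enabled by default.

The upstream detector used with the reference hardware is external
and unpublished in detail; this scheme reproduces its observable (AT
maps) with every constant exposed in configuration.

## Ventricular far-field handling

Beats are located on a dedicated ventricular reference channel at the
dominant excursion from the baseline median, with a 300 ms refractory
period; candidate peaks below 60% of the median peak amplitude
(T waves, atrial far-field) are rejected.  Cancellation subtracts a
per-channel averaged-beat QRST template at each fiducial over a
(−100, +500) ms window (sized for the equine QT of ≈500 ms).  With
three or more complete beats the template is the sample-wise *median*
across beats rather than the mean: atrial deflections are sparse and
asynchronous with the ventricular beat, so the median suppresses
their leakage into the template, which with few beats would otherwise
re-inject inverted deflections at every fiducial.  Optional per-beat
least-squares amplitude scaling accommodates beat-to-beat far-field
amplitude variation.  Samples outside beat windows are never
modified, and overlapping windows give precedence to the earlier
beat.  Cancellation is applied at every detected beat by default;
gating to "doubtful" beats only is available by passing a restricted
beat list.

## Conduction velocity, anisotropy, dissociation, AFCL

Local CV at an event is a least-squares plane
`T(x, y) = a·x + b·y + c` over the event and the nearest-in-time
activation of each direct neighbor within that relation's block limit
(conducted neighbors only).  The estimate is invalid with fewer than
3 conducted neighbors (rank requirement of the 3-parameter fit), with
a gradient below 10⁻⁶ ms/mm (simultaneous activation), or with
degenerate (collinear) neighbor geometry.  Speed is `100/√(a²+b²)`
cm/s; the reported direction `atan2(b, a)` is the direction of
propagation (the activation-time gradient points along travel).

Anisotropy per electrode is the mean resultant length `R̄` of the
valid conduction-direction unit vectors (1 = fixed preferential
direction, 0 = isotropic; circular variance `1 − R̄`), requiring at
least 3 valid estimates.  Directions are pooled over the whole
analysis window by default; callers can window the estimates
themselves before pooling.

Dissociation is `100 × blocked / paired` neighbor links.  Pairing
uses mutual-nearest matching within half the running cycle-length
estimate (to avoid cross-cycle pairing).  AFCL per electrode is the
median of successive inter-activation intervals (≥3 activations);
regional AFCL is the median of electrode values.  Wavelength is
`WL = ERP × CV`, returned in mm for ms and cm/s inputs.

## Waves, conduction paths, re-entry

Fibrillation waves are connected components of the event graph
(events at neighboring electrodes linked iff `|Δt| ≤` the relation's
limit).  Because the limits (≤17 ms) are far below the AFCL, cycles
separate naturally and no explicit cycle segmentation is imposed.
The earliest event of a wave decides its origin class — peripheral on
the array edge, breakthrough strictly inside — with simultaneous-time
ties broken toward peripheral.  Waves spanning fewer than 3 distinct
electrodes are filtered out and logged.  Counts are normalized as
`n × mean_AFCL / window`, and the breakthrough fraction is reported
as missing when there are no waves.

A wave's conduction path is computed on the directed version of its
event graph (edges run from earlier to later event, `Δt = 0` ties
oriented by electrode index; each step implies an apparent velocity
at or above the block threshold).  The trajectory is the
minimum-total-spatial-length path from the earliest to the latest
event ("start and end point" of the wave; spatial extremes were
rejected as inconsistent with trajectory continuity).  When wavefront
fusion makes the latest event unreachable through time-forward links,
re-entry detection falls back to the latest *reachable* event rather
than failing.

A local re-entry is a trajectory that revisits an electrode after at
least 75% of the mean AFCL; `n_revolutions` counts qualifying
revisits at the most-revisited electrode (matching the "maximal
rotation" reading).  The fraction of time re-entry is present uses
the union of the qualifying trajectories' time spans over the
analysis window — the choice made for simultaneous re-entries, which
is not otherwise specified.  On an ideal rotor of `n` cycles the path
from the first to the last event winds `n` times, giving exactly
`n − 1` qualifying revisits.

## Synthetic generator

Propagation is **earliest arrival on the lattice graph**, not a PDE
or eikonal continuum solver: edge traversal time is edge length /
speed, multiple sources compete by minimum arrival, and a
per-electrode refractory floor absorbs later arrivals (collision and
fusion).  This produces exactly the observables the analysis consumes
— activation times — with exact ground truth per event, at the price
of lattice-metric anisotropy in the wavefront shape (octagonal rather
than circular focal wavefronts).  Speeds may be a scalar or an
`(vx, vy)` pair; with a pair the link speed is the elliptical
`√((vx·cosθ)² + (vy·sinθ)²)`, giving a fixed anisotropy ratio.

Ground-truth *wave* labels are defined by applying the same
block-limit boundary rule to the noiseless true activation times:
waves are a construct of the observed activation map, so this is the
only self-consistent truth definition.  The generator computes the
labels with a scipy connected-components code path that is
independent of the networkx-based reconstruction in the analysis
module, so exact agreement between the two is a genuine two-route
check.

The compound AF episode launches one planar wavefront per cycle from
a random array edge (period = mean AFCL with Gaussian interval
jitter), adds Poisson focal breakthroughs from random interior sites,
and draws fresh random block walls each cycle.  Defaults — mean AFCL
185 ms, speed 80 cm/s, 1 focal breakthrough/s, 2 block walls of 5
lattice steps, 5 ms jitter — are chosen to resemble persistent-AF
epicardial maps in a large-animal atrium at baseline.  A rotor is
modeled ideally: activation phase proportional to the polar angle
about an interior core electrode (which stays silent, as the
functional pivot), with per-electrode cycle length exactly the
period.

Electrogram synthesis adds, per activation, a biphasic
derivative-of-Gaussian deflection (σ = 2 ms, 1 mV peak-to-peak,
steepest negative slope exactly at the AT).  The ventricular
far-field is a channel-identical synthetic QRST waveform (Gaussian R,
σ 15 ms; Gaussian T, σ 40 ms; 600 ms support; default RR 1,200 ms —
anesthetized-horse range) added at regular beat times and scalable
per beat and per channel; channel-identity makes averaged-template
cancellation exact in the noise-free case and is therefore a clean
oracle, at the cost of not modeling spatial far-field gradients.  A
clean ventricular reference channel is appended.  Optional
acquisition filters apply the hardware chain (first-order 0.56 Hz
high-pass, then 408 Hz low-pass, causal); they are off by default so
that noise-free fixtures stay analytically exact.  All randomness
derives from a single integer seed and is bit-reproducible.

What the generator does *not* emulate: ionic/cellular dynamics and
drug pharmacodynamics (drug effects enter only as parameter changes —
slower speed, longer cycle length, more block), curved continuum
wavefronts, electrode contact artifacts, baseline wander beyond the
first-order filters, 50/60 Hz interference, and spatially varying
far-field morphology.  Passing tests therefore demonstrate
correctness of the analysis operators on their defined observables,
not robustness to every artifact of in-vivo recordings.

## ECG intervals and QTc

ECG intervals are measured over 10 consecutive RR intervals
(requiring 11 detectable beats).  Per beat, the baseline is the
median of a pre-QRS segment; Q onset and S offset are the 5%-of-R
amplitude crossings walking out from the R peak; the T end uses the
tangent method — the steepest post-peak tangent of the T wave
extrapolated to the baseline (for a Gaussian T wave of width σ this
lands exactly 2σ after the peak, which the tests exploit as a
closed-form oracle).  Beats with an undetectable T wave are excluded
and counted.  Heart rate is `60000 / median RR`.

QT is rate-corrected by a continuous piecewise-linear model
`QTc = QT − (intercept_i + slope_i·HR)`; continuity across
breakpoints is validated at load time and the shipped default is the
identity placeholder, because piecewise correction coefficients are
population-specific and not publicly printed for the reference
population — users must supply their own via configuration.

## Summary tables and statistics

Group summaries report median and IQR (Q3 − Q1) with
linear-interpolation (type-7) quantiles — the convention is a
documented choice, since none is stated upstream.  Groups with fewer
than 4 observations are flagged and excluded from comparison.
Inferential statistics (repeated-measures ANOVA, post-hoc tests,
normality checks) are deliberately out of scope; the pipeline emits
tidy tables consumable by any statistics package.

## Problem sizes in the tests

The test fixtures are desk-scale by design: compound episodes of
2–6 s on the 249-electrode array (the reference mapping files span
10–60 s), 20 seeds for noise-free wave-count checks, SNR-10
electrogram runs with 8–9 ventricular beats (enough for a robust
median template), and 100 random lattices up to 10×10 for the
arrival-time oracle.  These sizes keep the full suite around ten
seconds while exercising every code path; all quantities scale with
recording length, not with any constant baked into the code.

## Known limitations

- The event-graph wave definition cannot distinguish a true block
  line from fast simultaneous activation on both sides (|Δt| below
  the limit across a physical block); ground truth shares this
  observable-level definition by construction.
- Re-entry detection follows the single-trajectory definition; phase
  mapping / phase-singularity methods are out of scope.
- Plane-fit CV assumes local planarity over the 3×3 neighborhood and
  degrades near wave collisions and block lines (estimates there are
  flagged invalid rather than extrapolated).
- The breakthrough class covers any wave starting inside the array;
  the generator cannot distinguish transmural from focal origin, and
  neither can the analysis.
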