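# Methods

`vftrig` analyzes optical-mapping recordings of ventricular tissue carrying
a *localized repolarization heterogeneity* — a region whose action
potential duration (APD) has been pharmacologically shortened (e.g. by
regional perfusion of the K_ATP opener pinacidil) — and characterizes the
spontaneous ventricular-fibrillation (VF) triggers such a substrate
produces.  Because no public dataset of this kind exists, the package
includes a synthetic-preparation generator whose defaults encode the
physiology of the pinacidil-perfused porcine right ventricle; every
analysis stage is validated by recovering the generator's known ground
truth through the full simulate → acquire → measure chain.

## The electrical substrate model

Tissue is a 2D monodomain sheet

    dV/dt = D ∇²V + h V²(1 − V)/τ_in − V/τ_out + I_stim(x, t)
    dh/dt = (1 − h)/τ_open            if V < V_gate
          = −h / (s(x) · τ_close)     otherwise

a two-variable excitable medium (Mitchell–Schaeffer form) with no-flux
boundaries, integrated by explicit forward Euler.  The recovery gate h
controls APD; the per-pixel scaling field `s(x)` multiplies the
gate-closing time constant, so `s < 1` shortens the local APD.  A
two-variable model was chosen deliberately: the scientific object here is
the *measurement pipeline*, and ground-truth control of APD matters more
than ionic realism.  Consequences of that choice are documented under
*Limitations*.

Defaults (units ms, mm):

| parameter | value | why |
|---|---|---|
| grid | 128×128 px, dx = 0.39 mm | the camera resolution of the emulated experiment (≈50×50 mm sheet) |
| D | 0.3 mm²/ms | gives conduction velocity ≈0.58 mm/ms, typical of ventricular epicardium |
| τ_in, τ_out, τ_open | 0.3, 6, 120 ms | standard excitable-medium values |
| τ_close | 158.5 ms | calibrated so normal-tissue APD80 ≈ 270 ms at 500-ms pacing |
| dt | 0.05 ms | well inside the diffusion stability limit dx²/4D ≈ 0.127 ms |
| frame interval | 1 ms | the emulated camera rate (movie downsampled from dt) |

### APD calibration

`s` is obtained by inverting a tabulated single-cell (0-D) curve of
steady-state APD80 versus scaling, computed at the protocol's pacing cycle
length (APD restitution makes the paced steady-state APD shorter than the
fully rested one, so calibrating at the protocol rate is essential).
Electrotonic coupling in the sheet additionally pulls the short-APD disc
toward its long-APD surround by ~10–15 ms; `calibrated_lesion_field`
removes this with a single Newton correction: one short paced probe
simulation measures the realized APD map, and the residual (target −
realized, smoothed) is added to the target before re-inverting.  The
correction is cached per configuration.  After it, the realized
core-minus-remote APD difference matches the prescribed −89 ms to ~1 ms.

### Lesion geometry

The lesion is a disc (default radius 7.71 mm ≈ 7.5% of the sheet,
≈1.9 cm²) with full shortening ΔAPD = −89 ms inside
`radius − w_b/2`, a linear radial ramp of width `w_b = 5.6 mm` across the
border, and zero outside; the "true border" contour is the circle at
`radius`, mid-ramp.  The ideal maximal border slope is therefore
|ΔAPD|/w_b ≈ 15.9 ms/mm.  Normal tissue additionally carries a weak linear
background gradient (default 1.5 m s/mm), zero-centered on the sheet.
Because half of the sheet then needs APD *above* the 270-ms baseline, the
scaling field exceeds 1 there (up to ≈1.2); the calibration table covers
s ∈ [0.15, 1.3], beyond which the paced steady state begins to destabilize.

### Ectopic triggers

The default trigger mechanism is *injected*: a suprathreshold stimulus at
a known border-zone site (default 1.2 mm inside the mid-ramp contour, at a
seeded random angle), which makes the origin, its timing, and its local
substrate exactly known for recovery tests.  Placed-by-rule ectopics are
short *arcs* along the border (half-angle 30°, half-width 1.4 mm) rather
than points: a point source confined to the recovered short-APD band
produces no measurable far-field ECG deflection, whereas the spatially
extended source — consistent with reexcitation arising along a border
zone — is visible at any realizable coupling.  Capture is scored as a
fresh upstroke (resting-to-depolarized transition) in undriven pixels of
the border band at the source radius; spillover into the earlier-recovered
core alone does not count, so every accepted trigger genuinely propagates
along the border zone.  Explicitly sited ectopics (used in refractoriness
tests) remain point stimuli.

The commanded coupling interval is drawn from N(297, 66²) ms clipped to
[140, 460] ms (the experimental trigger statistics).  Because "coupling
interval" is an ECG-level quantity, the stimulus time is adjusted in a
closed loop: the episode tail is re-simulated from a cached state
snapshot, the pseudo-ECG is re-analyzed *with the pipeline's own beat
detector*, and the stimulus is moved until the detected coupling matches
the drawn value (tolerance 1 ms by default and configurable — recovery
studies that are insensitive to trigger timing may relax it — with ≤4
iterations, forward 1–2-ms stepping out of refractory tissue, and
best-attempt tracking where the response is flat or discontinuous).  Two
physical floors remain and are reported honestly rather than hidden: a
stimulus cannot capture before local recovery (~230 ms at the default
site), and a confined wave only becomes ECG-visible once it can
propagate, so drawn couplings below ~250 ms pile up near the floor.
Individual realized couplings near the floor can also deviate by a few
tens of ms where the onset regime of the PVC complex changes; these
deviations are close to symmetric, and over 50 episodes the measured mean
lands within a few ms of the commanded 297 ms.

A single injected trigger in this substrate produces at most a short
reentrant echo (cycle ≈285 ms), not self-sustained sub-250-ms VF — a
known property of two-variable media at this heterogeneity strength.
Multi-cycle fibrillatory episodes (including deliberately sustained ≥8-s
ones) are constructed with the repetitive-trigger *burst* mode
(`n_ectopics > 1`, jittered ~225-ms intervals), which mirrors the
experimentally observed repetition of border-zone breakthroughs.  An
*emergent* mode (weak sustained injury-like border current) exists
best-effort, without timing guarantees.

### Acquisition and pseudo-ECG

Fluorescence rendering applies per-frame Gaussian blur (σ = 1 px),
min-max normalization of the initial segment to [0, 1], exponential
amplitude rundown (default 10%/min, emulating photobleaching under
continuous illumination), additive white noise (default sd 2% of the AP
amplitude) and a seeded set of dead (noise-only) pixels (0.5%).

The pseudo-ECG is the standard unipolar infinite-volume-conductor
far-field signal Φ(t) ∝ −Σ ∇V · ∇(1/r) dA, electrode 20 mm above the
sheet center, baseline-zeroed.  The electrode geometry of the emulated
experiment is not documented; the unipolar formulation is the
conventional default.  Ground truth records per-beat true activation
(50%-upstroke crossing of the clean voltage) and APD80 maps, the lesion
contour, and the trigger site/time/couplings.

## Analysis pipeline

**Conditioning** — sliding-minimum baseline removal (700-ms window,
smoothed), movie-wide polarity correction, optional Savitzky–Golay
temporal smoothing (7 ms, order 3; disabled in oracle tests).

**Maps** — activation = time of maximum dF/dt (parabolic sub-sample
refinement; a 50%-upstroke alternative is a switch); APD80 = interpolated
fall to 20% of the beat amplitude above the pre-upstroke diastolic
median, minus AT; RT = AT + APD80 exactly.  The repolarization search may
extend up to 420 ms past the beat window; a pixel re-excited before
reaching 80% repolarization yields no APD and is masked, as are pixels
with amplitude/noise below the SNR gate (default 5) — the analogue of the
"noisy" pixels excluded from experimental maps.  Because a premature
complex truncates repolarization around its own origin, substrate maps
for trigger characterization are taken from the latest *complete* beat
(the second-to-last before the trigger), which at steady-state pacing is
statistically identical to the last.

**Gradients and border** — maps first pass a 3×3 nan-median filter:
per-pixel APD estimates carry sparse impulse-like outliers that would
otherwise bias the gradient *magnitude* upward, and the median (exactly
unbiased on linear ramps) removes them while repairing isolated dead
pixels from their neighbors.  Gradient magnitude is then central
differences on a Gaussian-presmoothed map (σ = 1 px, normalized
convolution over valid pixels) divided by the pixel pitch; pixels whose
stencil touches clustered invalid regions are masked.  The estimator is
exact (<1%) on linear ramps of any orientation.  The short-APD region is
segmented on the same median-repaired map at an inter-mode minimum of its
smoothed histogram; because the short-APD mode may hold only a few
percent of pixels, sit at the histogram's edge, or compete with spurious
valleys inside the broad normal mode (removing the lesion's pixels leaves
a hole in the background-gradient distribution), all candidate valleys
are ranked by separation and screened by the plausibility of the
resulting mask (the short-APD region is the minority class); Otsu with a
separability check is the fallback and a manual threshold handles
non-bimodal maps.  The border zone is everything within 3.5 mm
(inclusive) of the boundary contour.

**Events** — beats are slope-feature peaks (8-ms smoothed |derivative| of
the 80-ms high-passed trace — the high-pass suppresses T waves, which are
prominent over a steep repolarization substrate) above an adaptive
threshold (10% of the median of the five tallest candidate deflections,
robust to a single very tall deflection, to the QRS duty cycle and to
long quiet segments); a beat's onset is the leading threshold crossing of
its contiguous supra-threshold activity, with ≤30-ms gaps bridged so that
a weak focal deflection and the later bulk sweep date as one complex.  PVCs are
non-paced beats earlier than 90% of the prevailing cycle (median of the
last five non-PVC intervals).  T-wave end uses the tangent method, with a
template from an earlier clean beat when the PVC obscures its own T wave.
VF = ≥4 consecutive cycles <250 ms with cycle-length CV > 0.1 (an
operational ECG-level rule; thresholds exposed); sustained ⇔ duration ≥
8 s (inclusive); spontaneous ⇔ pacing ≤ 2 Hz at onset (inclusive) and no
programmed extrastimulus within the preceding 2 s.

**Trigger localization and phase** — the trigger origin is the centroid
of the earliest-activated 1% of valid pixels of the trigger beat's AT
map; activation detection rejects window-edge maxima and traces already
elevated before the putative upstroke (the previous beat's plateau tail),
and a relative-amplitude gate (25% of the cohort's median beat amplitude)
excludes noise-only pixels whose SNR alone sits near the gate.  Phase is
the angle of the Hilbert analytic signal of the moving-mean-subtracted
trace, spatially smoothed in the complex domain (σ = 1 px) so acquisition
noise does not seed spurious short-lived singularity pairs; singularities
are 2×2 plaquettes with ±2π
winding, linked into tracks by nearest-neighbor association (3 px/frame
gate); an early-VF cycle is a "rotor" when a track overlapping it
persists at least one cycle length, otherwise a focal "breakthrough".
Analysis is restricted to the first ~5 post-trigger cycles, where optical
signals remain trustworthy under rundown.

**Statistics** — Shapiro–Wilk (α = 0.05) routes two-group comparisons to
t or rank tests; >2 groups use Kruskal–Wallis with Holm–Šidák-adjusted
pairwise rank sums; 2×2 tables use the two-sided Fisher exact test
(validated in-repo against a hypergeometric enumeration oracle).
Narrative rounding: means to one decimal, percentages and counts to
integers.

## What the generator does and does not emulate

It emulates: a localized graded APD-shortening substrate with realistic
size and gradient magnitudes, regular pacing or an intrinsic ~1.5-Hz
rhythm, border-zone ectopy with the experimental coupling distribution, a
far-field ECG with QRS/T morphology and PVCs, optical blur, noise,
rundown and dead pixels.  It does not emulate: 3D/transmural propagation,
anisotropic fiber architecture, motion artifact, ionic mechanisms of
K_ATP activation, spiral-wave breakup or the tissue-level mechanism that
converts a border ectopic into sustained fibrillation (episodes are
constructed, not emergent).  Passing recovery tests therefore demonstrate
that the *measurement chain* is unbiased under controlled conditions, not
that the model reproduces the full arrhythmia dynamics of real tissue.

## Numerical and design choices

- Explicit Euler with dt 0.05 ms; simulate() rejects steps beyond the
  stability limit.  Halving dt moves activation times by <0.5 ms.
- All randomness flows from a single integer seed (`numpy` Generator /
  `SeedSequence` spawning); identical seeds give byte-identical artifacts.
- The paced phase of an episode is independent of the episode seed and is
  cached (state + frames) across same-configuration episodes.
- Problem sizes in tests and in the acceptance script (10 preparations for
  map/gradient recovery, 50 coupling episodes in the acceptance script and
  28 in the test suite, mid-size grids for unit tests) were chosen as the
  smallest sets whose sampling error is well inside the recovery
  tolerances.
- Ties and degenerate inputs: activation picks the earliest
  supra-threshold upstroke; flat traces/windows yield absent values, not
  errors; a fully masked map, an empty site group, or a non-bimodal APD
  histogram raise informative errors.

## Known limitations

- The two-variable medium has no spike-and-dome morphology, so phase-2
  reexcitation is injected rather than emergent; the *emergent* mode is a
  crude injury-current stand-in.
- Realized coupling intervals cannot fall below the tissue's recovery +
  visibility floor (~250 ms at default calibration); the experimental
  range reached 140 ms, plausibly via stronger regional shortening than
  the −89-ms mean simulated here.
- Gradient magnitudes depend mildly on the estimator's smoothing scale;
  the default (σ = 1 px) is unbiased on the synthetic ramp but any
  reported ms/mm value carries this scale dependence.
- The bimodal border threshold assumes one dominant short-APD region;
  multi-lesion preparations need the manual threshold.
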