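# Methods

`olcam` reconstructs, as a tested pipeline, the analysis chain used to
study microdomain Ca²⁺ signalling in oligodendrocyte-lineage cells
(OLCs) of awake, head-fixed mice on an air-lifted homecage: dual-channel
two-photon movies (GCaMP green + tdTomato red) are motion-corrected,
segmented into Ca²⁺ microdomains (CaMs), scored for Ca²⁺ events on
z-scored, artifact-corrected traces, and aligned with locomotion
behavior; a separate branch stages cells along the oligodendrocyte
lineage from 2D morphology. Because the original in vivo recordings are
not publicly deposited, a synthetic-session generator with full ground
truth is a first-class component: every stage is validated closed-loop
against what the generator put in.

## Preprocessing

**Registration.** Rigid, integer-pixel translation per frame, estimated
by FFT phase correlation of the red channel against the median-intensity
projection of the red stack. The red fluorophore is Ca²⁺-independent, so
the reference is unaffected by activity. The same shift corrects both
channels. The median projection is computed on an even temporal
subsample (at most ~1000 frames), which is statistically equivalent for
a static scene and much cheaper. Sub-pixel motion is out of scope; the
estimator returns integers and the correction replicates edge pixels.

**Traces and z-scoring.** Per-CaM traces are the mean of member pixels
per frame. Each trace is flattened by least-squares *linear* detrending
and z-scored with the mean and SD of the whole detrended trace. A
constant trace yields an all-zero z-trace with a `degenerate` flag,
never a division error. A robust variant (median / 1.4826·MAD) exists
behind `robust_zscore` for event-rich traces whose transients inflate
the SD; the full-trace statistics remain the default. Note one
consequence used throughout validation: with long-duration or
high-rate activity the trace SD contains the events themselves, so the
*measured* z amplitude of an event depends on the session's duty cycle,
not only on the underlying signal.

**Ratiometric correction.** Rapid fluorescence changes shared by the
Ca²⁺-independent red channel are movement artifacts. The red trace is
z-scored per CaM and subtracted from the z-scored green trace. The
subtraction is done in z units because the two fluorophores have
incommensurate brightness; whether the original procedure subtracted
raw or normalised traces is not stated, so the z-unit form is a
documented package decision. The cost is that the corrected trace
carries the red channel's unit-variance noise; the benefit is that
shared artifacts cancel almost exactly (validated: ≥80% artifact
suppression with <10% event-amplitude change on simulated shared
pulses).

## Microdomain segmentation

The per-pixel activity score is the maximum over time of the pixel's
detrended, z-scored trace after ~1 s temporal smoothing (boxcar of
`frame_rate/smooth_hz` frames). Pixels with score ≥ 3 z form the
foreground; 8-connected components smaller than 1 µm² are dropped;
touching hotspots are split by watershed on the spatially smoothed
score, seeded at local maxima at least 2 µm apart. Every connected
component is guaranteed at least one watershed seed (distance-based
peak suppression can otherwise silently erase a weaker component). All
values are configurable; the same logic serves 5 Hz (0.17 µm/px) and
15 Hz (0.33 µm/px) data. For noisy data that hyper-segments (e.g.
noradrenergic fiber imaging), user-drawn masks bypass segmentation via
`load_manual_rois`. The original pixel classifier behind the published
CaM maps is described only in prior work; this activity-score
substitute is validated against the generator (single-footprint IoU
≥ 0.7, mean recovered area within 20% of the configured mean).

## Event detection

**Core (5 Hz) rules.** Candidate peaks are strict local maxima above
5 z (strictly greater), with plateaus taking their first frame and a
minimum peak separation equal to the duration floor. Each peak is
bracketed: the onset bracket is the last frame before the peak with
z < 1; the offset bracket is the first frame after the peak where z ≤ 1
for two consecutive frames, or where the trace falls back within 10% of
the onset value, whichever comes first (fallbacks: frame 0 / last
frame). The stored event is the contiguous run of frames at or above
1 z containing the peak — the bracket minus its sub-threshold end
frames — and must span at least 4 frames. Defining the event on the
elevated core makes the 4-frame duration floor act on the time the
signal is actually elevated (a 4-frame pulse is the shortest retained
pulse; a 3-frame pulse is rejected) and makes `duration_s` equal to the
elevated time. Overlapping candidates keep the higher peak. The "within
10% of the starting point" offset clause is ambiguous when the onset
value is near zero; the implementation uses the amplitude-relative form
z(t) ≤ z(onset) + 0.10·(z(peak) − z(onset)), which is scale-free and
never divides by zero; the literal reading is available via
`offset_mode="literal"`.

**Fast (15 Hz) variant.** Traces that never reach 7 z are excluded as
inactive or too noisy. Detection then runs twice: on the raw trace
(duration filter deferred, so noise-fragmented slow events are not
discarded prematurely) and on a zero-phase 4th-order Butterworth 1 Hz
low-passed copy. Raw detections provide event timing; raw fragments
closer than 0.2 s (strictly) are fused, transitively, into single
events — the hyper-segmentation repair. Low-passed detections that
overlap no raw event contribute slow events at the filtered bounds.
Amplitude (>5 z) and duration (≥4 frames) filters are re-applied on the
raw trace at the end. Preferring raw bounds keeps a 0.33 s transient at
its true ~0.33 s duration instead of inheriting the low-pass smear; the
filtered band exists to catch slow events the raw trace fragments. The
4-frame floor is kept at 15 Hz (0.27 s), where it is the documented
default rather than a restated rule.

## Behavior segmentation

The bout threshold is mean + 1 SD of the whole-session speed, bout
samples included (the rule as stated; it makes the threshold
activity-dependent, which is accepted). Maximal super-threshold runs
are candidate bouts; candidates whose peak never exceeds 20% of the
session maximum are discarded as pseudo-bouts. Survivors are extended
by 2.5 s (configurable) to absorb residual locomotion-driven Ca²⁺
activity; extensions are clipped at the next bout's raw start and
overlapping extended bouts merge. Resting periods are maximal
sub-threshold stretches outside all extended bouts lasting ≥ 30 s; each
speed sample is taken to cover one sampling interval, and one sampling
interval of slack is allowed on the duration so a gap constructed to
last exactly 30 s is not lost to boundary rounding. Time inside bout
extensions never counts as resting. One consequence worth knowing: in a
fully quiescent *noisy* session the threshold sits inside the jitter
noise and no 30-s uninterrupted sub-threshold run exists, so such
sessions have no formal resting periods; whole-session rates are the
appropriate quantity there.

## Event–behavior alignment and summaries

Events are labelled by the behavioral state at their *onset*: active
inside an extended bout, resting inside a resting period, otherwise
unclassified. Per cell and phase the summary reports events/min, active
CaMs/min (distinct CaMs with ≥1 event divided by phase minutes),
events/min/CaM, amplitude and duration statistics, and inter-spike
intervals pooled across the cell's CaMs within each phase (the only
reading consistent with sub-second ISIs at tens of active CaMs per
minute). The A/R ratio is active over resting events/min; a cell is
locomotion-responsive (LR) iff A/R strictly exceeds 1.5, else LNR;
undefined without resting minutes. The 4-s neuronal response window is
closed at both ends and the ≥50%-of-bouts criterion is inclusive.

**Response latency.** The bout-aligned response is the
gaussian-smoothed event-onset rate (the onset kernel is unbiased; the
active-CaM-extent kernel, available for display, lags by about half an
event duration). The latency is the first post-onset time the response
reaches half of its rise, with the plateau estimated as the 60th
percentile of the post-onset window (the window maximum rides on noise
and biases the crossing late) and the baseline excluding the 0.5 s
before onset into which smoothing leaks. A plain argmax is ill-defined
for sustained responses — after the rate switch the expected response
is flat, so the argmax lands uniformly over the plateau — which is why
the half-rise form is used. Single-bout latencies at realistic OPC
rates are high-variance; the session-averaged response is the reliable
estimator and is what the validation asserts on (recovering a 3.6 s
configured lag to ±0.5 s, and a 0.3 s lag at 15 Hz sampling to ≤0.5 s).

## Morphology staging

Three features from a manually segmented soma and the root points of
the primary processes: soma area (pixel count × pixel size²); soma
circularity 4πA/P², with the perimeter measured as the length of the
traced boundary polygon after a short (5-vertex) circular smoothing of
its vertices — the raw staircase polygon biases circularity low for
smooth shapes, and this corner correction keeps a rasterised disk at
≈1.0 while a square stays near its continuous π/4 limit; and branch
spread, the *population* standard deviation of consecutive inter-branch
arc distances expressed as fractions of the soma circumference (roots
snapped to the boundary polygon and ordered along it). The population
form keeps the statistic in [0, 0.5] for any root configuration. The
staging cascade is: circularity ≤ 0.72 → OPC (also OPC if the soma is
small, ≤52 µm², with high spread, ≥0.17); ≤ 0.83 → pmOL1; ≤ 0.92 →
pmOL2; above that OL if spread < 0.045, else pmOL2. Values exactly on
a cut go to the less-differentiated class. The published cut values are
not printed anywhere; these defaults are calibrated on the synthetic
morphology generator, are fully configurable, and make no claim about
the original thresholds. Closed-loop validation stages ≥90% (in
practice 100%) of 50 synthetic cells per class correctly.

## Synthetic-session generator

The generator emulates the *statistical* structure of the recordings —
not their optics. Defaults are the reported in vivo statistics:
footprint areas gamma-distributed with mean 4.64 µm² and SD 3.33 µm²
(gamma keeps the support positive; draws below the 1 µm² analysis floor
or too large for their grid cell are redrawn, so every ground-truth CaM
is in principle segmentable); per-cell Poisson event rates of 24.89
(resting) and 86.16 (active) events/min, switching 3.6 s after bout
start and back the same lag after bout end (a single fixed lag, not a
convolved kernel, because a single latency statistic is being
emulated); amplitudes ~N(8.6, 1.2) z; durations ~N(1.3, 0.5) s
truncated below the detector's 4-frame floor — the reported duration
statistics are themselves measured after that floor, so a generator
calibrated to them must draw from the post-floor distribution
(untruncated draws would place ~9% of events below the floor by
construction and the configured rate could not be recovered by any
implementation of the stated rules). Events are rendered as a 2-frame
linear rise followed by exponential decay with τ = duration/3, chosen
so the 1 z-crossing duration of a detected event approximates the
configured duration. Amplitudes are expressed in units of the per-pixel
noise SD (1 z ≡ 1 noise SD; one raw unit in the noiseless limit).

A cell is one field of `n_microdomains` CaMs (default 40; the reported
per-cell and per-CaM rates imply roughly 57–71 CaMs per cell, and 40
keeps per-CaM collision rates realistic while keeping the default movie
tractable), laid out on a jittered grid with a motion margin. The green
channel is baseline + faint static footprints + events + linear drift +
Gaussian noise (per-pixel; a Poisson shot-noise mode exists behind
`shot_noise` — detection operates on z-scores, where the Gaussian
regime is the relevant one); the red channel has bright static
footprints and the same drift/noise statistics but no events. Both
channels undergo the same rigid integer random-walk motion, clipped to
±`motion_amp_px` and re-centred on its modal position so that the
median-projection registration reference coincides with the unshifted
scene. Speed traces sample at 20 Hz: half-normal jitter (σ = 2 mm/s)
during quiescence and 60 mm/s raised-cosine-edged square bouts
(defaults: four 60-s bouts in a 600-s session, evenly spaced with
jittered starts) — chosen so the mean+1SD threshold sits well below
bout speed yet far above baseline jitter, as in typical recordings.

All randomness flows from one integer seed through a fixed
`SeedSequence` spawning scheme (speed, layout, events, noise/motion);
identical config and seed reproduce sessions bit for bit.

**What the generator does not model** — and hence what passing tests do
not establish about real data: optics (no PSF, no depth attenuation),
neuropil or background contamination, sub-pixel or non-rigid motion,
bleaching beyond a linear drift, amplitude–state coupling (the reported
amplitudes do not differ between phases, so the generator keeps the
amplitude distribution phase-independent), inhibitory coupling or
synchrony between CaMs, and 3D structure. Recoveries quantify the
pipeline's faithfulness to its own rules under realistic statistics,
not biological discovery power.

## Validation conditions and problem sizes

Rule cut-offs (4 frames, 5 z, 7 z, 0.2 s, 20%, 2.5 s, 30 s, A/R 1.5,
50% of bouts) are recovered exactly by grid scans over constructed
inputs. Rate recoveries run the full movie pipeline (simulate →
register → segment → extract → correct → detect → behavior → align) on
10-min single-cell sessions at the default rates; the acceptance script
averages 20 seeds per condition, the routine test suite 8. Expected
systematic offsets at the active rate: the 3.6-s onset lag dilutes the
active-labelled window by a few percent, and same-CaM event collisions
at active rates merge a few percent of events — both inherent to the
stated rules, together staying within the 15% acceptance band. Area
recovery segments 200 footprints across four 300-s fields at the
default 0.17 µm/px with per-CaM event rates matched to the in vivo
default. Morphology staging uses 50 synthetic cells per stage. These
sizes are the package's validation choices and are all configurable.

## Known limitations

- Detection merges same-CaM events whose elevated cores touch; at
  per-CaM rates far above the defaults the recovered rate
  underestimates accordingly (the original workflow faced the same
  limit for neurons and addressed it with spike inference, which is out
  of scope here).
- Registration is integer-pixel and rigid.
- The measured z amplitude of events is duty-cycle dependent (see
  z-scoring above); amplitude comparisons across very different
  activity regimes should use the robust z-scoring mode.
- Staging thresholds are generator-calibrated defaults, not published
  values; on real data they must be recalibrated.
- Hypothesis tests on population summaries are delegated to standard
  statistics libraries and are not part of this package.
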