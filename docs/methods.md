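# Methods

This note records the model behind `accelbird`, the parameters that matter,
the numerical choices made where the design was genuinely open, and what the
synthetic-data generator does and does not emulate.

## Signal model

A tag records tri-axial acceleration in g at a fixed rate (20 Hz for
chest-mounted video+acceleration tags, 25 Hz for back-mounted GPS tags).
The raw signal is modelled as the sum of a slowly varying gravitational
(postural) component and a fast propulsive component. The split is a
low-pass filter at 1.5 Hz — comfortably below the ~4 Hz cruising wingbeat —
realised as a windowed-sinc (Hamming) FIR of order 100 (101 taps). The
filter is applied forward-backward (`filtfilt`), so the static estimate has
zero phase lag and posture stays time-aligned with the events derived from
it; a causal single-pass option exists (`zero_phase=False`) and a test pins
down the alignment difference between the two. Dynamic acceleration is
defined as raw minus static, which makes the reconstruction identity exact
by construction rather than approximate.

Pitch is `arcsin(x_S)` in degrees, with x_S clipped to [−1, 1] first so
filter overshoot cannot produce NaNs; the operation is total. ODBA is the
L1 norm of the dynamic components; its 10 s moving mean uses centred
windows that shrink at the record edges (no padding). For even window
lengths the extra sample sits on the left of the centre.

Local extrema of a sampled signal are computed after collapsing runs of
equal values to their first sample, which guarantees strict max/min
alternation and gives plateaus a deterministic representative. A monotone
or constant signal has no extrema.

## Calibration from predicted flight minutes

Mounting position changes amplitude and orientation conventions, so no
threshold transfers across tags. Calibration instead finds minutes of
probable cruising flight spectrally: a Hann spectrogram of dynamic
dorsoventral acceleration (4 s window, 85% overlap, one-sided PSD scaling)
is summed inside a flapping-flight band, closed [3.5, 5] Hz, and a take-off
band (5, Nyquist] — a bin at exactly 5 Hz belongs to the flap band, reading
the band bounds inclusively. The flap-minus-takeoff difference is summed
in one-minute moving windows with a hop of one spectrogram frame. Because
the hop is one frame, a one-minute window is a fixed frame count; window
membership is computed by count rather than by floating-point time
comparison, which keeps ties exact and the greedy selection deterministic
(descending sum, earliest start on ties, starts at least 5 min apart).
Ten PFMs are selected for a chest-mounted recording and twenty per calendar
day for back-mounted multi-day recordings (final partial day pro-rated,
rounded up, minimum one). If fewer windows are separable a warning is
emitted and the shorter list used.

The flap amplitude threshold is derived per PFM from the peak–trough
differences of dynamic dorsoventral acceleration, which are bimodal in
flight (small glide-noise differences, large wingbeat differences). A
Gaussian KDE with the normal-reference (Silverman) bandwidth is evaluated
on a 512-point grid spanning the data range; the threshold is the lowest
density point strictly between the two highest interior modes (first such
abscissa on ties). PFMs with unimodal densities are skipped; densities with
more than two modes use the two largest and warn. The per-tag threshold is
the median of the per-PFM troughs (even-length medians average the central
pair, as everywhere in the package). Pitch statistics per PFM — maximum
successive pitch-extremum difference, minimum, mean, and population
variance (divide by n) of pitch — are combined as 1.5 × median, median,
median, median respectively. Chest-mounted tags record only ~2 h, so their
large-pitch-change thresholds are pooled (median across tags) before
classification.

## Classification rules

Flaps are successive z_D extremum pairs with difference at or above the
threshold (boundary inclusive). Flaps with gaps strictly under 0.5 s form
flapping bouts; bouts no more than 30 s apart form flight intervals, so
enclosed glides count as flight. A take-off is an upward large pitch change
whose start lies within ±2 s (configurable) of a flight onset; the take-off
interval spans the pitch excursion. A pitch-change event is timed at the
first extremum of its pair and its origin pitch is the value there. For
back-mounted tags, upward events originating above the median minimum PFM
pitch are removed once, at event-extraction time, before both take-off
detection and foraging grouping — in steady flight pitch already sits near
its median, so such events are flight artefacts rather than recoveries from
a low-pitch landing; the take-off detector applies the same filter
defensively if handed unfiltered events.

Large pitch changes chained within 23.3 s (the mean foraging bout duration)
share a group. Groups are screened for dives first: a dive runs from the
sample where pitch crosses below (median minimum PFM pitch − 30°) to the
first sample within 10 s where pitch exceeds (median mean PFM pitch +
2 × median PFM pitch variance); descents without recovery are not dives.
Events inside detected dives are then removed and the remainder of the
group is screened for surface seizing: a chain of 3+ events with successive
gaps ≤ 2 s, spanning from the first event to the end of the last.
"Within 2 s of one another" is read chain-wise, consistent with the other
grouping rules; an all-pairs reading is available behind a config switch.
Re-evaluating the chain after dive removal means a dive bisecting a burst
can break the burst below three events — such groups become unknown.
Rest is any run of the ODBA moving mean below 0.2 g. The assembled ethogram
labels every sample by precedence dive > surface seizing > take-off >
flight > rest > unknown, so it partitions the record exactly.

## Validation

Both ethograms are sampled on the acceleration clock (one label per sample,
0.05 s at 20 Hz; parameterised by rate). Sample instants on an interval
boundary take the right interval (half-open convention); instants outside
every interval read unknown. Rates are duration-based: TPR divides the
correctly predicted duration of a behaviour by its total reference
duration; FPR divides the duration wrongly predicted as the behaviour by
the total reference duration of *other* behaviours (the reference
complement, not the predicted one). Behaviours absent from the reference
report NaN, rendered "NA" in tables. Masked periods (e.g. where a
reference video was obscured) are dropped from both sequences before
counting.

## GPS integration

Speeds use a centred 5-fix window: great-circle distance between the
window's end fixes divided by its time span, shrinking at the track edges.
Using window endpoints suppresses position jitter, which a consecutive-fix
estimate integrates. Distance is the haversine great circle on the WGS84
mean radius (6371.0088 km); at trip scales of tens to hundreds of
kilometres this differs from a full ellipsoidal geodesic by far less than
any threshold in use (the speed cut-offs are 15 and 80 kph). Fixes within
1.5 km of the colony or above 80 kph are removed; the two filters commute.
A fix takes a foraging label if a dive or seizing interval lies within
±30 s, dives winning ties; foraging fixes moving strictly above 15 kph are
relabelled flight at the fix level only (the ethogram itself is not
rewritten). Flight and unknown intervals strictly shorter than 5 s are
pruned to unlabelled gaps. A trip is a maximal run of fixes outside the
colony radius; its duration is the ceiling of elapsed days and trips over
two days are "long". Daily budgets split the ethogram at local midnight
(configurable UTC offset, default +9 for the study region) into
forage / transit (flight + take-off) / rest / unknown seconds and
fractions; event counts land on the day containing the event start.

## The synthetic generator

The generator emits deterministic behaviour templates plus independent
Gaussian noise per axis, with the static channel always consistent with the
scripted pitch (x = sin(pitch) + noise), so the pitch estimator inverts the
generator in the noise-free limit. Defaults describe a 20 Hz chest-mounted
deployment: 4 Hz flapping at 0.4 g amplitude (0.8 g peak–trough) in 6–10 s
bursts separated by 2–3.5 s glides; >5 Hz take-off flapping at 0.6 g with a
pitch excursion to +40° starting from −10° (a bird sitting on the water
starts its upward rotation from low pitch, which is also why these events
survive the back-mounted origin filter); dives of 3.2 ± 1.2 s with a pitch
drop to −70° and recovery to +20°, with a brief sub-flap-amplitude entry
splash (0.08 g) — the signal shows an entry transient but no sustained
underwater flapping; surface seizing as alternating landings (1.5 ± 1.4 s,
clipped to 0.5–1.8 s so successive pitch swings stay within the 2 s burst
rule) and take-offs (0.6 ± 1.6 s, clipped 0.3–1.2 s) swinging pitch between
±25°; pre-flight take-offs of 3.0 ± 1.3 s; rest as low-variance noise.
The standard two-hour script is roughly two-thirds flight, a few percent
surface seizing, under a minute of dives, and the rest sit-on-water rest,
with foraging bouts buffered by rests longer than the 30 s bout-merging
gap.

Multi-day deployments script each trip to depart at 06:00 and return at
20:00 local, with colony rest between. GPS fixes every 5 s follow a
kinematic model: 45 kph persistent-heading flight (outbound until the
remaining scripted flight time just covers the distance home, then
inbound), slow drift (< 8 kph) during foraging and at-sea rest, stationary
jitter at the colony; drifting positions are kept outside 2 km of the
colony so a trip never fragments. A ten-day 25 Hz acceleration record is
several gigabytes of float64, so `include_accel=False` skips signal
synthesis for trip/budget analyses that consume only the ethogram and
track; short deployments generate the full signal.

What the generator does *not* emulate: realistic wingstroke waveforms
(sinusoids stand in for asymmetric strokes), heart-rate or wind artefacts,
GPS position error beyond white jitter, ocean-current drift, tag slippage,
or behavioural ambiguity (every scripted second has exactly one true
label). Passing recovery floors on this synthetic therefore demonstrates
the pipeline's internal consistency — thresholds calibrated from the signal
recover the structures the signal was built from — not field performance,
which depends on signal features the generator idealises away.

## Problem sizes and tolerances

Test and acceptance runs use two-hour 20 Hz records (144 000 samples) for
end-to-end checks, ten seeded replicates for recovery rates, 200 replicates
for the KDE-trough recovery of a 0.05 g / 0.8 g amplitude mixture, and a
ten-trip-day deployment (GPS + ethogram only) for trip and budget recovery;
these sizes exercise every code path at full fidelity while keeping the
whole suite in the tens of seconds. The decomposition identity is exact to
1e-9 (float64 round-off in practice); budget fractions agree with a
per-second sampling oracle to well under 0.1 percentage points; recovery
floors are flight TPR ≥ 0.90 / FPR ≤ 0.02, surface seizing ≥ 0.70 / ≤ 0.05,
dive ≥ 0.60 / ≤ 0.01. Dive TPR sits near 0.74 by construction: the
descent/ascent threshold crossings trim the shallow edges of each scripted
dive, so a detector cannot reach 1.0 without loosening the crossings.

## Known limitations

Calibration assumes the record contains enough separable flight minutes;
records without flight fail with a calibration error rather than guessing.
The KDE trough assumes a two-mode amplitude distribution — heavier
multimodality warns and uses the two largest modes. The 23.3 s grouping
constant and the 0.2 g rest threshold are species- and deployment-specific
inheritances exposed in configuration; transferring the pipeline to another
species means revisiting them. The fix-level 15 kph reclassification
deliberately leaves the ethogram untouched, so duration budgets and
fix-level foraging maps can disagree slightly by design.
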