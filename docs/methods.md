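# Methods

This note documents the models, parameters, and numerical choices behind
the package, in the spirit of a methods supplement: what each stage
assumes, which knobs matter, and what the synthetic benchmarks do and do
not establish.

## Signal chain

**Filtering.** Wideband data are band-passed 0.1–300 Hz with a 4th-order
Butterworth applied forward–backward (zero phase; the effective order is
8). Ripple- and gamma-band filters are linear-phase equiripple FIRs
(10 Hz transition bands, ≥ 40 dB stopband) applied with a centred kernel,
which compensates the group delay exactly. The filter order/width values
are conventional choices; results are insensitive to them because all
detection thresholds are defined in baseline-SD units of the filtered
signal itself.

**Downsampling** uses polyphase anti-alias filtering with integer
decimation (e.g., 30 kHz → 1 kHz). Sessions below 1 kHz are rejected at
validation.

**Velocity and immobility.** Tracking at 30 Hz is Gaussian-smoothed with
σ = 0.25 s before central differencing. The smoothing constant is not
reported with the immobility rule it serves; 0.25 s suppresses
frame-to-frame tracker jitter (which otherwise dominates speed at 30 Hz)
while preserving locomotor onsets of ≥ 1 s. Immobility is speed < 1 cm/s
sustained ≥ 30 s; analysis time within each run starts *after* the 30 s
qualification, which we read as the intent of "after … for 30 s or more".
The alternative (count the whole run) is available as
`immobility_intervals(..., count_whole_run=True)`. Sessions with < 10 min
of qualified immobility per hour are excluded; the 600 s boundary counts
as included.

## SWR detection

The ripple-band (150–250 Hz) envelope is the magnitude of the analytic
signal, Gaussian-smoothed with σ = 4 ms (about one ripple cycle; raw
Hilbert magnitude at 1 kHz is too rough to support a duration criterion).
Baseline mean and SD are computed in a single pass over immobility samples,
without iterative event exclusion — with events occupying ~2% of immobility
time the bias on the threshold is negligible.

Events are maximal runs above mean + 5 SD within immobility; runs closer
than 15 ms are merged (one event briefly dipping below threshold is one
event), and merged runs must last ≥ 15 ms. Event extent (`start_s`/`end_s`)
is then extended outward to the nearest baseline-mean crossing, clipped to
the enclosing immobility interval. The threshold-crossing time
(`trigger_s`) is stored separately and is t = 0 for all peri-event windows,
matching the convention "0–100 ms after ripple detection". The 125–250 Hz
band and the 3 SD threshold used for robustness checks are plain
parameters; by construction the 3 SD event set contains the 5 SD set.

**Abundance** divides the event count by qualified immobility time, making
it invariant to envelope scaling and comparable across sessions with
different amounts of rest.

**Multi-unit verification.** Spikes are upward crossings of 75 μV in the
600–6000 Hz band of the reference-subtracted wideband signal (1 ms
refractory). The modulation ratio compares the spike rate in
[trigger, trigger + 100 ms] windows to the immobility rate outside events;
pyramidal-layer sites show ratios well above 1.

## Slow-gamma feature

Spectrograms use the multitaper method: 100 ms sliding window, 10 ms step,
time–bandwidth NW = 2 with 3 DPSS tapers (the standard K = 2·NW − 1
choice; ±20 Hz effective bandwidth). Power is one-sided PSD in μV²/Hz, so
band-integrated power equals signal variance for stationary noise — an
invariant the tests check directly.

Each frequency bin is z-scored against the windows whose centres fall in
the session's immobility (the reference distribution is a deliberate
choice; a pre-event reference using the −500…−250 ms window is available
via `zref: preevent`). The per-event feature averages z over frequency bins
with centres in [30, 50] Hz and window centres in (0, 100] ms after the
trigger (right-closed by the centre convention); events without any window
there — possible only at recording edges — are skipped. Averaging order is
events → sites within a region → region value per session → unweighted mean
over sessions, so each mouse contributes one number per region and
day-to-day (e.g., estrous) variation is averaged out. Mice without sites in
a region carry NaN for that region; the sentinel propagates and is never
silently replaced by 0.

## Behavioral metrics

**MWM** (122 cm pool, 14×14 cm platform, 60 s trials): daily escape latency
is the mean of the four hidden trials; learning slope is the least-squares
slope of daily latency over an inclusive day range; overnight change is
first-trial-of-day-(d+1) minus last-trial-of-day-d latency (negative =
overnight improvement). Probe metrics: percent time in the platform's
quadrant (quadrants by half-open angular convention, so any track's four
quadrant times sum to 100%), target crossings (centre-point entries into
the axis-aligned platform square), and the trapezoid area under the
distance-to-platform curve over the first 5 s.

**APA** (40 cm arena at 1 rpm, 60° room-fixed shock zone, 10 min trials):
tracks are converted to the room frame by adding 6 deg/s × t to the arena
angle. Entrances use 0.5 s hysteresis (a new entrance requires 0.5 s
continuously outside), which removes frame-jitter double counts; an animal
*placed* inside the zone is not credited with an entrance, so a mouse
stationary in the arena frame sweeps up exactly 10 entrances per 600 s.
Latency to first entrance is capped at trial duration. Path length is
summed in the *arena* frame (the animal's own movement). The "opposite
quadrant" is the 90° sector antipodal to the zone centre. Movement bouts
are arena-frame speed > 2 cm/s sustained ≥ 0.5 s with < 1 s interruptions;
the bout metric is the net change in arc distance (at the bout's mean
radius) from the nearest zone boundary, positive away from the zone, with
a cumulative variant available — the bout thresholds and the net-vs-
cumulative choice are config keys because the metric has no published
formal definition. Pseudoshocks replay the shock schedule (shock at entry,
every 1.5 s while inside) on probe trials.

## Composite scores and prediction

Metrics are z-scored within a cohort using the sample SD (n − 1). The
learning score (MWM) averages the day-1–2 and day-1–3 latency slopes,
day-3 latency, and the first-night overnight change, all sign-inverted
(lower is better); the precision score (MWM) averages probe-1/2 quadrant
time, probe-1 crossings (higher is better), and probe-1/2 distance AUC
(lower is better). The APA learning score uses day-2 latency to first
entrance, path length, and opposite-quadrant time (higher is better); the
APA precision score uses day-2 entrances and day-2/3 bout distance (lower
is better). A mouse with fewer than half of a composite's metrics present
gets the missing sentinel. With no missing data a composite has cohort mean
0 (to 1e-9) and is invariant to per-metric affine rescaling.

Correlations use Pearson when both variables pass Shapiro–Wilk at α = 0.05,
otherwise Spearman. Families of p-values are adjusted with step-down
Holm–Šidák (max-formula, clipped at 1, returned in input order). Screen
enrichment uses the exact one-sided binomial upper tail P(X ≥ k) at the
test α. Redundancy is controlled by a greedy filter that keeps metrics in
declared order and drops any with pairwise R² ≥ 0.5 against a kept metric
(declaration order is the tie-break). Cross-cohort prediction fits OLS of
the score on the z-scored feature in the screen cohort and applies it to
the replication cohort's *re-z-scored* feature — z-scoring within each
cohort is what removes cohort-level shifts in the raw feature (e.g.,
different mean abundance). Every reported relationship carries a
leave-one-out robustness flag: significant at α = 0.05 on all n − 1
subsets.

## Synthetic data

**LFP sessions.** Per site, background is 1/f-shaped Gaussian noise
(exponent 1.0, 15 μV SD — a plausible hippocampal LFP spectrum; the
exponent and SD are free parameters). The immobility schedule is a
repeating (mobile, immobile) block pattern that must tile the session; the
default (60 s mobile, 240 s immobile) yields 10.5 min qualified immobility
per 15 min. The 30 Hz position track realizes the schedule (smooth walk in
a 30×15 cm cage vs sub-millimetre jitter), so immobility is *recovered*
from tracking, not handed to the detector.

Events are planted at a Poisson rate (0.2 events/s, the healthy-aged
anchor) inside qualified immobility with 0.2 s edge margins; a minimum
separation of 0.3 s is imposed by a count-preserving spacing transform so
the planted rate is exactly nominal. Each event adds: a ripple tone
(frequency uniform in 150–220 Hz, Gaussian envelope σ = 20 ms, peak
amplitude 8 ripple-band SDs by default) on CA1 pyramidal sites, a negative
sharp wave (100 μV, σ = 15 ms) on CA1 stratum radiatum, and a 40 Hz burst
(Hann envelope over the 0–100 ms post-onset window, amplitude `sg_mod_amp`
in SG-band SDs) on CA3/CA1-sr/DG. The default `sg_mod_amp` = 3 gives a
clearly detectable feature (z ≈ 1, the scale of empirically reported SG
modulation) while staying within single-trial physiological range. The
planted *event time* is defined as one envelope σ before the burst peak —
the e^{−1/2} rise point, which is where a 5 SD detector first sees an 8 SD
burst — so onset-error benchmarks measure detection jitter (~3–4 ms)
rather than an arbitrary convention offset.

**Behavior.** MWM trials are biased random swims whose homing bias grows
with day and skill (day-1 performance is naive at any skill); probe swims
concentrate near the platform in proportion to skill, and skill 0 gives
~25% quadrant occupancy. APA trials simulate the room-frame angle: passive
drift with the arena (counteracted in proportion to avoidance) plus
jitter; each approach to the zone boundary is either actively avoided
(hold just outside, with probability = avoidance) or swept through with a
fast shock-driven escape. Entrance counts fall monotonically from ~12 (at
avoidance 0) to ~0 (at 1).

**Cohorts.** Latent z-scored abundance and CA3 SG power are independent
standard normals (the two features are uncorrelated in the population).
Each composite-set metric is sqrt(r²)·feature + sqrt(1−r²)·noise on the
oriented scale, with the per-metric r² solved from the target composite
R² (r² = R²/(k(1−R²)+R²) for k equally loaded metrics), then mapped to a
plausible raw scale and orientation. Defaults plant R² = 0.51
(abundance → learning) and 0.77 (SG → precision) with screen/replication
abundance means 0.12/0.20 Hz. A trajectory mode maps latent ability through
the normal CDF to the behavioral generators; the planted-R² guarantee holds
only in metric mode.

**What passing these benchmarks shows — and does not.** The generator has
stationary 1/f noise, stereotyped events, and clean tracking; it contains
no artifacts, electrode drift, line noise, theta intrusions during brief
pauses, or behavioral idiosyncrasies. Recovery results therefore validate
the *implementation* (thresholding, windowing, aggregation, statistics)
under the stated model, not detector performance on real recordings; on
real data, detection quality must still be judged by the multi-unit
modulation check and by robustness to the band/threshold variants.

## Problem sizes and runtime choices

Validation sessions are 900 s with three 240 s immobile blocks (~630 s
qualified immobility — the session-inclusion floor of the study design,
reached in a quarter of the wall-clock time of a full hour), with only the
montage sites each experiment needs. Abundance recovery uses 100 sessions;
SG calibration uses 10 seeds × 4 amplitudes; prediction recovery uses 100
cohort pairs and type-I calibration 500 null cohorts. These sizes put every
Monte-Carlo standard error well below the tolerance it is compared against.

One statistical subtlety is documented here deliberately: the abundance
tolerance 2·√(rate/T) equals two Poisson standard errors of the planted
count, so the per-seed probability that an *exactly Poisson-limited,
unbiased* estimator lands inside it is 95.4% — a criterion of "≥ 95% of
seeds inside a 2σ band" sits on its own noise floor. The validation suite
therefore asserts the two sharp equivalents (ensemble unbiasedness at the
precision 100 seeds affords, and per-seed error measured against the
*realized* planted count, which isolates detector error) and reports the
literal band fraction alongside them.

## Known limitations

* CRCNS ingestion is a documented stub; real-data runs require writing a
  converter to the bundle format.
* The detector assumes a single detection site chosen a priori (first
  usable CA1 pyramidal site); it does not re-derive layer identity from
  the data beyond the multi-unit check.
* Spearman p-values at very small n use the approximate distribution via
  scipy; exact permutation p-values are not implemented.
* The synthetic behavioral generators aim at ordinal realism (metric
  orderings, ranges), not kinematic realism of rodent locomotion.
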