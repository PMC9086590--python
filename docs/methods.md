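# Methods

This note documents the models, parameter choices and numerical
conventions behind `ecogplv`, and what the synthetic-data studies do
and do not establish about real recordings.

## Recording model and formats

A session is a channels × samples float32 matrix in microvolts at a
single sampling rate (default 1 kHz), with per-channel montage
metadata: a cortical region from a closed set (posterior/anterior
temporal, frontal pole, VLPFC, OFC, other), a headstage *connector
group* of at most 32 channels, and a seed flag.  Time is milliseconds
from recording start; all event-relative windows are half-open
`[start, stop)`, so the −200..600 ms epoch holds exactly 800 samples at
1 kHz.  On disk a bundle is raw little-endian float32 plus JSON
metadata and a TSV event table; round trips are bit-exact.  Stored
amplitudes are taken to be microvolts — the scale on which the ±1000 µV
artifact rule is meaningful; no other calibration is assumed.

## Synthetic sessions

The generator's defaults are the study conditions the analysis is
designed for:

* **Schedule** — 1000 slots at 500 ms SOA; 10% omissions.  Exact-count
  mode places `round(n·p)` omissions uniformly at random (900 tones /
  100 omissions per session) with no adjacency constraint; Bernoulli
  mode draws slots independently.  The session adds 1000 ms lead and
  1100 ms tail padding so every epoch and the widest wavelet fit inside
  the recording.
* **Background** — independent per-channel 1/f<sup>α</sup> noise
  (spectral shaping of white Gaussian noise, α = 1) scaled exactly to
  20 µV rms, plus a 50 Hz line sinusoid of 2 µV with random phase per
  channel.  These levels are simulator conventions chosen to resemble
  band-limited intracranial recordings; no empirical noise floor was
  available to match.
* **Evoked templates** — per (region, condition), sums of Gaussian
  bumps `A·exp(−(t−λ)²/2w²)` added to every channel of the region at
  matching events.  Defaults: sharp early tone deflections in the
  temporal regions echoed (×0.7) frontally; an early broad positive
  omission deflection (anterior temporal, frontal pole, OFC); a late
  gradual rise in the temporal regions.  Peak amplitudes 6–25 µV.
* **Phase coupling** — per event a common phase φ ~ U(0, 2π) is drawn;
  a Hann-windowed tone burst `A·w(t)·cos(2πf(t−t_a)+φ)` is added to
  the seed channel, and each target channel receives a copy with an
  independent vonMises(0, κ) phase offset.  κ is therefore the
  concentration of the *seed−target phase difference*, and the
  population PLV at the injected bin is I₁(κ)/I₀(κ); κ ≥ 10⁶ encodes
  perfect locking.  The Hann envelope keeps the burst band-limited so
  it does not leak across the analysis bands.  Coupling is injected
  additively in the signal domain — not by editing extracted phases —
  so recovery tests exercise the whole measurement path.

One RNG stream per session is keyed by `(seed, CRC32(session_id))`, and
a `SimulationTruth` record (config + seed) regenerates any session
bit-exactly.  The generated signal is exactly the sum of its three
stages (background, templates, couplings) when the draw sequence is
replayed, which the tests verify.

Two emergent features of this design are *intentional* and also present
in real data of this paradigm: the 800 ms epoch contains the next event
at +500 ms, so omission epochs carry the following tone's evoked
response near 590 ms (the "flat omission ERP" property only holds for
sessions with nothing injected); and the group-mean re-reference
subtracts whatever the channels of a connector share, so coupling many
channels of one connector partially cancels the injected burst and
mirrors real common-reference artifacts.

## Preprocessing

All filters are 4th-order Butterworth applied forward–backward
(`scipy.signal.sosfiltfilt`): linear, zero-phase, so peak latencies are
preserved (verified on symmetric pulses).  The ERP path band-passes
1–30 Hz on the continuous signal *before* epoching.  The PLV path
re-references by subtracting each connector group's instantaneous mean
(idempotent; per-group mean exactly zero afterwards) and then notches
48–52 Hz; it never applies the ERP band-pass, because phase is
extracted per frequency by wavelet convolution.

Epoching cuts one trial per event over −200..600 ms; events whose
window would leave the recording are dropped with a warning rather than
zero-padded (padding would bias both ERPs and phase).  Artifact
rejection marks trials with any sample *strictly* exceeding ±1000 µV;
the boundary case (exactly 1000 µV) is kept, a deliberate literal
reading that makes the rule testable.  Trial equating randomly
subsamples kept tone trials down to the kept omission count; rejection
and equating only ever touch the kept mask, never sample values.

## ERP statistics

Per region and condition, kept trials are averaged across the region's
electrodes (one trace per trial), then across trials.  The test
population is *trials* of the region-averaged trace — the natural
exchangeable unit for a single session; multi-session pooling is plain
trial concatenation.  A pointwise one-sample t test (two-sided,
df = n−1) against zero is FDR-corrected over the 800 time points of one
(region, condition) trace at α = 10⁻⁶.  Zero-variance time points
return t = 0, p = 1 so degenerate synthetic inputs cannot propagate
NaNs.  No baseline correction is applied; the 1 Hz high-pass edge
serves that role, and adding an unstated step was deliberately avoided.

## Time-frequency phase and PLV

Phase comes from complex Morlet wavelets with a fixed 5 cycles at 1 Hz
spacing over 4–60 Hz, convolved with the *continuous* conditioned
signal (single FFT per channel, one inverse FFT per frequency) and only
then epoched.  The 4 Hz wavelet spans ≈1.6 s — twice the epoch — which
is why continuous-domain convolution is required; events too close to
the recording edges for the widest wavelet are dropped, and the PLV
path equates conditions *after* that exclusion so both always enter
with exactly equal trial counts.  Maps are decimated to 5 ms steps
(phase at ≤60 Hz is smooth on that scale; at the 200 Hz desk-scale
sampling rate 5 ms is exactly one sample).

PLV per (freq, time) bin is the mean resultant length of across-trial
phase differences.  Rayleigh significance uses the standard
large-sample approximation
`p = exp(√(1+4n+4(n²−R²)) − (1+2n))`, clipped to [0, 1]; the FDR family
is all bins of one seed × target × condition map at α = 0.05.  Band
summaries use half-open bands `[lo, hi)` on the integer grid so
adjacent bands never double-count an edge bin.

## Condition contrasts

Per bin, the two conditions' phase-difference samples are compared with
the two-sample circular common-median test: pool, take the pooled
circular median θ̂ (the data angle minimizing summed circular absolute
deviation, ties to the smallest wrapped angle; computed row-wise in
O(n log n) with prefix sums and verified against brute force), count
per sample the points strictly inside (θ̂, θ̂+π) — points on the median
diameter go to the lower arc — and refer
`P = N²/(M(N−M))·Σmᵢ²/nᵢ − NM/(N−M)` to χ²(1).  Degenerate splits
(all points one side) return p = 1 with a logged flag; per-sample sizes
below 10 are rejected because the χ² approximation is unreliable there.
Contrast p values are deliberately *uncorrected* (the per-bin map
convention); the FDR machinery remains available through configuration.

A bin's sign is the direction of the PLV difference where p < 0.05.
The band rule calls a band significant at a time point when more than
20% of its frequency bins carry a sign, with the majority direction
(an exact tie withdraws the call — the conservative choice).  "Data
points within the band" is read as frequency bins at each time sample,
the only reading that yields time-resolved band calls.  Pair-level
summaries: the signed significance ratio `(#+1 − #−1)/#pairs` per bin,
pooled over electrode pairs without per-session normalization, and the
signed electrode proportion per region and band, averaged over
half-open 10 ms windows (sample averaging within the window).  Swapping
the condition labels flips every sign and negates both summaries
exactly.

## Study sizes and numerical choices

Monte-Carlo studies in the tests and the acceptance script use
desk-scale sessions: 200 Hz sampling (the analysis is band-limited to
60 Hz), two regions of 2–16 channels with the connector size matched to
the region, and the full 1000-slot schedule so per-condition trial
counts (100 after equating) match the session design.  The κ=2
parameter-recovery study uses a 40 µV burst over a 200 ms window so
that additive-noise phase jitter attenuates the measured PLV by under
2% — the experiment isolates the jitter concentration, which is the
quantity under test; at the default 20 µV convention the measurement
would mostly reflect the noise floor instead.  Filter order (4),
wavelet width (5 cycles), grid steps (1 Hz, 5 ms) and the Gaussian
template truncation (5σ) are all configuration surface.

## Known limitations

* **The common-median test is nearly blind to concentration-only
  differences.**  A uniform circular sample shares *every* median, so
  when one condition has phase differences concentrated at some angle
  and the other is uniform, the test's null is effectively true; its
  rejection rate saturates near 20% regardless of trial count (the
  residual power comes only from variance inflation of the side
  counts).  Detection of an omission-only coupling therefore relies on
  aggregation — the 20% band rule across bins and time — and measured
  end-to-end detection of a 40 ms, κ=5 low-beta burst reaches ~75–90%
  per session rather than certainty.  The test is kept because it is
  the analysis's specified contrast statistic; a resultant-length
  permutation test would be the more powerful alternative for
  concentration differences.
* The test is also mildly anticonservative at n = 100 per sample
  (null rejection ≈ 0.06–0.07 at nominal 0.05), a property of the χ²
  approximation with discrete counts that the calibration studies make
  visible.
* A 40 ms burst is much shorter than the 5-cycle 18 Hz wavelet
  (σ_t ≈ 44 ms), so the wavelet dilutes it with surrounding noise and
  the measured PLV at the injected bin understates the injected
  concentration.
* The simulator makes no claim to biophysics: no volume conduction or
  source model, stationary noise, identical templates within a region,
  and coupling only where injected.  Passing recovery and calibration
  tests demonstrates the *analysis* is correct and calibrated under
  these conditions, not that real cortical effects will be of
  comparable size.
* Adjacent epochs overlap (800 ms epoch, 500 ms SOA) and low-frequency
  wavelets overlap neighbouring events, so trials are not perfectly
  independent; this is intrinsic to the paradigm and shared by real
  recordings.
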