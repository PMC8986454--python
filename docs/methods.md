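# Methods

## Signal model of the synthetic generator

Each synthetic patient record holds two synchronous channels nominally
digitized at 14 bit / 200 Hz, the acquisition format of wearable
ECG+SCG monitors this package targets.

**ECG.**  One stylized PQRST complex per beat, built from Gaussians
(P +0.15 at −160 ms, Q −0.12 at −20 ms, R +1.0 at 0, S −0.20 at +25 ms,
T +0.30 at +180 ms, all relative to R).  R is the unique per-beat maximum
by construction.  The Q offset (default 20 ms before R) is part of the
ground truth so Q-referenced intervals (PEP) can be validated.

**RR series.**  Sinus intervals are drawn from a normal law truncated to
[0.5, 1.5] × mean RR.  An ectopic event replaces one interval r by a
premature 0.6 r interval followed by a compensatory 1.4 r interval — the
standard stylization of a premature beat with compensatory pause; the beat
terminating the premature interval is labelled ectopic.

**SCG.**  Per beat, a sum of Gaussian-windowed cosine bumps, one per valve
event, centred at the configured latency (defaults MC 30, AO 80, AC 380,
MO 460 ms from R; amplitudes 1.0 / 2.0 / 1.2 / 0.9 with AO the most
prominent systolic complex, as on real dorso-ventral SCG).  The carrier is
15 Hz and the envelope σ is half the configured bump width (default width
20 ms → σ = 10 ms): both sit inside the 5–40 Hz analysis band, and the
narrow envelope keeps adjacent bumps (MC→AO spacing can be 35 ms in a
fast-rate patient) from shifting each other's extremum by more than a
sample.  The cosine peaks at the envelope centre, so each bump's local
maximum is the ground-truth latency.

**Non-traditional morphology.**  1–4 randomly chosen bumps are removed and
broadband 5–40 Hz colored noise is added at 50% of the full beat's
amplitude (the amplitude reference is always the *unsuppressed* template,
so noise levels mean the same for T and NT records).  This emulates
waveforms in which heart dysfunction obliterates some or all FP patterns
while possibly retaining others.  The distortion is not beat-locked:
ensemble averaging attenuates it as 1/√K, which is exactly how
non-repeatable distortion behaves; the residual-noise guard described
below is what keeps the classifier honest about what remains.

**Degradations.**  Respiratory amplitude modulation multiplies the SCG by
1 + d·sin(2πt/T_resp) (default depth 0.2, period 4 s); white measurement
noise is added at a configurable fraction of the beat's peak-to-peak
amplitude (default 5%); both channels are uniformly quantized to 14 bits
over their own full scale.

**Sonogram annotations.**  A contiguous run of 3–5 sinus beats is
annotated with the per-beat RR sequence and one valve-event time-from-R
equal to ground truth plus N(0, jitter²) reading error, rounded to the
2.64 ms pixel pitch of the emulated M-mode display.

**Cohorts.**  Patients are assigned a diagnosis group (default mix
MI 34/90, HF 49/90, TX 7/90) and a T/NT class by an independent Bernoulli
draw with per-group prevalence (defaults 26/34, 27/49, 3/7).  Per-patient
physiology is sampled in realistic ranges: mean RR 700–1100 ms, RR SD
20–60 ms, MC 20–45 ms, AO 65–110 ms, AC 330–420 ms and MO−AC 60–120 ms,
the diastolic latencies scaled by mean RR/1000 since diastole shortens at
faster rates.  Ejection fraction is drawn around group means of 43% (MI),
30% (HF), 57% (TX).  Cohort records default to 30 s rather than a full
5-minute monitoring session: downstream analysis consumes only the
earliest window of at least six good beats, so longer records change
nothing but runtime.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: genuine SCG morphology (real beats are not
sums of symmetric bumps, and real NT distortion is largely *repeatable*
beat to beat), baseline wander and motion artifacts, electrode noise with
realistic spectra, inter-beat morphology variability beyond respiratory
gain, atrial arrhythmias, and any coupling between diagnosis, EF and
waveform shape beyond the configured prevalences.  Results on synthetic
cohorts validate the *chain's* correctness against known ground truth, not
clinical performance.

## Processing chain

**Filtering.**  The SCG is band-passed 5–40 Hz with a 3rd-order
Butterworth applied forward-backward (zero net phase; effective magnitude
is the squared single-pass response).  Edge handling is odd-reflection
padding of length 3×(2·order+1).  The ECG gets a gentler 0.5–40 Hz
conditioning for R detection only.  Filtering precedes window selection.

**Resampling.**  Polyphase rational-ratio resampling to the 1 kHz analysis
rate, operating on the mean-removed signal (the anti-alias FIR's DC gain
is not exactly unity; removing and restoring the mean keeps constants
exact).  Line-extension padding avoids edge transients.

**R and Q detection.**  Peaks of the conditioned ECG above an adaptive
threshold (median + half of the 99.5th-percentile excursion) with a 200 ms
refractory period, refined to the raw-ECG maximum within ±10 ms.  Q is the
ECG minimum in [R−60, R−4] ms, missing where the window is truncated.

**Beat quality.**  A beat is *ectopic* when the RR interval ending on it
falls >20% below the running median of five (premature); an interval >20%
above the median marks ectopy only when not preceded by a premature one,
so the compensatory pause does not flag the following sinus beat.  A beat
is *noisy* when its SCG RMS over [−100, +600] ms exceeds 3× the median
beat RMS.  Thresholds are pragmatic defaults, configurable.

**Window selection and averaging.**  The earliest contiguous run of ≥6
good beats is averaged sample-wise after alignment at R (window −100 to
+600 ms, covering Q through MO at the rates the generator produces; both
configurable).  Segments truncated by record edges drop out of the
affected samples only.  When no such run exists, the single good beat with
the most regular RR is used and flagged — the fallback used for patients
with frequent ectopy.  Alignment is at sample resolution at 1 kHz; no
sub-sample registration.

**Fiducial detection.**  Each FP is the most topographically prominent
local maximum inside its search window (defaults, ms from R: MC [10, 60],
AO [45, 160], AC [250, 450], MO [AC+20, AC+180]; the diastolic windows
scale with mean RR/1000).  Search proceeds left to right — AO after the
detected MC, MO after the detected AC — and ties break toward the earlier
extremum.  Prominence, not raw amplitude, is the detection statistic, so
detection is invariant to baseline offset.  A per-point polarity switch
accommodates conventions that place events on valleys.  A point is *found*
when its prominence reaches 10% of the averaged beat's peak-to-peak
amplitude **and** 5× the average's residual-noise level.  The residual
level is the median per-sample standard error across the averaged beats,
computed during ensemble averaging: a repeatable pattern must stand clear
of what averaging left of the non-repeatable noise.  Without this guard, a
beat whose bumps are all absent consists of residual noise and would
normalize to its own peak-to-peak amplitude, making noise wiggles look
like prominent fiducial points.  For single-beat averages no residual
estimate exists and the relative criterion alone applies.

**Classification.**  The averaged waveform is *traditional* exactly when
all four FPs are found and ordered MC < AO < AC < MO; otherwise
non-traditional, with per-point availability retained (NT waveforms may
still support a subset of CTIs).  This is an explicit algorithmic
surrogate for the expert visual classification that is the field's
standard; outputs carry that provenance, and agreement with human calls on
real data is untested here.

**Cardiac time intervals.**  PEP = AO latency + Q-to-R; IVCT = AO − MC;
LVET = AC − AO; IVRT = MO − AC.  Partial FP sets yield partial interval
sets.  Two identities hold exactly on complete sets:
(PEP − Q-to-R) + LVET = AC latency, and IVCT + LVET + IVRT = MO − MC.

**Sonogram synchronization.**  The RR sequence read off the sonogram is
slid along the device RR series; the cost at each start is the mean
absolute interval difference, and the exhaustive scan over all starts *is*
the matcher's definition (the implementation vectorizes that same scan and
is tested for exact equality against a literal loop).  A match is accepted
when cost ≤ 15 ms and the runner-up trails by ≥ 10 ms — thresholds chosen
to sit well above the 2.64 ms pixel quantization plus reading jitter, and
deliberately conservative: a perfectly regular rhythm has margin 0 and is
rejected as ambiguous rather than guessed at, and in long low-variability
series correct 4-beat matches may be rejected too.  An optional search
centre and radius model the coarse event-button synchrony that precedes RR
refinement.

## Agreement statistics

Per patient and valve event, the Echo−FP difference is the mean over
repeated sonogram measures of (echo time-from-R − FP latency); negative
means the valve event precedes the FP.  Group statistics use the sample SD
(n−1).  The healthy 95% reference range is mean ± 1.96·SD from the
packaged healthy-subject statistics (MC 4±11 n=41, AO −3±11 n=39,
AC −5±12 n=39, MO −7±19 n=39).  Two range modes exist because the
published rounded ranges are not always self-consistent (1.96×12 = 23.5
prints as 23): `exact` computes 1.96·SD, `printed` uses the published
integer half-widths.  Range inclusion is inclusive at both bounds — one
published AO difference sits exactly on the range edge and is counted
inside.  One published within-range count (MO, 17) is not reproducible
from the published per-patient column, which enumerates to 16 under any
inclusion convention; the package reports the enumerated count and
surfaces the discrepancy in its outputs.  The packaged cohort fixture
likewise follows the published stratum counts exactly; these leave 4 of
the 90 patients without an EF value (the prose says five, the table sums
say four — the tables win).

Tests are computed from summary statistics, since the healthy reference
exists only as published means/SDs: Welch's unequal-variance t with
Welch–Satterthwaite degrees of freedom (two-sided); an F test of variance
equality with F = larger/smaller variance and a doubled upper tail capped
at 1 (at F = 1 with unequal group sizes this is slightly below 1 — the
price of the simple doubling rule); and the likelihood-ratio G test of
independence, G = 2·Σ O·ln(O/E), df = (r−1)(c−1), chi-square reference,
zero cells contributing nothing, with the Williams correction available
but off by default.

## Problem sizes and numerical choices

The package's validation runs use: 20–30 s records at 200 Hz (resampled to
1 kHz), 100–200-patient synthetic cohorts, 100 alignment trials over
300-beat RR series and 1,000 random matcher-equality instances.  These
sizes put Monte-Carlo assertions comfortably past their tolerances while
keeping a full validation run under a minute on one core.  Degenerate
inputs are handled explicitly: flat signals yield empty beat series (not
errors), beats with no usable quality raise a dedicated error, a zero-SD
reference range is returned degenerate, and windows that a beat does not
cover raise a coverage error naming the window.

## Known limitations

- The T/NT call is an algorithmic surrogate; concordance with expert
  visual classification of real SCG waveforms is unvalidated.
- FP search windows are literature-informed defaults, not fitted values;
  atypical conduction (long PR, bundle-branch block) may need custom
  windows.
- Only the dorso-ventral acceleration axis is modelled and analysed;
  rotational (gyroscopic) components are out of scope.
- The agreement layer reproduces group-level statistics from published
  per-patient data; raw healthy-subject distributions are not available,
  so only summary-statistic tests are possible.
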