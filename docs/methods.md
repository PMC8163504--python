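# Methods

## What is being modelled

One imaging session is a field of view (FOV) of dorsolateral striatum
recorded at 30 Hz while a head-fixed mouse alternates immobility and forward
locomotion on a circular treadmill. The analysis operates entirely at the
extracted-trace level: per-neuron raw fluorescence, a paired background
(neuropil) trace per neuron, a red-channel intensity per neuron, and a
velocity trace on the imaging frame clock. Motion correction and source
extraction are upstream of this package and out of scope.

## Trace processing

Neuropil correction subtracts the paired background trace with weight 1.0
(configurable in [0, 1]); correction happens before ΔF/F. F₀ is the 10th
percentile of the corrected trace — robust when transients are sparse, which
the detector's stringency guarantees. Smoothing is a centred moving average
over round(0.150 s × frame rate) frames, rounding half up (4.5 → 5 at
30 Hz), with shrinking windows at the edges so output length equals input
length and constants are preserved exactly. A moving average (not a
Gaussian) was chosen because nothing beyond "a 150 ms window" constrains the
shape, and the box kernel keeps the impulse response trivially verifiable.

## Transient detection

Baseline statistics are μ = median and σ = 1.4826 × MAD over the *full*
smoothed ΔF/F trace. Robust statistics, rather than a quiet-period
selection, make the estimate insensitive to the transients riding on the
baseline (a 1% contamination at +10 ΔF/F moves σ by < 2%); estimating σ from
immobility periods only is available as an alternative by passing a trace
slice. A peak is accepted when height above μ ≥ 5σ, topographic prominence
≥ 5σ, and width at half prominence ≥ 140 ms (linear interpolation between
frames, clipped at the prominence bases, so edge-truncated events are kept
when their measurable width already suffices). Implementation uses
scipy.signal.find_peaks/peak_widths — the Python counterpart of the MATLAB
findpeaks workflow — and the test suite holds it to exact equivalence with
an independent brute-force scan written from the definitions. Peaks closer
than one smoothing window are merged to the larger, ties to the earlier;
"amplitude" always means peak ΔF/F minus μ, with prominence reported
separately.

Two activity scopes exist because the field uses both: `session` (≥ 1
transient anywhere) and `locomotion` (≥ 1 transient peak inside a movement
bout). Locomotion scope is the default for every ensemble metric, since the
ensemble of interest is the movement-recruited one.

## Behavior segmentation

All intervals are half-open `[start, end)` in seconds on the frame grid.
Immobility: maximal runs with |v| < 0.2 cm/s, trimmed by 0.5 s at each end
that arises from an actual threshold crossing (session edges are not
trimmed), kept if ≥ 4 s remain. Bout candidates: maximal runs with |v| >
0.4 cm/s lasting ≥ 4 s. A candidate qualifies when an immobility interval
(≥ 4 s by construction) ends within 1.0 s before its start and another
begins within 1.0 s after its end. The 1.0 s gap tolerance exists because
the guard band plus the 0.2–0.4 cm/s acceleration band means a trimmed
immobility interval can never abut the candidate run exactly; 1.0 s covers
the guard (0.5 s) plus any realistic ramp through the inter-threshold band.
Onsets/offsets are refined to the first/last sample of the contiguous run
around the candidate that is ≥ 2 SD away from the mean immobile velocity
(session-wide over immobility samples), bounded by the adjacent immobility
intervals; if the candidate edge itself is within 2 SD the edge is kept, so
the rule always terminates. The published criterion also requires absence of
postural movement on video; video is out of scope here, so velocity alone
defines immobility — a documented limitation for real data.

## Classification

tdTomato-positive neurons (red intensity above an exact 1-D two-means split
of the red distribution) take the reporter line's labelled class.
Red-negative neurons are interneurons when their baseline fluorescence
exceeds mean + 2 SD of the red-negative population's baselines or their
immobile-period event rate exceeds 0.1 /s (tonic activity); otherwise they
take the complementary SPN class. The population statistics deliberately use
the plain (not robust) mean/SD of all red-negative baselines: SPNs dominate
that mixture and the interneuron minority inflates the SD, which places the
cut between the two modes instead of in the SPN distribution's upper tail.
Morphology and transient kinetics, which the original classification also
consulted, are unavailable at trace level; the declared thresholds stand in
for them.

## Ensemble metrics

Ensemble size = 100 × active / imaged per class (undefined, not zero, when a
class has no imaged neurons). Bias index = (d − i)/(d + i) ∈ [−1, 1].
Frequencies and amplitudes average over *active* neurons; ensemble size over
*all imaged* neurons. Velocity bins are [k·0.4, (k+1)·0.4) cm/s on |v|; the
occupancy-normalised rate satisfies Σ_b rate_b·time_b·n = total events
exactly. Event times are peak times throughout (the detector defines no
onset time); the difference from transient-onset binning is bounded by the
kernel rise time (~100 ms, i.e. at most one 0.4 cm/s bin during strong
accelerations). Per-SPN velocity rates normalise by active SPNs (matching
"per active" usage in the frequency metrics); per-imaged is an option.
Peri-bout curves are 200 ms histograms within ±4 s of onsets/offsets,
normalised by bouts × active neurons × bin width. Cumulative recruitment
takes, per locomotion-active neuron, the cumulative |v| distance at its
first in-bout event; the CDF is non-decreasing and reaches 1 by session
end. QC: ≥ 5 active dSPNs, ≥ 5 active iSPNs, ≥ 500 cm travelled.

## Group statistics

Mann-Whitney U and Wilcoxon signed-rank (scipy, exact for small untied
samples — verified against full permutation enumeration in tests), two-way
mixed ANOVA (pingouin; Greenhouse-Geisser correction when the repeated
factor has more than two levels), and Bonferroni-corrected within-group
paired t-tests against baseline when the interaction is significant at
0.05. Stars: */**/***/**** at 0.05/0.01/0.005/0.001. The experimental unit
is always the FOV. The turning bias index is (ipsi − contra)/total with
straight passes counted in the denominator by default (excludable), since
"total number of turns" is ambiguous on that point.

## Synthetic sessions: what they emulate, and what not

The generator's defaults are the study conditions: 327 neurons per FOV;
class fractions (0.475, 0.475, 0.05) — consistent with "~95% SPNs" and a
symmetric split, since exact printed values do not exist; ensemble fractions
0.169 (dSPN) and 0.186 (iSPN); per-2 s recruitment probability 0.10, which
fixes the members' locomotion event rate at −ln(0.9)/2 ≈ 0.0527 /s.
Locomotion state, for event generation, is the generated bout window itself
(ramps included): the recruitment calibration is a statement about 2 s
windows tiled over bouts, which is exactly what the analysis measures. All
SPNs fire at 0.005 /s while immobile ("exceedingly low" is the only
constraint the source offers; this puts the immobile:moving frequency ratio
near the 1:10–1:20 range the figures suggest). Non-member SPNs emit no
locomotion-locked events — the generator's ensemble is defined by movement
firing, as is the measured one. Interneurons fire at 0.2 /s regardless of
state and carry a +0.5 ΔF/F baseline offset, emulating tonically active
(cholinergic-like) cells.

Fluorescence: events ⊗ double-exponential kernel (rise 50 ms, decay 250 ms —
not printed anywhere; chosen to match published GCaMP6f kinetics and to give
a single rendered event a half-prominence width comfortably above 140 ms),
amplitudes log-normal with mean 0.8 and SD 0.4 ΔF/F, Gaussian noise SD 0.05
ΔF/F, per-neuron baselines N(1.0, 0.05) a.u., and a shared slow neuropil
signal added to every cell with weight 1.0 and recorded alone as the
background trace. Default SNR is therefore ~10 and the detector operates
away from its thresholds, which is the regime the published criteria
("intentionally stringent") imply.

Velocity: free mode draws bout plateau speeds N(8, 1.6) cm/s and durations
N(8, 1.2) s (clipped ≥ 5 s) at 2 bouts/min with inter-bout immobility ≥ 6 s
and 0.5 s linear ramps, plus immobile Gaussian noise of SD 0.03 cm/s so the
0.2 cm/s criterion is met with wide margin; every generated bout satisfies
the bout definition and is detected by the segmenter at default noise.
Motorized mode: 10 s lead-in, then 10 s bouts at 10 cm/s every 20 s.
Condition presets multiply the two ensemble fractions (capped at 1):
antagonist (0.5, 3.3), agonist_low (1.3, 1.0), agonist_high (0.6, 0.3),
ohda_day1 (0.5, 2.2), ohda_day30 (0.5, 1.0), ldopa_on_lesion (5.0, 0.5 —
i.e. 10× the lesioned dSPN fraction, half the pre-lesion iSPN fraction).

Default session length is 300 s. Real sessions run ≥ 20 min; 300 s at these
rates already gives every estimator (ensemble size, recruitment, state
frequencies) a sampling error well inside the recovery tolerances, and it
is the package's default problem size for tests and the acceptance script.

What the generator does *not* emulate — and hence what passing recovery
tests cannot certify about real recordings: photobleaching and slow drift,
motion artifacts, spatially correlated (distance-dependent) neuropil,
velocity-graded firing within bouts (rates are piecewise-constant by
state), dyskinetic or postural behavior, and pixel-level crosstalk between
neighbouring sources. Classification on real data additionally leans on
morphology and kinetics this package does not see.

## Numerical choices and degenerate inputs

Same seed + parameters → bit-identical sessions; the root seed is split
into named substreams (velocity, population, events, rendering), so each
stage is reproducible in isolation. Constant traces raise "degenerate
trace" rather than returning σ = 0; F₀ ≤ 0 raises naming the neuron row;
sessions too short for one bout raise; a session with no immobility yields
zero bouts with a warning; empty velocity bins and zero-imaged classes are
NaN, never zero. Exact-count (largest-remainder) class assignment is
available alongside the multinomial default for deterministic tests. The
1-D two-means red split is an exact scan, deterministic by construction.

## Known limitations

Peak time stands in for transient onset in all binning. Immobility lacks
the video criterion. The interneuron thresholds are declared, not derived.
The per-2 s recruitment measured from a single 300 s session carries a
sampling SE of ~0.8–0.9 percentage points (≈ 30 windows × ~50 members),
so single-session recovery scatters accordingly; multi-FOV quantities
average this away.
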