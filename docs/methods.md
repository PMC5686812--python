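# Methods

This note documents the models, estimators and numerical choices behind
`dendrocalc`, and what the synthetic-data experiments do and do not
establish about real recordings.

## Signal model and generator

Traces emulate 2 Hz GCaMP6s recordings in 60 s trials — five running trials
followed by one resting trial per session, matching the acquisition
protocol the analysis targets. Raw fluorescence is

    F(t) = f_rest · (1 + A(t)) + background + ε(t)

with `f_rest = 100` a.u. (per-ROI jitter ±10% by default), a constant
vessel background of 10 a.u., and additive Gaussian noise on raw F
(default SD 2, i.e. 2% of baseline; a multiplicative shot-noise-like mode
is available). `A(t)` sums plateau-shaped event waveforms: the signal rises
from baseline to the event amplitude within one sampling interval (the
onset frame is already at full amplitude; there is no intermediate
half-amplitude sample), stays flat for the drawn duration, then decays
exponentially with τ = 1.0 s. The decay tail is rendered as exactly zero
once below ΔF/F₀ = 10⁻³, which guarantees clean baseline samples between
events; events are placed with a one-frame guard gap so adjacent waveforms
never merge above any positive threshold. Placement retries uniform onsets
on collision — retrying the onset, never the duration, keeps the duration
distribution unbiased by crowding.

Event durations follow a two-component lognormal mixture: a short component
(median 2 s, σ = 0.5) for ordinary transients and a long component
(median 12 s, σ = 0.3) for prolonged plateau events, mixed with
probability `p_long` (0.10 by default; disease-like regimes use larger
values). Peak amplitude is coupled to duration as
`amp = 0.5 + 0.15·duration + N(0, 0.1)`, floored at 0.2, which reproduces
the positive duration–amplitude correlation of dendritic calcium spikes.
Event counts per trial are Poisson with 1 event/min on running trials
(half that when resting), or fixed per trial for deterministic recovery
experiments. No indicator kinetics or noise magnitudes were available for
the original recordings, so τ, the noise level and the mixture spreads are
engineering choices, stated here once and not tuned per experiment.

Spine traces are composed in fractional (ΔF/F-like) space —
`0.7 × parent-dendrite signal + intrinsic synaptic events` — and mapped
back to raw F on the spine's own baseline, so the 0.7 subtraction
downstream is exactly invertible at zero noise. Intrinsic events are drawn
from the short duration component only; each parent dendritic event
elicits a spine response with probability 0.6 by default, and an optional
depotentiation factor attenuates responses that follow an earlier
prolonged dendritic event within the same trial. All randomness flows
through one explicit seed; identical configurations are bit-identical.

## Baseline, threshold and detection

F₀ per ROI and per 1-minute window is the mean of the lowest
`ceil(0.1·n)` F samples (≥ 1); a short trailing remainder is merged into
the last window, and a window under 10 samples is an error. F₀ ≤ 0 raises,
as it indicates background over-subtraction.

The "3 × SD of baseline" rule needs a definition of *baseline samples*,
which the field rarely spells out. The default here is a two-pass scheme:
pass 1 takes the SD of the below-median ΔF/F₀ samples of the window and
forms a provisional threshold; pass 2 recomputes the SD over all samples
outside provisional crossings, and the final threshold is 3 × that SD.
Restricting instead to the lowest-10% (F₀) set systematically
underestimates the SD; that mode (`baseline_mode="f0_set"`) is retained
for sensitivity analysis. An absolute threshold floor of ΔF/F₀ = 0.05
guards degenerate zero-noise windows where the SD collapses; the stored
`baseline_sd` is always the measured SD, so `threshold = 3 × baseline_sd`
holds exactly whenever the floor is not binding.

Known limitation: when events occupy more than about half of a window
(several long plateaus in one minute), the window median itself is
elevated, pass 1 overestimates the baseline SD and the threshold inflates;
measured durations then shorten. At the default event rate this biases the
simulated prolonged-dendrite fraction by ≈ 0.01–0.02 — visible but well
inside the tolerance of the verification experiments below. Heavier
activity regimes should use longer windows or the `f0_set` mode.

Detection is a maximal-run scan: every run of consecutive samples with
ΔF/F₀ ≥ threshold is one transient, split at trial boundaries, with no gap
merging and a minimum length of one sample. Integrated activity sums the
full supra-threshold ΔF/F₀ × dt (a threshold-subtracted variant is a
config flag). Prolonged (> 8 s) and large-amplitude (> 400%) flags use
strict inequalities. The duration–amplitude correlation is Pearson by
default, Spearman selectable.

## Ground truth versus measured duration

The rendered waveform carries a decay tail, so the supra-threshold
duration a detector measures exceeds the drawn plateau duration by
τ·ln(amp/threshold). Recovery experiments therefore check against the
*exact expected measurement*: `GroundTruthEvents.expected_detections`
computes the supra-threshold runs of the clean (noiseless) trace at the
pipeline's own per-sample threshold, which at zero noise the detector must
reproduce sample-for-sample; plateau durations are additionally recovered
within one sample after subtracting the analytic decay allowance.

The same logic gives a closed-form expectation for the prolonged-dendrite
fraction: an event with plateau length n frames and amplitude A is
measured prolonged iff `n + floor(τ·fs·ln(A/θ))` frames exceed 8 s.
Integrating this discretised rule over the duration mixture and the
amplitude model (dense quadrature) yields the per-event probability p, and
with a Poisson(Λ) event count the fraction of *event-exhibiting* dendrites
with ≥ 1 prolonged event — the reported denominator — is
`(1 − e^{−Λp})/(1 − e^{−Λ})`. The verification experiment root-finds
`p_long` so this expectation equals 0.47, simulates 500 dendrites over a
5-minute running period at zero noise, and requires the pipeline's
estimate to land within 3 binomial standard errors.

## Spine unmixing and the first-vs-third comparison

`spine_specific` subtracts 0.7 × the parent dendrite ΔF/F₀ elementwise and
re-derives the 3 × SD threshold on the subtracted series with the same
two-pass rule. The 0.7 coefficient is fixed by the underlying
back-propagating-AP calibration but exposed for sensitivity analysis;
scale 0 reduces the pipeline to raw spine analysis. Activity calls take
the spine-specific peak within the dendritic event's [onset, offset]
window (the window definition is ours; nothing narrower is specified
anywhere). The structural variant classifies by head/shaft intensity
ratio with cutoff 1.0, the midpoint between the published active (1.56)
and inactive (0.46) means.

The first-vs-third comparison requires ≥ 3 dendritic transients in a
trial, pairs each spine's peak at the 1st and 3rd, and stratifies by
whether the 2nd lasted > 8 s. With more than three transients the first
triplet is primary; sliding triplets can be emitted but are flagged
non-independent. Peaks are measured on the spine-specific trace by
default (raw spine traces selectable).

The depotentiation verification experiment runs 200 replicates of one
dendrite with exactly three prolonged transients in a 180 s running trial
and 50 responding spines, 20% response attenuation after the first
prolonged event, and low trace noise (0.5% of baseline) so that the three
events are identified unambiguously — without gap merging, noise near the
threshold can fragment a decay tail into spurious short events, which
would scramble the 1st/2nd/3rd labelling rather than test the statistics.
The paired Wilcoxon route must detect the negative shift in ≥ 80% of
replicates; a no-effect control stratum (all-short transients) checks that
detections stay near the nominal false-positive rate.

## Morphometry

Size ratios are computed in the reduced Mean-OD form; the literal
Area-carrying expression is kept and asserted equal to machine precision,
since the unreduced form is what gets printed in methods sections. Shaft
and background samples are taken adjacent to each spine (per-segment
averaging is the caller's choice). The rendered-image round trip uses
measurement masks on the structure cores — the head disk eroded by 2 px
and the central shaft rows — as a careful analyst would place them; this
keeps the recovered ratio within 2% of truth at blur σ ≤ 1 px and noise
≤ 2% of dynamic range. Turnover calls a spine present when its ratio
reaches 0.2 (no criterion exists in the source material; the value is far
below any real spine's ratio and far above background), with stable,
eliminated and formed rates all relative to the session-0 count, so
stable + eliminated = 1.

## Statistics

Normality routing uses the Lilliefors-corrected KS test by default because
the plain KS against a Normal fitted to the same sample is
anticonservative; the plain test is selectable for fidelity with
SPSS-style output. Rank tests use mid-ranks with exact enumeration for
small tie-free samples and the normal approximation with continuity
correction otherwise. Zero-variance samples route to the nonparametric
branch with a warning; identical paired samples short-circuit to p = 1
with a warning, since neither test statistic is defined. No
multiple-testing correction is applied by default (Benjamini–Hochberg is
available on the comparisons table). Calibration: the routed procedure's
empirical type-I error stays within [0.035, 0.065] at α = 0.05 under both
Normal and lognormal nulls (2,000 replicates, n = 30/group).

## What the synthetic experiments do not show

The generator reproduces the statistical structure the analysis assumes —
plateau-shaped events, duration/amplitude coupling, the 0.7 dendritic
contamination, ratio-based spine intensities — but not optics (PSF,
depth-dependent scattering), motion artifacts, neuropil contamination,
indicator nonlinearity/saturation, or bleaching. Passing these experiments
therefore certifies the *computational* chain (definitions implemented
exactly, estimators unbiased at the stated noise levels, injected effects
recoverable at the stated power), not the biological validity of any
particular recording. Headline fractions from the original in-vivo
datasets (e.g. ~47% vs ~18% of dendrites with prolonged transients) derive
from recordings that are not publicly deposited and are not reproduced
here; the 0.47 figure is used only as the calibration target of the
closed-form recovery experiment.

## Problem sizes

Verification runs use 1,000 random traces for detector equivalence, 200
injected events for exact recovery, 10,000 random inputs for the formula
identities, 500 dendrites for the prolonged fraction, 200 replicates × 50
spines for depotentiation power, 2,000 replicates per null for routing
calibration, and 25 rendered images plus 100 simulated spines for the
morphometry round trip — sizes at which every Monte-Carlo tolerance above
is meaningful while the whole battery completes in well under a minute.
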