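"""Synthetic fluorescence traces and two-channel spine images with ground truth.

The generator emulates 2 Hz GCaMP6s recordings over 60 s trials (five running
trials plus one resting trial by default): somatic and dendritic calcium
events rendered as plateau waveforms (one-sample rise, flat top at the drawn
amplitude, exponential decay), spine traces composed of a 0.7-scaled copy of
the parent dendrite's fractional signal plus spine-intrinsic synaptic events,
and a vessel-background offset with additive Gaussian noise on raw F.  Event
durations follow a two-component lognormal mixture whose long component
models prolonged (plateau-like) dendritic events; peak amplitude is coupled
to duration as ``amp = a + b·duration + ε`` so the duration–amplitude
correlation of real dendritic calcium spikes is reproduced.

Every injected event is recorded in :class:`GroundTruthEvents` together with
the rendered noiseless fractional trace, so downstream stages can be checked
against exact expectations.  Because the rendered waveform carries a decay
tail, the supra-threshold duration a detector measures exceeds the drawn
plateau duration by the decay time above threshold;
:meth:`GroundTruthEvents.expected_detections` computes the exact expected
event boundaries for any threshold from the clean trace, and
:func:`prolonged_event_probability` gives the closed-form (quadrature)
probability that a single event is measured as prolonged, which
:func:`expected_prolonged_fraction` turns into the analytic fraction of
dendrites with at least one prolonged event.

All randomness flows through an explicit seed; identical configurations give
bit-identical output.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal

import numpy as np
from scipy import optimize, stats
from skimage.filters import gaussian as _gaussian_blur

from ._util import config_hash, contiguous_runs, split_runs_at_boundaries
from .imageio_roi import RawTraceSet


# ---------------------------------------------------------------------------
# configuration


@dataclass
class DurationMixture:
    """Two-component lognormal mixture of event durations (seconds).

    The short component models ordinary transients (median ~2 s); the long
    component models prolonged plateau events (median ~12 s).  ``p_long`` is
    the probability an event is drawn from the long component.
    """

    mu_short: float = math.log(2.0)
    sigma_short: float = 0.5
    mu_long: float = math.log(12.0)
    sigma_long: float = 0.3
    p_long: float = 0.10

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_long <= 1.0:
            raise ValueError("p_long must be in [0, 1]")
        if self.sigma_short <= 0 or self.sigma_long <= 0:
            raise ValueError("mixture sigmas must be > 0")

    def pdf(self, d: np.ndarray) -> np.ndarray:
        short = stats.lognorm.pdf(d, self.sigma_short, scale=math.exp(self.mu_short))
        long = stats.lognorm.pdf(d, self.sigma_long, scale=math.exp(self.mu_long))
        return (1.0 - self.p_long) * short + self.p_long * long


@dataclass
class AmpCoupling:
    """Peak amplitude model: amp = intercept + slope·duration + N(0, noise_sd)."""

    intercept: float = 0.5
    slope: float = 0.15
    noise_sd: float = 0.10
    min_amplitude: float = 0.2


@dataclass
class TraceGenConfig:
    """Acquisition and signal parameters of the trace generator.

    Defaults follow the recording protocol the analysis is built for: 2 Hz
    sampling, 60 s trials, five running trials and one resting trial.  Noise
    and kinetics are engineering choices (no indicator kinetics were
    specified for the original recordings): decay tau 1.0 s, 2% additive
    noise on raw F.
    """

    sampling_rate_hz: float = 2.0
    trial_length_s: float = 60.0
    n_running_trials: int = 5
    n_resting_trials: int = 1
    event_rate_per_min: float = 1.0
    resting_rate_factor: float = 0.5
    duration_dist: DurationMixture = field(default_factory=DurationMixture)
    amp_coupling: AmpCoupling = field(default_factory=AmpCoupling)
    spine_event_rate_per_min: float = 1.0
    #: probability a spine emits an intrinsic synaptic event at each parent
    #: dendritic event
    spine_response_prob: float = 0.6
    #: multiplier applied to spine responses occurring after an earlier
    #: prolonged dendritic event in the same trial (1.0 = no depotentiation)
    depotentiation_factor: float = 1.0
    bap_scale: float = 0.7
    tau_decay_s: float = 1.0
    #: fractional level below which the decay tail is rendered as exactly 0,
    #: guaranteeing clean baseline samples between events
    decay_cut: float = 1e-3
    noise_sd: float = 2.0
    noise_mode: Literal["additive", "multiplicative"] = "additive"
    f_rest: float = 100.0
    #: per-ROI baseline spread: f_rest drawn uniformly in ±jitter fraction
    f_rest_jitter: float = 0.1
    background_level: float = 10.0
    #: when set, every trial receives exactly this many events (no Poisson
    #: draw); useful for deterministic recovery experiments
    fixed_events_per_trial: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be > 0")
        if self.f_rest <= 0:
            raise ValueError("f_rest must be > 0")
        if not self.f_rest > self.background_level >= 0:
            raise ValueError("require f_rest > background_level >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.event_rate_per_min < 0 or self.spine_event_rate_per_min < 0:
            raise ValueError("event rates must be >= 0")
        if not 0.0 <= self.spine_response_prob <= 1.0:
            raise ValueError("spine_response_prob must be in [0, 1]")
        if self.tau_decay_s <= 0:
            raise ValueError("tau_decay_s must be > 0")

    @property
    def frames_per_trial(self) -> int:
        return int(round(self.trial_length_s * self.sampling_rate_hz))

    @property
    def n_trials(self) -> int:
        return self.n_running_trials + self.n_resting_trials


# ---------------------------------------------------------------------------
# ground truth containers


@dataclass
class GroundTruthEvent:
    """One injected somatic/dendritic event (plateau duration on the frame grid)."""

    roi_id: str
    trial: int
    onset_frame: int
    n_plateau: int
    duration_s: float
    amplitude: float
    long_component: bool
    prolonged: bool  # duration_s > 8 (plateau duration)


@dataclass
class SpineEventRecord:
    """One spine-intrinsic synaptic event."""

    spine_id: str
    trial: int
    onset_frame: int
    n_plateau: int
    duration_s: float
    amplitude: float
    kind: Literal["response", "spontaneous"]
    dendrite_event_index: int | None
    attenuated: bool


@dataclass
class GroundTruthEvents:
    """Everything the generator injected, plus the clean fractional traces."""

    events: dict[str, list[GroundTruthEvent]]
    spine_events: dict[str, list[SpineEventRecord]]
    clean: dict[str, np.ndarray]
    spine_intrinsic_clean: dict[str, np.ndarray]
    trial_index: np.ndarray
    sampling_rate_hz: float

    def n_events(self) -> int:
        return sum(len(v) for v in self.events.values())

    def expected_detections(
        self, roi_id: str, threshold: float | np.ndarray, intrinsic: bool = False
    ) -> list[tuple[int, int, float]]:
        """Exact supra-threshold runs of the clean trace: (onset, offset, peak).

        This is what an ideal detector operating at ``threshold`` measures on
        the noiseless signal; runs are split at trial boundaries.
        """
        x = (self.spine_intrinsic_clean if intrinsic else self.clean)[roi_id]
        runs = contiguous_runs(x >= threshold)
        boundaries = np.flatnonzero(np.diff(self.trial_index) != 0) + 1
        runs = split_runs_at_boundaries(runs, boundaries)
        return [(a, b, float(x[a : b + 1].max())) for a, b in runs]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "events": {k: [asdict(e) for e in v] for k, v in self.events.items()},
            "spine_events": {
                k: [asdict(e) for e in v] for k, v in self.spine_events.items()
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1))


# ---------------------------------------------------------------------------
# waveform rendering and placement


def _n_decay_frames(amplitude: float, level: float, fs: float, tau: float) -> int:
    """Frames the decay tail spends at or above ``level`` (tail starts one
    frame after the plateau at amp·exp(−dt/tau))."""
    if amplitude < level or level <= 0:
        return 0
    return int(math.floor(tau * fs * math.log(amplitude / level)))


def _render_event(
    sig: np.ndarray, onset: int, n_plateau: int, amp: float, fs: float, tau: float, cut: float
) -> None:
    """Add one plateau waveform in place: flat top then exponential decay,
    truncated to exactly zero once below ``cut``."""
    sig[onset : onset + n_plateau] += amp
    n_dec = _n_decay_frames(amp, cut, fs, tau)
    if n_dec > 0:
        j = np.arange(1, n_dec + 1)
        tail = amp * np.exp(-j / (fs * tau))
        stop = min(onset + n_plateau + n_dec, sig.size)
        k = stop - (onset + n_plateau)
        if k > 0:
            sig[onset + n_plateau : stop] += tail[:k]


def _extent_frames(n_plateau: int, amp: float, fs: float, tau: float, cut: float) -> int:
    return n_plateau + _n_decay_frames(amp, cut, fs, tau)


def _place_events(
    rng: np.random.Generator,
    occupancy: np.ndarray,
    start: int,
    stop: int,
    extents: list[int],
    max_tries: int = 500,
) -> list[int | None]:
    """Draw non-overlapping onsets in [start, stop) for events of given extents.

    Onsets are uniform, retried on collision (duration marginals are
    unaffected by onset retries); if no uniform draw fits, the first free slot
    is used; an event that cannot fit at all is dropped (returned as None).
    A one-frame guard gap is kept on both sides of every event so adjacent
    waveforms never merge above any positive threshold.
    """
    out: list[int | None] = []
    for ext in extents:
        hi = stop - ext
        placed = None
        if hi > start:
            for _ in range(max_tries):
                k = int(rng.integers(start, hi))
                lo, hi2 = max(start, k - 1), min(stop, k + ext + 1)
                if not occupancy[lo:hi2].any():
                    placed = k
                    break
            if placed is None:
                for k in range(start, hi):
                    lo, hi2 = max(start, k - 1), min(stop, k + ext + 1)
                    if not occupancy[lo:hi2].any():
                        placed = k
                        break
        if placed is not None:
            occupancy[placed : placed + ext + 1] = True
        out.append(placed)
    return out


def _draw_duration(rng: np.random.Generator, mix: DurationMixture) -> tuple[float, bool]:
    is_long = bool(rng.random() < mix.p_long)
    if is_long:
        return float(rng.lognormal(mix.mu_long, mix.sigma_long)), True
    return float(rng.lognormal(mix.mu_short, mix.sigma_short)), False


def _draw_amplitude(rng: np.random.Generator, amp: AmpCoupling, duration_s: float) -> float:
    a = amp.intercept + amp.slope * duration_s + rng.normal(0.0, amp.noise_sd)
    return max(amp.min_amplitude, float(a))


# ---------------------------------------------------------------------------
# trace generation


def generate_trace_set(
    cfg: TraceGenConfig,
    n_somas: int = 0,
    n_dendrites: int = 1,
    n_spines_per_dendrite: int = 0,
) -> tuple[RawTraceSet, GroundTruthEvents]:
    """Generate raw fluorescence traces plus full ground truth.

    Raw traces are ``F(t) = f_rest·(1 + A(t)) + background + noise`` where
    A(t) sums the plateau event waveforms; spine traces carry
    ``bap_scale × parent-dendrite fractional signal + intrinsic events``
    re-expressed on the spine's own baseline.
    """
    if n_somas < 0 or n_dendrites < 0 or n_spines_per_dendrite < 0:
        raise ValueError("ROI counts must be >= 0")
    rng = np.random.default_rng(cfg.seed)
    fs = cfg.sampling_rate_hz
    npt = cfg.frames_per_trial
    n_frames = npt * cfg.n_trials
    trial_index = np.repeat(np.arange(cfg.n_trials), npt)
    trial_states = {
        t: ("running" if t < cfg.n_running_trials else "resting")
        for t in range(cfg.n_trials)
    }
    trial_min = cfg.trial_length_s / 60.0

    soma_ids = [f"soma{i:02d}" for i in range(n_somas)]
    den_ids = [f"den{i:03d}" for i in range(n_dendrites)]
    spine_ids = {
        d: [f"sp{i:03d}_{j:02d}" for j in range(n_spines_per_dendrite)]
        for i, d in enumerate(den_ids)
    }

    events: dict[str, list[GroundTruthEvent]] = {}
    spine_events: dict[str, list[SpineEventRecord]] = {}
    clean: dict[str, np.ndarray] = {}
    intrinsic_clean: dict[str, np.ndarray] = {}

    def _trial_event_count(state: str) -> int:
        if cfg.fixed_events_per_trial is not None:
            return cfg.fixed_events_per_trial
        lam = cfg.event_rate_per_min * trial_min
        if state == "resting":
            lam *= cfg.resting_rate_factor
        return int(rng.poisson(lam))

    def _make_roi_events(roi_id: str) -> None:
        sig = np.zeros(n_frames)
        occ = np.zeros(n_frames, dtype=bool)
        ev_list: list[GroundTruthEvent] = []
        for t in range(cfg.n_trials):
            start, stop = t * npt, (t + 1) * npt
            n_ev = _trial_event_count(trial_states[t])
            drawn = []
            for _ in range(n_ev):
                d, is_long = _draw_duration(rng, cfg.duration_dist)
                amp = _draw_amplitude(rng, cfg.amp_coupling, d)
                n_plat = max(1, int(np.round(d * fs)))
                drawn.append((d, is_long, amp, n_plat))
            extents = [
                _extent_frames(n_plat, amp, fs, cfg.tau_decay_s, cfg.decay_cut)
                for (_, _, amp, n_plat) in drawn
            ]
            onsets = _place_events(rng, occ, start, stop, extents)
            for (d, is_long, amp, n_plat), onset in zip(drawn, onsets):
                if onset is None:
                    continue  # could not fit; dropped from truth and trace alike
                _render_event(sig, onset, n_plat, amp, fs, cfg.tau_decay_s, cfg.decay_cut)
                dur = n_plat / fs
                ev_list.append(
                    GroundTruthEvent(
                        roi_id=roi_id,
                        trial=t,
                        onset_frame=onset,
                        n_plateau=n_plat,
                        duration_s=dur,
                        amplitude=amp,
                        long_component=is_long,
                        prolonged=dur > 8.0,
                    )
                )
        ev_list.sort(key=lambda e: e.onset_frame)
        events[roi_id] = ev_list
        clean[roi_id] = sig

    for rid in soma_ids + den_ids:
        _make_roi_events(rid)

    # spines: inherited dendritic component + intrinsic synaptic events
    short_only = DurationMixture(
        mu_short=cfg.duration_dist.mu_short,
        sigma_short=cfg.duration_dist.sigma_short,
        mu_long=cfg.duration_dist.mu_long,
        sigma_long=cfg.duration_dist.sigma_long,
        p_long=0.0,
    )
    parents: dict[str, str] = {}
    for den in den_ids:
        den_events = events[den]
        for sp in spine_ids[den]:
            parents[sp] = den
            intr = np.zeros(n_frames)
            occ = np.zeros(n_frames, dtype=bool)
            recs: list[SpineEventRecord] = []
            # responses at parent dendritic events
            for t in range(cfg.n_trials):
                t_events = [e for e in den_events if e.trial == t]
                prolonged_seen = False
                for idx, de in enumerate(t_events):
                    responded = rng.random() < cfg.spine_response_prob
                    d, _ = _draw_duration(rng, short_only)
                    amp = _draw_amplitude(rng, cfg.amp_coupling, d)
                    if responded:
                        if prolonged_seen and cfg.depotentiation_factor != 1.0:
                            amp *= cfg.depotentiation_factor
                            att = True
                        else:
                            att = False
                        n_plat = max(1, int(np.round(d * fs)))
                        stop = (t + 1) * npt
                        n_plat = min(n_plat, stop - de.onset_frame)
                        _render_event(
                            intr, de.onset_frame, n_plat, amp, fs, cfg.tau_decay_s, cfg.decay_cut
                        )
                        ext = _extent_frames(n_plat, amp, fs, cfg.tau_decay_s, cfg.decay_cut)
                        occ[de.onset_frame : min(stop, de.onset_frame + ext + 1)] = True
                        recs.append(
                            SpineEventRecord(
                                spine_id=sp,
                                trial=t,
                                onset_frame=de.onset_frame,
                                n_plateau=n_plat,
                                duration_s=n_plat / fs,
                                amplitude=amp,
                                kind="response",
                                dendrite_event_index=idx,
                                attenuated=att,
                            )
                        )
                    if de.prolonged:
                        prolonged_seen = True
            # spontaneous intrinsic events
            for t in range(cfg.n_trials):
                start, stop = t * npt, (t + 1) * npt
                lam = cfg.spine_event_rate_per_min * trial_min
                if trial_states[t] == "resting":
                    lam *= cfg.resting_rate_factor
                n_ev = int(rng.poisson(lam))
                drawn = []
                for _ in range(n_ev):
                    d, _ = _draw_duration(rng, short_only)
                    amp = _draw_amplitude(rng, cfg.amp_coupling, d)
                    n_plat = max(1, int(np.round(d * fs)))
                    drawn.append((d, amp, n_plat))
                extents = [
                    _extent_frames(n_plat, amp, fs, cfg.tau_decay_s, cfg.decay_cut)
                    for (_, amp, n_plat) in drawn
                ]
                onsets = _place_events(rng, occ, start, stop, extents)
                for (d, amp, n_plat), onset in zip(drawn, onsets):
                    if onset is None:
                        continue
                    _render_event(intr, onset, n_plat, amp, fs, cfg.tau_decay_s, cfg.decay_cut)
                    recs.append(
                        SpineEventRecord(
                            spine_id=sp,
                            trial=t,
                            onset_frame=onset,
                            n_plateau=n_plat,
                            duration_s=n_plat / fs,
                            amplitude=amp,
                            kind="spontaneous",
                            dendrite_event_index=None,
                            attenuated=False,
                        )
                    )
                recs.sort(key=lambda r: r.onset_frame)
            spine_events[sp] = recs
            intrinsic_clean[sp] = intr
            clean[sp] = cfg.bap_scale * clean[den] + intr

    # assemble raw F
    all_ids = soma_ids + den_ids + [sp for den in den_ids for sp in spine_ids[den]]
    F = np.empty((n_frames, len(all_ids)))
    for j, rid in enumerate(all_ids):
        f_rest = cfg.f_rest
        if cfg.f_rest_jitter > 0:
            f_rest *= 1.0 + rng.uniform(-cfg.f_rest_jitter, cfg.f_rest_jitter)
        signal = f_rest * (1.0 + clean[rid])
        if cfg.noise_sd > 0:
            if cfg.noise_mode == "additive":
                signal = signal + rng.normal(0.0, cfg.noise_sd, n_frames)
            else:
                signal = signal * (1.0 + rng.normal(0.0, cfg.noise_sd, n_frames))
        F[:, j] = signal + cfg.background_level

    roles = (
        {s: "soma" for s in soma_ids}
        | {d: "dendrite" for d in den_ids}
        | {sp: "spine" for sp in parents}
    )
    ts = RawTraceSet(
        F=F,
        roi_ids=all_ids,
        sampling_rate_hz=fs,
        trial_index=trial_index,
        trial_states=trial_states,
        background=np.full(n_frames, float(cfg.background_level)),
        roi_roles=roles,
        roi_parents=parents,
    )
    gt = GroundTruthEvents(
        events=events,
        spine_events=spine_events,
        clean=clean,
        spine_intrinsic_clean=intrinsic_clean,
        trial_index=trial_index,
        sampling_rate_hz=fs,
    )
    return ts, gt


# ---------------------------------------------------------------------------
# analytic expectations


def prolonged_event_probability(
    cfg: TraceGenConfig,
    threshold: float,
    cutoff_s: float = 8.0,
    n_grid: int = 200_001,
) -> float:
    """P(one event is *measured* as prolonged) under ideal detection.

    The measured duration of an event with plateau length n_plateau frames
    and amplitude A at detection threshold θ is
    ``n_plateau + floor(τ·fs·ln(A/θ))`` frames (plateau plus the decay frames
    at or above θ).  The probability that this exceeds ``cutoff_s`` is
    integrated over the lognormal duration mixture and the amplitude model by
    dense quadrature — the analytic counterpart of what the detection
    pipeline estimates by simulation.
    """
    fs, tau = cfg.sampling_rate_hz, cfg.tau_decay_s
    amp = cfg.amp_coupling
    n_cut = int(math.floor(cutoff_s * fs)) + 1  # duration_s > cutoff  <=>  n >= n_cut
    d_max = math.exp(cfg.duration_dist.mu_long + 8 * cfg.duration_dist.sigma_long)
    d = np.linspace(1e-9, d_max, n_grid)
    pdf = cfg.duration_dist.pdf(d)
    n_plat = np.maximum(1, np.round(d * fs))
    q = n_cut - n_plat  # decay frames still needed
    # need floor(tau*fs*ln(A/theta)) >= q  <=>  A >= theta * exp(q/(tau*fs))
    t_req = threshold * np.exp(q / (tau * fs))
    mean_amp = amp.intercept + amp.slope * d
    if amp.noise_sd > 0:
        p_amp = stats.norm.sf((t_req - mean_amp) / amp.noise_sd)
    else:
        p_amp = (mean_amp >= t_req).astype(float)
    p_amp = np.where(t_req <= amp.min_amplitude, 1.0, p_amp)
    p = np.where(q <= 0, 1.0, p_amp)
    return float(np.trapezoid(p * pdf, d))


def expected_prolonged_fraction(
    cfg: TraceGenConfig,
    threshold: float,
    cutoff_s: float = 8.0,
    running_only: bool = True,
) -> float:
    """Analytic fraction of event-exhibiting dendrites with ≥1 prolonged event.

    With a Poisson event count of mean Λ over the observation and per-event
    prolonged probability p, the fraction among dendrites showing at least
    one transient (the reported denominator) is
    ``(1 − exp(−Λp)) / (1 − exp(−Λ))``.
    """
    minutes = cfg.n_running_trials * cfg.trial_length_s / 60.0
    if not running_only:
        minutes += (
            cfg.n_resting_trials * cfg.trial_length_s / 60.0 * cfg.resting_rate_factor
        )
    lam = cfg.event_rate_per_min * minutes
    if lam <= 0:
        raise ValueError("event rate must be positive")
    p = prolonged_event_probability(cfg, threshold, cutoff_s)
    return (1.0 - math.exp(-lam * p)) / (1.0 - math.exp(-lam))


def calibrate_p_long(
    cfg: TraceGenConfig,
    target_fraction: float,
    threshold: float,
    cutoff_s: float = 8.0,
) -> float:
    """Solve for the mixture's p_long so the analytic prolonged fraction hits
    ``target_fraction`` (root finding on the closed-form expectation)."""
    from dataclasses import replace

    def f(p_long: float) -> float:
        mix = replace(cfg.duration_dist, p_long=p_long)
        c = replace(cfg, duration_dist=mix)
        return expected_prolonged_fraction(c, threshold, cutoff_s) - target_fraction

    lo, hi = 0.0, 1.0
    if f(lo) > 0 or f(hi) < 0:
        raise ValueError("target fraction not reachable by p_long in [0, 1]")
    return float(optimize.brentq(f, lo, hi, xtol=1e-10))


# ---------------------------------------------------------------------------
# two-channel spine images


@dataclass
class ImageGenConfig:
    """Geometry and intensities of the rendered dendrite-plus-spine image.

    Intensities are (spine S, dendrite shaft D, background B) per channel;
    both channels share the geometry.  The spine head is a filled circle
    offset from the shaft; the shaft is a horizontal band across the image.
    """

    image_size_px: int = 64
    shaft_width_px: int = 6
    spine_radius_px: int = 5
    spine_offset_px: int = 12
    structural_intensities: tuple[float, float, float] = (200.0, 150.0, 50.0)
    functional_intensities: tuple[float, float, float] = (120.0, 100.0, 20.0)
    blur_sigma_px: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for s, d, b in (self.structural_intensities, self.functional_intensities):
            if not (s > b and d > b and b >= 0):
                raise ValueError("require S, D > B >= 0 per channel")
        row = self.image_size_px // 2 - self.spine_offset_px
        if row - self.spine_radius_px < 1:
            raise ValueError("spine placed outside image bounds")
        if self.spine_offset_px < self.shaft_width_px // 2 + self.spine_radius_px:
            raise ValueError("spine overlaps the shaft; increase spine_offset_px")


@dataclass
class SpineImagePair:
    structural: np.ndarray
    functional: np.ndarray
    masks: dict[str, np.ndarray]  # spine / shaft / background boolean masks
    true_ratio: float


def generate_spine_image_pair(cfg: ImageGenConfig) -> SpineImagePair:
    """Render a shaft + spine head on both channels; the structural-channel
    ``true_ratio`` is (S − B)/(D − B) before blur and noise."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.image_size_px
    mid = n // 2
    rows, cols = np.ogrid[:n, :n]

    shaft = np.zeros((n, n), dtype=bool)
    half = cfg.shaft_width_px / 2.0
    shaft[int(np.ceil(mid - half)) : int(np.ceil(mid + half)), :] = True

    sr, sc = mid - cfg.spine_offset_px, mid
    spine = (rows - sr) ** 2 + (cols - sc) ** 2 <= cfg.spine_radius_px**2

    def _render(intensities: tuple[float, float, float]) -> np.ndarray:
        s, d, b = intensities
        img = np.full((n, n), float(b))
        img[shaft] = d
        img[spine] = s
        if cfg.blur_sigma_px > 0:
            img = _gaussian_blur(img, sigma=cfg.blur_sigma_px, preserve_range=True)
        if cfg.noise_sd > 0:
            img = img + rng.normal(0.0, cfg.noise_sd, img.shape)
        return img

    structural = _render(cfg.structural_intensities)
    functional = _render(cfg.functional_intensities)

    # measurement masks sit on the structure cores (as a well-placed oval
    # would), so modest blur does not drag edge pixels into the mean: the
    # spine mask is the head disk eroded by 2 px, the shaft sample the
    # central shaft rows away from the spine
    core_r = max(1, cfg.spine_radius_px - 2)
    spine_core = (rows - sr) ** 2 + (cols - sc) ** 2 <= core_r**2
    shaft_sample = np.zeros((n, n), dtype=bool)
    r0 = int(np.ceil(mid - half)) + 2
    r1 = int(np.ceil(mid + half)) - 2
    shaft_sample[r0:max(r0 + 1, r1), :] = True
    shaft_sample[:, max(0, sc - 3 * cfg.spine_radius_px) : sc + 3 * cfg.spine_radius_px] = False
    bg_row = int(np.ceil(mid + half)) + 6
    background = np.zeros((n, n), dtype=bool)
    background[bg_row : min(n, bg_row + 6), 4 : n - 4] = True

    s, d, b = cfg.structural_intensities
    return SpineImagePair(
        structural=structural,
        functional=functional,
        masks={"spine": spine_core, "shaft": shaft_sample, "background": background},
        true_ratio=(s - b) / (d - b),
    )


def write_image_pair(path: str | Path, pair: SpineImagePair) -> None:
    """Write the two channels as a (2, H, W) multi-page TIFF."""
    import tifffile

    stack = np.stack([pair.structural, pair.functional]).astype(np.float32)
    tifffile.imwrite(str(path), stack)


def generate_spine_sessions(
    n_spines: int,
    shrink_factor: float,
    seed: int,
    base_cfg: ImageGenConfig | None = None,
    change_noise_sd: float = 0.02,
) -> list[dict]:
    """Two imaging sessions per spine for size-change experiments.

    Session-1 spine intensity is rescaled so the true background-corrected
    ratio changes by ``shrink_factor`` (times small per-spine lognormal-ish
    noise).  Returns one dict per spine with both rendered image pairs and
    the true per-spine change.
    """
    rng = np.random.default_rng(seed)
    base = base_cfg or ImageGenConfig(blur_sigma_px=0.5, noise_sd=1.0)
    out = []
    for i in range(n_spines):
        s0 = float(rng.uniform(150.0, 250.0))
        _, d, b = base.structural_intensities
        factor = shrink_factor * float(np.exp(rng.normal(0.0, change_noise_sd)))
        s1 = b + factor * (s0 - b)
        cfg0 = ImageGenConfig(
            **{
                **asdict(base),
                "structural_intensities": (s0, d, b),
                "seed": int(rng.integers(2**31)),
            }
        )
        cfg1 = ImageGenConfig(
            **{
                **asdict(base),
                "structural_intensities": (s1, d, b),
                "seed": int(rng.integers(2**31)),
            }
        )
        out.append(
            {
                "spine_id": f"sp{i:03d}",
                "session0": generate_spine_image_pair(cfg0),
                "session1": generate_spine_image_pair(cfg1),
                "true_change": factor,
            }
        )
    return out
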