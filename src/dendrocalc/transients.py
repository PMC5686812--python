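"""ΔF/F0 computation, calcium-transient detection and per-ROI activity metrics.

The fractional fluorescence change is ΔF/F0 = (F − F0)/F0, where F0 for each
one-minute analysis window is the mean of the lowest 10% of F samples in that
window (a robust baseline for sparsely active GCaMP traces).  A calcium
transient is a maximal run of consecutive samples with ΔF/F0 at or above a
detection threshold of three times the standard deviation of baseline
fluctuation.  Per-event metrics are duration (supra-threshold time), peak
ΔF/F0 and integrated activity (sum of supra-threshold ΔF/F0 × dt); per-ROI
summaries report event frequency per minute and accumulated activity per
minute, separately for resting and running trials.

Baseline SD estimation is not fully pinned down by the "3 × SD of baseline"
rule alone, so it is explicit and configurable here (see
:class:`DetectionConfig`): the default is a two-pass scheme — pass 1 takes the
SD of below-median samples, pass 2 recomputes the SD over all samples outside
provisional threshold crossings.  Restricting to the lowest-10% (F0) sample
set systematically underestimates the SD; that mode is retained for
sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
from scipy import stats

from ._util import contiguous_runs, split_runs_at_boundaries
from .imageio_roi import RawTraceSet

#: strict cutoffs from the abnormality criteria: a "prolonged" dendritic
#: transient lasts more than 8 s; a "large-amplitude" one peaks above 400%.
PROLONGED_CUTOFF_S = 8.0
LARGE_AMPLITUDE_CUTOFF = 4.0


@dataclass
class DetectionConfig:
    """Tunable parameters of baseline estimation and event detection."""

    window_s: float = 60.0
    f0_fraction: float = 0.10
    sd_multiplier: float = 3.0
    #: absolute ΔF/F0 floor for the threshold; guards degenerate zero-noise
    #: traces where the baseline SD collapses to 0.
    threshold_floor: float = 0.05
    baseline_mode: Literal["two_pass", "f0_set"] = "two_pass"
    prolonged_cutoff_s: float = PROLONGED_CUTOFF_S
    large_amplitude_cutoff: float = LARGE_AMPLITUDE_CUTOFF
    #: when True, integrated activity sums (ΔF/F0 − threshold); default sums
    #: the full supra-threshold ΔF/F0.
    integrate_above_threshold_only: bool = False


@dataclass
class DffTrace:
    """ΔF/F0 series for one ROI with its per-window baseline bookkeeping."""

    roi_id: str
    dff: np.ndarray
    f0: np.ndarray
    baseline_sd: np.ndarray
    threshold: np.ndarray
    window_bounds: np.ndarray  # (n_windows, 2), inclusive frame spans
    sampling_rate_hz: float
    trial_index: np.ndarray
    config: DetectionConfig = field(default_factory=DetectionConfig)

    def threshold_per_sample(self) -> np.ndarray:
        thr = np.empty_like(self.dff)
        for (a, b), t in zip(self.window_bounds, self.threshold):
            thr[a : b + 1] = t
        return thr


@dataclass
class CalciumTransient:
    """One detected calcium transient (inclusive 0-based frame span)."""

    roi_id: str
    trial: int
    onset_frame: int
    offset_frame: int
    duration_s: float
    peak_dff: float
    integrated_activity: float
    prolonged: bool
    large_amplitude: bool


@dataclass
class RoiActivitySummary:
    roi_id: str
    state: str
    n_events: int
    frequency_per_min: float
    mean_duration_s: float
    total_duration_s: float
    peaks: list[float]
    mean_peak: float
    total_integrated_activity_per_min: float
    minutes_observed: float


# ---------------------------------------------------------------------------
# baseline + ΔF/F0


def _baseline_sd(dff_w: np.ndarray, cfg: DetectionConfig, f0_count: int) -> float:
    """Baseline SD of one window's ΔF/F0 samples (see module docstring)."""
    if cfg.baseline_mode == "f0_set":
        order = np.argsort(dff_w, kind="stable")
        sel = dff_w[order[:f0_count]]
        return float(np.std(sel, ddof=1)) if sel.size > 1 else 0.0
    # two-pass: below-median SD -> provisional events -> SD of non-event samples
    med = np.median(dff_w)
    base1 = dff_w[dff_w < med]
    sd1 = float(np.std(base1, ddof=1)) if base1.size > 1 else 0.0
    thr1 = max(cfg.sd_multiplier * sd1, cfg.threshold_floor)
    keep = dff_w < thr1
    base2 = dff_w[keep]
    if base2.size < 2:
        return sd1
    return float(np.std(base2, ddof=1))


def _windows_for_trial(frames: np.ndarray, win_n: int) -> list[np.ndarray]:
    """Partition a trial's frames into analysis windows of win_n samples.

    A short remainder (< win_n) is merged into the preceding window; a trial
    shorter than one window is a single window.
    """
    n = frames.size
    if n <= win_n:
        return [frames]
    n_full = n // win_n
    out = [frames[i * win_n : (i + 1) * win_n] for i in range(n_full)]
    rem = frames[n_full * win_n :]
    if rem.size:
        out[-1] = np.concatenate([out[-1], rem])
    return out


def compute_dff(
    ts: RawTraceSet,
    config: DetectionConfig | None = None,
) -> dict[str, DffTrace]:
    """Compute ΔF/F0 per ROI with per-window F0 and detection thresholds.

    The background must already be subtracted (or absent).  For each window,
    F0 is the mean of the lowest ``ceil(f0_fraction * n)`` samples (at least
    one); an F0 ≤ 0 indicates background over-subtraction and raises.
    """
    cfg = config or DetectionConfig()
    if ts.background is not None and np.any(ts.background != 0):
        raise ValueError("background not subtracted; call subtract_background first")
    win_n = int(round(cfg.window_s * ts.sampling_rate_hz))
    if win_n < 10:
        raise ValueError("analysis window shorter than 10 samples")

    trials = sorted(set(ts.trial_index.tolist()))
    windows: list[np.ndarray] = []
    for t in trials:
        windows.extend(_windows_for_trial(ts.trial_frames(t), win_n))
    for w in windows:
        if w.size < 10:
            raise ValueError("analysis window shorter than 10 samples")

    out: dict[str, DffTrace] = {}
    for j, roi_id in enumerate(ts.roi_ids):
        f = ts.F[:, j]
        dff = np.empty_like(f)
        f0s, sds, thrs, bounds = [], [], [], []
        for w in windows:
            fw = f[w]
            k = max(1, int(np.ceil(cfg.f0_fraction * fw.size)))
            f0 = float(np.partition(fw, k - 1)[:k].mean())
            if f0 <= 0:
                raise ValueError(
                    f"ROI {roi_id!r}: F0 <= 0 in window [{w[0]}, {w[-1]}] "
                    "(background over-subtraction?)"
                )
            dff_w = (fw - f0) / f0
            dff[w] = dff_w
            sd = _baseline_sd(dff_w, cfg, k)
            f0s.append(f0)
            sds.append(sd)
            thrs.append(max(cfg.sd_multiplier * sd, cfg.threshold_floor))
            bounds.append((int(w[0]), int(w[-1])))
        out[roi_id] = DffTrace(
            roi_id=roi_id,
            dff=dff,
            f0=np.array(f0s),
            baseline_sd=np.array(sds),
            threshold=np.array(thrs),
            window_bounds=np.array(bounds, dtype=int),
            sampling_rate_hz=ts.sampling_rate_hz,
            trial_index=ts.trial_index.copy(),
            config=cfg,
        )
    return out


# ---------------------------------------------------------------------------
# detection


def detect_transients(d: DffTrace) -> list[CalciumTransient]:
    """Detect maximal supra-threshold runs as calcium transients.

    Each maximal run of consecutive samples with ΔF/F0 ≥ the (per-window)
    threshold is one transient; runs crossing a trial boundary are split at
    the boundary.  Returns an empty list when nothing crosses threshold.
    """
    cfg = d.config
    fs = d.sampling_rate_hz
    dt = 1.0 / fs
    thr = d.threshold_per_sample()
    supra = d.dff >= thr
    runs = contiguous_runs(supra)
    boundaries = np.flatnonzero(np.diff(d.trial_index) != 0) + 1
    runs = split_runs_at_boundaries(runs, boundaries)

    events: list[CalciumTransient] = []
    for a, b in runs:
        seg = d.dff[a : b + 1]
        if cfg.integrate_above_threshold_only:
            integ = float(np.sum(seg - thr[a : b + 1]) * dt)
        else:
            integ = float(np.sum(seg) * dt)
        dur = (b - a + 1) * dt
        peak = float(seg.max())
        events.append(
            CalciumTransient(
                roi_id=d.roi_id,
                trial=int(d.trial_index[a]),
                onset_frame=int(a),
                offset_frame=int(b),
                duration_s=dur,
                peak_dff=peak,
                integrated_activity=integ,
                prolonged=dur > cfg.prolonged_cutoff_s,
                large_amplitude=peak > cfg.large_amplitude_cutoff,
            )
        )
    return events


def detect_all(dffs: Mapping[str, DffTrace]) -> dict[str, list[CalciumTransient]]:
    return {rid: detect_transients(d) for rid, d in dffs.items()}


# ---------------------------------------------------------------------------
# summaries and derived fractions


def summarize_roi(
    events: Sequence[CalciumTransient],
    minutes_observed: float,
    roi_id: str | None = None,
    state: str = "running",
) -> RoiActivitySummary:
    """Per-ROI activity summary: frequency/min, durations, peaks, total activity/min."""
    if minutes_observed <= 0:
        raise ValueError("minutes_observed must be > 0")
    rids = {e.roi_id for e in events}
    if len(rids) > 1:
        raise ValueError(f"events from multiple ROIs: {sorted(rids)}")
    if roi_id is None:
        roi_id = next(iter(rids)) if rids else ""
    durations = [e.duration_s for e in events]
    peaks = [e.peak_dff for e in events]
    total_integ = sum(e.integrated_activity for e in events)
    n = len(events)
    return RoiActivitySummary(
        roi_id=roi_id,
        state=state,
        n_events=n,
        frequency_per_min=n / minutes_observed,
        mean_duration_s=float(np.mean(durations)) if n else 0.0,
        total_duration_s=float(np.sum(durations)) if n else 0.0,
        peaks=peaks,
        mean_peak=float(np.mean(peaks)) if n else 0.0,
        total_integrated_activity_per_min=total_integ / minutes_observed,
        minutes_observed=minutes_observed,
    )


def dendrite_fraction_with(
    events_by_dendrite: Mapping[str, Sequence[CalciumTransient]],
    predicate: Literal["prolonged", "large_amplitude"],
) -> float:
    """Fraction of active dendrites with ≥1 event satisfying the predicate.

    The denominator is dendrites that exhibited at least one detected
    transient during the observation; dendrites without events are excluded.
    """
    active = {k: v for k, v in events_by_dendrite.items() if len(v) > 0}
    if not active:
        raise ValueError("no dendrite exhibited any transient (empty denominator)")
    hits = sum(1 for v in active.values() if any(getattr(e, predicate) for e in v))
    return hits / len(active)


def duration_amplitude_correlation(
    events: Sequence[CalciumTransient],
    method: Literal["pearson", "spearman"] = "pearson",
) -> tuple[float, float]:
    """Correlation between per-event duration and peak ΔF/F0 across transients."""
    if len(events) < 3:
        raise ValueError("need at least 3 events")
    d = np.array([e.duration_s for e in events])
    p = np.array([e.peak_dff for e in events])
    if np.ptp(d) == 0 or np.ptp(p) == 0:
        raise ValueError("constant input vector; correlation undefined")
    if method == "pearson":
        r = stats.pearsonr(d, p)
    else:
        r = stats.spearmanr(d, p)
    return float(r.statistic), float(r.pvalue)
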