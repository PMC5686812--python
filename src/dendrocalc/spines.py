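"""Spine-specific calcium signals and depotentiation analysis.

A spine's raw ΔF/F0 mixes true synaptic input with calcium from
back-propagating action potentials and dendritic regenerative events.  The
spine-specific signal removes the inherited component by subtracting a scaled
copy of the parent dendritic shaft signal:

    ΔF/F0_specific = ΔF/F0_spine − 0.7 × ΔF/F0_dendrite

Spines are called *active* when the spine-specific trace crosses three times
the baseline SD (recomputed on the subtracted trace); a structural variant
classifies by the spine-head / adjacent-shaft fluorescence intensity ratio.

The first-vs-third comparison probes depotentiation: within a trial showing
at least three dendritic transients, each spine's peak at the 1st transient
is paired with its peak at the 3rd, stratified by whether the 2nd transient
was prolonged (> 8 s) — prolonged dendritic events are the candidate trigger
of spine depotentiation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np

from .transients import (
    CalciumTransient,
    DetectionConfig,
    DffTrace,
    _baseline_sd,
)

DEFAULT_BAP_SCALE = 0.7
DEFAULT_RATIO_CUTOFF = 1.0  # midpoint between reported active (1.56) and inactive (0.46) means


@dataclass
class SpineSpecificTrace:
    spine_id: str
    dendrite_id: str
    dff_specific: np.ndarray
    baseline_sd: np.ndarray
    threshold: np.ndarray
    window_bounds: np.ndarray
    sampling_rate_hz: float
    trial_index: np.ndarray
    scale: float
    config: DetectionConfig

    def threshold_per_sample(self) -> np.ndarray:
        thr = np.empty_like(self.dff_specific)
        for (a, b), t in zip(self.window_bounds, self.threshold):
            thr[a : b + 1] = t
        return thr

    def as_dff_trace(self) -> DffTrace:
        """View as a DffTrace so the standard detector applies unchanged
        (f0 is set to 1; the series is already fractional)."""
        return DffTrace(
            roi_id=self.spine_id,
            dff=self.dff_specific,
            f0=np.ones(len(self.threshold)),
            baseline_sd=self.baseline_sd,
            threshold=self.threshold,
            window_bounds=self.window_bounds,
            sampling_rate_hz=self.sampling_rate_hz,
            trial_index=self.trial_index,
            config=self.config,
        )


@dataclass
class SpineActivityCall:
    spine_id: str
    dendritic_event_id: int
    peak_specific: float
    threshold: float
    head_shaft_ratio: float | None
    active: bool
    rule: str


@dataclass
class FirstThirdComparison:
    spine_id: str
    dendrite_id: str
    trial: int
    peak_pre: float
    peak_post: float
    middle_duration_class: Literal["0-8 s", ">8 s"]
    triplet_start: int
    primary: bool  # first (independent) triplet of the trial


def spine_specific(
    dff_spine: DffTrace,
    dff_dendrite: DffTrace,
    scale: float = DEFAULT_BAP_SCALE,
    parent_map: Mapping[str, str] | None = None,
) -> SpineSpecificTrace:
    """Subtract the scaled dendritic signal and re-derive the 3×SD threshold.

    The baseline SD is recomputed on the subtracted series with the same
    two-pass rule used for raw ΔF/F0 (windows inherited from the spine
    trace).
    """
    if dff_spine.dff.shape != dff_dendrite.dff.shape:
        raise ValueError("spine and dendrite traces have different lengths")
    if parent_map is not None:
        expected = parent_map.get(dff_spine.roi_id)
        if expected != dff_dendrite.roi_id:
            raise ValueError(
                f"{dff_spine.roi_id!r} is not a spine of {dff_dendrite.roi_id!r}"
            )
    cfg = dff_spine.config
    specific = dff_spine.dff - scale * dff_dendrite.dff
    sds, thrs = [], []
    for a, b in dff_spine.window_bounds:
        w = specific[a : b + 1]
        k = max(1, int(np.ceil(cfg.f0_fraction * w.size)))
        sd = _baseline_sd(w, cfg, k)
        sds.append(sd)
        thrs.append(max(cfg.sd_multiplier * sd, cfg.threshold_floor))
    return SpineSpecificTrace(
        spine_id=dff_spine.roi_id,
        dendrite_id=dff_dendrite.roi_id,
        dff_specific=specific,
        baseline_sd=np.array(sds),
        threshold=np.array(thrs),
        window_bounds=dff_spine.window_bounds.copy(),
        sampling_rate_hz=dff_spine.sampling_rate_hz,
        trial_index=dff_spine.trial_index.copy(),
        scale=scale,
        config=cfg,
    )


def classify_active(
    sst: SpineSpecificTrace,
    event_window: tuple[int, int],
    dendritic_event_id: int = 0,
    rule: Literal["threshold", "ratio"] = "threshold",
    head_shaft_ratio: float | None = None,
    ratio_cutoff: float = DEFAULT_RATIO_CUTOFF,
) -> SpineActivityCall:
    """Call a spine active/inactive at one dendritic event.

    rule="threshold": active iff the spine-specific ΔF/F0 within the event
    window reaches the spine's 3×SD threshold.  rule="ratio": active iff the
    supplied spine-head / adjacent-shaft intensity ratio is ≥ ``ratio_cutoff``
    (structural-experiment variant).
    """
    a, b = event_window
    if b < a or a < 0 or b >= sst.dff_specific.size:
        raise ValueError("empty or out-of-range event window")
    thr = float(sst.threshold_per_sample()[a : b + 1].max())
    peak = float(sst.dff_specific[a : b + 1].max())
    if rule == "threshold":
        active = peak >= thr
    elif rule == "ratio":
        if head_shaft_ratio is None:
            raise ValueError("ratio rule requires head_shaft_ratio")
        if head_shaft_ratio < 0:
            raise ValueError("head_shaft_ratio must be >= 0")
        active = head_shaft_ratio >= ratio_cutoff
    else:
        raise ValueError(f"unknown rule {rule!r}")
    return SpineActivityCall(
        spine_id=sst.spine_id,
        dendritic_event_id=dendritic_event_id,
        peak_specific=peak,
        threshold=thr,
        head_shaft_ratio=head_shaft_ratio,
        active=bool(active),
        rule=rule,
    )


def spine_peak_in_window(trace: SpineSpecificTrace | DffTrace, window: tuple[int, int]) -> float:
    a, b = window
    series = trace.dff_specific if isinstance(trace, SpineSpecificTrace) else trace.dff
    return float(series[a : b + 1].max())


def first_third_comparison(
    dendrite_events: Sequence[CalciumTransient],
    spine_traces: Mapping[str, SpineSpecificTrace],
    dendrite_id: str | None = None,
    prolonged_cutoff_s: float = 8.0,
    all_triplets: bool = False,
) -> list[FirstThirdComparison]:
    """Pair each spine's peak at the 1st and 3rd dendritic transient of a trial.

    Trials with fewer than three dendritic transients are skipped.  The
    stratum is set by the 2nd transient's duration (strictly > 8 s vs not).
    When more than three transients occur, the first triplet is primary;
    sliding triplets are emitted only with ``all_triplets=True`` and flagged
    non-independent (primary=False).
    """
    if dendrite_id is None:
        dendrite_id = dendrite_events[0].roi_id if dendrite_events else ""
    out: list[FirstThirdComparison] = []
    trials = sorted({e.trial for e in dendrite_events})
    for t in trials:
        evs = sorted(
            (e for e in dendrite_events if e.trial == t), key=lambda e: e.onset_frame
        )
        if len(evs) < 3:
            continue
        n_triplets = len(evs) - 2 if all_triplets else 1
        for k in range(n_triplets):
            e1, e2, e3 = evs[k], evs[k + 1], evs[k + 2]
            cls: Literal["0-8 s", ">8 s"] = (
                ">8 s" if e2.duration_s > prolonged_cutoff_s else "0-8 s"
            )
            for sp_id, sst in spine_traces.items():
                out.append(
                    FirstThirdComparison(
                        spine_id=sp_id,
                        dendrite_id=dendrite_id,
                        trial=t,
                        peak_pre=spine_peak_in_window(sst, (e1.onset_frame, e1.offset_frame)),
                        peak_post=spine_peak_in_window(sst, (e3.onset_frame, e3.offset_frame)),
                        middle_duration_class=cls,
                        triplet_start=k,
                        primary=(k == 0),
                    )
                )
    return out
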