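"""Spine-head size from two-channel images and longitudinal size change.

Spine size is read out on the structural (tdTomato) channel as a
background-corrected intensity ratio between the spine head and the adjacent
dendritic shaft.  With Area the pixel count of an oval around the spine head
and Mean OD the mean pixel brightness, the full ratio is

    (Area·MeanOD_spine − Area·MeanOD_background)
    ─────────────────────────────────────────────
    (Area·MeanOD_dendrite − Area·MeanOD_background)

The common Area factor cancels algebraically, so the implementation computes
the reduced Mean-OD ratio; the literal Area-carrying form is kept in
:func:`size_ratio_literal` for verification.  The ratio is invariant under
per-image affine intensity transforms (gain/offset) as long as the
background ROI shares them.

Size change between imaging sessions is ratio(later)/ratio(earlier) per
stable spine; turnover classifies spines as stable, eliminated or formed
from their presence in the two sessions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: presence call for turnover: a spine counts as present when its
#: structural-channel size ratio reaches this value
DEFAULT_PRESENCE_RATIO = 0.2


@dataclass
class SpineSizeMeasurement:
    spine_id: str
    session: str
    area_px: int
    mean_od_spine: float
    mean_od_dendrite: float
    mean_od_background: float

    def __post_init__(self) -> None:
        if self.area_px < 1:
            raise ValueError("spine ROI must contain at least one pixel")
        if self.mean_od_dendrite <= self.mean_od_background:
            raise ValueError(
                "shaft Mean OD must exceed background Mean OD (bad ROI placement?)"
            )

    @property
    def size_ratio(self) -> float:
        return (self.mean_od_spine - self.mean_od_background) / (
            self.mean_od_dendrite - self.mean_od_background
        )


def size_ratio_literal(
    area_px: int, od_spine: float, od_dendrite: float, od_background: float
) -> float:
    """The unreduced Area-carrying ratio (identical to the reduced form)."""
    num = area_px * od_spine - area_px * od_background
    den = area_px * od_dendrite - area_px * od_background
    if den <= 0:
        raise ValueError("non-positive denominator (bad ROI placement?)")
    return num / den


def measure_spine_size(
    structural_image: np.ndarray,
    spine_mask: np.ndarray,
    shaft_mask: np.ndarray,
    background_mask: np.ndarray,
    spine_id: str = "",
    session: str = "0h",
) -> SpineSizeMeasurement:
    """Mean-OD bookkeeping for one spine on the structural channel.

    The three ROIs must be disjoint; shaft and background samples are taken
    next to the spine (averaging per dendrite segment, when wanted, is done
    by the caller across spines of a segment).
    """
    img = np.asarray(structural_image, dtype=float)
    masks = [np.asarray(m, dtype=bool) for m in (spine_mask, shaft_mask, background_mask)]
    for m in masks:
        if m.shape != img.shape:
            raise ValueError("mask shape does not match image")
        if not m.any():
            raise ValueError("empty ROI mask")
    if (masks[0] & masks[1]).any() or (masks[0] & masks[2]).any() or (masks[1] & masks[2]).any():
        raise ValueError("spine/shaft/background ROIs must be disjoint")
    return SpineSizeMeasurement(
        spine_id=spine_id,
        session=session,
        area_px=int(masks[0].sum()),
        mean_od_spine=float(img[masks[0]].mean()),
        mean_od_dendrite=float(img[masks[1]].mean()),
        mean_od_background=float(img[masks[2]].mean()),
    )


def measurements_frame(measurements: Sequence[SpineSizeMeasurement]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "spine_id": [m.spine_id for m in measurements],
            "session": [m.session for m in measurements],
            "area_px": [m.area_px for m in measurements],
            "mean_od_spine": [m.mean_od_spine for m in measurements],
            "mean_od_dendrite": [m.mean_od_dendrite for m in measurements],
            "mean_od_background": [m.mean_od_background for m in measurements],
            "size_ratio": [m.size_ratio for m in measurements],
        }
    )


def size_change(
    session0: Sequence[SpineSizeMeasurement],
    session1: Sequence[SpineSizeMeasurement],
    groups: Mapping[str, dict] | None = None,
) -> pd.DataFrame:
    """Per-spine size change ratio(session1)/ratio(session0) for matched ids.

    ``groups`` optionally maps spine_id to annotation columns (e.g. active
    flag and the parent dendrite's duration class) that are joined onto the
    table for stratified statistics.  Unmatched spines are excluded here —
    they belong to turnover.
    """
    df0 = measurements_frame(session0).set_index("spine_id")
    df1 = measurements_frame(session1).set_index("spine_id")
    common = df0.index.intersection(df1.index)
    out = pd.DataFrame(
        {
            "spine_id": common,
            "ratio_session0": df0.loc[common, "size_ratio"].to_numpy(),
            "ratio_session1": df1.loc[common, "size_ratio"].to_numpy(),
        }
    )
    out["size_change"] = out["ratio_session1"] / out["ratio_session0"]
    if groups:
        ann = pd.DataFrame.from_dict(groups, orient="index")
        ann.index.name = "spine_id"
        out = out.merge(ann, on="spine_id", how="left")
    return out


def turnover(
    session0: Sequence[SpineSizeMeasurement] | Sequence[str],
    session1: Sequence[SpineSizeMeasurement] | Sequence[str],
    presence_ratio: float = DEFAULT_PRESENCE_RATIO,
) -> dict:
    """Stable / eliminated / formed rates between two sessions.

    Accepts measurement lists (presence = size_ratio ≥ ``presence_ratio``)
    or plain id collections (everything listed is present).  Stable and
    elimination rates are relative to the session-0 spine count, as is the
    formation rate (convention; stable + eliminated = 1 among session-0
    spines).
    """

    def _present(session) -> set[str]:
        ids = set()
        for item in session:
            if isinstance(item, SpineSizeMeasurement):
                if item.size_ratio >= presence_ratio:
                    ids.add(item.spine_id)
            else:
                ids.add(str(item))
        return ids

    p0, p1 = _present(session0), _present(session1)
    if not p0:
        raise ValueError("no spines present at session 0")
    stable = p0 & p1
    eliminated = p0 - p1
    formed = p1 - p0
    n0 = len(p0)
    return {
        "n_session0": n0,
        "n_session1": len(p1),
        "stable_rate": len(stable) / n0,
        "elimination_rate": len(eliminated) / n0,
        "formation_rate": len(formed) / n0,
        "stable_ids": sorted(stable),
        "eliminated_ids": sorted(eliminated),
        "formed_ids": sorted(formed),
    }
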