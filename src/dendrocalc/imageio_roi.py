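"""Image stacks, ROI definitions and per-ROI trace extraction.

Fluorescence is measured by averaging pixels within each region of interest
(ROI) on every frame.  ROIs carry a role (soma, dendrite, spine or
background_vessel) and, for spines, the identity of the parent dendrite.  The
vessel-background ROIs supply a per-frame scalar that is subtracted from every
trace before ΔF/F0 analysis.

Coordinates are 0-based, row-major pixel indices.  Polygon ROIs are rasterised
with centre-of-pixel inclusion (``skimage.draw.polygon``).
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import tifffile
from skimage.draw import disk, polygon

from ._util import config_hash

ROI_ROLES = ("soma", "dendrite", "spine", "background_vessel")

_BACKGROUND_COL = "__background__"


@dataclass
class RoiDef:
    """Geometry and role of one region of interest.

    geometry is one of
      - ``("mask", bool_array)`` — explicit pixel mask (full image size),
      - ``("polygon", vertices)`` — (N, 2) array of (row, col) vertices,
      - ``("rect", (r0, c0, r1, c1))`` — half-open rectangle,
      - ``("disk", (r, c, radius))`` — filled circle.
    """

    roi_id: str
    role: str
    geometry: tuple
    parent_id: str = ""
    channel: int = 0

    def __post_init__(self) -> None:
        if self.role not in ROI_ROLES:
            raise ValueError(f"unknown ROI role {self.role!r}; expected one of {ROI_ROLES}")
        if self.role == "spine" and not self.parent_id:
            raise ValueError(f"spine ROI {self.roi_id!r} must declare a parent dendrite")

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Rasterise the geometry onto an image of the given (rows, cols) shape."""
        kind, data = self.geometry
        out = np.zeros(shape, dtype=bool)
        if kind == "mask":
            m = np.asarray(data, dtype=bool)
            if m.shape != shape:
                raise ValueError(
                    f"ROI {self.roi_id!r}: mask shape {m.shape} != image shape {shape}"
                )
            out = m
        elif kind == "polygon":
            verts = np.asarray(data, dtype=float)
            rr, cc = polygon(verts[:, 0], verts[:, 1], shape=shape)
            out[rr, cc] = True
        elif kind == "rect":
            r0, c0, r1, c1 = (int(v) for v in data)
            if r0 < 0 or c0 < 0 or r1 > shape[0] or c1 > shape[1]:
                raise ValueError(f"ROI {self.roi_id!r} out of image bounds")
            out[r0:r1, c0:c1] = True
        elif kind == "disk":
            r, c, rad = data
            rr, cc = disk((r, c), rad, shape=shape)
            out[rr, cc] = True
        elif kind == "pixels":
            pix = np.asarray(data, dtype=int)
            if pix.size and (
                pix.min() < 0 or pix[:, 0].max() >= shape[0] or pix[:, 1].max() >= shape[1]
            ):
                raise ValueError(f"ROI {self.roi_id!r} out of image bounds")
            out[pix[:, 0], pix[:, 1]] = True
        else:
            raise ValueError(f"unknown geometry kind {kind!r}")
        if not out.any():
            raise ValueError(f"ROI {self.roi_id!r} rasterises to an empty mask")
        return out

    def to_jsonable(self) -> dict:
        kind, data = self.geometry
        if kind == "mask":
            data = [[int(r), int(c)] for r, c in zip(*np.nonzero(np.asarray(data)))]
            kind = "pixels"
        elif kind == "pixels":
            data = np.asarray(data, dtype=int).tolist()
        elif kind == "polygon":
            data = np.asarray(data, dtype=float).tolist()
        else:
            data = list(data)
        return {
            "id": self.roi_id,
            "role": self.role,
            "geometry": {"kind": kind, "data": data},
            "parent_id": self.parent_id,
            "channel": self.channel,
        }


def validate_rois(rois: Sequence[RoiDef]) -> None:
    """Check id uniqueness and spine→dendrite parentage."""
    ids = [r.roi_id for r in rois]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate roi_id values")
    dendrites = {r.roi_id for r in rois if r.role == "dendrite"}
    for r in rois:
        if r.role == "spine" and r.parent_id not in dendrites:
            raise ValueError(
                f"spine {r.roi_id!r} references missing dendrite {r.parent_id!r}"
            )


def write_rois_json(rois: Sequence[RoiDef], path: str | Path) -> None:
    validate_rois(rois)
    payload = {"schema": "dendrocalc-roi-v1", "rois": [r.to_jsonable() for r in rois]}
    Path(path).write_text(json.dumps(payload, indent=1))


def read_rois_json(path: str | Path) -> list[RoiDef]:
    payload = json.loads(Path(path).read_text())
    rois = []
    for entry in payload["rois"]:
        geo = entry["geometry"]
        kind, data = geo["kind"], geo["data"]
        if kind == "pixels":
            geometry = ("pixels", np.asarray(data, dtype=int))
        elif kind == "polygon":
            geometry = ("polygon", np.asarray(data, dtype=float))
        else:
            geometry = (kind, tuple(data))
        rois.append(
            RoiDef(
                roi_id=entry["id"],
                role=entry["role"],
                geometry=geometry,
                parent_id=entry.get("parent_id", ""),
                channel=entry.get("channel", 0),
            )
        )
    validate_rois(rois)
    return rois


@dataclass
class RawTraceSet:
    """Per-ROI raw fluorescence traces with trial structure.

    F is (n_frames, n_rois); ``background`` is the per-frame vessel value (or
    None once subtracted / when absent).  ``trial_states`` maps trial index to
    "running" or "resting".
    """

    F: np.ndarray
    roi_ids: list[str]
    sampling_rate_hz: float
    trial_index: np.ndarray
    trial_states: dict[int, str]
    background: np.ndarray | None = None
    roi_roles: dict[str, str] = field(default_factory=dict)
    roi_parents: dict[str, str] = field(default_factory=dict)
    saturated: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F, dtype=float)
        self.trial_index = np.asarray(self.trial_index, dtype=int)
        if self.F.ndim != 2 or self.F.shape[1] != len(self.roi_ids):
            raise ValueError("F must be (n_frames, n_rois) matching roi_ids")
        if not np.all(np.isfinite(self.F)):
            raise ValueError("non-finite fluorescence values")
        if self.trial_index.shape[0] != self.F.shape[0]:
            raise ValueError("trial_index length mismatch")
        # trial blocks must be contiguous
        change = np.flatnonzero(np.diff(self.trial_index) != 0)
        seen = self.trial_index[np.concatenate([[0], change + 1])] if self.F.shape[0] else []
        if len(set(np.asarray(seen).tolist())) != len(np.asarray(seen)):
            raise ValueError("trial blocks are not contiguous")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be > 0")
        if self.background is not None:
            self.background = np.asarray(self.background, dtype=float)
            if self.background.shape != (self.F.shape[0],):
                raise ValueError("background must be per-frame")

    # -- accessors ---------------------------------------------------------
    @property
    def n_frames(self) -> int:
        return self.F.shape[0]

    def column(self, roi_id: str) -> np.ndarray:
        return self.F[:, self.roi_ids.index(roi_id)]

    def trial_frames(self, trial: int) -> np.ndarray:
        return np.flatnonzero(self.trial_index == trial)

    def minutes_observed(self, state: str | None = None) -> float:
        if state is None:
            n = self.n_frames
        else:
            keep = [t for t, s in self.trial_states.items() if s == state]
            n = int(np.isin(self.trial_index, keep).sum())
        return n / self.sampling_rate_hz / 60.0

    # -- I/O ---------------------------------------------------------------
    def to_csv(self, path: str | Path, meta: dict | None = None) -> None:
        """Long-format CSV (trial, frame, roi_id, F) with a provenance header.

        The vessel background series, when present, is written under the
        reserved roi_id ``__background__``.
        """
        frames = np.arange(self.n_frames)
        parts = []
        for j, rid in enumerate(self.roi_ids):
            parts.append(
                pd.DataFrame(
                    {"trial": self.trial_index, "frame": frames, "roi_id": rid, "F": self.F[:, j]}
                )
            )
        if self.background is not None:
            parts.append(
                pd.DataFrame(
                    {
                        "trial": self.trial_index,
                        "frame": frames,
                        "roi_id": _BACKGROUND_COL,
                        "F": self.background,
                    }
                )
            )
        df = pd.concat(parts, ignore_index=True)
        header = {
            "schema": "dendrocalc-traces-v1",
            "sampling_rate_hz": self.sampling_rate_hz,
            "trial_states": {str(k): v for k, v in sorted(self.trial_states.items())},
            "roi_roles": self.roi_roles,
            "roi_parents": self.roi_parents,
            "config_hash": config_hash(meta or {}),
        }
        buf = io.StringIO()
        buf.write("# " + json.dumps(header) + "\n")
        df.to_csv(buf, index=False, float_format="%.10g")
        Path(path).write_text(buf.getvalue())

    @classmethod
    def from_csv(cls, path: str | Path) -> "RawTraceSet":
        text = Path(path).read_text()
        first, _, rest = text.partition("\n")
        if not first.startswith("#"):
            raise ValueError("trace CSV missing provenance header line")
        header = json.loads(first.lstrip("# "))
        df = pd.read_csv(io.StringIO(rest))
        bg_df = df[df.roi_id == _BACKGROUND_COL]
        df = df[df.roi_id != _BACKGROUND_COL]
        roi_ids = list(dict.fromkeys(df.roi_id))
        wide = df.pivot_table(index="frame", columns="roi_id", values="F", sort=False)
        wide = wide[roi_ids].sort_index()
        trial = df.drop_duplicates("frame").sort_values("frame").trial.to_numpy()
        background = None
        if len(bg_df):
            background = bg_df.sort_values("frame").F.to_numpy()
        return cls(
            F=wide.to_numpy(),
            roi_ids=roi_ids,
            sampling_rate_hz=float(header["sampling_rate_hz"]),
            trial_index=trial,
            trial_states={int(k): v for k, v in header["trial_states"].items()},
            background=background,
            roi_roles=header.get("roi_roles", {}),
            roi_parents=header.get("roi_parents", {}),
        )


def extract_traces(
    stack: np.ndarray,
    rois: Sequence[RoiDef],
    sampling_rate_hz: float,
    trial_index: np.ndarray | None = None,
    trial_states: dict[int, str] | None = None,
    saturation_level: float | None = None,
) -> RawTraceSet:
    """Mean-pixel trace per ROI per frame; vessel ROIs become the background series.

    ``stack`` is (frames, rows, cols) or (frames, channels, rows, cols); each
    ROI is measured on its declared channel.  Frames containing saturated
    pixels inside an ROI are flagged, not dropped.
    """
    stack = np.asarray(stack)
    if stack.ndim == 3:
        stack = stack[:, None, :, :]
    if stack.ndim != 4:
        raise ValueError("stack must be (frames[, channels], rows, cols)")
    n_frames, n_channels, h, w = stack.shape
    validate_rois(rois)

    signal_rois = [r for r in rois if r.role != "background_vessel"]
    vessel_rois = [r for r in rois if r.role == "background_vessel"]

    def _measure(roi: RoiDef) -> tuple[np.ndarray, np.ndarray]:
        if roi.channel >= n_channels:
            raise ValueError(f"ROI {roi.roi_id!r} channel {roi.channel} not in stack")
        m = roi.mask((h, w))
        pix = stack[:, roi.channel][:, m].astype(float)
        trace = pix.mean(axis=1)
        if saturation_level is not None:
            sat = (pix >= saturation_level).any(axis=1)
        else:
            sat = np.zeros(n_frames, dtype=bool)
        return trace, sat

    F = np.empty((n_frames, len(signal_rois)))
    saturated = np.zeros((n_frames, len(signal_rois)), dtype=bool)
    for j, roi in enumerate(signal_rois):
        F[:, j], saturated[:, j] = _measure(roi)

    background = None
    if vessel_rois:
        background = np.mean([_measure(r)[0] for r in vessel_rois], axis=0)

    if trial_index is None:
        trial_index = np.zeros(n_frames, dtype=int)
    if trial_states is None:
        trial_states = {int(t): "running" for t in np.unique(trial_index)}
    return RawTraceSet(
        F=F,
        roi_ids=[r.roi_id for r in signal_rois],
        sampling_rate_hz=sampling_rate_hz,
        trial_index=np.asarray(trial_index),
        trial_states=trial_states,
        background=background,
        roi_roles={r.roi_id: r.role for r in signal_rois},
        roi_parents={r.roi_id: r.parent_id for r in signal_rois if r.parent_id},
        saturated=saturated,
    )


def subtract_background(ts: RawTraceSet) -> RawTraceSet:
    """Subtract the per-frame vessel background from every trace.

    Negative values are permitted and preserved; the background field is
    zeroed so downstream ΔF/F0 computation knows subtraction happened.
    """
    if ts.background is None:
        raise ValueError("no background series defined; cannot subtract")
    return replace(
        ts,
        F=ts.F - ts.background[:, None],
        background=np.zeros_like(ts.background),
    )


def read_stack(path: str | Path) -> np.ndarray:
    """Read a multi-page TIFF into (frames[, channels], rows, cols)."""
    return tifffile.imread(str(path))


def write_stack(path: str | Path, stack: np.ndarray) -> None:
    tifffile.imwrite(str(path), np.asarray(stack))
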