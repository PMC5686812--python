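"""Small shared helpers: provenance hashing and run-length utilities."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from typing import Any

import numpy as np


def config_hash(obj: Any) -> str:
    """Stable short hash of a configuration object (dataclass, dict, or mapping)."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        obj = dataclasses.asdict(obj)

    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        return str(o)

    payload = json.dumps(obj, sort_keys=True, default=_default)
    return hashlib.sha1(payload.encode()).hexdigest()[:12]


def contiguous_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True in a boolean array as inclusive (start, stop) pairs."""
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        return []
    padded = np.concatenate([[False], mask, [False]]).astype(np.int8)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1) - 1
    return list(zip(starts.tolist(), stops.tolist()))


def split_runs_at_boundaries(
    runs: list[tuple[int, int]], boundaries: np.ndarray
) -> list[tuple[int, int]]:
    """Split inclusive runs so none crosses a trial boundary.

    ``boundaries`` holds the first frame of each block (sorted); a run spanning
    a boundary b is split into [..., b-1] and [b, ...].
    """
    out: list[tuple[int, int]] = []
    for start, stop in runs:
        cuts = [b for b in boundaries if start < b <= stop]
        lo = start
        for b in cuts:
            out.append((lo, b - 1))
            lo = b
        out.append((lo, stop))
    return out
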