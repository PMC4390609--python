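"""Optional per-base conservation consumed from a precomputed bedGraph.

Conservation is never computed here: the pipeline accepts an externally
produced per-base score track (e.g. a phastCons export) and averages it
over predicted seed intervals.  When no track is supplied, conservation
fields stay null and conservation-based filters are disabled.
"""

from __future__ import annotations

from collections import defaultdict

import numpy as np


class ConservationTrack:
    """Per-chromosome interval score arrays with overlap-weighted means."""

    def __init__(self, data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]):
        self._data = data

    @classmethod
    def from_bedgraph(cls, path) -> "ConservationTrack":
        raw: dict[str, list[tuple[int, int, float]]] = defaultdict(list)
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                chrom, start, end, value = line.split()[:4]
                raw[chrom].append((int(start), int(end), float(value)))
        data = {}
        for chrom, rows in raw.items():
            rows.sort()
            starts = np.array([r[0] for r in rows])
            ends = np.array([r[1] for r in rows])
            vals = np.array([r[2] for r in rows])
            data[chrom] = (starts, ends, vals)
        return cls(data)

    def mean(self, chrom: str, start: int, end: int) -> float | None:
        """Overlap-weighted mean score over [start, end); None if no data."""
        if chrom not in self._data or end <= start:
            return None
        starts, ends, vals = self._data[chrom]
        lo = np.searchsorted(ends, start, side="right")
        hi = np.searchsorted(starts, end, side="left")
        if lo >= hi:
            return None
        ov = np.minimum(ends[lo:hi], end) - np.maximum(starts[lo:hi], start)
        ov = np.clip(ov, 0, None)
        total = ov.sum()
        if total == 0:
            return None
        return float((vals[lo:hi] * ov).sum() / total)
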