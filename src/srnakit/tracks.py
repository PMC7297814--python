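"""Genomic coverage tracks with bedGraph semantics.

A track is a set of scored, non-overlapping, half-open intervals per
chromosome (0-based coordinates).  Bases not covered by any interval have an
implicit value of 0, which matches how both the conservation averaging and
the ChIP-seq signal extraction treat missing data.  Only the text bedGraph
format is supported; it round-trips exactly and is diffable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CoverageTrack", "read_bedgraph", "write_bedgraph"]


@dataclass
class CoverageTrack:
    """Sparse per-chromosome step function: sorted scored intervals.

    Parameters
    ----------
    data
        DataFrame with columns ``chrom``, ``start``, ``end``, ``value``.
        Intervals on the same chromosome must not overlap.
    label
        Optional track name (e.g. the ChIP-seq transcription factor).
    """

    data: pd.DataFrame
    label: str | None = None
    _index: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        df = self.data
        required = {"chrom", "start", "end", "value"}
        if not required.issubset(df.columns):
            raise ValueError(f"track needs columns {sorted(required)}")
        if len(df) and (df["end"] <= df["start"]).any():
            raise ValueError("track intervals must satisfy start < end")
        for chrom, sub in df.groupby("chrom", sort=True):
            sub = sub.sort_values("start")
            starts = sub["start"].to_numpy(dtype=np.int64)
            ends = sub["end"].to_numpy(dtype=np.int64)
            if (starts[1:] < ends[:-1]).any():
                raise ValueError(f"overlapping track intervals on {chrom}")
            self._index[chrom] = (starts, ends, sub["value"].to_numpy(dtype=float))

    @property
    def chroms(self) -> list[str]:
        return sorted(self._index)

    def interval_sum(self, chrom: str, start: int, end: int) -> float:
        """Sum of per-base values over [start, end); uncovered bases add 0."""
        if end <= start:
            raise ValueError(f"zero-length interval {chrom}:{start}-{end}")
        if chrom not in self._index:
            return 0.0
        starts, ends, values = self._index[chrom]
        i0 = int(np.searchsorted(ends, start, side="right"))
        i1 = int(np.searchsorted(starts, end, side="left"))
        if i1 <= i0:
            return 0.0
        ov = np.minimum(ends[i0:i1], end) - np.maximum(starts[i0:i1], start)
        return float(np.sum(values[i0:i1] * np.clip(ov, 0, None)))

    def interval_mean(self, chrom: str, start: int, end: int) -> float:
        """Mean per-base value over [start, end), uncovered bases counted as 0."""
        return self.interval_sum(chrom, start, end) / (end - start)

    def per_base(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Dense per-base values over [start, end) (0 where uncovered)."""
        if end <= start:
            raise ValueError(f"zero-length interval {chrom}:{start}-{end}")
        out = np.zeros(end - start, dtype=float)
        if chrom not in self._index:
            return out
        starts, ends, values = self._index[chrom]
        i0 = int(np.searchsorted(ends, start, side="right"))
        i1 = int(np.searchsorted(starts, end, side="left"))
        for s, e, v in zip(starts[i0:i1], ends[i0:i1], values[i0:i1]):
            a = max(s, start) - start
            b = min(e, end) - start
            if b > a:
                out[a:b] = v
        return out

    @classmethod
    def from_dense(
        cls, values: np.ndarray, chrom: str = "chrSim", label: str | None = None
    ) -> "CoverageTrack":
        """Run-length encode a dense per-base array, dropping zero runs."""
        values = np.asarray(values, dtype=float)
        if values.size == 0:
            return cls(pd.DataFrame(columns=["chrom", "start", "end", "value"]), label)
        change = np.flatnonzero(values[1:] != values[:-1]) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [values.size]])
        vals = values[starts]
        keep = vals != 0.0
        df = pd.DataFrame(
            {"chrom": chrom, "start": starts[keep], "end": ends[keep], "value": vals[keep]}
        )
        return cls(df, label)


def read_bedgraph(path, label: str | None = None) -> CoverageTrack:
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["chrom", "start", "end", "value"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "value": float},
    )
    return CoverageTrack(df, label=label)


def write_bedgraph(track: CoverageTrack, path) -> None:
    df = track.data.sort_values(["chrom", "start"])
    df.to_csv(path, sep="\t", header=False, index=False, float_format="%.6g")
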