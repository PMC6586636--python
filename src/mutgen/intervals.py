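"""Genomic interval sets with 1-based inclusive coordinates.

All coordinates inside the package are 1-based inclusive; BED input/output is
converted at the boundary (see :mod:`mutgen.io`). Interval sets are kept
per-chromosome as sorted, merged ``(start, end)`` arrays so that set
difference, intersection and membership are O(n log n).
"""

from __future__ import annotations

import re
import warnings
from typing import Dict, Iterable, Iterator, Tuple

import numpy as np

_AUTOSOME_RE = re.compile(r"^(chr)?(\d+)$")


def is_autosome(chrom: str) -> bool:
    """True for chromosome names like ``chr7`` or ``12`` (not X/Y/M)."""
    return _AUTOSOME_RE.match(chrom) is not None


class IntervalSet:
    """A set of genomic intervals, normalized to sorted non-overlapping form.

    Parameters
    ----------
    intervals
        Iterable of ``(chrom, start, end)`` with 1-based inclusive bounds.
        Overlapping, adjacent or unsorted inputs are merged/sorted with a
        warning; ``start > end`` raises ``ValueError``.
    """

    def __init__(self, intervals: Iterable[Tuple[str, int, int]] = ()):
        raw: Dict[str, list] = {}
        for chrom, start, end in intervals:
            start, end = int(start), int(end)
            if start > end:
                raise ValueError(f"interval start {start} > end {end} on {chrom}")
            if start < 1:
                raise ValueError(f"1-based coordinate must be >= 1, got {start}")
            raw.setdefault(str(chrom), []).append((start, end))
        self._data: Dict[str, np.ndarray] = {}
        needed_normalizing = False
        for chrom, ivals in raw.items():
            original = np.array(ivals, dtype=np.int64)
            arr = np.array(sorted(ivals), dtype=np.int64)
            if not np.array_equal(original, arr):
                needed_normalizing = True
            merged = [list(arr[0])]
            for s, e in arr[1:]:
                if s <= merged[-1][1]:  # true overlap
                    needed_normalizing = True
                if s <= merged[-1][1] + 1:  # merge overlapping or adjacent
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            self._data[chrom] = np.array(merged, dtype=np.int64)
        if needed_normalizing:
            warnings.warn("input intervals were unsorted or overlapping; normalized", stacklevel=2)

    # -- construction -----------------------------------------------------
    @classmethod
    def _from_normalized(cls, data: Dict[str, np.ndarray]) -> "IntervalSet":
        obj = cls.__new__(cls)
        obj._data = {c: a.copy() for c, a in data.items() if len(a)}
        return obj

    # -- basic queries -----------------------------------------------------
    def __iter__(self) -> Iterator[Tuple[str, int, int]]:
        for chrom in sorted(self._data):
            for s, e in self._data[chrom]:
                yield chrom, int(s), int(e)

    def __len__(self) -> int:
        return sum(len(a) for a in self._data.values())

    def __eq__(self, other) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return list(self) == list(other)

    @property
    def chroms(self):
        return sorted(self._data)

    @property
    def total_bp(self) -> int:
        """Total nucleotides covered (1-based inclusive lengths)."""
        return int(sum((a[:, 1] - a[:, 0] + 1).sum() for a in self._data.values()))

    def contains(self, chrom: str, pos: int) -> bool:
        arr = self._data.get(str(chrom))
        if arr is None or not len(arr):
            return False
        i = int(np.searchsorted(arr[:, 0], pos, side="right")) - 1
        return i >= 0 and pos <= arr[i, 1]

    # -- set algebra -------------------------------------------------------
    def difference(self, other: "IntervalSet") -> "IntervalSet":
        """Self minus other, per base."""
        out: Dict[str, np.ndarray] = {}
        for chrom, arr in self._data.items():
            sub = other._data.get(chrom)
            if sub is None or not len(sub):
                out[chrom] = arr.copy()
                continue
            pieces = []
            j = 0
            for s, e in arr:
                cur = s
                while j < len(sub) and sub[j, 1] < cur:
                    j += 1
                k = j
                while k < len(sub) and sub[k, 0] <= e:
                    if sub[k, 0] > cur:
                        pieces.append((cur, sub[k, 0] - 1))
                    cur = max(cur, sub[k, 1] + 1)
                    k += 1
                if cur <= e:
                    pieces.append((cur, e))
            if pieces:
                out[chrom] = np.array(pieces, dtype=np.int64)
        return IntervalSet._from_normalized(out)

    def intersection(self, other: "IntervalSet") -> "IntervalSet":
        out: Dict[str, np.ndarray] = {}
        for chrom, arr in self._data.items():
            oth = other._data.get(chrom)
            if oth is None or not len(oth):
                continue
            pieces = []
            i = j = 0
            while i < len(arr) and j < len(oth):
                s = max(arr[i, 0], oth[j, 0])
                e = min(arr[i, 1], oth[j, 1])
                if s <= e:
                    pieces.append((s, e))
                if arr[i, 1] < oth[j, 1]:
                    i += 1
                else:
                    j += 1
            if pieces:
                out[chrom] = np.array(pieces, dtype=np.int64)
        return IntervalSet._from_normalized(out)

    def restrict_autosomes(self) -> "IntervalSet":
        return IntervalSet._from_normalized(
            {c: a for c, a in self._data.items() if is_autosome(c)}
        )

    def __repr__(self) -> str:  # pragma: no cover
        return f"IntervalSet({len(self)} intervals, {self.total_bp} bp, {len(self._data)} chroms)"
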