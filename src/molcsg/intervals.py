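"""Sorted disjoint closed intervals of a segment parameter.

Every CSG decision along a line segment reduces to set algebra over the
"inside" stretches of the segment parameter ``t``.  :class:`IntervalSet`
holds those stretches as closed intervals ``[lo, hi]``, normalized so that
intervals are sorted and pairwise disjoint; intervals whose gap is below
``EPS_TANGENT`` are merged, which prevents spurious zero-width exterior
slivers from tangency handling.
"""

from __future__ import annotations

import numpy as np

#: Separation of the two artificial intersection points generated at a
#: tangency, in Angstroms.  Also the merge tolerance for normalization.
EPS_TANGENT = 1e-9


class IntervalSet:
    """An ordered set of disjoint closed intervals ``[lo, hi]`` on t.

    Parameters
    ----------
    intervals : iterable of (lo, hi)
        Raw intervals; they may overlap or touch and are normalized.
    """

    __slots__ = ("_iv",)

    def __init__(self, intervals=()):
        arr = np.asarray(list(intervals), dtype=float)
        if arr.size == 0:
            self._iv = np.empty((0, 2), dtype=float)
            return
        arr = arr.reshape(-1, 2)
        if np.any(arr[:, 0] > arr[:, 1]):
            raise ValueError("interval with lo > hi")
        order = np.argsort(arr[:, 0], kind="stable")
        arr = arr[order]
        merged = [arr[0].copy()]
        for lo, hi in arr[1:]:
            if lo - merged[-1][1] < EPS_TANGENT:  # overlap or near-touch
                merged[-1][1] = max(merged[-1][1], hi)
            else:
                merged.append(np.array([lo, hi]))
        self._iv = np.array(merged, dtype=float)

    # -- construction helpers ------------------------------------------

    @classmethod
    def empty(cls) -> "IntervalSet":
        return cls()

    @classmethod
    def _wrap(cls, arr: np.ndarray) -> "IntervalSet":
        out = cls.__new__(cls)
        out._iv = arr
        return out

    # -- inspection ----------------------------------------------------

    @property
    def intervals(self) -> np.ndarray:
        """(n, 2) array of [lo, hi] rows."""
        return self._iv

    def __len__(self) -> int:
        return len(self._iv)

    def __iter__(self):
        return iter(map(tuple, self._iv))

    def __bool__(self) -> bool:
        return len(self._iv) > 0

    def __eq__(self, other) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return self._iv.shape == other._iv.shape and np.allclose(
            self._iv, other._iv, atol=1e-12, rtol=0.0
        )

    def __repr__(self) -> str:
        body = ", ".join(f"[{lo:g}, {hi:g}]" for lo, hi in self._iv)
        return f"IntervalSet({body})"

    def total_length(self) -> float:
        if not len(self._iv):
            return 0.0
        return float(np.sum(self._iv[:, 1] - self._iv[:, 0]))

    def boundaries(self) -> np.ndarray:
        """All interval endpoints, ascending."""
        return self._iv.ravel()

    def contains_t(self, t: float, tol: float = 0.0) -> bool:
        """True if t lies inside any interval (closed, with slack tol)."""
        iv = self._iv
        if not len(iv):
            return False
        return bool(np.any((iv[:, 0] - tol <= t) & (t <= iv[:, 1] + tol)))

    def midpoints(self) -> np.ndarray:
        return 0.5 * (self._iv[:, 0] + self._iv[:, 1]) if len(self._iv) else np.empty(0)

    # -- algebra -------------------------------------------------------

    def union(self, other: "IntervalSet") -> "IntervalSet":
        if not len(self._iv):
            return other
        if not len(other._iv):
            return self
        return IntervalSet(np.vstack([self._iv, other._iv]))

    def intersection(self, other: "IntervalSet") -> "IntervalSet":
        a, b = self._iv, other._iv
        out = []
        i = j = 0
        while i < len(a) and j < len(b):
            lo = max(a[i, 0], b[j, 0])
            hi = min(a[i, 1], b[j, 1])
            if lo <= hi:
                out.append((lo, hi))
            if a[i, 1] < b[j, 1]:
                i += 1
            else:
                j += 1
        return IntervalSet(out)

    def difference(self, other: "IntervalSet") -> "IntervalSet":
        """Set difference self minus other.

        Closed-minus-closed is re-closed: removing [1, 3] from [0, 2]
        yields [0, 1].  A point exactly on the boundary of ``other`` is
        treated as removed, consistent with the global surface-is-inside
        rule; the output interval is closed at the cut.
        """
        if not len(self._iv) or not len(other._iv):
            return self
        out = []
        b = other._iv
        for lo, hi in self._iv:
            cur = lo
            for blo, bhi in b:
                if bhi < cur or blo > hi:
                    continue
                if blo > cur:
                    out.append((cur, min(blo, hi)))
                cur = max(cur, bhi)
                if cur >= hi:
                    break
            if cur < hi:
                out.append((cur, hi))
        return IntervalSet(out)

    def clip(self, lo: float, hi: float) -> "IntervalSet":
        """Intersect with the single interval [lo, hi]."""
        return self.intersection(IntervalSet([(lo, hi)]))

    __or__ = union
    __and__ = intersection
    __sub__ = difference
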