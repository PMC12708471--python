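"""Canonical abridged age grid: 0, 1-4, 5-9, ..., 80-84, 85+.

All surfaces in this package live on this grid. Groups are half-open
intervals [start, start + width); the terminal group is open-ended,
[85, inf). Ages at group boundaries are exact integers.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Start of the open-ended terminal group (years).
TERMINAL_AGE = 85

#: Offset added to the terminal start to get a nominal midpoint for basis
#: construction and coefficient extrapolation (85+ -> 92.5).
TERMINAL_MIDPOINT_OFFSET = 7.5


@dataclass(frozen=True)
class AgeGrid:
    """Ordered, contiguous age groups with exactly one open terminal group.

    Parameters
    ----------
    starts : tuple of int
        Lower bound of each group, ascending.
    widths : tuple of float
        Width of each group in years; ``inf`` marks the open terminal group.
    """

    starts: tuple
    widths: tuple

    def __post_init__(self):
        starts = tuple(self.starts)
        widths = tuple(self.widths)
        if len(starts) != len(widths) or not starts:
            raise ValueError("starts and widths must be equal-length, non-empty")
        opens = [i for i, w in enumerate(widths) if np.isinf(w)]
        if opens != [len(starts) - 1]:
            raise ValueError("exactly one open-ended group, in terminal position")
        for i in range(len(starts) - 1):
            if starts[i] + widths[i] != starts[i + 1]:
                raise ValueError(
                    f"groups must be contiguous: [{starts[i]}, {starts[i] + widths[i]})"
                    f" then {starts[i + 1]}"
                )
        object.__setattr__(self, "starts", starts)
        object.__setattr__(self, "widths", widths)

    @classmethod
    def canonical(cls) -> "AgeGrid":
        """The 19-group abridged grid 0, 1-4, 5-9, ..., 80-84, 85+."""
        starts = (0, 1) + tuple(range(5, TERMINAL_AGE + 1, 5))
        widths = (1, 4) + (5,) * 16 + (np.inf,)
        return cls(starts, widths)

    def __len__(self) -> int:
        return len(self.starts)

    @property
    def midpoints(self) -> np.ndarray:
        """Nominal group midpoints (terminal: start + 7.5)."""
        mids = [
            s + (TERMINAL_MIDPOINT_OFFSET if np.isinf(w) else w / 2.0)
            for s, w in zip(self.starts, self.widths)
        ]
        return np.asarray(mids, dtype=float)

    @property
    def labels(self) -> list:
        out = []
        for s, w in zip(self.starts, self.widths):
            if np.isinf(w):
                out.append(f"{s}+")
            elif w == 1:
                out.append(str(s))
            else:
                out.append(f"{s}-{int(s + w - 1)}")
        return out

    def index_of(self, age: float) -> int:
        """Index of the group whose interval contains ``age``."""
        if age < self.starts[0]:
            raise ValueError(f"age {age} below grid start {self.starts[0]}")
        for i, (s, w) in enumerate(zip(self.starts, self.widths)):
            if np.isinf(w) or s <= age < s + w:
                if age >= s:
                    return i
        raise ValueError(f"age {age} not on grid")  # pragma: no cover

    def start_of(self, age: float) -> int:
        """Start of the group containing ``age``."""
        return self.starts[self.index_of(age)]


#: Module-level canonical grid shared by all surfaces.
CANONICAL = AgeGrid.canonical()

#: Canonical group starts as a plain tuple, for fast membership checks.
CANONICAL_STARTS = CANONICAL.starts
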