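"""Informative-site reduction of a (target, parentA, parentB) triplet.

A column is informative when the two parents differ, all three characters
are unambiguous bases (A/C/G/T), and the target matches exactly one parent.
Sites where the target matches neither parent carry no signal for the
parent pairing and would dilute the background match proportion, so they
are excluded. The ordered site list, with a boolean flag "target matches
parentB", is the coordinate system of every window statistic.

Internally coordinates are 0-based alignment columns; user-facing reports
convert to 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TripletProfile", "extract_profile", "sites_from_ascii"]

# membership table: ASCII code -> is unambiguous base
_IS_BASE = np.zeros(256, dtype=bool)
for _c in b"ACGT":
    _IS_BASE[_c] = True


@dataclass(frozen=True)
class TripletProfile:
    """Informative sites of one directed triplet comparison.

    ``columns`` are strictly increasing 0-based alignment columns;
    ``matches_b[i]`` is True when the target equals parentB at
    ``columns[i]``. ``L`` (the number of informative sites) is the total
    sequence length in the window statistic's coordinate system.
    """

    target_id: str
    parent_a_id: str
    parent_b_id: str
    columns: np.ndarray
    matches_b: np.ndarray

    def __post_init__(self) -> None:
        if self.columns.shape != self.matches_b.shape:
            raise ValueError("columns and matches_b must have equal length")
        if self.columns.size > 1 and not (np.diff(self.columns) > 0).all():
            raise ValueError("columns must be strictly increasing")

    @property
    def L(self) -> int:
        return int(self.columns.size)

    def swapped(self) -> "TripletProfile":
        """The same triplet with parent roles exchanged.

        The site set is identical; every match flag is complemented.
        """
        return TripletProfile(
            target_id=self.target_id,
            parent_a_id=self.parent_b_id,
            parent_b_id=self.parent_a_id,
            columns=self.columns,
            matches_b=~self.matches_b,
        )


def sites_from_ascii(
    target: np.ndarray, parent_a: np.ndarray, parent_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Informative-site reduction on uint8 ASCII arrays.

    Returns ``(columns, matches_b)``. Shared by the string front-end and
    the simulator's fast path.
    """
    ok = _IS_BASE[target] & _IS_BASE[parent_a] & _IS_BASE[parent_b]
    informative = (
        ok
        & (parent_a != parent_b)
        & ((target == parent_a) | (target == parent_b))
    )
    columns = np.flatnonzero(informative)
    return columns, target[columns] == parent_b[columns]


def extract_profile(
    target: str,
    parent_a: str,
    parent_b: str,
    *,
    target_id: str = "target",
    parent_a_id: str = "parentA",
    parent_b_id: str = "parentB",
) -> TripletProfile:
    """Reduce three equal-length aligned sequences to a :class:`TripletProfile`.

    Columns containing gaps, N or ambiguity codes in any of the three
    sequences are excluded, as are columns where the target matches
    neither parent.
    """
    if not (len(target) == len(parent_a) == len(parent_b)):
        raise ValueError(
            "triplet sequences must have equal length: "
            f"{len(target)}, {len(parent_a)}, {len(parent_b)}"
        )
    t = np.frombuffer(target.encode("ascii"), dtype=np.uint8)
    a = np.frombuffer(parent_a.encode("ascii"), dtype=np.uint8)
    b = np.frombuffer(parent_b.encode("ascii"), dtype=np.uint8)
    columns, matches_b = sites_from_ascii(t, a, b)
    return TripletProfile(
        target_id=target_id,
        parent_a_id=parent_a_id,
        parent_b_id=parent_b_id,
        columns=columns,
        matches_b=matches_b,
    )
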