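"""Test-point layouts for Humphrey 24-2 and 30-2 perimetry grids.

All layouts are stored in right-eye format: x in degrees, positive toward the
temporal field (where the blind spot sits at 15 degrees); y in degrees,
positive toward the superior field.  Locations are ordered row-major from the
superior to the inferior row and, within a row, from nasal to temporal
(ascending x).  The two locations that fall on the physiologic blind spot at
(15, +-3) are carried in the layout but excluded from every analysis vector,
so the analysis dimension is 52 for 24-2 and 74 for 30-2.

Left-eye fields are measured on the mirror image of these layouts; the mirror
layout uses the same ordering convention applied to the mirrored coordinates,
which makes left-to-right conversion a pure index permutation
(:func:`mirror_permutation`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Tuple


class VFFormatError(ValueError):
    """A record or file does not conform to a known visual-field format."""


class VFDataError(ValueError):
    """Structurally valid input carrying unusable values."""


BLIND_SPOT = ((15, 3), (15, -3))

# Half-row widths: y -> tuple of x coordinates (right-eye format).
_ROWS_24_2 = {
    21: (-9, -3, 3, 9),
    15: (-15, -9, -3, 3, 9, 15),
    9: (-21, -15, -9, -3, 3, 9, 15, 21),
    # the 24-2 pattern reaches 27 degrees on the nasal side only
    3: (-27, -21, -15, -9, -3, 3, 9, 15, 21),
}

_ROWS_30_2 = {
    27: (-9, -3, 3, 9),
    21: (-15, -9, -3, 3, 9, 15),
    15: (-21, -15, -9, -3, 3, 9, 15, 21),
    9: (-27, -21, -15, -9, -3, 3, 9, 15, 21, 27),
    3: (-27, -21, -15, -9, -3, 3, 9, 15, 21, 27),
}


def _build_locations(rows: dict) -> Tuple[Tuple[int, int], ...]:
    locs = []
    ys = sorted(rows, reverse=True)
    for y in ys:
        locs.extend((x, y) for x in rows[y])
    for y in sorted(rows):
        locs.extend((x, -y) for x in rows[y])
    # re-sort to the documented order: superior to inferior, nasal to temporal
    locs.sort(key=lambda xy: (-xy[1], xy[0]))
    return tuple(locs)


@dataclass(frozen=True)
class GridSpec:
    """Immutable description of a perimetry test-point pattern."""

    pattern_id: str
    locations: Tuple[Tuple[int, int], ...]
    blind_spot_indices: frozenset = field(default_factory=frozenset)

    @property
    def n_locations(self) -> int:
        return len(self.locations)

    @property
    def analysis_indices(self) -> Tuple[int, ...]:
        """Indices of locations that enter analysis vectors (blind spot excluded)."""
        return tuple(
            i for i in range(len(self.locations)) if i not in self.blind_spot_indices
        )

    @property
    def analysis_locations(self) -> Tuple[Tuple[int, int], ...]:
        return tuple(self.locations[i] for i in self.analysis_indices)

    @property
    def n_analysis(self) -> int:
        return len(self.locations) - len(self.blind_spot_indices)


def _make_grid(pattern_id: str, rows: dict) -> GridSpec:
    locs = _build_locations(rows)
    bs = frozenset(locs.index(p) for p in BLIND_SPOT)
    return GridSpec(pattern_id=pattern_id, locations=locs, blind_spot_indices=bs)


GRID_24_2 = _make_grid("24-2", _ROWS_24_2)
GRID_30_2 = _make_grid("30-2", _ROWS_30_2)

_GRIDS = {"24-2": GRID_24_2, "30-2": GRID_30_2}


def get_grid(pattern_id: str) -> GridSpec:
    try:
        return _GRIDS[pattern_id]
    except KeyError:
        raise VFFormatError(f"unknown grid pattern {pattern_id!r}; known: 24-2, 30-2")


def mirror_permutation(grid: GridSpec) -> Tuple[int, ...]:
    """Permutation taking a left-eye analysis vector to right-eye format.

    The left-eye layout is the mirror image of ``grid`` sorted in the same
    documented order.  Entry ``j`` of the returned tuple is the index, in the
    left-eye layout, of the value that belongs at right-eye analysis index
    ``j``:  ``right_vec = left_vec[perm]``.  The permutation is an involution
    because mirroring twice is the identity.
    """
    right = grid.analysis_locations
    mirrored = sorted(((-x, y) for (x, y) in right), key=lambda xy: (-xy[1], xy[0]))
    pos = {xy: i for i, xy in enumerate(mirrored)}
    return tuple(pos[(-x, y)] for (x, y) in right)


def mirrored_analysis_locations(grid: GridSpec) -> Tuple[Tuple[int, int], ...]:
    """The left-eye layout: mirrored coordinates in the documented order."""
    return tuple(
        sorted(((-x, y) for (x, y) in grid.analysis_locations),
               key=lambda xy: (-xy[1], xy[0]))
    )


def subset_indices_mirrored(small: GridSpec, large: GridSpec) -> Tuple[int, ...]:
    """As :func:`subset_indices`, but between the mirrored (left-eye) layouts."""
    pos = {xy: i for i, xy in enumerate(mirrored_analysis_locations(large))}
    out = []
    for xy in mirrored_analysis_locations(small):
        if xy not in pos:
            raise VFDataError(
                f"location {xy} of mirrored {small.pattern_id} absent from "
                f"mirrored {large.pattern_id}"
            )
        out.append(pos[xy])
    return tuple(out)


def subset_indices(small: GridSpec, large: GridSpec) -> Tuple[int, ...]:
    """Indices into ``large``'s analysis vector for each ``small`` analysis location.

    Raises
    ------
    VFDataError
        If a location of ``small`` has no coincident location in ``large``.
    """
    pos = {xy: i for i, xy in enumerate(large.analysis_locations)}
    out = []
    for xy in small.analysis_locations:
        if xy not in pos:
            raise VFDataError(
                f"location {xy} of {small.pattern_id} absent from {large.pattern_id}"
            )
        out.append(pos[xy])
    return tuple(out)
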