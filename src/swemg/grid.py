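"""Electrode-grid geometry for the 64-channel swallowing HD-sEMG array.

The array covers two muscle groups:

* **infrahyoid** — two mirrored 6-row x 4-column patches below the hyoid,
  11 mm row and column pitch; channels 1-24 on the subject's left,
  41-64 on the right.
* **submental** — a single 2-row x 8-column patch above the hyoid spanning
  the midline, 5.5 mm row pitch and 11 mm column pitch; channels 25-40.

Coordinates are planar, in millimetres, with the origin on the body midline
at the hyoid level, ``x`` positive toward the subject's left and ``y``
positive superior.  Every channel is paired with its mirror image about
``x = 0``: 8 pairs inside the submental patch and 24 pairs across the two
infrahyoid patches.  The left/right RMS-ratio symmetry statistic and the
activity barycenter depend only on this pairing and on the coordinates,
not on which physical electrode carries which number.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

SUBMENTAL = "submental"
INFRAHYOID_LEFT = "infrahyoid_left"
INFRAHYOID_RIGHT = "infrahyoid_right"

REGIONS = (SUBMENTAL, INFRAHYOID_LEFT, INFRAHYOID_RIGHT)

#: spacing constants (mm)
INFRAHYOID_PITCH = 11.0
SUBMENTAL_ROW_PITCH = 5.5
SUBMENTAL_COL_PITCH = 11.0

N_CHANNELS = 64


@dataclass(frozen=True)
class Electrode:
    """A single channel of the grid."""

    channel_id: int          # 1..64
    x_mm: float
    y_mm: float
    region: str
    pair_id: int             # shared by the two mirrored channels of a pair


@dataclass
class ElectrodeGrid:
    """The full 64-channel grid with left/right mirror pairing."""

    electrodes: list[Electrode] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = sorted(e.channel_id for e in self.electrodes)
        if ids != list(range(1, N_CHANNELS + 1)):
            raise ValueError("grid must contain channel ids 1..64 exactly once")
        self._by_id = {e.channel_id: e for e in self.electrodes}

    # -- basic accessors -------------------------------------------------
    def __len__(self) -> int:
        return len(self.electrodes)

    def electrode(self, channel_id: int) -> Electrode:
        return self._by_id[channel_id]

    def positions(self, channel_ids=None) -> np.ndarray:
        """(n, 2) array of x/y coordinates in channel-id order."""
        if channel_ids is None:
            channel_ids = range(1, N_CHANNELS + 1)
        return np.array([[self._by_id[c].x_mm, self._by_id[c].y_mm]
                         for c in channel_ids])

    def channels_in_region(self, region: str) -> list[int]:
        """Channel ids in one region.

        ``"infrahyoid"`` is accepted as the union of left and right patches.
        """
        if region == "infrahyoid":
            return (self.channels_in_region(INFRAHYOID_LEFT)
                    + self.channels_in_region(INFRAHYOID_RIGHT))
        if region not in REGIONS:
            raise ValueError(f"unknown region {region!r}")
        return sorted(e.channel_id for e in self.electrodes
                      if e.region == region)

    # -- pairing ---------------------------------------------------------
    def mirror_channel(self, channel_id: int) -> int:
        """The channel paired with *channel_id* (an involution)."""
        e = self._by_id[channel_id]
        (other,) = [o.channel_id for o in self.electrodes
                    if o.pair_id == e.pair_id and o.channel_id != channel_id]
        return other

    def pairs(self, region: str) -> list[tuple[int, int]]:
        """(left, right) channel-id pairs for ``"submental"`` or ``"infrahyoid"``.

        "Left" is the member with ``x > 0`` (x positive toward the subject's
        left).  Submental yields 8 pairs, infrahyoid 24.
        """
        if region == SUBMENTAL:
            members = [e for e in self.electrodes if e.region == SUBMENTAL]
        elif region == "infrahyoid":
            members = [e for e in self.electrodes
                       if e.region in (INFRAHYOID_LEFT, INFRAHYOID_RIGHT)]
        else:
            raise ValueError("region must be 'submental' or 'infrahyoid'")
        by_pair: dict[int, list[Electrode]] = {}
        for e in members:
            by_pair.setdefault(e.pair_id, []).append(e)
        out = []
        for pid in sorted(by_pair):
            a, b = by_pair[pid]
            left, right = (a, b) if a.x_mm > b.x_mm else (b, a)
            out.append((left.channel_id, right.channel_id))
        return out

    # -- serialization ---------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        payload = [{"channel_id": e.channel_id, "x_mm": e.x_mm,
                    "y_mm": e.y_mm, "region": e.region, "pair_id": e.pair_id}
                   for e in self.electrodes]
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ElectrodeGrid":
        payload = json.loads(Path(path).read_text())
        return cls([Electrode(int(d["channel_id"]), float(d["x_mm"]),
                              float(d["y_mm"]), d["region"], int(d["pair_id"]))
                    for d in payload])


def build_default_grid() -> ElectrodeGrid:
    """Construct the standard 64-channel grid.

    Numbering is row-major within each patch, columns ordered by increasing
    ``x`` and rows from superior to inferior.  The exact number-to-node
    assignment is a documented convention; the symmetry pairing and the
    coordinates are what the downstream indicators consume.
    """
    electrodes: list[Electrode] = []

    # Submental patch: 2 rows x 8 columns straddling the midline.
    # Columns at +/-5.5, +/-16.5, +/-27.5, +/-38.5; rows at y = 30.0, 24.5.
    sub_cols = (np.arange(8) - 3.5) * SUBMENTAL_COL_PITCH
    sub_rows = np.array([30.0, 30.0 - SUBMENTAL_ROW_PITCH])
    # pair ids 1..8: mirror columns c and 7-c within a row
    for r in range(2):
        for c in range(8):
            cid = 25 + r * 8 + c
            pid = 1 + r * 4 + min(c, 7 - c)
            electrodes.append(Electrode(cid, float(sub_cols[c]),
                                        float(sub_rows[r]), SUBMENTAL, pid))

    # Infrahyoid patches: 6 rows x 4 columns each side, 11 mm pitch.
    # Left columns at x = 11, 22, 33, 44; rows at y = -11 .. -66.
    inf_cols = INFRAHYOID_PITCH * np.arange(1, 5)
    inf_rows = -INFRAHYOID_PITCH * np.arange(1, 7)
    for r in range(6):
        for c in range(4):
            idx = r * 4 + c
            pid = 9 + idx
            y = float(inf_rows[r])
            electrodes.append(Electrode(1 + idx, float(inf_cols[c]), y,
                                        INFRAHYOID_LEFT, pid))
            electrodes.append(Electrode(41 + idx, float(-inf_cols[c]), y,
                                        INFRAHYOID_RIGHT, pid))

    return ElectrodeGrid(sorted(electrodes, key=lambda e: e.channel_id))
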