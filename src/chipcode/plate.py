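"""Declarative plate-scan model: grid geometry, ROI, and well semantics.

A :class:`PlateLayout` describes everything the image stage needs to know
about a scanned well plate without looking at pixel content: where the well
centers are (origin + pitch, axis-aligned grid), the shape of the region of
interest summed per well, and which sensor / buffer condition / role each
well carries.  Scans made on a flatbed with a film area guide are
axis-aligned, so no rotation or registration is modelled.

Coordinate convention: 0-based pixel coordinates, origin at the image's
top-left corner, x increasing rightward (columns), y increasing downward
(rows).
"""

from __future__ import annotations

import json
import re
import string
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .errors import BoundsError, LayoutError, PairingError

ROW_LETTERS = string.ascii_uppercase
CHANNELS = ("R", "G", "B")

#: Canonical digit ordering: sensors ascending, conditions ascending, R,G,B.
DEFAULT_ORDERING_ID = "DC-asc.cond-asc.RGB"

_WELL_RE = re.compile(r"^([A-Z])(\d{1,2})$")


def sensor_sort_key(sensor_id: str) -> tuple:
    """Natural sort key so DC2 precedes DC10."""
    m = re.match(r"^([A-Za-z]*)(\d*)$", sensor_id)
    if m and m.group(2):
        return (m.group(1), int(m.group(2)))
    return (sensor_id, -1)


@dataclass(frozen=True, order=True)
class WellAddress:
    """Standard 96-well address: row letter A-H, 1-based column number."""

    row: str
    col: int

    def __post_init__(self):
        if self.row not in ROW_LETTERS:
            raise LayoutError(f"well row must be a single uppercase letter, got {self.row!r}")
        if self.col < 1:
            raise LayoutError(f"well column must be >= 1, got {self.col}")

    @classmethod
    def parse(cls, s: str) -> "WellAddress":
        m = _WELL_RE.match(s.strip().upper())
        if not m:
            raise LayoutError(f"cannot parse well address {s!r} (expected e.g. 'A1')")
        return cls(m.group(1), int(m.group(2)))

    @property
    def row_index(self) -> int:
        """0-based row index (A -> 0)."""
        return ROW_LETTERS.index(self.row)

    def __str__(self) -> str:
        return f"{self.row}{self.col}"


@dataclass(frozen=True)
class RoiSpec:
    """Region summed per well: a disk (radius px) or square (half-width px).

    A pixel belongs to a disk ROI iff its center lies at Euclidean distance
    <= radius from the well center; a square ROI iff both |dx| and |dy| are
    <= the half-width.  This rasterization rule is deterministic and is what
    the brute-force test oracle implements independently.
    """

    shape: str = "disk"
    size: float = 10.0

    def __post_init__(self):
        if self.shape not in ("disk", "square"):
            raise LayoutError(f"ROI shape must be 'disk' or 'square', got {self.shape!r}")
        if self.size <= 0:
            raise LayoutError(f"ROI size must be > 0 px, got {self.size}")


@dataclass(frozen=True)
class WellAssignment:
    """Semantics of one well: sensor, buffer condition, role, pair id."""

    sensor: str
    condition: int
    role: str
    pair: str

    def __post_init__(self):
        if self.role not in ("control", "analyte"):
            raise LayoutError(f"role must be 'control' or 'analyte', got {self.role!r}")


@dataclass
class PlateLayout:
    """Grid geometry plus the map from wells to sensor/condition/role.

    Parameters
    ----------
    n_rows, n_cols
        Grid dimensions (8 x 12 for a 96-well plate).
    origin_x, origin_y
        Pixel coordinates of the center of well A1.
    pitch_x, pitch_y
        Pixel spacing between adjacent well centers.
    roi
        Region-of-interest shape summed per well.
    well_map
        Mapping from :class:`WellAddress` to :class:`WellAssignment`.
        Only mapped wells are analyzed.
    """

    n_rows: int
    n_cols: int
    origin_x: float
    origin_y: float
    pitch_x: float
    pitch_y: float
    roi: RoiSpec = field(default_factory=RoiSpec)
    well_map: dict = field(default_factory=dict)
    ordering_id: str = DEFAULT_ORDERING_ID

    def __post_init__(self):
        self.validate()

    # -- validation ----------------------------------------------------

    def validate(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise LayoutError("grid must have at least one row and one column")
        if self.n_rows > len(ROW_LETTERS):
            raise LayoutError(f"n_rows cannot exceed {len(ROW_LETTERS)}")
        if self.pitch_x <= 0 or self.pitch_y <= 0:
            raise LayoutError("pitch must be positive in both directions")
        # ROI must fit within the well pitch (diameter < pitch)
        diameter = 2 * self.roi.size
        if diameter >= min(self.pitch_x, self.pitch_y):
            raise LayoutError(
                f"ROI diameter {diameter} px does not fit within pitch "
                f"({self.pitch_x} x {self.pitch_y} px)"
            )
        for addr in self.well_map:
            if addr.row_index >= self.n_rows or addr.col > self.n_cols:
                raise BoundsError(f"mapped well {addr} lies outside the {self.n_rows}x{self.n_cols} grid")
        self._validate_pairing()

    def _validate_pairing(self) -> None:
        by_pair: dict = {}
        for addr, a in self.well_map.items():
            by_pair.setdefault(a.pair, []).append((addr, a))
        bad = []
        for pair, members in by_pair.items():
            controls = [m for m in members if m[1].role == "control"]
            analytes = [m for m in members if m[1].role == "analyte"]
            if len(controls) != 1 or len(analytes) != 1:
                bad.append(pair)
                continue
            c, a = controls[0][1], analytes[0][1]
            if (c.sensor, c.condition) != (a.sensor, a.condition):
                bad.append(pair)
        if bad:
            raise PairingError(
                "each pair must contain exactly one control and one analyte well "
                f"with matching sensor and condition; offending pairs: {sorted(bad)}"
            )

    # -- derived structure --------------------------------------------

    @property
    def sensors(self) -> list:
        return sorted({a.sensor for a in self.well_map.values()}, key=sensor_sort_key)

    @property
    def conditions(self) -> list:
        return sorted({a.condition for a in self.well_map.values()})

    @property
    def code_length(self) -> int:
        """Digits in one identification code: sensors x conditions x 3 channels."""
        return len(self.sensors) * len(self.conditions) * len(CHANNELS)

    def digit_slots(self) -> list:
        """All (sensor, condition, channel) slots in canonical code order."""
        return [
            (s, c, ch)
            for s in self.sensors
            for c in self.conditions
            for ch in CHANNELS
        ]

    def pairs(self) -> dict:
        """pair id -> (control address, analyte address)."""
        ctl: dict = {}
        ana: dict = {}
        for addr, a in self.well_map.items():
            (ctl if a.role == "control" else ana)[a.pair] = addr
        return {p: (ctl[p], ana[p]) for p in sorted(ctl)}

    def pair_slot(self, pair: str) -> tuple:
        """(sensor, condition) of a pair."""
        for a in self.well_map.values():
            if a.pair == pair:
                return (a.sensor, a.condition)
        raise LayoutError(f"unknown pair id {pair!r}")

    # -- geometry ------------------------------------------------------

    def well_center(self, addr: WellAddress) -> tuple:
        """Pixel coordinates (x, y) of a well center."""
        if addr.row_index >= self.n_rows or addr.col > self.n_cols:
            raise BoundsError(
                f"well {addr} outside {self.n_rows}x{self.n_cols} grid"
            )
        x = self.origin_x + (addr.col - 1) * self.pitch_x
        y = self.origin_y + addr.row_index * self.pitch_y
        return (x, y)

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "n_rows": self.n_rows,
            "n_cols": self.n_cols,
            "origin": [self.origin_x, self.origin_y],
            "pitch": [self.pitch_x, self.pitch_y],
            "roi": {"shape": self.roi.shape, "size": self.roi.size},
            "ordering_id": self.ordering_id,
            "wells": [
                {
                    "well": str(addr),
                    "sensor": a.sensor,
                    "condition": a.condition,
                    "role": a.role,
                    "pair": a.pair,
                }
                for addr, a in sorted(self.well_map.items())
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PlateLayout":
        try:
            origin = d["origin"]
            pitch = d["pitch"]
            roi_d = d.get("roi", {})
            wells = d["wells"]
            layout = cls(
                n_rows=int(d["n_rows"]),
                n_cols=int(d["n_cols"]),
                origin_x=float(origin[0]),
                origin_y=float(origin[1]),
                pitch_x=float(pitch[0]),
                pitch_y=float(pitch[1]),
                roi=RoiSpec(roi_d.get("shape", "disk"), float(roi_d.get("size", 10.0))),
                well_map={
                    WellAddress.parse(w["well"]): WellAssignment(
                        sensor=w["sensor"],
                        condition=int(w["condition"]),
                        role=w["role"],
                        pair=w["pair"],
                    )
                    for w in wells
                },
                ordering_id=d.get("ordering_id", DEFAULT_ORDERING_ID),
            )
        except (KeyError, TypeError, ValueError, IndexError) as e:
            raise LayoutError(f"layout config schema violation: {e!r}") from e
        return layout

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


def load_layout(path) -> PlateLayout:
    """Load and validate a layout config (JSON) from disk."""
    p = Path(path)
    if not p.exists():
        raise LayoutError(f"layout file not found: {p}")
    try:
        d = json.loads(p.read_text())
    except json.JSONDecodeError as e:
        raise LayoutError(f"layout file {p} is not valid JSON: {e}") from e
    return PlateLayout.from_dict(d)


def default_layout() -> PlateLayout:
    """The shipped default 96-well layout: 8 sensors x 2 conditions x 3 assays.

    Row r carries sensor DC(r+1); columns 1-6 are buffer condition 1 and
    7-12 condition 2; within each condition the three (control, analyte)
    column pairs (1,2), (3,4), (5,6) are assays 1-3.  Code length 48.
    """
    with resources.files("chipcode.data").joinpath("default_layout_96.json").open() as fh:
        return PlateLayout.from_dict(json.load(fh))
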