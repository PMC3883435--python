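"""Binary fingerprint coding: channel differences, threshold digits, codes,
color-change counts, and library identification.

The significance rule is the heart of the assay's readout: a channel's
control-minus-analyte difference whose magnitude reaches the threshold
(default 1000 color-sum units, calibrated for 8-bit channel sums) encodes a
"1" — a color change — otherwise "0".  Concatenating the digit of every
(sensor, condition, channel) slot in the layout's canonical order yields the
identification code (48 digits for the default 8-sensor, 2-condition
layout), which is matched against a library by Hamming distance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from .errors import (
    AssemblyError,
    CompatibilityError,
    EmptyLibraryError,
    PairingError,
)
from .plate import CHANNELS, DEFAULT_ORDERING_ID, PlateLayout

#: Default significance threshold in color-sum units.
DEFAULT_THRESHOLD = 1000


@dataclass(frozen=True)
class CodingConfig:
    """Significance threshold for digit assignment, in color-sum units."""

    threshold: int = DEFAULT_THRESHOLD

    def __post_init__(self):
        if self.threshold <= 0:
            raise ValueError(f"threshold must be positive, got {self.threshold}")


@dataclass(frozen=True)
class ChannelDifference:
    """Signed control − analyte total for one channel of one well pair."""

    pair: str
    sensor: str
    condition: int
    channel: str
    delta: int


@dataclass(frozen=True)
class BinaryCode:
    """Ordered 0/1 digit string plus the digit-ordering convention it uses."""

    digits: str
    ordering_id: str = DEFAULT_ORDERING_ID

    def __post_init__(self):
        if set(self.digits) - {"0", "1"}:
            raise ValueError(f"code digits must be 0/1, got {self.digits!r}")

    def __len__(self) -> int:
        return len(self.digits)

    def __str__(self) -> str:
        return self.digits


@dataclass(frozen=True)
class LibraryEntry:
    analyte: str
    concentration_mM: float | None
    code: BinaryCode


@dataclass
class CodeLibrary:
    """Reference fingerprints for known analytes (one shared code length)."""

    entries: list = field(default_factory=list)

    def __post_init__(self):
        lengths = {len(e.code) for e in self.entries}
        orders = {e.code.ordering_id for e in self.entries}
        if len(lengths) > 1 or len(orders) > 1:
            raise CompatibilityError(
                "all library codes must share one length and ordering "
                f"(lengths {sorted(lengths)}, orderings {sorted(orders)})"
            )

    def __len__(self) -> int:
        return len(self.entries)

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                [
                    {
                        "analyte": e.analyte,
                        "concentration_mM": e.concentration_mM,
                        "code": e.code.digits,
                        "ordering_id": e.code.ordering_id,
                    }
                    for e in self.entries
                ],
                indent=1,
            )
        )

    @classmethod
    def from_json(cls, path) -> "CodeLibrary":
        raw = json.loads(Path(path).read_text())
        return cls(
            [
                LibraryEntry(
                    analyte=d["analyte"],
                    concentration_mM=d.get("concentration_mM"),
                    code=BinaryCode(d["code"], d.get("ordering_id", DEFAULT_ORDERING_ID)),
                )
                for d in raw
            ]
        )


@dataclass
class MatchResult:
    """All library entries at minimal Hamming distance; ties are reported."""

    best_matches: list
    distance: int


# ---------------------------------------------------------------------------


def compute_differences(totals, layout: PlateLayout) -> list:
    """Control − analyte channel totals for every pair, signed.

    One :class:`ChannelDifference` per (pair, channel), ordered by the
    canonical slot order then pair id.
    """
    by_addr = {t.addr: t for t in totals}
    diffs = []
    pairs = layout.pairs()
    missing = [
        p for p, (c, a) in pairs.items() if c not in by_addr or a not in by_addr
    ]
    if missing:
        raise PairingError(f"totals missing for wells of pairs: {sorted(missing)}")
    slot_of = {p: layout.pair_slot(p) for p in pairs}
    order = {slot: i for i, slot in enumerate(layout.digit_slots())}
    for p in sorted(pairs, key=lambda p: (order[slot_of[p] + ("R",)], p)):
        ctl, ana = pairs[p]
        sensor, condition = slot_of[p]
        for ch in CHANNELS:
            diffs.append(
                ChannelDifference(
                    pair=p,
                    sensor=sensor,
                    condition=condition,
                    channel=ch,
                    delta=by_addr[ctl].total(ch) - by_addr[ana].total(ch),
                )
            )
    return diffs


def digit_from_difference(d: ChannelDifference, cfg: CodingConfig = CodingConfig()) -> int:
    """1 iff the difference magnitude reaches the threshold (inclusive).

    A color change in either direction counts; the boundary |delta| ==
    threshold encodes 1, so the printed threshold itself is significant.
    """
    return 1 if abs(d.delta) >= cfg.threshold else 0


def assemble_code(digits_by_slot: dict, layout: PlateLayout) -> BinaryCode:
    """Concatenate per-slot digits in the layout's canonical order.

    ``digits_by_slot`` maps (sensor, condition, channel) -> 0/1 and must
    cover every slot of the layout exactly once.
    """
    slots = layout.digit_slots()
    missing = [s for s in slots if s not in digits_by_slot]
    extra = [s for s in digits_by_slot if s not in set(slots)]
    if missing or extra:
        raise AssemblyError(f"digit slots mismatch: missing {missing}, unexpected {extra}")
    bad = {s: d for s, d in digits_by_slot.items() if d not in (0, 1)}
    if bad:
        raise AssemblyError(f"digits must be 0 or 1: {bad}")
    return BinaryCode("".join(str(digits_by_slot[s]) for s in slots), layout.ordering_id)


def codes_by_assay(diffs, layout: PlateLayout, cfg: CodingConfig = CodingConfig()) -> list:
    """One identification code per assay replicate on the plate.

    Pairs sharing a (sensor, condition) slot are assay replicates; the
    k-th pair of each slot (pairs sorted by id) forms the k-th assay's code.
    Every slot must carry the same number of pairs.
    """
    by_slot: dict = {}
    for d in diffs:
        by_slot.setdefault((d.sensor, d.condition), {}).setdefault(d.pair, {})[d.channel] = d
    counts = {len(v) for v in by_slot.values()}
    if len(counts) != 1:
        raise AssemblyError(f"unequal pair counts per slot: {sorted(counts)}")
    n_assays = counts.pop()
    codes = []
    for k in range(n_assays):
        digits = {}
        for (sensor, condition), by_pair in by_slot.items():
            pair = sorted(by_pair)[k]
            for ch, d in by_pair[pair].items():
                digits[(sensor, condition, ch)] = digit_from_difference(d, cfg)
        codes.append(assemble_code(digits, layout))
    return codes


def count_color_changes(code: BinaryCode) -> int:
    """Number of significant color changes — the count of '1' digits."""
    return code.digits.count("1")


def hamming(a: BinaryCode, b: BinaryCode) -> int:
    if len(a) != len(b):
        raise CompatibilityError(f"code lengths differ: {len(a)} vs {len(b)}")
    if a.ordering_id != b.ordering_id:
        raise CompatibilityError(
            f"digit orderings differ: {a.ordering_id!r} vs {b.ordering_id!r}"
        )
    return sum(x != y for x, y in zip(a.digits, b.digits))


def match_code(code: BinaryCode, lib: CodeLibrary) -> MatchResult:
    """Nearest library entries by Hamming distance; ties all reported."""
    if len(lib) == 0:
        raise EmptyLibraryError("cannot identify against an empty code library")
    dists = [(hamming(code, e.code), e) for e in lib.entries]
    best = min(d for d, _ in dists)
    return MatchResult(best_matches=[e for d, e in dists if d == best], distance=best)


def differences_to_frame(diffs):
    """Differences as a DataFrame with the documented differences.csv columns."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "pair": d.pair,
                "sensor": d.sensor,
                "condition": d.condition,
                "channel": d.channel,
                "delta": d.delta,
            }
            for d in diffs
        ],
        columns=["pair", "sensor", "condition", "channel", "delta"],
    )
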