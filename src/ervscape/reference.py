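"""Proviral consensus reference and its six-region layout.

A full-length betaretrovirus-like (HML-8) provirus carries two long terminal
repeats flanking four internal open reading frames:

    5'LTR - gag - pro - pol - env - 3'LTR

Coordinates are 1-based inclusive on the consensus.  Adjacent ORF intervals
may overlap (the gag/pro, pro/pol and pol/env junctions of the
MER11A-HERVK11-MER11A consensus model overlap by design), but the two LTRs
must not: the 5'LTR starts at position 1 and the 3'LTR ends at the last base
of the consensus.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

REGION_NAMES = ("5'LTR", "gag", "pro", "pol", "env", "3'LTR")

#: Region layout of the 10485-bp MER11A-HERVK11-MER11A consensus (Dfam).
DEFAULT_LAYOUT: dict[str, tuple[int, int]] = {
    "5'LTR": (1, 1266),
    "gag": (1422, 3530),
    "pro": (3341, 4345),
    "pol": (4303, 7032),
    "env": (6890, 9217),
    "3'LTR": (9220, 10485),
}


class LayoutError(ValueError):
    """A region layout violates the proviral structure invariants."""


def validate_layout(layout: dict[str, tuple[int, int]], length: int | None = None) -> int:
    """Validate a region layout; return the implied consensus length.

    The implied length is the 3'LTR end.  If ``length`` is given it must
    match.  Raises :class:`LayoutError` on any violation.
    """
    if set(layout) != set(REGION_NAMES):
        raise LayoutError(
            f"layout must name exactly {set(REGION_NAMES)}, got {set(layout)}"
        )
    for name, (start, end) in layout.items():
        if start < 1 or end < start:
            raise LayoutError(f"region {name}: bad interval [{start}, {end}]")
    if layout["5'LTR"][0] != 1:
        raise LayoutError("5'LTR must start at position 1")
    total = layout["3'LTR"][1]
    if length is not None and total != length:
        raise LayoutError(
            f"3'LTR ends at {total} but declared sequence length is {length}"
        )
    for name, (start, end) in layout.items():
        if end > total:
            raise LayoutError(f"region {name} extends past consensus end {total}")
    if layout["5'LTR"][1] >= layout["3'LTR"][0]:
        raise LayoutError("5'LTR and 3'LTR overlap")
    return total


@dataclass(frozen=True)
class ProviralReference:
    """Consensus sequence plus its six-region coordinate layout."""

    name: str
    sequence: str
    layout: dict[str, tuple[int, int]] = field(default_factory=lambda: dict(DEFAULT_LAYOUT))

    def __post_init__(self) -> None:
        validate_layout(self.layout, length=len(self.sequence))

    def __len__(self) -> int:
        return len(self.sequence)

    def region_interval(self, region: str) -> tuple[int, int]:
        return self.layout[region]

    def region_length(self, region: str) -> int:
        start, end = self.layout[region]
        return end - start + 1

    def region_sequence(self, region: str) -> str:
        start, end = self.layout[region]
        return self.sequence[start - 1 : end]


def load_layout(path) -> dict[str, tuple[int, int]]:
    """Read a region layout from a 3-column TSV (region, start, end)."""
    layout: dict[str, tuple[int, int]] = {}
    with open(path, newline="") as handle:
        for row in csv.reader(handle, delimiter="\t"):
            if not row or row[0].startswith("#") or row[0] == "region":
                continue
            layout[row[0]] = (int(row[1]), int(row[2]))
    validate_layout(layout)
    return layout


def write_layout(layout: dict[str, tuple[int, int]], path) -> None:
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t")
        writer.writerow(["region", "start", "end"])
        for name in REGION_NAMES:
            start, end = layout[name]
            writer.writerow([name, start, end])
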