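"""IMGT region definitions for immunoglobulin variable domains.

The IMGT unique numbering assigns positions 1-128 to a V domain; the
hypervariable loops (CDR1/2/3) and framework regions (FR1-4) occupy fixed
position ranges.  CDR3 runs 105-117, with insertion codes at positions
111/112 for loops longer than 13 residues and gaps in the middle of the
range for shorter loops.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from string import ascii_uppercase

REGIONS = ("FR1", "CDR1", "FR2", "CDR2", "FR3", "CDR3", "FR4")

_DEFAULT_BOUNDS = {
    "FR1": (1, 26),
    "CDR1": (27, 38),
    "FR2": (39, 55),
    "CDR2": (56, 65),
    "FR3": (66, 104),
    "CDR3": (105, 117),
    "FR4": (118, 128),
}


@dataclass(frozen=True)
class RegionSpec:
    """One region of the IMGT partition, with an inclusive position range."""

    region: str
    start_imgt: int
    end_imgt: int

    def __contains__(self, imgt_position: int) -> bool:
        return self.start_imgt <= imgt_position <= self.end_imgt


def default_region_spec() -> dict[str, RegionSpec]:
    """The standard IMGT partition of positions 1-128 into FR/CDR regions."""
    return {name: RegionSpec(name, lo, hi) for name, (lo, hi) in _DEFAULT_BOUNDS.items()}


def region_of(imgt_position: int, spec: dict[str, RegionSpec] | None = None) -> str:
    """Region name containing ``imgt_position``; raises for positions outside 1-128."""
    spec = spec or default_region_spec()
    for rs in spec.values():
        if imgt_position in rs:
            return rs.region
    raise ValueError(f"IMGT position {imgt_position} is outside the region partition")


def imgt_cdr3_positions(length: int) -> list[tuple[int, str]]:
    """IMGT position/insertion-code pairs for a CDR3 of ``length`` residues.

    Shorter loops leave gaps in the middle of 105-117; longer loops insert at
    111 (ascending letters) then 112 (descending letters), so the returned
    list is in loop order and non-decreasing in position number.
    """
    if length < 0:
        raise ValueError("CDR3 length must be non-negative")
    canonical = list(range(105, 118))
    if length <= 13:
        head = canonical[: math.ceil(length / 2)]
        tail = canonical[13 - length // 2:]
        return [(p, "") for p in head + tail]
    extra = length - 13
    n111 = math.ceil(extra / 2)
    n112 = extra // 2
    if max(n111, n112) > len(ascii_uppercase):
        raise ValueError(f"CDR3 length {length} exceeds supported insertion range")
    out: list[tuple[int, str]] = [(p, "") for p in range(105, 112)]
    out += [(111, ascii_uppercase[i]) for i in range(n111)]
    out += [(112, ascii_uppercase[i]) for i in reversed(range(n112))]
    out += [(p, "") for p in range(112, 118)]
    return out
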