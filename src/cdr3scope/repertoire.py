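"""Annotated VHH repertoires: ingestion, region slicing, and filtering.

A repertoire here is a set of unique amino-acid sequences with per-position
IMGT numbering, a read count, a species tag, and an optional germline label.
Numbering and germline assignment are consumed as input (produced upstream
by ANARCI-style tools); this module only validates and analyses them.

The standard cleaning procedure applied before any correlation analysis is
a three-stage filter, in this order:

1. drop sequences observed fewer than ``min_count`` times (PCR/sequencing
   error suppression);
2. deduplicate at the amino-acid level, keeping the highest-count
   representative and recording the summed count;
3. drop CDR3-length outliers with absolute z-score >= ``z_max``, where the
   mean and (sample) standard deviation are taken over the surviving set.
"""

from __future__ import annotations

import csv
import json
import logging
import math
import statistics
from dataclasses import dataclass, field
from pathlib import Path

from .regions import RegionSpec, default_region_spec

logger = logging.getLogger(__name__)

SPECIES = ("alpaca", "llama", "bactrian", "human", "other")

Numbering = tuple[tuple[int, str, str], ...]


class RepertoireFormatError(ValueError):
    """Raised when a repertoire table is structurally invalid."""


@dataclass(frozen=True)
class AnnotatedVHH:
    """One unique VHH (or VH) amino-acid sequence with IMGT annotation.

    ``numbering`` is an ordered tuple of (imgt_position, insertion_code,
    residue); concatenating its residues must reproduce ``sequence``.
    """

    id: str
    species: str
    sequence: str
    numbering: Numbering
    count: int
    germline: str = ""

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError(f"{self.id}: read count must be >= 1, got {self.count}")
        if "".join(res for _, _, res in self.numbering) != self.sequence:
            raise ValueError(f"{self.id}: numbering residues do not concatenate to sequence")
        positions = [p for p, _, _ in self.numbering]
        if any(b < a for a, b in zip(positions, positions[1:])):
            raise ValueError(f"{self.id}: IMGT positions must be non-decreasing")
        if self.species not in SPECIES:
            raise ValueError(f"{self.id}: unknown species {self.species!r}")


@dataclass(frozen=True)
class FilterStep:
    name: str
    parameter: object
    n_before: int
    n_after: int


@dataclass
class Repertoire:
    """A collection of annotated sequences plus the provenance of applied filters."""

    members: list[AnnotatedVHH]
    filters_applied: list[FilterStep] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.members)

    def cdr3_lengths(self, spec: dict[str, RegionSpec] | None = None) -> list[int]:
        return [cdr3_length(m, spec) for m in self.members]


def _parse_numbering(encoded: str) -> Numbering:
    """Decode 'pos:icode:res' triplets joined by commas, e.g. '105::G,111:A:S'."""
    out = []
    for token in encoded.split(","):
        parts = token.split(":")
        if len(parts) != 3:
            raise ValueError(f"malformed numbering token {token!r}")
        pos, icode, res = parts
        out.append((int(pos), icode, res))
    return tuple(out)


def encode_numbering(numbering: Numbering) -> str:
    return ",".join(f"{p}:{ic}:{res}" for p, ic, res in numbering)


REQUIRED_COLUMNS = ("id", "sequence", "numbering", "count")


def parse_repertoire(path: str | Path, species: str) -> Repertoire:
    """Read a tab-separated repertoire table into an unfiltered Repertoire.

    Malformed rows are collected and reported together in a
    :class:`RepertoireFormatError`; nothing is silently dropped.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        missing = [c for c in REQUIRED_COLUMNS if c not in header]
        if missing:
            raise RepertoireFormatError(f"{path}: missing required column(s) {missing}")
        members: list[AnnotatedVHH] = []
        row_errors: list[str] = []
        seen_ids: dict[str, int] = {}
        for row in reader:
            rid = row["id"]
            seen_ids[rid] = seen_ids.get(rid, 0) + 1
            try:
                members.append(
                    AnnotatedVHH(
                        id=rid,
                        species=species,
                        sequence=row["sequence"],
                        numbering=_parse_numbering(row["numbering"]),
                        count=int(row["count"]),
                        germline=row.get("germline", "") or "",
                    )
                )
            except (ValueError, KeyError) as exc:
                row_errors.append(f"row {rid!r}: {exc}")
    duplicates = sorted(rid for rid, n in seen_ids.items() if n > 1)
    if duplicates:
        raise RepertoireFormatError(f"{path}: duplicated ids {duplicates}")
    if row_errors:
        raise RepertoireFormatError(f"{path}: {len(row_errors)} malformed row(s): " + "; ".join(row_errors))
    return Repertoire(members=members)


def write_repertoire(rep: Repertoire, path: str | Path) -> None:
    """Write the repertoire back out in the same tab-separated dialect."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["id", "sequence", "numbering", "count", "germline"])
        for m in rep.members:
            writer.writerow([m.id, m.sequence, encode_numbering(m.numbering), m.count, m.germline])


def write_filter_log(rep: Repertoire, path: str | Path) -> None:
    """Filter provenance as JSON lines, one record per applied step."""
    with Path(path).open("w") as fh:
        for step in rep.filters_applied:
            fh.write(json.dumps({
                "filter": step.name,
                "parameter": step.parameter,
                "n_before": step.n_before,
                "n_after": step.n_after,
            }) + "\n")


def region_slice(
    v: AnnotatedVHH,
    spec: dict[str, RegionSpec] | None = None,
    region: str = "CDR3",
) -> str:
    """Residues of ``v`` whose IMGT position falls in ``region`` (inclusive).

    Insertion-coded positions inherit the region of their anchor position.
    Returns "" when no position falls in range.
    """
    spec = spec or default_region_spec()
    if region not in spec:
        raise ValueError(f"unknown region {region!r}; expected one of {sorted(spec)}")
    rs = spec[region]
    return "".join(res for pos, _, res in v.numbering if pos in rs)


def cdr3_length(v: AnnotatedVHH, spec: dict[str, RegionSpec] | None = None) -> int:
    return len(region_slice(v, spec, "CDR3"))


def filter_repertoire(r: Repertoire, min_count: int = 5, z_max: float = 2.5) -> Repertoire:
    """Apply the three-stage cleaning filter (count >= min_count, dedup, |z| < z_max).

    An empty survivor set at any stage yields an empty result with a logged
    warning rather than an exception.  Dedup keeps the highest-count
    representative; summed counts per surviving id are recorded under
    ``metadata['dedup_total_counts']``.
    """
    steps: list[FilterStep] = []
    members = list(r.members)

    n0 = len(members)
    members = [m for m in members if m.count >= min_count]
    steps.append(FilterStep("min_count", min_count, n0, len(members)))

    n1 = len(members)
    by_seq: dict[str, list[AnnotatedVHH]] = {}
    for m in members:
        by_seq.setdefault(m.sequence, []).append(m)
    survivors: list[AnnotatedVHH] = []
    total_counts: dict[str, int] = {}
    for group in by_seq.values():
        best = max(group, key=lambda m: m.count)
        survivors.append(best)
        total_counts[best.id] = sum(m.count for m in group)
    survivors.sort(key=lambda m: m.id)
    steps.append(FilterStep("dedup_amino_acid", None, n1, len(survivors)))

    n2 = len(survivors)
    if n2 >= 2:
        lengths = [cdr3_length(m) for m in survivors]
        mu = statistics.fmean(lengths)
        sd = statistics.stdev(lengths)
        if sd > 0:
            survivors = [
                m for m, L in zip(survivors, lengths) if abs((L - mu) / sd) < z_max
            ]
    steps.append(FilterStep("cdr3_length_zscore", z_max, n2, len(survivors)))

    if not survivors:
        logger.warning("filter_repertoire: no sequences survive the filter chain")
    return Repertoire(
        members=survivors,
        filters_applied=list(r.filters_applied) + steps,
        metadata={**r.metadata, "dedup_total_counts": total_counts},
    )


def length_summary(r: Repertoire) -> dict:
    """Count / mean / standard error / median / sample std of CDR3 lengths.

    With a single member the standard error and std are undefined and
    reported as NaN.
    """
    if not r.members:
        raise ValueError("length_summary requires a nonempty repertoire")
    lengths = r.cdr3_lengths()
    n = len(lengths)
    mean = statistics.fmean(lengths)
    median = statistics.median(lengths)
    if n > 1:
        std = statistics.stdev(lengths)
        se = std / math.sqrt(n)
    else:
        std = math.nan
        se = math.nan
    return {"count": n, "mean": mean, "se": se, "median": median, "std": std}
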