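"""Amino-acid usage versus CDR3 length, per region and per IMGT position.

Regional usage correlates each residue's per-sequence frequency within a
region against CDR3 length.  Positional usage correlates, for every
(position, residue) cell, the presence/absence indicator at that position
against CDR3 length across the sequences occupying the position; since a
position carries exactly one residue per sequence, the indicator encoding is
equivalent to frequency-vs-length.  Both screens are BH-FDR corrected over
their whole family of tests.
"""

from __future__ import annotations

import itertools
import logging
import math

import numpy as np
import pandas as pd

from .regions import RegionSpec, default_region_spec
from .repertoire import Repertoire, cdr3_length, region_slice
from .seqfeatures import KYTE_DOOLITTLE
from .stats import bh_fdr, mann_whitney_u, pearson_with_test, stars

logger = logging.getLogger(__name__)

AMINO_ACIDS = tuple(sorted(KYTE_DOOLITTLE))


def _finalize(report: pd.DataFrame, fdr_level: float) -> pd.DataFrame:
    report["p_adj"] = math.nan
    tested = report["p_raw"].notna()
    if tested.any():
        report.loc[tested, "p_adj"] = bh_fdr(report.loc[tested, "p_raw"].to_numpy())
    report["stars"] = [stars(p) if np.isfinite(p) else "na" for p in report["p_adj"]]
    report["significant"] = report["p_adj"] < fdr_level
    return report


def regional_usage_vs_length(
    r: Repertoire,
    region: str,
    spec: dict[str, RegionSpec] | None = None,
    fdr_level: float = 0.05,
) -> pd.DataFrame:
    """Pearson correlation of per-sequence residue frequency in ``region``
    with CDR3 length, one row per residue, BH-corrected over residues."""
    spec = spec or default_region_spec()
    lengths: list[int] = []
    slices: list[str] = []
    for m in r.members:
        s = region_slice(m, spec, region)
        if s:
            slices.append(s)
            lengths.append(cdr3_length(m, spec))
    if not slices:
        logger.warning("regional_usage_vs_length: region %s absent in all members", region)
        return pd.DataFrame(
            columns=["region", "residue", "n", "r", "p_raw", "p_adj", "stars", "significant"]
        )
    if len(set(lengths)) < 3:
        raise ValueError("need >= 3 distinct CDR3 lengths for a correlation screen")
    L = np.asarray(lengths, dtype=float)
    rows = []
    for aa in AMINO_ACIDS:
        freq = np.array([s.count(aa) / len(s) for s in slices])
        try:
            rr, p, n = pearson_with_test(L, freq)
        except ValueError:
            rr, p, n = math.nan, math.nan, len(L)
        rows.append({"region": region, "residue": aa, "n": n, "r": rr, "p_raw": p})
    return _finalize(pd.DataFrame(rows), fdr_level)


def positional_usage_vs_length(
    r: Repertoire,
    region: str,
    spec: dict[str, RegionSpec] | None = None,
    min_n: int = 100,
    fdr_level: float = 0.05,
    shuffle_lengths: np.random.Generator | None = None,
) -> pd.DataFrame:
    """(position, residue) indicator vs CDR3 length across sequences occupying
    the position; BH-FDR applied over the whole matrix of tested cells.

    Positions occupied by fewer than ``min_n`` sequences are masked, as are
    cells with zero variance (position monomorphic, or residue carried by
    all occupants).  Residues never observed at a position are simply absent
    from the report.  ``shuffle_lengths`` permutes the CDR3 lengths relative
    to the sequences before correlating — the permutation null used for
    calibration checks.
    """
    spec = spec or default_region_spec()
    if region not in spec:
        raise ValueError(f"unknown region {region!r}")
    rs = spec[region]

    lengths = np.array([cdr3_length(m, spec) for m in r.members], dtype=float)
    if shuffle_lengths is not None:
        lengths = shuffle_lengths.permutation(lengths)
    if np.unique(lengths).size < 3:
        raise ValueError("need >= 3 distinct CDR3 lengths for a correlation screen")

    occupants: dict[tuple[int, str], list[tuple[int, str]]] = {}
    for idx, m in enumerate(r.members):
        for pos, icode, res in m.numbering:
            if pos in rs:
                occupants.setdefault((pos, icode), []).append((idx, res))

    rows = []
    for (pos, icode), entries in sorted(occupants.items()):
        if len(entries) < min_n:
            continue
        idxs = np.array([i for i, _ in entries])
        residues = np.array([res for _, res in entries])
        pos_lengths = lengths[idxs]
        for aa in np.unique(residues):
            indicator = (residues == aa).astype(float)
            try:
                rr, p, n = pearson_with_test(pos_lengths, indicator)
            except ValueError:
                rr, p, n = math.nan, math.nan, len(entries)
            rows.append({
                "region": region, "position": pos, "insertion": icode,
                "residue": aa, "n": n, "r": rr, "p_raw": p,
            })
    report = pd.DataFrame(
        rows,
        columns=["region", "position", "insertion", "residue", "n", "r", "p_raw"],
    )
    return _finalize(report, fdr_level)


def germline_length_preference(
    r: Repertoire,
    spec: dict[str, RegionSpec] | None = None,
    fdr_level: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-germline CDR3 length summary plus pairwise two-tailed
    Mann-Whitney tests with BH correction.

    Germlines with a single sequence are summarized but excluded from
    testing (logged).  Raises if no germline labels are present.
    """
    spec = spec or default_region_spec()
    by_germline: dict[str, list[int]] = {}
    for m in r.members:
        if m.germline:
            by_germline.setdefault(m.germline, []).append(cdr3_length(m, spec))
    if len(by_germline) < 2:
        raise ValueError("germline_length_preference requires labels for >= 2 germlines")

    summary = pd.DataFrame([
        {
            "germline": g,
            "n": len(v),
            "mean_cdr3_length": float(np.mean(v)),
            "std_cdr3_length": float(np.std(v, ddof=1)) if len(v) > 1 else math.nan,
        }
        for g, v in sorted(by_germline.items())
    ])

    testable = {g: v for g, v in by_germline.items() if len(v) > 1}
    skipped = sorted(set(by_germline) - set(testable))
    if skipped:
        logger.warning("germlines excluded from testing (n=1): %s", skipped)
    rows = []
    for g1, g2 in itertools.combinations(sorted(testable), 2):
        u, p = mann_whitney_u(testable[g1], testable[g2])
        rows.append({"germline_a": g1, "germline_b": g2, "U": u, "p_raw": p})
    pairwise = pd.DataFrame(rows, columns=["germline_a", "germline_b", "U", "p_raw"])
    pairwise = _finalize(pairwise, fdr_level)
    return summary, pairwise
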