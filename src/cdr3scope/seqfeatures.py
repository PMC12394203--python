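"""Per-region biophysical sequence features for VHH domains.

Net charge at pH 7.4 is a simple counting model: D and E contribute -1,
R and K contribute +1, and H contributes +0.1 (its partial protonation at
physiological pH); all other residues are neutral.  Hydropathy uses the
Kyte-Doolittle index, averaged over the region.  Residue classes follow the
standard seven-way biochemical grouping (aliphatic, aromatic,
sulfur-containing, hydroxyl, basic, acidic, amine).
"""

from __future__ import annotations

import logging

import pandas as pd

from .regions import REGIONS, RegionSpec, default_region_spec
from .repertoire import Repertoire, cdr3_length, region_slice

logger = logging.getLogger(__name__)

#: Residue charges at pH 7.4; every unlisted standard residue is neutral.
CHARGE_SCALE: dict[str, float] = {"D": -1.0, "E": -1.0, "R": 1.0, "K": 1.0, "H": 0.1}

#: Kyte-Doolittle hydropathy index for the 20 standard residues.
KYTE_DOOLITTLE: dict[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

STANDARD_AA = frozenset(KYTE_DOOLITTLE)

AA_CLASS_NAMES = ("aliphatic", "aromatic", "sulfur-containing", "hydroxyl", "basic", "acidic", "amine")

#: Default seven-class residue grouping.  Y is counted aromatic (not
#: hydroxyl) and G/P aliphatic; pass an alternative mapping to override.
DEFAULT_AA_CLASSES: dict[str, str] = {
    **{aa: "aliphatic" for aa in "AVLIGP"},
    **{aa: "aromatic" for aa in "FWY"},
    **{aa: "sulfur-containing" for aa in "CM"},
    **{aa: "hydroxyl" for aa in "ST"},
    **{aa: "basic" for aa in "KRH"},
    **{aa: "acidic" for aa in "DE"},
    **{aa: "amine" for aa in "NQ"},
}


def _check_sequence(seq: str, allow_x: bool = True) -> None:
    bad = {c for c in seq if c not in STANDARD_AA and not (allow_x and c == "X")}
    if bad:
        raise ValueError(f"non-amino-acid character(s) {sorted(bad)} in sequence")


def net_charge(seq: str, scale: dict[str, float] | None = None) -> float:
    """Sum of per-residue charges; X contributes 0 (with a warning)."""
    scale = scale if scale is not None else CHARGE_SCALE
    _check_sequence(seq)
    if "X" in seq:
        logger.warning("net_charge: sequence contains X; treated as uncharged")
    return float(sum(scale.get(c, 0.0) for c in seq))


def mean_hydropathy(seq: str, scale: dict[str, float] | None = None) -> float:
    """Arithmetic mean Kyte-Doolittle index; NaN for an empty sequence."""
    scale = scale if scale is not None else KYTE_DOOLITTLE
    _check_sequence(seq)
    known = [c for c in seq if c in scale]
    if len(known) < len(seq):
        logger.warning("mean_hydropathy: residues without a scale entry are ignored")
    if not known:
        return float("nan")
    return sum(scale[c] for c in known) / len(known)


def classify_residues(seq: str, scheme: dict[str, str] | None = None) -> dict[str, float]:
    """Fraction of residues per seven-way class; all-NaN for an empty input."""
    scheme = scheme if scheme is not None else DEFAULT_AA_CLASSES
    _check_sequence(seq, allow_x=False)
    if not seq:
        return {name: float("nan") for name in AA_CLASS_NAMES}
    counts = {name: 0 for name in AA_CLASS_NAMES}
    for c in seq:
        counts[scheme[c]] += 1
    return {name: counts[name] / len(seq) for name in AA_CLASS_NAMES}


#: Column blocks emitted by region_feature_table, in order: the seven IMGT
#: regions, the pooled CDR concatenation, and the full domain.
FEATURE_BLOCKS = REGIONS + ("CDR", "VHH")


def region_feature_table(r: Repertoire, spec: dict[str, RegionSpec] | None = None) -> pd.DataFrame:
    """One row per member: CDR3 length plus net charge and mean hydropathy
    for each region, the pooled CDRs, and the full VHH."""
    spec = spec or default_region_spec()
    rows = []
    for m in r.members:
        parts = {reg: region_slice(m, spec, reg) for reg in REGIONS}
        parts["CDR"] = parts["CDR1"] + parts["CDR2"] + parts["CDR3"]
        parts["VHH"] = m.sequence
        row: dict[str, object] = {
            "id": m.id,
            "species": m.species,
            "germline": m.germline,
            "cdr3_length": cdr3_length(m, spec),
        }
        for block in FEATURE_BLOCKS:
            row[f"{block}_charge"] = net_charge(parts[block])
            row[f"{block}_hydropathy"] = mean_hydropathy(parts[block])
        rows.append(row)
    columns = ["id", "species", "germline", "cdr3_length"] + [
        f"{block}_{feat}" for block in FEATURE_BLOCKS for feat in ("charge", "hydropathy")
    ]
    return pd.DataFrame(rows, columns=columns)
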