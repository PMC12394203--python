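"""Structural features: contacts, CDR3 geometry, conformation classes, SASA.

The geometric core of the analysis:

* residue contacts — two residues are in contact when any atom pair lies
  within a distance threshold (default 4 Å), evaluated with a KD-tree;
* ``FR2_CDR3_Dis`` — the minimum distance between the heavy-atom centroid
  of the residue at IMGT position 42 (in FR2) and the centroids of CDR3
  residues after trimming the first and last two; small values indicate a
  CDR3 loop bent down toward the framework;
* conformation classification — a Gaussian KDE over FR2_CDR3_Dis values is
  bimodal for mixed datasets; the density trough between the two main peaks
  separates bent (below) from extended (at/above) loops;
* solvent-accessible surface area — Shrake-Rupley point sampling on a
  deterministic spherical point set, from which buried surface areas and
  the SASA-weighted surface hydrophobicity score are derived.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import argrelextrema
from scipy.spatial import cKDTree
from scipy.stats import gaussian_kde

from .seqfeatures import AA_CLASS_NAMES, KYTE_DOOLITTLE, classify_residues
from .structure_io import AtomRecord, ComplexModel, ResidueKey, SS_CODES, StructureModel, coords

logger = logging.getLogger(__name__)

SEGMENTS = ("FR1", "CDR1", "FR2", "CDR2", "FR3", "FR4")

#: Van der Waals radii (Å) per element for SASA; configurable per call.
VDW_RADII: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "SE": 1.90, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
}


@dataclass(frozen=True)
class ContactRecord:
    residue_a: ResidueKey
    residue_b: ResidueKey
    min_distance: float


def contact_residues(
    m: ComplexModel,
    threshold: float = 4.0,
    mode: str = "vhh_antigen",
    exclude_adjacent: int = 1,
) -> list[ContactRecord]:
    """Residue pairs with any atom pair within ``threshold`` Å.

    ``vhh_antigen`` pairs VHH residues against antigen residues;
    ``intra_vhh`` pairs VHH residues with each other, excluding pairs within
    ``exclude_adjacent`` positions in chain order (trivial backbone
    neighbours).  Each record carries the minimal interatomic distance.
    """
    if mode == "vhh_antigen":
        set_a = m.vhh_atoms()
        set_b = m.antigen_atoms()
        allowed = None
    elif mode == "intra_vhh":
        set_a = set_b = m.vhh_atoms()
        order = {k: i for i, k in enumerate(m.vhh_residues())}
        allowed = lambda ka, kb: abs(order[ka] - order[kb]) > exclude_adjacent
    else:
        raise ValueError(f"unknown contact mode {mode!r}")
    if not set_a or not set_b:
        return []

    tree_b = cKDTree(coords(set_b))
    pairs = cKDTree(coords(set_a)).query_ball_tree(tree_b, r=threshold)
    best: dict[tuple[ResidueKey, ResidueKey], float] = {}
    for ia, hits in enumerate(pairs):
        a = set_a[ia]
        for ib in hits:
            b = set_b[ib]
            ka, kb = a.key, b.key
            if ka == kb:
                continue
            if mode == "intra_vhh":
                if not allowed(ka, kb):
                    continue
                if order[ka] > order[kb]:  # one record per unordered pair, chain order
                    continue
            d = math.dist(a.xyz, b.xyz)
            pair = (ka, kb)
            if d < best.get(pair, math.inf):
                best[pair] = d
    return [ContactRecord(ka, kb, d) for (ka, kb), d in sorted(best.items())]


def segment_interaction_profile(
    m: ComplexModel,
    threshold: float = 4.0,
    contacts: list[ContactRecord] | None = None,
) -> dict[str, int]:
    """Counts of intra-VHH residue-pair contacts between CDR3 and each other
    segment, plus CDR3-internal pairs (counted once each)."""
    if contacts is None:
        contacts = contact_residues(m, threshold, mode="intra_vhh")
    profile = {seg: 0 for seg in SEGMENTS}
    profile["CDR3_internal"] = 0
    for c in contacts:
        ra, rb = m.region[c.residue_a], m.region[c.residue_b]
        if ra == "CDR3" and rb == "CDR3":
            profile["CDR3_internal"] += 1
        elif ra == "CDR3":
            profile[rb] += 1
        elif rb == "CDR3":
            profile[ra] += 1
    return profile


def residue_centroid(m: ComplexModel, key: ResidueKey) -> np.ndarray:
    """Unweighted mean of heavy-atom coordinates (hydrogens excluded)."""
    heavy = [a for a in m.atoms_of(key) if a.element.upper() != "H"]
    if not heavy:
        raise ValueError(f"residue {key} has no heavy atoms")
    return coords(heavy).mean(axis=0)


def fr2_cdr3_dis(m: ComplexModel) -> float:
    """Minimum centroid distance between IMGT position 42 and trimmed CDR3.

    The first and last two CDR3 residues (in loop order) are excluded; a
    CDR3 shorter than 5 residues leaves nothing to measure and yields NaN.
    Raises if position 42 is absent.
    """
    anchors = [k for k in m.vhh_residues() if k[1] == 42]
    if not anchors:
        raise ValueError(f"{m.name or 'model'}: IMGT position 42 absent")
    anchor = residue_centroid(m, anchors[0])
    cdr3 = m.cdr3_residues()
    trimmed = cdr3[2:-2]
    if len(cdr3) < 5 or not trimmed:
        logger.warning("%s: CDR3 too short to trim; FR2_CDR3_Dis undefined", m.name)
        return math.nan
    return min(float(np.linalg.norm(residue_centroid(m, k) - anchor)) for k in trimmed)


@dataclass
class ConformationResult:
    threshold: float | None
    labels: list[str]
    bimodal: bool
    grid: np.ndarray = field(repr=False, default=None)
    density: np.ndarray = field(repr=False, default=None)


def classify_conformation(
    values,
    grid_points: int = 512,
    bandwidth: str | float = "scott",
    unimodal_cut: float = 10.0,
    max_trough_ratio: float = 0.8,
) -> ConformationResult:
    """Split FR2_CDR3_Dis values into bent / extended at the KDE trough.

    A Gaussian KDE (Scott's rule by default) is evaluated on a grid spanning
    the data; the threshold is the density minimum between the two highest
    local maxima.  Values below the threshold are bent, at or above it
    extended.  The two peaks count as distinct only when the trough dips
    below ``max_trough_ratio`` of the smaller peak; otherwise — and for a
    plainly unimodal density — no threshold exists: all values get a single
    fallback class (bent if the main peak is below ``unimodal_cut`` Å, a
    nominal midpoint between typical bent and extended loop geometries,
    else extended) and a warning is issued.
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size < 20:
        raise ValueError(f"classify_conformation requires >= 20 values, got {values.size}")
    kde = gaussian_kde(values, bw_method=bandwidth)
    grid = np.linspace(values.min(), values.max(), grid_points)
    density = kde(grid)

    maxima = argrelextrema(density, np.greater)[0]
    if density[0] > density[1]:
        maxima = np.append(0, maxima)
    if density[-1] > density[-2]:
        maxima = np.append(maxima, grid_points - 1)

    threshold = None
    if maxima.size >= 2:
        top_two = maxima[np.argsort(density[maxima])[-2:]]
        lo, hi = int(top_two.min()), int(top_two.max())
        trough_idx = lo + int(np.argmin(density[lo:hi + 1]))
        if density[trough_idx] <= max_trough_ratio * min(density[lo], density[hi]):
            threshold = float(grid[trough_idx])

    if threshold is None:
        peak = grid[int(np.argmax(density))]
        label = "bent" if peak < unimodal_cut else "extended"
        warnings.warn("FR2_CDR3_Dis density is unimodal; no bent/extended threshold", stacklevel=2)
        return ConformationResult(None, [label] * values.size, False, grid, density)

    labels = ["bent" if v < threshold else "extended" for v in values]
    return ConformationResult(threshold, labels, True, grid, density)


# -- Shrake-Rupley SASA --------------------------------------------------

def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = math.pi * (1 + math.sqrt(5)) * i
    return np.column_stack([
        np.cos(theta) * np.sin(phi),
        np.sin(theta) * np.sin(phi),
        np.cos(phi),
    ])


def shrake_rupley_sasa(
    m: ComplexModel,
    probe: float = 1.4,
    n_points: int = 960,
    radii: dict[str, float] | None = None,
    atoms: list[AtomRecord] | None = None,
) -> dict[ResidueKey, float]:
    """Per-residue solvent-accessible surface area (Å²).

    Each atom's solvent sphere (van der Waals radius + probe) is sampled
    with a fixed point set; points inside any neighbouring sphere are
    occluded.  Deterministic given the point set.
    """
    radii = radii if radii is not None else VDW_RADII
    atoms = atoms if atoms is not None else m.atoms
    if not atoms:
        return {}
    try:
        r_atom = np.array([radii[a.element.upper()] for a in atoms])
    except KeyError as exc:
        bad = next(a for a in atoms if a.element.upper() not in radii)
        raise ValueError(f"unknown element {exc} for atom {bad.atom_name} at {bad.key}") from exc
    xyz = coords(atoms)
    r_solv = r_atom + probe
    unit = _sphere_points(n_points)

    tree = cKDTree(xyz)
    neighbour_lists = tree.query_ball_tree(tree, r=2 * r_solv.max())
    r2 = r_solv ** 2
    sasa: dict[ResidueKey, float] = {}
    for i, a in enumerate(atoms):
        nb = np.array([j for j in neighbour_lists[i] if j != i], dtype=int)
        if nb.size:
            dc = np.linalg.norm(xyz[nb] - xyz[i], axis=1)
            nb = nb[dc < r_solv[i] + r_solv[nb]]
        if nb.size:
            pts = xyz[i] + r_solv[i] * unit
            nbx = xyz[nb]
            d2 = (
                (pts * pts).sum(axis=1)[:, None]
                - 2.0 * pts @ nbx.T
                + (nbx * nbx).sum(axis=1)[None, :]
            )
            exposed = int((d2 > r2[nb][None, :]).all(axis=1).sum())
        else:
            exposed = n_points
        area = 4.0 * math.pi * r2[i] * exposed / n_points
        sasa[a.key] = sasa.get(a.key, 0.0) + area
    return sasa


def buried_surface_area(m: ComplexModel, probe: float = 1.4, n_points: int = 960) -> dict:
    """BSA bookkeeping: monomer SASAs minus complex SASA, total and per side (Å²)."""
    if not m.antigen_chains:
        raise ValueError("buried_surface_area requires antigen chains")
    sasa_complex = shrake_rupley_sasa(m, probe, n_points)
    sasa_vhh = shrake_rupley_sasa(m, probe, n_points, atoms=m.vhh_atoms())
    sasa_ag = shrake_rupley_sasa(m, probe, n_points, atoms=m.antigen_atoms())

    vhh_keys = set(m.vhh_residues())
    complex_vhh = sum(v for k, v in sasa_complex.items() if k in vhh_keys)
    complex_ag = sum(v for k, v in sasa_complex.items() if k not in vhh_keys)
    mono_vhh = sum(sasa_vhh.values())
    mono_ag = sum(sasa_ag.values())
    return {
        "interface_bsa": mono_vhh + mono_ag - (complex_vhh + complex_ag),
        "paratope_bsa": mono_vhh - complex_vhh,
        "epitope_bsa": mono_ag - complex_ag,
        "sasa_vhh_monomer": mono_vhh,
        "sasa_antigen_monomer": mono_ag,
        "sasa_complex": complex_vhh + complex_ag,
    }


def surface_hydrophobicity(
    m: StructureModel,
    scale: dict[str, float] | None = None,
    sasa: dict[ResidueKey, float] | None = None,
    probe: float = 1.4,
    n_points: int = 960,
) -> float:
    """Sum over residues of SASA × hydropathy index (VHH monomer)."""
    scale = scale if scale is not None else KYTE_DOOLITTLE
    if sasa is None:
        sasa = shrake_rupley_sasa(m, probe, n_points, atoms=m.vhh_atoms())
    return float(sum(area * scale[m.residue_letter[key]] for key, area in sasa.items()))


# -- interface summaries -------------------------------------------------

@dataclass
class InterfaceSummary:
    paratope: list[ResidueKey]
    epitope: list[ResidueKey]
    paratope_counts: dict[str, int]
    fr2_involved: bool
    paratope_classes: dict[str, float]
    epitope_classes: dict[str, float]
    rejected: bool
    bsa: dict | None = None


def interface_summary(
    m: ComplexModel,
    threshold: float = 4.0,
    min_epitope: int = 6,
    with_bsa: bool = False,
) -> InterfaceSummary:
    """Paratope/epitope sets at the contact threshold with per-segment
    bookkeeping and seven-class compositions.

    Complexes whose epitope carries fewer than ``min_epitope`` residues are
    flagged ``rejected`` (to be excluded from correlation input) but still
    summarized.
    """
    contacts = contact_residues(m, threshold, mode="vhh_antigen")
    paratope = sorted({c.residue_a for c in contacts})
    epitope = sorted({c.residue_b for c in contacts})
    counts = {seg: 0 for seg in (*SEGMENTS, "CDR3")}
    for key in paratope:
        counts[m.region[key]] += 1
    summary = InterfaceSummary(
        paratope=paratope,
        epitope=epitope,
        paratope_counts=counts,
        fr2_involved=counts["FR2"] > 0,
        paratope_classes=classify_residues(m.residue_sequence(paratope)) if paratope
        else {c: math.nan for c in AA_CLASS_NAMES},
        epitope_classes=classify_residues(m.residue_sequence(epitope)) if epitope
        else {c: math.nan for c in AA_CLASS_NAMES},
        rejected=len(epitope) < min_epitope,
    )
    if with_bsa:
        summary.bsa = buried_surface_area(m)
    return summary


def ss_usage(m: ComplexModel, region: str = "CDR3") -> dict[str, float] | None:
    """Fractions of DSSP codes (H,G,I,E,T,S,C) over the region's residues.

    Returns None (logged) when the model carries no secondary-structure
    labels — the analysis is simply unavailable for that structure.
    """
    if m.ss_labels is None:
        logger.warning("%s: no secondary-structure labels; ss_usage unavailable", m.name)
        return None
    keys = [k for k in m.region_residues(region) if k in m.ss_labels]
    if not keys:
        return {code: math.nan for code in SS_CODES}
    counts = {code: 0 for code in SS_CODES}
    for k in keys:
        code = m.ss_labels[k]
        if code not in counts:
            raise ValueError(f"unknown secondary-structure code {code!r} at {k}")
        counts[code] += 1
    return {code: counts[code] / len(keys) for code in SS_CODES}
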