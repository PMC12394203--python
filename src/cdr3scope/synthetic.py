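"""Synthetic repertoires and toy 3D structures with planted, recoverable effects.

The generators emulate the statistical structure the analysis pipeline
assumes, so every stage is testable without NGS or crystallographic data:

* repertoires — near-normal CDR3 length distributions (discretized,
  truncated at >= 5 residues, with the pre-truncation moments solved so the
  realized mean/std match the recipe); germline-linked length preference
  with hallmark position-specific residues (Y/F at IMGT 42 among them); a
  planted negative charge-vs-length slope realized through length-dependent
  acidic-residue placement in CDR3; C enrichment and position-105 N
  depletion in long CDR3s; read counts, amino-acid duplicates and length
  outliers injected at recipe rates;
* structures — a fixed pseudo-atom framework scaffold with labeled IMGT
  positions, a CDR3 hairpin that is either extended (projecting away from
  the position-42 anchor) or bent (curving down toward FR2/CDR2), longer
  loops biased toward bent; an antigen blob docked against the loop (plus
  an FR2-adjacent patch for extended structures only); DSSP-style
  secondary-structure labels emitted per conformation.

Each residue of a pseudo-structure carries one backbone-like centroid atom
and two side-chain pseudo-atoms — enough to exercise all-atom contact,
centroid, and SASA code without full-atom realism.  Every planted effect is
recorded in a ground-truth sidecar.  Outputs are bit-identical for
identical seeds.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import optimize
from scipy.stats import truncnorm

from .regions import imgt_cdr3_positions
from .repertoire import AnnotatedVHH, Repertoire
from .structure_io import AtomRecord, ComplexModel, write_dssp, write_pdb

# -- sequence templates ---------------------------------------------------

# Base VHH scaffold, one residue per occupied IMGT position per region.
FR1_POSITIONS = list(range(1, 27))
FR1_TEMPLATE = "QVQLVESGGGLVQAGGSLRLSCAASG"
CDR1_POSITIONS = [27, 28, 29, 30, 31, 32, 35, 36, 37, 38]
CDR1_TEMPLATE = "GRTFSSYAMG"
FR2_POSITIONS = list(range(39, 56))
FR2_TEMPLATE = "WFRQAPGKEREFVAAIS"
CDR2_POSITIONS = [56, 57, 58, 59, 62, 63, 64, 65]
CDR2_TEMPLATE = "ISSGGSTN"
FR3_POSITIONS = list(range(66, 105))
FR3_TEMPLATE = "YADSVKGRFTISRDNAKNTVYLQMNSLKPEDTAVYYCAA"
FR4_POSITIONS = list(range(118, 129))
FR4_TEMPLATE = "WGQGTQVTVSS"

SCAFFOLD = list(
    zip(
        FR1_POSITIONS + CDR1_POSITIONS + FR2_POSITIONS + CDR2_POSITIONS + FR3_POSITIONS,
        FR1_TEMPLATE + CDR1_TEMPLATE + FR2_TEMPLATE + CDR2_TEMPLATE + FR3_TEMPLATE,
    )
)

#: CDR3 background pool: neutral residues only, excluding the hallmark
#: letters (C, N) and all charged residues, so the planted acidic-residue
#: slope and C/N usage effects are not diluted by background noise.
CDR3_POOL = "GSTAYVWLPQF"
ALL_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class GermlineProfile:
    """A V-gene germline: sampling weight, CDR3-length shift (residues),
    and hallmark residue overrides keyed by IMGT position."""

    name: str
    weight: float
    length_shift: float
    overrides: dict[int, str] = field(default_factory=dict)


#: Default germline set: short-CDR3 germlines carry Y at IMGT 42 (and I in
#: CDR1), long-CDR3 germlines carry F at 42 (and Y in CDR1), reproducing the
#: germline-linked Y<->F switch and CDR1 composition drift.
DEFAULT_GERMLINES = (
    GermlineProfile("IGHV3S53*01", 0.35, -2.5, {37: "I", 42: "Y", 49: "Q", 52: "L"}),
    GermlineProfile("IGHV3S65*01", 0.25, +2.5, {35: "D", 36: "Y", 37: "Y", 42: "F", 49: "E", 52: "G"}),
    GermlineProfile("IGHV3S61*01", 0.20, +1.0, {42: "F", 49: "E", 62: "D"}),
    GermlineProfile("IGHV3S1*01", 0.20, 0.0, {}),
)


@dataclass
class RepertoireRecipe:
    n: int = 10_000
    species: str = "alpaca"
    length_mean: float = 15.7
    length_std: float = 4.6
    germlines: tuple[GermlineProfile, ...] = DEFAULT_GERMLINES
    charge_slope: float = -0.1          # d(CDR3 charge)/d(length)
    acid_baseline: float = 1.5          # mean acidic residues at the mean length
    cdr3_C_enrichment: float = 0.01     # d P(C per CDR3 residue) / d(length)
    cdr3_C_baseline: float = 0.05
    pos105_N_depletion: float = 0.04    # -d P(N at 105) / d(length)
    pos105_N_baseline: float = 0.5
    mutation_noise: float = 0.01        # per-position off-template substitution rate
    count_geometric_p: float = 0.12     # read counts ~ 1 + Geometric
    duplicate_rate: float = 0.05
    outlier_rate: float = 0.005
    min_length: int = 5
    seed: int = 0

    def validate(self) -> None:
        weights = [g.weight for g in self.germlines]
        if abs(sum(weights) - 1.0) > 1e-9:
            raise ValueError("germline weights must sum to 1")
        if self.length_std <= 0:
            raise ValueError("length_std must be positive")
        if self.length_mean < self.min_length:
            raise ValueError("length_mean below the minimum CDR3 length is infeasible")


def _truncnorm_base_params(target_mean: float, target_std: float, lower: float) -> tuple[float, float]:
    """Pre-truncation (mu, sigma) whose lower-truncated normal matches the targets."""

    def residual(params):
        mu, sigma = params
        sigma = abs(sigma)
        a = (lower - mu) / sigma
        m, v = truncnorm.stats(a, np.inf, loc=mu, scale=sigma, moments="mv")
        return [m - target_mean, math.sqrt(v) - target_std]

    mu, sigma = optimize.fsolve(residual, [target_mean, target_std], full_output=False)
    return float(mu), float(abs(sigma))


def _draw_cdr3(rng: np.random.Generator, length: int, recipe: RepertoireRecipe) -> str:
    """CDR3 residues with planted length-dependent acidic / C / N-at-105 usage."""
    Lref = recipe.length_mean
    p_C = float(np.clip(recipe.cdr3_C_baseline + recipe.cdr3_C_enrichment * (length - Lref), 0.0, 0.3))
    p_N105 = float(np.clip(recipe.pos105_N_baseline - recipe.pos105_N_depletion * (length - Lref), 0.02, 0.95))
    target_acid = max(0.0, recipe.acid_baseline - recipe.charge_slope * (length - Lref))

    residues = []
    for i in range(length):
        if i == 0 and rng.random() < p_N105:
            residues.append("N")
        elif rng.random() < p_C:
            residues.append("C")
        else:
            residues.append(CDR3_POOL[rng.integers(len(CDR3_POOL))])
    free = [i for i, r in enumerate(residues) if r not in ("N", "C")]
    if free:
        p_acid = min(0.9, target_acid / len(free))
        for i in free:
            if rng.random() < p_acid:
                residues[i] = "D" if rng.random() < 0.5 else "E"
    return "".join(residues)


def _assemble_member(
    rng: np.random.Generator,
    idx: int,
    length: int,
    germline: GermlineProfile,
    recipe: RepertoireRecipe,
) -> AnnotatedVHH:
    numbering = []
    for pos, res in SCAFFOLD:
        res = germline.overrides.get(pos, res)
        if pos not in germline.overrides and rng.random() < recipe.mutation_noise:
            res = ALL_AA[rng.integers(len(ALL_AA))]
        numbering.append((pos, "", res))
    cdr3 = _draw_cdr3(rng, length, recipe)
    for (pos, icode), res in zip(imgt_cdr3_positions(length), cdr3):
        numbering.append((pos, icode, res))
    for pos, res in zip(FR4_POSITIONS, FR4_TEMPLATE):
        numbering.append((pos, "", res))
    sequence = "".join(res for _, _, res in numbering)
    return AnnotatedVHH(
        id=f"seq{idx:06d}",
        species=recipe.species,
        sequence=sequence,
        numbering=tuple(numbering),
        count=1 + int(rng.geometric(recipe.count_geometric_p)),
        germline=germline.name,
    )


def generate_repertoire(recipe: RepertoireRecipe) -> tuple[Repertoire, dict]:
    """Deterministic synthetic repertoire plus a ground-truth sidecar.

    The sidecar records every planted effect size so downstream recovery
    tests can assert signs and magnitudes against it.
    """
    recipe.validate()
    rng = np.random.default_rng(recipe.seed)

    weights = np.array([g.weight for g in recipe.germlines])
    shifts = np.array([g.length_shift for g in recipe.germlines])
    mean_shift = float(weights @ shifts)
    var_shift = float(weights @ (shifts - mean_shift) ** 2)
    if var_shift >= recipe.length_std ** 2:
        raise ValueError("germline length shifts exceed the recipe length variance")

    # Solve the pre-truncation moments so that the rounded, >=min_length
    # marginal hits the recipe mean/std (rounding at x >= min_length - 0.5).
    mu0, sigma0 = _truncnorm_base_params(recipe.length_mean, recipe.length_std, recipe.min_length - 0.5)
    sigma_within = math.sqrt(max(sigma0 ** 2 - var_shift, 0.25))

    members: list[AnnotatedVHH] = []
    idx = 0
    for _ in range(recipe.n):
        g = recipe.germlines[rng.choice(len(recipe.germlines), p=weights)]
        if rng.random() < recipe.outlier_rate:
            length = int(round(recipe.length_mean + 4 * recipe.length_std + abs(rng.normal(0, 1))))
        else:
            loc = mu0 - mean_shift + g.length_shift
            a = (recipe.min_length - 0.5 - loc) / sigma_within
            length = int(round(truncnorm.rvs(a, np.inf, loc=loc, scale=sigma_within, random_state=rng)))
        members.append(_assemble_member(rng, idx, length, g, recipe))
        idx += 1

    n_dup = int(rng.binomial(recipe.n, recipe.duplicate_rate))
    for _ in range(n_dup):
        src = members[rng.integers(len(members))]
        members.append(AnnotatedVHH(
            id=f"seq{idx:06d}",
            species=src.species,
            sequence=src.sequence,
            numbering=src.numbering,
            count=1 + int(rng.geometric(recipe.count_geometric_p)),
            germline=src.germline,
        ))
        idx += 1

    sidecar = {
        "seed": recipe.seed,
        "n_unique": recipe.n,
        "n_duplicates": n_dup,
        "length_mean": recipe.length_mean,
        "length_std": recipe.length_std,
        "charge_slope": recipe.charge_slope,
        "cdr3_C_enrichment": recipe.cdr3_C_enrichment,
        "pos105_N_depletion": recipe.pos105_N_depletion,
        "duplicate_rate": recipe.duplicate_rate,
        "outlier_rate": recipe.outlier_rate,
        "germlines": [
            {"name": g.name, "weight": g.weight, "length_shift": g.length_shift,
             "imgt42": g.overrides.get(42, dict(SCAFFOLD)[42])}
            for g in recipe.germlines
        ],
    }
    return Repertoire(members=members), sidecar


# -- toy structures -------------------------------------------------------

P42_ANCHOR = np.array([0.0, -7.0, -3.0])
CDR3_BASE_START = np.array([-2.2, 0.0, 0.0])
CDR3_BASE_END = np.array([2.2, 0.0, 0.0])
BENT_APEX = np.array([1.2, -5.6, -1.4])
CDR1_RING_CENTER = np.array([-5.0, -2.0, 2.5])
CDR2_RING_CENTER = np.array([4.5, -9.0, -2.5])

SS_FRAMEWORK = {"E": 0.60, "C": 0.20, "T": 0.10, "S": 0.05, "G": 0.03, "H": 0.02}
SS_CDR3_BENT = {"G": 0.12, "T": 0.18, "S": 0.25, "C": 0.38, "E": 0.05, "H": 0.01, "I": 0.01}
SS_CDR3_EXTENDED = {"E": 0.45, "T": 0.22, "C": 0.22, "S": 0.06, "G": 0.03, "H": 0.01, "I": 0.01}


@dataclass
class StructureRecipe:
    n: int = 200
    bent_fraction: float = 0.5
    length_mean: float = 14.0
    length_std: float = 4.0
    length_range: tuple[int, int] = (9, 24)
    conformation_length_slope: float = 0.07  # d P(bent) / d(length)
    backbone_jitter: float = 0.15            # Å, on backbone pseudo-atoms
    sidechain_length: float = 1.5            # Å, fixed side-chain offset norm
    antigen_offset: float = 3.5              # Å, antigen-to-loop docking distance
    vhh_chain: str = "A"
    antigen_chain: str = "B"
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.bent_fraction <= 1.0:
            raise ValueError("bent_fraction must lie in [0, 1]")
        if self.length_range[0] < 9:
            raise ValueError("structure CDR3 lengths below 9 cannot host a >= 6-residue epitope")


def _ring(center: np.ndarray, n: int, radius: float, plane: str) -> np.ndarray:
    theta = 2 * math.pi * np.arange(n) / n
    pts = np.tile(center, (n, 1))
    if plane == "xy":
        pts[:, 0] += radius * np.cos(theta)
        pts[:, 1] += radius * np.sin(theta)
    else:  # xz
        pts[:, 0] += radius * np.cos(theta)
        pts[:, 2] += radius * np.sin(theta)
    return pts


def _helix(center: np.ndarray, n: int, radius: float = 3.0, pitch: float = 1.0) -> np.ndarray:
    theta = 1.75 * np.arange(n)
    return np.column_stack([
        center[0] + radius * np.cos(theta),
        center[1] + radius * np.sin(theta),
        center[2] + pitch * np.arange(n) / 3.0,
    ])


def _framework_layout() -> dict[int, np.ndarray]:
    """Backbone coordinates for every occupied framework/CDR1/CDR2 position."""
    layout: dict[int, np.ndarray] = {}
    for pos, pt in zip(FR1_POSITIONS, _helix(np.array([-12.0, 5.0, -8.0]), len(FR1_POSITIONS))):
        layout[pos] = pt
    for pos, pt in zip(CDR1_POSITIONS, _ring(CDR1_RING_CENTER, len(CDR1_POSITIONS), 2.0, "xz")):
        layout[pos] = pt
    for i, pos in enumerate(FR2_POSITIONS):  # strand along x; position 42 at the anchor
        layout[pos] = P42_ANCHOR + np.array([(i - 3) * 1.6, 0.0, 0.0])
    for pos, pt in zip(CDR2_POSITIONS, _ring(CDR2_RING_CENTER, len(CDR2_POSITIONS), 2.0, "xy")):
        layout[pos] = pt
    for pos, pt in zip(FR3_POSITIONS, _helix(np.array([10.0, 4.0, -8.0]), len(FR3_POSITIONS))):
        layout[pos] = pt
    for i, pos in enumerate(FR4_POSITIONS):
        layout[pos] = np.array([-6.0 + i, 2.5, -2.0])
    return layout


_LAYOUT = _framework_layout()


def _bezier(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, t: np.ndarray) -> np.ndarray:
    t = t[:, None]
    return (1 - t) ** 2 * p0 + 2 * t * (1 - t) * p1 + t ** 2 * p2


_DIP_WINDOW = 0.22  # fraction of the loop (around the apex) pulled down toward FR2


def _cdr3_backbone(length: int, bent: bool) -> np.ndarray:
    """Hairpin backbone for the CDR3 loop.

    Extended loops arc away from the framework (+z), apex height growing
    with length.  Bent loops keep a low arc but pull the apex-adjacent
    residues down toward the position-42 anchor; the residue nearest the
    apex is snapped onto the dip target so the CDR3-FR2/CDR2 contacts are
    guaranteed, not merely probable.
    """
    t = np.linspace(0.0, 1.0, length)
    height = 5.0 if bent else 4.0 + 0.8 * length
    control = np.array([0.0, 0.0, 2 * height])
    arc = _bezier(CDR3_BASE_START, control, CDR3_BASE_END, t)
    if bent:
        w = np.where(
            np.abs(t - 0.5) < _DIP_WINDOW,
            np.cos((t - 0.5) / _DIP_WINDOW * math.pi / 2) ** 2,
            0.0,
        )
        w[int(np.argmin(np.abs(t - 0.5)))] = 1.0
        arc = (1 - w[:, None]) * arc + w[:, None] * BENT_APEX
    return arc


def _docking_band(length: int) -> np.ndarray:
    """Loop indices the antigen docks against: the outer half of the hairpin,
    clear of the bent dip window."""
    t = np.linspace(0.0, 1.0, length)
    return np.flatnonzero(np.abs(t - 0.5) >= 0.25)


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _emit_residue(
    atoms: list[AtomRecord],
    rng: np.random.Generator,
    chain: str,
    pos: int,
    icode: str,
    residue: str,
    backbone: np.ndarray,
    recipe: StructureRecipe,
) -> None:
    pt = backbone + rng.normal(0.0, recipe.backbone_jitter, 3)
    for name, element, offset in (
        ("CA", "C", np.zeros(3)),
        ("CB", "C", recipe.sidechain_length * _random_unit(rng)),
        ("CG", "O", recipe.sidechain_length * _random_unit(rng)),
    ):
        x, y, z = pt + offset
        atoms.append(AtomRecord(chain, pos, icode, residue, name, element, (x, y, z)))


def _sample_ss(rng: np.random.Generator, dist: dict[str, float]) -> str:
    codes = list(dist)
    return str(rng.choice(codes, p=np.array([dist[c] for c in codes])))


def generate_structures(recipe: StructureRecipe) -> tuple[list[ComplexModel], dict]:
    """Synthetic VHH-antigen complexes plus a ground-truth sidecar.

    Longer CDR3 loops are biased toward the bent conformation; bent loops
    guarantee CDR3-FR2 and CDR3-CDR2 contacts while extended loops project
    away from both.  The antigen blob always docks against the loop (the
    CDR3 paratope grows with loop length); for extended structures an extra
    antigen patch sits against FR2, for bent ones against CDR1, so FR2
    involvement tracks the conformation.
    """
    recipe.validate()
    rng = np.random.default_rng(recipe.seed)
    lo, hi = recipe.length_range

    models: list[ComplexModel] = []
    truth: list[dict] = []
    for i in range(recipe.n):
        length = int(np.clip(round(rng.normal(recipe.length_mean, recipe.length_std)), lo, hi))
        if recipe.bent_fraction in (0.0, 1.0):
            p_bent = recipe.bent_fraction
        else:
            p_bent = float(np.clip(
                recipe.bent_fraction + recipe.conformation_length_slope * (length - recipe.length_mean),
                0.02, 0.98,
            ))
        bent = bool(rng.random() < p_bent)

        atoms: list[AtomRecord] = []
        # framework + CDR1/CDR2 scaffold
        for pos, res in SCAFFOLD:
            _emit_residue(atoms, rng, recipe.vhh_chain, pos, "", res, _LAYOUT[pos], recipe)
        # CDR3 hairpin
        loop = _cdr3_backbone(length, bent)
        cdr3_positions = imgt_cdr3_positions(length)
        cdr3_seq = [CDR3_POOL[rng.integers(len(CDR3_POOL))] for _ in range(length)]
        for (pos, icode), res, pt in zip(cdr3_positions, cdr3_seq, loop):
            _emit_residue(atoms, rng, recipe.vhh_chain, pos, icode, res, pt, recipe)
        for pos, res in zip(FR4_POSITIONS, FR4_TEMPLATE):
            _emit_residue(atoms, rng, recipe.vhh_chain, pos, "", res, _LAYOUT[pos], recipe)

        # antigen: one residue docked (+y, the free face) against each loop
        # residue in the outer band, plus a conformation-specific patch
        # (FR2 for extended, CDR1 for bent)
        ag_points: list[np.ndarray] = []
        band = loop[_docking_band(length)]
        direction = np.array([0.0, 1.0, 0.0])
        for pt in band:
            ag_points.append(pt + recipe.antigen_offset * direction)
        if bent:
            ring = _ring(CDR1_RING_CENTER, len(CDR1_POSITIONS), 2.0, "xz")
            for pt in ring[:2]:  # pad the epitope against two CDR1 residues
                out = (pt - CDR1_RING_CENTER) / np.linalg.norm(pt - CDR1_RING_CENTER)
                ag_points.append(pt + recipe.antigen_offset * out)
            fr2_patch = 0
        else:
            for pos in (41, 42, 43):
                ag_points.append(_LAYOUT[pos] + np.array([0.0, -recipe.antigen_offset, 0.0]))
            fr2_patch = 3
        for j, pt in enumerate(ag_points, start=1):
            res = ALL_AA[rng.integers(len(ALL_AA))]
            _emit_residue(atoms, rng, recipe.antigen_chain, j, "", res, pt, recipe)

        # secondary-structure labels
        ss: dict[tuple[str, int, str], str] = {}
        for pos, _ in SCAFFOLD:
            ss[(recipe.vhh_chain, pos, "")] = _sample_ss(rng, SS_FRAMEWORK)
        cdr3_dist = SS_CDR3_BENT if bent else SS_CDR3_EXTENDED
        for pos, icode in cdr3_positions:
            ss[(recipe.vhh_chain, pos, icode)] = _sample_ss(rng, cdr3_dist)
        for pos in FR4_POSITIONS:
            ss[(recipe.vhh_chain, pos, "")] = _sample_ss(rng, SS_FRAMEWORK)

        name = f"vhh{i:04d}"
        models.append(ComplexModel(
            atoms,
            vhh_chain=recipe.vhh_chain,
            antigen_chains=(recipe.antigen_chain,),
            ss_labels=ss,
            name=name,
        ))
        truth.append({
            "id": name,
            "cdr3_length": length,
            "conformation": "bent" if bent else "extended",
            "fr2_involved": not bent,
            "cdr3_docked_residues": len(band),
            "fr2_patch_residues": fr2_patch,
        })

    sidecar = {
        "seed": recipe.seed,
        "n": recipe.n,
        "bent_fraction": recipe.bent_fraction,
        "conformation_length_slope": recipe.conformation_length_slope,
        "length_mean": recipe.length_mean,
        "length_std": recipe.length_std,
        "planted_signs": {
            "r_length_fr2_cdr3_dis": -1,
            "r_length_cdr3_paratope": +1,
            "r_length_fr2_paratope": -1,
        },
        "structures": truth,
    }
    return models, sidecar


def write_structure_set(models: list[ComplexModel], sidecar: dict, out_dir: str | Path) -> None:
    """Write PDB + DSSP-format files, a chain map, and the ground-truth sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for m in models:
        write_pdb(m, out_dir / f"{m.name}.pdb")
        write_dssp(m, out_dir / f"{m.name}.dssp")
    chainmap = {"vhh_chain": models[0].vhh_chain, "antigen_chains": list(models[0].antigen_chains)}
    (out_dir / "chainmap.json").write_text(json.dumps(chainmap, indent=2) + "\n")
    (out_dir / "ground_truth.json").write_text(json.dumps(sidecar, indent=2) + "\n")
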