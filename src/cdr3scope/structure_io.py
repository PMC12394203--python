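"""Atom-level structure containers and PDB / DSSP ingestion.

Structures are held as flat lists of :class:`AtomRecord` keyed by
(chain, IMGT position, insertion code).  PDB files are read through gemmi
(model 1, waters and heteroatoms excluded, alternate locations resolved to
the highest-occupancy conformer); the chain map names the VHH chain, the
antigen chains, and — when the file is not already IMGT-renumbered — an
author-numbering-to-IMGT mapping table.

Secondary-structure labels are ingested from DSSP-format files (the classic
fixed-column layout), never computed here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from .regions import RegionSpec, default_region_spec, region_of

ResidueKey = tuple[str, int, str]  # (chain, imgt_position, insertion code)

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

SS_CODES = ("H", "G", "I", "E", "T", "S", "C")


@dataclass(frozen=True)
class AtomRecord:
    chain: str
    imgt_position: int
    insertion: str
    residue: str  # one-letter code
    atom_name: str
    element: str
    xyz: tuple[float, float, float]

    @property
    def key(self) -> ResidueKey:
        return (self.chain, self.imgt_position, self.insertion)


class ComplexModel:
    """A VHH (optionally with antigen chains) as a flat atom table.

    Residue order within each chain follows first appearance in the input,
    which for PDB files and the synthetic generator is chain/loop order;
    adjacency and CDR3 trimming rely on that order.
    """

    def __init__(
        self,
        atoms: list[AtomRecord],
        vhh_chain: str,
        antigen_chains: tuple[str, ...] = (),
        ss_labels: dict[ResidueKey, str] | None = None,
        spec: dict[str, RegionSpec] | None = None,
        name: str = "",
    ):
        if vhh_chain in antigen_chains:
            raise ValueError("VHH chain must be disjoint from antigen chains")
        self.atoms = list(atoms)
        self.vhh_chain = vhh_chain
        self.antigen_chains = tuple(antigen_chains)
        self.ss_labels = ss_labels
        self.name = name
        self.spec = spec or default_region_spec()

        self.residue_order: dict[str, list[ResidueKey]] = {}
        self.residue_letter: dict[ResidueKey, str] = {}
        self._atoms_by_residue: dict[ResidueKey, list[AtomRecord]] = {}
        for a in self.atoms:
            key = a.key
            if key not in self._atoms_by_residue:
                self.residue_order.setdefault(a.chain, []).append(key)
                self.residue_letter[key] = a.residue
                self._atoms_by_residue[key] = []
            elif self.residue_letter[key] != a.residue:
                raise ValueError(f"inconsistent residue identity at {key}")
            self._atoms_by_residue[key].append(a)

        self.region: dict[ResidueKey, str] = {}
        bad = []
        for key in self.residue_order.get(vhh_chain, []):
            try:
                self.region[key] = region_of(key[1], self.spec)
            except ValueError:
                bad.append(key)
        if bad:
            raise ValueError(f"VHH residues outside the IMGT partition: {bad}")

    # -- accessors -------------------------------------------------------
    def vhh_residues(self) -> list[ResidueKey]:
        return list(self.residue_order.get(self.vhh_chain, []))

    def antigen_residues(self) -> list[ResidueKey]:
        out: list[ResidueKey] = []
        for ch in self.antigen_chains:
            out.extend(self.residue_order.get(ch, []))
        return out

    def region_residues(self, region: str) -> list[ResidueKey]:
        return [k for k in self.vhh_residues() if self.region[k] == region]

    def cdr3_residues(self) -> list[ResidueKey]:
        return self.region_residues("CDR3")

    def atoms_of(self, key: ResidueKey) -> list[AtomRecord]:
        return self._atoms_by_residue[key]

    def chain_atoms(self, chains) -> list[AtomRecord]:
        chains = set(chains)
        return [a for a in self.atoms if a.chain in chains]

    def vhh_atoms(self) -> list[AtomRecord]:
        return self.chain_atoms({self.vhh_chain})

    def antigen_atoms(self) -> list[AtomRecord]:
        return self.chain_atoms(self.antigen_chains)

    def subset(self, chains) -> "ComplexModel":
        chains = set(chains)
        return ComplexModel(
            self.chain_atoms(chains),
            vhh_chain=self.vhh_chain if self.vhh_chain in chains else next(iter(chains)),
            antigen_chains=tuple(c for c in self.antigen_chains if c in chains and c != self.vhh_chain),
            ss_labels=self.ss_labels,
            spec=self.spec,
            name=self.name,
        )

    def residue_sequence(self, keys) -> str:
        return "".join(self.residue_letter[k] for k in keys)

    def vhh_sequence(self) -> str:
        return self.residue_sequence(self.vhh_residues())


#: A lone-domain structure is just a complex with no antigen chains.
StructureModel = ComplexModel


def coords(atoms: list[AtomRecord]) -> np.ndarray:
    return np.array([a.xyz for a in atoms], dtype=float)


def load_chainmap(source) -> dict:
    """Chain map from a dict or a JSON file path."""
    if isinstance(source, dict):
        cm = dict(source)
    else:
        cm = json.loads(Path(source).read_text())
    if "vhh_chain" not in cm:
        raise ValueError("chain map must name 'vhh_chain'")
    cm.setdefault("antigen_chains", [])
    return cm


def load_complex(pdb_path: str | Path, chainmap, spec: dict[str, RegionSpec] | None = None) -> ComplexModel:
    """Read a PDB file into a :class:`ComplexModel`.

    ``chainmap`` (dict or JSON path) carries ``vhh_chain``,
    ``antigen_chains``, and optionally ``renumber`` — a per-chain table
    mapping author residue ids (e.g. "100A") to ``[imgt_position, icode]``.
    Without a renumber table the file is assumed IMGT-renumbered already.
    VHH residues that cannot be mapped into the IMGT partition are reported
    together as an error.
    """
    cm = load_chainmap(chainmap)
    vhh_chain = cm["vhh_chain"]
    antigen_chains = tuple(cm["antigen_chains"])
    renumber = cm.get("renumber", {})

    st = gemmi.read_structure(str(pdb_path))
    st.remove_ligands_and_waters()
    if len(st) == 0:
        raise ValueError(f"{pdb_path}: no models")
    model = st[0]  # first model only

    wanted = {vhh_chain, *antigen_chains}
    seen_chains = set()
    atoms: list[AtomRecord] = []
    unmapped: list[str] = []
    for chain in model:
        if chain.name not in wanted:
            continue
        seen_chains.add(chain.name)
        table = renumber.get(chain.name)
        for res in chain:
            if res.het_flag != "A":
                continue
            one = THREE_TO_ONE.get(res.name.upper())
            if one is None:
                unmapped.append(f"{chain.name}/{res.seqid.num}{res.seqid.icode.strip()}:{res.name}")
                continue
            author_id = f"{res.seqid.num}{res.seqid.icode.strip()}"
            if table is not None:
                if author_id not in table:
                    unmapped.append(f"{chain.name}/{author_id}")
                    continue
                pos, icode = table[author_id]
                pos = int(pos)
            else:
                pos, icode = res.seqid.num, res.seqid.icode.strip()
            # resolve altlocs: highest occupancy per atom name
            best: dict[str, gemmi.Atom] = {}
            for atom in res:
                prev = best.get(atom.name)
                if prev is None or atom.occ > prev.occ:
                    best[atom.name] = atom
            for atom in best.values():
                atoms.append(AtomRecord(
                    chain=chain.name,
                    imgt_position=pos,
                    insertion=icode,
                    residue=one,
                    atom_name=atom.name,
                    element=atom.element.name,
                    xyz=(atom.pos.x, atom.pos.y, atom.pos.z),
                ))
    missing = wanted - seen_chains
    if missing:
        raise ValueError(f"{pdb_path}: chain(s) {sorted(missing)} not found")
    if unmapped:
        raise ValueError(f"{pdb_path}: unmapped residue(s): {unmapped}")
    return ComplexModel(atoms, vhh_chain, antigen_chains, spec=spec, name=Path(pdb_path).stem)


def write_pdb(model: ComplexModel, path: str | Path) -> None:
    """Serialize a model back to PDB through gemmi."""
    st = gemmi.Structure()
    st.name = model.name or "model"
    gm = gemmi.Model("1")
    for chain_name, keys in model.residue_order.items():
        ch = gemmi.Chain(chain_name)
        for key in keys:
            _, pos, icode = key
            res = gemmi.Residue()
            res.name = ONE_TO_THREE[model.residue_letter[key]]
            res.seqid = gemmi.SeqId(pos, icode if icode else " ")
            res.het_flag = "A"
            for a in model.atoms_of(key):
                atom = gemmi.Atom()
                atom.name = a.atom_name
                atom.element = gemmi.Element(a.element)
                atom.pos = gemmi.Position(*a.xyz)
                atom.occ = 1.0
                res.add_atom(atom)
            ch.add_residue(res)
        gm.add_chain(ch)
    st.add_model(gm)
    st.setup_entities()
    st.write_pdb(str(path))


# -- DSSP-format secondary structure ------------------------------------

_DSSP_HEADER = "  #  RESIDUE"


def parse_dssp(path: str | Path) -> dict[ResidueKey, str]:
    """Per-residue secondary-structure codes from a classic DSSP file.

    Blank structure codes are read as coil (C); chain-break records are
    skipped.
    """
    labels: dict[ResidueKey, str] = {}
    in_body = False
    for line in Path(path).read_text().splitlines():
        if not in_body:
            if line.startswith(_DSSP_HEADER):
                in_body = True
            continue
        if len(line) < 17 or line[13] == "!":
            continue
        pos = int(line[5:10])
        icode = line[10].strip()
        chain = line[11].strip()
        ss = line[16].strip() or "C"
        labels[(chain, pos, icode)] = ss
    return labels


def write_dssp(model: ComplexModel, path: str | Path) -> None:
    """Emit per-residue labels of ``model.ss_labels`` in the classic DSSP column layout."""
    if model.ss_labels is None:
        raise ValueError("model carries no secondary-structure labels")
    lines = [
        "==== Secondary structure definition, DSSP-format labels ====",
        _DSSP_HEADER + " AA STRUCTURE BP1 BP2  ACC",
    ]
    i = 0
    for chain_name, keys in model.residue_order.items():
        for key in keys:
            if key not in model.ss_labels:
                continue
            i += 1
            _, pos, icode = key
            aa = model.residue_letter[key]
            ss = model.ss_labels[key]
            lines.append(f"{i:5d}{pos:5d}{icode or ' '}{chain_name} {aa}  {ss}")
    Path(path).write_text("\n".join(lines) + "\n")
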