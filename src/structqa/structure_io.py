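"""Structure file I/O with per-residue confidence and entity bookkeeping.

Predicted models follow the AlphaFold-DB convention: the per-residue
confidence score (pLDDT, 0-100) is stored in the B-factor field of every
atom of the residue. We read it from the C-alpha atom, which is the single
authoritative source when atoms disagree. Entities (distinct polymer
sequences; several chains may instantiate one entity) come from the mmCIF
entity records, or are inferred by exact chain-sequence equality for PDB
input, which carries no entity information.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import gemmi
import numpy as np
from Bio import SeqIO

__all__ = [
    "Residue",
    "StructureModel",
    "ConfidenceProfile",
    "StructureParseError",
    "read_structure",
    "write_structure",
    "extract_profile",
    "read_fasta",
]

AA1_TO_3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
    "X": "UNK",
}
AA3_TO_1 = {v: k for k, v in AA1_TO_3.items()}


class StructureParseError(ValueError):
    """Raised when a structure file violates the expected conventions."""


@dataclass
class Residue:
    chain_id: str
    entity_id: str
    seq_index: int                     # 1-based position within the chain
    aa_code: str                       # one-letter amino acid
    ca_coord: Optional[np.ndarray]     # Angstrom; None if unresolved
    cb_coord: Optional[np.ndarray]     # None is legal for glycine / incomplete
    plddt: float                       # confidence, 0-100
    resolved: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.plddt <= 100.0):
            raise ValueError(
                f"plddt {self.plddt} outside [0, 100] at {self.chain_id}:{self.seq_index}"
            )
        if self.ca_coord is not None:
            self.ca_coord = np.asarray(self.ca_coord, dtype=float)
        if self.cb_coord is not None:
            self.cb_coord = np.asarray(self.cb_coord, dtype=float)


@dataclass
class StructureModel:
    """Ordered residues plus the chain -> entity map.

    Residues are kept sorted by (chain_id, seq_index); seq_index is unique
    within a chain and every chain maps to exactly one entity.
    """

    residues: list[Residue]
    entities: dict[str, str] = field(default_factory=dict)
    source_format: str = "memory"

    def __post_init__(self) -> None:
        self.residues = sorted(self.residues, key=lambda r: (r.chain_id, r.seq_index))
        seen: set[tuple[str, int]] = set()
        for r in self.residues:
            key = (r.chain_id, r.seq_index)
            if key in seen:
                raise ValueError(f"duplicate residue {key}")
            seen.add(key)
            if r.chain_id not in self.entities:
                self.entities[r.chain_id] = r.entity_id
            elif self.entities[r.chain_id] != r.entity_id:
                raise ValueError(f"chain {r.chain_id} maps to multiple entities")

    @property
    def chains(self) -> list[str]:
        out: list[str] = []
        for r in self.residues:
            if not out or out[-1] != r.chain_id:
                if r.chain_id in out:
                    continue
                out.append(r.chain_id)
        return out

    def chain_residues(self, chain_id: str) -> list[Residue]:
        res = [r for r in self.residues if r.chain_id == chain_id]
        if not res:
            raise KeyError(f"unknown chain {chain_id!r}")
        return res

    def chain_sequence(self, chain_id: str) -> str:
        return "".join(r.aa_code for r in self.chain_residues(chain_id))


@dataclass
class ConfidenceProfile:
    """Per-residue confidence (pLDDT, 0-100) for one protein sequence."""

    protein_id: str
    plddt: np.ndarray

    def __post_init__(self) -> None:
        self.plddt = np.asarray(self.plddt, dtype=float)
        if self.plddt.ndim != 1:
            raise ValueError("plddt must be one-dimensional")
        if self.plddt.size and (self.plddt.min() < 0 or self.plddt.max() > 100):
            raise ValueError("plddt values outside [0, 100]")

    @property
    def length(self) -> int:
        return int(self.plddt.size)


def _pick_atom(residue: gemmi.Residue, name: str) -> Optional[gemmi.Atom]:
    """Highest-occupancy atom of the given name; ties broken first-in-file."""
    best = None
    for atom in residue:
        if atom.name != name:
            continue
        if best is None or atom.occ > best.occ:
            best = atom
    return best


def read_structure(path: str | Path, format: Optional[str] = None) -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    pLDDT is taken from the C-alpha B-factor. Residues without a C-alpha are
    flagged ``resolved=False`` and excluded from coordinate-based operations.
    For mmCIF the entity assignment comes from the entity records; for PDB it
    is inferred from exact chain-sequence equality.
    """
    path = Path(path)
    fmt = format or ("pdb" if path.suffix.lower() in {".pdb", ".ent"} else "mmcif")
    try:
        if fmt == "pdb":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
        elif fmt == "mmcif":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        else:
            raise ValueError(f"unknown format {fmt!r}")
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"cannot parse {path} as {fmt}: {exc}") from exc
    if len(st) == 0:
        raise StructureParseError(f"{path}: no models in file")
    model = st[0]

    # mmCIF entity lookup: subchain id -> entity name
    sub_to_entity: dict[str, str] = {}
    for ent in st.entities:
        for sub in ent.subchains:
            sub_to_entity[sub] = ent.name

    residues: list[Residue] = []
    chain_seqs: dict[str, str] = {}
    for chain in model:
        seq_chars: list[str] = []
        for res in chain:
            if res.seqid.icode not in ("", " ", "\x00"):
                raise StructureParseError(
                    f"{path}: insertion code {res.seqid.icode!r} at "
                    f"{chain.name} {res.seqid.num} is not supported"
                )
            aa = AA3_TO_1.get(res.name, "X")
            seq_chars.append(aa)
            ca = _pick_atom(res, "CA")
            cb = _pick_atom(res, "CB")
            entity = sub_to_entity.get(res.subchain, "")
            residues.append(
                Residue(
                    chain_id=chain.name,
                    entity_id=entity,
                    seq_index=res.seqid.num,
                    aa_code=aa,
                    ca_coord=np.array(ca.pos.tolist()) if ca else None,
                    cb_coord=np.array(cb.pos.tolist()) if cb else None,
                    plddt=float(ca.b_iso) if ca else 0.0,
                    resolved=ca is not None,
                )
            )
        chain_seqs[chain.name] = "".join(seq_chars)

    if fmt == "pdb" or not sub_to_entity:
        # infer entities by exact sequence equality
        seq_to_entity: dict[str, str] = {}
        chain_entity: dict[str, str] = {}
        for cname, seq in chain_seqs.items():
            if seq not in seq_to_entity:
                seq_to_entity[seq] = str(len(seq_to_entity) + 1)
            chain_entity[cname] = seq_to_entity[seq]
        for r in residues:
            r.entity_id = chain_entity[r.chain_id]

    return StructureModel(residues=residues, source_format=fmt)


def write_structure(model: StructureModel, path: str | Path, format: Optional[str] = None) -> None:
    """Write a model to PDB or mmCIF, confidence in the B-factor column.

    mmCIF output carries one entity record per distinct entity_id, so that
    homomer/heteromer semantics round-trip.
    """
    path = Path(path)
    fmt = format or ("pdb" if path.suffix.lower() in {".pdb", ".ent"} else "mmcif")
    for r in model.residues:
        if not (0.0 <= r.plddt <= 100.0):
            raise ValueError(f"plddt out of range at {r.chain_id}:{r.seq_index}")

    st = gemmi.Structure()
    st.name = "structqa"
    gmodel = gemmi.Model("1")
    entity_subchains: dict[str, list[str]] = {}
    for chain_id in model.chains:
        chain = gemmi.Chain(chain_id)
        subchain_id = f"{chain_id}sub"
        entity_subchains.setdefault(model.entities[chain_id], []).append(subchain_id)
        for r in model.chain_residues(chain_id):
            res = gemmi.Residue()
            res.name = AA1_TO_3.get(r.aa_code, "UNK")
            res.seqid = gemmi.SeqId(r.seq_index, " ")
            res.subchain = subchain_id
            res.label_seq = r.seq_index
            res.entity_type = gemmi.EntityType.Polymer
            for aname, coord, element in (("CA", r.ca_coord, "C"), ("CB", r.cb_coord, "C")):
                if coord is None:
                    continue
                atom = gemmi.Atom()
                atom.name = aname
                atom.element = gemmi.Element(element)
                atom.pos = gemmi.Position(*[float(x) for x in coord])
                atom.occ = 1.0
                atom.b_iso = round(float(r.plddt), 2)
                res.add_atom(atom)
            chain.add_residue(res)
        gmodel.add_chain(chain)
    st.add_model(gmodel)
    for entity_id, subchains in entity_subchains.items():
        ent = gemmi.Entity(entity_id)
        ent.entity_type = gemmi.EntityType.Polymer
        ent.polymer_type = gemmi.PolymerType.PeptideL
        ent.subchains = subchains
        st.entities.append(ent)
    st.setup_cell_images()
    if fmt == "pdb":
        st.write_pdb(str(path))
    elif fmt == "mmcif":
        st.make_mmcif_document().write_file(str(path))
    else:
        raise ValueError(f"unknown format {fmt!r}")


def extract_profile(model: StructureModel, chain_id: str) -> ConfidenceProfile:
    """Per-residue confidence of one chain, ordered by seq_index."""
    res = model.chain_residues(chain_id)
    return ConfidenceProfile(protein_id=chain_id, plddt=np.array([r.plddt for r in res]))


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an id -> sequence mapping."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
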