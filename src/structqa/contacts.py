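"""Residue-contact detection and interface classification.

Two residues are in contact when their C-beta atoms (C-alpha for glycine)
are within 8 A; same-chain pairs must additionally be separated by at least
three intervening residues, which excludes the trivial i,i+3 contacts of an
alpha-helix. Contacts are classified by the chain/entity relationship of the
pair: intra-chain, homomeric (cross-chain, same entity) or heterotypic
(cross-chain, different entities). The heterotypic fraction
heterotypic / (intra_chain + homomeric + heterotypic) summarises how much a
chain's structure depends on partners of a different sequence — a regime in
which single-chain prediction accuracy drops.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structure_io import Residue, StructureModel

logger = logging.getLogger(__name__)

CONTACT_CLASSES = ("intra_chain", "homomeric", "heterotypic")

__all__ = [
    "CONTACT_CLASSES",
    "Contact",
    "ContactSet",
    "representative_atom",
    "find_contacts",
    "heterotypic_ratio_profile",
    "accuracy_vs_ratio_table",
]


@dataclass(frozen=True)
class Contact:
    residue_a: tuple[str, int]  # (chain_id, seq_index), lexicographically first
    residue_b: tuple[str, int]
    distance: float
    contact_class: str


@dataclass
class ContactSet:
    contacts: list[Contact]

    @property
    def counts(self) -> dict[str, int]:
        out = {c: 0 for c in CONTACT_CLASSES}
        for c in self.contacts:
            out[c.contact_class] += 1
        return out

    @property
    def ratio_heterotypic(self) -> float:
        total = len(self.contacts)
        return self.counts["heterotypic"] / total if total else 0.0


def representative_atom(residue: Residue, missing_cb: str = "ca") -> np.ndarray:
    """Contact-detection coordinate: C-beta, or C-alpha for glycine.

    ``missing_cb`` controls non-glycine residues without a C-beta: "ca"
    falls back to the C-alpha with a warning, "strict" raises.
    """
    if residue.aa_code == "G":
        if residue.ca_coord is None:
            raise ValueError(f"glycine {residue.chain_id}:{residue.seq_index} has no CA")
        return residue.ca_coord
    if residue.cb_coord is not None:
        return residue.cb_coord
    if missing_cb == "strict":
        raise ValueError(f"residue {residue.chain_id}:{residue.seq_index} has no CB")
    if residue.ca_coord is None:
        raise ValueError(f"residue {residue.chain_id}:{residue.seq_index} has no coordinates")
    logger.warning(
        "residue %s:%d lacks CB; falling back to CA", residue.chain_id, residue.seq_index
    )
    return residue.ca_coord


def _classify(a: Residue, b: Residue) -> str:
    if a.chain_id == b.chain_id:
        return "intra_chain"
    if a.entity_id == b.entity_id:
        return "homomeric"
    return "heterotypic"


def find_contacts(
    structure: StructureModel,
    cutoff: float = 8.0,
    min_sep: int = 4,
    missing_cb: str = "ca",
) -> ContactSet:
    """All residue contacts of a structure, classified by pair relationship.

    Same-chain pairs require |i - j| >= min_sep (default 4: at least three
    intervening residues); cross-chain pairs have no separation requirement.
    Detection uses a k-d tree over representative atoms; unresolved residues
    are excluded.
    """
    residues = [r for r in structure.residues if r.resolved]
    if not structure.residues:
        raise ValueError("structure has no residues")
    coords = []
    kept: list[Residue] = []
    for r in residues:
        try:
            coords.append(representative_atom(r, missing_cb=missing_cb))
            kept.append(r)
        except ValueError:
            continue
    if not kept:
        return ContactSet(contacts=[])
    pts = np.asarray(coords)
    tree = cKDTree(pts)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    contacts: list[Contact] = []
    for ia, ib in pairs:
        a, b = kept[ia], kept[ib]
        if a.chain_id == b.chain_id and abs(a.seq_index - b.seq_index) < min_sep:
            continue
        dist = float(np.linalg.norm(pts[ia] - pts[ib]))
        ka, kb = (a.chain_id, a.seq_index), (b.chain_id, b.seq_index)
        if kb < ka:
            ka, kb = kb, ka
        contacts.append(Contact(ka, kb, dist, _classify(a, b)))
    contacts.sort(key=lambda c: (c.residue_a, c.residue_b))
    return ContactSet(contacts=contacts)


def heterotypic_ratio_profile(
    structure: StructureModel,
    chain_id: str,
    cutoff: float = 8.0,
    min_sep: int = 4,
) -> tuple[float, bool]:
    """Heterotypic contact ratio over contacts involving one chain.

    Returns (ratio, has_contacts); a chain with zero contacts reports ratio
    0 with the flag lowered.
    """
    if chain_id not in structure.chains:
        raise KeyError(f"unknown chain {chain_id!r}")
    cs = find_contacts(structure, cutoff=cutoff, min_sep=min_sep)
    involved = [c for c in cs.contacts if chain_id in (c.residue_a[0], c.residue_b[0])]
    if not involved:
        return 0.0, False
    het = sum(1 for c in involved if c.contact_class == "heterotypic")
    return het / len(involved), True


def accuracy_vs_ratio_table(
    records: Sequence[tuple[float, float]],
    bin_edges: Sequence[float] = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0),
) -> pd.DataFrame:
    """Accuracy distribution stratified by heterotypic-contact ratio.

    ``records`` are (ratio, accuracy) pairs. Bins are right-open except the
    last, which is closed. Returns per-bin count, median and quartiles of
    the accuracy score; empty bins are omitted.
    """
    if not len(records):
        raise ValueError("no records")
    ratios = np.array([r for r, _ in records], dtype=float)
    acc = np.array([a for _, a in records], dtype=float)
    if ratios.min() < 0 or ratios.max() > 1:
        raise ValueError("ratios must lie in [0, 1]")
    edges = np.asarray(bin_edges, dtype=float)
    idx = np.digitize(ratios, edges, right=False) - 1
    idx[ratios == edges[-1]] = len(edges) - 2  # last bin closed on the right
    rows = []
    for b in range(len(edges) - 1):
        sel = acc[idx == b]
        if sel.size == 0:
            continue
        rows.append(
            {
                "bin_low": edges[b],
                "bin_high": edges[b + 1],
                "count": int(sel.size),
                "q1": float(np.percentile(sel, 25)),
                "median": float(np.median(sel)),
                "q3": float(np.percentile(sel, 75)),
            }
        )
    return pd.DataFrame(rows)


def contacts_to_frame(cs: ContactSet) -> pd.DataFrame:
    """TSV-ready contact table (chain_a, idx_a, chain_b, idx_b, distance, class)."""
    return pd.DataFrame(
        [
            {
                "chain_a": c.residue_a[0],
                "idx_a": c.residue_a[1],
                "chain_b": c.residue_b[0],
                "idx_b": c.residue_b[1],
                "distance": c.distance,
                "class": c.contact_class,
            }
            for c in cs.contacts
        ]
    )
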