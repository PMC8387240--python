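"""Synthetic inputs with recorded ground truth for every pipeline stage.

Everything the analyses consume — multi-chain structures with entity
assignments and constructed interfaces, confidence profiles with a
controlled linear relation to true accuracy, disorder proteomes with
separated score distributions, template-hit tables, chain metadata with
designed filter violations, and a toy ontology — is generated here from a
seed, alongside the bookkeeping needed to check every downstream statistic
exactly. Geometry is a C-alpha trace with a pseudo-C-beta (full-atom detail
is not needed by any implemented metric); chains use 3.8 A consecutive
spacing, ideal helix/strand geometry or a self-avoiding walk.

Determinism contract: the same spec (including seed) produces bit-identical
outputs. Per-protein random streams are derived by keyed seeding
(``default_rng([seed, key, index])``) so enlarging a cohort does not shift
earlier entries.
"""
from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .structure_io import ConfidenceProfile, Residue, StructureModel

__all__ = [
    "GeneratorSpec",
    "make_chain",
    "perturb",
    "simulate_plddt",
    "make_calibration_pairs",
    "make_complex",
    "heterodimer_fixture",
    "make_disorder_proteome",
    "make_banded_proteome",
    "make_coverage_proteome",
    "make_multidomain_cohort",
    "make_hit_table",
    "recent_pdb_fixture",
    "order_sensitivity_fixture",
    "toy_ontology_obo",
    "toy_ontology_fixture",
    "brute_force_contact_counts",
]

CA_SPACING = 3.8  # Angstrom, consecutive C-alpha distance
_HELIX_RADIUS = 2.3
_HELIX_TURN = np.deg2rad(100.0)
# rise solved so the consecutive C-alpha distance is exactly CA_SPACING
_HELIX_CHORD = 2.0 * _HELIX_RADIUS * np.sin(_HELIX_TURN / 2.0)
_HELIX_RISE = float(np.sqrt(CA_SPACING**2 - _HELIX_CHORD**2))
_STRAND_STEP_X = 3.3
_STRAND_STEP_Y = float(np.sqrt(CA_SPACING**2 - _STRAND_STEP_X**2))
_CLASH_DISTANCE = 3.4  # self-avoidance limit for non-adjacent residues

_AA20 = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class GeneratorSpec:
    """Study conditions for the synthetic proteome.

    Defaults mirror the analysed regime: chain lengths within the 16-2,700
    range attempted at proteome scale, a 0.4 disorder fraction (the human
    proteome is estimated at 37-50% disordered residues), confidence bands
    targeting (0.35, 0.25, 0.2, 0.2), and a calibration relation close to
    the published fit (slope 0.967, intercept 1.9).
    """

    seed: int = 0
    n_proteins: int = 200
    length_distribution: tuple[int, int] = (60, 350)
    disorder_fraction: float = 0.4
    calibration: tuple[float, float, float] = (0.967, 1.9, 5.0)  # slope, intercept, noise sd
    band_targets: dict[str, float] = field(
        default_factory=lambda: {
            "very_high": 0.35,
            "confident": 0.25,
            "low": 0.2,
            "very_low": 0.2,
        }
    )
    complex_spec: list[tuple[int, tuple[str, ...], int]] = field(
        default_factory=lambda: [(3, ("1", "1", "2"), 30)]
    )

    def __post_init__(self) -> None:
        lo, hi = self.length_distribution
        if lo < 16 or hi > 2700:
            raise ValueError("chain lengths must stay within 16-2,700 residues")
        if not (0.0 <= self.disorder_fraction <= 1.0):
            raise ValueError("disorder_fraction must be in [0, 1]")
        if abs(sum(self.band_targets.values()) - 1.0) > 1e-9:
            raise ValueError("band_targets must sum to 1")


def _pseudo_cb(ca: np.ndarray, i: int) -> Optional[np.ndarray]:
    """Tetrahedral-ish C-beta offset from the local C-alpha frame."""
    n = ca.shape[0]
    j = min(max(i, 1), n - 2)  # endpoints borrow the nearest interior frame
    v1 = ca[j - 1] - ca[j]
    v2 = ca[j + 1] - ca[j]
    v1 /= np.linalg.norm(v1)
    v2 /= np.linalg.norm(v2)
    bis = -(v1 + v2)
    nrm = np.cross(v1, v2)
    if np.linalg.norm(bis) < 1e-8:
        bis = np.array([0.0, 0.0, 1.0])
    if np.linalg.norm(nrm) < 1e-8:
        nrm = np.array([1.0, 0.0, 0.0])
    direction = bis / np.linalg.norm(bis) + 0.8 * nrm / np.linalg.norm(nrm)
    direction /= np.linalg.norm(direction)
    return ca[i] + 1.53 * direction


def _helix_trace(n: int) -> np.ndarray:
    i = np.arange(n)
    return np.column_stack(
        [
            _HELIX_RADIUS * np.cos(i * _HELIX_TURN),
            _HELIX_RADIUS * np.sin(i * _HELIX_TURN),
            i * _HELIX_RISE,
        ]
    )


def _strand_trace(n: int) -> np.ndarray:
    i = np.arange(n)
    return np.column_stack([i * _STRAND_STEP_X, (i % 2) * _STRAND_STEP_Y, np.zeros(n)])


def _walk_trace(n: int, rng: np.random.Generator, max_restarts: int = 40) -> np.ndarray:
    for _ in range(max_restarts):
        pts = [np.zeros(3)]
        ok = True
        for _step in range(n - 1):
            placed = False
            for _try in range(60):
                v = rng.normal(size=3)
                v *= CA_SPACING / np.linalg.norm(v)
                cand = pts[-1] + v
                prev = np.asarray(pts[:-1])
                if prev.size == 0 or np.min(np.linalg.norm(prev - cand, axis=1)) >= _CLASH_DISTANCE:
                    pts.append(cand)
                    placed = True
                    break
            if not placed:
                ok = False
                break
        if ok:
            return np.asarray(pts)
    raise RuntimeError(f"self-avoiding walk failed for n={n}")


def make_chain(
    n: int,
    topology: str = "random_walk",
    seed: int = 0,
    chain_id: str = "A",
    entity_id: str = "1",
    glycine_fraction: float = 0.1,
    plddt: float = 90.0,
) -> StructureModel:
    """Single-chain C-alpha trace with pseudo-C-beta atoms.

    ``topology`` is helix, strand, coil or random_walk (coil and random_walk
    are both self-avoiding walks). Consecutive C-alpha spacing is exactly
    3.8 A. A configurable fraction of residues are glycines, which carry no
    C-beta.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = np.random.default_rng([seed, 7])
    if topology == "helix":
        ca = _helix_trace(n)
    elif topology == "strand":
        ca = _strand_trace(n)
    elif topology in ("coil", "random_walk"):
        ca = _walk_trace(n, rng)
    else:
        raise ValueError(f"unknown topology {topology!r}")
    is_gly = rng.random(n) < glycine_fraction
    non_gly = [c for c in _AA20 if c != "G"]
    residues = []
    for i in range(n):
        aa = "G" if is_gly[i] else non_gly[int(rng.integers(0, len(non_gly)))]
        cb = None if aa == "G" else _pseudo_cb(ca, i)
        residues.append(
            Residue(
                chain_id=chain_id,
                entity_id=entity_id,
                seq_index=i + 1,
                aa_code=aa,
                ca_coord=ca[i].copy(),
                cb_coord=cb,
                plddt=plddt,
            )
        )
    return StructureModel(residues=residues)


def perturb(
    model: StructureModel, sigma_profile: np.ndarray | float, seed: int = 0
) -> StructureModel:
    """Isotropic Gaussian displacement of each residue's atoms (sigma in A)."""
    rng = np.random.default_rng([seed, 11])
    n = len(model.residues)
    sigma = np.broadcast_to(np.asarray(sigma_profile, dtype=float), (n,))
    if (sigma < 0).any():
        raise ValueError("sigma must be >= 0")
    residues = []
    for r, s in zip(model.residues, sigma):
        shift = rng.normal(0.0, 1.0, size=3) * s if s > 0 else np.zeros(3)
        residues.append(
            Residue(
                chain_id=r.chain_id,
                entity_id=r.entity_id,
                seq_index=r.seq_index,
                aa_code=r.aa_code,
                ca_coord=None if r.ca_coord is None else r.ca_coord + shift,
                cb_coord=None if r.cb_coord is None else r.cb_coord + shift,
                plddt=r.plddt,
                resolved=r.resolved,
            )
        )
    return StructureModel(residues=residues, source_format=model.source_format)


def simulate_plddt(
    true_lddt: np.ndarray,
    slope: float = 0.967,
    intercept: float = 1.9,
    noise_sd: float = 0.0,
    seed: int = 0,
    protein_id: str = "sim",
) -> ConfidenceProfile:
    """Confidence profile consistent with a linear calibration relation.

    Inverts observed ~= slope x pLDDT + intercept, adds Gaussian noise, and
    truncates to [0, 100].
    """
    true_lddt = np.asarray(true_lddt, dtype=float)
    rng = np.random.default_rng([seed, 13])
    plddt = (true_lddt - intercept) / slope
    if noise_sd > 0:
        plddt = plddt + rng.normal(0.0, noise_sd, size=plddt.shape)
    return ConfidenceProfile(protein_id=protein_id, plddt=np.clip(plddt, 0.0, 100.0))


def make_calibration_pairs(
    n: int,
    slope: float = 0.95,
    intercept: float = 2.0,
    noise_sd: float = 5.0,
    seed: int = 0,
    plddt_range: tuple[float, float] = (20.0, 85.0),
) -> tuple[np.ndarray, np.ndarray]:
    """(pLDDT, observed lDDT) pairs with noise on the observed side.

    pLDDT is uniform on ``plddt_range`` and the observed accuracy is
    slope x pLDDT + intercept + N(0, noise_sd), untruncated, so ordinary
    least squares of observed on predicted recovers the generating
    parameters without attenuation or edge bias.
    """
    rng = np.random.default_rng([seed, 17])
    x = rng.uniform(*plddt_range, size=n)
    y = slope * x + intercept + rng.normal(0.0, noise_sd, size=n)
    return x, y


def _representative(r: Residue) -> Optional[np.ndarray]:
    if r.aa_code == "G":
        return r.ca_coord
    return r.cb_coord if r.cb_coord is not None else r.ca_coord


def brute_force_contact_counts(
    model: StructureModel, cutoff: float = 8.0, min_sep: int = 4
) -> dict[str, int]:
    """Independent all-pairs double loop over the contact definition.

    Used for ground-truth bookkeeping; deliberately does not share code with
    the contact-detection module.
    """
    res = [r for r in model.residues if r.resolved]
    counts = {"intra_chain": 0, "homomeric": 0, "heterotypic": 0}
    for i in range(len(res)):
        a = res[i]
        pa = _representative(a)
        if pa is None:
            continue
        for j in range(i + 1, len(res)):
            b = res[j]
            pb = _representative(b)
            if pb is None:
                continue
            if a.chain_id == b.chain_id and abs(a.seq_index - b.seq_index) < min_sep:
                continue
            if np.linalg.norm(pa - pb) > cutoff:
                continue
            if a.chain_id == b.chain_id:
                counts["intra_chain"] += 1
            elif a.entity_id == b.entity_id:
                counts["homomeric"] += 1
            else:
                counts["heterotypic"] += 1
    return counts


def make_complex(
    n_chains: int,
    entities: Sequence[str],
    seed: int = 0,
    chain_length: int = 30,
    interface: bool = True,
    spacing: Optional[float] = None,
) -> tuple[StructureModel, dict]:
    """Multi-chain assembly with a designed amount of cross-chain interface.

    Chains of one entity share a sequence (the homomer/heteromer semantics
    depend on it). Parallel helical chains are placed on a line; with
    ``interface`` they are close enough for cross-chain representative-atom
    pairs within 8 A, otherwise far apart. Realised contact counts are
    recomputed by brute force and returned as ground truth.
    """
    if len(entities) != n_chains:
        raise ValueError("one entity id per chain required")
    if spacing is None:
        spacing = 8.5 if interface else 30.0
    rng = np.random.default_rng([seed, 19])
    chain_ids = [chr(ord("A") + k) for k in range(n_chains)]
    # one sequence per entity, shared by its chains
    entity_templates: dict[str, StructureModel] = {}
    for ent in dict.fromkeys(entities):
        entity_templates[ent] = make_chain(
            chain_length,
            topology="helix",
            seed=int(rng.integers(0, 2**31 - 1)),
            entity_id=ent,
        )
    residues: list[Residue] = []
    for k, (cid, ent) in enumerate(zip(chain_ids, entities)):
        template = entity_templates[ent]
        offset = np.array([k * spacing, 0.0, 0.0])
        for r in template.residues:
            residues.append(
                Residue(
                    chain_id=cid,
                    entity_id=ent,
                    seq_index=r.seq_index,
                    aa_code=r.aa_code,
                    ca_coord=r.ca_coord + offset,
                    cb_coord=None if r.cb_coord is None else r.cb_coord + offset,
                    plddt=r.plddt,
                )
            )
    model = StructureModel(residues=residues)
    truth = {"contact_counts": brute_force_contact_counts(model)}
    return model, truth


def heterodimer_fixture() -> tuple[StructureModel, dict]:
    """Hand-placed three-chain complex with hand-counted contacts.

    Chains A and B share entity 1; chain C is entity 2. Representative atoms
    are laid out in the z=0 plane so every contact can be verified on paper:
    7 intra-chain contacts within A, 2 homomeric A-B contacts, 3 heterotypic
    A-C contacts — total 12, heterotypic ratio 3/12 = 0.25.
    """
    a_xy = [(0, 0), (4, 0), (8, 0), (12, 0), (12, 4), (8, 4), (4, 4), (0, 4), (-4, 4)]
    b_xy = [(16, 2)] + [(30 + 4 * k, -40) for k in range(8)]
    c_xy = [(0, 8.5)] + [(4 * k, -80) for k in range(4)]
    seq_ab = "LKLKLKLKL"  # 9 residues, shared by A and B (entity 1)
    seq_c = "VVVVV"
    residues = []
    for cid, ent, seq, coords in (
        ("A", "1", seq_ab, a_xy),
        ("B", "1", seq_ab, b_xy),
        ("C", "2", seq_c, c_xy),
    ):
        for i, ((x, y), aa) in enumerate(zip(coords, seq)):
            cb = np.array([float(x), float(y), 0.0])
            residues.append(
                Residue(
                    chain_id=cid,
                    entity_id=ent,
                    seq_index=i + 1,
                    aa_code=aa,
                    ca_coord=cb + np.array([0.0, 0.0, -1.53]),
                    cb_coord=cb,
                    plddt=90.0,
                )
            )
    truth = {
        "contact_counts": {"intra_chain": 7, "homomeric": 2, "heterotypic": 3},
        "ratio_heterotypic": 0.25,
        "chain_a_contacts": 12,
    }
    return StructureModel(residues=residues), truth


def make_disorder_proteome(spec: GeneratorSpec) -> tuple[list[dict], dict]:
    """Proteome of confidence profiles with known disorder labels.

    Each protein alternates ordered and disordered segments; the disordered
    residue count is round(fraction x length) exactly. Disordered residues
    draw pLDDT from Uniform(20, 50) and ordered ones from Uniform(70, 98) —
    distributions chosen to straddle the 50 and 70 cut-offs.

    Returns (proteins, ground_truth): each protein dict has id, sequence,
    profile, labels and segments.
    """
    lo, hi = spec.length_distribution
    proteins = []
    total = 0
    total_dis = 0
    for i in range(spec.n_proteins):
        rng = np.random.default_rng([spec.seed, 23, i])
        length = int(rng.integers(lo, hi + 1))
        n_dis = int(round(spec.disorder_fraction * length))
        labels = np.zeros(length, dtype=int)
        if n_dis > 0:
            n_segments = int(rng.integers(1, 4))
            n_segments = min(n_segments, n_dis)
            cuts = np.sort(rng.choice(np.arange(1, n_dis), size=n_segments - 1, replace=False)) if n_segments > 1 else np.array([], dtype=int)
            sizes = np.diff(np.r_[0, cuts, n_dis])
            for size in sizes:
                placed = False
                for _ in range(200):
                    start = int(rng.integers(0, length - size + 1))
                    if not labels[start : start + size].any():
                        labels[start : start + size] = 1
                        placed = True
                        break
                if not placed:  # fragmentation fallback: first free positions
                    free = np.flatnonzero(labels == 0)[: int(size)]
                    labels[free] = 1
        plddt = np.where(
            labels == 1,
            rng.uniform(20.0, 50.0, size=length),
            rng.uniform(70.0, 98.0, size=length),
        )
        seq = "".join(_AA20[k] for k in rng.integers(0, len(_AA20), size=length))
        pid = f"synth{i:04d}"
        segments = _runs(labels)
        proteins.append(
            {
                "protein_id": pid,
                "sequence": seq,
                "profile": ConfidenceProfile(protein_id=pid, plddt=plddt),
                "labels": labels,
                "segments": segments,
            }
        )
        total += length
        total_dis += int(labels.sum())
    truth = {
        "target_disorder_fraction": spec.disorder_fraction,
        "realized_disorder_fraction": total_dis / total,
        "total_residues": total,
    }
    return proteins, truth


def _runs(labels: np.ndarray) -> list[tuple[int, int]]:
    out = []
    start = None
    for i, v in enumerate(labels):
        if v and start is None:
            start = i
        elif not v and start is not None:
            out.append((start + 1, i))
            start = None
    if start is not None:
        out.append((start + 1, len(labels)))
    return out


_BAND_SAMPLING = {
    "very_high": (90.5, 99.5),
    "confident": (70.5, 89.5),
    "low": (50.5, 69.5),
    "very_low": (5.0, 49.5),
}


def make_banded_proteome(spec: GeneratorSpec) -> tuple[list[ConfidenceProfile], dict]:
    """Profiles whose proteome-wide band composition matches the targets exactly.

    Band counts are fixed by largest-remainder apportionment of the target
    fractions over the total residue count, then shuffled across proteins,
    so the recovered fractions are exact integer ratios.
    """
    rng = np.random.default_rng([spec.seed, 29])
    lo, hi = spec.length_distribution
    lengths = rng.integers(lo, hi + 1, size=spec.n_proteins)
    total = int(lengths.sum())
    bands = list(spec.band_targets)
    exact = {b: spec.band_targets[b] * total for b in bands}
    counts = {b: int(np.floor(exact[b])) for b in bands}
    remainder = total - sum(counts.values())
    for b in sorted(bands, key=lambda b: exact[b] - counts[b], reverse=True)[:remainder]:
        counts[b] += 1
    pool = np.concatenate(
        [rng.uniform(*_BAND_SAMPLING[b], size=counts[b]) for b in bands]
    )
    rng.shuffle(pool)
    profiles = []
    pos = 0
    for i, length in enumerate(lengths):
        profiles.append(
            ConfidenceProfile(protein_id=f"band{i:04d}", plddt=pool[pos : pos + length])
        )
        pos += int(length)
    truth = {"band_counts": counts, "total_residues": total}
    return profiles, truth


def make_coverage_proteome(
    n_proteins: int = 200,
    pass_fraction: float = 0.4,
    seed: int = 0,
    length_range: tuple[int, int] = (100, 400),
) -> tuple[list[ConfidenceProfile], dict]:
    """Profiles with a designed fraction of proteins confident on >= 3/4 of residues."""
    n_pass = int(round(pass_fraction * n_proteins))
    profiles = []
    pass_ids = []
    for i in range(n_proteins):
        rng = np.random.default_rng([seed, 31, i])
        length = int(rng.integers(*length_range))
        passes = i < n_pass
        n_conf = int(np.ceil(0.8 * length)) if passes else int(np.floor(0.5 * length))
        plddt = np.full(length, 40.0)
        plddt[:n_conf] = 85.0
        rng.shuffle(plddt)
        pid = f"cov{i:04d}"
        profiles.append(ConfidenceProfile(protein_id=pid, plddt=plddt))
        if passes:
            pass_ids.append(pid)
    truth = {"pass_ids": pass_ids, "pass_fraction": len(pass_ids) / n_proteins}
    return profiles, truth


def make_multidomain_cohort(
    n: int = 50, seed: int = 0
) -> tuple[list[dict], dict]:
    """Candidate entries for the multi-domain screen with a known pass-set.

    Each entry carries a profile, the best >50%-coverage template identity
    (0 = none) and a weighted-TM value; the generator applies its own copy
    of the rule (>= 600 confident residues, over half the sequence, no
    high-coverage template) to record which ids should survive.
    """
    entries = []
    pass_ids = []
    for i in range(n):
        rng = np.random.default_rng([seed, 37, i])
        length = int(rng.integers(400, 1600))
        conf_frac = float(rng.uniform(0.2, 0.95))
        n_conf = int(round(conf_frac * length))
        plddt = np.full(length, 40.0)
        plddt[:n_conf] = 85.0
        rng.shuffle(plddt)
        has_template = bool(rng.random() < 0.3)
        identity = float(rng.uniform(30, 90)) if has_template else 0.0
        wtm = float(rng.uniform(0.4, 0.95))
        pid = f"md{i:03d}"
        entries.append(
            {
                "protein_id": pid,
                "profile": ConfidenceProfile(protein_id=pid, plddt=plddt),
                "best_high_coverage_identity": identity,
                "weighted_tm": wtm,
            }
        )
        if n_conf >= 600 and n_conf > 0.5 * length and not has_template:
            pass_ids.append(pid)
    return entries, {"pass_ids": pass_ids}


def make_hit_table(
    seq_len: int = 200, n_hits: int = 12, seed: int = 0, query_id: str = "Q1"
) -> tuple[pd.DataFrame, dict]:
    """Random template-hit table with brute-force per-residue identity maxima."""
    rng = np.random.default_rng([seed, 41])
    rows = []
    for _ in range(n_hits):
        start = int(rng.integers(1, seq_len))
        end = int(rng.integers(start, seq_len + 1))
        rows.append(
            {
                "query_id": query_id,
                "query_start": start,
                "query_end": end,
                "identity_pct": float(np.round(rng.uniform(10, 95), 1)),
                "coverage_pct": float(np.round(100.0 * (end - start + 1) / seq_len, 1)),
                "template_release_date": "2017-06-01",
            }
        )
    df = pd.DataFrame(rows)
    expected = np.zeros(seq_len)
    for pos in range(1, seq_len + 1):  # independent per-position maximum
        best = 0.0
        for row in rows:
            if row["query_start"] <= pos <= row["query_end"]:
                best = max(best, row["identity_pct"])
        expected[pos - 1] = best
    return df, {"per_residue_max": expected}


def recent_pdb_fixture() -> tuple[pd.DataFrame, dict]:
    """12 chain-metadata records exercising each evaluation-set rule once.

    Hand-traced outcome: c01 release-date, c02 single-residue, c03 ambiguous
    component, c04 missing cluster, c06 duplicate of c05 with fewer resolved
    residues, c07 too few resolved, c08 unknown residues, c09 NMR, c10 loses
    the cluster-K10 resolution tie to c11. Survivors: c05, c11, c12.
    """
    base = {
        "release_date": "2019-06-01",
        "method": "xray",
        "has_ambiguous_component": False,
        "n_resolved": 100,
    }
    seq = "ACDEFGHIKLMNPQRSTVWY" * 5
    rows = [
        {**base, "chain_id": "c01", "release_date": "2018-04-30",
         "sequence": seq + "A", "cluster40_id": "K01", "resolution": 2.0},
        {**base, "chain_id": "c02", "sequence": "A", "cluster40_id": "K02", "resolution": 2.0},
        {**base, "chain_id": "c03", "sequence": seq + "C", "cluster40_id": "K03",
         "resolution": 2.0, "has_ambiguous_component": True},
        {**base, "chain_id": "c04", "sequence": seq + "D", "cluster40_id": None, "resolution": 2.0},
        {**base, "chain_id": "c05", "sequence": seq + "E", "cluster40_id": "K05",
         "resolution": 2.0, "n_resolved": 120},
        {**base, "chain_id": "c06", "sequence": seq + "E", "cluster40_id": "K05",
         "resolution": 1.0, "n_resolved": 80},
        {**base, "chain_id": "c07", "sequence": seq + "F", "cluster40_id": "K07",
         "resolution": 2.0, "n_resolved": 10},
        {**base, "chain_id": "c08", "sequence": seq + "X", "cluster40_id": "K08", "resolution": 2.0},
        {**base, "chain_id": "c09", "sequence": seq + "H", "cluster40_id": "K09",
         "resolution": None, "method": "nmr"},
        {**base, "chain_id": "c10", "sequence": seq + "I", "cluster40_id": "K10", "resolution": 2.5},
        {**base, "chain_id": "c11", "sequence": seq + "K", "cluster40_id": "K10", "resolution": 1.8},
        {**base, "chain_id": "c12", "sequence": seq + "L", "cluster40_id": "K12", "resolution": 1.5},
    ]
    truth = {
        "survivors": ["c05", "c11", "c12"],
        "drops": {
            "c01": "rule1_release_date",
            "c02": "rule2_single_residue",
            "c03": "rule3_ambiguous_component",
            "c04": "rule4_no_cluster",
            "c06": "rule5_duplicate_sequence",
            "c07": "rule6_too_few_resolved",
            "c08": "rule7_unknown_residues",
            "c09": "rule8_nmr",
            "c10": "rule9_cluster_redundancy",
        },
    }
    return pd.DataFrame(rows), truth


def order_sensitivity_fixture() -> tuple[pd.DataFrame, dict]:
    """Two duplicate-sequence records where swapping rules 5 and 9 flips the survivor.

    In the documented rule order, deduplication keeps X (more resolved residues,
    120 vs 80) and redundancy reduction then keeps it trivially. Applying
    redundancy reduction first would keep Y (better resolution, 1.5 vs 3.0).
    """
    seq = "ACDEFGHIKLMNPQRSTVWY" * 3
    rows = [
        {"chain_id": "X", "release_date": "2019-06-01", "method": "xray", "resolution": 3.0,
         "cluster40_id": "K", "n_resolved": 120, "sequence": seq, "has_ambiguous_component": False},
        {"chain_id": "Y", "release_date": "2019-06-01", "method": "xray", "resolution": 1.5,
         "cluster40_id": "K", "n_resolved": 80, "sequence": seq, "has_ambiguous_component": False},
    ]
    return pd.DataFrame(rows), {"survivors_in_order": ["X"], "survivors_reordered": ["Y"]}


_TOY_OBO = """format-version: 1.2
ontology: toy

[Term]
id: GO:0000001
name: catalytic activity
namespace: molecular_function

[Term]
id: GO:0000002
name: hydrolase activity
namespace: molecular_function
is_a: GO:0000001 ! catalytic activity

[Term]
id: GO:0000003
name: ligase activity
namespace: molecular_function
is_a: GO:0000001 ! catalytic activity

[Term]
id: GO:0000004
name: peptidase activity
namespace: molecular_function
is_a: GO:0000002 ! hydrolase activity

[Term]
id: GO:0000005
name: metallopeptidase activity
namespace: molecular_function
relationship: part_of GO:0000004 ! peptidase activity

[Term]
id: GO:0000006
name: membrane
namespace: cellular_component
alt_id: GO:0000106

[Term]
id: GO:0000007
name: transporter activity
namespace: molecular_function
is_a: GO:0000001 ! catalytic activity

[Term]
id: GO:0000008
name: retired term
namespace: molecular_function
is_obsolete: true
"""


def toy_ontology_obo() -> str:
    """OBO text of the hand-designed toy ontology (see toy_ontology_fixture)."""
    return _TOY_OBO


def toy_ontology_fixture() -> dict:
    """Toy ontology plus designed counts and the hand-derived display answer.

    The count table gives GO:0000001 5000, GO:0000002 4000, GO:0000003 2500,
    GO:0000004 3500, GO:0000005 1000, GO:0000006 3001, GO:0000007 40. With a
    threshold of 3000, GO:0000001 and GO:0000002 fail the moderately-specific
    rule (each has a child above threshold), leaving GO:0000004 and
    GO:0000006.
    """
    counts = {
        "GO:0000001": 5000,
        "GO:0000002": 4000,
        "GO:0000003": 2500,
        "GO:0000004": 3500,
        "GO:0000005": 1000,
        "GO:0000006": 3001,
        "GO:0000007": 40,
    }
    annotations = {
        "P1": {"GO:0000005"},
        "P2": {"GO:0000106"},  # alt id of GO:0000006
        "P3": {"GO:0000003", "GO:0000004"},
    }
    expected_propagated = {
        "P1": {"GO:0000005", "GO:0000004", "GO:0000002", "GO:0000001"},
        "P2": {"GO:0000006"},
        "P3": {"GO:0000003", "GO:0000004", "GO:0000002", "GO:0000001"},
    }
    return {
        "obo": _TOY_OBO,
        "counts": counts,
        "expected_display": ["GO:0000004", "GO:0000006"],
        "annotations": annotations,
        "expected_propagated": expected_propagated,
    }
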