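"""Structure-comparison metrics.

Implements the three scores used to judge predicted protein models:

* Kabsch least-squares superposition and RMSD;
* lDDT-C-alpha — a superposition-free local metric: for each residue, the
  fraction of reference C-alpha pair distances (within a 15 A inclusion
  radius) preserved by the model within tolerances {0.5, 1, 2, 4} A,
  averaged over tolerances and expressed on 0-100;
* TM-score — length-normalised global similarity, sum of 1/(1+(d_i/d0)^2)
  over corresponding residues divided by the reference length, maximised
  over superpositions found by a seed-and-extend search;
* resolvability-weighted aggregation of per-residue scores (the weighting
  behind predicted-TM-style summaries, where each residue contributes in
  proportion to its probability of being experimentally resolved).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .structure_io import StructureModel

__all__ = [
    "Superposition",
    "LddtResult",
    "TmResult",
    "kabsch_superpose",
    "lddt_ca",
    "lddt_ca_arrays",
    "tm_d0",
    "tm_score",
    "weighted_aggregate",
]


@dataclass
class Superposition:
    rotation: np.ndarray     # 3x3, det +1
    translation: np.ndarray  # 3-vector, Angstrom
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class LddtResult:
    per_residue: np.ndarray  # 0-100, NaN where unscorable
    global_lddt: float
    inclusion_radius: float
    thresholds: tuple[float, ...]


@dataclass
class TmResult:
    score: float
    d0: float
    aligned_length: int
    reference_length: int
    superposition: Optional[Superposition] = None


def kabsch_superpose(moving: np.ndarray, fixed: np.ndarray) -> Superposition:
    """Least-squares rigid superposition of ``moving`` onto ``fixed``.

    Returns the rotation/translation minimising RMSD over the paired points,
    with a proper rotation (det = +1) enforced via the standard sign
    correction of the smallest singular vector.
    """
    moving = np.asarray(moving, dtype=float)
    fixed = np.asarray(fixed, dtype=float)
    if moving.shape != fixed.shape or moving.ndim != 2 or moving.shape[1] != 3:
        raise ValueError("paired Nx3 coordinate arrays required")
    n = moving.shape[0]
    if n < 3:
        raise ValueError("at least 3 paired points required")
    mc = moving.mean(axis=0)
    fc = fixed.mean(axis=0)
    m0 = moving - mc
    f0 = fixed - fc
    h = m0.T @ f0
    # collinear (rank < 2) point sets do not determine a rotation
    if np.linalg.matrix_rank(m0, tol=1e-9) < 2 or np.linalg.matrix_rank(f0, tol=1e-9) < 2:
        raise ValueError("degenerate (collinear) input")
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rot = vt.T @ diag @ u.T
    trans = fc - rot @ mc
    moved = m0 @ rot.T
    rmsd = float(np.sqrt(np.mean(np.sum((moved - f0) ** 2, axis=1))))
    return Superposition(rotation=rot, translation=trans, rmsd=rmsd)


def lddt_ca_arrays(
    ref_coords: np.ndarray,
    model_coords: np.ndarray,
    inclusion_radius: float = 15.0,
    thresholds: Sequence[float] = (0.5, 1.0, 2.0, 4.0),
) -> LddtResult:
    """lDDT-C-alpha over two position-aligned coordinate arrays.

    Arrays are (N, 3); unresolved positions are NaN rows. The reference
    defines both the scored residue set and the pair inclusion (reference
    distance < inclusion_radius, i != j). Pairs whose model side is missing
    count as violated at every tolerance. Residues with no scorable pair are
    NaN in ``per_residue`` and excluded from the global mean.
    """
    ref = np.asarray(ref_coords, dtype=float)
    mod = np.asarray(model_coords, dtype=float)
    if ref.shape != mod.shape:
        raise ValueError("reference and model arrays must align position-wise")
    n = ref.shape[0]
    ref_ok = ~np.isnan(ref).any(axis=1)
    mod_ok = ~np.isnan(mod).any(axis=1)
    thresholds = tuple(float(t) for t in thresholds)

    dref = np.linalg.norm(ref[:, None, :] - ref[None, :, :], axis=-1)
    dmod = np.linalg.norm(mod[:, None, :] - mod[None, :, :], axis=-1)
    pair_mask = (
        ref_ok[:, None]
        & ref_ok[None, :]
        & (dref < inclusion_radius)
        & ~np.eye(n, dtype=bool)
    )
    both_mod = mod_ok[:, None] & mod_ok[None, :]
    diff = np.abs(dmod - dref)

    per_residue = np.full(n, np.nan)
    for i in range(n):
        cols = np.flatnonzero(pair_mask[i])
        if cols.size == 0:
            continue
        preserved = np.zeros(cols.size)
        usable = both_mod[i, cols]
        for t in thresholds:
            preserved += np.where(usable, diff[i, cols] < t, False)
        per_residue[i] = 100.0 * preserved.mean() / len(thresholds)
    scored = ~np.isnan(per_residue)
    global_lddt = float(per_residue[scored].mean()) if scored.any() else float("nan")
    return LddtResult(
        per_residue=per_residue,
        global_lddt=global_lddt,
        inclusion_radius=inclusion_radius,
        thresholds=thresholds,
    )


def _chain_coord_table(
    reference: StructureModel,
    model: StructureModel,
    chain_id: Optional[str],
) -> tuple[np.ndarray, np.ndarray]:
    """Position-aligned C-alpha arrays keyed by seq_index (NaN = unresolved)."""
    ref_chain = chain_id or reference.chains[0]
    mod_chain = chain_id or model.chains[0]
    ref_res = {r.seq_index: r for r in reference.chain_residues(ref_chain)}
    mod_res = {r.seq_index: r for r in model.chain_residues(mod_chain)}
    indices = sorted(set(ref_res) | set(mod_res))
    ref_arr = np.full((len(indices), 3), np.nan)
    mod_arr = np.full((len(indices), 3), np.nan)
    for k, idx in enumerate(indices):
        r = ref_res.get(idx)
        if r is not None and r.resolved and r.ca_coord is not None:
            ref_arr[k] = r.ca_coord
        m = mod_res.get(idx)
        if m is not None and m.resolved and m.ca_coord is not None:
            mod_arr[k] = m.ca_coord
    return ref_arr, mod_arr


def lddt_ca(
    reference: StructureModel,
    model: StructureModel,
    chain_id: Optional[str] = None,
    inclusion_radius: float = 15.0,
    thresholds: Sequence[float] = (0.5, 1.0, 2.0, 4.0),
) -> LddtResult:
    """lDDT-C-alpha of ``model`` against ``reference`` for one chain.

    Residue correspondence is by seq_index (same sequence, no alignment).
    The reference's resolved residues define the scored set, so the metric
    is directional: swapping arguments changes the scored pairs.
    """
    ref_arr, mod_arr = _chain_coord_table(reference, model, chain_id)
    return lddt_ca_arrays(ref_arr, mod_arr, inclusion_radius, thresholds)


def tm_d0(L: int) -> float:
    """TM-score length normalisation d0(L) = 1.24 (L-15)^(1/3) - 1.8, floored at 0.5 A."""
    if L < 1:
        raise ValueError("L must be >= 1")
    if L <= 21:
        return 0.5
    return max(0.5, 1.24 * (L - 15.0) ** (1.0 / 3.0) - 1.8)


def _tm_from_superposition(
    sup: Superposition, ref: np.ndarray, mod: np.ndarray, d0: float, l_ref: int
) -> float:
    d = np.linalg.norm(sup.apply(mod) - ref, axis=1)
    return float(np.sum(1.0 / (1.0 + (d / d0) ** 2)) / l_ref)


def _refine_tm(
    ref: np.ndarray,
    mod: np.ndarray,
    seed: np.ndarray,
    d0: float,
    l_ref: int,
    cutoff: float,
    max_iter: int = 20,
) -> float:
    """Iteratively re-superpose on the close-pair subset until stable.

    The score is taken from the converged superposition, so every seed whose
    refinement reaches the same stable pair set contributes the same score.
    """
    included = seed
    sup = None
    for _ in range(max_iter):
        if included.size < 3:
            break
        try:
            sup = kabsch_superpose(mod[included], ref[included])
        except ValueError:
            break
        d = np.linalg.norm(sup.apply(mod) - ref, axis=1)
        new_included = np.flatnonzero(d < cutoff)
        if new_included.size >= 3 and not np.array_equal(new_included, included):
            included = new_included
        else:
            break
    if sup is None:
        return -1.0
    return _tm_from_superposition(sup, ref, mod, d0, l_ref)


def tm_score(
    reference: np.ndarray,
    model: np.ndarray,
    correspondence: Optional[np.ndarray] = None,
    reference_length: Optional[int] = None,
    max_iter: int = 20,
) -> TmResult:
    """TM-score of model vs reference coordinates under a fixed correspondence.

    The search superposes on every contiguous seed fragment of lengths
    L, L/2 and L/4 (minimum 4), then iteratively re-superposes on the pairs
    closer than the inclusion cutoff max(d0, 2 A) until the included set is
    stable, keeping the best score seen. Normalisation is by the reference
    length with the standard d0 (floored at 0.5 A for short chains).
    """
    ref = np.asarray(reference, dtype=float)
    mod = np.asarray(model, dtype=float)
    if correspondence is not None:
        corr = np.asarray(correspondence, dtype=int)
        ref = ref[corr[:, 0]]
        mod = mod[corr[:, 1]]
    if ref.shape != mod.shape:
        raise ValueError("reference and model must pair one-to-one")
    n = ref.shape[0]
    if n < 4:
        raise ValueError("at least 4 corresponding pairs required")
    l_ref = int(reference_length) if reference_length else n
    d0 = tm_d0(l_ref)
    cutoff = max(d0, 2.0)

    seed_lengths = sorted({n, max(4, n // 2), max(4, n // 4)}, reverse=True)
    best = -1.0
    for sl in seed_lengths:
        for start in range(0, n - sl + 1):
            seed = np.arange(start, start + sl)
            best = max(best, _refine_tm(ref, mod, seed, d0, l_ref, cutoff, max_iter))
    sup = kabsch_superpose(mod, ref)  # reported superposition: all-pair fit
    return TmResult(
        score=best,
        d0=d0,
        aligned_length=n,
        reference_length=l_ref,
        superposition=sup,
    )


def weighted_aggregate(per_residue_scores: np.ndarray, weights: np.ndarray) -> float:
    """Weighted mean sum(w s)/sum(w) of per-residue scores.

    With weights equal to resolvability probabilities this is the weighted
    aggregation used to summarise a per-residue score into a single
    chain-level number that downweights unstructured regions.
    """
    s = np.asarray(per_residue_scores, dtype=float)
    w = np.asarray(weights, dtype=float)
    if s.shape != w.shape:
        raise ValueError("scores and weights must have equal length")
    total = w.sum()
    if total <= 0:
        raise ValueError("weights must have positive sum")
    return float(np.sum(w * s) / total)
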