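"""Independent reference implementations used only to check the library.

Each oracle recomputes a quantity by direct enumeration or a different
algorithm (quaternion superposition, exhaustive seeds, transitive closure),
sharing no code with the implementation under test.
"""
from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation


def brute_lddt(
    ref: np.ndarray,
    mod: np.ndarray,
    radius: float = 15.0,
    thresholds=(0.5, 1.0, 2.0, 4.0),
) -> tuple[np.ndarray, float]:
    """Per-residue lDDT by direct all-pairs enumeration (NaN rows = unresolved)."""
    n = len(ref)
    per = np.full(n, np.nan)
    for i in range(n):
        if np.isnan(ref[i]).any():
            continue
        hits = 0
        total = 0
        for j in range(n):
            if j == i or np.isnan(ref[j]).any():
                continue
            dref = float(np.sqrt(((ref[i] - ref[j]) ** 2).sum()))
            if dref >= radius:
                continue
            for t in thresholds:
                total += 1
                if np.isnan(mod[i]).any() or np.isnan(mod[j]).any():
                    continue
                dmod = float(np.sqrt(((mod[i] - mod[j]) ** 2).sum()))
                if abs(dmod - dref) < t:
                    hits += 1
        if total:
            per[i] = 100.0 * hits / total
    scored = per[~np.isnan(per)]
    return per, float(scored.mean()) if scored.size else float("nan")


def quaternion_rmsd(moving: np.ndarray, fixed: np.ndarray) -> float:
    """Minimum RMSD via Horn's closed-form quaternion method."""
    m = moving - moving.mean(axis=0)
    f = fixed - fixed.mean(axis=0)
    s = m.T @ f
    sxx, sxy, sxz = s[0]
    syx, syy, syz = s[1]
    szx, szy, szz = s[2]
    k = np.array(
        [
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
            [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
            [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
        ]
    )
    lam = np.linalg.eigvalsh(k)[-1]
    n = m.shape[0]
    sq = ((m**2).sum() + (f**2).sum() - 2.0 * lam) / n
    return float(np.sqrt(max(sq, 0.0)))


def _align(mov: np.ndarray, fix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mc, fc = mov.mean(axis=0), fix.mean(axis=0)
    rot, _ = Rotation.align_vectors(fix - fc, mov - mc)
    rm = rot.as_matrix()
    return rm, fc - rm @ mc


def exhaustive_tm(ref: np.ndarray, mod: np.ndarray, max_iter: int = 20) -> float:
    """TM-score via every contiguous seed (length >= 4) and subset-stable refinement."""
    n = len(ref)
    l_ref = n
    d0 = 0.5 if l_ref <= 21 else max(0.5, 1.24 * (l_ref - 15.0) ** (1.0 / 3.0) - 1.8)
    cutoff = max(d0, 2.0)
    best = -1.0
    for seed_len in range(4, n + 1):
        for start in range(0, n - seed_len + 1):
            included = np.arange(start, start + seed_len)
            rm = trans = None
            for _ in range(max_iter):
                if included.size < 3:
                    break
                rm, trans = _align(mod[included], ref[included])
                d = np.linalg.norm(mod @ rm.T + trans - ref, axis=1)
                new = np.flatnonzero(d < cutoff)
                if new.size >= 3 and not np.array_equal(new, included):
                    included = new
                else:
                    break
            if rm is None:
                continue
            d = np.linalg.norm(mod @ rm.T + trans - ref, axis=1)
            best = max(best, float(np.sum(1.0 / (1.0 + (d / d0) ** 2)) / l_ref))
    return best


def pair_count_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC by counting all positive x negative score pairs (ties count half)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def brute_contacts(model, cutoff: float = 8.0, min_sep: int = 4):
    """All-pairs contact set {(key_a, key_b): class} by double loop."""
    res = [r for r in model.residues if r.resolved]
    out = {}
    for i in range(len(res)):
        a = res[i]
        pa = a.ca_coord if a.aa_code == "G" or a.cb_coord is None else a.cb_coord
        for j in range(i + 1, len(res)):
            b = res[j]
            pb = b.ca_coord if b.aa_code == "G" or b.cb_coord is None else b.cb_coord
            if a.chain_id == b.chain_id and abs(a.seq_index - b.seq_index) < min_sep:
                continue
            if float(np.linalg.norm(pa - pb)) > cutoff:
                continue
            if a.chain_id == b.chain_id:
                cls = "intra_chain"
            elif a.entity_id == b.entity_id:
                cls = "homomeric"
            else:
                cls = "heterotypic"
            ka = (a.chain_id, a.seq_index)
            kb = (b.chain_id, b.seq_index)
            if kb < ka:
                ka, kb = kb, ka
            out[(ka, kb)] = cls
    return out


def brute_regions(values: np.ndarray, predicate: str, threshold: float, min_len: int):
    """Maximal runs by per-index membership checking."""
    import operator

    cmp = {"gt": operator.gt, "ge": operator.ge, "lt": operator.lt, "le": operator.le}[predicate]
    member = [bool(cmp(v, threshold)) for v in values]
    runs = []
    i = 0
    n = len(member)
    while i < n:
        if member[i]:
            j = i
            while j + 1 < n and member[j + 1]:
                j += 1
            if j - i + 1 >= min_len:
                runs.append((i + 1, j + 1))
            i = j + 1
        else:
            i += 1
    return runs


def transitive_ancestors(parents: dict[str, set[str]], term: str) -> set[str]:
    """Ancestor set by repeated expansion until fixpoint."""
    out: set[str] = set()
    frontier = set(parents.get(term, set()))
    while frontier:
        out |= frontier
        frontier = set().union(*(parents.get(t, set()) for t in frontier)) - out
    return out
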