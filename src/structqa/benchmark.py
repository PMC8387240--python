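"""Statistical evaluation: disorder ROC/AUC, confidence calibration, CAID preprocessing.

AUC is computed from the Mann-Whitney rank statistic with midrank tie
handling, so it equals the probability that a random disordered residue
outscores a random ordered one, plus half the tie probability. Calibration
of predicted confidence against observed lDDT-C-alpha is an ordinary
least-squares fit with percentile-bootstrap confidence intervals over
residues.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "LabelledScores",
    "CalibrationFit",
    "roc_auc",
    "roc_curve",
    "calibration_fit",
    "binned_calibration",
    "caid_preprocess",
    "concat_segment_scores",
    "read_caid_reference",
]


@dataclass
class LabelledScores:
    """Per-residue scores with binary labels (1 = disordered).

    ``mask`` selects the scorable residues; by default all are scored.
    """

    scores: np.ndarray
    labels: np.ndarray
    mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.scores.shape != self.labels.shape:
            raise ValueError("scores and labels must have equal length")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.scores.shape:
                raise ValueError("mask must align with scores")

    def masked(self) -> tuple[np.ndarray, np.ndarray]:
        if self.mask is None:
            return self.scores, self.labels
        return self.scores[self.mask], self.labels[self.mask]


@dataclass
class CalibrationFit:
    slope: float
    intercept: float
    pearson_r: float
    ci_slope: tuple[float, float]
    ci_intercept: tuple[float, float]
    n_boot: int
    seed: int


def roc_auc(data: LabelledScores) -> float:
    """Area under the ROC curve via the rank (Mann-Whitney U) statistic."""
    scores, labels = data.masked()
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes among scored residues")
    ranks = rankdata(scores)  # midranks for ties
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def roc_curve(data: LabelledScores) -> pd.DataFrame:
    """ROC points (fpr, tpr, threshold) at every distinct score."""
    scores, labels = data.masked()
    order = np.argsort(-scores, kind="mergesort")
    s, y = scores[order], labels[order]
    distinct = np.r_[np.flatnonzero(np.diff(s)), s.size - 1]
    tp = np.cumsum(y)[distinct]
    fp = np.cumsum(1 - y)[distinct]
    return pd.DataFrame(
        {"fpr": fp / max(fp[-1], 1), "tpr": tp / max(tp[-1], 1), "threshold": s[distinct]}
    )


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    xm, ym = x.mean(), y.mean()
    vx = np.mean(x * x) - xm * xm
    slope = (np.mean(x * y) - xm * ym) / vx
    return slope, ym - slope * xm


def calibration_fit(
    predicted: np.ndarray,
    observed: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
    ci_level: float = 95.0,
) -> CalibrationFit:
    """OLS fit of observed accuracy on predicted confidence, with bootstrap CIs.

    Resamples residues with replacement ``n_boot`` times (seeded) and
    reports percentile confidence intervals for slope and intercept.
    """
    x = np.asarray(predicted, dtype=float)
    y = np.asarray(observed, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need paired arrays of length >= 3")
    if np.var(x) == 0:
        raise ValueError("zero variance in predicted values")
    slope, intercept = _ols(x, y)
    r = float(np.corrcoef(x, y)[0, 1])

    rng = np.random.default_rng(seed)
    n = x.size
    slopes = np.empty(n_boot)
    intercepts = np.empty(n_boot)
    # resampling with replacement == multiplicity weights; bincount keeps the
    # per-replicate cost at O(n) instead of an O(n) random gather
    xx = x * x
    xy = x * y
    for b in range(n_boot):
        w = np.bincount(rng.integers(0, n, size=n), minlength=n).astype(float)
        xm = w @ x / n
        ym = w @ y / n
        vx = w @ xx / n - xm * xm
        sl = (w @ xy / n - xm * ym) / vx
        slopes[b] = sl
        intercepts[b] = ym - sl * xm
    lo = (100.0 - ci_level) / 2.0
    hi = 100.0 - lo
    return CalibrationFit(
        slope=float(slope),
        intercept=float(intercept),
        pearson_r=r,
        ci_slope=(float(np.percentile(slopes, lo)), float(np.percentile(slopes, hi))),
        ci_intercept=(
            float(np.percentile(intercepts, lo)),
            float(np.percentile(intercepts, hi)),
        ),
        n_boot=n_boot,
        seed=seed,
    )


def binned_calibration(
    predicted: np.ndarray,
    observed: np.ndarray,
    bin_width: float = 5.0,
) -> pd.DataFrame:
    """Mean observed accuracy within right-open predicted-confidence bins over [0, 100]."""
    x = np.asarray(predicted, dtype=float)
    y = np.asarray(observed, dtype=float)
    edges = np.arange(0.0, 100.0 + bin_width, bin_width)
    idx = np.clip(np.digitize(x, edges, right=False) - 1, 0, len(edges) - 2)
    rows = []
    for b in range(len(edges) - 1):
        sel = y[idx == b]
        if sel.size == 0:
            continue
        rows.append(
            {
                "bin_low": edges[b],
                "bin_high": edges[b + 1],
                "mean_observed": float(sel.mean()),
                "count": int(sel.size),
            }
        )
    return pd.DataFrame(rows)


_STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")


def caid_preprocess(sequence: str, max_len: int = 2000) -> tuple[list[tuple[int, int]], str]:
    """Disorder-benchmark sequence preprocessing.

    Non-standard residues X and U are remapped to glycine; any other
    non-standard code is an error. Sequences longer than ``max_len`` are
    split into two segments, 1..max_len and max_len+1..end (1-based,
    inclusive), so that per-segment score arrays concatenate back to the
    full length. Returns (segments, remapped_sequence).
    """
    remapped = sequence.replace("X", "G").replace("U", "G")
    bad = [i + 1 for i, c in enumerate(remapped) if c not in _STANDARD_AA]
    if bad:
        raise ValueError(f"non-standard residue codes at positions {bad}")
    n = len(remapped)
    if n <= max_len:
        segments = [(1, n)]
    else:
        segments = [(1, max_len), (max_len + 1, n)]
    return segments, remapped


def concat_segment_scores(
    segments: Sequence[tuple[int, int]], segment_scores: Sequence[np.ndarray]
) -> np.ndarray:
    """Stitch per-segment score arrays back into one full-length array."""
    if len(segments) != len(segment_scores):
        raise ValueError("one score array per segment required")
    parts = []
    for (start, end), arr in zip(segments, segment_scores):
        arr = np.asarray(arr, dtype=float)
        if arr.size != end - start + 1:
            raise ValueError(f"segment {start}-{end} expects {end - start + 1} scores")
        parts.append(arr)
    return np.concatenate(parts) if parts else np.empty(0)


def read_caid_reference(path: str | Path) -> dict[str, tuple[str, np.ndarray, np.ndarray]]:
    """Read a disorder reference file: >id / sequence / 0,1,- label line.

    Returns id -> (sequence, labels, mask) where '-' positions are masked
    out (label 0, mask False).
    """
    out: dict[str, tuple[str, np.ndarray, np.ndarray]] = {}
    lines = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    i = 0
    while i < len(lines):
        if not lines[i].startswith(">"):
            raise ValueError(f"expected header at line {i + 1}")
        pid = lines[i][1:].split()[0]
        seq, lab = lines[i + 1], lines[i + 2]
        if len(seq) != len(lab):
            raise ValueError(f"{pid}: sequence/label length mismatch")
        labels = np.array([1 if c == "1" else 0 for c in lab])
        mask = np.array([c in "01" for c in lab])
        out[pid] = (seq, labels, mask)
        i += 3
    return out
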