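"""Confidence banding, coverage statistics, disorder scoring and region finding.

The four-way confidence partition follows the standard pLDDT interpretation:
pLDDT > 90 marks very high accuracy (side chains frequently correct),
pLDDT > 70 a generally correct backbone, and pLDDT < 50 a strong signal of
disorder rather than structure. Band assignment uses strict inequalities at
the upper boundaries, so 90.0 falls in "confident" and 70.0 in "low".
"""
from __future__ import annotations

import logging
import operator
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .structure_io import ConfidenceProfile

logger = logging.getLogger(__name__)

BAND_LABELS = ("very_high", "confident", "low", "very_low")
#: upper-boundary cut-offs of the partition of [0, 100]
BAND_CUTOFFS = (90.0, 70.0, 50.0)

_COMPARATORS = {"gt": operator.gt, "ge": operator.ge, "lt": operator.lt, "le": operator.le}

__all__ = [
    "BAND_LABELS",
    "BAND_CUTOFFS",
    "BandSummary",
    "Region",
    "MultidomainEntry",
    "MultidomainResult",
    "assign_band",
    "band_summary",
    "confident_fraction",
    "fraction_mostly_confident",
    "disorder_score",
    "find_regions",
    "multidomain_candidates",
]


@dataclass
class BandSummary:
    residue_counts: dict[str, int]
    total_residues: int

    @property
    def fractions(self) -> dict[str, float]:
        return {k: v / self.total_residues for k, v in self.residue_counts.items()}


@dataclass(frozen=True)
class Region:
    protein_id: str
    start: int  # 1-based inclusive
    end: int    # inclusive

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def assign_band(plddt: float) -> str:
    """Band label for one pLDDT value (very_high / confident / low / very_low)."""
    if not (0.0 <= plddt <= 100.0):
        raise ValueError(f"plddt {plddt} outside [0, 100]")
    if plddt > 90.0:
        return "very_high"
    if plddt > 70.0:
        return "confident"
    if plddt >= 50.0:
        return "low"
    return "very_low"


def _band_counts(values: np.ndarray) -> dict[str, int]:
    return {
        "very_high": int(np.sum(values > 90.0)),
        "confident": int(np.sum((values > 70.0) & (values <= 90.0))),
        "low": int(np.sum((values >= 50.0) & (values <= 70.0))),
        "very_low": int(np.sum(values < 50.0)),
    }


def band_summary(profiles: Iterable[ConfidenceProfile]) -> BandSummary:
    """Residue counts and fractions per confidence band over a set of profiles."""
    profiles = list(profiles)
    if not profiles:
        raise ValueError("band_summary requires at least one profile")
    counts = {label: 0 for label in BAND_LABELS}
    total = 0
    for p in profiles:
        for label, c in _band_counts(p.plddt).items():
            counts[label] += c
        total += p.length
    if total == 0:
        raise ValueError("band_summary requires at least one residue")
    return BandSummary(residue_counts=counts, total_residues=total)


def confident_fraction(profile: ConfidenceProfile, threshold: float = 70.0) -> float:
    """Fraction of residues predicted confidently (pLDDT strictly above threshold)."""
    if profile.length == 0:
        raise ValueError("empty profile")
    return float(np.mean(profile.plddt > threshold))


def fraction_mostly_confident(
    profiles: Iterable[ConfidenceProfile],
    min_fraction: float = 0.75,
    threshold: float = 70.0,
) -> float:
    """Fraction of proteins confidently predicted on at least ``min_fraction`` of their sequence."""
    profiles = list(profiles)
    if not profiles:
        raise ValueError("no profiles")
    passing = sum(confident_fraction(p, threshold) >= min_fraction for p in profiles)
    return passing / len(profiles)


def disorder_score(profile: ConfidenceProfile) -> np.ndarray:
    """Per-residue disorder propensity, 1 - 0.01 x pLDDT (in [0, 1])."""
    return 1.0 - 0.01 * profile.plddt


def find_regions(
    profile: ConfidenceProfile,
    predicate: str,
    threshold: float,
    min_len: int = 1,
) -> list[Region]:
    """Maximal contiguous runs where ``plddt <predicate> threshold`` holds.

    ``predicate`` is one of gt/ge/lt/le. Runs shorter than ``min_len`` are
    dropped; regions are 1-based inclusive and ordered by start.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    cmp = _COMPARATORS[predicate]
    mask = cmp(profile.plddt, threshold)
    regions: list[Region] = []
    start = None
    for i, ok in enumerate(mask):
        if ok and start is None:
            start = i
        elif not ok and start is not None:
            regions.append(Region(profile.protein_id, start + 1, i))
            start = None
    if start is not None:
        regions.append(Region(profile.protein_id, start + 1, len(mask)))
    return [r for r in regions if r.length >= min_len]


@dataclass
class MultidomainEntry:
    """One candidate for the multi-domain screen.

    ``best_high_coverage_identity`` is the highest sequence identity of any
    template hit covering more than half the sequence; 0 means no such hit,
    None means the template information is missing.
    """

    protein_id: str
    profile: ConfidenceProfile
    best_high_coverage_identity: Optional[float]
    weighted_tm: Optional[float] = None


@dataclass
class MultidomainResult:
    kept: list[MultidomainEntry]             # sorted by confident residues, desc
    confident_counts: dict[str, int]
    n_above: dict[float, int]                # weighted-TM threshold -> count
    skipped: list[str]


def multidomain_candidates(
    entries: Iterable[MultidomainEntry],
    min_confident_residues: int = 600,
    min_confident_fraction: float = 0.5,
    plddt_threshold: float = 70.0,
    tm_thresholds: Sequence[float] = (0.7, 0.8),
) -> MultidomainResult:
    """Screen for likely-novel multi-domain predictions.

    Keeps entries with pLDDT > 70 on at least 600 residues constituting over
    half the sequence, and no template hit covering more than half the
    sequence. Reports how many kept entries clear each weighted-TM threshold.
    """
    kept: list[MultidomainEntry] = []
    counts: dict[str, int] = {}
    skipped: list[str] = []
    for e in entries:
        if e.best_high_coverage_identity is None:
            logger.warning("skipping %s: missing template information", e.protein_id)
            skipped.append(e.protein_id)
            continue
        n_conf = int(np.sum(e.profile.plddt > plddt_threshold))
        if (
            n_conf >= min_confident_residues
            and n_conf > min_confident_fraction * e.profile.length
            and e.best_high_coverage_identity == 0
        ):
            kept.append(e)
            counts[e.protein_id] = n_conf
    kept.sort(key=lambda e: counts[e.protein_id], reverse=True)
    n_above = {
        t: sum(1 for e in kept if e.weighted_tm is not None and e.weighted_tm > t)
        for t in tm_thresholds
    }
    return MultidomainResult(kept=kept, confident_counts=counts, n_above=n_above, skipped=skipped)
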