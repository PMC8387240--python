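"""Template-coverage scoring and evaluation-dataset filtering rules.

Template coverage is computed from tabular homology-hit records (query
interval, percent identity, percent query coverage, template release date)
rather than by running the search tool, so the rule logic is testable in
isolation. The evaluation-set filter reproduces, in order, the chain-level
exclusion rules used to build a held-out recent-PDB test set: release-date
cutoff, degenerate sequences, ambiguous components, missing 40% sequence
clustering, exact-duplicate collapse by resolved-residue count, minimum
resolved residues, unknown residues, NMR exclusion, and per-cluster
redundancy reduction by best non-zero resolution.
"""
from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TemplateHit",
    "ChainRecord",
    "per_residue_template_identity",
    "best_high_coverage_identity",
    "recent_pdb_filter",
    "long_chain_subset",
    "RECENT_PDB_DATE_CUTOFF",
]

RECENT_PDB_DATE_CUTOFF = dt.date(2018, 4, 30)


@dataclass(frozen=True)
class TemplateHit:
    query_id: str
    query_start: int  # 1-based inclusive
    query_end: int    # inclusive
    identity_pct: float
    coverage_pct: float
    template_release_date: Optional[dt.date] = None

    def __post_init__(self) -> None:
        if self.query_start > self.query_end:
            raise ValueError("query_start must be <= query_end")
        if not (0 <= self.identity_pct <= 100 and 0 <= self.coverage_pct <= 100):
            raise ValueError("percentages must be in [0, 100]")


@dataclass
class ChainRecord:
    chain_id: str
    release_date: dt.date
    method: str                      # xray / em / nmr / other
    resolution: Optional[float]      # Angstrom, None if not applicable
    cluster40_id: Optional[str]
    n_resolved: int
    sequence: str
    has_ambiguous_component: bool = False


def per_residue_template_identity(
    hits: Iterable[TemplateHit],
    seq_len: int,
    date_cutoff: Optional[dt.date] = None,
) -> np.ndarray:
    """Per-position maximum template identity over all hits covering each residue.

    Positions covered by no hit get 0. ``date_cutoff`` keeps only hits whose
    template was released strictly before the cutoff (undated hits are kept).
    """
    out = np.zeros(seq_len)
    for h in hits:
        if h.query_start < 1 or h.query_end > seq_len:
            raise ValueError(
                f"hit interval {h.query_start}-{h.query_end} outside [1, {seq_len}]"
            )
        if (
            date_cutoff is not None
            and h.template_release_date is not None
            and h.template_release_date >= date_cutoff
        ):
            continue
        lo, hi = h.query_start - 1, h.query_end
        out[lo:hi] = np.maximum(out[lo:hi], h.identity_pct)
    return out


def best_high_coverage_identity(
    hits: Iterable[TemplateHit], min_coverage: float = 50.0
) -> float:
    """Highest identity among hits covering strictly more than ``min_coverage`` %; 0 if none."""
    best = 0.0
    for h in hits:
        if h.coverage_pct > min_coverage:
            best = max(best, h.identity_pct)
    return best


_UNKNOWN_CODES = set("XBJOUZ")


def _has_unknown_residue(seq: str) -> bool:
    return any(c in _UNKNOWN_CODES for c in seq)


def recent_pdb_filter(
    records: Sequence[ChainRecord],
    date_cutoff: dt.date = RECENT_PDB_DATE_CUTOFF,
) -> tuple[list[ChainRecord], list[tuple[str, str]]]:
    """Build the held-out evaluation set; returns (survivors, drop audit).

    Rules apply strictly in order; the audit lists (chain_id, rule) for every
    dropped record so that survivors + drops partition the input.

    1. release_date strictly after the cutoff
    2. drop single-residue sequences
    3. drop chains with an ambiguous chemical component
    4. drop chains without a 40% sequence clustering id
    5. collapse exact-duplicate sequences, keeping the most resolved chain
    6. drop chains with fewer than 16 resolved residues
    7. drop sequences containing unknown residue codes
    8. drop NMR structures
    9. per cluster, keep the chain with the best (smallest) non-zero
       resolution; chains without a positive resolution lose ties, and a
       cluster with no positive resolution contributes nothing
    """
    audit: list[tuple[str, str]] = []
    current = list(records)

    def drop(rec: ChainRecord, rule: str) -> None:
        audit.append((rec.chain_id, rule))

    kept = []
    for r in current:
        (kept.append(r) if r.release_date > date_cutoff else drop(r, "rule1_release_date"))
    current = kept

    kept = []
    for r in current:
        (kept.append(r) if len(r.sequence) > 1 else drop(r, "rule2_single_residue"))
    current = kept

    kept = []
    for r in current:
        (drop(r, "rule3_ambiguous_component") if r.has_ambiguous_component else kept.append(r))
    current = kept

    kept = []
    for r in current:
        (kept.append(r) if r.cluster40_id else drop(r, "rule4_no_cluster"))
    current = kept

    # rule 5: exact duplicates -> keep most resolved (ties: first in input)
    best_by_seq: dict[str, ChainRecord] = {}
    for r in current:
        b = best_by_seq.get(r.sequence)
        if b is None or r.n_resolved > b.n_resolved:
            best_by_seq[r.sequence] = r
    kept = []
    for r in current:
        (kept.append(r) if best_by_seq[r.sequence] is r else drop(r, "rule5_duplicate_sequence"))
    current = kept

    kept = []
    for r in current:
        (kept.append(r) if r.n_resolved >= 16 else drop(r, "rule6_too_few_resolved"))
    current = kept

    kept = []
    for r in current:
        (drop(r, "rule7_unknown_residues") if _has_unknown_residue(r.sequence) else kept.append(r))
    current = kept

    kept = []
    for r in current:
        (drop(r, "rule8_nmr") if r.method == "nmr" else kept.append(r))
    current = kept

    # rule 9: redundancy reduction by best non-zero resolution per cluster
    best_by_cluster: dict[str, ChainRecord] = {}
    for r in current:
        if r.resolution is None or r.resolution <= 0:
            continue
        b = best_by_cluster.get(r.cluster40_id)
        if b is None or r.resolution < b.resolution:
            best_by_cluster[r.cluster40_id] = r
    kept = []
    for r in current:
        (kept.append(r) if best_by_cluster.get(r.cluster40_id) is r
         else drop(r, "rule9_cluster_redundancy"))
    current = kept

    return current, audit


def long_chain_subset(
    records: Sequence[ChainRecord],
    hits_by_chain: dict[str, Sequence[TemplateHit]],
    min_resolved: int = 800,
    max_template_identity: float = 30.0,
) -> list[ChainRecord]:
    """Long, template-poor chains: > ``min_resolved`` resolved residues and the
    best >50%-coverage template below ``max_template_identity`` % identity."""
    out = []
    for r in records:
        hits = hits_by_chain.get(r.chain_id, [])
        if r.n_resolved > min_resolved and best_high_coverage_identity(hits) < max_template_identity:
            out.append(r)
    return out


def hits_from_frame(df: pd.DataFrame) -> list[TemplateHit]:
    """TemplateHit records from a TSV-derived DataFrame.

    Expected columns: query_id, query_start, query_end, identity_pct,
    coverage_pct and optionally template_release_date (ISO format).
    """
    hits = []
    for row in df.itertuples(index=False):
        date = getattr(row, "template_release_date", None)
        if isinstance(date, str):
            date = dt.date.fromisoformat(date)
        elif pd.isna(date):
            date = None
        hits.append(
            TemplateHit(
                query_id=str(row.query_id),
                query_start=int(row.query_start),
                query_end=int(row.query_end),
                identity_pct=float(row.identity_pct),
                coverage_pct=float(row.coverage_pct),
                template_release_date=date,
            )
        )
    return hits


def records_from_frame(df: pd.DataFrame) -> list[ChainRecord]:
    """ChainRecord list from a TSV-derived DataFrame (documented schema in README)."""
    recs = []
    for row in df.itertuples(index=False):
        resolution = row.resolution
        cluster = row.cluster40_id
        recs.append(
            ChainRecord(
                chain_id=str(row.chain_id),
                release_date=dt.date.fromisoformat(str(row.release_date)),
                method=str(row.method),
                resolution=None if pd.isna(resolution) else float(resolution),
                cluster40_id=None if (pd.isna(cluster) or cluster == "") else str(cluster),
                n_resolved=int(row.n_resolved),
                sequence=str(row.sequence),
                has_ambiguous_component=bool(row.has_ambiguous_component),
            )
        )
    return recs
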