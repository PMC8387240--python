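"""Gene Ontology parsing, annotation propagation and coverage breakdown.

Annotations are propagated up the ontology along is_a and part_of edges
(the transitive closure of direct annotations), with alternative term ids
resolved to their primary id. Display-term selection picks moderately
specific high-level terms: those with more than a threshold number of
annotations, none of whose children exceed the threshold.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np
import obonet
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Ontology",
    "AnnotationSet",
    "parse_obo",
    "propagate",
    "select_display_terms",
    "residue_coverage_by_term",
]

PROPAGATION_RELATIONS = ("is_a", "part_of")


@dataclass
class TermInfo:
    term_id: str
    name: str
    namespace: str
    parents_is_a: set[str] = field(default_factory=set)
    parents_part_of: set[str] = field(default_factory=set)
    obsolete: bool = False

    @property
    def parents(self) -> set[str]:
        return self.parents_is_a | self.parents_part_of


@dataclass
class Ontology:
    terms: dict[str, TermInfo]
    alt_ids: dict[str, str]  # alternative id -> primary id

    def resolve(self, term_id: str) -> Optional[str]:
        if term_id in self.terms:
            return term_id
        return self.alt_ids.get(term_id)

    def parents(self, term_id: str) -> set[str]:
        return self.terms[term_id].parents

    def children(self, term_id: str) -> set[str]:
        return {t for t, info in self.terms.items() if term_id in info.parents}

    def ancestors(self, term_id: str) -> set[str]:
        """All terms reachable from ``term_id`` via is_a/part_of (exclusive)."""
        out: set[str] = set()
        stack = list(self.parents(term_id))
        while stack:
            t = stack.pop()
            if t in out or t not in self.terms:
                continue
            out.add(t)
            stack.extend(self.parents(t))
        return out

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        for t, info in self.terms.items():
            for p in info.parents:
                if p in self.terms:
                    g.add_edge(t, p)
        return g


@dataclass
class AnnotationSet:
    direct: dict[str, set[str]]
    propagated: dict[str, set[str]]


def parse_obo(
    path: str | Path,
    remove_edges: Sequence[tuple[str, str]] = (),
) -> Ontology:
    """Parse an OBO 1.2-style ontology file.

    Captures id, name, namespace, is_a parents, part_of relationships,
    alternative ids and obsolete flags. Obsolete terms are excluded from the
    propagation graph. ``remove_edges`` deletes configured (child, parent)
    edges — curated fixes for erroneous relationships — and the resulting
    graph is checked to be acyclic.
    """
    graph = obonet.read_obo(str(path), ignore_obsolete=False)
    terms: dict[str, TermInfo] = {}
    alt_ids: dict[str, str] = {}
    for node, data in graph.nodes(data=True):
        obsolete = str(data.get("is_obsolete", "false")).lower() == "true"
        info = TermInfo(
            term_id=node,
            name=data.get("name", ""),
            namespace=data.get("namespace", ""),
            obsolete=obsolete,
        )
        for alt in data.get("alt_id", []):
            alt_ids[alt] = node
        terms[node] = info
    for child, parent, key in graph.edges(keys=True):
        if key not in PROPAGATION_RELATIONS:
            continue
        if terms[child].obsolete or terms[parent].obsolete:
            continue
        if (child, parent) in set(map(tuple, remove_edges)):
            logger.info("removing configured edge %s -> %s", child, parent)
            continue
        if key == "is_a":
            terms[child].parents_is_a.add(parent)
        else:
            terms[child].parents_part_of.add(parent)
    ont = Ontology(terms=terms, alt_ids=alt_ids)
    g = ont.graph()
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        raise ValueError(f"ontology graph is cyclic: {cycle}")
    return ont


def propagate(direct: dict[str, Iterable[str]], ontology: Ontology) -> AnnotationSet:
    """Propagate direct annotations to all ancestors via is_a/part_of.

    Alternative ids in the input are resolved to primary ids; unresolvable
    ids raise an error listing them.
    """
    resolved_direct: dict[str, set[str]] = {}
    bad: list[str] = []
    for pid, term_ids in direct.items():
        terms = set()
        for t in term_ids:
            primary = ontology.resolve(t)
            if primary is None:
                bad.append(t)
            else:
                terms.add(primary)
        resolved_direct[pid] = terms
    if bad:
        raise ValueError(f"unresolvable term ids: {sorted(set(bad))}")
    propagated = {
        pid: set().union(*({t} | ontology.ancestors(t) for t in terms)) if terms else set()
        for pid, terms in resolved_direct.items()
    }
    return AnnotationSet(direct=resolved_direct, propagated=propagated)


def select_display_terms(
    counts: dict[str, int],
    ontology: Ontology,
    threshold: int = 3000,
    namespaces: Optional[Sequence[str]] = None,
) -> list[str]:
    """Moderately specific high-level terms for display.

    Keeps terms with strictly more than ``threshold`` annotations whose
    every direct child (via is_a/part_of) has at most ``threshold``
    annotations. Optionally restricted to the given namespaces.
    """
    selected = []
    for term, count in counts.items():
        if term not in ontology.terms or count <= threshold:
            continue
        if namespaces and ontology.terms[term].namespace not in namespaces:
            continue
        if any(counts.get(c, 0) > threshold for c in ontology.children(term)):
            continue
        selected.append(term)
    return sorted(selected)


def annotation_counts(annotations: AnnotationSet) -> dict[str, int]:
    """Per-term protein counts on the propagated annotation sets."""
    counts: dict[str, int] = {}
    for terms in annotations.propagated.values():
        for t in terms:
            counts[t] = counts.get(t, 0) + 1
    return counts


def residue_coverage_by_term(
    annotations: AnnotationSet,
    plddt_profiles: dict[str, np.ndarray],
    template_identity: dict[str, np.ndarray],
    terms: Sequence[str],
    identity_cutoff: float = 50.0,
) -> pd.DataFrame:
    """Added residue-level coverage per ontology term, split by confidence band.

    For each term, counts residues of annotated proteins by confidence band,
    restricted to residues not already covered by a template with identity
    above ``identity_cutoff``. Proteins annotated to several terms are
    counted in each term's row (documented double-counting). Proteins
    missing from either per-residue input are logged and skipped.
    """
    from .confidence import BAND_LABELS, assign_band

    rows = []
    for term in terms:
        counts = {b: 0 for b in BAND_LABELS}
        n_proteins = 0
        for pid, term_set in annotations.propagated.items():
            if term not in term_set:
                continue
            if pid not in plddt_profiles or pid not in template_identity:
                logger.warning("skipping %s for term %s: missing per-residue data", pid, term)
                continue
            plddt = np.asarray(plddt_profiles[pid], dtype=float)
            ident = np.asarray(template_identity[pid], dtype=float)
            novel = ident <= identity_cutoff
            n_proteins += 1
            for p in plddt[novel]:
                counts[assign_band(float(p))] += 1
        row = {"term": term, "n_proteins": n_proteins}
        row.update(counts)
        rows.append(row)
    return pd.DataFrame(rows)
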