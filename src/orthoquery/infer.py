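"""Desk-scale ortholog-group inference: reciprocal best hits + graph clustering.

Production orthology inference runs an all-vs-all aligner over full
proteomes and clusters the resulting hit graph. This module is a simplified,
self-contained stand-in with a compatible output schema: every protein's
best global-alignment hit in every other species forms a directed graph;
reciprocal edges above a score threshold are kept; connected components of
the reciprocal graph are the ortholog groups. It is not a re-implementation
of any production tool's scoring or in-paralog rules — the group-file parser
(:mod:`orthoquery.groups`) remains the fidelity path for real upstream
output — but it lets the whole pipeline run with no external binary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx

from .align import ScoringScheme, global_align
from .groups import OrthologGroupTable, from_rows
from .seqio import ProteinRecord

logger = logging.getLogger(__name__)

Key = tuple[str, str]  # (species_code, protein_id)

DEFAULT_MIN_SCORE = 0.05


@dataclass
class HitGraph:
    """Directed best-hit relations between proteins of different species.

    Each node is a (species_code, protein_id) pair; each node has at most
    one outgoing edge per target species, weighted by the alignment score
    normalized by the query's self-alignment score (hence <= 1).
    """

    graph: nx.DiGraph = field(default_factory=nx.DiGraph)

    def add_hit(self, source: Key, target: Key, normalized_score: float) -> None:
        if not 0.0 <= normalized_score <= 1.0 + 1e-9:
            raise ValueError(f"normalized score {normalized_score} outside [0, 1]")
        for _, existing in list(self.graph.out_edges(source)):
            if existing[0] == target[0]:
                raise ValueError(f"{source} already has a best hit in species {target[0]}")
        self.graph.add_edge(source, target, score=min(normalized_score, 1.0))

    def reciprocal_pairs(self, min_score: float) -> list[tuple[Key, Key]]:
        pairs = []
        for u, v, data in self.graph.edges(data=True):
            if u < v and self.graph.has_edge(v, u):
                if data["score"] >= min_score and self.graph[v][u]["score"] >= min_score:
                    pairs.append((u, v))
        return pairs


def _key(rec: ProteinRecord, species: str) -> Key:
    return (species, rec.protein_id if rec.protein_id is not None else rec.raw_header)


def all_vs_all(proteomes: Mapping[str, Sequence[ProteinRecord]],
               scheme: ScoringScheme | None = None) -> HitGraph:
    """Best cross-species hit for every protein under optimal global alignment.

    ``proteomes`` maps species code -> records. For each protein and each
    *other* species, the highest-scoring target is recorded with its
    normalized score; score ties are broken by lexicographically smallest
    protein id. Quadratic in total protein count — intended for small inputs.
    """
    scheme = scheme or ScoringScheme.blosum62()
    if len(proteomes) < 2:
        raise ValueError("all-vs-all inference needs at least 2 species")
    for species, records in proteomes.items():
        if not records:
            raise ValueError(f"proteome {species!r} is empty")
        keys = [_key(r, species) for r in records]
        if len(set(keys)) != len(keys):
            raise ValueError(f"duplicate protein ids in proteome {species!r}")
    graph = HitGraph()
    species_list = sorted(proteomes)
    cache: dict[tuple[Key, Key], float] = {}

    def pair_score(qs: str, q: ProteinRecord, ts: str, t: ProteinRecord) -> float:
        k = (_key(q, qs), _key(t, ts))
        rk = (k[1], k[0])
        if rk in cache:
            return cache[rk]
        if k not in cache:
            cache[k] = global_align(q.sequence, t.sequence, scheme)[2]
        return cache[k]

    for qs in species_list:
        for query in proteomes[qs]:
            self_score = scheme.self_score(query.sequence)
            for ts in species_list:
                if ts == qs:
                    continue
                best_key, best_score = None, None
                for target in sorted(proteomes[ts], key=lambda r: _key(r, ts)):
                    sc = pair_score(qs, query, ts, target)
                    if best_score is None or sc > best_score + 1e-12:
                        best_key, best_score = _key(target, ts), sc
                norm = max(best_score, 0.0) / self_score if self_score > 0 else 0.0
                graph.add_hit(_key(query, qs), best_key, norm)
    return graph


def cluster_orthologs(graph: HitGraph, min_score: float = DEFAULT_MIN_SCORE,
                      species_roster: list[str] | None = None) -> OrthologGroupTable:
    """Ortholog groups = connected components of the reciprocal-best-hit graph.

    Edges are kept only when both directions exist with normalized score
    >= ``min_score``; singleton proteins (no surviving reciprocal hit) are
    excluded. Group ids are ordinals assigned by each component's smallest
    member key, so output is deterministic.
    """
    und = nx.Graph()
    und.add_edges_from(graph.reciprocal_pairs(min_score))
    components = [sorted(c) for c in nx.connected_components(und)]
    components.sort(key=lambda c: c[0])
    rows = [(str(gid), sp, pid)
            for gid, comp in enumerate(components, start=1)
            for sp, pid in comp]
    if not rows:
        logger.warning("no reciprocal best hits survived min_score=%s", min_score)
        import pandas as pd
        return OrthologGroupTable(
            pd.DataFrame(columns=["group_id", "species_code", "protein_id", "member_score"]),
            species_roster=species_roster or [])
    roster = species_roster or sorted({sp for _, sp, _ in rows})
    return from_rows(rows, species_roster=roster)


def infer_groups(proteomes: Mapping[str, Sequence[ProteinRecord]],
                 scheme: ScoringScheme | None = None,
                 min_score: float = DEFAULT_MIN_SCORE) -> OrthologGroupTable:
    """Convenience composition: :func:`all_vs_all` then :func:`cluster_orthologs`."""
    graph = all_vs_all(proteomes, scheme)
    return cluster_orthologs(graph, min_score=min_score,
                             species_roster=sorted(proteomes))
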