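"""End-to-end ortholog query: match, collect, align, score, build the tree.

Given a directory of proteome FASTA files, an ortholog-group table (parsed
from an upstream flat file or inferred in-process), and a query FASTA, this
module finds the group(s) the query proteins belong to, gathers the member
sequences, aligns them, computes the percent identity matrix, and builds a
midpoint-rooted neighbor-joining tree. Matching is a three-stage cascade —
exact sequence identity, then (species, protein-id) header identity, then
best-alignment identity above a threshold — because a query protein from a
species without a public proteome can never header-match and must be placed
by sequence alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Mapping, Sequence

from . import __version__
from .align import (MultipleAlignment, PercentIdentityMatrix, ScoringScheme,
                    pairwise_identity, percent_identity_matrix, progressive_msa)
from .groups import OrthologGroupTable, parse_group_file
from .infer import infer_groups
from .phylo import TreeNode, distance_from_pim, midpoint_root, neighbor_joining
from .seqio import ProteinRecord, read_fasta, read_fasta_dir, unique_keys

logger = logging.getLogger(__name__)

INFER = "infer"  #: sentinel for ``groups_source`` requesting built-in inference

DEFAULT_MATCH_THRESHOLD = 90.0


@dataclass
class PipelineParams:
    """Tunable knobs of one pipeline run (all have working defaults)."""

    gap_open: float = 10.0
    gap_extend: float = 1.0
    pim_denominator: str = "co_residue"
    match_threshold: float = DEFAULT_MATCH_THRESHOLD
    midpoint_rooting: bool = True
    include_unmatched: bool = False
    dialect: str = "default"
    field_order: str = "species_protein_group"
    min_infer_score: float = 0.05

    def scheme(self) -> ScoringScheme:
        return ScoringScheme.blosum62(gap_open=self.gap_open, gap_extend=self.gap_extend)


@dataclass
class QueryMatch:
    query_header: str
    group_id: str | None
    mode: str  # exact-sequence | header | best-alignment | unmatched
    identity: float | None = None


@dataclass
class QueryResult:
    """Everything one run produces, before any file is written."""

    query_records: list[ProteinRecord]
    matches: list[QueryMatch]
    ortholog_records: list[ProteinRecord]
    alignment: MultipleAlignment | None
    pim: PercentIdentityMatrix | None
    tree: TreeNode | None
    groups: OrthologGroupTable
    provenance: dict = field(default_factory=dict)

    @property
    def matched_groups(self) -> list[str]:
        seen = dict.fromkeys(m.group_id for m in self.matches if m.group_id is not None)
        return list(seen)


def match_queries(queries: Sequence[ProteinRecord], table: OrthologGroupTable,
                  sequences: Mapping[tuple[str, str], ProteinRecord],
                  threshold: float = DEFAULT_MATCH_THRESHOLD,
                  scheme: ScoringScheme | None = None) -> list[QueryMatch]:
    """Assign each query to an ortholog group via the matching cascade.

    1. exact sequence identity against any member sequence;
    2. exact (species_code, protein_id) match against the group table;
    3. best global-alignment percent identity >= ``threshold``.

    Unmatched queries are reported with mode ``unmatched``, never an error.
    """
    if not queries:
        raise ValueError("no query records")
    scheme = scheme or ScoringScheme.blosum62()
    member_keys = set(map(tuple, table.data[["species_code", "protein_id"]].itertuples(index=False)))
    seq_index: dict[str, tuple[str, str]] = {}
    for key, rec in sequences.items():
        if key in member_keys:
            seq_index.setdefault(rec.sequence, key)
    out: list[QueryMatch] = []
    for q in queries:
        key = seq_index.get(q.sequence)
        if key is not None:
            out.append(QueryMatch(q.raw_header, table.group_of(*key), "exact-sequence", 100.0))
            continue
        if q.species_code is not None and (q.species_code, q.protein_id) in member_keys:
            gid = table.group_of(q.species_code, q.protein_id)
            out.append(QueryMatch(q.raw_header, gid, "header"))
            continue
        best_key, best_ident = None, -1.0
        for key in sorted(member_keys):
            rec = sequences.get(key)
            if rec is None:
                continue
            ident = pairwise_identity(q.sequence, rec.sequence, scheme)
            if ident > best_ident + 1e-12:
                best_key, best_ident = key, ident
        if best_key is not None and best_ident >= threshold:
            out.append(QueryMatch(q.raw_header, table.group_of(*best_key),
                                  "best-alignment", best_ident))
        else:
            out.append(QueryMatch(q.raw_header, None, "unmatched",
                                  best_ident if best_ident >= 0 else None))
    return out


def run_pipeline(proteome_dir: str | Path, groups_source: str | Path,
                 query_path: str | Path,
                 params: PipelineParams | None = None) -> QueryResult:
    """Run the full query workflow and return an in-memory :class:`QueryResult`.

    ``groups_source`` is either a path to an upstream group flat file or the
    sentinel string ``"infer"`` requesting built-in reciprocal-best-hit
    inference over the proteome directory. Members whose sequence cannot be
    resolved in the proteomes are dropped with a warning and listed in
    provenance; fewer than two resolvable sequences skips the alignment, PIM
    and tree (the ortholog table is still returned); zero resolvable
    orthologs is a hard error.
    """
    params = params or PipelineParams()
    scheme = params.scheme()
    proteomes = read_fasta_dir(proteome_dir, field_order=params.field_order)
    sequences = unique_keys([r for recs in proteomes.values() for r in recs])
    # fall back to the file stem as the species code when headers lack one
    by_stem: dict[tuple[str, str], ProteinRecord] = {}
    for recs in proteomes.values():
        for r in recs:
            stem = Path(r.origin_file).stem
            pid = r.protein_id if r.protein_id is not None else r.raw_header
            by_stem.setdefault((stem, pid), r)
    sequences = {**by_stem, **sequences}

    if str(groups_source) == INFER:
        table = infer_groups(proteomes, scheme, min_score=params.min_infer_score)
    else:
        table = parse_group_file(groups_source, dialect=params.dialect)

    queries = read_fasta(query_path, field_order=params.field_order)
    matches = match_queries(queries, table, sequences,
                            threshold=params.match_threshold, scheme=scheme)

    dropped: list[str] = []
    records: list[ProteinRecord] = []
    seen_keys: set[tuple[str, str]] = set()
    for gid in dict.fromkeys(m.group_id for m in matches if m.group_id is not None):
        for key in table.lookup_group(gid):
            if key in seen_keys:
                continue
            seen_keys.add(key)
            rec = sequences.get(key)
            if rec is None:
                logger.warning("member %s|%s has no sequence in the proteome directory; dropped",
                               *key)
                dropped.append("|".join(key))
            else:
                records.append(rec)

    # the query itself is always an alignment row; skip byte-identical dups
    member_seqs = {r.sequence for r in records}
    for q, m in zip(queries, matches):
        include = m.group_id is not None or params.include_unmatched
        if include and q.sequence not in member_seqs:
            records.insert(0, q)
            member_seqs.add(q.sequence)

    if not records:
        raise RuntimeError(
            f"no resolvable orthologs: {len(queries)} queries, "
            f"{sum(m.group_id is not None for m in matches)} matched, "
            f"{len(dropped)} members dropped")

    labels = _dedup_labels([r.raw_header for r in records])
    alignment = pim = tree = None
    if len(records) >= 2:
        alignment = progressive_msa(
            [(lab, r.sequence) for lab, r in zip(labels, records)], scheme)
        pim = percent_identity_matrix(alignment, denominator=params.pim_denominator)
        dm = distance_from_pim(pim)
        tree = neighbor_joining(dm)
        if params.midpoint_rooting:
            tree = midpoint_root(tree)
    else:
        logger.warning("only one resolvable sequence; alignment, PIM and tree skipped")

    provenance = {
        "tool": "orthoquery",
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(timespec="seconds"),
        "proteome_dir": str(proteome_dir),
        "groups_source": str(groups_source),
        "query_path": str(query_path),
        "params": vars(params).copy(),
        "dropped_members": dropped,
        "match_modes": {m.query_header: m.mode for m in matches},
    }
    return QueryResult(query_records=queries, matches=matches, ortholog_records=records,
                       alignment=alignment, pim=pim, tree=tree, groups=table,
                       provenance=provenance)


def _dedup_labels(labels: list[str]) -> list[str]:
    seen: dict[str, int] = {}
    out = []
    for lab in labels:
        n = seen.get(lab, 0)
        seen[lab] = n + 1
        out.append(lab if n == 0 else f"{lab}#{n}")
    return out
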