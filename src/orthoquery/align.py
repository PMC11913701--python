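"""Protein alignment: affine-gap global alignment, progressive MSA, percent identity.

The pipeline needs three alignment primitives and nothing else: an optimal
pairwise global aligner (Needleman–Wunsch with affine gap penalties), a
classic progressive multiple aligner (neighbor-joining guide tree, then
profile–profile merges in guide-tree order), and the percent identity matrix
(PIM) computed from the finished multiple alignment — the quantity the
heatmaps display. The aligner is deliberately self-contained: no external
alignment binary is required, and determinism (fixed traceback tie-breaks)
is favoured over engine-for-engine fidelity with any particular MSA tool.

Gap convention: a gap run of length L costs ``gap_open + (L-1) * gap_extend``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from Bio.Align import substitution_matrices

logger = logging.getLogger(__name__)

GAP = "-"
_NEG = -1.0e30


class ScoringError(ValueError):
    """Raised when a sequence contains a residue the scheme cannot score."""


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix plus affine gap penalties.

    ``matrix`` maps residue pairs to integer-valued scores and must be
    symmetric; ``gap_extend <= gap_open`` so that extending a gap is never
    dearer than opening a new one.
    """

    alphabet: str
    matrix: np.ndarray  # square, symmetric, indexed by alphabet position
    gap_open: float = 10.0
    gap_extend: float = 1.0
    name: str = "custom"

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.alphabet), len(self.alphabet)):
            raise ValueError("matrix shape does not match alphabet")
        if not np.array_equal(m, m.T):
            raise ValueError("substitution matrix must be symmetric")
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be non-negative")
        if self.gap_extend > self.gap_open:
            raise ValueError("gap_extend must not exceed gap_open")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "_index", {c: i for i, c in enumerate(self.alphabet)})

    @classmethod
    def blosum62(cls, gap_open: float = 10.0, gap_extend: float = 1.0) -> "ScoringScheme":
        """BLOSUM62 defaults. U (selenocysteine) and O score as X."""
        b62 = substitution_matrices.load("BLOSUM62")
        alphabet = str(b62.alphabet) + "UO"
        n = len(alphabet)
        m = np.zeros((n, n))
        base = len(b62.alphabet)
        m[:base, :base] = np.asarray(b62)
        x = b62.alphabet.index("X")
        for extra in range(base, n):
            m[extra, :base] = m[x, :base]
            m[:base, extra] = m[:base, x]
            m[extra, base:] = m[x, x]
        return cls(alphabet=alphabet, matrix=m, gap_open=gap_open,
                   gap_extend=gap_extend, name="BLOSUM62")

    def encode(self, seq: str) -> np.ndarray:
        idx = self._index  # type: ignore[attr-defined]
        try:
            return np.fromiter((idx[c] for c in seq), dtype=np.intp, count=len(seq))
        except KeyError:
            bad = next(c for c in seq if c not in idx)
            raise ScoringError(f"residue {bad!r} absent from substitution matrix "
                               f"({self.name})") from None

    def score_pair(self, x: str, y: str) -> float:
        i = self._index  # type: ignore[attr-defined]
        return float(self.matrix[i[x], i[y]])

    def self_score(self, seq: str) -> float:
        """Score of a sequence aligned to itself (no DP needed)."""
        e = self.encode(seq)
        return float(self.matrix[e, e].sum())


def _fill(S: np.ndarray, gap_open: float, gap_extend: float
          ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Affine-gap DP over a precomputed (n, m) position-score matrix.

    Returns the three state matrices (match, gap-in-second/up, gap-in-first/
    left), each (n+1, m+1). The left-gap state is filled with a running-max
    scan, which is exact because re-opening a gap inside a gap run is never
    better than extending it (gap_extend <= gap_open).
    """
    n, m = S.shape
    M = np.full((n + 1, m + 1), _NEG)
    Iy = np.full((n + 1, m + 1), _NEG)  # up: row consumed, gap in second seq
    Ix = np.full((n + 1, m + 1), _NEG)  # left: column consumed, gap in first
    M[0, 0] = 0.0
    if m:
        Ix[0, 1:] = -(gap_open + np.arange(m) * gap_extend)
    jj = np.arange(m + 1) * gap_extend
    for i in range(1, n + 1):
        prev_best = np.maximum(np.maximum(M[i - 1], Ix[i - 1]), Iy[i - 1])
        M[i, 1:] = prev_best[:-1] + S[i - 1]
        Iy[i] = np.maximum(np.maximum(M[i - 1] - gap_open, Iy[i - 1] - gap_extend),
                           Ix[i - 1] - gap_open)
        entry = np.maximum(M[i], Iy[i]) - gap_open
        run = np.maximum.accumulate(entry + jj)
        Ix[i, 1:] = run[:-1] - jj[1:] + gap_extend
    return M, Iy, Ix


def _traceback(M: np.ndarray, Iy: np.ndarray, Ix: np.ndarray,
               gap_open: float, gap_extend: float) -> list[str]:
    """Recover one optimal path; ties prefer diagonal, then up, then left."""
    tol = 1e-9
    i, j = M.shape[0] - 1, M.shape[1] - 1
    best = max(M[i, j], Iy[i, j], Ix[i, j])
    for state, val in (("M", M[i, j]), ("Iy", Iy[i, j]), ("Ix", Ix[i, j])):
        if val >= best - tol:
            break
    moves: list[str] = []
    while i > 0 or j > 0:
        if state == "M":
            moves.append("D")
            i, j = i - 1, j - 1
            cands = (("M", M[i, j]), ("Iy", Iy[i, j]), ("Ix", Ix[i, j]))
            top = max(c[1] for c in cands)
            for name, val in cands:  # deterministic priority on ties
                if val >= top - tol:
                    state = name
                    break
        elif state == "Iy":
            moves.append("U")
            here = Iy[i, j]
            i -= 1
            cands = (("M", M[i, j] - gap_open), ("Iy", Iy[i, j] - gap_extend),
                     ("Ix", Ix[i, j] - gap_open))
            for name, val in cands:
                if abs(val - here) <= tol:
                    state = name
                    break
            else:  # boundary column: stay in the gap state
                state = "Iy"
        else:
            moves.append("L")
            here = Ix[i, j]
            j -= 1
            cands = (("M", M[i, j] - gap_open), ("Iy", Iy[i, j] - gap_open),
                     ("Ix", Ix[i, j] - gap_extend))
            for name, val in cands:
                if abs(val - here) <= tol:
                    state = name
                    break
            else:
                state = "Ix"
    moves.reverse()
    return moves


def global_align(a: str, b: str, scheme: ScoringScheme | None = None
                 ) -> tuple[str, str, float]:
    """Optimal global alignment of two protein sequences.

    Returns the two gapped sequences and the optimal score under ``scheme``
    (BLOSUM62 / 10 / 1 by default). Traceback is deterministic: on ties the
    diagonal move wins, then the up move (gap in ``b``), then the left move.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    scheme = scheme or ScoringScheme.blosum62()
    ea, eb = scheme.encode(a), scheme.encode(b)
    S = scheme.matrix[np.ix_(ea, eb)]
    M, Iy, Ix = _fill(S, scheme.gap_open, scheme.gap_extend)
    score = float(max(M[-1, -1], Iy[-1, -1], Ix[-1, -1]))
    moves = _traceback(M, Iy, Ix, scheme.gap_open, scheme.gap_extend)
    ga, gb, i, j = [], [], 0, 0
    for mv in moves:
        if mv == "D":
            ga.append(a[i]); gb.append(b[j]); i += 1; j += 1
        elif mv == "U":
            ga.append(a[i]); gb.append(GAP); i += 1
        else:
            ga.append(GAP); gb.append(b[j]); j += 1
    return "".join(ga), "".join(gb), score


@dataclass
class MultipleAlignment:
    """Gapped, equal-length rows over the protein alphabet plus ``-``."""

    labels: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.rows):
            raise ValueError("labels and rows differ in length")
        if not self.rows:
            raise ValueError("empty alignment")
        L = len(self.rows[0])
        if any(len(r) != L for r in self.rows):
            raise ValueError("alignment rows must have equal length")
        if L and any(all(r[c] == GAP for r in self.rows) for c in range(L)):
            raise ValueError("alignment contains an all-gap column")

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    def degapped(self, i: int) -> str:
        return self.rows[i].replace(GAP, "")


@dataclass
class PercentIdentityMatrix:
    """Symmetric pairwise percent-identity values in [0, 100], diagonal 100."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("values shape does not match labels")
        if not np.allclose(v, v.T):
            raise ValueError("percent identity matrix must be symmetric")
        if np.any((v < 0) | (v > 100)):
            raise ValueError("percent identities must lie in [0, 100]")
        self.values = v

    def pair(self, la: str, lb: str) -> float:
        return float(self.values[self.labels.index(la), self.labels.index(lb)])


def _pairs(records: Iterable) -> list[tuple[str, str]]:
    out = []
    for r in records:
        if hasattr(r, "raw_header"):
            out.append((r.raw_header, r.sequence))
        else:
            label, seq = r
            out.append((str(label), str(seq)))
    return out


class _Profile:
    """A set of gapped rows plus per-column residue counts for profile scoring."""

    def __init__(self, indices: list[int], rows: list[str], scheme: ScoringScheme):
        self.indices = indices
        self.rows = rows
        self.scheme = scheme
        n_sym = len(scheme.alphabet)
        L = len(rows[0])
        counts = np.zeros((L, n_sym))
        for row in rows:
            for c, ch in enumerate(row):
                if ch != GAP:
                    counts[c, scheme._index[ch]] += 1  # type: ignore[attr-defined]
        self.counts = counts

    def column_scores(self, other: "_Profile") -> np.ndarray:
        """Mean pairwise substitution score between columns; gap pairs score 0."""
        denom = len(self.rows) * len(other.rows)
        return (self.counts @ self.scheme.matrix @ other.counts.T) / denom

    def merge(self, other: "_Profile") -> "_Profile":
        S = self.column_scores(other)
        M, Iy, Ix = _fill(S, self.scheme.gap_open, self.scheme.gap_extend)
        moves = _traceback(M, Iy, Ix, self.scheme.gap_open, self.scheme.gap_extend)
        rows_a = [[] for _ in self.rows]
        rows_b = [[] for _ in other.rows]
        i = j = 0
        for mv in moves:
            take_a = mv in ("D", "U")
            take_b = mv in ("D", "L")
            for k, row in enumerate(self.rows):
                rows_a[k].append(row[i] if take_a else GAP)
            for k, row in enumerate(other.rows):
                rows_b[k].append(row[j] if take_b else GAP)
            i += take_a
            j += take_b
        merged_rows = ["".join(r) for r in rows_a] + ["".join(r) for r in rows_b]
        # drop columns that became all-gap (possible after profile merging)
        keep = [c for c in range(len(merged_rows[0]))
                if any(row[c] != GAP for row in merged_rows)]
        merged_rows = ["".join(row[c] for c in keep) for row in merged_rows]
        return _Profile(self.indices + other.indices, merged_rows, self.scheme)


def pairwise_identity(a: str, b: str, scheme: ScoringScheme | None = None) -> float:
    """Percent identity of the optimal global alignment of two sequences."""
    ga, gb, _ = global_align(a, b, scheme)
    both = [(x, y) for x, y in zip(ga, gb) if x != GAP and y != GAP]
    if not both:
        return 0.0
    return 100.0 * sum(x == y for x, y in both) / len(both)


def _guide_order(pairs: list[tuple[str, str]], scheme: ScoringScheme):
    """Neighbor-joining guide tree on pairwise p-distances; returns merge plan."""
    from . import phylo  # local import: phylo does not import this module's MSA

    n = len(pairs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            p = 1.0 - pairwise_identity(pairs[i][1], pairs[j][1], scheme) / 100.0
            d[i, j] = d[j, i] = p
    ids = [str(i) for i in range(n)]
    tree = phylo.neighbor_joining(phylo.DistanceMatrix(d, ids=ids))
    return tree


def progressive_msa(records: Iterable, scheme: ScoringScheme | None = None
                    ) -> MultipleAlignment:
    """Progressive multiple alignment (guide tree + profile–profile merges).

    The guide tree is a neighbor-joining tree on pairwise p-distances from
    optimal pairwise alignments; profiles are merged bottom-up in guide-tree
    order by affine-gap dynamic programming over mean column substitution
    scores. Output row order equals input order and de-gapping any output
    row reproduces the corresponding input sequence.
    """
    scheme = scheme or ScoringScheme.blosum62()
    pairs = _pairs(records)
    if not pairs:
        raise ValueError("no records to align")
    for label, seq in pairs:
        if not seq:
            raise ValueError(f"record {label!r} has an empty sequence")
    if len(pairs) == 1:
        warnings.warn("single-record alignment is degenerate", stacklevel=2)
        return MultipleAlignment([pairs[0][0]], [pairs[0][1]])
    if len(pairs) == 2:
        ga, gb, _ = global_align(pairs[0][1], pairs[1][1], scheme)
        return MultipleAlignment([p[0] for p in pairs], [ga, gb])

    tree = _guide_order(pairs, scheme)

    def build(node) -> _Profile:
        if node.is_tip():
            i = int(node.name)
            return _Profile([i], [pairs[i][1]], scheme)
        children = [build(c) for c in node.children]
        prof = children[0]
        for nxt in children[1:]:
            prof = prof.merge(nxt)
        return prof

    prof = build(tree)
    order = np.argsort(prof.indices)
    rows = [prof.rows[k] for k in order]
    return MultipleAlignment([p[0] for p in pairs], rows)


def percent_identity_matrix(msa: MultipleAlignment,
                            denominator: str = "co_residue") -> PercentIdentityMatrix:
    """Pairwise percent identity over a multiple alignment.

    ``denominator`` selects what pairwise identity is divided by:

    - ``co_residue`` (default): columns where both rows carry a residue;
    - ``shorter``: the shorter of the two ungapped sequence lengths;
    - ``alignment``: the full alignment length.

    Pairs with no co-residue columns are reported as 0 with a warning.
    """
    if denominator not in ("co_residue", "shorter", "alignment"):
        raise ValueError(f"unknown denominator mode {denominator!r}")
    n = len(msa)
    arr = np.frombuffer("".join(msa.rows).encode("ascii"), dtype="S1").reshape(n, -1)
    is_res = arr != GAP.encode()
    values = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            both = is_res[i] & is_res[j]
            ident = int(np.count_nonzero(both & (arr[i] == arr[j])))
            if denominator == "co_residue":
                denom = int(np.count_nonzero(both))
            elif denominator == "shorter":
                denom = min(int(is_res[i].sum()), int(is_res[j].sum()))
            else:
                denom = msa.n_columns
            if denom == 0:
                logger.warning("rows %r and %r share no co-residue columns; identity 0",
                               msa.labels[i], msa.labels[j])
                pid = 0.0
            else:
                pid = 100.0 * ident / denom
            values[i, j] = values[j, i] = pid
    return PercentIdentityMatrix(list(msa.labels), values)
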