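"""Synthetic proteomes with known ground truth: evolve families down a tree.

Real inputs to the pipeline are bulk proteome downloads plus an upstream
orthology run over them — far too large for tests, and with no known truth.
This generator replaces them: protein families evolve down a known species
tree under a transparent substitution process (per-site replacement with a
uniformly chosen *different* residue, probability = branch length) plus
optional single-residue indels, so every stage of the pipeline can be
checked against the generating tree and the true family membership.
Everything is driven by one integer seed and is byte-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
from skbio import TreeNode

from .groups import Dialect, OrthologGroupTable, from_rows, _get_dialect
from .phylo import from_newick
from .seqio import AMINO_ACIDS, ProteinRecord, write_fasta

_AA = np.frombuffer(AMINO_ACIDS.encode(), dtype="S1")


@dataclass
class SimulationSpec:
    """Parameters of one simulated dataset.

    ``species_tree`` branch lengths are expected substitutions per site; the
    substitution process replaces a site with a *different* residue with
    probability min(branch length, 1), so realized per-branch divergence is
    binomial around the branch length. ``indel_rate`` is the per-site
    probability (per branch) of a single-residue insertion or deletion,
    applied before substitutions.
    """

    species_tree: TreeNode
    n_families: int = 3
    family_length: int = 120
    indel_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.species_tree, str):
            self.species_tree = from_newick(self.species_tree)
        if self.n_families < 1 or self.family_length < 1:
            raise ValueError("n_families and family_length must be positive")
        if not 0.0 <= self.indel_rate < 1.0:
            raise ValueError("indel_rate must lie in [0, 1)")
        tips = [t.name for t in self.species_tree.tips()]
        if len(tips) != len(set(tips)) or any(t is None for t in tips):
            raise ValueError("species tree leaves must carry unique names")


def balanced_species_tree(n_species: int = 8, branch_length: float = 0.05,
                          prefix: str = "Alg") -> TreeNode:
    """A deterministic caterpillar-free test tree with uniform branch lengths.

    Species codes are short portal-style strings (``Alg01`` ...). The tree is
    built by successive pairing, giving a balanced shape for powers of two.
    """
    if n_species < 2:
        raise ValueError("need at least 2 species")
    nodes = [TreeNode(name=f"{prefix}{i + 1:02d}", length=branch_length)
             for i in range(n_species)]
    while len(nodes) > 2:
        paired = []
        it = iter(nodes)
        for a in it:
            b = next(it, None)
            if b is None:
                paired.append(a)
            else:
                paired.append(TreeNode(children=[a, b], length=branch_length))
        nodes = paired
    root = TreeNode(children=nodes)
    return root


def random_tree(n_leaves: int, rng: np.random.Generator,
                min_branch: float = 0.1, max_branch: float = 1.0,
                prefix: str = "T") -> TreeNode:
    """A random binary tree with uniform random branch lengths.

    Built by repeatedly joining two uniformly chosen subtrees, giving a
    uniform-ish topology distribution; leaves are ``T01, T02, ...``. Useful
    as the generator behind additive-distance and rooting property tests.
    """
    if n_leaves < 2:
        raise ValueError("need at least 2 leaves")

    def bl() -> float:
        return float(rng.uniform(min_branch, max_branch))

    nodes = [TreeNode(name=f"{prefix}{i + 1:02d}", length=bl())
             for i in range(n_leaves)]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(TreeNode(children=[a, b], length=bl()))
    return TreeNode(children=nodes)


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Replace each site with a different residue with probability ``rate``."""
    if rate <= 0:
        return seq.copy()
    hit = rng.random(seq.size) < min(rate, 1.0)
    out = seq.copy()
    if hit.any():
        # draw an offset in 1..19 so the replacement always differs
        cur = np.searchsorted(_AA, out[hit])
        off = rng.integers(1, len(_AA), size=int(hit.sum()))
        out[hit] = _AA[(cur + off) % len(_AA)]
    return out


def _indels(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    if rate <= 0 or seq.size == 0:
        return seq
    keep = rng.random(seq.size) >= rate / 2.0  # deletions
    seq = seq[keep]
    ins = rng.random(seq.size + 1) < rate / 2.0  # insertions between sites
    if ins.any():
        parts = []
        for i in range(seq.size + 1):
            if ins[i]:
                parts.append(_AA[rng.integers(0, len(_AA), size=1)])
            if i < seq.size:
                parts.append(seq[i:i + 1])
        seq = np.concatenate(parts)
    return seq


def _evolve(tree: TreeNode, root_seq: np.ndarray, indel_rate: float,
            rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Evolve the root sequence down the tree; returns leaf name -> sequence."""
    out: dict[str, np.ndarray] = {}

    def walk(node: TreeNode, seq: np.ndarray) -> None:
        for child in node.children:
            s = _indels(seq, indel_rate, rng)
            s = _mutate(s, float(child.length or 0.0), rng)
            if child.is_tip():
                out[child.name] = s
            else:
                walk(child, s)

    walk(tree, root_seq)
    return out


def simulate_proteomes(spec: SimulationSpec, out_dir: str | Path
                       ) -> tuple[Path, OrthologGroupTable, dict[str, TreeNode]]:
    """Write one proteome FASTA per species; return the truth alongside.

    Each family contributes exactly one protein per species (single-copy).
    Headers follow the portal convention ``jgi|<species>|<protein id>|<group>``;
    protein ids are unique within a species only, as in real proteome dumps.
    Returns (proteome directory, true group table, per-family generating tree).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    species = [t.name for t in spec.species_tree.tips()]
    per_species: dict[str, list[ProteinRecord]] = {sp: [] for sp in species}
    rows = []
    family_trees: dict[str, TreeNode] = {}
    for fam in range(1, spec.n_families + 1):
        gid = str(fam)
        root_seq = _AA[rng.integers(0, len(_AA), size=spec.family_length)]
        leaf_seqs = _evolve(spec.species_tree, root_seq, spec.indel_rate, rng)
        family_trees[gid] = spec.species_tree.copy()
        for sp in species:
            pid = str(1000 * fam + species.index(sp))
            header = f"jgi|{sp}|{pid}|{gid}"
            seq = leaf_seqs[sp].tobytes().decode()
            per_species[sp].append(ProteinRecord(
                raw_header=header, sequence=seq, source_tag="jgi",
                species_code=sp, protein_id=pid, group_id=gid,
                origin_file=f"{sp}.fa"))
            rows.append((gid, sp, pid))
    for sp in species:
        write_fasta(per_species[sp], out_dir / f"{sp}.fa")
    table = from_rows(rows, species_roster=species)
    return out_dir, table, family_trees


def make_group_file(table: OrthologGroupTable, path: str | Path,
                    dialect: str | Dialect = "default") -> Path:
    """Render a table back into the wide one-row-per-group flat-file format.

    Inverse of :func:`orthoquery.groups.parse_group_file` for the same
    dialect: members of one species joined by the member separator, species
    without a member written as the placeholder token.
    """
    d = _get_dialect(dialect)
    path = Path(path)
    roster = table.species_roster
    lines = [d.column_sep.join([d.group_column] + roster)]
    df = table.sorted_data()
    for gid, sub in df.groupby("group_id", sort=False):
        cells = [str(gid)]
        for sp in roster:
            members = sub[sub["species_code"] == sp]
            if members.empty:
                cells.append(d.placeholder)
            else:
                toks = []
                for _, row in members.iterrows():
                    score = row["member_score"]
                    if isinstance(score, float) and not math.isnan(score):
                        toks.append(f"{row['protein_id']}{d.score_sep}{score:g}")
                    else:
                        toks.append(str(row["protein_id"]))
                cells.append(d.member_sep.join(toks))
        lines.append(d.column_sep.join(cells))
    path.write_text("\n".join(lines) + "\n")
    return path
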