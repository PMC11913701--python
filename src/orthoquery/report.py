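"""Artifact writers: ortholog table, PIM matrix + heatmap, alignment, tree, manifest.

Every run emits plain-text artifacts (tidy TSV, square TSV, aligned FASTA,
Newick) so results can be re-loaded by other software; the heatmap image is
optional so headless environments never fail on a graphics stack. Percent
identities are printed to one decimal place, matching the precision the
field reports them at.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from .align import GAP, MultipleAlignment, PercentIdentityMatrix
from .groups import OrthologGroupTable, write_group_table
from .phylo import TreeNode, to_newick
from .pipeline import QueryResult

logger = logging.getLogger(__name__)

FORMATS = ("tsv", "png", "html")


def pim_frame(pim: PercentIdentityMatrix, order: list[str] | None = None) -> pd.DataFrame:
    df = pd.DataFrame(pim.values, index=pim.labels, columns=pim.labels)
    if order:
        df = df.loc[order, order]
    return df.round(1)


def _leaf_order(tree: TreeNode | None, labels: list[str]) -> list[str]:
    if tree is None:
        return labels
    order = [t.name for t in tree.tips()]
    return order if sorted(order) == sorted(labels) else labels


def write_pim(pim: PercentIdentityMatrix, path: Path, tree: TreeNode | None = None) -> Path:
    """Square TSV of percent identities, one decimal place, tree leaf order."""
    df = pim_frame(pim, _leaf_order(tree, pim.labels))
    df.to_csv(path, sep="\t", float_format="%.1f", index_label="")
    return path


def read_pim_tsv(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_heatmap(pim: PercentIdentityMatrix, path: Path, fmt: str = "png",
                  tree: TreeNode | None = None) -> Path:
    """Render the PIM as a heatmap (png via matplotlib, html as a value table)."""
    if fmt not in ("png", "html"):
        raise ValueError(f"unknown heatmap format {fmt!r}; choose png or html")
    df = pim_frame(pim, _leaf_order(tree, pim.labels))
    if fmt == "html":
        path.write_text("<html><body>\n" + df.to_html(float_format="%.1f")
                        + "\n</body></html>\n")
        return path
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    n = len(df)
    fig, ax = plt.subplots(figsize=(max(4, 0.45 * n + 2),) * 2)
    im = ax.imshow(df.values, vmin=0, vmax=100, cmap="viridis")
    ax.set_xticks(range(n), df.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(n), df.index, fontsize=7)
    if n <= 20:
        for i in range(n):
            for j in range(n):
                ax.text(j, i, f"{df.values[i, j]:.1f}", ha="center", va="center",
                        fontsize=6, color="white" if df.values[i, j] < 60 else "black")
    fig.colorbar(im, ax=ax, label="percent identity (%)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def write_alignment(msa: MultipleAlignment, path: Path, wrap: int = 60) -> Path:
    """Aligned FASTA (gapped rows)."""
    with open(path, "w") as fh:
        for label, row in zip(msa.labels, msa.rows):
            fh.write(f">{label}\n")
            for i in range(0, len(row), wrap):
                fh.write(row[i:i + wrap] + "\n")
    return path


def write_tree(tree: TreeNode, path: Path) -> Path:
    path.write_text(to_newick(tree) + "\n")
    return path


def write_orthologs(result: QueryResult, path: Path) -> Path:
    """Tidy TSV of the members of every matched group."""
    rows = []
    for gid in result.matched_groups:
        for sp, pid in result.groups.lookup_group(gid):
            rows.append((gid, sp, pid))
    df = pd.DataFrame(rows, columns=["group_id", "species_code", "protein_id"])
    df.to_csv(path, sep="\t", index=False)
    return path


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def write_artifacts(result: QueryResult, out_dir: str | Path,
                    fmt: str = "tsv") -> dict[str, Path]:
    """Write every artifact for a run; the manifest is written last.

    Returns a name -> path map. ``fmt`` adds an optional heatmap rendering
    on top of the always-written TSVs.
    """
    if fmt not in FORMATS:
        raise ValueError(f"unknown output format {fmt!r}; choose one of {FORMATS}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    written["orthologs"] = write_orthologs(result, out / "orthologs.tsv")
    if len(result.groups):
        written["groups"] = write_group_table(result.groups, out / "groups.tsv")
    if result.alignment is not None:
        written["alignment"] = write_alignment(result.alignment, out / "alignment.afa")
    if result.pim is not None:
        written["pim"] = write_pim(result.pim, out / "pim.tsv", tree=result.tree)
        if fmt in ("png", "html"):
            written["heatmap"] = write_heatmap(result.pim, out / f"heatmap.{fmt}",
                                               fmt=fmt, tree=result.tree)
    if result.tree is not None:
        written["tree"] = write_tree(result.tree, out / "tree.nwk")

    manifest = {
        "provenance": result.provenance,
        "counts": {
            "queries": len(result.query_records),
            "matched": sum(m.group_id is not None for m in result.matches),
            "groups": len(result.matched_groups),
            "orthologs": len(result.ortholog_records),
            "dropped": len(result.provenance.get("dropped_members", [])),
        },
        "matches": [vars(m) for m in result.matches],
        "outputs": {name: {"path": p.name, "sha256_16": _digest(p)}
                    for name, p in written.items()},
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    written["manifest"] = manifest_path
    return written
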