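"""Independent oracles used by the tests: brute-force alignment scoring and
unrooted Robinson-Foulds distance via dendropy."""

from __future__ import annotations

import dendropy
from dendropy.calculate import treecompare

GAP = "-"


def score_gapped_pair(ga: str, gb: str, scheme) -> float:
    """Score an explicit gapped alignment: substitution sums plus affine gap
    runs costing gap_open + (L-1) * gap_extend each."""
    assert len(ga) == len(gb)
    total = 0.0
    for row in (ga, gb):
        run = 0
        for ch in row:
            if ch == GAP:
                run += 1
            else:
                if run:
                    total -= scheme.gap_open + (run - 1) * scheme.gap_extend
                run = 0
        if run:
            total -= scheme.gap_open + (run - 1) * scheme.gap_extend
    for x, y in zip(ga, gb):
        if x != GAP and y != GAP:
            total += scheme.score_pair(x, y)
    return total


def brute_force_optimum(a: str, b: str, scheme) -> float:
    """Optimal global alignment score by exhaustive enumeration (tiny inputs)."""
    best = [float("-inf")]

    def rec(i: int, j: int, ga: list[str], gb: list[str]) -> None:
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score_gapped_pair("".join(ga), "".join(gb), scheme))
            return
        if i < len(a) and j < len(b):
            ga.append(a[i]); gb.append(b[j])
            rec(i + 1, j + 1, ga, gb)
            ga.pop(); gb.pop()
        if i < len(a):
            ga.append(a[i]); gb.append(GAP)
            rec(i + 1, j, ga, gb)
            ga.pop(); gb.pop()
        if j < len(b):
            ga.append(GAP); gb.append(b[j])
            rec(i, j + 1, ga, gb)
            ga.pop(); gb.pop()

    rec(0, 0, [], [])
    return best[0]


def rf_distance(newick1: str, newick2: str) -> int:
    """Unrooted Robinson-Foulds (symmetric bipartition difference)."""
    tns = dendropy.TaxonNamespace()
    t1 = dendropy.Tree.get(data=newick1, schema="newick", taxon_namespace=tns)
    t2 = dendropy.Tree.get(data=newick2, schema="newick", taxon_namespace=tns)
    t1.encode_bipartitions()
    t2.encode_bipartitions()
    return int(treecompare.symmetric_difference(t1, t2, is_bipartitions_updated=True))
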