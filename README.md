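# orthoquery

Find, align and visualize putative protein orthologs across a set of
proteomes — from a shell, with no external alignment or orthology binaries.

## The problem

Choosing a bioengineering target usually starts from a protein whose effect
is known in one species (a stress-response transcription factor, an enzyme
at a pathway branch point, a cell-wall synthase) and asks: *which other
species carry an ortholog, and how similar is it?* Orthology inference
tools answer the first half at genome scale, but their output — one wide
row per ortholog group, one column per species, accession lists packed into
cells — is awkward to query for a single protein of interest, especially
when the query comes from a species whose proteome is not public.

`orthoquery` takes:

1. a directory of proteome FASTA files (one per species; file stem =
   species code; headers in the pipe-delimited portal convention
   `jgi|<species code>|<protein id>|<group id>`),
2. an ortholog-group flat file from an upstream inference run — or, for
   small inputs, its own built-in reciprocal-best-hit inference, and
3. a query FASTA with any number of protein sequences,

and produces the ortholog table, a multiple alignment, the **percent
identity matrix** (PIM) behind the similarity heatmap, and a
**midpoint-rooted neighbor-joining tree**, all as plain-text artifacts.

## The method

- Queries are matched to groups by a cascade: exact sequence identity →
  exact `(species, protein id)` header match → best global-alignment
  identity ≥ a threshold (default 90%), so unannotated or unsequenced-species
  queries are still placed.
- Pairwise alignment is Needleman–Wunsch with affine gaps (BLOSUM62,
  gap open 10, extend 1; a length-*L* gap costs `open + (L−1)·extend`).
- The multiple alignment is classic progressive alignment: a
  neighbor-joining guide tree on pairwise p-distances, then profile–profile
  dynamic programming in guide-tree order.
- PIM entries are `100 · (identical co-residue columns) / (co-residue
  columns)` for each row pair — gaps never count against either sequence
  (other denominators are available as a configuration option).
- Distances are p-distances `d = 1 − PIM/100`; the tree is Saitou–Nei
  neighbor joining, rooted at the midpoint of the path between the two most
  distant taxa (disable with `--no-midpoint-root`).

## Worked example

Simulate a small study with known truth (8 species, 3 single-copy protein
families evolved down a known species tree), then query one protein:

```python
from orthoquery.fixtures import (SimulationSpec, balanced_species_tree,
                                 make_group_file, simulate_proteomes)
from orthoquery.seqio import read_fasta, write_fasta

spec = SimulationSpec(species_tree=balanced_species_tree(8, 0.05),
                      n_families=3, family_length=120, indel_rate=0.01, seed=7)
pdir, truth, _ = simulate_proteomes(spec, "proteomes")
make_group_file(truth, "groups.txt")
write_fasta([read_fasta("proteomes/Alg01.fa")[0]], "query.fa")
```

```bash
orthoquery --proteomes proteomes --query query.fa --groups groups.txt --out out
```

prints

```
query 'jgi|Alg01|1000|1': group 1 (exact-sequence)
8 sequences; artifacts in out
```

meaning the query was placed in group 1 by exact sequence identity and the
8 group members (one per species) were aligned. `out/` then contains
`orthologs.tsv`, `pim.tsv`, `alignment.afa`, `tree.nwk`, and
`manifest.json`. The first PIM row (`out/pim.tsv`, values in percent, one
decimal place) for this run is

```
jgi|Alg01|1000|1: 100.0  92.4  81.0  81.7  73.0  72.9  76.1  74.4
```

— the query's top off-diagonal partner (92.4%) is `Alg02`, its sister
species in the generating tree, and the tree in `tree.nwk` reproduces the
generating topology. Swap `--groups groups.txt` for `--infer` to let the
built-in reciprocal-best-hit stage build the group table instead.

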