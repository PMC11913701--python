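import pytest

from orthoquery.align import ScoringScheme
from orthoquery.fixtures import (SimulationSpec, balanced_species_tree,
                                 make_group_file, simulate_proteomes)
from orthoquery.seqio import read_fasta, write_fasta


@pytest.fixture(scope="session")
def scheme():
    return ScoringScheme.blosum62()


@pytest.fixture(scope="session")
def sim_dataset(tmp_path_factory):
    """One simulated study: 8 species, 3 single-copy families, low divergence."""
    root = tmp_path_factory.mktemp("sim")
    tree = balanced_species_tree(8, branch_length=0.05)
    spec = SimulationSpec(species_tree=tree, n_families=3, family_length=120,
                          indel_rate=0.01, seed=11)
    proteome_dir, table, family_trees = simulate_proteomes(spec, root / "proteomes")
    group_file = make_group_file(table, root / "groups.txt")
    query_rec = read_fasta(proteome_dir / "Alg01.fa")[0]  # family 1 member
    query_path = write_fasta([query_rec], root / "query.fa")
    return {
        "root": root,
        "spec": spec,
        "species_tree": tree,
        "proteome_dir": proteome_dir,
        "table": table,
        "family_trees": family_trees,
        "group_file": group_file,
        "query_path": query_path,
        "query_record": query_rec,
    }
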