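import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from e3ome.evidence import (
    CuratorVote,
    EvidenceItem,
    EvidenceLedger,
    GeneRecord,
)


@pytest.fixture
def toy_ledger() -> EvidenceLedger:
    """Three genes with mixed votes and evidence, covering all categories."""
    genes = [
        GeneRecord("RNF31", frozenset({"HOIP"})),
        GeneRecord("SKP2", frozenset()),
        GeneRecord("FAKE1", frozenset({"FK1"})),
    ]
    votes = [
        CuratorVote("RNF31", "alice", "RBR", "yes"),
        CuratorVote("SKP2", "bob", "CRL1_SR", "no"),
    ]
    evidence = [
        EvidenceItem("RNF31", "interpro_domain", "RING1"),
        EvidenceItem("RNF31", "interpro_domain", "IBR"),
        EvidenceItem("SKP2", "interpro_domain", "F-box"),
        EvidenceItem("SKP2", "biogrid_interaction", "CUL1"),
    ]
    return EvidenceLedger(genes, votes, evidence)


@pytest.fixture
def toy_tables(tmp_path):
    """The toy ledger as TSV files on disk."""
    gene_table = tmp_path / "genes.tsv"
    gene_table.write_text(
        "symbol\taliases\tprotein_coding\n"
        "RNF31\tHOIP\t1\n"
        "SKP2\t\t1\n"
        "FAKE1\tFK1\t0\n"
    )
    vote_table = tmp_path / "votes.tsv"
    vote_table.write_text(
        "symbol\tcurator\tfamily\tverdict\n"
        "RNF31\talice\tRBR\tyes\n"
        "SKP2\tbob\tCRL1_SR\tno\n"
    )
    evidence_table = tmp_path / "evidence.tsv"
    evidence_table.write_text(
        "symbol\tsource\tclaim\treference\n"
        "RNF31\tinterpro_domain\tRING1\tIPR001\n"
        "RNF31\tinterpro_domain\tIBR\tIPR002\n"
        "SKP2\tinterpro_domain\tF-box\tIPR003\n"
        "SKP2\tbiogrid_interaction\tCUL1\tBG1\n"
    )
    return gene_table, vote_table, evidence_table
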