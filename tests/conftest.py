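import numpy as np
import pytest

from termstoich import GeneRecord, GenomeBundle

TWO_GENE_FASTA = {
    "ctg1": (
        "ATGAAACCCGGGTTTACTGATGCACTGACGT"  # gene g1: 1..24 (+)
        "ACGTACGTACGTACGTACGT"
        "ATGCCCAAATTTGGGCATCAT"             # gene g2 on the minus strand
        "ACGTACGTAC"
    )
}


def two_gene_bundle() -> GenomeBundle:
    return GenomeBundle(
        contigs=dict(TWO_GENE_FASTA),
        genes=[
            GeneRecord("g1", "ctg1", 1, 24, "+", "SBP"),
            GeneRecord("g2", "ctg1", 52, 72, "-", "TMD"),
        ],
    )


def write_gff3(path, bundle: GenomeBundle, with_roles: bool = True) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for contig, seq in bundle.contigs.items():
            fh.write(f"##sequence-region {contig} 1 {len(seq)}\n")
        for g in bundle.genes:
            attrs = f"ID={g.gene_id}"
            if with_roles:
                attrs += f";role={g.role}"
            fh.write(
                f"{g.contig}\ttest\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )


def write_fasta(path, contigs) -> None:
    with open(path, "w") as fh:
        for name, seq in contigs.items():
            fh.write(f">{name}\n{seq}\n")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def gff_fixture(tmp_path):
    """Minimal two-gene GFF3 + FASTA on disk; returns (gff, fasta, bundle)."""
    bundle = two_gene_bundle()
    gff = tmp_path / "mini.gff3"
    fasta = tmp_path / "mini.fasta"
    write_gff3(gff, bundle)
    write_fasta(fasta, bundle.contigs)
    return gff, fasta, bundle
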