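"""ABC-importer cluster detection, SBP-position typing and intergenic regions.

A cluster is a maximal run of adjacent, same-strand genes with transporter
roles (SBP/TMD/NBD), uninterrupted by an other-role gene or by a gap larger
than ``max_intergene_gap`` (default 300 bp), containing at least one SBP and
at least two genes.  Clusters are reported in transcriptional (5'->3') order,
so a minus-strand cluster lists its genes by descending coordinate.

Intergenic regions (IRs) are the exclusive gaps between adjacent cluster
genes on the transcribed strand, as RNA; "long" means strictly more than
50 bp, the gate used for stem-loop and promoter scanning downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .io_annot import GeneRecord, GenomeBundle, dna_to_rna, reverse_complement

CLUSTER_ROLES = {"SBP", "TMD", "NBD"}
LONG_IR_BP = 50  # "long" is strictly greater than this
SBP_POSITIONS = ("five_prime", "middle", "three_prime", "none", "multiple")


@dataclass
class GeneCluster:
    cluster_id: str
    genes: list[GeneRecord]  # transcriptional order
    strand: str
    arrangement: str
    sbp_position: str

    def __post_init__(self) -> None:
        if len(self.genes) < 2:
            raise ValueError(f"{self.cluster_id}: a cluster needs >=2 genes")
        if any(g.strand != self.strand for g in self.genes):
            raise ValueError(f"{self.cluster_id}: mixed strands")
        if len({g.contig for g in self.genes}) != 1:
            raise ValueError(f"{self.cluster_id}: genes span multiple contigs")
        if self.sbp_position not in SBP_POSITIONS:
            raise ValueError(f"{self.cluster_id}: bad sbp_position {self.sbp_position!r}")


@dataclass
class IntergenicRegion:
    ir_id: str
    cluster_id: str
    upstream_gene: str
    downstream_gene: str
    gap_bp: int
    sequence: str  # sense-strand RNA (ACGU; may contain N)
    is_long: bool
    context: str  # SBP_X | X_SBP | TMD_NBD | other

    def __post_init__(self) -> None:
        if len(self.sequence) != max(self.gap_bp, 0):
            raise ValueError(
                f"{self.ir_id}: sequence length {len(self.sequence)} != gap {self.gap_bp}"
            )


def intergenic_gap(upstream: GeneRecord, downstream: GeneRecord) -> int:
    """Exclusive bp between two genes in transcriptional order (may be < 0).

    On '+' the downstream gene has the larger coordinates; on '-' the smaller.
    Abutting genes give 0; overlapping genes give a negative gap.
    """
    if upstream.strand != downstream.strand:
        raise ValueError(
            f"genes {upstream.gene_id}/{downstream.gene_id} are on different strands"
        )
    if upstream.contig != downstream.contig:
        raise ValueError(
            f"genes {upstream.gene_id}/{downstream.gene_id} are on different contigs"
        )
    if upstream.strand == "+":
        return downstream.start - upstream.end - 1
    return upstream.start - downstream.end - 1


def _sbp_position(genes: list[GeneRecord]) -> str:
    sbp_idx = [i for i, g in enumerate(genes) if g.role == "SBP"]
    if not sbp_idx:
        return "none"
    if len(sbp_idx) > 1:
        return "multiple"
    i = sbp_idx[0]
    if i == 0:
        return "five_prime"
    if i == len(genes) - 1:
        return "three_prime"
    return "middle"


def find_importer_clusters(
    bundle: GenomeBundle,
    max_intergene_gap: int = 300,
    max_genes: int = 6,
) -> list[GeneCluster]:
    """Detect importer gene clusters (see module docstring for the rule)."""
    clusters: list[GeneCluster] = []
    run: list[GeneRecord] = []

    def flush() -> None:
        nonlocal run
        for piece in _split_run(run, max_genes):
            if len(piece) >= 2 and any(g.role == "SBP" for g in piece):
                ordered = piece if piece[0].strand == "+" else list(reversed(piece))
                clusters.append(
                    GeneCluster(
                        cluster_id=f"CL{len(clusters) + 1:04d}",
                        genes=ordered,
                        strand=ordered[0].strand,
                        arrangement="-".join(g.role for g in ordered),
                        sbp_position=_sbp_position(ordered),
                    )
                )
        run = []

    prev: Optional[GeneRecord] = None
    for gene in bundle.genes:  # sorted by (contig, start)
        joins = (
            gene.role in CLUSTER_ROLES
            and prev is not None
            and run
            and gene.contig == prev.contig
            and gene.strand == prev.strand
            and gene.start - prev.end - 1 <= max_intergene_gap
        )
        if joins:
            run.append(gene)
        else:
            flush()
            if gene.role in CLUSTER_ROLES:
                run = [gene]
        prev = gene
    flush()
    return clusters


def _split_run(run: list[GeneRecord], max_genes: int) -> list[list[GeneRecord]]:
    if len(run) <= max_genes:
        return [run] if run else []
    return [run[i : i + max_genes] for i in range(0, len(run), max_genes)]


def extract_intergenic_regions(
    cluster: GeneCluster, bundle: GenomeBundle
) -> list[IntergenicRegion]:
    """One IR per adjacent gene pair with gap >= 1 bp, as sense-strand RNA."""
    irs: list[IntergenicRegion] = []
    contig_seq = bundle.contigs[cluster.genes[0].contig]
    for n, (up, down) in enumerate(zip(cluster.genes, cluster.genes[1:]), start=1):
        gap = intergenic_gap(up, down)
        if gap < 1:
            continue
        if cluster.strand == "+":
            dna = contig_seq[up.end : down.start - 1]
        else:
            dna = reverse_complement(contig_seq[down.end : up.start - 1])
        irs.append(
            IntergenicRegion(
                ir_id=f"{cluster.cluster_id}_ir{n}",
                cluster_id=cluster.cluster_id,
                upstream_gene=up.gene_id,
                downstream_gene=down.gene_id,
                gap_bp=gap,
                sequence=dna_to_rna(dna),
                is_long=gap > LONG_IR_BP,
                context=_pair_context(up, down),
            )
        )
    return irs


def _pair_context(up: GeneRecord, down: GeneRecord) -> str:
    if up.role == "SBP":
        return "SBP_X"
    if down.role == "SBP":
        return "X_SBP"
    if {up.role, down.role} <= {"TMD", "NBD"}:
        return "TMD_NBD"
    return "other"


@dataclass
class ArchitectureSummary:
    n_clusters: int
    sbp_position_counts: dict[str, int]
    arrangement_counts: dict[str, int]
    gap_histogram: dict[str, int]  # "<0", "[0,20)", "[20,40)", ...
    mean_gap_by_context: dict[str, float]
    gaps: list[int] = field(default_factory=list, repr=False)


def summarize_architecture(
    clusters: list[GeneCluster], bin_width: int = 20
) -> ArchitectureSummary:
    """Counts per SBP position and arrangement plus the intergenic-gap
    histogram (20-bp bins and a "<0" overlap bin) and mean gap per context."""
    pos_counts = {p: 0 for p in SBP_POSITIONS}
    arr_counts: dict[str, int] = {}
    gaps: list[int] = []
    ctx_gaps: dict[str, list[int]] = {}
    for cl in clusters:
        pos_counts[cl.sbp_position] += 1
        arr_counts[cl.arrangement] = arr_counts.get(cl.arrangement, 0) + 1
        for up, down in zip(cl.genes, cl.genes[1:]):
            g = intergenic_gap(up, down)
            gaps.append(g)
            ctx_gaps.setdefault(_pair_context(up, down), []).append(g)

    hist: dict[str, int] = {"<0": 0}
    top = max((g for g in gaps if g >= 0), default=-1)
    n_bins = (top // bin_width) + 1 if top >= 0 else 0
    for b in range(n_bins):
        hist[f"[{b * bin_width},{(b + 1) * bin_width})"] = 0
    for g in gaps:
        if g < 0:
            hist["<0"] += 1
        else:
            b = g // bin_width
            hist[f"[{b * bin_width},{(b + 1) * bin_width})"] += 1

    means = {ctx: sum(v) / len(v) for ctx, v in ctx_gaps.items()}
    return ArchitectureSummary(
        n_clusters=len(clusters),
        sbp_position_counts=pos_counts,
        arrangement_counts=arr_counts,
        gap_histogram=hist,
        mean_gap_by_context=means,
        gaps=gaps,
    )
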