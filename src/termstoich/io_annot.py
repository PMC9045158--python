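"""Genome annotation / sequence IO and tabular output.

Reads a GFF3 (+ separate FASTA) or a GenBank flat file into a
:class:`GenomeBundle`, attaches functional roles (SBP / TMD / NBD / other)
from a GFF3 ``role`` attribute or a side TSV, and writes all tabular results
as TSV.  Coordinates are 1-based inclusive throughout (GFF3 convention); the
GenBank reader converts to the same.
"""

from __future__ import annotations

import dataclasses
import logging
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO

log = logging.getLogger(__name__)

ROLES = ("SBP", "TMD", "NBD", "other")

#: optional keyword fallback for role assignment from product strings,
#: off by default (the upstream homology-based assignment is an input here)
ROLE_KEYWORDS = {
    "substrate-binding": "SBP",
    "permease": "TMD",
    "ATP-binding": "NBD",
}


@dataclass(frozen=True)
class GeneRecord:
    """One annotated gene: 1-based inclusive coordinates, strand, role."""

    gene_id: str
    contig: str
    start: int  # 1-based, inclusive
    end: int    # inclusive, end >= start
    strand: str  # '+' or '-'
    role: str = "other"

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"{self.gene_id}: start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(f"{self.gene_id}: end ({self.end}) < start ({self.start})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-', got {self.strand!r}")
        if self.role not in ROLES:
            raise ValueError(f"{self.gene_id}: role must be one of {ROLES}, got {self.role!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class GenomeBundle:
    """Contig sequences plus genes sorted by (contig, start)."""

    contigs: dict[str, str]
    genes: list[GeneRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.contigs = {name: seq.upper() for name, seq in self.contigs.items()}
        self.genes = sorted(self.genes, key=lambda g: (g.contig, g.start))
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise ValueError(f"duplicate gene_id {g.gene_id!r}")
            seen.add(g.gene_id)
            if g.contig not in self.contigs:
                raise KeyError(
                    f"gene {g.gene_id} annotated on contig {g.contig!r} "
                    "but no sequence was provided for that contig"
                )
            if g.end > len(self.contigs[g.contig]):
                raise ValueError(
                    f"gene {g.gene_id} extends past end of contig {g.contig} "
                    f"({g.end} > {len(self.contigs[g.contig])})"
                )

    def gene_sequence(self, gene: GeneRecord) -> str:
        """Sense-strand DNA of *gene* (reverse complement for '-' strand)."""
        raw = self.contigs[gene.contig][gene.start - 1 : gene.end]
        return reverse_complement(raw) if gene.strand == "-" else raw


_COMP = str.maketrans("ACGTUN", "TGCAAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def dna_to_rna(seq: str) -> str:
    return seq.replace("T", "U")


def _read_role_table(path: str | os.PathLike) -> dict[str, str]:
    tbl = pd.read_csv(path, sep="\t", dtype=str)
    if tbl.shape[1] < 2:
        raise ValueError(f"role table {path} needs >=2 columns (gene_id, role)")
    id_col, role_col = tbl.columns[0], tbl.columns[1]
    roles = {}
    for _, row in tbl.iterrows():
        role = str(row[role_col]).strip()
        if role not in ROLES:
            raise ValueError(f"role table {path}: unknown role {role!r} for {row[id_col]!r}")
        roles[str(row[id_col]).strip()] = role
    return roles


def _role_from_keywords(product: str) -> Optional[str]:
    p = product.lower()
    for kw, role in ROLE_KEYWORDS.items():
        if kw.lower() in p:
            return role
    return None


def read_annotation(
    annotation_path: str | os.PathLike,
    fasta_path: str | os.PathLike | None = None,
    role_table: str | os.PathLike | None = None,
    use_keyword_fallback: bool = False,
) -> GenomeBundle:
    """Read a GFF3 (+ FASTA) or GenBank file into a :class:`GenomeBundle`.

    Roles come, in order of precedence, from the side *role_table* TSV
    (gene_id → role), then from a ``role=`` attribute in GFF3 column 9 (or a
    ``/role`` qualifier in GenBank), then — only if *use_keyword_fallback* —
    from product-string keywords; anything else is ``other``.
    """
    annotation_path = Path(annotation_path)
    roles = _read_role_table(role_table) if role_table is not None else {}

    if annotation_path.suffix.lower() in (".gb", ".gbk", ".gbff", ".genbank"):
        contigs, genes = _read_genbank(annotation_path, roles, use_keyword_fallback)
    else:
        if fasta_path is None:
            raise ValueError("GFF3 input requires a separate FASTA (fasta_path)")
        contigs, genes = _read_gff3(annotation_path, fasta_path, roles, use_keyword_fallback)

    return GenomeBundle(contigs=contigs, genes=genes)


def _resolve_role(
    gene_id: str,
    attr_role: Optional[str],
    product: Optional[str],
    roles: Mapping[str, str],
    use_keyword_fallback: bool,
) -> str:
    if gene_id in roles:
        return roles[gene_id]
    if attr_role:
        if attr_role not in ROLES:
            raise ValueError(f"gene {gene_id}: unknown role attribute {attr_role!r}")
        return attr_role
    if use_keyword_fallback and product:
        kw = _role_from_keywords(product)
        if kw:
            return kw
    return "other"


def _read_gff3(gff_path, fasta_path, roles, use_keyword_fallback):
    contigs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    db = gffutils.create_db(
        str(gff_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="error",
    )
    genes = []
    for feat in db.features_of_type(("gene", "CDS")):
        # prefer gene features; fall back to CDS only for ids not already seen
        if feat.featuretype == "CDS" and any(g.gene_id == feat.id for g in genes):
            continue
        attr_role = feat.attributes.get("role", [None])[0]
        product = feat.attributes.get("product", [None])[0]
        genes.append(
            GeneRecord(
                gene_id=feat.id,
                contig=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand,
                role=_resolve_role(feat.id, attr_role, product, roles, use_keyword_fallback),
            )
        )
    return contigs, genes


def _read_genbank(gb_path, roles, use_keyword_fallback):
    contigs: dict[str, str] = {}
    genes: list[GeneRecord] = []
    for rec in SeqIO.parse(str(gb_path), "genbank"):
        contigs[rec.id] = str(rec.seq).upper()
        for feat in rec.features:
            if feat.type not in ("gene", "CDS"):
                continue
            quals = feat.qualifiers
            gene_id = (
                quals.get("locus_tag", [None])[0]
                or quals.get("gene", [None])[0]
                or quals.get("ID", [None])[0]
            )
            if gene_id is None:
                continue
            if any(g.gene_id == gene_id for g in genes):
                continue  # gene + CDS pairs share a locus_tag
            genes.append(
                GeneRecord(
                    gene_id=gene_id,
                    contig=rec.id,
                    # Biopython locations are 0-based half-open; convert
                    start=int(feat.location.start) + 1,
                    end=int(feat.location.end),
                    strand="+" if feat.location.strand >= 0 else "-",
                    role=_resolve_role(
                        gene_id,
                        quals.get("role", [None])[0],
                        quals.get("product", [None])[0],
                        roles,
                        use_keyword_fallback,
                    ),
                )
            )
    return contigs, genes


def to_dataframe(records: Sequence) -> pd.DataFrame:
    """Dataclass instances (or dicts) → DataFrame with stable column order."""
    if len(records) == 0:
        return pd.DataFrame()
    first = records[0]
    if dataclasses.is_dataclass(first):
        cols = [f.name for f in dataclasses.fields(first)]
        return pd.DataFrame([dataclasses.asdict(r) for r in records], columns=cols)
    return pd.DataFrame(list(records))


def write_table(records, path: str | os.PathLike, columns: Optional[list[str]] = None) -> None:
    """Write any tabular result (DataFrame, dataclasses, dicts) as TSV.

    Floats keep >=6 significant digits; an empty input with *columns* given
    yields a header-only file.
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        df = to_dataframe(records)
    if df.empty and columns is not None:
        df = pd.DataFrame(columns=columns)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_table(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_fasta(entries: Iterable[tuple[str, str]], path: str | os.PathLike) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for name, seq in entries:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
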