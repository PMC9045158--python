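"""Ground-truth synthetic data: annotated genomes with embedded importer
clusters and typed terminators, reporter-assay tables, and calibration
datasets.

The generator emulates the study conditions the pipeline targets:

* multi-gene same-strand importer clusters with the SBP gene at the 5' end,
  middle or 3' end (heavily 5'-biased, as observed for cellulolytic
  Clostridia), Clostridia-like AT-rich background (GC 0.35 by default);
* a bimodal intergenic-gap distribution for SBP-adjacent gaps (peaks at
  0-20 bp and 60-100 bp);
* intrinsic-terminator stem-loops of Types I-IV with folding energies in
  the observed range (roughly -38 to -10 kcal/mol), embedded in the IR
  immediately downstream of the SBP;
* band-intensity and qPCR tables with known true termination efficiencies
  plus Gaussian noise;
* a TE-vs-poly(U)-length dataset with an analytically calibrated linear
  relationship.

Terminator construction is rejection sampling against the real fold +
classify stack (never a parallel re-implementation), so every emitted
terminator is guaranteed to refold and classify as its requested type;
downstream recovery failures therefore isolate pipeline bugs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .io_annot import GeneRecord, GenomeBundle, dna_to_rna, reverse_complement, write_fasta
from .rna_fold import DEFAULT_PARAMS, EnergyParams, min_hairpin
from .te_quant import BandIntensityRecord, QpcrRecord
from .terminator_classify import CascadeConfig, DEFAULT_CASCADE, call_terminator

TERM_TYPES = ("I", "II", "III", "IV")

#: per-type mean folding-energy targets (kcal/mol); Type I hairpins are the
#: weakest on average, Type IV (long GC-rich distal arm) the strongest
TYPE_DG_MEAN = {"I": -18.3, "II": -21.0, "III": -25.0, "IV": -28.4}
TYPE_DG_SD = 3.0


@dataclass
class SyntheticConfig:
    seed: int = 0
    n_clusters: int = 30
    sbp_position_mix: dict[str, float] = field(
        default_factory=lambda: {"five_prime": 0.70, "middle": 0.01, "three_prime": 0.29}
    )
    arrangement_mix: dict[str, float] = field(
        # core arrangements without the SBP; the SBP is inserted per position
        default_factory=lambda: {"TMD-TMD": 0.55, "TMD-NBD": 0.25, "TMD-TMD-NBD": 0.20}
    )
    gap_model: dict[str, float] = field(
        default_factory=lambda: {
            "weight_short": 0.45,
            "short_low": 0, "short_high": 20,
            "long_low": 60, "long_high": 100,
        }
    )
    terminator_type_mix: dict[str, float] = field(
        default_factory=lambda: {"I": 0.11, "II": 0.40, "III": 0.28, "IV": 0.08, "none": 0.13}
    )
    dG_window: tuple[float, float] = (-35.0, -12.0)
    te_noise_sd: float = 3.0     # percent, band intensities
    qpcr_noise_sd: float = 0.15  # cycles
    gc_background: float = 0.35

    def __post_init__(self) -> None:
        for name, mix in (
            ("sbp_position_mix", self.sbp_position_mix),
            ("arrangement_mix", self.arrangement_mix),
            ("terminator_type_mix", self.terminator_type_mix),
        ):
            if abs(sum(mix.values()) - 1.0) > 1e-6:
                raise ValueError(f"{name} probabilities must sum to 1")
        lo, hi = self.dG_window
        if not (-40.0 <= lo < hi <= -10.0):
            raise ValueError("dG_window must lie within [-40, -10]")


# ---------------------------------------------------------------------------
# terminator construction


def _choice(rng: np.random.Generator, mix: dict[str, float]) -> str:
    keys = sorted(mix)
    return keys[rng.choice(len(keys), p=[mix[k] for k in keys])]


_RNA_COMP = {"A": "U", "U": "A", "G": "C", "C": "G"}


def _rc_rna(s: str) -> str:
    return "".join(_RNA_COMP[b] for b in reversed(s))


def _draw_arm(rng: np.random.Generator, length: int) -> str:
    """C-rich 5' stem arm (the 3' arm is its complement, hence G-rich)."""
    return "".join(rng.choice(["C", "G", "A", "U"], p=[0.55, 0.25, 0.10, 0.10])
                   for _ in range(length))


def _tail_for_type(term_type: str, rng: np.random.Generator) -> str:
    if term_type == "I":
        return "U" * int(rng.integers(6, 9)) + "C"
    if term_type == "II":
        n_u = int(rng.integers(2, 5))
        tail = ["A", "C", "A", "C", "A", "C", "A"][:7]
        pos = rng.choice(7, size=n_u, replace=False)
        for p in pos:
            tail[p] = "U"
        return "".join(tail)
    if term_type == "III":
        return "UACC"
    return "ACCA"  # IV: essentially no U


def _assemble(term_type: str, m: int, arm: str, loop: str, tail: str,
              distal5: str, distal3: str) -> str:
    arm5 = arm[:m]
    arm3 = _rc_rna(arm5)
    if term_type in ("I", "II"):
        return arm5 + loop + arm3 + tail
    # III/IV: distal helix + 1x1 internal loop (A opposite C) + inner stem
    return distal5 + "A" + arm5 + loop + arm3 + "C" + distal3 + tail


def gen_terminator(
    term_type: str,
    dG_target: float,
    rng: np.random.Generator,
    params: EnergyParams = DEFAULT_PARAMS,
    cascade: CascadeConfig = DEFAULT_CASCADE,
    max_attempts: int = 100,
) -> tuple[str, dict]:
    """Construct an RNA terminator of the requested type whose refolded MFE
    is within +/-2 kcal/mol of *dG_target*.

    Returns (sequence, ground_truth) where the ground truth records the
    requested type, the refolded dG and structural summary.  Raises if the
    target is unreachable after *max_attempts* template draws.
    """
    if term_type not in TERM_TYPES:
        raise ValueError(f"unknown terminator type {term_type!r}")
    if not (-40.0 <= dG_target <= -10.0):
        raise ValueError(f"dG_target {dG_target} outside the supported [-40, -10] window")
    m_est = max(3, round(1 + (5.6 - dG_target) / 3.0))
    for _ in range(max_attempts):
        arm = _draw_arm(rng, m_est + 6)
        loop = "".join(rng.choice(["A", "C"], p=[0.7, 0.3]) for _ in range(4))
        tail = _tail_for_type(term_type, rng)
        if term_type == "III":
            d = int(rng.integers(2, 5))
            distal5 = "G" + "A" * (d - 1)
            distal3 = "U" * (d - 1) + "C"
        elif term_type == "IV":
            d = int(rng.integers(5, 7))
            distal5 = "".join(rng.choice(["G", "C"], p=[0.6, 0.4]) for _ in range(d))
            distal3 = _rc_rna(distal5)
        else:
            distal5 = distal3 = ""
        for m in range(max(3, m_est - 3), m_est + 4):
            seq = _assemble(term_type, m, arm, loop, tail, distal5, distal3)
            st = min_hairpin(seq, params=params)
            if st is None or not (dG_target - 2.0 <= st.dG <= dG_target + 2.0):
                continue
            call = call_terminator("gen", st, cascade)
            if call.type_label == term_type:
                truth = {
                    "type": term_type,
                    "dG": st.dG,
                    "dG_target": dG_target,
                    "stem_bp": st.stem_bp,
                    "sequence": seq,
                }
                return seq, truth
    raise RuntimeError(
        f"could not reach dG {dG_target:+.1f} kcal/mol for Type {term_type} "
        f"after {max_attempts} attempts"
    )


# ---------------------------------------------------------------------------
# genome generation


def _bg_dna(rng: np.random.Generator, length: int, gc: float) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(["A", "C", "G", "T"], p=p, size=length))


#: flanks placed around an embedded terminator; drawn from pairing-inert
#: alphabets so the designed hairpin stays the MFE of its IR
_GUARD_5P = "CUCCUC"
_CAP_3P = "CUCC"


def _gap_draw(rng: np.random.Generator, gm: dict[str, float], force_long: bool = False) -> int:
    if not force_long and rng.random() < gm["weight_short"]:
        return int(rng.integers(gm["short_low"], gm["short_high"] + 1))
    return int(rng.integers(gm["long_low"], gm["long_high"] + 1))


def _embed_terminator_ir(
    term_type: str,
    config: SyntheticConfig,
    rng: np.random.Generator,
    params: EnergyParams,
    max_attempts: int = 20,
) -> tuple[str, dict]:
    """Build a full IR (RNA, sense strand) embedding a typed terminator and
    verify that scan+classify on the IR recovers the type; redraw otherwise."""
    lo, hi = config.dG_window
    for _ in range(max_attempts):
        target = float(np.clip(rng.normal(TYPE_DG_MEAN[term_type], TYPE_DG_SD), lo, hi))
        term_seq, truth = gen_terminator(term_type, target, rng, params=params)
        core = _GUARD_5P + term_seq + _CAP_3P
        gap = max(_gap_draw(rng, config.gap_model, force_long=True), len(core) + 12)
        prefix_len = int(rng.integers(3, 9))
        suffix_len = gap - len(core) - prefix_len
        ir = (
            dna_to_rna(_bg_dna(rng, prefix_len, 0.15))
            + core
            + dna_to_rna(_bg_dna(rng, suffix_len, 0.15))
        )
        st = min_hairpin(ir, params=params)
        if st is None or st.dG >= -10.0:
            continue
        call = call_terminator("embed", st)
        if call.type_label == term_type:
            truth = dict(truth, ir_gap=gap)
            return ir, truth
    raise RuntimeError(f"could not embed a recoverable Type {term_type} terminator")


@dataclass
class SyntheticGenome:
    bundle: GenomeBundle
    cluster_truth: pd.DataFrame

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        gff = out / "genome.gff3"
        fasta = out / "genome.fasta"
        truth = out / "cluster_truth.tsv"
        with open(gff, "w") as fh:
            fh.write("##gff-version 3\n")
            for contig, seq in self.bundle.contigs.items():
                fh.write(f"##sequence-region {contig} 1 {len(seq)}\n")
            for g in self.bundle.genes:
                fh.write(
                    f"{g.contig}\ttermstoich_sim\tgene\t{g.start}\t{g.end}\t.\t"
                    f"{g.strand}\t.\tID={g.gene_id};role={g.role}\n"
                )
        write_fasta(self.bundle.contigs.items(), fasta)
        self.cluster_truth.to_csv(truth, sep="\t", index=False, float_format="%.6g")
        return {"gff": gff, "fasta": fasta, "truth": truth}


def gen_genome(
    config: SyntheticConfig,
    rng: Optional[np.random.Generator] = None,
    params: EnergyParams = DEFAULT_PARAMS,
) -> SyntheticGenome:
    """Generate an annotated genome with known importer clusters.

    Clusters are placed non-overlapping on both strands, separated by > 300
    bp spacers (occasionally containing an other-role gene); the terminator,
    when the drawn type is not "none", sits in the IR immediately downstream
    of the SBP gene.  Deterministic for a fixed config seed.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    genome_parts: list[str] = []
    genes: list[GeneRecord] = []
    truth_rows: list[dict] = []
    offset = 0
    gene_counter = 0
    contig = "chr1"

    def emit_spacer() -> None:
        nonlocal offset, gene_counter
        pre = _bg_dna(rng, int(rng.integers(150, 300)), config.gc_background)
        genome_parts.append(pre)
        offset += len(pre)
        if rng.random() < 0.3:  # occasional unrelated gene inside the spacer
            glen = int(rng.integers(600, 1200))
            gseq = _bg_dna(rng, glen, config.gc_background)
            genome_parts.append(gseq)
            gene_counter += 1
            genes.append(
                GeneRecord(
                    gene_id=f"g{gene_counter:04d}",
                    contig=contig,
                    start=offset + 1,
                    end=offset + glen,
                    strand="+" if rng.random() < 0.5 else "-",
                    role="other",
                )
            )
            offset += glen
        post = _bg_dna(rng, int(rng.integers(200, 400)), config.gc_background)
        genome_parts.append(post)
        offset += len(post)

    emit_spacer()
    for ci in range(config.n_clusters):
        pos = _choice(rng, config.sbp_position_mix)
        core = _choice(rng, config.arrangement_mix).split("-")
        if pos == "five_prime":
            roles = ["SBP"] + core
        elif pos == "three_prime":
            roles = core + ["SBP"]
        else:
            roles = [core[0], "SBP"] + core[1:]
        strand = "+" if rng.random() < 0.5 else "-"
        sbp_idx = roles.index("SBP")

        term_type = _choice(rng, config.terminator_type_mix)
        if sbp_idx == len(roles) - 1:
            term_type = "none"  # no downstream IR inside the cluster

        # build the cluster block in transcriptional orientation
        block = ""
        intervals: list[tuple[int, int]] = []  # (start0, end0-exclusive) per gene
        term_truth: dict = {}
        for gi, role in enumerate(roles):
            glen = int(rng.integers(900, 1800))
            intervals.append((len(block), len(block) + glen))
            block += _bg_dna(rng, glen, config.gc_background)
            if gi == len(roles) - 1:
                break
            if gi == sbp_idx and term_type != "none":
                ir_rna, term_truth = _embed_terminator_ir(term_type, config, rng, params)
                block += ir_rna.replace("U", "T")
            else:
                is_sbp_adjacent = gi == sbp_idx or gi + 1 == sbp_idx
                gap = (
                    _gap_draw(rng, config.gap_model)
                    if is_sbp_adjacent
                    else int(rng.integers(0, 21))
                )
                block += _bg_dna(rng, gap, config.gc_background)

        L = len(block)
        if strand == "-":
            genome_parts.append(reverse_complement(block))
        else:
            genome_parts.append(block)
        cluster_gene_ids = []
        for gi, (a, b) in enumerate(intervals):
            gene_counter += 1
            gid = f"g{gene_counter:04d}"
            cluster_gene_ids.append(gid)
            if strand == "+":
                start, end = offset + a + 1, offset + b
            else:
                start, end = offset + L - b + 1, offset + L - a
            genes.append(
                GeneRecord(
                    gene_id=gid, contig=contig, start=start, end=end,
                    strand=strand, role=roles[gi],
                )
            )
        offset += L
        truth_rows.append(
            {
                "cluster_index": ci,
                "strand": strand,
                "arrangement": "-".join(roles),
                "sbp_position": pos,
                "n_genes": len(roles),
                "gene_ids": ",".join(cluster_gene_ids),
                "terminator_type": term_type,
                "terminator_dG": term_truth.get("dG", float("nan")),
                "terminator_seq": term_truth.get("sequence", ""),
                "ir_gap": term_truth.get("ir_gap", 0),
            }
        )
        emit_spacer()

    genome = "".join(genome_parts)
    bundle = GenomeBundle(contigs={contig: genome}, genes=genes)
    cols = [
        "cluster_index", "strand", "arrangement", "sbp_position", "n_genes",
        "gene_ids", "terminator_type", "terminator_dG", "terminator_seq", "ir_gap",
    ]
    return SyntheticGenome(bundle=bundle, cluster_truth=pd.DataFrame(truth_rows, columns=cols))


# ---------------------------------------------------------------------------
# assay tables


def gen_band_table(
    true_te: dict[str, float],
    noise_sd: float,
    replicates: int,
    rng: np.random.Generator,
) -> list[BandIntensityRecord]:
    """Band intensities on an arbitrary per-replicate scale: mono ~ TE,
    bi ~ 100 - TE, plus additive Gaussian noise, truncated at 0."""
    records = []
    for cid in sorted(true_te):
        te = true_te[cid]
        for rep in range(1, replicates + 1):
            scale = rng.uniform(0.5, 2.0)
            mono = max(te + rng.normal(0.0, noise_sd), 0.0) * scale
            bi = max((100.0 - te) + rng.normal(0.0, noise_sd), 0.0) * scale
            records.append(
                BandIntensityRecord(
                    construct_id=cid, probe="fbfp", I_mono=mono, I_bi=bi, replicate=rep
                )
            )
    return records


def gen_qpcr_table(
    true_te: dict[str, float],
    noise_sd_cycles: float,
    replicates: int,
    rng: np.random.Generator,
) -> list[QpcrRecord]:
    """Ct tables for the fbfp/mcherry reporter pair plus a reference gene.

    The mcherry level is (1 - TE/100) of the fbfp level; a fully terminated
    construct gives an mcherry Ct ~15 cycles late (below detection)."""
    records = []
    for cid in sorted(true_te):
        te = true_te[cid]
        for rep in range(1, replicates + 1):
            ref = rng.uniform(18.0, 22.0)
            rel_f = rng.uniform(0.5, 2.0)
            ct_f = ref - math.log2(rel_f)
            rel_m = rel_f * (1.0 - te / 100.0)
            ct_m = (ref - math.log2(rel_m)) if rel_m > 0 else ref + 15.0
            for gene, ct in (("fbfp", ct_f), ("mcherry", ct_m), ("reference", ref)):
                records.append(
                    QpcrRecord(
                        construct_id=cid,
                        gene=gene,
                        Ct=ct + rng.normal(0.0, noise_sd_cycles),
                        replicate=rep,
                    )
                )
    return records


def gen_te_polyU_dataset(
    n: int,
    target_r2: float,
    rng: np.random.Generator,
    intercept: float = 20.0,
    slope: float = 8.0,
) -> tuple[np.ndarray, np.ndarray]:
    """(poly(U) length 0-8, TE %) pairs with TE = a + b*u + eps.

    The noise variance is solved analytically so the expected coefficient of
    determination equals *target_r2*:

        r2 = b^2 Var(u) / (b^2 Var(u) + sigma^2)
        =>  sigma^2 = b^2 Var(u) (1 - r2) / r2

    with Var(u) = 80/12 for u uniform on {0..8}.  target_r2 = 1 gives an
    exact line; target_r2 = 0 sets the slope to zero.
    """
    if not (0.0 <= target_r2 <= 1.0):
        raise ValueError("target_r2 must be in [0, 1]")
    u = rng.integers(0, 9, size=n).astype(float)
    var_u = 80.0 / 12.0
    if target_r2 == 0.0:
        te = intercept + slope * 4.0 + rng.normal(0.0, 5.0, size=n)
        return u, te
    if target_r2 == 1.0:
        return u, intercept + slope * u
    sigma = math.sqrt(slope**2 * var_u * (1.0 - target_r2) / target_r2)
    te = intercept + slope * u + rng.normal(0.0, sigma, size=n)
    return u, te
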