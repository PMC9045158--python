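# termstoich

**Internal intrinsic terminators and transcript stoichiometry in
ABC-importer operons.**

Bacterial ABC importers need their extracellular substrate-binding protein
(SBP) in large molar excess over the membrane translocator (TMD/NBD)
subunits, yet all of these genes usually sit in one operon under one
promoter. One mechanism that produces the imbalance is an *internal
intrinsic terminator*: a GC-rich stem-loop with a U-rich 3' tract placed in
the intergenic region just downstream of the SBP gene. A fraction of RNA
polymerases terminates there, so the upstream SBP transcript accumulates
while the downstream translocator transcript stays scarce — the
stoichiometric ratio of the flanking transcripts is set by the terminator's
termination efficiency (TE) and folding energy.

`termstoich` is a library (plus a thin CLI) for analysing this mechanism
genome-wide and quantitatively:

| module | what it does |
|---|---|
| `io_annot` | GFF3+FASTA / GenBank reading with SBP/TMD/NBD role labels; TSV output |
| `cluster_survey` | importer-cluster detection, SBP-position typing (5'/middle/3'), intergenic regions |
| `rna_fold` | single-hairpin MFE folding with an embedded nearest-neighbor model and a brute-force enumeration oracle |
| `terminator_classify` | terminator feature extraction, Type I–IV classification, mutation operators |
| `te_quant` | TE from Northern band intensities and from qPCR ΔCt, replicate statistics, correlations |
| `enrichment_stats` | exact one-sided hypergeometric enrichment tests |
| `synthetic_data` | ground-truth genomes, terminators and assay tables for end-to-end validation |

## The quantities at the core

For an intergenic region (IR) of more than 50 bp between an SBP gene and
its downstream gene, the minimum-free-energy single hairpin is computed as

    ΔG = Σ stack(b_i b_j , b_k b_l) + hairpin_init(loop)
         + Σ bulge/internal penalties + terminal non-GC penalty   [kcal/mol, 37 °C]

and the IR is called a stem-loop when ΔG < −10 kcal/mol. Called stem-loops
are typed by a decision cascade on the U-rich window 3' of the stem (or
distal to a 1–2 nt unpaired region in the stem): **Type I** poly(U) run ≥ 5;
**Type II** U-rich but no ≥5 run and an uninterrupted stem; **Type III**
a short paired U-rich tract after the unpaired region; **Type IV** a long
(≥5 bp) GC-rich distal arm with little U.

Termination efficiency comes from the dual-reporter assay as

    TE_northern = 100 · I_mono / (I_mono + I_bi)
    TE_qpcr     = 100 · (1 − level_mcherry / level_fbfp),
    level_g     = E^(Ct_ref − Ct_g)

and feature enrichment by cluster side is an exact hypergeometric upper
tail P(X ≥ k) computed in log space.

## Worked example

```python
import numpy as np
from termstoich import call_terminator, min_hairpin
from termstoich.synthetic_data import TYPE_DG_MEAN, gen_terminator

rng = np.random.default_rng(42)
for t in ("I", "II", "III", "IV"):
    seq, _ = gen_terminator(t, TYPE_DG_MEAN[t], rng)
    st = min_hairpin(seq)
    f = call_terminator("demo", st).features
    print(t, round(st.dG, 1), f.polyU_run, f.tail_U_count, st.dot_bracket())
```

prints

```
I -16.3 6 6 (((((((((....))))))))).......
II -19.0 2 3 ((((((((((....)))))))))).......
III -23.7 3 4 ((((.(((((((((((....))))))))))).))))....
IV -28.5 0 0 ((((((.(((((((((....))))))))).))))))....
```

— one terminator per type, refolded to the requested free energy (kcal/mol,
second column), with the poly(U) run and U count of its 3' window (third
and fourth columns) sitting on the correct side of every classification
boundary. The enrichment test on the genome-survey count table
(221 five-prime-SBP IRs / 85 three-prime-SBP IRs):

```
stemloop: 5'  87.3%  3'  23.5%  -> five_prime_enriched  (p = 1.73e-26)
promoter: 5'  20.8%  3'  52.9%  -> three_prime_enriched  (p = 7.94e-08)
```

Stem-loops concentrate downstream of 5'-end SBPs; promoters upstream of
3'-end SBPs. The `examples/` directory has one short narrative script per
capability (survey, fold+classify, TE quantification, enrichment,
terminator mutagenesis); each prints what it computes and what the numbers
mean. The same pipeline is available from a shell:

```bash
termstoich all --seed 5 --n-clusters 20 --out run/
```

which writes `clusters.tsv`, `intergenic_regions.tsv`, `folds.tsv`,
`terminator_calls.tsv`, TE tables, the enrichment table and a
`manifest.json` with checksums (two runs with one seed are byte-identical).

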