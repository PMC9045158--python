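# Methods

This note records the models, parameter choices and numerical decisions
behind `termstoich`, and what the synthetic-data tests do and do not show
about real genomes.

## Cluster survey

A cluster is a maximal run of adjacent genes on one strand whose functional
roles are all in {SBP, TMD, NBD}, with no intervening other-role gene and
no gap above `max_intergene_gap` (default 300 bp, comfortably above every
within-operon gap the gap model produces; observed importer-operon gaps
average 50–80 bp). Only runs with at least two genes and at least one SBP
are reported. Role assignment is an *input* (GFF3 `role` attribute or a
side TSV): homology-based role inference is deliberately out of scope, and
the optional keyword fallback (product strings containing
"substrate-binding" / "permease" / "ATP-binding") is off by default because
it is a much weaker stand-in.

Design choices that were genuinely open:

* **"Distance" means the exclusive gap** between gene ends (negative for
  overlaps), not start-to-start distance, because the worked intergenic
  lengths the survey reasons about (24 bp, 106 bp) are lengths of the
  region between the genes.
* **"Long" IR is strictly > 50 bp**; the boundary value 50 is not long.
* Clusters with more than one SBP get `sbp_position = "multiple"` and are
  excluded from the per-side enrichment denominators — the three-way 5' /
  middle / 3' typology presumes a single SBP.
* Coordinates are 1-based inclusive everywhere (GFF3 convention); the
  GenBank reader converts on input. IR sequences are reported as
  sense-strand RNA (reverse-complemented first for minus-strand clusters).
* Runs longer than `max_genes` (default 6) are split; in practice importer
  clusters have 2–5 genes and the cap never binds.

## Hairpin folding

The folding engine searches **single stem-loops only**: one terminal loop
(≥ 3 nt) closed by a chain of nested pairs, consecutive pairs either
stacked or separated by a bulge / internal loop of ≤ 6 nt per side. No
multiloops, no pseudoknots, no dangling ends. This matches the biological
object (intrinsic-terminator hairpins), keeps the dynamic program simple,
and — critically — makes the search space small enough that a brute-force
enumeration oracle can verify the DP exhaustively on short sequences. The
observed unpaired regions in real internal terminators are 1–2 nt, far
inside the 6-nt defect cap.

Energies are a component sum over the chain: nearest-neighbor stacking for
directly stacked pairs, an initiation penalty for each bulge / internal
loop and for the terminal loop, and a +0.5 kcal/mol penalty when the
outermost pair is not G-C. The embedded table
(`version_tag = "embedded-nn-turner99-1.0"`) is the widely reproduced
Turner-1999 stacking matrix over {AU, UA, CG, GC, GU, UG} (GU wobble
allowed in stems) with hairpin initiation tabulated for loops 3–10 and
bulge/internal initiation for 1–6 / 2–6 nt; larger loops use the
Jacobson–Stockmayer extrapolation ΔG(n) = ΔG(n_max) + 1.75·R·T·ln(n/n_max)
at T = 310.15 K. Sequence-dependent 1×1 internal-loop terms, coaxial
stacking and dangling ends are intentionally omitted. **Absolute ΔG values
therefore differ from Mfold/UNAFold**; energies are comparable within this
model, and per-structure energies quoted elsewhere are indicative rather
than targets. The −10 kcal/mol stem-loop gate and the −40..−10 generator
window are applied on this model's scale.

Numerical decisions: ties in the MFE search are broken toward the larger
total stem, then the 5'-most outermost pair, so outputs are bit-stable
across platforms; energy comparisons use a 1e-9 tolerance so float
summation order cannot flip a tie; a structure counts as a fold only if its
energy is negative beyond that tolerance; `min_stem` (default 3) is
enforced via a capped pair-count dimension in the DP, so the reported
optimum is the true optimum over structures with at least that many pairs.
Sequences containing N are never folded (the pipeline skips them with a
warning). `scan_ir` applies the ΔG gate strictly (< −10, not ≤) and records
up to 10 nt of 3' tail context.

The enumeration oracle (`enumerate_hairpins`, guarded at 30 nt) generates
every valid chain recursively and sums its energy incrementally — an
evaluation path independent of both the DP and `hairpin_energy` — and the
test suite checks exact agreement of the minima on hundreds of random
sequences, plus recomputability of every emitted structure's energy.

## Terminator typing

The U-rich window is located structurally: if the stem carries a 1–2 nt
unpaired region (per-side size; a 1×1 internal loop counts as 1), the
window starts at the first 3'-arm base distal to it, because in Types III
and IV the putative U-rich tract is the paired sequence downstream of the
defect; otherwise the window starts at the first unpaired base 3' of the
stem. The window is 8 nt with U counted over the first 7 (the span over
which real terminator tails show a conserved U), clipped at the sequence
end.

The published type descriptions are qualitative except for the ≥ 5 poly(U)
rule, so the cascade constants are the smallest crisp set consistent with
all four descriptions, and they live in `CascadeConfig`:

1. poly(U) run ≥ 5 → **I**
2. no unpaired region and ≥ 2 U in the first 7 nt → **II**
3. 1–2 nt unpaired region, window paired (≥ 2 paired bases), distal arm
   ≤ 4 bp, ≥ 2 U → **III**
4. 1–2 nt unpaired region and (distal arm ≥ 5 bp or < 2 U) → **IV**
5. otherwise **unclassified** — a first-class outcome, since genome scans
   yield hairpins outside the typology. The cascade does not attempt to
   relocate Type IV U-tracts to the stem bottom; that possibility is
   flagged, not guessed.

Mutation operators return plain RNA strings meant to be refolded:
`mutate_delete_5arm` removes 5'-arm bases (testing whether pairing of the
3' U-tract is required), `mutate_stem` adds G-C pairs or deletes pairs at
the loop-proximal end, and `mutate_pair_unpaired` converts the unpaired
region to Watson–Crick pairs — internal loops by rewriting the 3'-arm side
as the reverse complement of the 5'-arm side (A opposite the gap → new A-U
pair), pure bulges by inserting the complementary base(s) on the empty
side. On every Type III/IV generator fixture this strictly lowers the
refolded ΔG (by ~4–6 kcal/mol at defaults), the direction the wet-lab
pairing experiments show.

## Termination efficiency

Northern TE uses the fbfp-probe lane only (both transcript species carry
the upstream reporter); mcherry-probe intensities are consistency checks.
The qPCR mapping TE = 1 − mcherry/fbfp is not written out in the source
experiments; it is the only mapping consistent with comparing qPCR-derived
TE against Northern TE, and is flagged as such. Ratios above 1 are clipped
to TE = 0 with a flag rather than reported negative. ΔCt normalisation
uses a configurable amplification efficiency (default 2.0, perfect
doubling — no efficiencies were available to embed). Replicate summaries
report the sample sd (n−1); single replicates report sd 0 with a
`single_replicate` flag. Correlations are ordinary least squares
(Pearson r, r², slope, intercept) and refuse n < 3 or zero-variance input.

## Enrichment statistics

`hypergeom_sf` computes the exact one-sided upper tail from log-space
binomial coefficients (`lgamma`), with exact short-circuits at k = 0 (p = 1)
and k beyond the support (p = 0); no normal approximation at any size. The
test is one-sided toward the side with the higher hit percentage because
the scientific claim is enrichment; no multiple-testing correction is
applied (two tests are reported). Promoter hits come from an input score
table thresholded at score > 0.9 — the promoter predictor itself is out of
scope. The suite verifies the tail against exhaustive enumeration of all
draws for every parameter combination with N ≤ 12 and against an
independent library implementation at survey size.

## Synthetic data

The generator's defaults are the study conditions, not tuning knobs:

* 30 clusters per genome; SBP position mix 0.70 / 0.01 / 0.29
  (5' / middle / 3'), reflecting the strong 5' bias with ends dominating;
  core arrangements TMD-TMD : TMD-NBD : TMD-TMD-NBD = 0.55 : 0.25 : 0.20
  (one SBP plus two translocator genes is the commonest architecture).
* SBP-adjacent gaps from a bimodal mixture — uniform 0–20 bp (weight 0.45)
  and uniform 60–100 bp — matching the two observed peaks; TMD–NBD gaps
  uniform 0–20 bp (near-seamless linkage).
* Terminator type mix I : II : III : IV : none =
  0.11 : 0.40 : 0.28 : 0.08 : 0.13, the observed type tallies rescaled with
  a "no stem-loop" remainder matching the fraction of long 5'-SBP IRs
  without a call. Per-type ΔG targets are N(μ_t, 3) clipped to [−35, −12],
  with μ_I = −18.3 and μ_IV = −28.4 kcal/mol (Type I weakest, Type IV
  strongest on average) and II/III between.
* Background GC 0.35 (Clostridia-like); assay noise: additive Gaussian on
  band intensities (sd 3 % of the TE scale) and Gaussian Ct noise
  (sd 0.15 cycles), the simplest models consistent with triplicate-sd
  reporting.

Terminator construction is **rejection sampling against the real
fold + classify stack** — never a parallel re-implementation — so an
emitted Type III is whatever the package itself calls Type III. Embedded
terminators are additionally verified in their full IR context
(scan + classify on the exact sense-strand IR the survey will extract),
with the immediate flanks drawn from pairing-inert alphabets so the
designed hairpin remains the MFE of its IR.

The TE-vs-poly(U) calibration dataset uses TE = a + b·u + ε with
σ² = b²·Var(u)·(1 − r²)/r² and Var(u) = 80/12 for u uniform on {0..8}, so
the expected r² equals the requested value; sample r² at n = 200 scatters
a few hundredths around it.

What passing these tests shows — and does not. Recovery is exact by
construction at the annotation level (no coordinate noise), so the survey
round trip demonstrates coordinate/strand correctness, not robustness to
mis-annotation. The generator does not emulate codon structure, real
promoters, RNA degradation kinetics, overlapping genes inside clusters, or
terminators whose MFE competes closely with alternative folds; real
genomes will produce more `unclassified` calls and N-containing IRs are
skipped rather than resolved.

## Problem sizes

The shipped verification runs use 500 random sequences (12–28 nt) for the
fold oracle, 100–200 generator terminators per type for classifier
recovery, 30-cluster genomes for round trips, and n = 200 for the
correlation calibration — sizes at which every stochastic bound in the
suite is comfortably stable while a full run stays around a minute.

## Known limitations

* The energy model is deliberately reduced; ΔG values are not directly
  comparable to Mfold's, so genome-wide counts conditioned on the
  −10 kcal/mol gate will differ from counts produced with other folders.
* Single-hairpin search cannot represent attenuator-style alternative
  structures (none are expected in these operons, but none would be found).
* Whether an IR should be folded with flanking gene sequence is unresolved;
  the pipeline folds the IR alone (`scan_ir` accepts pre-flanked input if a
  caller disagrees).
* Fused SBP-permease genes are treated as `other` unless the input labels
  them; the typology presumes a discrete SBP gene.
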