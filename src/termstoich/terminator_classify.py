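"""Terminator feature extraction, Type I-IV classification and the mutation
operators used to build variant sequences.

Intrinsic (Rho-independent) terminators are GC-rich hairpins followed by a
U-rich tract.  Internal terminators inside ABC-importer operons fall into
four structural types:

* **Type I** — canonical: a poly(U) tail with a consecutive-U run of >= 5.
* **Type II** — the poly(U) tail is replaced by a U-rich tract with fewer
  than five consecutive U.
* **Type III** — a short paired 3' U-rich tract *after* a 1-2 nt unpaired
  region (bulge / small internal loop) in the stem.
* **Type IV** — like Type III but the paired region distal to the unpaired
  region is longer (>= 5 bp) and has little or no U.

The U-rich window is located structurally: if the stem carries a 1-2 nt
unpaired region, the window starts at the first 3'-arm base distal
(downstream) of it; otherwise at the first unpaired base 3' of the stem.
The window is 8 nt, with U counted over its first 7 positions.

Classification thresholds are module constants (``CascadeConfig``); the
qualitative type descriptions pin down only the >= 5 poly(U) rule, so the
remaining constants are the smallest crisp set consistent with all four
descriptions.  ``unclassified`` is a first-class outcome: genome scans
produce hairpins outside the typology.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .rna_fold import Defect, HairpinStructure, PAIRABLE

WINDOW_NT = 8        # U-rich window length
COUNT_NT = 7         # positions over which tail U content is counted
BASES = ("A", "C", "G", "U")

_RNA_WC = {"A": "U", "U": "A", "G": "C", "C": "G"}


@dataclass(frozen=True)
class CascadeConfig:
    """Pinned decision-cascade constants."""

    polyU_type1: int = 5          # consecutive U needed for Type I
    urich_min_U: int = 2          # "U-rich" = at least this many U in the first 7 nt
    max_unpaired: int = 2         # unpaired-region size qualifying for III/IV
    type3_max_distal_bp: int = 4  # distal arm <= this -> III
    type4_min_distal_bp: int = 5  # distal arm >= this -> IV
    type4_max_U: int = 2          # "lower U content": tail_U_count < this -> IV


DEFAULT_CASCADE = CascadeConfig()


@dataclass
class TerminatorFeatures:
    polyU_run: int
    tail_U_count: int
    urich_window: str
    tail_paired: bool
    stem_bp: int
    has_unpaired_region: bool
    unpaired_size: int
    distal_arm_bp: int
    dG: float


@dataclass
class TerminatorCall:
    ir_id: str
    structure: HairpinStructure
    features: TerminatorFeatures
    type_label: str  # I | II | III | IV | unclassified


def _qualifying_defect(
    structure: HairpinStructure, config: CascadeConfig
) -> Optional[Defect]:
    """Loop-proximal 1-2 nt unpaired region (per-side size), if any."""
    for d in structure.defects:  # ordered loop -> outward
        if 1 <= max(d.size_5p, d.size_3p) <= config.max_unpaired:
            return d
    return None


def extract_features(
    structure: HairpinStructure, config: CascadeConfig = DEFAULT_CASCADE
) -> TerminatorFeatures:
    """Locate the U-rich window of *structure* and compute tail/stem features.

    Window rule: (a) with a 1-2 nt unpaired region in the stem the window
    starts at the first 3'-arm base distal to it (the putative U-rich tract
    of Types III/IV is paired sequence downstream of the defect); (b)
    otherwise it starts at the first unpaired base 3' of the stem.  The
    window is clipped at the end of the available sequence.
    """
    seq = structure.sequence
    pairs = sorted(structure.pairs)
    defect = _qualifying_defect(structure, config)
    if defect is not None:
        # outer closing pair of the defect step: pairs are outermost-first,
        # the defect sits between helix `position` (outer side) and
        # `position - 1` (loop side); count pairs outside the defect.
        n_outside = sum(len(seg) for seg in structure.stem_segments[: -defect.position])
        outer_pair = pairs[n_outside - 1]
        start = outer_pair[1]  # 3' base of that pair: first base distal to the defect
        distal_arm_bp = n_outside
    else:
        start = pairs[0][1] + 1 if pairs else 0
        distal_arm_bp = 0

    window = seq[start : start + WINDOW_NT]
    paired = structure.paired_positions()
    n_window_paired = sum(1 for p in range(start, min(start + WINDOW_NT, len(seq))) if p in paired)
    count_region = window[:COUNT_NT]
    return TerminatorFeatures(
        polyU_run=_longest_run(window, "U"),
        tail_U_count=count_region.count("U"),
        urich_window=window,
        tail_paired=n_window_paired >= 2,
        stem_bp=structure.stem_bp,
        has_unpaired_region=len(structure.defects) > 0,
        unpaired_size=(max(defect.size_5p, defect.size_3p) if defect is not None else 0),
        distal_arm_bp=distal_arm_bp,
        dG=structure.dG,
    )


def _longest_run(s: str, ch: str) -> int:
    best = cur = 0
    for c in s:
        cur = cur + 1 if c == ch else 0
        best = max(best, cur)
    return best


def classify_type(
    features: TerminatorFeatures, config: CascadeConfig = DEFAULT_CASCADE
) -> str:
    """Deterministic decision cascade over extracted features."""
    f, c = features, config
    small_defect = f.has_unpaired_region and 1 <= f.unpaired_size <= c.max_unpaired
    if f.polyU_run >= c.polyU_type1:
        return "I"
    if not f.has_unpaired_region and f.tail_U_count >= c.urich_min_U:
        return "II"
    if (
        small_defect
        and f.tail_paired
        and f.distal_arm_bp <= c.type3_max_distal_bp
        and f.tail_U_count >= c.urich_min_U
    ):
        return "III"
    if small_defect and (
        f.distal_arm_bp >= c.type4_min_distal_bp or f.tail_U_count < c.urich_min_U
    ):
        return "IV"
    return "unclassified"


def call_terminator(
    ir_id: str, structure: HairpinStructure, config: CascadeConfig = DEFAULT_CASCADE
) -> TerminatorCall:
    features = extract_features(structure, config)
    return TerminatorCall(
        ir_id=ir_id,
        structure=structure,
        features=features,
        type_label=classify_type(features, config),
    )


# ---------------------------------------------------------------------------
# sequence-conservation summary of the tails


def tail_logo_counts(
    calls: list[TerminatorCall],
) -> tuple[np.ndarray, np.ndarray]:
    """Position x base count matrix over the first 7 window positions, plus
    per-position information content in bits (log2(4) - Shannon entropy).

    Column sums equal the number of calls whose window reaches that position.
    """
    counts = np.zeros((COUNT_NT, len(BASES)), dtype=int)
    for call in calls:
        for pos, base in enumerate(call.features.urich_window[:COUNT_NT]):
            if base in BASES:
                counts[pos, BASES.index(base)] += 1
    info = np.zeros(COUNT_NT)
    for pos in range(COUNT_NT):
        total = counts[pos].sum()
        if total == 0:
            continue
        freqs = counts[pos] / total
        entropy = -sum(p * math.log2(p) for p in freqs if p > 0)
        info[pos] = math.log2(4) - entropy
    return counts, info


# ---------------------------------------------------------------------------
# mutation operators (all return an RNA string meant to be refolded)


def mutate_delete_5arm(structure: HairpinStructure, n: int) -> str:
    """Delete the *n* 5'-most bases of the 5' arm (the experiment that tests
    whether pairing of the 3' U-tract with 5' sequence is required)."""
    if n < 0:
        raise ValueError("n must be >= 0")
    if n == 0:
        return structure.sequence
    if not structure.pairs:
        raise ValueError("structure has no stem to truncate")
    i0 = sorted(structure.pairs)[0][0]
    return structure.sequence[:i0] + structure.sequence[i0 + n :]


def mutate_stem(structure: HairpinStructure, delta_bp: int) -> str:
    """Shorten (delta < 0) or lengthen (delta > 0) the stem at its
    loop-proximal end; positive deltas insert G-C pairs."""
    seq = structure.sequence
    if delta_bp == 0:
        return seq
    pairs = sorted(structure.pairs)
    if not pairs:
        raise ValueError("structure has no stem to modify")
    if delta_bp > 0:
        k, l = pairs[-1]
        return seq[: k + 1] + "G" * delta_bp + seq[k + 1 : l] + "C" * delta_bp + seq[l:]
    n_del = min(-delta_bp, len(pairs))
    drop = {p for pair in pairs[-n_del:] for p in pair}
    return "".join(b for idx, b in enumerate(seq) if idx not in drop)


def mutate_pair_unpaired(
    structure: HairpinStructure, config: CascadeConfig = DEFAULT_CASCADE
) -> str:
    """Convert the 1-2 nt unpaired region into Watson-Crick pairs.

    Internal loops: the 3'-arm side is rewritten as the reverse complement of
    the 5'-arm side (an A opposite the gap acquires a U partner; a G a C —
    the A-T / G-C outcomes of the pairing experiment).  Pure bulges: the
    complementary base(s) are inserted on the empty side.  Refolding the
    result removes the unpaired region and lowers dG.  A structure without a
    qualifying unpaired region is returned unchanged with a warning.
    """
    seq = structure.sequence
    defect = _qualifying_defect(structure, config)
    if defect is None:
        warnings.warn("structure has no 1-2 nt unpaired region; sequence unchanged")
        return seq
    pairs = sorted(structure.pairs)
    n_outside = sum(len(seg) for seg in structure.stem_segments[: -defect.position])
    i, j = pairs[n_outside - 1]   # outer closing pair of the defect step
    k, l = pairs[n_outside]       # inner closing pair
    gap5 = seq[i + 1 : k]
    gap3 = seq[l + 1 : j]
    if gap5 and gap3:
        new_gap3 = _revcomp_rna(gap5)
        return seq[: l + 1] + new_gap3 + seq[j:]
    if gap5:  # bulge on the 5' arm: insert partners on the 3' side
        return seq[: l + 1] + _revcomp_rna(gap5) + seq[l + 1 :]
    # bulge on the 3' arm: insert partners on the 5' side
    return seq[: i + 1] + _revcomp_rna(gap3) + seq[i + 1 :]


def _revcomp_rna(s: str) -> str:
    return "".join(_RNA_WC[b] for b in reversed(s))


def parse_dot_bracket(db: str) -> list[tuple[int, int]]:
    """Dot-bracket notation -> sorted pair list (used by the CLI round trip)."""
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for idx, ch in enumerate(db):
        if ch == "(":
            stack.append(idx)
        elif ch == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket string")
            pairs.append((stack.pop(), idx))
    if stack:
        raise ValueError("unbalanced dot-bracket string")
    return sorted(pairs)
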