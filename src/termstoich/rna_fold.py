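"""Minimum-free-energy single-hairpin folding with an embedded
nearest-neighbor thermodynamic model.

The search space is the space of single stem-loops: one terminal loop
(>= ``min_loop`` nt) closed by a chain of nested base pairs, where
consecutive pairs are either stacked or separated by a bulge / internal
loop of at most 6 unpaired nt per side.  Multiloops and pseudoknots are
outside the space — the biological objects of interest here are intrinsic
terminator hairpins, which are single stem-loops.

The energy of a structure is the component sum

    dG = sum(stacking terms) + hairpin_init(loop size)
         + sum(bulge/internal-loop penalties) + terminal non-GC penalty

evaluated with an embedded nearest-neighbor parameter set at 37 degC
(Turner-1999-style stacking including GU wobble; Jacobson-Stockmayer
extrapolation for loop sizes beyond the tables).  Absolute values differ
from Mfold/UNAFold, so per-structure free energies are comparable within
this model, not across predictors.

``min_hairpin`` is a dynamic program over closing pairs; ``enumerate_hairpins``
is the brute-force enumeration of the identical space, kept as an
independent test oracle for short sequences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

# ---------------------------------------------------------------------------
# energy parameters

R_KCAL = 1.987e-3  # kcal / (mol K)
T_KELVIN = 310.15  # 37 degC
JS_COEF = 1.75     # Jacobson-Stockmayer loop-entropy coefficient

PAIRABLE = {"AU", "UA", "CG", "GC", "GU", "UG"}
WC = {"AU", "UA", "CG", "GC"}
_PAIR_ORDER = ("CG", "GC", "GU", "UG", "AU", "UA")

# stack[outer][inner-reversed]: free energy (kcal/mol) of inner pair (k,l)
# stacked directly on outer pair (i,j), indexed as M[bp(i,j)][bp(l,k)].
# Symmetric 6x6 table over the pair order above.
_STACK_MATRIX = [
    # CG     GC     GU     UG     AU     UA
    [-2.40, -3.30, -2.10, -1.40, -2.10, -2.10],  # CG
    [-3.30, -3.40, -2.50, -1.50, -2.20, -2.40],  # GC
    [-2.10, -2.50, +1.30, -0.50, -1.40, -1.30],  # GU
    [-1.40, -1.50, -0.50, +0.30, -0.60, -1.00],  # UG
    [-2.10, -2.20, -1.40, -0.60, -1.10, -0.90],  # AU
    [-2.10, -2.40, -1.30, -1.00, -0.90, -1.30],  # UA
]

_HAIRPIN_INIT_TABLE = {
    3: 5.70, 4: 5.60, 5: 5.60, 6: 5.40, 7: 5.90, 8: 5.60, 9: 6.40, 10: 6.50,
}
_BULGE_INIT_TABLE = {1: 3.80, 2: 2.80, 3: 3.20, 4: 3.60, 5: 4.00, 6: 4.40}
_INTERNAL_INIT_TABLE = {2: 1.50, 3: 1.60, 4: 1.70, 5: 1.80, 6: 2.00}


def _extend_table(tbl: dict[int, float], n_max: int) -> dict[int, float]:
    out = dict(tbl)
    base = max(tbl)
    for n in range(base + 1, n_max + 1):
        out[n] = tbl[base] + JS_COEF * R_KCAL * T_KELVIN * math.log(n / base)
    return out


@dataclass(frozen=True)
class EnergyParams:
    """Nearest-neighbor parameter set (37 degC, kcal/mol)."""

    stack_dG: dict[str, float]          # key "XY|ZW": outer pair XY, inner pair ZW
    hairpin_init: dict[int, float]      # loop size 3..30
    bulge_init: dict[int, float]        # 1..6
    internal_init: dict[int, float]     # 2..6 (total unpaired nt)
    terminal_AU_penalty: float
    version_tag: str

    def stack(self, outer: str, inner: str) -> float:
        return self.stack_dG[f"{outer}|{inner}"]

    def loop_penalty(self, table: dict[int, float], n: int) -> float:
        if n in table:
            return table[n]
        n_max = max(table)
        return table[n_max] + JS_COEF * R_KCAL * T_KELVIN * math.log(n / n_max)

    def scaled(self, factor: float) -> "EnergyParams":
        return EnergyParams(
            stack_dG={k: v * factor for k, v in self.stack_dG.items()},
            hairpin_init={k: v * factor for k, v in self.hairpin_init.items()},
            bulge_init={k: v * factor for k, v in self.bulge_init.items()},
            internal_init={k: v * factor for k, v in self.internal_init.items()},
            terminal_AU_penalty=self.terminal_AU_penalty * factor,
            version_tag=f"{self.version_tag}-x{factor:g}",
        )


def _build_default_params() -> EnergyParams:
    stack = {}
    for a, outer in enumerate(_PAIR_ORDER):
        for b, inner_rev in enumerate(_PAIR_ORDER):
            inner = inner_rev[::-1]  # matrix is indexed by the reversed inner pair
            stack[f"{outer}|{inner}"] = _STACK_MATRIX[a][b]
    return EnergyParams(
        stack_dG=stack,
        hairpin_init=_extend_table(_HAIRPIN_INIT_TABLE, 30),
        bulge_init=dict(_BULGE_INIT_TABLE),
        internal_init=dict(_INTERNAL_INIT_TABLE),
        terminal_AU_penalty=0.50,
        version_tag="embedded-nn-turner99-1.0",
    )


DEFAULT_PARAMS = _build_default_params()

MAX_DEFECT_SIDE = 6   # max unpaired nt per side of a bulge / internal loop
TAIL_RECORD_NT = 10   # 3'/5' unpaired context recorded on structures

# ---------------------------------------------------------------------------
# structures


@dataclass(frozen=True)
class Defect:
    kind: str      # "bulge" | "internal"
    size_5p: int
    size_3p: int
    position: int  # helix index from the loop (1 = just outside the loop-proximal helix)


@dataclass
class HairpinStructure:
    """A single stem-loop: nested pair chain, per-element defects, energy.

    ``pairs`` are 0-based (i, j) indices into ``sequence``, sorted outermost
    first.  ``dG`` is recomputable from the attached parameter set via
    :func:`hairpin_energy`.
    """

    sequence: str
    pairs: list[tuple[int, int]]
    loop_size: int
    stem_segments: list[list[tuple[int, int]]] = field(default_factory=list)
    defects: list[Defect] = field(default_factory=list)
    tail_5p: str = ""
    tail_3p: str = ""
    dG: float = 0.0

    @property
    def stem_bp(self) -> int:
        return len(self.pairs)

    @property
    def outermost(self) -> Optional[tuple[int, int]]:
        return self.pairs[0] if self.pairs else None

    @property
    def innermost(self) -> Optional[tuple[int, int]]:
        return self.pairs[-1] if self.pairs else None

    def paired_positions(self) -> set[int]:
        out: set[int] = set()
        for i, j in self.pairs:
            out.add(i)
            out.add(j)
        return out

    def dot_bracket(self) -> str:
        db = ["." for _ in self.sequence]
        for i, j in self.pairs:
            db[i], db[j] = "(", ")"
        return "".join(db)


def _validate_rna(seq: str) -> None:
    bad = set(seq) - set("ACGU")
    if bad:
        raise ValueError(f"non-ACGU characters in RNA sequence: {sorted(bad)}")


def structure_from_pairs(
    sequence: str, pairs: list[tuple[int, int]], dG: float = 0.0
) -> HairpinStructure:
    """Build a :class:`HairpinStructure` (segments, defects, tails) from a
    nested single-hairpin pair chain; validates the chain shape."""
    _validate_rna(sequence)
    pairs = sorted(pairs)
    if not pairs:
        return HairpinStructure(sequence=sequence, pairs=[], loop_size=0, dG=dG)
    for i, j in pairs:
        if not (0 <= i < j < len(sequence)):
            raise ValueError(f"pair ({i},{j}) out of range")
        if sequence[i] + sequence[j] not in PAIRABLE:
            raise ValueError(
                f"bases {sequence[i]}{sequence[j]} at ({i},{j}) cannot pair"
            )
    for (i, j), (k, l) in zip(pairs, pairs[1:]):
        if not (i < k < l < j):
            raise ValueError("pairs do not form a single nested hairpin chain")
        if k - i - 1 > MAX_DEFECT_SIDE or j - l - 1 > MAX_DEFECT_SIDE:
            raise ValueError("bulge/internal loop larger than 6 nt per side")
    ki, kj = pairs[-1]
    loop = kj - ki - 1
    if loop < 3:
        raise ValueError(f"terminal loop of {loop} nt (< 3)")

    # helices and defects, walking from the loop outwards
    rev = list(reversed(pairs))  # innermost first
    segments_rev: list[list[tuple[int, int]]] = [[rev[0]]]
    defects: list[Defect] = []
    for inner, outer in zip(rev, rev[1:]):
        d5 = inner[0] - outer[0] - 1
        d3 = outer[1] - inner[1] - 1
        if d5 == 0 and d3 == 0:
            segments_rev[-1].append(outer)
        else:
            defects.append(
                Defect(
                    kind="bulge" if (d5 == 0 or d3 == 0) else "internal",
                    size_5p=d5,
                    size_3p=d3,
                    position=len(segments_rev),
                )
            )
            segments_rev.append([outer])
    segments = [sorted(seg) for seg in segments_rev[::-1]]
    i0, j0 = pairs[0]
    return HairpinStructure(
        sequence=sequence,
        pairs=pairs,
        loop_size=loop,
        stem_segments=segments,
        defects=defects,
        tail_5p=sequence[max(0, i0 - TAIL_RECORD_NT) : i0],
        tail_3p=sequence[j0 + 1 : j0 + 1 + TAIL_RECORD_NT],
        dG=dG,
    )


# ---------------------------------------------------------------------------
# energy evaluation


def hairpin_energy(structure: HairpinStructure, params: EnergyParams = DEFAULT_PARAMS) -> float:
    """Recompute the component-sum free energy of *structure* (kcal/mol).

    A structure with no pairs has dG = 0 by definition.
    """
    seq = structure.sequence
    pairs = sorted(structure.pairs)
    if not pairs:
        return 0.0
    for i, j in pairs:
        if seq[i] + seq[j] not in PAIRABLE:
            raise ValueError(f"bases {seq[i]}{seq[j]} at ({i},{j}) cannot pair")
    e = 0.0
    for (i, j), (k, l) in zip(pairs, pairs[1:]):
        d5, d3 = k - i - 1, j - l - 1
        if d5 == 0 and d3 == 0:
            e += params.stack(seq[i] + seq[j], seq[k] + seq[l])
        elif d5 == 0 or d3 == 0:
            e += params.loop_penalty(params.bulge_init, d5 + d3)
        else:
            e += params.loop_penalty(params.internal_init, d5 + d3)
    ki, kj = pairs[-1]
    loop = kj - ki - 1
    if loop < 3:
        raise ValueError("terminal loop smaller than 3 nt")
    e += params.loop_penalty(params.hairpin_init, loop)
    i0, j0 = pairs[0]
    if seq[i0] + seq[j0] not in ("CG", "GC"):
        e += params.terminal_AU_penalty
    return e


# ---------------------------------------------------------------------------
# MFE search (dynamic programming)

_EPS = 1e-9


def min_hairpin(
    sequence: str,
    params: EnergyParams = DEFAULT_PARAMS,
    min_stem: int = 3,
    min_loop: int = 3,
) -> Optional[HairpinStructure]:
    """Minimum-dG single hairpin in *sequence*, or None if no structure with
    dG < 0 and at least *min_stem* pairs exists.

    Ties in energy are broken toward the larger total stem, then the
    5'-most outermost pair, so output is platform-stable.
    """
    _validate_rna(sequence)
    n = len(sequence)
    if n < 2 * min_stem + min_loop:
        return None

    can_pair = [[sequence[i] + sequence[j] in PAIRABLE for j in range(n)] for i in range(n)]

    # V[(i, j)][c] = best (dG, total_bp) over structures closed by pair (i,j)
    # containing c pairs, with c capped at min_stem ("min_stem or more").
    V: dict[tuple[int, int], list[Optional[tuple[float, int]]]] = {}
    choice: dict[tuple[int, int, int], tuple] = {}

    hp_tbl, bg_tbl, in_tbl = params.hairpin_init, params.bulge_init, params.internal_init

    for span in range(min_loop + 1, n):
        for i in range(0, n - span):
            j = i + span
            if not can_pair[i][j]:
                continue
            best: list[Optional[tuple[float, int]]] = [None] * (min_stem + 1)
            pick: list[Optional[tuple]] = [None] * (min_stem + 1)

            loop = j - i - 1
            if loop >= min_loop:
                best[1] = (params.loop_penalty(hp_tbl, loop), 1)
                pick[1] = ("hairpin",)

            outer_bp = sequence[i] + sequence[j]
            for k in range(i + 1, min(i + MAX_DEFECT_SIDE + 2, j)):
                d5 = k - i - 1
                for l in range(max(j - MAX_DEFECT_SIDE - 1, k + 1), j):
                    inner = V.get((k, l))
                    if inner is None or not can_pair[k][l]:
                        continue
                    d3 = j - l - 1
                    if d5 == 0 and d3 == 0:
                        pen = params.stack(outer_bp, sequence[k] + sequence[l])
                    elif d5 == 0 or d3 == 0:
                        pen = params.loop_penalty(bg_tbl, d5 + d3)
                    else:
                        pen = params.loop_penalty(in_tbl, d5 + d3)
                    for c_in in range(1, min_stem + 1):
                        if inner[c_in] is None:
                            continue
                        e_in, bp_in = inner[c_in]
                        c_new = min(c_in + 1, min_stem)
                        cand = (pen + e_in, bp_in + 1)
                        cur = best[c_new]
                        if (
                            cur is None
                            or cand[0] < cur[0] - _EPS
                            or (abs(cand[0] - cur[0]) <= _EPS and cand[1] > cur[1])
                        ):
                            best[c_new] = cand
                            pick[c_new] = ("extend", k, l, c_in)
            if any(b is not None for b in best):
                V[(i, j)] = best
                for c in range(1, min_stem + 1):
                    if pick[c] is not None:
                        choice[(i, j, c)] = pick[c]

    # global optimum over outermost pairs with >= min_stem pairs
    winner: Optional[tuple[float, int, int, int, int]] = None  # (dG, -bp, i, j)
    for (i, j), arr in V.items():
        if arr[min_stem] is None:
            continue
        e, bp = arr[min_stem]
        bp_str = sequence[i] + sequence[j]
        total = e + (0.0 if bp_str in ("CG", "GC") else params.terminal_AU_penalty)
        key = (total, -bp, i, j)
        if winner is None or _lex_less(key, winner):
            winner = key
    if winner is None or winner[0] >= -_EPS:
        return None

    total_dG, _, i0, j0 = winner
    pairs: list[tuple[int, int]] = []
    i, j, c = i0, j0, min_stem
    while True:
        pairs.append((i, j))
        step = choice[(i, j, c)]
        if step[0] == "hairpin":
            break
        _, i, j, c = step
    return structure_from_pairs(sequence, pairs, dG=total_dG)


def _lex_less(a: tuple, b: tuple) -> bool:
    # energies compared with a small tolerance, remaining fields exactly
    if a[0] < b[0] - _EPS:
        return True
    if a[0] > b[0] + _EPS:
        return False
    return a[1:] < b[1:]


# ---------------------------------------------------------------------------
# brute-force oracle

MAX_ENUM_LEN = 30


def enumerate_hairpins(
    sequence: str,
    params: EnergyParams = DEFAULT_PARAMS,
    min_loop: int = 3,
    min_stem: int = 1,
) -> list[tuple[HairpinStructure, float]]:
    """Exhaustively enumerate every valid single-hairpin structure of a short
    sequence (guarded at 30 nt) with its component-sum energy.

    This is the independent test oracle for :func:`min_hairpin`: its chains
    are generated by recursive extension and scored by
    :func:`hairpin_energy`, not by the dynamic program.
    """
    _validate_rna(sequence)
    n = len(sequence)
    if n > MAX_ENUM_LEN:
        raise ValueError(f"enumerate_hairpins is limited to {MAX_ENUM_LEN} nt (got {n})")
    results: list[tuple[HairpinStructure, float]] = []
    au = params.terminal_AU_penalty

    # energies are summed incrementally along each chain — an independent
    # second evaluation path from both min_hairpin's DP and hairpin_energy
    def extend(chain: list[tuple[int, int]], e_acc: float) -> None:
        i, j = chain[-1]
        loop = j - i - 1
        if loop >= min_loop and len(chain) >= min_stem:
            i0, j0 = chain[0]
            e = (
                e_acc
                + params.loop_penalty(params.hairpin_init, loop)
                + (0.0 if sequence[i0] + sequence[j0] in ("CG", "GC") else au)
            )
            st = HairpinStructure(
                sequence=sequence, pairs=list(chain), loop_size=loop, dG=e
            )
            results.append((st, e))
        for k in range(i + 1, min(i + MAX_DEFECT_SIDE + 2, j)):
            d5 = k - i - 1
            for l in range(max(j - MAX_DEFECT_SIDE - 1, k + 1), j):
                if sequence[k] + sequence[l] not in PAIRABLE:
                    continue
                d3 = j - l - 1
                if d5 == 0 and d3 == 0:
                    step = params.stack(sequence[i] + sequence[j], sequence[k] + sequence[l])
                elif d5 == 0 or d3 == 0:
                    step = params.loop_penalty(params.bulge_init, d5 + d3)
                else:
                    step = params.loop_penalty(params.internal_init, d5 + d3)
                chain.append((k, l))
                extend(chain, e_acc + step)
                chain.pop()

    for i in range(n):
        for j in range(i + min_loop + 1, n):
            if sequence[i] + sequence[j] in PAIRABLE:
                extend([(i, j)], 0.0)
    return results


# ---------------------------------------------------------------------------
# IR scanning


def scan_ir(
    ir,
    params: EnergyParams = DEFAULT_PARAMS,
    dG_threshold: float = -10.0,
    min_stem: int = 3,
    min_loop: int = 3,
) -> Optional[HairpinStructure]:
    """MFE hairpin of an intergenic region, reported only if its free energy
    is strictly below *dG_threshold* (default -10 kcal/mol, the stem-loop
    calling gate).  Regions containing N are not folded (returns None; the
    caller is expected to have filtered and warned)."""
    seq = ir.sequence if hasattr(ir, "sequence") else str(ir)
    if "N" in seq:
        return None
    st = min_hairpin(seq, params=params, min_stem=min_stem, min_loop=min_loop)
    if st is None or st.dG >= dG_threshold:
        return None
    return st
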