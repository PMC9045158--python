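"""Termination-efficiency (TE) quantification from Northern-blot band
intensities and from dual-reporter qPCR, with replicate statistics.

In the dual-fluorescence reporter assay a candidate terminator is inserted
between an upstream reporter (*fbfp*) and a downstream reporter (*mcherry*).
Termination produces a monocistronic *fbfp* transcript; read-through
produces the bicistronic *fbfp-mcherry* transcript.  From band
densitometry,

    TE = 100 * I_mono / (I_mono + I_bi)        (fbfp-probe lane)

and from qPCR relative levels, since every transcript carries *fbfp* but
only read-through carries *mcherry*,

    TE = 100 * (1 - level_mcherry / level_fbfp), clipped to [0, 100].

Relative levels follow the delta-Ct method against a reference gene with a
configurable amplification efficiency (default 2.0 per cycle).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class BandIntensityRecord:
    construct_id: str
    probe: str  # "fbfp" | "mcherry"
    I_mono: float
    I_bi: float
    replicate: int

    def __post_init__(self) -> None:
        if self.I_mono < 0 or self.I_bi < 0:
            raise ValueError(f"{self.construct_id}: negative band intensity")


@dataclass(frozen=True)
class QpcrRecord:
    construct_id: str
    gene: str  # "fbfp" | "mcherry" | "reference"
    Ct: float
    replicate: int

    def __post_init__(self) -> None:
        if self.Ct <= 0:
            raise ValueError(f"{self.construct_id}: Ct must be > 0")


@dataclass
class TEMeasurement:
    construct_id: str
    te_percent: float
    sd_percent: float
    method: str  # "northern" | "qpcr"
    n_replicates: int
    single_replicate: bool = False  # sd reported as 0 from a lone replicate
    clipped: bool = False


def te_from_bands(record: BandIntensityRecord) -> float:
    """TE (%) from one fbfp-probe lane: 100 * mono / (mono + bi)."""
    total = record.I_mono + record.I_bi
    if total <= 0:
        raise ValueError(
            f"{record.construct_id} rep {record.replicate}: both band intensities are zero"
        )
    return 100.0 * record.I_mono / total


def te_from_qpcr(rel_fbfp: float, rel_mcherry: float) -> tuple[float, bool]:
    """TE (%) from relative transcript levels; returns (te, clipped)."""
    if rel_fbfp <= 0:
        raise ValueError("relative fbfp level must be > 0")
    te = 100.0 * (1.0 - rel_mcherry / rel_fbfp)
    if te < 0.0:
        return 0.0, True
    if te > 100.0:
        return 100.0, True
    return te, False


def relative_level(target_Ct: float, ref_Ct: float, efficiency: float = 2.0) -> float:
    """Reference-normalised expression: efficiency ** (ref_Ct - target_Ct)."""
    if efficiency <= 1.0:
        raise ValueError("amplification efficiency must be > 1")
    return efficiency ** (ref_Ct - target_Ct)


def read_through_fraction(record: BandIntensityRecord) -> float:
    return 100.0 - te_from_bands(record)


def aggregate_te(records: Sequence, method: str, efficiency: float = 2.0) -> list[TEMeasurement]:
    """Per-construct mean and sample sd (n-1) of per-replicate TEs.

    ``method="northern"`` expects :class:`BandIntensityRecord` (fbfp probe
    only is used); ``method="qpcr"`` expects :class:`QpcrRecord` triples
    (fbfp / mcherry / reference per replicate).  Records for which TE cannot
    be computed are excluded with a warning.
    """
    per_construct: dict[str, list[float]] = {}
    any_clip = set()
    if method == "northern":
        for rec in records:
            if rec.probe != "fbfp":
                continue  # mcherry-probe lanes are consistency checks, not TE
            try:
                te = te_from_bands(rec)
            except ValueError as exc:
                log.warning("excluding band record: %s", exc)
                continue
            per_construct.setdefault(rec.construct_id, []).append(te)
    elif method == "qpcr":
        by_key: dict[tuple[str, int], dict[str, float]] = {}
        for rec in records:
            by_key.setdefault((rec.construct_id, rec.replicate), {})[rec.gene] = rec.Ct
        for (cid, rep), cts in sorted(by_key.items()):
            if not {"fbfp", "mcherry", "reference"} <= set(cts):
                log.warning("excluding qPCR replicate %s/%s: incomplete gene set", cid, rep)
                continue
            rel_f = relative_level(cts["fbfp"], cts["reference"], efficiency)
            rel_m = relative_level(cts["mcherry"], cts["reference"], efficiency)
            te, clipped = te_from_qpcr(rel_f, rel_m)
            if clipped:
                any_clip.add(cid)
            per_construct.setdefault(cid, []).append(te)
    else:
        raise ValueError(f"unknown method {method!r}")

    out = []
    for cid in sorted(per_construct):
        tes = per_construct[cid]
        n = len(tes)
        mean = float(np.mean(tes))
        sd = float(np.std(tes, ddof=1)) if n >= 2 else 0.0
        out.append(
            TEMeasurement(
                construct_id=cid,
                te_percent=mean,
                sd_percent=sd,
                method=method,
                n_replicates=n,
                single_replicate=(n < 2),
                clipped=(cid in any_clip),
            )
        )
    return out


@dataclass
class CorrelationResult:
    r: float
    r2: float
    slope: float
    intercept: float
    n: int


def correlate(x: Iterable[float], y: Iterable[float]) -> CorrelationResult:
    """Pearson correlation and least-squares line between two measurements."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 points to correlate")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in input")
    fit = stats.linregress(x, y)
    return CorrelationResult(
        r=float(fit.rvalue),
        r2=float(fit.rvalue**2),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        n=len(x),
    )


def log2_fold_change(upstream_level: float, downstream_level: float) -> float:
    """log2(upstream / downstream) transcript-level fold change."""
    if upstream_level <= 0 or downstream_level <= 0:
        raise ValueError("levels must be > 0")
    return math.log2(upstream_level / downstream_level)
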