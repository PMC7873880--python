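"""From scan p-values to detection statistics.

Per replicate and model: apply BH-FDR genome-wide (each scan adjusted
separately, never pooled across traits), call a QTN "detected" when any
significant marker lies within a physical window of it, and flag an error
when a significant marker falls outside every QTN window.  Per scenario:
percentages over replicates.  The multivariate rates under the independent
and linked architectures are the "spurious pleiotropy detection rate" —
the joint test flags both QTN neighborhoods even though no single locus is
pleiotropic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from pleiolink.genotypes import GenotypeMatrix, pairwise_r2
from pleiolink.mlm import ScanResult
from pleiolink.traits import QTNAssignment, ScenarioConfig

logger = logging.getLogger(__name__)

__all__ = [
    "DetectionOutcome",
    "DetectionSummary",
    "bh_adjust",
    "detect_qtn",
    "score_replicate",
    "summarize_scenario",
    "regional_ld",
]


@dataclass
class DetectionOutcome:
    """Flags for one replicate under one model."""

    model: str
    detected_t1: bool
    detected_t2: bool
    detected_both: bool
    error_flag: bool


@dataclass
class DetectionSummary:
    """Percentages over replicates for one scenario x model."""

    model: str
    rate_t1: float
    rate_t2: float
    rate_both: float
    error_rate: float
    n_replicates: int
    label: str  # "QTN detection rate" | "spurious pleiotropy detection rate"


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (original order)."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals.copy()
    if np.any(~np.isfinite(pvals)) or np.any(pvals <= 0) or np.any(pvals > 1):
        raise ValueError("p-values must be finite and in (0, 1]; drop undefined rows first")
    return multipletests(pvals, method="fdr_bh")[1]


def detect_qtn(
    significant: list[tuple[str, int]], qtn: tuple[str, int], window_bp: float
) -> bool:
    """True iff any significant marker is on the QTN's chromosome within the
    window (boundary inclusive)."""
    if window_bp <= 0:
        raise ValueError("window must be positive")
    chrom_q, pos_q = qtn
    return any(
        chrom == str(chrom_q) and abs(int(pos) - int(pos_q)) <= window_bp
        for chrom, pos in significant
    )


def _significant_markers(scan: ScanResult, fdr_level: float) -> list[tuple[str, int]]:
    t = scan.table
    ok = np.isfinite(t["p"].to_numpy())
    if not ok.any():
        return []
    adj = bh_adjust(t.loc[ok, "p"].to_numpy())
    sig = t.loc[ok].loc[adj < fdr_level]
    return [(str(c), int(p)) for c, p in zip(sig["chrom"], sig["pos"])]


def score_replicate(
    scans: dict[str, ScanResult],
    assignment: QTNAssignment,
    window_bp: float,
    fdr_level: float,
) -> list[DetectionOutcome]:
    """Detection flags for the univariate and multivariate models of one replicate.

    BH is applied per scan.  The multivariate model's trait-t flag uses
    trait t's QTN window (the two windows coincide under pleiotropy); the
    univariate model's trait-t flag uses trait t's own scan and window.
    The error flag marks any significant marker outside both QTN windows
    (for the univariate model, evaluated per scan and OR-ed).
    """
    for key in ("univariate_trait1", "univariate_trait2", "multivariate"):
        if key not in scans:
            raise ValueError(f"missing scan {key!r}")
    q1 = (assignment.chrom1, assignment.pos1)
    q2 = (assignment.chrom2, assignment.pos2)

    def outside_both(sig: list[tuple[str, int]]) -> bool:
        return any(
            not detect_qtn([m], q1, window_bp) and not detect_qtn([m], q2, window_bp)
            for m in sig
        )

    sig_m = _significant_markers(scans["multivariate"], fdr_level)
    m_t1 = detect_qtn(sig_m, q1, window_bp)
    m_t2 = detect_qtn(sig_m, q2, window_bp)
    multi = DetectionOutcome(
        "multivariate", m_t1, m_t2, m_t1 and m_t2, outside_both(sig_m)
    )

    sig_u1 = _significant_markers(scans["univariate_trait1"], fdr_level)
    sig_u2 = _significant_markers(scans["univariate_trait2"], fdr_level)
    u_t1 = detect_qtn(sig_u1, q1, window_bp)
    u_t2 = detect_qtn(sig_u2, q2, window_bp)
    uni = DetectionOutcome(
        "univariate",
        u_t1,
        u_t2,
        u_t1 and u_t2,
        outside_both(sig_u1) or outside_both(sig_u2),
    )
    return [uni, multi]


def summarize_scenario(
    outcomes: list[DetectionOutcome], scenario: ScenarioConfig
) -> list[DetectionSummary]:
    """Percentages over replicates, one summary per model."""
    if not outcomes:
        raise ValueError("no outcomes to summarize")
    summaries = []
    for model in ("univariate", "multivariate"):
        rows = [o for o in outcomes if o.model == model]
        if not rows:
            continue
        n = len(rows)
        label = (
            "spurious pleiotropy detection rate"
            if model == "multivariate"
            and scenario.architecture in ("independent", "ld_direct", "ld_indirect")
            else "QTN detection rate"
        )
        summaries.append(
            DetectionSummary(
                model=model,
                rate_t1=100.0 * sum(o.detected_t1 for o in rows) / n,
                rate_t2=100.0 * sum(o.detected_t2 for o in rows) / n,
                rate_both=100.0 * sum(o.detected_both for o in rows) / n,
                error_rate=100.0 * sum(o.error_flag for o in rows) / n,
                n_replicates=n,
                label=label,
            )
        )
    return summaries


def regional_ld(G: GenotypeMatrix, qtn_index: int, flank: int = 20) -> np.ndarray:
    """r2 between the QTN and up to ``flank`` markers on each side (same
    chromosome, truncated at the ends; monomorphic neighbors skipped)."""
    chroms = G.marker_map["chrom"].to_numpy()
    same = np.flatnonzero(chroms == chroms[qtn_index])
    k = int(np.searchsorted(same, qtn_index))
    neighbors = np.concatenate([same[max(0, k - flank) : k], same[k + 1 : k + 1 + flank]])
    x = G.dosages[:, qtn_index]
    if np.ptp(x) == 0:
        raise ValueError("QTN is monomorphic")
    out = []
    for j in neighbors:
        if np.ptp(G.dosages[:, j]) == 0:
            logger.info("skipping monomorphic neighbor at index %d", j)
            continue
        out.append(pairwise_r2(x, G.dosages[:, j]))
    return np.asarray(out)
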