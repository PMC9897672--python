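"""Zygotic DEG calling and its relationship to disrupted TAD boundaries.

The differential-expression statistics themselves are inputs (log2FC and p- or
q-values per gene); this module applies the zygotic filter (maternally
deposited genes removed), the strict DEG thresholds |log2FC| > 0.7 and
FDR < 0.05, promoter/insulator-peak overlap (TSS +/- 500 bp), DEG-to-boundary
distance comparisons, and enhancer-hijacking candidate detection: up-regulated
zygotic DEGs whose TSS lies in one of the two TADs flanking a disrupted
boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import TestResult, bh_adjust, fisher_exact_2x2, ks_two_sample

logger = logging.getLogger(__name__)

LFC_MIN = 0.7
Q_MAX = 0.05
PROMOTER_FLANK = 500


@dataclass
class HijackCandidate:
    gene_id: str
    boundary_position: int
    side: str  # which flanking TAD, 'left' or 'right'
    log2fc: float


def filter_zygotic(genes: pd.DataFrame) -> pd.DataFrame:
    """Drop maternally deposited genes (maternal flag true)."""
    if "maternal" not in genes.columns:
        raise ValueError("gene table has no 'maternal' column")
    n_mat = int(genes["maternal"].sum())
    logger.info("zygotic filter: removing %d maternal of %d genes", n_mat, len(genes))
    return genes.loc[~genes["maternal"]].reset_index(drop=True)


def call_degs(genes: pd.DataFrame, lfc_min: float = LFC_MIN,
              q_max: float = Q_MAX, contrast: str = "") -> pd.DataFrame:
    """Strict DEG call: |log2FC| > lfc_min and q < q_max.

    Expects a zygotic gene table.  If no q-values are present, BH adjustment
    is applied to the p-values within the supplied (zygotic) universe.
    """
    genes = genes.copy()
    if "qvalue" not in genes.columns:
        if "pvalue" not in genes.columns:
            raise ValueError("gene table has neither q-values nor p-values")
        genes["qvalue"] = bh_adjust(genes["pvalue"])
    keep = (genes["log2fc"].abs() > lfc_min) & (genes["qvalue"] < q_max)
    degs = genes.loc[keep].copy()
    degs["direction"] = np.where(degs["log2fc"] > 0, "up", "down")
    degs["contrast"] = contrast
    return degs.reset_index(drop=True)


def promoter_overlap(degs: pd.DataFrame, peakset, universe: pd.DataFrame,
                     flank: int = PROMOTER_FLANK
                     ) -> tuple[float, TestResult, np.ndarray]:
    """Fraction of DEGs whose promoter (TSS +/- flank, half-open) overlaps a peak.

    Returns (fraction bound, Fisher test of bound x DEG over the zygotic
    universe, per-DEG bound mask).  A peak overlaps the promoter iff
    peak.start < tss + flank and peak.end > tss - flank.
    """
    if len(universe) == 0:
        raise ValueError("empty gene universe")
    starts = np.array([p.start for p in peakset], dtype=float)
    ends = np.array([p.end for p in peakset], dtype=float)
    chroms = np.array([p.chrom for p in peakset])

    def bound_mask(table: pd.DataFrame) -> np.ndarray:
        out = np.zeros(len(table), dtype=bool)
        for i, (chrom, tss) in enumerate(zip(table["chrom"], table["tss"])):
            on = chroms == chrom
            out[i] = bool(np.any((starts[on] < tss + flank) & (ends[on] > tss - flank)))
        return out

    deg_bound = bound_mask(degs)
    deg_ids = set(degs["gene_id"])
    nondeg = universe.loc[~universe["gene_id"].isin(deg_ids)]
    nondeg_bound = bound_mask(nondeg)
    a = int(deg_bound.sum())
    b = int(len(degs) - a)
    c = int(nondeg_bound.sum())
    d = int(len(nondeg) - c)
    frac = a / len(degs) if len(degs) else 0.0
    return frac, fisher_exact_2x2(a, b, c, d), deg_bound


def distance_to_disrupted(degs: pd.DataFrame, disrupted_positions,
                          background_positions
                          ) -> tuple[np.ndarray, np.ndarray, TestResult]:
    """Per-DEG min |TSS - boundary| to disrupted and background boundary sets."""
    disrupted = np.sort(np.asarray(list(disrupted_positions), dtype=float))
    background = np.sort(np.asarray(list(background_positions), dtype=float))
    if disrupted.size == 0 or background.size == 0:
        raise ValueError("empty boundary set")

    def dists(positions: np.ndarray) -> np.ndarray:
        tss = degs["tss"].to_numpy(dtype=float)
        j = np.searchsorted(positions, tss)
        left = positions[np.clip(j - 1, 0, positions.size - 1)]
        right = positions[np.clip(j, 0, positions.size - 1)]
        return np.minimum(np.abs(tss - left), np.abs(tss - right))

    dd = dists(disrupted)
    db = dists(background)
    return dd, db, ks_two_sample(dd, db)


def hijack_candidates(degs: pd.DataFrame, disrupted_positions,
                      tads) -> list[HijackCandidate]:
    """Up-regulated zygotic DEGs in a TAD flanking a disrupted boundary.

    ``tads`` are half-open bp intervals tiling the chromosome; each disrupted
    boundary position must be a shared TAD edge.  A gene adjacent to two
    disrupted boundaries is reported once per boundary.
    """
    tads = [(int(a), int(b)) for a, b in tads]
    up = degs.loc[degs["log2fc"] > 0]
    out: list[HijackCandidate] = []
    for pos in sorted(int(p) for p in disrupted_positions):
        left = [t for t in tads if t[1] == pos]
        right = [t for t in tads if t[0] == pos]
        if not left or not right:
            raise ValueError(f"disrupted boundary at {pos} is not a TAD edge")
        for side, (a, b) in (("left", left[0]), ("right", right[0])):
            in_tad = (up["tss"] >= a) & (up["tss"] < b)
            for _, g in up.loc[in_tad].iterrows():
                out.append(HijackCandidate(gene_id=g["gene_id"],
                                           boundary_position=pos, side=side,
                                           log2fc=float(g["log2fc"])))
    return out
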