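"""Combinatorial insulator-binding analysis at summits and TAD boundaries.

Summit colocalization uses single-linkage chaining: two summits join one group
whenever they lie within the radius (default 200 bp), and the group's label is
the set of factors present — the rows of an UpSet table.  Boundary occupancy
assigns a factor to a boundary iff at least one of its summits falls in the
10-kb boundary region [position - 5 kb, position + 5 kb), and classes are the
resulting factor combinations (possibly empty), which partition the boundaries.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .formats import PeakSet
from .insulation import BoundaryCall, InsulationTrack
from .stats import TestResult, ks_two_sample, pearson_r

COLOCALIZATION_RADIUS = 200
BOUNDARY_WINDOW = 10_000


@dataclass
class SummitGroup:
    chrom: str
    label: frozenset
    positions: tuple[float, ...]
    factors: tuple[str, ...]


def _boundary_position(b) -> float:
    return float(b.position) if isinstance(b, BoundaryCall) else float(b)


def colocalize_summits(peaksets: dict[str, PeakSet],
                       radius: float = COLOCALIZATION_RADIUS) -> list[SummitGroup]:
    """Single-linkage clustering of all summits within ``radius`` bp, per chromosome."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    entries = []  # (chrom, pos, factor)
    for factor, ps in peaksets.items():
        for p in ps:
            entries.append((p.chrom, float(p.summit_pos), factor))
    groups: list[SummitGroup] = []
    for chrom in sorted({e[0] for e in entries}):
        sub = sorted((e[1], e[2]) for e in entries if e[0] == chrom)
        cur: list[tuple[float, str]] = []
        for pos, factor in sub:
            if cur and pos - cur[-1][0] > radius:
                groups.append(_close_group(chrom, cur))
                cur = []
            cur.append((pos, factor))
        if cur:
            groups.append(_close_group(chrom, cur))
    return groups


def _close_group(chrom: str, members) -> SummitGroup:
    return SummitGroup(chrom=chrom,
                       label=frozenset(f for _, f in members),
                       positions=tuple(p for p, _ in members),
                       factors=tuple(f for _, f in members))


def upset_counts(groups) -> pd.DataFrame:
    """UpSet table: one row per factor-combination label with its group count."""
    counts = Counter("+".join(sorted(g.label)) for g in groups)
    df = pd.DataFrame(sorted(counts.items()), columns=["label", "count"])
    return df.sort_values(["count", "label"], ascending=[False, True]).reset_index(drop=True)


def boundary_occupancy(boundaries, peaksets: dict[str, PeakSet],
                       window: float = BOUNDARY_WINDOW) -> pd.DataFrame:
    """Per-boundary occupancy class and per-factor summit counts.

    A factor occupies a boundary iff >= 1 summit lies in
    [position - window/2, position + window/2); an empty label marks an
    unbound boundary.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    half = window / 2.0
    factors = sorted(peaksets)
    summits = {f: np.sort(peaksets[f].summit_positions()) for f in factors}
    rows = []
    for b in boundaries:
        pos = _boundary_position(b)
        row = {"position": pos,
               "bin": b.bin if isinstance(b, BoundaryCall) else None}
        present = []
        for f in factors:
            s = summits[f]
            n_in = int(np.searchsorted(s, pos + half, side="left")
                       - np.searchsorted(s, pos - half, side="left"))
            row[f"n_{f}"] = n_in
            if n_in >= 1:
                present.append(f)
        row["label"] = "+".join(present)
        row["n_factors"] = len(present)
        rows.append(row)
    return pd.DataFrame(rows)


def stratify_by_class(boundaries, track: InsulationTrack,
                      occupancy: pd.DataFrame,
                      min_members: int = 2) -> tuple[pd.DataFrame, dict]:
    """Insulation-score distributions per occupancy class, plus pairwise KS tests.

    Classes are ordered by median score ascending (strongest insulation first);
    classes with fewer than ``min_members`` boundaries are flagged and excluded
    from the tests but kept in the table.
    """
    scores = []
    for b in boundaries:
        i = (b.bin if isinstance(b, BoundaryCall)
             else int(b) // track.bin_size)
        if not track.valid[i]:
            raise ValueError(f"boundary bin {i} masked in the insulation track")
        scores.append(track.score[i])
    occ = occupancy.copy()
    occ["score"] = scores
    by_class = occ.groupby("label")["score"]
    table = by_class.agg(["count", "median", "mean"]).reset_index()
    table["testable"] = table["count"] >= min_members
    table = table.sort_values(["median", "label"]).reset_index(drop=True)
    tests: dict[tuple[str, str], TestResult] = {}
    testable = table.loc[table["testable"], "label"].tolist()
    for a_i, la in enumerate(testable):
        for lb in testable[a_i + 1:]:
            tests[(la, lb)] = ks_two_sample(
                occ.loc[occ["label"] == la, "score"],
                occ.loc[occ["label"] == lb, "score"])
    return table, tests


def correlate_intensity(boundaries, peaksets: dict[str, PeakSet],
                        track: InsulationTrack,
                        window: float = BOUNDARY_WINDOW) -> dict[str, float]:
    """Per factor: Pearson r of max summit height in the boundary window vs score."""
    half = window / 2.0
    out = {}
    for factor, ps in peaksets.items():
        pos_all = ps.summit_positions()
        h_all = ps.heights()
        xs, ys = [], []
        for b in boundaries:
            pos = _boundary_position(b)
            i = (b.bin if isinstance(b, BoundaryCall)
                 else int(b) // track.bin_size)
            in_win = (pos_all >= pos - half) & (pos_all < pos + half)
            if in_win.any() and track.valid[i]:
                xs.append(h_all[in_win].max())
                ys.append(track.score[i])
        out[factor] = pearson_r(xs, ys) if len(xs) >= 3 else float("nan")
    return out


def distance_to_nearest_peak(query_boundaries, peakset: PeakSet,
                             background_boundaries
                             ) -> tuple[np.ndarray, np.ndarray, TestResult]:
    """Min |summit - position| for query and background boundaries, plus KS."""
    if len(peakset) == 0:
        raise ValueError("empty peak set")
    summits = np.sort(peakset.summit_positions())

    def dists(boundaries):
        out = []
        for b in boundaries:
            pos = _boundary_position(b)
            j = np.searchsorted(summits, pos)
            cands = summits[max(j - 1, 0):j + 1]
            out.append(float(np.min(np.abs(cands - pos))))
        return np.array(out)

    dq = dists(query_boundaries)
    db = dists(background_boundaries)
    return dq, db, ks_two_sample(dq, db)
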