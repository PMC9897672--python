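"""Kernel-correlation boundary scoring and differential (depletion - WT) analysis.

Each called boundary gets, per condition, the Pearson correlation between the
log2 observed/expected window around the boundary and an idealized boundary
kernel, plus a signal-to-noise ratio (snr) contrasting within-TAD against
cross-boundary quadrants.  The differential score is depletion minus WT on
depth-matched matrices (binomial thinning of the deeper one), so a negative
score means loss of the boundary pattern.  Boundaries with WT snr below a
cutoff (default 5) are excluded, and results are stratified into the top
changing set versus a "stable" set with the smallest absolute change.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .formats import ContactMatrix
from .insulation import BoundaryCall, expected_by_distance
from .synthetic import BoundarySpec, DecayModel, TadLayout, expected_matrix

AFFECTED_CUTOFF_LENIENT = -0.1
AFFECTED_CUTOFF_STRINGENT = -0.2


@dataclass(frozen=True)
class BorderKernel:
    """Zero-mean, unit-variance (2r+1)^2 boundary template."""

    radius: int
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        r = self.radius
        if v.shape != (2 * r + 1, 2 * r + 1):
            raise ValueError("kernel shape must be (2r+1, 2r+1)")
        if abs(v.mean()) > 1e-9 or abs(v.std() - 1.0) > 1e-9:
            raise ValueError("kernel must have mean 0 and sd 1")
        if not np.allclose(v, v.T, atol=1e-9):
            raise ValueError("kernel must be symmetric under transposition")


@dataclass
class DiffBoundaryResult:
    boundary: BoundaryCall
    score_wt: float
    score_dep: float
    snr: float

    @property
    def diff_score(self) -> float:
        return self.score_dep - self.score_wt

    @property
    def affected_lenient(self) -> bool:
        return self.diff_score < AFFECTED_CUTOFF_LENIENT

    @property
    def affected_stringent(self) -> bool:
        return self.diff_score < AFFECTED_CUTOFF_STRINGENT


def _quadrant_masks(r: int) -> tuple[np.ndarray, np.ndarray]:
    """(within-TAD, cross-boundary) masks for a window centred on the boundary bin.

    Cell (a, b) of the window is the pair (c + a, c + b) with the boundary
    between bins c - 1 and c; the pair crosses the boundary iff exactly one of
    a, b is negative.
    """
    offs = np.arange(-r, r + 1)
    left = offs[:, None] < 0
    right = offs[None, :] < 0
    cross = left ^ right
    return ~cross, cross


def make_border_kernel(decay: DecayModel, s_ref: float = 0.5, r: int = 8) -> BorderKernel:
    """Build the expected boundary template from the decay model.

    The noise-free matrix for a single boundary of strength ``s_ref`` is
    detrended by pure decay and log2-transformed, then the (2r+1) window
    centred on the boundary is standardized to mean 0, sd 1.
    """
    if not 0.0 < s_ref < 1.0:
        raise ValueError("s_ref must lie strictly in (0, 1)")
    if r < 3:
        raise ValueError("kernel radius must be at least 3")
    n = 2 * r + 3
    m = r + 1
    layout = TadLayout(chrom="kernel", bin_size=1, n_bins=n,
                       boundaries=(BoundarySpec(bin=m, strength=s_ref),))
    exp = expected_matrix(layout, decay).counts
    idx = np.arange(n)
    dist = np.abs(idx[:, None] - idx[None, :])
    ratio = np.log2(exp / decay.expected(dist))
    window = ratio[m - r:m + r + 1, m - r:m + r + 1]
    sd = window.std()
    if sd <= 1e-12:
        raise ValueError("degenerate kernel window (all values equal)")
    values = (window - window.mean()) / sd
    return BorderKernel(radius=r, values=values)


def boundary_score(matrix: ContactMatrix, bin: int, kernel: BorderKernel,
                   ps: np.ndarray | None = None) -> tuple[float, float]:
    """(Pearson score, snr) of the window centred on ``bin`` against the kernel.

    Windows that run off the chromosome yield (nan, nan) — masked, not an
    error.  The window is detrended as log2((counts + 1) / (P(s) + 1)) with
    the matrix's own expected-by-distance curve.
    """
    r = kernel.radius
    n = matrix.n_bins
    if bin - r < 0 or bin + r >= n:
        return (float("nan"), float("nan"))
    if ps is None:
        ps = expected_by_distance(matrix)
    sl = slice(bin - r, bin + r + 1)
    idx = np.arange(bin - r, bin + r + 1)
    dist = np.abs(idx[:, None] - idx[None, :])
    w = np.log2((matrix.counts[sl, sl] + 1.0) / (ps[dist] + 1.0))
    within, cross = _quadrant_masks(r)
    if np.ptp(w) == 0:
        return (float("nan"), 0.0)
    kf = kernel.values.ravel()
    wf = w.ravel()
    score = float(np.corrcoef(wf, kf)[0, 1])
    # contrast-to-noise: quadrant contrast over the pooled residual sd after
    # removing the two quadrant-class means (the noise, not the signal, sets
    # the denominator)
    mw, mc = w[within].mean(), w[cross].mean()
    resid = np.concatenate([w[within] - mw, w[cross] - mc])
    sd_resid = resid.std()
    snr = float("inf") if sd_resid <= 1e-12 else float(abs(mw - mc) / sd_resid)
    return (score, snr)


def _thin_to_depth(matrix: ContactMatrix, target_total: float,
                   seed: int) -> ContactMatrix:
    """Binomial thinning of the whole matrix to a target total count."""
    total = matrix.total
    if total <= target_total:
        return matrix
    p = target_total / total
    rng = np.random.default_rng(seed)
    upper = np.triu(matrix.counts)
    thinned = rng.binomial(np.round(upper).astype(np.int64), p).astype(float)
    counts = np.triu(thinned) + np.triu(thinned, k=1).T
    return ContactMatrix(chrom=matrix.chrom, bin_size=matrix.bin_size, counts=counts)


def differential_scores(matrix_wt: ContactMatrix, matrix_dep: ContactMatrix,
                        boundaries, kernel: BorderKernel,
                        snr_min: float = 5.0,
                        seed: int = 17) -> list[DiffBoundaryResult]:
    """Per-boundary kernel scores in both conditions and their difference.

    The deeper matrix is subsampled (binomial thinning, seeded) to the
    shallower one's total count before scoring; boundaries whose WT snr is
    below ``snr_min`` — or whose window is masked in either condition — are
    excluded.  No correlation or contrast-to-noise prefilters are applied.
    """
    if (matrix_wt.bin_size != matrix_dep.bin_size
            or matrix_wt.n_bins != matrix_dep.n_bins):
        raise ValueError("matrices must share binning")
    target = min(matrix_wt.total, matrix_dep.total)
    wt = _thin_to_depth(matrix_wt, target, seed)
    dep = _thin_to_depth(matrix_dep, target, seed + 1)
    ps_wt = expected_by_distance(wt)
    ps_dep = expected_by_distance(dep)
    results = []
    for b in boundaries:
        call = b if isinstance(b, BoundaryCall) else BoundaryCall(
            chrom=matrix_wt.chrom, bin=int(b), position=int(b) * matrix_wt.bin_size,
            sep_score=float("nan"), prominence=float("nan"), pvalue=float("nan"))
        s_wt, snr = boundary_score(wt, call.bin, kernel, ps=ps_wt)
        s_dep, _ = boundary_score(dep, call.bin, kernel, ps=ps_dep)
        if np.isnan(s_wt) or np.isnan(s_dep) or snr < snr_min:
            continue
        results.append(DiffBoundaryResult(boundary=call, score_wt=s_wt,
                                          score_dep=s_dep, snr=snr))
    return results


def stratify(results, top_k: int = 100, n_stable: int = 200
             ) -> tuple[list[DiffBoundaryResult], list[DiffBoundaryResult]]:
    """Top changing boundaries vs a disjoint stable set.

    ``top`` = the ``top_k`` most-negative diff_scores; ``stable`` = among the
    remainder, the ``n_stable`` smallest |diff_score|.  Ties break by boundary
    position, ascending.
    """
    results = list(results)
    if len(results) < top_k + n_stable:
        raise ValueError(
            f"need at least top_k + n_stable = {top_k + n_stable} boundaries "
            f"after snr filtering, got {len(results)} "
            f"(short by {top_k + n_stable - len(results)})")
    by_diff = sorted(results, key=lambda x: (x.diff_score, x.boundary.position))
    top = by_diff[:top_k]
    rest = by_diff[top_k:]
    stable = sorted(rest, key=lambda x: (abs(x.diff_score), x.boundary.position))[:n_stable]
    return top, stable
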