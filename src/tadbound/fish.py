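"""3-D DNA-FISH quantification: spot detection, pairwise distances, fractions.

Spots are detected per channel as 26-connected components of voxels at or
above an intensity threshold; each component's centre is the
background-subtracted intensity-weighted centroid, converted to nm with the
anisotropic voxel sizes (z step 200 nm by default).  Alleles are formed by
mutual-nearest pairing of spots across two channels within a radius, and the
per-allele 3-D centre-to-centre distances feed the strict <250 nm ("contact")
and >600 nm ("open") fractions and KS comparisons between conditions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.measure import label as cc_label

from .stats import TestResult, ks_two_sample
from .synthetic import DistanceSample, ImageStack

logger = logging.getLogger(__name__)

NEAR_NM = 250.0
FAR_NM = 600.0
MIN_COMPONENT_VOXELS = 4


@dataclass
class ThresholdFractions:
    pct_near: float
    pct_far: float
    n_alleles: int
    near_nm: float = NEAR_NM
    far_nm: float = FAR_NM


def detect_spots(stack: ImageStack, channel: str, threshold: float,
                 background: float,
                 min_voxels: int = MIN_COMPONENT_VOXELS) -> pd.DataFrame:
    """Detect spots in one channel; returns a table of centres in nm.

    Voxels with intensity >= threshold form 26-connected components; each
    component at least ``min_voxels`` large contributes one spot at its
    intensity-weighted centroid after background subtraction (negative
    residuals clamped to zero).
    """
    if threshold <= background:
        raise ValueError("threshold must exceed background")
    if background < 0:
        raise ValueError("background must be non-negative")
    img = stack.channel(channel)
    if img.size == 0:
        raise ValueError("empty stack")
    mask = img >= threshold
    labels = cc_label(mask, connectivity=3)  # 26-connectivity in 3-D
    rows = []
    vz, vy, vx = stack.voxel_size_nm
    for lab in range(1, labels.max() + 1):
        sel = labels == lab
        if int(sel.sum()) < min_voxels:
            continue
        weights = np.clip(img[sel] - background, 0.0, None)
        coords = np.argwhere(sel).astype(float)  # (n, 3) as (z, y, x)
        wsum = weights.sum()
        if wsum <= 0:
            continue
        centroid = (coords * weights[:, None]).sum(axis=0) / wsum
        rows.append({"channel": channel,
                     "z_nm": centroid[0] * vz,
                     "y_nm": centroid[1] * vy,
                     "x_nm": centroid[2] * vx,
                     "n_voxels": int(sel.sum())})
    return pd.DataFrame(rows, columns=["channel", "z_nm", "y_nm", "x_nm", "n_voxels"])


def _euclidean_nm(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return np.sqrt(((a[:, None, :] - b[None, :, :]) ** 2).sum(axis=-1))


def pairwise_distances(spots: pd.DataFrame, channel_pair: tuple[str, str],
                       pairing_radius_nm: float = 1000.0,
                       condition: str = "") -> DistanceSample:
    """Per-allele 3-D distance between the two channels' spot centres.

    If the spot table carries an ``allele`` column, spots are paired within
    alleles (each allele must contribute one spot per channel; incomplete
    alleles are skipped and counted).  Otherwise alleles are formed by
    mutual-nearest-neighbour pairing within ``pairing_radius_nm``.
    """
    ch_a, ch_b = channel_pair
    cols = ["z_nm", "y_nm", "x_nm"]
    a = spots[spots["channel"] == ch_a]
    b = spots[spots["channel"] == ch_b]
    dists: list[float] = []
    skipped = 0
    if "allele" in spots.columns:
        for allele, grp in spots.groupby("allele"):
            pa = grp.loc[grp["channel"] == ch_a, cols].to_numpy()
            pb = grp.loc[grp["channel"] == ch_b, cols].to_numpy()
            if len(pa) == 1 and len(pb) == 1:
                dists.append(float(np.linalg.norm(pa[0] - pb[0])))
            else:
                skipped += 1
    else:
        pa = a[cols].to_numpy()
        pb = b[cols].to_numpy()
        if len(pa) and len(pb):
            dm = _euclidean_nm(pa, pb)
            nearest_b = dm.argmin(axis=1)
            nearest_a = dm.argmin(axis=0)
            for i, j in enumerate(nearest_b):
                d = dm[i, j]
                if nearest_a[j] == i and d <= pairing_radius_nm:
                    dists.append(float(d))
                else:
                    skipped += 1
    if skipped:
        logger.info("pairwise_distances: skipped %d incomplete/unpaired clusters", skipped)
    return DistanceSample(distances=np.array(dists), condition=condition)


def threshold_fractions(sample: DistanceSample, near: float = NEAR_NM,
                        far: float = FAR_NM) -> ThresholdFractions:
    """Percentages of alleles with distance strictly < near and strictly > far."""
    d = sample.distances
    if d.size == 0:
        raise ValueError("empty distance sample")
    return ThresholdFractions(pct_near=100.0 * float(np.mean(d < near)),
                              pct_far=100.0 * float(np.mean(d > far)),
                              n_alleles=d.size, near_nm=near, far_nm=far)


def compare_conditions(a: DistanceSample, b: DistanceSample) -> TestResult:
    """Two-sided KS test between the distance distributions of two conditions."""
    return ks_two_sample(a.distances, b.distances)
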