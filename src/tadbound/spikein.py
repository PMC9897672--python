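"""Cross-species spike-in normalization of C&T coverage.

Every sample carries a fixed amount of exogenous (spike-in) chromatin, so the
ratio of spike-in read counts calibrates tagmentation/sequencing depth between
samples: each track is rescaled by reference_spike / sample_spike (reference =
the WT sample of a pair).  Binding loss at reference peaks is the ratio of
scaled mean coverage in summit +/- 500 bp windows, with a pseudo-count of 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .formats import BinnedTrack, PeakSet

QUANT_FLANK = 500  # summit +/- 500 bp quantification window


@dataclass(frozen=True)
class SpikePair:
    sample: str
    target_reads: float
    spike_reads: float
    reference_spike_reads: float

    def __post_init__(self) -> None:
        if self.spike_reads <= 0 or self.reference_spike_reads <= 0:
            raise ValueError("spike-in read counts must be positive")

    @property
    def scale_factor(self) -> float:
        return scale_factor(self.spike_reads, self.reference_spike_reads)


def scale_factor(sample_spike: float, reference_spike: float) -> float:
    """reference_spike / sample_spike (> 0)."""
    if sample_spike <= 0 or reference_spike <= 0:
        raise ValueError("spike-in read counts must be positive")
    return reference_spike / sample_spike


def apply_scaling(track: BinnedTrack, factor: float) -> BinnedTrack:
    if factor <= 0:
        raise ValueError("scale factor must be positive")
    return BinnedTrack(chrom=track.chrom, bin_size=track.bin_size,
                       values=track.values * factor)


def _window_mean(track: BinnedTrack, center_bp: int, flank: int) -> float:
    lo = (center_bp - flank) // track.bin_size
    hi = (center_bp + flank + track.bin_size - 1) // track.bin_size
    if lo < 0 or hi > track.values.size:
        raise ValueError(f"peak window {center_bp} +/- {flank} off the chromosome")
    return float(track.values[lo:hi].mean())


def peak_signal_loss(track_wt: BinnedTrack, track_dep: BinnedTrack,
                     peaks: PeakSet,
                     spike_wt: float = 1.0, spike_dep: float = 1.0,
                     flank: int = QUANT_FLANK) -> pd.DataFrame:
    """Per-peak depletion/WT signal ratio after spike-in rescaling.

    The WT sample is the scaling reference, so WT keeps factor 1 and the
    depletion track is multiplied by spike_wt / spike_dep.  Signal is mean
    scaled coverage in summit +/- flank; ratio = (dep + 1) / (wt + 1).
    """
    wt = track_wt
    dep = apply_scaling(track_dep, scale_factor(spike_dep, spike_wt))
    rows = []
    for p in peaks:
        s_wt = _window_mean(wt, p.summit_pos, flank)
        s_dep = _window_mean(dep, p.summit_pos, flank)
        rows.append({"name": p.name, "summit": p.summit_pos,
                     "signal_wt": s_wt, "signal_dep": s_dep,
                     "ratio": (s_dep + 1.0) / (s_wt + 1.0)})
    return pd.DataFrame(rows)
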