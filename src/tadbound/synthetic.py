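"""Seed-reproducible generators for every input the pipeline consumes.

The generators emulate the statistical structure of early-embryo chromatin
data at desk scale:

* Hi-C contact matrices follow a power-law distance decay with Poisson count
  noise; a TAD boundary of strength ``s`` removes a fraction ``s`` of the
  expected cross-boundary contacts, and attenuation composes multiplicatively
  across every boundary a pair of bins straddles.  A matched "depletion"
  condition reduces each strength to ``s * (1 - w)``.
* Insulator peak sets place one summit per (boundary, assigned factor) with
  Gaussian positional jitter, plus uniform background peaks, with log-normal
  summit heights.
* Expression tables place gene TSSs uniformly within TADs and plant
  log2 fold-change effects for enhancer-hijacking candidates; p-values come
  from the declared normal z-model p = 2 * (1 - Phi(|log2FC| / sigma)).
* FISH allele distances are a two-state mixture: with probability ``pi`` the
  allele is in the "contact" state (folded-normal distance), otherwise "open"
  (zero-truncated normal).  ``render_stack`` turns spot coordinates into a 3-D
  image with anisotropic voxels and Poisson background.
* Spike-in C&T pairs share a per-sample sequencing-depth factor between the
  target-genome coverage and the spike-in read count, so spike rescaling
  cancels depth by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .formats import BinnedTrack, ContactMatrix, Peak, PeakSet

INSULATOR_FACTORS = ("BEAF-32", "CTCF", "Su(Hw)", "CP190")

#: Working resolution of the whole package: a 20-Mb chromosome at 10-kb bins.
DEFAULT_BIN_SIZE = 10_000
DEFAULT_N_BINS = 2_000


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DecayModel:
    """Power-law distance decay: E[count] = A * d^(-alpha), diagonal A * c0."""

    amplitude: float = 2000.0
    alpha: float = 0.75
    diagonal_level: float = 2.0

    def __post_init__(self) -> None:
        for name in ("amplitude", "alpha", "diagonal_level"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"DecayModel.{name} must be a positive finite number")

    def expected(self, distance) -> np.ndarray:
        """Expected count at a bin distance (vectorized; distance 0 = diagonal)."""
        d = np.asarray(distance, dtype=float)
        out = np.empty_like(d)
        zero = d == 0
        out[zero] = self.amplitude * self.diagonal_level
        with np.errstate(divide="ignore"):
            out[~zero] = self.amplitude * d[~zero] ** (-self.alpha)
        return out


@dataclass(frozen=True)
class BoundarySpec:
    """A TAD boundary: ``bin`` is the first bin of the right-hand TAD.

    ``strength`` is the fraction of expected cross-boundary contacts removed;
    ``weakening`` scales it down to ``strength * (1 - weakening)`` in the
    depletion condition.
    """

    bin: int
    strength: float
    weakening: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.strength < 1.0:
            raise ValueError("boundary strength must lie in [0, 1)")
        if not 0.0 <= self.weakening <= 1.0:
            raise ValueError("boundary weakening must lie in [0, 1]")

    @property
    def depleted_strength(self) -> float:
        return self.strength * (1.0 - self.weakening)


@dataclass(frozen=True)
class TadLayout:
    """A chromosome tiled by TADs between consecutive boundaries."""

    chrom: str = "chrS"
    bin_size: int = DEFAULT_BIN_SIZE
    n_bins: int = DEFAULT_N_BINS
    boundaries: tuple[BoundarySpec, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "boundaries", tuple(self.boundaries))
        if self.n_bins < 4:
            raise ValueError("a layout needs at least 4 bins")
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        bins = [b.bin for b in self.boundaries]
        if any(not 1 <= b <= self.n_bins - 1 for b in bins):
            raise ValueError("boundary bins must lie in [1, n_bins - 1]")
        if any(b2 <= b1 for b1, b2 in zip(bins, bins[1:])):
            raise ValueError("boundary bins must be strictly increasing")

    @property
    def boundary_bins(self) -> np.ndarray:
        return np.array([b.bin for b in self.boundaries], dtype=int)

    @property
    def boundary_positions(self) -> np.ndarray:
        """Boundary coordinates in bp (left edge of the boundary bin)."""
        return self.boundary_bins * self.bin_size

    @property
    def chrom_length(self) -> int:
        return self.n_bins * self.bin_size

    @property
    def tad_bins(self) -> list[tuple[int, int]]:
        """Half-open bin intervals tiling [0, n_bins)."""
        edges = [0, *self.boundary_bins.tolist(), self.n_bins]
        return [(a, b) for a, b in zip(edges, edges[1:])]

    @property
    def tads(self) -> list[tuple[int, int]]:
        """Half-open bp intervals tiling the chromosome."""
        return [(a * self.bin_size, b * self.bin_size) for a, b in self.tad_bins]


@dataclass(frozen=True)
class FishCondition:
    """Two-state allele mixture: 'contact' vs 'open' pairwise distances (nm)."""

    contact_prob: float = 0.34
    mu_contact: float = 120.0
    sigma_contact: float = 90.0
    mu_open: float = 650.0
    sigma_open: float = 280.0
    label: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.contact_prob <= 1.0:
            raise ValueError("contact_prob must lie in [0, 1]")
        if self.sigma_contact <= 0 or self.sigma_open <= 0:
            raise ValueError("sigmas must be positive")
        if not self.mu_contact < self.mu_open:
            raise ValueError("contact distances must centre below open distances")

    def _contact_dist(self):
        return sps.foldnorm(c=self.mu_contact / self.sigma_contact,
                            loc=0.0, scale=self.sigma_contact)

    def _open_dist(self):
        a = (0.0 - self.mu_open) / self.sigma_open
        return sps.truncnorm(a=a, b=np.inf, loc=self.mu_open, scale=self.sigma_open)

    def fraction_below(self, t_nm: float) -> float:
        """Analytic mixture P(distance < t)."""
        return float(self.contact_prob * self._contact_dist().cdf(t_nm)
                     + (1 - self.contact_prob) * self._open_dist().cdf(t_nm))

    def fraction_above(self, t_nm: float) -> float:
        return float(self.contact_prob * self._contact_dist().sf(t_nm)
                     + (1 - self.contact_prob) * self._open_dist().sf(t_nm))


@dataclass
class DistanceSample:
    """Per-allele pairwise 3-D distances (nm) for one condition."""

    distances: np.ndarray
    condition: str = ""
    n_embryos: int = 1
    states: np.ndarray | None = None  # planted truth: 1 = contact state

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float)
        if np.any(self.distances < 0):
            raise ValueError("distances must be non-negative")

    @property
    def n_alleles(self) -> int:
        return self.distances.size


@dataclass
class ImageStack:
    """3-D (or multi-channel 4-D) intensity stack with anisotropic voxels.

    ``data`` has axes (channel, z, y, x) and ``voxel_size_nm`` is (z, y, x);
    the default voxel is 60 x 60 nm laterally with a 200-nm z step.
    """

    data: np.ndarray
    voxel_size_nm: tuple[float, float, float] = (200.0, 60.0, 60.0)
    channels: tuple[str, ...] = ("ch0",)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim == 3:
            self.data = self.data[None]
        if self.data.ndim != 4:
            raise ValueError("stack must be (z, y, x) or (channel, z, y, x)")
        if min(self.data.shape) < 1:
            raise ValueError("all stack dimensions must be >= 1")
        if any(v <= 0 for v in self.voxel_size_nm):
            raise ValueError("voxel sizes must be positive")
        if len(self.channels) != self.data.shape[0]:
            raise ValueError("channel names must match the channel axis")

    def channel(self, name: str) -> np.ndarray:
        return self.data[self.channels.index(name)]


# ---------------------------------------------------------------------------
# Hi-C matrices
# ---------------------------------------------------------------------------


def expected_matrix(layout: TadLayout, decay: DecayModel,
                    depleted: bool = False) -> ContactMatrix:
    """Noise-free expected contact matrix lambda(i, j).

    lambda(i, j) = decay(|i-j|) * prod over boundaries b with min(i,j) < b <= max(i,j)
    of (1 - s_b); the diagonal is A * c0.
    """
    n = layout.n_bins
    idx = np.arange(n)
    lam = decay.expected(np.abs(idx[:, None] - idx[None, :]))
    # cumulative log-attenuation g(i) = sum_{b <= i} log(1 - s_b): a pair (i<j)
    # crosses exactly the boundaries with i < b <= j, so att = exp(g(j) - g(i)).
    g = np.zeros(n)
    for b in layout.boundaries:
        s = b.depleted_strength if depleted else b.strength
        if s > 0:
            g[b.bin:] += np.log1p(-s)
    att = np.exp(-np.abs(g[:, None] - g[None, :]))
    lam *= att
    return ContactMatrix(chrom=layout.chrom, bin_size=layout.bin_size, counts=lam)


def gen_contact_matrix(layout: TadLayout, decay: DecayModel,
                       use_depletion_strengths: bool = False,
                       seed: int = 0) -> ContactMatrix:
    """Poisson draw around the expected matrix; one draw per unordered pair."""
    lam = expected_matrix(layout, decay, depleted=use_depletion_strengths).counts
    rng = np.random.default_rng(seed)
    draw = rng.poisson(lam).astype(float)
    counts = np.triu(draw) + np.triu(draw, k=1).T
    return ContactMatrix(chrom=layout.chrom, bin_size=layout.bin_size, counts=counts)


def gen_depletion_pair(layout: TadLayout, decay: DecayModel,
                       seed: int = 0) -> tuple[ContactMatrix, ContactMatrix]:
    """Matched WT / depletion matrices with independent sub-seeded noise."""
    if all(b.weakening == 0.0 for b in layout.boundaries):
        warnings.warn("all weakenings are 0: the pair is exchangeable",
                      stacklevel=2)
    ss = np.random.SeedSequence(seed).spawn(2)
    wt = gen_contact_matrix(layout, decay, use_depletion_strengths=False, seed=ss[0])
    dep = gen_contact_matrix(layout, decay, use_depletion_strengths=True, seed=ss[1])
    return wt, dep


# ---------------------------------------------------------------------------
# insulator peaks
# ---------------------------------------------------------------------------


def gen_peaks(layout: TadLayout,
              class_assignment: dict[int, frozenset | set | tuple],
              jitter_sd: float = 1000.0,
              n_background: int = 50,
              seed: int = 0,
              peak_halfwidth: int = 250,
              factors: tuple[str, ...] = INSULATOR_FACTORS) -> dict[str, PeakSet]:
    """One summit per (boundary, assigned factor) plus uniform background peaks.

    ``class_assignment`` maps boundary bin -> set of factor names bound there.
    Summits sit at the boundary position + Normal(0, jitter_sd), clipped to the
    chromosome; heights are log-normal and independent of boundary strength.
    """
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be non-negative")
    known = set(factors)
    for bin_, fset in class_assignment.items():
        if bin_ not in set(layout.boundary_bins.tolist()):
            raise ValueError(f"class assignment names unknown boundary bin {bin_}")
        unknown = set(fset) - known
        if unknown:
            raise ValueError(f"unknown factors {unknown}")
    rng = np.random.default_rng(seed)
    chrom_len = layout.chrom_length
    out: dict[str, PeakSet] = {}
    for factor in factors:
        summits: list[float] = []
        for bin_ in sorted(class_assignment):
            if factor in class_assignment[bin_]:
                pos = bin_ * layout.bin_size
                if jitter_sd > 0:
                    pos = pos + rng.normal(0.0, jitter_sd)
                summits.append(pos)
        if n_background > 0:
            summits.extend(rng.uniform(0, chrom_len, size=n_background))
        heights = rng.lognormal(mean=np.log(50.0), sigma=1.0, size=len(summits))
        peaks = []
        for k, (s, h) in enumerate(zip(summits, heights)):
            s = int(np.clip(round(s), peak_halfwidth, chrom_len - peak_halfwidth - 1))
            start = s - peak_halfwidth
            end = s + peak_halfwidth
            peaks.append(Peak(chrom=layout.chrom, start=start, end=end,
                              summit=s - start, height=float(h),
                              factor=factor, name=f"{factor}_{k}"))
        peaks.sort(key=lambda p: p.start)
        out[factor] = PeakSet(factor=factor, peaks=peaks)
    return out


# ---------------------------------------------------------------------------
# expression tables
# ---------------------------------------------------------------------------


def gene_id(tad_index: int, k: int) -> str:
    return f"g{tad_index:03d}_{k}"


def gen_expression(layout: TadLayout,
                   genes_per_tad: int = 3,
                   hijack_plan: list[tuple[str, int, float]] | None = None,
                   noise_sd: float = 0.1,
                   maternal_fraction: float = 0.3,
                   seed: int = 0) -> pd.DataFrame:
    """Gene table with TSSs uniform within TADs and planted hijacking effects.

    ``hijack_plan`` entries are (gene_id, boundary_bin, log2fc); the named gene
    must live in one of the two TADs flanking that boundary (gene ids are
    deterministic: gene k of TAD t is ``g{t:03d}_{k}``).  Observed log2FC is
    the planted effect plus Normal(0, noise_sd); p-values follow the declared
    z-model p = 2 * (1 - Phi(|log2FC| / max(noise_sd, 1e-8))), which is
    uniform for null genes when noise_sd > 0.
    """
    hijack_plan = hijack_plan or []
    rng = np.random.default_rng(seed)
    tad_bp = layout.tads
    rows = []
    for t, (start, end) in enumerate(tad_bp):
        for k in range(genes_per_tad):
            rows.append({
                "gene_id": gene_id(t, k),
                "chrom": layout.chrom,
                "tss": int(rng.integers(start, end)),
                "strand": "+" if rng.random() < 0.5 else "-",
                "planted_log2fc": 0.0,
            })
    genes = pd.DataFrame(rows)
    ids = set(genes["gene_id"])

    boundary_bins = layout.boundary_bins.tolist()
    for gid, bbin, lfc in hijack_plan:
        if gid not in ids:
            raise ValueError(f"hijack plan names unknown gene {gid!r}")
        if bbin not in boundary_bins:
            raise ValueError(f"hijack plan names unknown boundary bin {bbin}")
        t = int(gid[1:4])
        bidx = boundary_bins.index(bbin)
        if t not in (bidx, bidx + 1):  # boundary b separates TAD b and TAD b+1
            raise ValueError(
                f"hijack gene {gid} is not in a TAD adjacent to boundary bin {bbin}")
        genes.loc[genes["gene_id"] == gid, "planted_log2fc"] = lfc

    noise = rng.normal(0.0, noise_sd, size=len(genes)) if noise_sd > 0 else 0.0
    genes["log2fc"] = genes["planted_log2fc"] + noise
    se = max(noise_sd, 1e-8)
    genes["pvalue"] = np.clip(2.0 * sps.norm.sf(np.abs(genes["log2fc"]) / se), 0.0, 1.0)

    n_mat = int(round(maternal_fraction * len(genes)))
    planted = genes["planted_log2fc"] != 0
    pool = genes.index[~planted].to_numpy()
    rng.shuffle(pool)
    chosen = list(pool[:n_mat])
    if n_mat > len(pool):  # only when maternal_fraction forces planted genes too
        extra = genes.index[planted].to_numpy()
        rng.shuffle(extra)
        chosen += list(extra[: n_mat - len(pool)])
    genes["maternal"] = genes.index.isin(chosen)
    return genes


# ---------------------------------------------------------------------------
# FISH samples and rendered stacks
# ---------------------------------------------------------------------------


def gen_fish_sample(cond: FishCondition, n_alleles: int, seed: int = 0,
                    n_embryos: int = 3) -> DistanceSample:
    """Draw per-allele states and distances from the two-state mixture."""
    if n_alleles < 1:
        raise ValueError("need at least one allele")
    rng = np.random.default_rng(seed)
    states = (rng.random(n_alleles) < cond.contact_prob).astype(int)
    contact = np.abs(rng.normal(cond.mu_contact, cond.sigma_contact, size=n_alleles))
    a = (0.0 - cond.mu_open) / cond.sigma_open
    open_ = sps.truncnorm.rvs(a=a, b=np.inf, loc=cond.mu_open, scale=cond.sigma_open,
                              size=n_alleles, random_state=rng)
    distances = np.where(states == 1, contact, open_)
    return DistanceSample(distances=distances, condition=cond.label,
                          n_embryos=n_embryos, states=states)


def spot_table(centers_nm: np.ndarray, channels: list[str],
               alleles: list[int] | None = None) -> pd.DataFrame:
    """Assemble a SpotSet table; centers are (z, y, x) in nm."""
    centers_nm = np.asarray(centers_nm, dtype=float)
    df = pd.DataFrame(centers_nm, columns=["z_nm", "y_nm", "x_nm"])
    df.insert(0, "channel", channels)
    df.insert(0, "allele", alleles if alleles is not None else range(len(df)))
    return df


def render_stack(spots: pd.DataFrame,
                 shape: tuple[int, int, int] = (30, 128, 128),
                 voxel_size_nm: tuple[float, float, float] = (200.0, 60.0, 60.0),
                 blob_sigma_nm: tuple[float, float, float] = (250.0, 120.0, 120.0),
                 amplitude: float = 400.0,
                 background: float = 2.0,
                 seed: int = 0) -> ImageStack:
    """Render a SpotSet as Gaussian blobs plus Poisson background.

    One 3-D image per channel present in ``spots``; spot centers are in nm and
    voxels are anisotropic (default 60 x 60 x 200 nm).
    """
    if any(v <= 0 for v in voxel_size_nm):
        raise ValueError("voxel sizes must be positive")
    rng = np.random.default_rng(seed)
    channels = tuple(dict.fromkeys(spots["channel"]))
    nz, ny, nx = shape
    vz, vy, vx = voxel_size_nm
    data = np.zeros((len(channels), nz, ny, nx))
    grid_z = np.arange(nz) * vz
    grid_y = np.arange(ny) * vy
    grid_x = np.arange(nx) * vx
    sz, sy, sx = blob_sigma_nm
    for ci, ch in enumerate(channels):
        sub = spots[spots["channel"] == ch]
        for _, row in sub.iterrows():
            gz = np.exp(-0.5 * ((grid_z - row["z_nm"]) / sz) ** 2)
            gy = np.exp(-0.5 * ((grid_y - row["y_nm"]) / sy) ** 2)
            gx = np.exp(-0.5 * ((grid_x - row["x_nm"]) / sx) ** 2)
            data[ci] += amplitude * gz[:, None, None] * gy[None, :, None] * gx[None, None, :]
    data += rng.poisson(background, size=data.shape)
    return ImageStack(data=data, voxel_size_nm=voxel_size_nm, channels=channels)


# ---------------------------------------------------------------------------
# spike-in C&T pairs
# ---------------------------------------------------------------------------


def gen_spikein_pair(peakset: PeakSet,
                     chrom: str,
                     chrom_length: int,
                     bin_size: int = 100,
                     background: float = 2.0,
                     peak_amplitude: float = 100.0,
                     peak_sd_bp: float = 300.0,
                     depletion: float = 0.0,
                     depth_wt: float = 1.0,
                     depth_dep: float = 1.0,
                     spike_expected: float = 200_000.0,
                     seed: int = 0) -> dict:
    """Matched WT / depletion C&T coverage with species spike-in counts.

    Each sample's coverage is Poisson around depth * (background + peak bumps),
    with the depletion condition removing a ``depletion`` fraction of the peak
    component; the spike-in read count is Poisson around depth * spike_expected,
    so the spike scale factor cancels the per-sample depth.
    """
    if not 0.0 <= depletion <= 1.0:
        raise ValueError("depletion must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_bins = chrom_length // bin_size
    centers = np.arange(n_bins) * bin_size + bin_size / 2.0
    bump = np.zeros(n_bins)
    for p in peakset:
        if p.chrom != chrom:
            continue
        bump += p.height / 50.0 * peak_amplitude * np.exp(
            -0.5 * ((centers - p.summit_pos) / peak_sd_bp) ** 2)
    tracks = {}
    for label, depth, keep in (("wt", depth_wt, 1.0),
                               ("dep", depth_dep, 1.0 - depletion)):
        lam = depth * (background + keep * bump)
        values = rng.poisson(lam).astype(float)
        tracks[label] = BinnedTrack(chrom=chrom, bin_size=bin_size, values=values)
        tracks[f"spike_{label}"] = int(rng.poisson(depth * spike_expected))
    return tracks


# ---------------------------------------------------------------------------
# canned layouts
# ---------------------------------------------------------------------------


def evenly_spaced_layout(n_boundaries: int = 10,
                         strength: float = 0.7,
                         weakened: dict[int, float] | None = None,
                         n_bins: int = DEFAULT_N_BINS,
                         bin_size: int = DEFAULT_BIN_SIZE,
                         chrom: str = "chrS") -> TadLayout:
    """Evenly spaced boundaries; ``weakened`` maps boundary index -> weakening."""
    weakened = weakened or {}
    step = n_bins // (n_boundaries + 1)
    specs = [
        BoundarySpec(bin=(i + 1) * step, strength=strength,
                     weakening=weakened.get(i, 0.0))
        for i in range(n_boundaries)
    ]
    return TadLayout(chrom=chrom, bin_size=bin_size, n_bins=n_bins,
                     boundaries=tuple(specs))
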