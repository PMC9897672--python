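"""Containers and file formats used across the pipeline.

All interval arithmetic inside the package is 0-based, half-open; conversion
happens only at the file edge (narrowPeak/BED/bedGraph are already 0-based
half-open on disk, so round-trips are exact).

Contact matrices travel as plain text in two dialects:

``triplet``
    header lines ``# chrom=<name>``, ``# bin_size=<bp>``, ``# n_bins=<int>``
    followed by whitespace-separated ``bin1 bin2 count`` rows (0-based bins,
    upper triangle is sufficient; the reader mirrors whatever triangle is
    stored).

``dense``
    same header followed by an ``n_bins`` x ``n_bins`` tab-separated matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_SYMMETRY_TOL = 1e-9

GENE_REQUIRED_COLUMNS = ("gene_id", "chrom", "tss", "strand", "log2fc", "pvalue")


@dataclass
class ContactMatrix:
    """Symmetric per-chromosome binned contact counts at fixed bin size."""

    chrom: str
    bin_size: int
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.bin_size <= 0:
            raise ValueError(f"bin_size must be positive, got {self.bin_size}")
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError(f"counts must be square, got shape {self.counts.shape}")
        if not np.all(np.isfinite(self.counts)):
            raise ValueError("contact matrix contains non-finite values")
        if np.any(self.counts < 0):
            raise ValueError("contact matrix contains negative counts")
        if not np.allclose(self.counts, self.counts.T, atol=_SYMMETRY_TOL, rtol=0):
            raise ValueError("contact matrix is asymmetric beyond tolerance 1e-9")

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def binned(self, position: int) -> int:
        """Bin index containing a bp position."""
        return int(position) // self.bin_size


@dataclass
class Peak:
    """A called binding site; ``summit`` is the bp offset from ``start``."""

    chrom: str
    start: int
    end: int
    summit: int
    height: float = 0.0
    factor: str = ""
    name: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"peak end must exceed start ({self.start}, {self.end})")
        if not 0 <= self.summit < self.end - self.start:
            raise ValueError(
                f"summit offset {self.summit} outside peak of length {self.end - self.start}"
            )
        if self.height < 0:
            raise ValueError("peak height must be non-negative")

    @property
    def summit_pos(self) -> int:
        return self.start + self.summit


@dataclass
class PeakSet:
    """All peaks of one factor on one (or more) chromosomes."""

    factor: str
    peaks: list[Peak] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def summit_positions(self, chrom: str | None = None) -> np.ndarray:
        return np.array(
            [p.summit_pos for p in self.peaks if chrom is None or p.chrom == chrom],
            dtype=float,
        )

    def heights(self, chrom: str | None = None) -> np.ndarray:
        return np.array(
            [p.height for p in self.peaks if chrom is None or p.chrom == chrom],
            dtype=float,
        )


@dataclass
class BinnedTrack:
    """Fixed-step per-bin signal (coverage, insulation, ...)."""

    chrom: str
    bin_size: int
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if self.values.ndim != 1:
            raise ValueError("track values must be 1-D")


# ---------------------------------------------------------------------------
# contact matrices
# ---------------------------------------------------------------------------


def _write_header(fh, matrix: ContactMatrix) -> None:
    fh.write(f"# chrom={matrix.chrom}\n")
    fh.write(f"# bin_size={matrix.bin_size}\n")
    fh.write(f"# n_bins={matrix.n_bins}\n")


def _read_header(lines) -> tuple[dict, int]:
    meta: dict[str, str] = {}
    consumed = 0
    for line in lines:
        if not line.startswith("#"):
            break
        consumed += 1
        body = line[1:].strip()
        if "=" in body:
            key, value = body.split("=", 1)
            meta[key.strip()] = value.strip()
    for key in ("chrom", "bin_size", "n_bins"):
        if key not in meta:
            raise ValueError(f"matrix header missing required field '{key}'")
    return meta, consumed


def write_matrix(matrix: ContactMatrix, path, dialect: str = "triplet") -> None:
    if dialect not in ("triplet", "dense"):
        raise ValueError(f"unknown matrix dialect '{dialect}'")
    with open(path, "w") as fh:
        _write_header(fh, matrix)
        if dialect == "dense":
            for row in matrix.counts:
                fh.write("\t".join(format(v, ".10g") for v in row) + "\n")
        else:
            iu = np.triu_indices(matrix.n_bins)
            vals = matrix.counts[iu]
            nz = vals != 0
            body = pd.DataFrame({"bin1": iu[0][nz], "bin2": iu[1][nz],
                                 "count": vals[nz]})
            body.to_csv(fh, sep="\t", header=False, index=False,
                        float_format="%.10g")


def read_matrix(path, dialect: str = "triplet") -> ContactMatrix:
    if dialect not in ("triplet", "dense"):
        raise ValueError(f"unknown matrix dialect '{dialect}'")
    with open(path) as fh:
        lines = fh.read().splitlines()
    meta, consumed = _read_header(lines)
    chrom = meta["chrom"]
    bin_size = int(meta["bin_size"])
    n_bins = int(meta["n_bins"])
    body = [ln for ln in lines[consumed:] if ln.strip()]
    if dialect == "dense":
        if len(body) != n_bins:
            raise ValueError(f"dense matrix has {len(body)} rows, header says {n_bins}")
        counts = np.array([[float(v) for v in ln.split("\t")] for ln in body])
        if counts.shape != (n_bins, n_bins):
            raise ValueError("dense matrix is not square")
        if not np.allclose(counts, counts.T, atol=_SYMMETRY_TOL, rtol=0):
            raise ValueError("dense matrix asymmetric beyond tolerance 1e-9")
    else:
        counts = np.zeros((n_bins, n_bins))
        if body:
            import io

            table = pd.read_csv(io.StringIO("\n".join(body)), sep=r"\s+",
                                header=None, names=["bin1", "bin2", "count"])
            if table.isna().any().any():
                raise ValueError("malformed triplet line (expected 'bin1 bin2 count')")
            i = table["bin1"].to_numpy(dtype=np.int64)
            j = table["bin2"].to_numpy(dtype=np.int64)
            v = table["count"].to_numpy(dtype=float)
            if np.any((i < 0) | (i >= n_bins) | (j < 0) | (j >= n_bins)):
                raise ValueError(f"bin index out of range (n_bins={n_bins})")
            if np.any(v < 0):
                raise ValueError("negative count in triplet matrix")
            counts[i, j] = v
            counts[j, i] = v  # mirror the stored triangle
    return ContactMatrix(chrom=chrom, bin_size=bin_size, counts=counts)


# ---------------------------------------------------------------------------
# narrowPeak
# ---------------------------------------------------------------------------


def write_peaks(peakset: PeakSet, path) -> None:
    """Write a PeakSet as BED6+4 narrowPeak (summit in column 10)."""
    with open(path, "w") as fh:
        for k, p in enumerate(peakset.peaks):
            name = p.name or f"{peakset.factor or 'peak'}_{k}"
            score = int(min(1000, round(p.height)))
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\t{name}\t{score}\t.\t"
                f"{format(p.height, '.6g')}\t-1\t-1\t{p.summit}\n"
            )


def read_peaks(path, factor: str | None = None) -> PeakSet:
    """Read a narrowPeak file.

    A summit of -1 (unknown) is replaced by the interval midpoint; extra
    columns beyond the ten narrowPeak fields are ignored.  Both are logged.
    """
    peaks: list[Peak] = []
    warned_extra = False
    with open(path) as fh:
        for ln in fh:
            ln = ln.strip()
            if not ln or ln.startswith(("#", "track", "browser")):
                continue
            parts = ln.split("\t")
            if len(parts) < 10:
                raise ValueError(f"narrowPeak needs 10 columns, got {len(parts)}: {ln!r}")
            if len(parts) > 10 and not warned_extra:
                logger.warning("ignoring extra columns beyond narrowPeak's 10 in %s", path)
                warned_extra = True
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            name, height, summit = parts[3], float(parts[6]), int(parts[9])
            if summit == -1:
                summit = (end - start) // 2
                logger.info("summit -1 for %s; using interval midpoint", name)
            peaks.append(
                Peak(chrom=chrom, start=start, end=end, summit=summit,
                     height=height, factor=factor or "", name=name)
            )
    return PeakSet(factor=factor or "", peaks=peaks)


# ---------------------------------------------------------------------------
# gene tables
# ---------------------------------------------------------------------------


def validate_genes(genes: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in GENE_REQUIRED_COLUMNS if c not in genes.columns]
    if missing:
        raise ValueError(f"gene table missing required columns: {missing}")
    if not genes["strand"].isin(["+", "-"]).all():
        raise ValueError("gene strand must be '+' or '-'")
    p = genes["pvalue"].to_numpy(dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("gene p-values must lie in [0, 1]")
    if "qvalue" in genes.columns:
        q = genes["qvalue"].to_numpy(dtype=float)
        if np.any((q < 0) | (q > 1) | ~np.isfinite(q)):
            raise ValueError("gene q-values must lie in [0, 1]")
    return genes


def read_genes(path) -> pd.DataFrame:
    genes = pd.read_csv(path, sep="\t")
    if "maternal" in genes.columns:
        genes["maternal"] = genes["maternal"].astype(bool)
    extra = [c for c in genes.columns
             if c not in GENE_REQUIRED_COLUMNS + ("qvalue", "maternal", "planted_log2fc")]
    if extra:
        logger.warning("gene table %s has unrecognised columns %s (kept as-is)", path, extra)
    return validate_genes(genes)


def write_genes(genes: pd.DataFrame, path) -> None:
    validate_genes(genes).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# bedGraph
# ---------------------------------------------------------------------------


def write_bedgraph(track: BinnedTrack, path, valid: np.ndarray | None = None) -> None:
    """Write per-bin values as bedGraph; bins flagged invalid are omitted."""
    with open(path, "w") as fh:
        for i, v in enumerate(track.values):
            if valid is not None and not valid[i]:
                continue
            start = i * track.bin_size
            fh.write(f"{track.chrom}\t{start}\t{start + track.bin_size}\t{format(v, '.6g')}\n")


def read_bedgraph(path, bin_size: int, n_bins: int, fill: float = np.nan) -> BinnedTrack:
    values = np.full(n_bins, fill)
    chrom = ""
    with open(path) as fh:
        for ln in fh:
            if not ln.strip() or ln.startswith(("#", "track")):
                continue
            c, start, end, v = ln.split("\t")
            chrom = c
            i = int(start) // bin_size
            if not 0 <= i < n_bins:
                raise ValueError(f"bedGraph interval {start}-{end} outside track")
            values[i] = float(v)
    return BinnedTrack(chrom=chrom, bin_size=bin_size, values=values)
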