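"""Fixed-width genomic bins and per-bin read-count profiles.

The coordinate backbone of the pipeline: every chromosome is tiled left to
right with ``bin_width`` windows (0-based, half-open), the last window of a
chromosome may be shorter.  Aligned reads are assigned to exactly one bin by
their leftmost aligned base; paired-end fragments are counted once.

Counts live in :class:`BinProfile` objects which move through three stages:
``raw`` integer counts, ``gc_corrected`` ratios and ``pca_normalized``
ratios, the latter two rescaled so the mean over QC-passing autosomal bins
is exactly 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError
from .genomes import is_autosome, is_ignored_contig, normalize_chrom

logger = logging.getLogger(__name__)

DEFAULT_BIN_WIDTH = 20_000
DEFAULT_MIN_MAPQ = 20

#: Terminal bins shorter than this fraction of the bin width are flagged for
#: QC exclusion; their counts are not comparable to full-width bins.
SHORT_BIN_FRACTION = 0.9

STAGE_RAW = "raw"
STAGE_GC = "gc_corrected"
STAGE_PCA = "pca_normalized"
STAGES = (STAGE_RAW, STAGE_GC, STAGE_PCA)

#: Tolerance of the renormalization contract (mean over QC autosomal bins).
RENORM_TOL = 1e-9


@dataclass(frozen=True)
class GenomeBinning:
    """Ordered fixed-width bins over a chromosome set.

    Attributes
    ----------
    chrom_names : tuple of str
        Chromosome names in input order (as given by the caller).
    chrom_lengths : ndarray of int
        Length in bp of each chromosome.
    bin_width : int
        Nominal bin width in bp.
    bin_chrom : ndarray of int
        Per-bin chromosome index into ``chrom_names``.
    start, end : ndarray of int
        Per-bin 0-based half-open coordinates.
    autosome_mask : ndarray of bool
        True for bins on chromosomes 1-22.
    short_bin_mask : ndarray of bool
        True for terminal bins shorter than ``SHORT_BIN_FRACTION * bin_width``.
    """

    chrom_names: tuple[str, ...]
    chrom_lengths: np.ndarray
    bin_width: int
    bin_chrom: np.ndarray
    start: np.ndarray
    end: np.ndarray
    autosome_mask: np.ndarray
    short_bin_mask: np.ndarray

    @property
    def n_bins(self) -> int:
        return self.start.size

    def chrom_slice(self, chrom: str) -> slice:
        """Global bin-index slice of one chromosome."""
        idx = self.chrom_index(chrom)
        lo = int(np.searchsorted(self.bin_chrom, idx, side="left"))
        hi = int(np.searchsorted(self.bin_chrom, idx, side="right"))
        return slice(lo, hi)

    def chrom_index(self, chrom: str) -> int:
        """Resolve a chromosome name (tolerating the "chr" prefix) to its index."""
        canon = normalize_chrom(chrom)
        for i, name in enumerate(self.chrom_names):
            if normalize_chrom(name) == canon:
                return i
        raise KeyError(f"chromosome {chrom!r} not in binning")

    def has_chrom(self, chrom: str) -> bool:
        try:
            self.chrom_index(chrom)
            return True
        except KeyError:
            return False

    def sex_mask(self, which: str) -> np.ndarray:
        """Boolean bin mask for chromosome X or Y (all-False if absent)."""
        if not self.has_chrom(which):
            return np.zeros(self.n_bins, dtype=bool)
        sl = self.chrom_slice(which)
        mask = np.zeros(self.n_bins, dtype=bool)
        mask[sl] = True
        return mask

    def compatible_with(self, other: "GenomeBinning") -> bool:
        return (
            self.bin_width == other.bin_width
            and self.chrom_names == other.chrom_names
            and np.array_equal(self.chrom_lengths, other.chrom_lengths)
        )


def make_binning(
    chrom_sizes: Mapping[str, int] | Sequence[tuple[str, int]],
    bin_width: int = DEFAULT_BIN_WIDTH,
    keep_all_contigs: bool = False,
) -> GenomeBinning:
    """Tile each chromosome with fixed-width bins.

    Parameters
    ----------
    chrom_sizes : mapping or sequence of (name, length)
        Chromosome lengths in bp, in the desired order.
    bin_width : int
        Bin width in bp (default 20 kb).
    keep_all_contigs : bool
        Keep mitochondrial/unplaced contigs instead of dropping them.
    """
    if bin_width <= 0:
        raise ValueError(f"bin_width must be positive, got {bin_width}")
    items = list(chrom_sizes.items()) if isinstance(chrom_sizes, Mapping) else list(chrom_sizes)
    seen: set[str] = set()
    names: list[str] = []
    lengths: list[int] = []
    for name, length in items:
        canon = normalize_chrom(name)
        if canon in seen:
            raise FormatError(f"duplicate chromosome name: {name}")
        seen.add(canon)
        if not keep_all_contigs and is_ignored_contig(name):
            continue
        if int(length) <= 0:
            raise ValueError(f"non-positive length for chromosome {name}: {length}")
        names.append(str(name))
        lengths.append(int(length))
    if not names:
        raise ValueError("no usable chromosomes in chrom_sizes")

    chrom_idx, starts, ends = [], [], []
    for i, length in enumerate(lengths):
        s = np.arange(0, length, bin_width, dtype=np.int64)
        e = np.minimum(s + bin_width, length)
        chrom_idx.append(np.full(s.size, i, dtype=np.int32))
        starts.append(s)
        ends.append(e)
    bin_chrom = np.concatenate(chrom_idx)
    start = np.concatenate(starts)
    end = np.concatenate(ends)
    auto_by_chrom = np.array([is_autosome(n) for n in names], dtype=bool)
    return GenomeBinning(
        chrom_names=tuple(names),
        chrom_lengths=np.asarray(lengths, dtype=np.int64),
        bin_width=int(bin_width),
        bin_chrom=bin_chrom,
        start=start,
        end=end,
        autosome_mask=auto_by_chrom[bin_chrom],
        short_bin_mask=(end - start) < SHORT_BIN_FRACTION * bin_width,
    )


@dataclass
class BinProfile:
    """Per-bin values for one sample at a given processing stage."""

    binning: GenomeBinning
    values: np.ndarray
    qc_mask: np.ndarray
    total_umr: int
    stage: str = STAGE_RAW
    gc: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.qc_mask = np.asarray(self.qc_mask, dtype=bool)
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.values.shape != (self.binning.n_bins,):
            raise FormatError(
                f"profile has {self.values.size} values but binning has "
                f"{self.binning.n_bins} bins"
            )
        if self.qc_mask.shape != self.values.shape:
            raise FormatError("qc_mask length does not match binning")
        if self.gc is not None:
            self.gc = np.asarray(self.gc, dtype=float)
            if self.gc.shape != self.values.shape:
                raise FormatError("gc length does not match binning")
        if self.stage == STAGE_RAW:
            if np.any(self.values < 0) or np.any(self.values != np.round(self.values)):
                raise ValueError("raw profile values must be non-negative integers")
            if self.values.sum() > self.total_umr:
                raise ValueError("sum of bin counts exceeds total_umr")

    @property
    def autosomal_qc(self) -> np.ndarray:
        """QC-passing autosomal bin mask."""
        return self.qc_mask & self.binning.autosome_mask

    def renormalize(self) -> None:
        """Rescale so the mean over QC-passing autosomal bins is exactly 1."""
        m = self.values[self.autosomal_qc].mean()
        if not np.isfinite(m) or m <= 0:
            raise ValueError("cannot renormalize: non-positive autosomal mean")
        self.values = self.values / m

    def copy(self) -> "BinProfile":
        return BinProfile(
            binning=self.binning,
            values=self.values.copy(),
            qc_mask=self.qc_mask.copy(),
            total_umr=self.total_umr,
            stage=self.stage,
            gc=None if self.gc is None else self.gc.copy(),
        )


def default_qc_mask(binning: GenomeBinning) -> np.ndarray:
    """Initial QC mask: everything except short terminal bins."""
    return ~binning.short_bin_mask


def count_reads(
    alignment_path: str | Path,
    binning: GenomeBinning,
    min_mapq: int = DEFAULT_MIN_MAPQ,
) -> BinProfile:
    """Count uniquely mapped reads per bin from a coordinate-sorted BAM/SAM.

    A read is assigned to one bin by its leftmost aligned base.  Unmapped,
    secondary, supplementary, duplicate and sub-``min_mapq`` reads are
    excluded; paired-end fragments are counted once (second-in-pair mates
    with a mapped mate are skipped).
    """
    import pysam

    path = str(alignment_path)
    mode = "r" if path.endswith(".sam") else "rb"
    counts = np.zeros(binning.n_bins, dtype=np.int64)
    offsets = {}
    for i, name in enumerate(binning.chrom_names):
        sl = binning.chrom_slice(name)
        offsets[normalize_chrom(name)] = sl.start
    unknown: set[str] = set()
    total = 0
    with pysam.AlignmentFile(path, mode, check_sq=False) as af:
        for read in af.fetch(until_eof=True):
            if read.is_unmapped or read.is_secondary or read.is_supplementary or read.is_duplicate:
                continue
            if read.mapping_quality < min_mapq:
                continue
            if read.is_paired and read.is_read2 and not read.mate_is_unmapped:
                continue
            ref = read.reference_name
            canon = normalize_chrom(ref)
            off = offsets.get(canon)
            if off is None:
                if ref not in unknown:
                    unknown.add(ref)
                    logger.warning("read on chromosome %r absent from binning; skipped", ref)
                continue
            counts[off + read.reference_start // binning.bin_width] += 1
            total += 1
    return BinProfile(
        binning=binning,
        values=counts,
        qc_mask=default_qc_mask(binning),
        total_umr=total,
        stage=STAGE_RAW,
    )


def _read_table(path: str | Path, value_col: str) -> pd.DataFrame:
    """Read a 4-column TSV with optional header (BED dialect accepted)."""
    with open(path) as fh:
        first = fh.readline()
    if not first:
        raise FormatError(f"empty counts file: {path}")
    has_header = any(tok.lower() in ("chrom", "chr", "start", "end", value_col) for tok in first.rstrip("\n").split("\t"))
    df = pd.read_csv(
        path,
        sep="\t",
        header=0 if has_header else None,
        comment="#",
    )
    if df.shape[1] < 4:
        raise FormatError(f"expected 4 columns (chrom, start, end, {value_col}) in {path}")
    df = df.iloc[:, :5] if df.shape[1] >= 5 else df.iloc[:, :4]
    cols = ["chrom", "start", "end", value_col] + (["qc"] if df.shape[1] == 5 else [])
    df.columns = cols
    return df


def read_counts_table(path: str | Path, binning: GenomeBinning) -> BinProfile:
    """Read a raw-count profile from a TSV/BED-like file.

    Columns: chrom, start, end, count (tab-separated, header optional).
    Rows may be in any order; they are matched to the binning by
    (chromosome, start).
    """
    df = _read_table(path, "count")
    if len(df) != binning.n_bins:
        raise FormatError(
            f"{path}: {len(df)} rows but binning has {binning.n_bins} bins"
        )
    counts = _align_rows_to_binning(df, binning, "count")
    if np.any(counts < 0):
        raise ValueError(f"negative count in {path}")
    counts = counts.astype(np.int64)
    return BinProfile(
        binning=binning,
        values=counts,
        qc_mask=default_qc_mask(binning),
        total_umr=int(counts.sum()),
        stage=STAGE_RAW,
    )


def _align_rows_to_binning(df: pd.DataFrame, binning: GenomeBinning, col: str) -> np.ndarray:
    order = {}
    for i, name in enumerate(binning.chrom_names):
        order[normalize_chrom(name)] = i
    try:
        chrom_idx = df["chrom"].map(lambda c: order[normalize_chrom(c)]).to_numpy()
    except KeyError as exc:
        raise FormatError(f"chromosome {exc.args[0]!r} not in binning") from exc
    key = np.lexsort((df["start"].to_numpy(), chrom_idx))
    df = df.iloc[key]
    if not np.array_equal(df["start"].to_numpy(), binning.start) or not np.array_equal(
        df["end"].to_numpy(), binning.end
    ):
        raise FormatError("bin coordinates in file do not match the binning")
    return df[col].to_numpy(dtype=float)


def write_counts_table(profile: BinProfile, path: str | Path, header: bool = True) -> None:
    """Write a raw-count profile as TSV (chrom, start, end, count)."""
    _write_table(profile, path, "count", profile.values.astype(np.int64), header)


def read_profile_table(path: str | Path, binning: GenomeBinning, stage: str) -> BinProfile:
    """Read a normalized profile (chrom, start, end, value[, qc])."""
    df = _read_table(path, "value")
    if len(df) != binning.n_bins:
        raise FormatError(f"{path}: row count mismatch vs binning")
    values = _align_rows_to_binning(df, binning, "value")
    if "qc" in df.columns:
        qc = _align_rows_to_binning(df, binning, "qc").astype(bool)
    else:
        qc = default_qc_mask(binning)
    return BinProfile(
        binning=binning, values=values, qc_mask=qc, total_umr=0, stage=stage
    )


def write_profile_table(profile: BinProfile, path: str | Path) -> None:
    _write_table(profile, path, "value", profile.values, header=True, qc=profile.qc_mask)


def _write_table(profile, path, col, values, header, qc=None) -> None:
    b = profile.binning
    data = {
        "chrom": [b.chrom_names[i] for i in b.bin_chrom],
        "start": b.start,
        "end": b.end,
        col: values,
    }
    if qc is not None:
        data["qc"] = qc.astype(int)
    pd.DataFrame(data).to_csv(path, sep="\t", index=False, header=header)


def downsample_counts(profile: BinProfile, target_umr: int, seed: int) -> BinProfile:
    """In-silico downsampling by binomial thinning of each bin.

    Each read is retained independently with probability
    ``target_umr / total_umr``; no upsampling is allowed.
    """
    if profile.stage != STAGE_RAW:
        raise ValueError("downsampling applies to raw count profiles")
    if profile.total_umr <= 0:
        raise ValueError("profile has no reads")
    if target_umr > profile.total_umr:
        raise ValueError(
            f"target_umr {target_umr} exceeds total_umr {profile.total_umr}; upsampling not supported"
        )
    p = target_umr / profile.total_umr
    if p == 1.0:
        out = profile.copy()
        return out
    rng = np.random.default_rng(seed)
    thinned = rng.binomial(profile.values.astype(np.int64), p)
    return BinProfile(
        binning=profile.binning,
        values=thinned,
        qc_mask=profile.qc_mask.copy(),
        total_umr=int(thinned.sum()),
        stage=STAGE_RAW,
        gc=None if profile.gc is None else profile.gc.copy(),
    )
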