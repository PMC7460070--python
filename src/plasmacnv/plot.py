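"""Per-chromosome visualization of normalized profiles, segments and calls.

Layout follows the conventions of NIPT CNV review plots: per-bin normalized
levels as gray dots, segment means as horizontal lines (red for called
regions, with the z-score printed above), vertical black bands over bins
that failed QC, a shaded highlight over called regions, and two pairs of
dashed detection-limit lines — the fetal pair at 1 -/+ ff/2 and the
maternal pair at 1 -/+ 1/2.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .binning import BinProfile
from .calling import CNVCall, DetectionLimits
from .segmentation import Segment


def plot_chromosome(
    profile: BinProfile,
    segments: list[Segment],
    calls: list[CNVCall],
    limits: DetectionLimits | None,
    chrom: str,
    path: str | Path,
) -> Path:
    """Render one chromosome to an image file (format from the suffix)."""
    binning = profile.binning
    if not binning.has_chrom(chrom):
        raise ValueError(f"unknown chromosome {chrom!r}")
    sl = binning.chrom_slice(chrom)
    pos = (binning.start[sl] + binning.end[sl]) / 2 / 1e6
    vals = profile.values[sl]
    qc = profile.qc_mask[sl]

    fig, ax = plt.subplots(figsize=(10, 3.2))
    ax.plot(pos[qc], vals[qc], ".", color="0.6", ms=2, rasterized=True)

    # failed-QC bins as black bands along the bottom
    if (~qc).any():
        for s, e in _runs(~qc):
            ax.axvspan(binning.start[sl][s] / 1e6, binning.end[sl][e - 1] / 1e6, ymin=0.0, ymax=0.03, color="black")

    call_bins = {(c.segment.start_bin, c.segment.end_bin) for c in calls if c.chrom == chrom}
    for seg in segments:
        if seg.chrom != chrom:
            continue
        x0, x1 = binning.start[seg.start_bin] / 1e6, binning.end[seg.end_bin - 1] / 1e6
        called = (seg.start_bin, seg.end_bin) in call_bins
        ax.hlines(seg.mean_level, x0, x1, color="red" if called else "tab:blue", lw=2, zorder=5)
    for c in calls:
        if c.chrom != chrom:
            continue
        ax.axvspan(c.start_bp / 1e6, c.end_bp / 1e6, color="red", alpha=0.12, zorder=1)
        ax.annotate(
            f"z={c.z_score:.1f}",
            ((c.start_bp + c.end_bp) / 2e6, c.mean_level),
            textcoords="offset points",
            xytext=(0, 10),
            ha="center",
            fontsize=8,
            color="darkred",
        )

    if limits is not None:
        for y in (limits.fetal_level_loss, limits.fetal_level_gain):
            ax.axhline(y, color="red", ls="--", lw=0.8)
        for y in (limits.maternal_level_loss, limits.maternal_level_gain):
            ax.axhline(y, color="magenta", ls="--", lw=0.8)

    ax.set_xlabel(f"{chrom} position (Mb)")
    ax.set_ylabel("normalized level")
    ax.set_ylim(0.3, 1.7)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def plot_genome(profile, segments, calls, limits, out_dir: str | Path, fmt: str = "png") -> list[Path]:
    """One figure per chromosome, including X and Y."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    return [
        plot_chromosome(profile, segments, calls, limits, chrom, out_dir / f"{chrom}.{fmt}")
        for chrom in profile.binning.chrom_names
    ]


def _runs(mask: np.ndarray):
    """(start, end) index pairs of consecutive True runs."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    return list(zip(idx[::2], idx[1::2]))
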