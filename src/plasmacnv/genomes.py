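"""Chromosome naming, built-in genome presets and chrom.sizes I/O.

Chromosome names are normalized internally ("chr1" and "1" are the same
chromosome); autosomes are the chromosomes named 1-22.  Mitochondrial and
unplaced/alternate contigs are ignored by default when building binnings,
since low-pass cfDNA pipelines operate on the nuclear primary assembly.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .errors import FormatError

#: hg19 / GRCh37 primary-assembly chromosome lengths (bp).
HG19_SIZES: dict[str, int] = {
    "chr1": 249250621,
    "chr2": 243199373,
    "chr3": 198022430,
    "chr4": 191154276,
    "chr5": 180915260,
    "chr6": 171115067,
    "chr7": 159138663,
    "chr8": 146364022,
    "chr9": 141213431,
    "chr10": 135534747,
    "chr11": 135006516,
    "chr12": 133851895,
    "chr13": 115169878,
    "chr14": 107349540,
    "chr15": 102531392,
    "chr16": 90354753,
    "chr17": 81195210,
    "chr18": 78077248,
    "chr19": 59128983,
    "chr20": 63025520,
    "chr21": 48129895,
    "chr22": 51304566,
    "chrX": 155270560,
    "chrY": 59373566,
}

AUTOSOME_NAMES = {str(i) for i in range(1, 23)}

IGNORED_KEYWORDS = ("_", "un", "random", "alt", "hap", "fix")


def normalize_chrom(name: str) -> str:
    """Return the canonical short name of a chromosome ("chr1" -> "1")."""
    s = str(name).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    if s.upper() in ("X", "Y"):
        return s.upper()
    if s.upper() in ("M", "MT"):
        return "MT"
    return s


def is_autosome(name: str) -> bool:
    return normalize_chrom(name) in AUTOSOME_NAMES


def is_ignored_contig(name: str) -> bool:
    """Mitochondrion, unplaced and alternate contigs are skipped by default."""
    canon = normalize_chrom(name)
    if canon == "MT":
        return True
    low = str(name).lower()
    return any(k in low for k in IGNORED_KEYWORDS)


def toy_chrom_sizes(include_sex: bool = True) -> dict[str, int]:
    """A 60 Mb reduced genome used for fast tests and examples.

    Three autosomes plus (optionally) short stand-ins for X and Y.  Run it
    with a proportionally reduced read count so the per-bin depth matches
    the full-genome regime.
    """
    sizes = {"chr1": 24_000_000, "chr2": 18_000_000, "chr3": 12_000_000}
    if include_sex:
        sizes["chrX"] = 3_600_000
        sizes["chrY"] = 2_400_000
    return sizes


def proportional_umr(chrom_sizes: dict[str, int], reads_per_bp: float = 20e6 / 3.095e9) -> int:
    """Read count giving the same per-bp depth as 20 M reads on hg19."""
    return int(round(sum(chrom_sizes.values()) * reads_per_bp))


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Read a two-column chrom/length TSV (UCSC chrom.sizes style)."""
    try:
        df = pd.read_csv(path, sep="\t", header=None, usecols=[0, 1], names=["chrom", "length"])
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"cannot parse chrom.sizes file {path}: {exc}") from exc
    if df["chrom"].duplicated().any():
        dup = df.loc[df["chrom"].duplicated(), "chrom"].iloc[0]
        raise FormatError(f"duplicate chromosome name in {path}: {dup}")
    sizes = {}
    for chrom, length in zip(df["chrom"], df["length"]):
        try:
            length = int(length)
        except (TypeError, ValueError) as exc:
            raise FormatError(f"non-integer length for {chrom} in {path}") from exc
        sizes[str(chrom)] = length
    return sizes
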