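"""Ground-truthed simulation of cfDNA bin-count profiles.

The simulator emulates the data regime of low-pass plasma sequencing in an
NIPT-like setting: ~20 M uniquely mapped reads spread over 20 kb bins, a
smooth multiplicative GC bias, shared cohort artifact vectors with random
per-sample loadings, a small set of effectively unmappable bins, counting
noise (Poisson or negative-binomial), and spiked fetal/maternal CNVs whose
expected read-depth ratio follows the two-genome mixture model:

    ratio = 1 + m * (copy_delta / 2) * mosaic_fraction

with mixture weight m = ff for a fetal-only CNV, 1 - ff for a maternal-only
CNV and 1 for a CNV shared by mother and fetus.  A male fetus contributes
chromosome Y reads in proportion to ff/2, on top of a small female
mismapping background.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .binning import (
    BinProfile,
    DEFAULT_BIN_WIDTH,
    GenomeBinning,
    STAGE_RAW,
    default_qc_mask,
    make_binning,
)
from .errors import ConfigError
from .genomes import HG19_SIZES, proportional_umr, toy_chrom_sizes

DIRECTION_LOSS = "loss"
DIRECTION_GAIN = "gain"
CARRIERS = ("fetal", "maternal_only", "fetomaternal")

#: Default multiplicative GC-bias polynomial in (gc - 0.42): 1 + c1*d + c2*d^2.
DEFAULT_GC_BIAS = (1.0, 0.6, -12.0)

#: Relative read level of a chrY bin in a pregnancy with a female fetus
#: (mismapping background).
DEFAULT_Y_BACKGROUND = 0.002


@dataclass(frozen=True)
class CNVSpec:
    """Ground-truth description of one spiked copy number variant."""

    chrom: str
    start: int
    end: int
    carrier: str  # fetal | maternal_only | fetomaternal
    copy_delta: int  # -1 heterozygous loss, +1 heterozygous gain, +2 tetraplication-like
    mosaic_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("CNV end must exceed start")
        if self.carrier not in CARRIERS:
            raise ValueError(f"unknown carrier {self.carrier!r}")
        if self.copy_delta not in (-1, 1, 2):
            raise ValueError("copy_delta must be -1, +1 or +2")
        if not (0 < self.mosaic_fraction <= 1):
            raise ValueError("mosaic_fraction must be in (0, 1]")

    @property
    def direction(self) -> str:
        return DIRECTION_LOSS if self.copy_delta < 0 else DIRECTION_GAIN

    @property
    def size_bp(self) -> int:
        return self.end - self.start

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CNVSpec":
        return cls(**{k: d[k] for k in ("chrom", "start", "end", "carrier", "copy_delta", "mosaic_fraction")})


def expected_bin_ratio(spec: CNVSpec, ff: float) -> float:
    """Expected normalized read-depth ratio of bins fully inside a CNV.

    Under the mother/fetus mixture model a heterozygous fetal deletion gives
    1 - ff/2, a maternal-only heterozygous deletion 0.5 + ff/2, a shared
    (fetomaternal) heterozygous deletion 0.5, and a fetal two-copy gain
    1 + ff.
    """
    if not (0 < ff < 0.5):
        raise ValueError(f"ff must be in (0, 0.5), got {ff}")
    m = {"fetal": ff, "maternal_only": 1.0 - ff, "fetomaternal": 1.0}[spec.carrier]
    return 1.0 + m * (spec.copy_delta / 2.0) * spec.mosaic_fraction


@dataclass
class SimulatedGenome:
    """Fixed, cohort-shared context: binning, per-bin GC, artifact vectors,
    and the unmappable-bin mask.  Samples from one study share one genome."""

    binning: GenomeBinning
    gc: np.ndarray
    artifact_vectors: np.ndarray  # (k, n_bins), unit per-bin RMS over autosomes
    dropout_mask: np.ndarray  # bins with near-zero mappability

    @property
    def n_artifacts(self) -> int:
        return self.artifact_vectors.shape[0]


def _smooth_per_chrom(x: np.ndarray, binning: GenomeBinning, window: int) -> np.ndarray:
    out = np.empty_like(x)
    kernel = np.ones(window) / window
    for name in binning.chrom_names:
        sl = binning.chrom_slice(name)
        seg = x[sl]
        if seg.size >= window:
            sm = np.convolve(seg, kernel, mode="same")
        else:
            sm = np.full(seg.size, seg.mean())
        out[sl] = sm
    return out


def simulate_genome(
    chrom_sizes: dict[str, int] | None = None,
    bin_width: int = DEFAULT_BIN_WIDTH,
    n_artifacts: int = 3,
    dropout_fraction: float = 0.01,
    seed: int | np.random.Generator = 0,
    artifact_smoothing: int = 1,
) -> SimulatedGenome:
    """Build the shared genome context for a simulated cohort.

    Per-bin GC is a smoothed Gaussian field around 0.42 (sd ~0.04 after
    smoothing), artifact vectors are random fields normalized to unit
    per-bin RMS, and a ``dropout_fraction`` of bins is made effectively
    unmappable (emulating e.g. centromeric regions).

    Artifact vectors are per-bin by default (no spatial correlation):
    bin-specific systematic responses whose loadings vary by sample, the
    regime panel PCA is designed for.  Spatially smooth artifact fields at
    comparable amplitude would put multi-megabase waves at the scale of the
    fetal detection limit into every profile, which contradicts the
    operating characteristics low-pass CNV pipelines demonstrably have;
    ``artifact_smoothing`` > 1 restores smooth fields for stress testing.
    """
    if chrom_sizes is None:
        chrom_sizes = HG19_SIZES
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    binning = make_binning(chrom_sizes, bin_width)
    n = binning.n_bins

    gc = rng.normal(0.42, 0.08, n)
    gc = _smooth_per_chrom(gc, binning, 5)
    gc = np.clip(gc, 0.28, 0.65)

    vecs = np.empty((n_artifacts, n))
    for a in range(n_artifacts):
        v = _smooth_per_chrom(rng.normal(0.0, 1.0, n), binning, max(1, artifact_smoothing))
        rms = np.sqrt(np.mean(v[binning.autosome_mask] ** 2))
        vecs[a] = v / rms
    dropout = rng.random(n) < dropout_fraction
    return SimulatedGenome(binning=binning, gc=gc, artifact_vectors=vecs, dropout_mask=dropout)


def toy_genome(seed: int = 0, include_sex: bool = True, **kw) -> SimulatedGenome:
    """Reduced 60 Mb genome for fast tests (proportional read counts)."""
    return simulate_genome(toy_chrom_sizes(include_sex), seed=seed, **kw)


@dataclass
class SimulationConfig:
    """Everything needed to realize one plasma sample.

    ``genome`` carries the cohort-shared context (GC field, artifact vectors,
    dropout bins); if omitted it is built from ``chrom_sizes`` and ``seed``.
    ``noise`` is "poisson" or ("neg_binomial", dispersion).
    """

    chrom_sizes: dict[str, int] | None = None
    bin_width: int = DEFAULT_BIN_WIDTH
    total_umr: int = 20_000_000
    ff: float = 0.13
    fetal_sex: str = "XY"
    gc_bias: tuple[float, ...] | None = DEFAULT_GC_BIAS
    artifact_loading_sd: float = 0.04
    noise: object = "poisson"
    cnvs: list[CNVSpec] = field(default_factory=list)
    y_background: float = DEFAULT_Y_BACKGROUND
    seed: int = 0
    genome: SimulatedGenome | None = None

    def __post_init__(self) -> None:
        if not (0 < self.ff < 0.5):
            raise ConfigError(f"ff must be in (0, 0.5), got {self.ff}")
        if self.total_umr <= 0:
            raise ConfigError("total_umr must be positive")
        if self.fetal_sex not in ("XX", "XY"):
            raise ConfigError("fetal_sex must be XX or XY")

    def resolve_genome(self) -> SimulatedGenome:
        if self.genome is None:
            self.genome = simulate_genome(self.chrom_sizes, self.bin_width, seed=self.seed + 10_007)
        return self.genome


def _gc_bias_factor(gc: np.ndarray, coeffs) -> np.ndarray:
    if coeffs is None or coeffs == "none":
        return np.ones_like(gc)
    d = gc - 0.42
    out = np.zeros_like(gc)
    for p, c in enumerate(coeffs):
        out += c * d**p
    return np.clip(out, 0.05, None)


def _cnv_overlap_fractions(binning: GenomeBinning, spec: CNVSpec) -> tuple[slice, np.ndarray]:
    sl = binning.chrom_slice(spec.chrom)
    starts = binning.start[sl]
    ends = binning.end[sl]
    ov = np.clip(np.minimum(ends, spec.end) - np.maximum(starts, spec.start), 0, None)
    frac = ov / (ends - starts)
    return sl, frac


def simulate_sample(config: SimulationConfig) -> tuple[BinProfile, dict]:
    """Realize one sample's raw bin counts plus its ground-truth manifest."""
    genome = config.resolve_genome()
    binning = genome.binning
    for spec in config.cnvs:
        sl = binning.chrom_slice(spec.chrom)
        chrom_len = int(binning.end[sl][-1])
        if spec.start < 0 or spec.end > chrom_len:
            raise ConfigError(f"CNV {spec} exceeds chromosome bounds (0, {chrom_len})")

    rng = np.random.default_rng(config.seed)
    n = binning.n_bins
    w = np.ones(n)
    w[genome.dropout_mask] = 1e-3

    w *= _gc_bias_factor(genome.gc, config.gc_bias)

    if genome.n_artifacts and config.artifact_loading_sd > 0:
        loadings = rng.normal(0.0, config.artifact_loading_sd, genome.n_artifacts)
        w *= np.clip(1.0 + loadings @ genome.artifact_vectors, 0.05, None)
    else:
        loadings = np.zeros(genome.n_artifacts)

    xmask = binning.sex_mask("X")
    ymask = binning.sex_mask("Y")
    if config.fetal_sex == "XY":
        w[xmask] *= 1.0 - config.ff / 2.0
        w[ymask] *= config.ff / 2.0 + config.y_background
    else:
        w[ymask] *= config.y_background

    truth_cnvs = []
    for spec in config.cnvs:
        ratio = expected_bin_ratio(spec, config.ff)
        sl, frac = _cnv_overlap_fractions(binning, spec)
        w[sl] *= 1.0 + (ratio - 1.0) * frac
        truth_cnvs.append({**spec.to_dict(), "expected_ratio": ratio})

    if np.any(w <= 0):
        raise ConfigError("expected count non-positive in some bin; check bias settings")
    mu = config.total_umr * (w / w.sum())

    if config.noise == "poisson":
        counts = rng.poisson(mu)
    else:
        kind, disp = config.noise
        if kind != "neg_binomial":
            raise ConfigError(f"unknown noise model {config.noise!r}")
        # Gamma-Poisson mixture: var = mu * (1 + disp * mu)
        lam = rng.gamma(shape=1.0 / disp, scale=disp * mu)
        counts = rng.poisson(lam)

    profile = BinProfile(
        binning=binning,
        values=counts,
        qc_mask=default_qc_mask(binning),
        total_umr=int(counts.sum()),
        stage=STAGE_RAW,
        gc=genome.gc.copy(),
    )
    manifest = {
        "ff": config.ff,
        "fetal_sex": config.fetal_sex,
        "target_umr": config.total_umr,
        "realized_umr": int(counts.sum()),
        "noise": config.noise if isinstance(config.noise, str) else list(config.noise),
        "seed": config.seed,
        "artifact_loadings": [float(x) for x in loadings],
        "cnvs": truth_cnvs,
    }
    return profile, manifest


def save_manifest(manifest: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True))


def load_manifest(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def simulate_panel(
    n: int,
    config_base: SimulationConfig,
    ff_range: tuple[float, float] = (0.07, 0.25),
) -> list[BinProfile]:
    """Simulate ``n`` CNV-free reference pregnancies sharing one genome.

    Panel members carry no CNVs, have female fetuses (so chromosome Y holds
    only the mismapping background usable to calibrate fetal-fraction
    estimation) and random fetal fractions and artifact loadings.
    """
    if n < 8:
        raise ValueError(f"reference panel needs at least 8 samples, got {n}")
    genome = config_base.resolve_genome()
    rng = np.random.default_rng(config_base.seed)
    profiles = []
    for i in range(n):
        ff = float(rng.uniform(*ff_range))
        cfg = SimulationConfig(
            bin_width=config_base.bin_width,
            total_umr=config_base.total_umr,
            ff=ff,
            fetal_sex="XX",
            gc_bias=config_base.gc_bias,
            artifact_loading_sd=config_base.artifact_loading_sd,
            noise=config_base.noise,
            cnvs=[],
            y_background=config_base.y_background,
            seed=int(rng.integers(0, 2**31 - 1)),
            genome=genome,
        )
        profiles.append(simulate_sample(cfg)[0])
    return profiles


def random_cnv_spec(
    binning: GenomeBinning,
    size_bp: int,
    rng: np.random.Generator,
    carrier: str = "fetal",
    copy_delta: int | None = None,
    edge_margin_bp: int = 2_000_000,
) -> CNVSpec:
    """Place one CNV of the given size uniformly at random on a random autosome.

    Placement avoids ``edge_margin_bp`` at chromosome ends by default so size
    effects are not confounded with edge effects.
    """
    autosomes = [
        name
        for i, name in enumerate(binning.chrom_names)
        if binning.autosome_mask[binning.chrom_slice(name)].any()
        and int(binning.chrom_lengths[i]) >= size_bp + 2 * edge_margin_bp
    ]
    if not autosomes:
        raise ValueError(f"no autosome can hold a {size_bp} bp CNV with the requested margins")
    chrom = autosomes[int(rng.integers(len(autosomes)))]
    chrom_len = int(binning.chrom_lengths[binning.chrom_index(chrom)])
    start = int(rng.integers(edge_margin_bp, chrom_len - edge_margin_bp - size_bp + 1))
    if copy_delta is None:
        copy_delta = int(rng.choice([-1, 1]))
    return CNVSpec(chrom=chrom, start=start, end=start + size_bp, carrier=carrier, copy_delta=copy_delta)


def sensitivity_grid(
    sizes: Sequence[int],
    ffs: Sequence[float],
    n_rep: int,
    pipeline_params=None,
    seed: int = 0,
    config_base: SimulationConfig | None = None,
    panel_size: int = 12,
):
    """Empirical detection-rate grid over CNV size and fetal fraction.

    For each (size, ff) cell, ``n_rep`` samples are simulated with one fetal
    heterozygous CNV placed at random, pushed through the full pipeline, and
    a spike counts as detected when a call of matching direction overlaps at
    least 50% of the truth interval.  Returns a tidy DataFrame with one row
    per cell.
    """
    import pandas as pd

    from .normalization import fit_reference_panel, loess_gc_correct, pca_normalize
    from .pipeline import PipelineParams, run_sample

    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    params = pipeline_params or PipelineParams()
    base = config_base or SimulationConfig(chrom_sizes=toy_chrom_sizes(), total_umr=proportional_umr(toy_chrom_sizes()), seed=seed)
    genome = base.resolve_genome()
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)

    panel_base = SimulationConfig(
        bin_width=base.bin_width,
        total_umr=base.total_umr,
        gc_bias=base.gc_bias,
        artifact_loading_sd=base.artifact_loading_sd,
        noise=base.noise,
        y_background=base.y_background,
        seed=int(rng.integers(0, 2**31 - 1)),
        genome=genome,
    )
    panel_profiles = [loess_gc_correct(p, span=params.loess_span) for p in simulate_panel(panel_size, panel_base)]
    panel = fit_reference_panel(panel_profiles, n_components=params.n_components)

    rows = []
    for size in sizes:
        for ff in ffs:
            detected = 0
            for _ in range(n_rep):
                spec = random_cnv_spec(genome.binning, int(size), rng)
                cfg = SimulationConfig(
                    bin_width=base.bin_width,
                    total_umr=base.total_umr,
                    ff=float(ff),
                    fetal_sex="XY",
                    gc_bias=base.gc_bias,
                    artifact_loading_sd=base.artifact_loading_sd,
                    noise=base.noise,
                    cnvs=[spec],
                    y_background=base.y_background,
                    seed=int(rng.integers(0, 2**31 - 1)),
                    genome=genome,
                )
                raw, _ = simulate_sample(cfg)
                result = run_sample(raw, panel, params, ff=float(ff))
                if any(_call_matches(c, spec) for c in result.calls):
                    detected += 1
            rows.append(
                {"size_bp": int(size), "ff": float(ff), "n_rep": n_rep, "detected": detected, "rate": detected / n_rep}
            )
    return pd.DataFrame(rows)


def _call_matches(call, spec: CNVSpec, min_overlap: float = 0.5) -> bool:
    """Does a call overlap >= ``min_overlap`` of the truth with the right sign?"""
    from .genomes import normalize_chrom

    if normalize_chrom(call.chrom) != normalize_chrom(spec.chrom):
        return False
    if call.direction != spec.direction:
        return False
    ov = min(call.end_bp, spec.end) - max(call.start_bp, spec.start)
    return ov >= min_overlap * spec.size_bp


def summarize_grid(grid, size_cutoff_bp: int = 3_000_000, ff_cutoff: float = 0.10):
    """Collapse a sensitivity grid into the size / fetal-fraction groupings
    (< 3 Mb vs >= 3 Mb; ff < 10% vs >= 10%)."""
    import pandas as pd

    def rate(mask):
        sub = grid[mask]
        n = sub["n_rep"].sum()
        return float("nan") if n == 0 else sub["detected"].sum() / n

    return pd.Series(
        {
            "overall": rate(grid["size_bp"] > 0),
            "lt_3Mb": rate(grid["size_bp"] < size_cutoff_bp),
            "ge_3Mb": rate(grid["size_bp"] >= size_cutoff_bp),
            "ff_lt_10": rate(grid["ff"] < ff_cutoff),
            "ff_ge_10": rate(grid["ff"] >= ff_cutoff),
        }
    )
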