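"""End-to-end orchestration: count -> GC-correct -> PCA-normalize ->
segment -> call -> classify, with a file-based configuration layer for the
command line and a light in-memory entry point (:func:`run_sample`) for
programmatic use and simulation harnesses.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import __version__
from .binning import (
    BinProfile,
    DEFAULT_BIN_WIDTH,
    make_binning,
    read_counts_table,
    write_profile_table,
)
from .calling import (
    CNVCall,
    DEFAULT_MIN_CALL_BINS,
    DEFAULT_MIN_FFCNV,
    DEFAULT_Z_THRESHOLD,
    call_cnvs,
    detection_limits,
    write_calls_table,
)
from .errors import ConfigError
from .fetal_fraction import FetalFractionEstimate, YCalibration, estimate_ff_chry, resolve_ff
from .genomes import read_chrom_sizes
from .normalization import (
    DEFAULT_LOESS_SPAN,
    ReferencePanel,
    fit_reference_panel,
    loess_gc_correct,
    pca_normalize,
)
from .segmentation import (
    DEFAULT_ALPHA,
    DEFAULT_MIN_WIDTH,
    DEFAULT_N_PERM,
    Segment,
    segment_profile,
    write_segments_table,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineParams:
    """Numerical knobs of every stage, with the package defaults."""

    bin_width: int = DEFAULT_BIN_WIDTH
    min_mapq: int = 20
    loess_span: float = DEFAULT_LOESS_SPAN
    n_components: int | str = "auto"
    alpha: float = DEFAULT_ALPHA
    n_perm: int = DEFAULT_N_PERM
    min_width: int = DEFAULT_MIN_WIDTH
    z_threshold: float = DEFAULT_Z_THRESHOLD
    min_ffcnv: float = DEFAULT_MIN_FFCNV
    min_call_bins: int = DEFAULT_MIN_CALL_BINS
    #: Sex chromosomes are excluded from default segmentation: their dosage
    #: reflects fetal sex and (for X) un-removed cohort artifacts, and CNV
    #: calls are autosomal.  Review plotting re-segments X/Y on demand.
    segment_sex_chroms: bool = False
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SampleResult:
    """Everything the pipeline produced for one sample."""

    normalized: BinProfile
    segments: list[Segment]
    calls: list[CNVCall]
    ff: float | None
    ff_estimate: FetalFractionEstimate | None = None


def run_sample(
    raw: BinProfile,
    panel: ReferencePanel,
    params: PipelineParams | None = None,
    ff: float | None = None,
    calibration: YCalibration | None = None,
    gc: np.ndarray | None = None,
) -> SampleResult:
    """Normalize, segment and call one raw profile against a fitted panel.

    ``ff`` may be supplied externally; otherwise, when a chrY calibration is
    given, it is estimated from the chromosome-Y read share (male fetuses).
    Without either, calls are made but origin classes are ambiguous.
    """
    params = params or PipelineParams()
    ff_est = None
    if ff is None and calibration is not None:
        ff_est = estimate_ff_chry(raw, calibration)
        try:
            ff = resolve_ff(ff_est)
        except ConfigError:
            ff = None
    corrected = loess_gc_correct(raw, gc=gc, span=params.loess_span)
    normalized = pca_normalize(corrected, panel)
    chroms = None
    if not params.segment_sex_chroms:
        chroms = [c for c in normalized.binning.chrom_names if normalized.binning.autosome_mask[normalized.binning.chrom_slice(c)].any()]
    segments = segment_profile(
        normalized,
        alpha=params.alpha,
        n_perm=params.n_perm,
        min_width=params.min_width,
        seed=params.seed,
        chroms=chroms,
    )
    calls = call_cnvs(
        segments,
        normalized,
        ff=ff,
        z_threshold=params.z_threshold,
        min_ffcnv=params.min_ffcnv,
        min_bins=params.min_call_bins,
    )
    return SampleResult(normalized=normalized, segments=segments, calls=calls, ff=ff, ff_estimate=ff_est)


@dataclass
class PipelineConfig:
    """File-based run configuration (see :func:`load_config`)."""

    counts: str
    chrom_sizes: str
    panel_counts: list[str] = field(default_factory=list)
    panel: str | None = None
    gc: str | None = None
    out_dir: str = "plasmacnv_out"
    ff: float | None = None
    ff_source: str = "external"  # external | chrY
    params: PipelineParams = field(default_factory=PipelineParams)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["params"] = self.params.to_dict()
        return d


def load_config(path: str | Path) -> PipelineConfig:
    """Read a TOML run configuration with per-stage sections."""
    import tomllib

    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    paths = raw.get("paths", {})
    run = raw.get("run", {})
    params = PipelineParams(**raw.get("params", {}))
    try:
        return PipelineConfig(
            counts=paths["counts"],
            chrom_sizes=paths["chrom_sizes"],
            panel_counts=paths.get("panel_counts", []),
            panel=paths.get("panel"),
            gc=paths.get("gc"),
            out_dir=paths.get("out_dir", "plasmacnv_out"),
            ff=run.get("ff"),
            ff_source=run.get("ff_source", "external"),
            params=params,
        )
    except KeyError as exc:
        raise ConfigError(f"missing required config key: paths.{exc.args[0]}") from exc


def write_config(config: PipelineConfig, path: str | Path) -> None:
    """Write a config back to TOML (lossless round trip with load_config)."""

    def fmt(v):
        if isinstance(v, bool):
            return "true" if v else "false"
        if isinstance(v, (int, float)):
            return repr(v)
        if isinstance(v, list):
            return "[" + ", ".join(fmt(x) for x in v) + "]"
        return json.dumps(str(v))

    lines = ["[paths]"]
    lines.append(f"counts = {fmt(config.counts)}")
    lines.append(f"chrom_sizes = {fmt(config.chrom_sizes)}")
    if config.panel_counts:
        lines.append(f"panel_counts = {fmt(config.panel_counts)}")
    if config.panel:
        lines.append(f"panel = {fmt(config.panel)}")
    if config.gc:
        lines.append(f"gc = {fmt(config.gc)}")
    lines.append(f"out_dir = {fmt(config.out_dir)}")
    lines.append("")
    lines.append("[run]")
    if config.ff is not None:
        lines.append(f"ff = {fmt(config.ff)}")
    lines.append(f"ff_source = {fmt(config.ff_source)}")
    lines.append("")
    lines.append("[params]")
    for k, v in config.params.to_dict().items():
        lines.append(f"{k} = {fmt(v)}")
    Path(path).write_text("\n".join(lines) + "\n")


def _read_gc_table(path: str | Path, binning) -> np.ndarray:
    import pandas as pd

    from .binning import _align_rows_to_binning, _read_table

    df = _read_table(path, "gc")
    return _align_rows_to_binning(df, binning, "gc")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline from files and write per-stage artifacts.

    Returns the JSON-serializable run report (also written to the output
    directory).  A failing stage aborts with the stage named; artifacts of
    completed stages are retained.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "parameters": config.to_dict(),
        "stages": [],
    }
    stage_t0 = time.perf_counter()

    def done(stage: str) -> None:
        nonlocal stage_t0
        dt = time.perf_counter() - stage_t0
        report["stages"].append({"stage": stage, "seconds": round(dt, 3)})
        logger.info("stage %-14s %.2fs", stage, dt)
        stage_t0 = time.perf_counter()

    stage = "load"
    try:
        sizes = read_chrom_sizes(config.chrom_sizes)
        binning = make_binning(sizes, config.params.bin_width)
        raw = read_counts_table(config.counts, binning)
        gc = _read_gc_table(config.gc, binning) if config.gc else None
        done(stage)

        stage = "panel"
        calibration = None
        if config.panel:
            panel = ReferencePanel.load(config.panel)
        elif config.panel_counts:
            panel_raw = [read_counts_table(p, binning) for p in config.panel_counts]
            panel_gc = [loess_gc_correct(p, gc=gc, span=config.params.loess_span) for p in panel_raw]
            panel = fit_reference_panel(panel_gc, n_components=config.params.n_components)
            if config.ff_source == "chrY":
                from .fetal_fraction import calibrate_from_panel

                calibration = calibrate_from_panel(panel_raw)
        else:
            raise ConfigError("either paths.panel or paths.panel_counts is required")
        done(stage)

        stage = "normalize+segment+call"
        ff = config.ff if config.ff_source == "external" else None
        result = run_sample(raw, panel, config.params, ff=ff, calibration=calibration, gc=gc)
        done(stage)

        stage = "write"
        write_profile_table(result.normalized, out / "normalized.tsv")
        write_segments_table(result.segments, binning, out / "segments.tsv")
        write_calls_table(result.calls, out / "calls.tsv")
        by_origin: dict[str, int] = {}
        for c in result.calls:
            by_origin[c.origin_class] = by_origin.get(c.origin_class, 0) + 1
        report["ff"] = result.ff
        report["n_segments"] = len(result.segments)
        report["n_calls"] = len(result.calls)
        report["calls_by_origin"] = by_origin
        if result.ff is not None:
            lim = detection_limits(result.ff)
            report["detection_limits"] = {
                "fetal_level_loss": lim.fetal_level_loss,
                "fetal_level_gain": lim.fetal_level_gain,
                "maternal_level_loss": lim.maternal_level_loss,
                "maternal_level_gain": lim.maternal_level_gain,
            }
        done(stage)
    except Exception as exc:
        raise type(exc)(f"pipeline stage '{stage}' failed: {exc}") from exc

    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
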