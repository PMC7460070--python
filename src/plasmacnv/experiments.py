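"""Desk-scale simulation studies of pipeline performance.

These harnesses reproduce, on synthetic cohorts, the validation experiments
a clinical low-pass cfDNA CNV pipeline is judged by: detection sensitivity
of spiked fetal CNVs across size and fetal fraction, the ~100% CNV-fraction
signature of maternal/fetomaternal variants, CNV-fraction recovery of the
fetal fraction, and specificity on CNV-free genomes.

All randomness flows from a single integer seed through
``numpy.random.SeedSequence`` spawning, so every experiment is exactly
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .binning import BinProfile
from .normalization import ReferencePanel, fit_reference_panel, loess_gc_correct
from .pipeline import PipelineParams, run_sample
from .simulate import (
    CNVSpec,
    SimulatedGenome,
    SimulationConfig,
    _call_matches,
    random_cnv_spec,
    simulate_genome,
    simulate_panel,
    simulate_sample,
)


@dataclass
class CohortContext:
    """Shared context of one simulated study: genome, fitted panel, base config."""

    genome: SimulatedGenome
    panel: ReferencePanel
    panel_raw: list[BinProfile]
    base: SimulationConfig


def _seed_of(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31))


def build_cohort(
    seed: int,
    panel_size: int = 20,
    chrom_sizes: dict[str, int] | None = None,
    total_umr: int = 20_000_000,
    loess_span: float = 0.3,
) -> CohortContext:
    """Simulate a reference cohort and fit the normalization panel.

    The genome context (GC field, artifact vectors, unmappable bins) is
    shared by the panel and by every test sample drawn against it, as it
    would be for samples processed on one platform.
    """
    ss = np.random.SeedSequence(seed)
    s_genome, s_panel = ss.spawn(2)
    genome = simulate_genome(chrom_sizes, seed=np.random.default_rng(s_genome))
    base = SimulationConfig(total_umr=total_umr, seed=_seed_of(s_panel), genome=genome)
    panel_raw = simulate_panel(panel_size, base)
    panel_gc = [loess_gc_correct(p, span=loess_span) for p in panel_raw]
    panel = fit_reference_panel(panel_gc)
    return CohortContext(genome=genome, panel=panel, panel_raw=panel_raw, base=base)


def spiked_cnv_study(
    ctx: CohortContext,
    n_samples: int,
    size_range_bp: tuple[float, float],
    ff_range: tuple[float, float],
    carrier: str = "fetal",
    copy_delta: int | None = None,
    params: PipelineParams | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate ``n_samples`` pregnancies, one spiked CNV each, and call them.

    CNV sizes are drawn log-uniformly from ``size_range_bp`` and fetal
    fractions uniformly from ``ff_range``; the CNV lands at a uniform
    position on a random autosome (2 Mb away from ends), with a random
    direction unless ``copy_delta`` is fixed.  A spike counts as detected
    when a call of matching direction overlaps at least half of it; the
    matched call's CNV fraction and its relative difference from the true
    fetal fraction are recorded.
    """
    params = params or PipelineParams()
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    rows = []
    for i in range(n_samples):
        lo, hi = size_range_bp
        size = int(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        ff = float(rng.uniform(*ff_range))
        spec = random_cnv_spec(ctx.genome.binning, size, rng, carrier=carrier, copy_delta=copy_delta)
        cfg = SimulationConfig(
            total_umr=ctx.base.total_umr,
            ff=ff,
            fetal_sex="XX",
            gc_bias=ctx.base.gc_bias,
            artifact_loading_sd=ctx.base.artifact_loading_sd,
            noise=ctx.base.noise,
            cnvs=[spec],
            y_background=ctx.base.y_background,
            seed=int(rng.integers(0, 2**31 - 1)),
            genome=ctx.genome,
        )
        raw, manifest = simulate_sample(cfg)
        result = run_sample(raw, ctx.panel, params, ff=ff)
        matched = [c for c in result.calls if _call_matches(c, spec)]
        ffcnv = max((c.cnv_fraction for c in matched), default=np.nan)
        rows.append(
            {
                "sample": i,
                "chrom": spec.chrom,
                "size_bp": size,
                "ff": ff,
                "carrier": carrier,
                "copy_delta": spec.copy_delta,
                "direction": spec.direction,
                "expected_ratio": manifest["cnvs"][0]["expected_ratio"],
                "n_calls": len(result.calls),
                "detected": bool(matched),
                "ffcnv": ffcnv,
                "rel_diff_vs_ff": abs(ffcnv - ff) / ff if matched else np.nan,
            }
        )
    return pd.DataFrame(rows)


def specificity_study(
    ctx: CohortContext,
    n_samples: int,
    params: PipelineParams | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """CNV-free genomes through the full pipeline; one row per sample with
    its call count (the paper-level expectation is zero everywhere)."""
    params = params or PipelineParams()
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    rows = []
    for i in range(n_samples):
        cfg = SimulationConfig(
            total_umr=ctx.base.total_umr,
            ff=float(rng.uniform(0.07, 0.30)),
            fetal_sex="XX",
            gc_bias=ctx.base.gc_bias,
            artifact_loading_sd=ctx.base.artifact_loading_sd,
            noise=ctx.base.noise,
            y_background=ctx.base.y_background,
            seed=int(rng.integers(0, 2**31 - 1)),
            genome=ctx.genome,
        )
        raw, _ = simulate_sample(cfg)
        result = run_sample(raw, ctx.panel, params, ff=cfg.ff)
        rows.append({"sample": i, "n_calls": len(result.calls)})
    return pd.DataFrame(rows)


def ff_recovery_study(
    genome: SimulatedGenome,
    calibration,
    true_ff: float,
    n_rep: int,
    total_umr: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Male-fetus samples at a fixed true fetal fraction; chrY estimates."""
    from .fetal_fraction import estimate_ff_chry

    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    rows = []
    for i in range(n_rep):
        cfg = SimulationConfig(
            total_umr=total_umr,
            ff=true_ff,
            fetal_sex="XY",
            seed=int(rng.integers(0, 2**31 - 1)),
            genome=genome,
        )
        raw, _ = simulate_sample(cfg)
        est = estimate_ff_chry(raw, calibration)
        rows.append({"rep": i, "ff_true": true_ff, "ff_est": est.ff, "sex_call": est.sex_call})
    return pd.DataFrame(rows)
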