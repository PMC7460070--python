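"""Fetal fraction from the chromosome-Y read share.

In a pregnancy with a male fetus the placental (fetal) cfDNA contributes
one Y chromosome per diploid genome equivalent, so the share of reads
mapping to chrY rises linearly with the fetal fraction above a small female
mismapping background.  With calibration constants f0 (background chrY
share of female-fetus pregnancies) and male_share (chrY share of a pure
adult male genome),

    ff = (y_share - f0) / slope,   clamped to [0, 1],

where slope is d(y_share)/d(ff) at ff = 0 (falling back to the chord
male_share - f0 when only the two endpoints are known).  For female
fetuses this signal is absent; an externally computed fetal
fraction must be supplied (e.g. from a combined multi-feature estimator),
and :func:`resolve_ff` refuses to silently default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .binning import BinProfile, GenomeBinning
from .errors import ConfigError, MissingFetalFractionError

#: Fetal fraction at the midpoint rule used for sex calling: a sample is
#: called XY when its chrY share exceeds both the statistical band of the
#: female background and the share expected at this (very low) ff.
SEX_CALL_MIN_FF = 0.02


@dataclass
class YCalibration:
    """Calibration of the chrY share scale.

    f0 : chrY read share of female-fetus pregnancies (mismapping background)
    sd_f0 : its across-sample standard deviation
    male_share : chrY read share of a pure adult male genome
    y_slope : d(y_share)/d(ff) at ff = 0.  The share curve is mildly convex
        (the denominator shrinks as chrX dosage falls), so the chord from f0
        to the adult-male share underestimates ff by ~2% relative; the exact
        small-ff slope removes that bias.  When absent, the chord
        (male_share - f0) is used.
    """

    f0: float
    sd_f0: float
    male_share: float
    y_slope: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.f0 < self.male_share):
            raise ConfigError("calibration requires 0 <= f0 < male_share")

    @property
    def slope(self) -> float:
        return self.y_slope if self.y_slope is not None else self.male_share - self.f0


@dataclass
class FetalFractionEstimate:
    ff: float
    method: str  # chrY | external
    y_share: float
    sex_call: str  # XX | XY


def y_share(profile: BinProfile) -> float:
    """Fraction of QC-passing reads on chromosome Y."""
    binning = profile.binning
    ymask = binning.sex_mask("Y")
    if not ymask.any():
        raise ConfigError("binning has no chrY bins")
    qc = profile.qc_mask
    total = profile.values[qc].sum()
    if total <= 0:
        raise ConfigError("profile has no QC-passing reads")
    return float(profile.values[qc & ymask].sum() / total)


def male_equivalent_y_share(binning: GenomeBinning, qc_mask: np.ndarray | None = None) -> float:
    """Analytic chrY share of an adult male genome on this binning.

    Autosomal bins carry weight 1 (two copies), X and Y bins weight 1/2
    (one copy each); the share is the Y weight over the total.
    """
    if qc_mask is None:
        qc_mask = ~binning.short_bin_mask
    auto = (binning.autosome_mask & qc_mask).sum()
    nx = (binning.sex_mask("X") & qc_mask).sum()
    ny = (binning.sex_mask("Y") & qc_mask).sum()
    if ny == 0:
        raise ConfigError("binning has no QC-passing chrY bins")
    return 0.5 * ny / (auto + 0.5 * nx + 0.5 * ny)


def calibrate_from_panel(panel_profiles: list[BinProfile]) -> YCalibration:
    """Derive f0 and its SD from female-fetus panel samples; male_share from
    the binning geometry."""
    if len(panel_profiles) < 3:
        raise ConfigError("need at least 3 female panel samples to calibrate f0")
    shares = np.array([y_share(p) for p in panel_profiles])
    binning = panel_profiles[0].binning
    qc = np.logical_and.reduce([p.qc_mask for p in panel_profiles])
    na = (binning.autosome_mask & qc).sum()
    nx = (binning.sex_mask("X") & qc).sum()
    ny = (binning.sex_mask("Y") & qc).sum()
    return YCalibration(
        f0=float(shares.mean()),
        sd_f0=float(shares.std(ddof=1)),
        male_share=male_equivalent_y_share(binning, qc),
        # exact slope of the chrY share in ff at ff = 0 (female denominator)
        y_slope=float(0.5 * ny / (na + nx)),
    )


def estimate_ff_chry(profile: BinProfile, calibration: YCalibration) -> FetalFractionEstimate:
    """Estimate fetal fraction and fetal sex from the chrY read share.

    The XY call requires the share to clear both f0 + 3*sd_f0 and the share
    expected at a minimal detectable fetal fraction; the latter keeps the
    false-XY rate negligible when the background spread is tiny.
    """
    ys = y_share(profile)
    slope = calibration.slope
    threshold = max(
        calibration.f0 + 3.0 * calibration.sd_f0,
        calibration.f0 + (SEX_CALL_MIN_FF / 2.0) * slope,
    )
    sex = "XY" if ys > threshold else "XX"
    ff = (ys - calibration.f0) / slope
    ff = float(np.clip(ff, 0.0, 1.0))
    if sex == "XX":
        ff = 0.0
    return FetalFractionEstimate(ff=ff, method="chrY", y_share=ys, sex_call=sex)


def resolve_ff(
    estimate: FetalFractionEstimate | None = None,
    external_ff: float | None = None,
) -> float:
    """Final fetal fraction: the chrY estimate for XY, an external value otherwise.

    Raises if a female-fetus sample has no externally supplied value —
    defaulting silently would corrupt every downstream origin call.
    """
    if estimate is not None and estimate.sex_call == "XY":
        return estimate.ff
    if external_ff is not None:
        if not (0 < external_ff < 1):
            raise ConfigError(f"external fetal fraction out of range: {external_ff}")
        return float(external_ff)
    raise MissingFetalFractionError(
        "no chrY-based estimate (female fetus?) and no external fetal fraction supplied"
    )
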