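"""Two-step normalization of raw bin counts.

Step one removes the dependence of bin counts on GC content with a locally
weighted regression (LOESS) of count on GC fitted over QC-passing autosomal
bins.  Step two removes recurring higher-order cohort artifacts by
projecting the sample onto the top principal components of a reference
panel of unaffected pregnancies and subtracting the reconstruction; PCA is
restricted to autosomes, sex chromosomes are only divided by the panel
baseline.

Both normalized stages obey the renormalization contract: the mean over
QC-passing autosomal bins is exactly 1 (to 1e-9).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess

from .binning import (
    BinProfile,
    GenomeBinning,
    STAGE_GC,
    STAGE_PCA,
    STAGE_RAW,
)
from .errors import FormatError, InsufficientDataError
from .genomes import normalize_chrom

logger = logging.getLogger(__name__)

DEFAULT_LOESS_SPAN = 0.3
#: Fraction of ambiguous (non-ACGT) bases above which a bin's GC is missing.
MAX_AMBIGUOUS_FRACTION = 0.10
#: Panel coefficient-of-variation quantile above which bins are masked.
QC_CV_QUANTILE = 0.99
#: Robust-SD multiple beyond which a bin is excluded from a sample's own
#: component-score fit (protects large CNVs from normalizing themselves away).
SCORE_OUTLIER_SD = 4.0
#: Cap on automatically selected principal components.
MAX_AUTO_COMPONENTS = 5


def compute_gc(binning: GenomeBinning, fasta_path: str | Path) -> np.ndarray:
    """Per-bin GC fraction from a reference FASTA.

    GC = (G+C)/(A+C+G+T); bins with more than 10% ambiguous bases are
    returned as NaN (missing).
    """
    from pyfaidx import Fasta

    fa = Fasta(str(fasta_path))
    keys = {normalize_chrom(k): k for k in fa.keys()}
    missing = [c for c in binning.chrom_names if normalize_chrom(c) not in keys]
    if missing:
        raise FormatError(f"chromosomes missing from FASTA: {', '.join(missing)}")
    gc = np.full(binning.n_bins, np.nan)
    for name in binning.chrom_names:
        sl = binning.chrom_slice(name)
        seq = str(fa[keys[normalize_chrom(name)]][:]).upper()
        for i in range(sl.start, sl.stop):
            sub = seq[binning.start[i] : binning.end[i]]
            n_len = len(sub)
            if n_len == 0:
                continue
            a, c, g, t = sub.count("A"), sub.count("C"), sub.count("G"), sub.count("T")
            acgt = a + c + g + t
            if acgt < (1.0 - MAX_AMBIGUOUS_FRACTION) * n_len:
                continue  # stays NaN
            gc[i] = (g + c) / acgt
    return gc


def loess_gc_correct(
    profile: BinProfile,
    gc: np.ndarray | None = None,
    span: float = DEFAULT_LOESS_SPAN,
) -> BinProfile:
    """LOESS-based GC correction of a raw count profile.

    A locally weighted degree-1 regression of count on GC is fitted over
    QC-passing autosomal bins; every bin's value becomes count/fitted(GC)
    and the result is rescaled to mean 1 over QC-passing autosomal bins.
    Bins with missing GC or a non-positive fitted value are masked.
    """
    if profile.stage != STAGE_RAW:
        raise ValueError(f"GC correction expects a raw profile, got {profile.stage}")
    if gc is None:
        gc = profile.gc
    if gc is None:
        raise ValueError("no GC annotation available")
    gc = np.asarray(gc, dtype=float)

    qc = profile.qc_mask & ~np.isnan(gc)
    fit_mask = qc & profile.binning.autosome_mask
    n_auto_qc = (profile.qc_mask & profile.binning.autosome_mask).sum()
    if n_auto_qc and fit_mask.sum() / n_auto_qc < 0.90:
        raise InsufficientDataError("GC known for <90% of QC-passing autosomal bins")
    if fit_mask.sum() < 100:
        raise InsufficientDataError(f"only {fit_mask.sum()} usable bins for LOESS fit")

    x = gc[fit_mask]
    y = profile.values[fit_mask]
    delta = 0.005 * (x.max() - x.min())
    fitted_grid = lowess(y, x, frac=span, it=2, delta=delta, return_sorted=True)
    gx, gy = fitted_grid[:, 0], fitted_grid[:, 1]
    # evaluate the curve at every bin's GC (flat extrapolation beyond range)
    fitted = np.interp(gc, gx, gy, left=gy[0], right=gy[-1])

    values = np.full(profile.values.shape, np.nan)
    good = ~np.isnan(gc) & (fitted > 0)
    bad_fit = ~np.isnan(gc) & (fitted <= 0)
    if bad_fit.any():
        logger.warning("%d bins had non-positive fitted GC level; masked", int(bad_fit.sum()))
    values[good] = profile.values[good] / fitted[good]
    qc = qc & good
    values[~good] = 0.0

    out = BinProfile(
        binning=profile.binning,
        values=values,
        qc_mask=qc,
        total_umr=profile.total_umr,
        stage=STAGE_GC,
        gc=gc.copy(),
    )
    out.renormalize()
    return out


@dataclass
class ReferencePanel:
    """Fitted normalization state learned from unaffected pregnancies.

    ``components`` (k x m) and ``pca_mean`` (m) live on the QC-passing
    autosomal bin subset indexed by ``autosomal_qc_idx``; ``baseline`` is
    the panel mean level for every bin.
    """

    binning: GenomeBinning
    qc_mask: np.ndarray
    baseline: np.ndarray
    autosomal_qc_idx: np.ndarray
    components: np.ndarray
    pca_mean: np.ndarray
    n_samples: int
    component_variances: np.ndarray

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    def save(self, path: str | Path) -> None:
        """Serialize to a single .npz archive with a JSON metadata manifest."""
        meta = {
            "chrom_names": list(self.binning.chrom_names),
            "chrom_lengths": [int(x) for x in self.binning.chrom_lengths],
            "bin_width": self.binning.bin_width,
            "n_samples": self.n_samples,
        }
        np.savez_compressed(
            path,
            manifest=np.array(json.dumps(meta)),
            qc_mask=self.qc_mask,
            baseline=self.baseline,
            autosomal_qc_idx=self.autosomal_qc_idx,
            components=self.components,
            pca_mean=self.pca_mean,
            component_variances=self.component_variances,
        )

    @classmethod
    def load(cls, path: str | Path) -> "ReferencePanel":
        from .binning import make_binning

        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["manifest"]))
            binning = make_binning(
                list(zip(meta["chrom_names"], meta["chrom_lengths"])), meta["bin_width"], keep_all_contigs=True
            )
            return cls(
                binning=binning,
                qc_mask=z["qc_mask"],
                baseline=z["baseline"],
                autosomal_qc_idx=z["autosomal_qc_idx"],
                components=z["components"],
                pca_mean=z["pca_mean"],
                n_samples=int(meta["n_samples"]),
                component_variances=z["component_variances"],
            )


def fit_reference_panel(
    panel_profiles: list[BinProfile],
    n_components: int | str = "auto",
    cv_quantile: float = QC_CV_QUANTILE,
) -> ReferencePanel:
    """Learn baseline, QC mask and principal artifact components from a panel.

    The QC mask excludes short terminal bins, bins any panel member masked
    (missing GC, zero fitted level), bins with zero median level across the
    panel, and bins whose across-panel coefficient of variation exceeds the
    ``cv_quantile`` quantile.  Components are fitted on the panel's
    QC-passing autosomal bins after per-bin baseline division and
    mean-centering.

    ``n_components="auto"`` keeps components whose panel variance exceeds
    twice the median eigenvalue (a Marchenko-Pastur-style noise estimate),
    capped at 5.
    """
    if not panel_profiles:
        raise ValueError("empty panel")
    binning = panel_profiles[0].binning
    for p in panel_profiles[1:]:
        if not p.binning.compatible_with(binning):
            raise FormatError("panel profiles do not share one binning")
    for p in panel_profiles:
        if p.stage != STAGE_GC:
            raise ValueError("panel profiles must be GC-corrected")
    n = len(panel_profiles)
    k_req = None if n_components == "auto" else int(n_components)
    if k_req is not None and k_req >= n:
        raise ValueError(f"n_components={k_req} must be < panel size {n}")
    if n < max(8, (k_req or 0) + 1):
        raise ValueError(f"panel of {n} samples is too small")

    V = np.stack([p.values for p in panel_profiles])  # (n, bins)
    qc = ~binning.short_bin_mask
    for p in panel_profiles:
        qc &= p.qc_mask
    med = np.median(V, axis=0)
    qc &= med > 0
    mean = V.mean(axis=0)
    sd = V.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = np.where(mean > 0, sd / mean, np.inf)
    auto = binning.autosome_mask
    cand = qc & auto
    if cand.sum() < 100:
        raise InsufficientDataError("fewer than 100 QC-passing autosomal bins in panel")
    thr = np.quantile(cv[cand], cv_quantile)
    qc &= ~(cv > thr)

    baseline = V.mean(axis=0)
    idx = np.flatnonzero(qc & auto)
    R = V[:, idx] / baseline[idx]
    pca_mean = R.mean(axis=0)
    C = R - pca_mean

    # principal directions of the centered panel (rows of Vt are orthonormal)
    _, svals, Vt = np.linalg.svd(C, full_matrices=False)
    eig = svals**2 / max(n - 1, 1)
    if k_req is None:
        if eig.size == 0 or eig.max() <= 0:
            k = 0
        else:
            noise = 2.0 * np.median(eig)
            k = int(min(MAX_AUTO_COMPONENTS, n - 1, np.sum(eig > max(noise, 1e-18))))
    else:
        k = k_req
    components = Vt[:k]
    return ReferencePanel(
        binning=binning,
        qc_mask=qc,
        baseline=baseline,
        autosomal_qc_idx=idx,
        components=components,
        pca_mean=pca_mean,
        n_samples=n,
        component_variances=eig[:k] if k else np.zeros(0),
    )


def pca_normalize(profile: BinProfile, panel: ReferencePanel) -> BinProfile:
    """Remove panel artifact components from a GC-corrected profile.

    Over QC-passing autosomal bins the value is divided by the panel
    baseline, the sample's projection onto the panel's top components is
    subtracted, and the result is rescaled to mean 1.  Non-autosomal bins
    are divided by baseline only.

    Bins deviating more than 4 robust SD from baseline are excluded from
    the score fit so large (maternal-scale) CNVs do not corrupt their own
    normalization; fetal-scale CNVs sit within the noise band, but their
    leverage on the global score fit is proportional to the fraction of
    bins they cover and is negligible at genome scale.
    """
    if not profile.binning.compatible_with(panel.binning):
        raise FormatError("profile and panel binning mismatch")
    if profile.stage not in (STAGE_GC, STAGE_PCA):
        raise ValueError(f"PCA normalization expects a GC-corrected profile, got {profile.stage}")

    values = profile.values.astype(float).copy()
    qc = profile.qc_mask & panel.qc_mask
    # an already-normalized profile has the baseline divided out and the
    # artifact projection removed; reapplying is a rescale-only no-op
    first_pass = profile.stage == STAGE_GC

    if first_pass:
        with np.errstate(invalid="ignore", divide="ignore"):
            ratio = np.where(panel.baseline > 0, values / panel.baseline, 0.0)
        qc &= panel.baseline > 0
        values = ratio

    idx = panel.autosomal_qc_idx
    if panel.n_components > 0 and first_pass:
        r = values[idx]
        c = r - panel.pca_mean
        med = np.median(c)
        rsd = 1.4826 * np.median(np.abs(c - med))
        include = np.abs(c - med) <= SCORE_OUTLIER_SD * max(rsd, 1e-12)
        # remove the include-set mean before fitting: a constant offset is
        # handled by the final rescaling, and keeping it out of the score
        # fit makes repeated normalization a fixed point
        c = c - c[include].mean()
        Vt = panel.components
        Vi = Vt[:, include]
        gram = Vi @ Vi.T
        scores = np.linalg.solve(gram + 1e-12 * np.eye(Vt.shape[0]), Vi @ c[include])
        values[idx] = r - scores @ Vt

    out = BinProfile(
        binning=profile.binning,
        values=values,
        qc_mask=qc,
        total_umr=profile.total_umr,
        stage=STAGE_PCA,
        gc=None if profile.gc is None else profile.gc.copy(),
    )
    out.renormalize()
    return out
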