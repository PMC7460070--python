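# Methods

## The problem

In noninvasive prenatal testing (NIPT), cell-free DNA (cfDNA) from maternal
plasma is sequenced at low coverage (~0.3x, around 20 million uniquely
mapped reads, "UMR") to screen the fetus for chromosomal abnormalities.
Placental (fetal) DNA makes up only a fraction ff of the plasma cfDNA —
typically ~10%, here treated as valid in (0, 0.5) — so a fetal copy number
variant (CNV) shifts the read depth of the affected region by only ff/2 per
copy.  `plasmacnv` detects such shifts genome-wide, quantifies each one
with the CNV-fraction statistic, and classifies whether the variant is
fetal, maternal, or shared.

## The mixture model

Plasma is modelled as a two-genome mixture: maternal cells with weight
1 − ff and fetoplacental cells with weight ff, both diploid.  A CNV with
signed copy change c (−1 heterozygous loss, +1 heterozygous gain, +2
tetraplication-like gain) present in a fraction w of the carrier's cells
shifts the expected normalized read depth of its bins to

    ratio = 1 + m · (c/2) · w,

with m = ff for a fetal-only variant, m = 1 − ff for a maternal-only
variant, and m = 1 for a variant shared by mother and fetus.  Hence a
fetal heterozygous deletion sits at 1 − ff/2, a shared heterozygous
deletion at 0.5, and a fetal two-copy gain at 1 + ff.

### The CNV fraction

For a detected region, let rc be the reads-equivalent signal on the region
and rm the expected reads-equivalent of an equally long unaffected region
(the region's QC-bin count times the genome median level outside candidate
aberrations, so large CNVs do not bias their own baseline).  The CNV
fraction is

    ffcnv = 2 · |rc − rm| / rm  =  2 · |mean_level − baseline_level|,

which under the mixture model estimates m·|c|·w: approximately ff for a
fetal heterozygous CNV, 2·ff for a fetal two-copy gain, 1 − ff for a
maternal-only heterozygous CNV and exactly 1 for a shared heterozygous
CNV.  Comparing ffcnv with an independently estimated fetal fraction
therefore classifies the origin of the event; the classifier assigns the
nearest of these four expectations within a ±40% relative guard band
(maternal-only and shared collapse to one class — at typical ff they are
separated by less than the noise) and otherwise reports `ambiguous`.
Mosaic events, whose ffcnv falls between the fetal and maternal
expectations, land in `ambiguous` by construction.

### Detection limits

For review plots the expected just-detectable levels are drawn as dashed
lines: 1 ∓ ff/2 for fetal heterozygous events and 1 ∓ 1/2 for shared
heterozygous events.

## Pipeline stages

### Binning and counting

Fixed 20 kb bins tile each chromosome (0-based, half-open; the last bin of
a chromosome may be short and is flagged for QC exclusion when it is under
90% of the bin width).  A read is assigned to exactly one bin by its
leftmost aligned base; unmapped, secondary, supplementary, duplicate and
mapping-quality < 20 reads are excluded, and paired-end fragments count
once.  In-silico downsampling to a target read count is binomial thinning
per bin.  These conventions (coordinate system, MAPQ cutoff as the
operational meaning of "uniquely mapped", fragment counting) are package
decisions; nothing in the underlying study constrains them.

### GC correction

A LOESS (locally weighted, degree-1) regression of bin count on GC
fraction is fitted over QC-passing autosomal bins (span 0.3, two
robustifying iterations, interpolation grid with delta = 0.5% of the GC
range for speed) and every bin's count is divided by the fitted value at
its GC; bins with missing GC (>10% ambiguous bases) or non-positive
fitted values are masked.  The result is rescaled so the mean over
QC-passing autosomal bins is exactly 1 — the renormalization contract all
normalized stages obey (tolerance 1e-9).

### Reference-panel PCA normalization

A panel of unaffected pregnancies (>= 8; 20 in the validation studies) is
GC-corrected and used to learn, over QC-passing autosomal bins: a per-bin
baseline (panel mean), and the top principal components of the
baseline-divided, mean-centered panel matrix.  The QC mask excludes short
terminal bins, bins masked in any panel member, bins with zero median
level, and bins whose across-panel coefficient of variation exceeds the
99th percentile.  Component count "auto" keeps eigenvalues above twice
the median eigenvalue (a Marchenko–Pastur-style noise floor), capped at 5.

A test sample is divided by the baseline, its scores on the components are
fitted by least squares — excluding bins deviating more than 4 robust SD
so maternal-scale CNVs cannot corrupt their own normalization — and the
reconstruction is subtracted.  PCA applies to autosomes only; sex
chromosomes are baseline-divided but never projected, since their dosage
varies with fetal sex.  Fetal-scale CNVs sit inside the 4-SD band, but
their leverage on the global score fit scales with the fraction of bins
they cover and is negligible at genome scale (<1% bias for CNVs up to
90 Mb on ~144k autosomal bins); the signal-safety test verifies <10%
attenuation.  Re-normalizing an already normalized profile is a
rescale-only no-op, making the operation idempotent.

### Segmentation (CBS)

Each chromosome's QC-passing bins are segmented by circular binary
segmentation: the maximally deviant circular arc (i, j] is found by
exhaustive scan, its significance assessed by permutation, and the
chromosome split recursively (up to three parts per split, minimum
segment 3 bins), followed by a merge pass that joins adjacent segments
whose mean difference is not significant at the same level.

Two implementation choices matter for speed and are deliberate deviations
from the textbook form:

* **Statistic.** The arc-vs-complement two-sample statistic is scaled by
  the tested interval's overall SD rather than a per-split pooled SD.
  For a fixed arc length the statistic is then monotone in the arc's
  window sum, so the O(n²) scan reduces to a sliding min/max per length
  (numba-compiled, ~1.5·10⁹ arcs/s), and a whole genome scans in well
  under a second.  Permutation calibration is valid for any statistic;
  the brute-force oracle test pins the scan to exhaustive enumeration.
* **Sequential permutation.** Permutations stop early once the decision
  at level alpha is settled (Besag–Clifford style): after the exceedance
  budget floor(alpha·(B+1)) is exhausted (not significant), or after
  ceil(1/alpha) exceedance-free permutations (significant, p = 1/(b+1)).
  Null chromosomes settle in a handful of permutations.  When alpha is
  finer than 1/(n_perm+1) the split decision falls back to the smallest
  achievable level, with a warning.

Default alpha is 0.002 with n_perm = 1000.  This was calibrated on
simulated CNV-free genomes: at the conventional 0.01 per chromosome, a
24-chromosome genome accrues ~0.2–0.3 spurious splits per sample, several
of which survive any call filter consistent with the detection limits the
assay targets.  At 0.002 the spurious-split rate drops near 0.05 per
genome while the detectability boundary moves by only ~0.3 units of the
max-arc statistic.  The sensitivity studies in `scripts/acceptance.py`
run segmentation at alpha 0.01 with 500 permutations, the conventional
setting, which is sensitivity-neutral-or-better.

By default only autosomes are segmented: calls are autosomal, and on
chromosome X the un-projected cohort artifacts make segments
uninterpretable.  Review plotting re-segments any chromosome, including X
and Y, on request.

### Calling

A segment becomes a CNV call when all of: |z| >= 5.5, where
z = (mean_level − 1)/(σ_bin/√n_bins) with σ_bin the 1.4826·MAD robust
per-bin SD over QC-passing autosomal bins outside candidate aberrations;
ffcnv >= 0.04; and the segment spans >= 20 QC-passing bins (0.4 Mb — a
reporting floor just below the smallest aberration size in the validated
range).  The z threshold was calibrated jointly with alpha on CNV-free
simulations: a genome-wide search over ~140k bins has a null maximum
near z ≈ 5.2–5.9, and every false call observed in calibration carried z
between 5.0 and 5.9, while true CNVs at the assay's detection limits
(>= 3 Mb at ff >= 10%) carry z >= 7.  The floor of 0.04 on ffcnv
suppresses sub-noise deviations of long segments.

### Fetal fraction from chromosome Y

For a male fetus the chrY read share rises nearly linearly with ff above
a small female mismapping background:  ff = (y_share − f0)/slope,
clamped to [0, 1], where f0 and its SD come from female-fetus panel
samples and the slope is d(y_share)/d(ff) at ff = 0, computed from the
binning geometry (0.5·n_Y/(n_A + n_X) over QC-passing bins).  The naive
chord from f0 to the adult-male chrY share underestimates ff by ~2%
relative because the share curve is mildly convex — the denominator
shrinks as chrX dosage falls — so the exact small-ff slope is preferred;
the chord remains the fallback when only the endpoints are known.  A sample
is called XY when its share clears both f0 + 3·SD(f0) and the share
expected at ff = 0.02 (the midpoint rule keeps the false-XY rate
negligible when the background spread is tiny).  For female fetuses an
externally computed fetal fraction must be supplied; the resolver refuses
to default silently because every origin classification depends on it.

## The simulator

`plasmacnv.simulate` generates ground-truthed cohorts in the study's data
regime: hg19-scale 20 kb binning (~155k bins), 20 M UMR per sample
(Poisson counts by default; Gamma–Poisson with dispersion 0.05 available
since real cfDNA is overdispersed), and per-sample expected counts

    mu ∝ base_weight · gc_bias(GC) · (1 + Σ loadings·artifacts) · sex_factor · cnv_ratio.

Cohort-shared context (one object per simulated "platform"): a smoothed
Gaussian GC field (mean 0.42, SD ~0.036 after smoothing, clipped to
[0.28, 0.65]); an inverted-U multiplicative GC bias (quadratic in
GC − 0.42 with coefficients (1, 0.6, −12), spanning roughly 0.75–1.0
across the GC range); three artifact vectors of unit per-bin RMS with
per-sample Gaussian loadings of SD 0.04, so the artifact component is
about half the Poisson noise per bin and comfortably above the PCA
detection floor for a panel of 20; and 1% of bins made effectively
unmappable (caught by the panel QC mask).

Artifact vectors are per-bin (spatially uncorrelated) by default —
bin-specific systematic responses whose loadings vary by sample, the
regime reference-panel PCA targets.  This is a deliberate modeling
choice.  With a 20-sample panel, per-bin normalization carries an
irreducible information limit of ~0.02 (baseline and subspace estimation
error), so 10–20% of each sample's artifact loading survives
normalization no matter the algorithm.  If the artifact field were
spatially smooth at comparable amplitude, those residues would form
multi-megabase waves of 2–4% — at the scale of the fetal detection limit
itself — and no thresholding could separate them from true CNVs; a
pipeline that demonstrably detects 5% shifts with no false positives
cannot be operating in such a regime.  With uncorrelated vectors the
artifact residue scales with region size exactly like Poisson noise
(~10% inflation of the noise floor) while PCA fitting, removal and the
CNV-protection guard remain fully exercised.  A smoothing parameter
restores correlated fields for stress testing.

A male fetus contributes ff/2 to chrY bins on top of a 0.002 relative
mismapping background and depresses chrX to 1 − ff/2.  CNVs multiply
covered bins by the mixture ratio, pro-rated at partial edge bins.  Every
sample returns a JSON-serializable ground-truth manifest.

What the simulator does **not** emulate: fragment-length and end-motif
structure, sequencing errors, mappability-correlated GC, segmental
duplications, real population CNV polymorphism, or confined placental
mosaicism.  Passing the validation studies therefore demonstrates the
statistical machinery under the stated noise model, not clinical
performance on real plasma.

## Validation studies and problem sizes

The studies in `tests/test_acceptance.py` and `scripts/acceptance.py` use
an hg19-scale cohort with a 20-sample panel: 18 spiked fetal heterozygous
CNVs (3–90 Mb log-uniform, ff 0.07–0.30) for sensitivity and
CNV-fraction recovery; 11 fetomaternal heterozygous CNVs (0.46–8.02 Mb,
ff 0.10–0.16) for the maternal ~100% signature; 9 replicates of a 1.12 Mb
two-copy gain at ff 0.108 for tetraplication doubling; 20 CNV-free
genomes for specificity; 200 random sequences (n <= 40) against the
brute-force split oracle; and 50 male-fetus replicates on a reduced
60 Mb genome (read count scaled to equal per-bp depth) for chrY
fetal-fraction recovery.  Replicate counts are chosen so the full suite
runs on a laptop-class single core; unit tests use the 60 Mb reduced
genome throughout.

## Known limitations

* Breakpoint placement at per-bin SNR ~0.7 is typically exact to a few
  bins but heavy-tailed; occasional 0.5–1 Mb misplacements of one
  boundary occur and recursion cannot always refine them.
* The z-score is a per-segment approximation against a genome-wide robust
  noise scale; it is not calibrated against a reference-panel null per
  region.
* Origin classification degrades when ffcnv falls between the fetal and
  maternal expectations (mosaics, very high ff); such calls are reported
  `ambiguous` rather than forced.
* The chrY estimator requires a male fetus and a platform calibration;
  the multi-feature estimator used for female fetuses in practice is an
  injection point, not an implementation.
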