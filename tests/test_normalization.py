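"""GC computation, LOESS correction, panel fitting and PCA normalization."""

import numpy as np
import pytest

from plasmacnv.binning import BinProfile, default_qc_mask, make_binning
from plasmacnv.errors import FormatError
from plasmacnv.normalization import (
    ReferencePanel,
    compute_gc,
    fit_reference_panel,
    loess_gc_correct,
    pca_normalize,
)
from plasmacnv.simulate import CNVSpec, simulate_sample

from conftest import toy_config


class TestComputeGC:
    @pytest.fixture()
    def fasta(self, tmp_path):
        # 3 bins of 100 bp: all G | ACGT repeats | half N
        seq = "G" * 100 + "ACGT" * 25 + "N" * 50 + "A" * 50
        f = tmp_path / "ref.fa"
        f.write_text(">chr1\n" + "\n".join(seq[i : i + 60] for i in range(0, len(seq), 60)) + "\n")
        return f

    def test_gc_values_and_ambiguity_rule(self, fasta):
        b = make_binning({"chr1": 300}, 100)
        gc = compute_gc(b, fasta)
        assert gc[0] == 1.0
        assert gc[1] == 0.5
        assert np.isnan(gc[2])  # 50% N > 10% ambiguity cutoff

    def test_missing_chromosome_listed(self, fasta):
        b = make_binning({"chr1": 300, "chr2": 300}, 100)
        with pytest.raises(FormatError, match="chr2"):
            compute_gc(b, fasta)


class TestLoessCorrection:
    def test_flat_counts_give_unit_values(self):
        b = make_binning({"chr1": 20_000 * 600}, 20_000)
        rng = np.random.default_rng(0)
        gc = rng.uniform(0.3, 0.6, b.n_bins)
        prof = BinProfile(b, np.full(b.n_bins, 100), default_qc_mask(b), 100 * b.n_bins, gc=gc)
        out = loess_gc_correct(prof)
        assert np.allclose(out.values[out.qc_mask], 1.0, atol=1e-6)

    def test_quadratic_gc_bias_removed(self, toy_genome_shared):
        cfg = toy_config(toy_genome_shared, ff=0.15, fetal_sex="XX", seed=13,
                         artifact_loading_sd=0.0)
        raw, _ = simulate_sample(cfg)  # default quadratic gc_bias
        out = loess_gc_correct(raw)
        m = out.autosomal_qc
        r = np.corrcoef(out.values[m], out.gc[m])[0, 1]
        raw_r = np.corrcoef(raw.values[m], raw.gc[m])[0, 1]
        assert abs(raw_r) > 0.1  # the injected bias is visible above noise...
        assert abs(r) < 0.05  # ...and the correction removes it

    def test_spiked_deletion_survives_correction(self, toy_genome_shared):
        # deep coverage so the 0.005 tolerance probes LOESS bias, not
        # counting noise (per-bin SE ~0.002 at 10x the survey depth)
        from conftest import TOY_UMR

        spec = CNVSpec("chr1", 8_000_000, 13_000_000, "fetal", -1)
        cfg = toy_config(toy_genome_shared, ff=0.10, cnvs=[spec], seed=14,
                         artifact_loading_sd=0.0, total_umr=10 * TOY_UMR)
        raw, manifest = simulate_sample(cfg)
        out = loess_gc_correct(raw)
        b = out.binning
        sl = b.chrom_slice("chr1")
        inside = np.zeros(b.n_bins, bool)
        inside[sl] = (b.start[sl] >= spec.start) & (b.end[sl] <= spec.end)
        inside &= out.qc_mask
        outside = out.autosomal_qc & ~inside
        ratio = out.values[inside].mean() / out.values[outside].mean()
        assert ratio == pytest.approx(0.95, abs=0.005)

    def test_renormalization_contract(self, toy_panel_gc):
        for p in toy_panel_gc:
            assert p.values[p.autosomal_qc].mean() == pytest.approx(1.0, abs=1e-9)

    def test_raw_stage_required(self, toy_panel_gc):
        with pytest.raises(ValueError):
            loess_gc_correct(toy_panel_gc[0])


def _flat_gc_profiles(n, n_bins=3000, seed=0, noise=0.0, extra=None):
    """Panel of unit-level gc_corrected profiles on a one-chromosome binning."""
    b = make_binning({"chr1": 20_000 * n_bins}, 20_000)
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        v = np.ones(b.n_bins)
        if noise:
            v = v + rng.normal(0, noise, b.n_bins)
        if extra is not None:
            v = v + extra(i, rng)
        prof = BinProfile(b, v, default_qc_mask(b), 0, stage="gc_corrected",
                          gc=np.full(b.n_bins, 0.4))
        prof.renormalize()
        out.append(prof)
    return out


class TestFitReferencePanel:
    def test_identical_panel_degenerates_to_baseline_division(self):
        panel = fit_reference_panel(_flat_gc_profiles(8))
        assert panel.n_components == 0
        assert np.allclose(panel.baseline[panel.qc_mask], 1.0)

    def test_planted_artifacts_recovered(self):
        rng0 = np.random.default_rng(99)
        n_bins = 3000
        v1 = rng0.normal(0, 1, n_bins)
        v2 = rng0.normal(0, 1, n_bins)
        v1 /= np.sqrt((v1**2).mean())
        v2 /= np.sqrt((v2**2).mean())

        def extra(i, rng):
            return rng.normal(0, 0.1) * v1 + rng.normal(0, 0.1) * v2

        panel = fit_reference_panel(_flat_gc_profiles(20, n_bins, seed=1, noise=0.01, extra=extra))
        assert panel.n_components == 2
        # principal angle between fitted and planted subspaces < 5 degrees
        planted = np.stack([v1, v2])[:, panel.autosomal_qc_idx]
        q_p, _ = np.linalg.qr(planted.T)
        q_f, _ = np.linalg.qr(panel.components.T)
        sv = np.linalg.svd(q_p.T @ q_f, compute_uv=False)
        angle = np.degrees(np.arccos(np.clip(sv.min(), -1, 1)))
        assert angle < 5

    def test_auto_selects_zero_components_on_white_noise(self):
        panel = fit_reference_panel(_flat_gc_profiles(12, seed=2, noise=0.05))
        assert panel.n_components == 0

    def test_too_many_components_rejected(self):
        with pytest.raises(ValueError):
            fit_reference_panel(_flat_gc_profiles(8), n_components=8)

    def test_small_panel_rejected(self):
        with pytest.raises(ValueError):
            fit_reference_panel(_flat_gc_profiles(4))

    def test_heterogeneous_binning_rejected(self):
        a = _flat_gc_profiles(8)
        b = _flat_gc_profiles(8, n_bins=2999)
        with pytest.raises(FormatError):
            fit_reference_panel(a[:4] + b[:4])

    def test_zero_median_bins_masked(self, toy_panel, toy_panel_raw):
        V = np.stack([p.values for p in toy_panel_raw])
        dead = np.median(V, axis=0) == 0
        assert not (toy_panel.qc_mask & dead).any()

    def test_panel_round_trips_through_archive(self, toy_panel, tmp_path):
        f = tmp_path / "panel.npz"
        toy_panel.save(f)
        back = ReferencePanel.load(f)
        assert back.binning.compatible_with(toy_panel.binning)
        for attr in ("qc_mask", "baseline", "autosomal_qc_idx", "components", "pca_mean"):
            assert np.array_equal(getattr(back, attr), getattr(toy_panel, attr))
        assert back.n_samples == toy_panel.n_samples

    def test_components_orthonormal(self, toy_panel):
        if toy_panel.n_components:
            g = toy_panel.components @ toy_panel.components.T
            assert np.allclose(g, np.eye(toy_panel.n_components), atol=1e-8)


class TestPcaNormalize:
    def test_zero_components_is_baseline_division(self):
        profiles = _flat_gc_profiles(8, seed=3, noise=0.02)
        panel = fit_reference_panel(profiles, n_components=0)
        out = pca_normalize(profiles[0], panel)
        manual = profiles[0].values / panel.baseline
        manual /= manual[out.autosomal_qc].mean()
        assert np.allclose(out.values[out.qc_mask], manual[out.qc_mask], atol=1e-12)

    def test_flat_profile_equal_to_baseline_gives_ones(self):
        profiles = _flat_gc_profiles(8)
        panel = fit_reference_panel(profiles)
        out = pca_normalize(profiles[0], panel)
        assert np.allclose(out.values[out.qc_mask], 1.0)

    def test_artifact_removal_spares_spiked_duplication(self):
        # deep-coverage sample sharing the panel's artifact vectors, with a
        # spiked duplication covering ~1.5% of autosomal bins.  Unsmoothed
        # artifact vectors keep the toy genome in the regime where CNV
        # leverage on the score fit is provably small; spatially smooth
        # artifacts at full genome scale behave the same (coverage fraction
        # ~10x lower).
        from conftest import TOY_UMR, TOY_SIZES

        from plasmacnv.simulate import SimulationConfig, simulate_genome, simulate_panel

        genome = simulate_genome(TOY_SIZES, seed=311, artifact_smoothing=1)
        base = SimulationConfig(total_umr=TOY_UMR, seed=312, genome=genome, artifact_loading_sd=0.08)
        panel = fit_reference_panel([loess_gc_correct(p) for p in simulate_panel(12, base)])
        assert panel.n_components == 3

        spec = CNVSpec("chr1", 6_000_000, 6_800_000, "fetal", 1)
        cfg = toy_config(
            genome, ff=0.25, cnvs=[spec], seed=55, total_umr=20 * TOY_UMR, artifact_loading_sd=0.08
        )
        raw, manifest = simulate_sample(cfg)
        corr = loess_gc_correct(raw)
        out = pca_normalize(corr, panel)

        b = out.binning
        sl = b.chrom_slice("chr1")
        inside = np.zeros(b.n_bins, bool)
        inside[sl] = (b.start[sl] >= spec.start) & (b.end[sl] <= spec.end)
        outside_auto = out.autosomal_qc & ~inside
        inside &= out.qc_mask

        var_before = corr.values[corr.autosomal_qc & ~inside].var()
        var_after = out.values[outside_auto].var()
        assert var_after < 0.5 * var_before  # artifacts dominate and are removed

        dev_expected = manifest["cnvs"][0]["expected_ratio"] - 1.0
        dev_after = out.values[inside].mean() / out.values[outside_auto].mean() - 1.0
        # the spike's deviation survives normalization to within 10% relative
        assert abs(dev_after - dev_expected) / abs(dev_expected) < 0.10

    def test_renormalization_contract(self, toy_panel, toy_panel_gc):
        out = pca_normalize(toy_panel_gc[0], toy_panel)
        assert out.values[out.autosomal_qc].mean() == pytest.approx(1.0, abs=1e-9)

    def test_idempotent_within_tolerance(self, toy_panel, toy_panel_gc):
        once = pca_normalize(toy_panel_gc[1], toy_panel)
        twice = pca_normalize(once, toy_panel)
        assert np.allclose(twice.values[twice.qc_mask], once.values[twice.qc_mask], atol=1e-6)

    def test_binning_mismatch_rejected(self, toy_panel):
        other = _flat_gc_profiles(1, n_bins=100)[0]
        with pytest.raises(FormatError):
            pca_normalize(other, toy_panel)
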