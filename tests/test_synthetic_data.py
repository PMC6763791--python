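"""The generator must reproduce the statistical structure the analysis assumes."""

import math

import numpy as np
import pytest
from scipy import stats

from baitcall.errors import ConfigurationError, GenerationError
from baitcall.synthetic_data import (
    SimConfig,
    generate_apms_dataset,
    generate_image_pair,
    generate_scaffold_with_peptides,
    generate_sequences,
)


class TestApmsGenerator:
    def test_exclusive_only(self):
        cfg = SimConfig(n_background=0, n_interactors=0, n_exclusive=1, seed=0)
        table, truth = generate_apms_dataset(cfg)
        assert table.n_proteins == 1
        assert np.all(table.control == 0)
        assert np.all(table.bait > 0)
        assert list(truth.labels.values()) == ["exclusive"]

    def test_noise_free_limit(self):
        cfg = SimConfig(n_background=50, n_interactors=0, n_exclusive=0,
                        replicate_cv=1e-12, seed=2)
        table, _ = generate_apms_dataset(cfg)
        assert np.allclose(table.bait, table.bait[:, [0]], rtol=1e-9)
        r = stats.pearsonr(np.log(table.bait[:, 0]), np.log(table.bait[:, 1])).statistic
        assert r == pytest.approx(1.0, abs=1e-9)

    def test_background_log2_ratio_moments_match_monte_carlo(self):
        # oracle: direct Monte-Carlo of the generative model at 10x sample size
        cfg = SimConfig(n_background=2000, n_interactors=0, n_exclusive=0, seed=1)
        table, _ = generate_apms_dataset(cfg)
        lr = np.log2(table.bait.mean(axis=1) / table.control.mean(axis=1))

        rng = np.random.default_rng(999)
        s = math.sqrt(math.log1p(cfg.replicate_cv**2))
        n_mc = 20000
        noise = rng.lognormal(-0.5 * s * s, s, size=(n_mc, 2, cfg.n_replicates))
        mc = np.log2(noise[:, 0].mean(axis=1) / noise[:, 1].mean(axis=1))
        se_mean = mc.std() / math.sqrt(len(lr))
        assert abs(lr.mean() - mc.mean()) < 3 * se_mean
        # SD agreement within 3 SE of the sample SD
        se_sd = mc.std() / math.sqrt(2 * (len(lr) - 1))
        assert abs(lr.std() - mc.std()) < 3 * se_sd

    def test_interactor_expectation_scales_with_fold_change(self):
        cfg = SimConfig(n_background=0, n_interactors=400, n_exclusive=0,
                        interactor_log2_fc_range=(4.0, 4.0 + 1e-9), seed=5)
        table, truth = generate_apms_dataset(cfg)
        lr = np.log2(table.bait.mean(axis=1) / table.control.mean(axis=1))
        assert lr.mean() == pytest.approx(4.0, abs=0.1)

    def test_background_ratios_pass_normality(self):
        cfg = SimConfig(n_background=3000, n_interactors=0, n_exclusive=0, seed=11)
        table, _ = generate_apms_dataset(cfg)
        lr = np.log2(table.bait.mean(axis=1) / table.control.mean(axis=1))
        # moment-based normality check at alpha = 0.01
        assert stats.normaltest(lr).pvalue > 0.01

    def test_fixed_seed_reproducible(self):
        cfg = SimConfig(seed=42)
        t1, tr1 = generate_apms_dataset(cfg)
        t2, tr2 = generate_apms_dataset(SimConfig(seed=42))
        assert t1.equals(t2)
        assert tr1.labels == tr2.labels

    def test_nonnegative_and_peptide_range(self):
        cfg = SimConfig(seed=3, peptide_count_range=(2, 25))
        table, _ = generate_apms_dataset(cfg)
        assert np.all(table.bait >= 0) and np.all(table.control >= 0)
        assert table.meta["unique_peptides"].between(2, 25).all()

    @pytest.mark.parametrize(
        "field,value",
        [
            ("n_background", -1),
            ("n_replicates", 1),
            ("replicate_cv", 0.0),
            ("interactor_log2_fc_range", (5.0, 3.0)),
            ("peptide_count_range", (5, 2)),
        ],
    )
    def test_invalid_config_names_field(self, field, value):
        cfg = SimConfig()
        setattr(cfg, field, value)
        with pytest.raises(ConfigurationError):
            cfg.validate()


class TestSequenceGenerator:
    def test_fixed_length_and_determinism(self):
        s1 = generate_sequences(1, (50, 50), seed=7)
        s2 = generate_sequences(1, (50, 50), seed=7)
        assert s1 == s2
        assert len(next(iter(s1.values()))) == 50

    def test_kr_frequency_within_binomial_ci(self):
        seqs = generate_sequences(100, (200, 400), seed=8)
        residues = "".join(seqs.values())
        k = sum(c in "KR" for c in residues)
        n = len(residues)
        p = 2 / 20  # uniform residue distribution
        lo, hi = stats.binom.interval(0.99, n, p)
        assert lo <= k <= hi

    def test_min_length_guard(self):
        with pytest.raises(ConfigurationError):
            generate_sequences(1, (10, 50), seed=0)


class TestScaffold:
    def test_embedded_peptides_are_tryptic_fragments(self):
        from baitcall.coverage import tryptic_digest

        peps = ["AAAK", "CCDDR", "EEPK"]
        seq = generate_scaffold_with_peptides(peps, 80, seed=1)
        assert len(seq) == 80
        frags = tryptic_digest(seq)
        for p in peps:
            assert p in frags
            assert seq.count(p) == 1

    def test_too_short_raises(self):
        with pytest.raises(GenerationError):
            generate_scaffold_with_peptides(["AAAK"], 5, seed=0)

    def test_internal_cleavage_site_rejected(self):
        with pytest.raises(GenerationError):
            generate_scaffold_with_peptides(["AKAK"], 100, seed=0)


class TestImagePairGenerator:
    def test_full_overlap_identical_supports(self):
        pair, truth = generate_image_pair((20, 64, 64), n_vesicles=8,
                                          overlap_fraction=1.0, seed=1)
        assert truth == 1.0
        assert np.array_equal(pair.ch1 > 0, pair.ch2 > 0)

    def test_zero_overlap_disjoint(self):
        pair, truth = generate_image_pair((20, 64, 64), n_vesicles=8,
                                          overlap_fraction=0.0, seed=1)
        assert truth == 0.0
        assert not np.any((pair.ch1 > 0) & (pair.ch2 > 0))

    def test_half_overlap_mass_fraction(self):
        # oracle: voxel-wise summation over the known supports
        pair, truth = generate_image_pair((24, 96, 96), n_vesicles=10,
                                          overlap_fraction=0.5, seed=2)
        assert truth == 0.5
        in_ch2 = pair.ch1[pair.ch2 > 0].sum()
        assert in_ch2 / pair.ch1.sum() == pytest.approx(0.5, abs=1e-12)

    def test_shape_too_small(self):
        with pytest.raises(GenerationError):
            generate_image_pair((5, 5, 5), n_vesicles=3, overlap_fraction=0.5, seed=0)
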