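"""Histogram binning, Gaussian null fit, fraction-of-peak threshold, classes."""

import math

import numpy as np
import pytest
from scipy.optimize import brentq

from baitcall.enrichment import EnrichmentRecord
from baitcall.errors import ModelError, ParameterError
from baitcall.null_model import (
    GaussianFit,
    build_histogram,
    classify,
    derive_threshold,
    fit_gaussian,
)


def records_from(values, exclusive_accs=(), fail_floor_accs=()):
    recs = []
    for i, v in enumerate(values):
        acc = f"P{i}"
        recs.append(
            EnrichmentRecord(
                accession=acc,
                mean_bait=2000.0,
                mean_control=2000.0,
                ratio=2.0**v,
                log2_ratio=float(v),
                exclusive=False,
                passes_floor=acc not in fail_floor_accs,
            )
        )
    for j, acc in enumerate(exclusive_accs):
        recs.append(
            EnrichmentRecord(
                accession=acc, mean_bait=2000.0, mean_control=0.0,
                ratio=None, log2_ratio=None, exclusive=True, passes_floor=True,
            )
        )
    return recs


class TestBuildHistogram:
    def test_two_values_one_bin(self):
        h = build_histogram(records_from([0.05, 0.15]), bin_width=0.2)
        assert h.counts.tolist() == [2]
        assert h.bin_edges[0] == 0.0 and h.bin_edges[-1] == pytest.approx(0.2)

    def test_edge_value_goes_to_upper_bin(self):
        h = build_histogram(records_from([0.05, 0.2]), bin_width=0.2)
        assert h.counts.tolist() == [1, 1]
        # 0.2 sits in [0.2, 0.4), not [0.0, 0.2)
        assert h.bin_edges[1] == pytest.approx(0.2)

    def test_matches_numpy_binning(self):
        # oracle: independent binning with np.histogram on pre-anchored edges
        rng = np.random.default_rng(0)
        vals = rng.normal(0, 1, 10000)
        h = build_histogram(records_from(vals), bin_width=0.2)
        expected, _ = np.histogram(vals, bins=h.bin_edges)
        # np.histogram closes the last bin; our last value may differ there
        assert h.counts[:-1].tolist() == expected[:-1].tolist()
        assert h.counts.sum() == h.n_total == 10000

    def test_excludes_exclusives_and_floor_failures(self):
        recs = records_from([0.1, 0.3], exclusive_accs=("X1",), fail_floor_accs=("P0",))
        h = build_histogram(recs)
        assert h.n_total == 1

    def test_no_eligible_records(self):
        with pytest.raises(ModelError):
            build_histogram(records_from([], exclusive_accs=("X1",)))


class TestFitGaussian:
    def test_exact_curve_recovery(self):
        # counts sampled exactly from the model curve: fit is self-consistent
        edges = np.arange(-30, 31) * 0.2
        centers = 0.5 * (edges[:-1] + edges[1:])
        counts = 100.0 * np.exp(-(centers**2) / 2.0)
        from baitcall.null_model import RatioHistogram

        h = RatioHistogram(bin_width=0.2, bin_edges=edges,
                           counts=counts, n_total=int(counts.sum()))
        f = fit_gaussian(h)
        assert f.amplitude == pytest.approx(100.0, abs=1e-6)
        assert f.mu == pytest.approx(0.0, abs=1e-6)
        assert f.sigma == pytest.approx(1.0, abs=1e-6)

    def test_monte_carlo_recovery(self):
        rng = np.random.default_rng(42)
        vals = rng.normal(0.0, 1.0, 50000)
        f = fit_gaussian(build_histogram(records_from(vals)))
        assert abs(f.mu) < 0.02
        assert abs(f.sigma - 1.0) < 0.03

    def test_contaminated_mixture_mode_window(self):
        rng = np.random.default_rng(7)
        vals = np.concatenate(
            [rng.normal(0, 1, 47500), rng.normal(8, 0.5, 2500)]
        )
        f = fit_gaussian(build_histogram(records_from(vals)))
        assert abs(f.mu) < 0.1

    def test_too_few_bins(self):
        with pytest.raises(ModelError):
            fit_gaussian(build_histogram(records_from([0.1, 0.1, 0.3])))


class TestDeriveThreshold:
    def test_closed_form_matches_root_finder(self):
        f = GaussianFit(amplitude=1.0, mu=0.0, sigma=1.0, rss=0.0)
        t = derive_threshold(f, fraction=0.10)
        root = brentq(lambda x: math.exp(-x * x / 2.0) - 0.10, 0.0, 10.0)
        assert t.threshold_log2 == pytest.approx(root, abs=1e-6)
        assert t.threshold_log2 == pytest.approx(2.14597, abs=1e-5)

    def test_fraction_one_is_peak(self):
        f = GaussianFit(amplitude=5.0, mu=0.7, sigma=1.3, rss=0.0)
        assert derive_threshold(f, fraction=1.0).threshold_log2 == pytest.approx(0.7)

    def test_magnitude_of_screen_scale_threshold(self):
        f = GaussianFit(amplitude=50.0, mu=0.8, sigma=2.1, rss=0.0)
        t = derive_threshold(f, fraction=0.10)
        assert t.threshold_log2 == pytest.approx(0.8 + 2.14597 * 2.1, abs=1e-4)
        assert t.threshold_log2 == pytest.approx(5.307, abs=0.001)

    def test_invalid_fraction(self):
        f = GaussianFit(amplitude=1.0, mu=0.0, sigma=1.0, rss=0.0)
        for bad in (0.0, -0.1, 1.5):
            with pytest.raises(ParameterError):
                derive_threshold(f, fraction=bad)

    def test_monotone_in_sigma_and_fraction(self):
        sigmas = [0.5, 1.0, 2.0]
        ts = [
            derive_threshold(GaussianFit(1, 0, s, 0), 0.10).threshold_log2
            for s in sigmas
        ]
        assert ts == sorted(ts)
        fracs = [0.05, 0.10, 0.5]
        tf = [
            derive_threshold(GaussianFit(1, 0, 1, 0), fr).threshold_log2
            for fr in fracs
        ]
        assert tf == sorted(tf, reverse=True)


class TestClassify:
    def make_threshold(self):
        return derive_threshold(GaussianFit(1.0, 0.0, 1.0, 0.0), 0.10)

    def test_boundary_is_specific(self):
        t = self.make_threshold()
        recs = records_from([t.threshold_log2])
        assert classify(recs, t)["P0"] == "specific"

    def test_exclusive_overrides(self):
        t = self.make_threshold()
        recs = records_from([], exclusive_accs=("X1",))
        assert classify(recs, t)["X1"] == "exclusive"

    def test_partition_and_band(self):
        t = self.make_threshold()
        vals = [t.threshold_log2 - 0.1, t.threshold_log2 - 0.5, -1.0, 3.0]
        classes = classify(records_from(vals), t)
        assert list(classes.values()) == [
            "borderline", "unspecific", "unspecific", "specific",
        ]
        assert len(classes) == len(vals)

    def test_spikein_sensitivity_by_construction(self, spikein_dataset):
        from baitcall.enrichment import compute_enrichment

        _, table, truth = spikein_dataset
        recs = compute_enrichment(table)
        h = build_histogram(recs)
        t = derive_threshold(fit_gaussian(h))
        classes = classify(recs, t)
        spiked = truth.of_label("interactor")
        assert all(classes[a] == "specific" for a in spiked)
        assert all(classes[a] == "exclusive" for a in truth.of_label("exclusive"))
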