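"""Gaussian background model over log2 enrichment ratios.

Unspecific binders load equally onto bait and control resins, so their log2
bait/control ratios form a single Gaussian mode centered near zero. The
model bins the ratios (0.2 log2-unit bins), fits A*exp(-(x-mu)^2/(2*sigma^2))
to the bin counts by least squares within a window around the modal bin
(so the enriched right tail cannot bias the null fit), and places the
specificity threshold where the fitted curve falls to a fraction of its
peak height on the *upper* flank:

    threshold = mu + sigma * sqrt(-2 * ln(fraction))

For the default fraction 0.10 the offset is sigma * sqrt(2 ln 10)
= 2.14597 sigma. Proteins are then tri-classified: ``specific`` at or above
the threshold, ``borderline`` within one band (default one bin width) below
it, else ``unspecific``; bait-exclusive proteins are a class of their own
since their ratio is undefined.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .enrichment import EnrichmentRecord
from .errors import ModelError, ParameterError

DEFAULT_BIN_WIDTH = 0.2
DEFAULT_FRACTION_OF_PEAK = 0.10

CLASSES = ("unspecific", "borderline", "specific", "exclusive")


@dataclass
class RatioHistogram:
    """Uniform-bin histogram of log2 ratios, edges anchored at k*bin_width."""

    bin_width: float
    bin_edges: np.ndarray  # len = n_bins + 1
    counts: np.ndarray  # nonnegative ints, len = n_bins
    n_total: int

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass
class GaussianFit:
    amplitude: float  # peak height, in counts
    mu: float  # log2 units
    sigma: float  # log2 units, > 0
    rss: float  # residual sum of squares over the fit window
    window: tuple[float, float] = (-np.inf, np.inf)


@dataclass
class ThresholdResult:
    fraction_of_peak: float
    threshold_log2: float
    borderline_lower: float
    mu: float = 0.0
    sigma: float = 1.0


def _bin_index(x: float, width: float) -> int:
    """Index of the half-open bin [k*width, (k+1)*width) containing x.

    Values within one part in 1e9 of an upper edge are assigned to the
    upper bin, so exact edges land upward regardless of float rounding.
    """
    q = x / width
    k = math.floor(q)
    if q - k > 1.0 - 1e-9:
        k += 1
    return k


def build_histogram(
    records: list[EnrichmentRecord], bin_width: float = DEFAULT_BIN_WIDTH
) -> RatioHistogram:
    """Bin the defined log2 ratios of floor-passing, non-exclusive records.

    Bin edges sit at integer multiples of ``bin_width``; bins are half-open
    ``[lo, hi)`` so a ratio exactly on an edge goes to the upper bin.
    """
    if bin_width <= 0:
        raise ParameterError(f"bin_width must be > 0, got {bin_width}")
    values = [
        r.log2_ratio
        for r in records
        if r.log2_ratio is not None and r.passes_floor and not r.exclusive
    ]
    if not values:
        raise ModelError("no eligible records (defined log2 ratio above the floor)")
    idx = np.array([_bin_index(v, bin_width) for v in values])
    k_min, k_max = int(idx.min()), int(idx.max())
    counts = np.bincount(idx - k_min, minlength=k_max - k_min + 1)
    edges = np.arange(k_min, k_max + 2) * bin_width
    return RatioHistogram(
        bin_width=bin_width, bin_edges=edges, counts=counts, n_total=len(values)
    )


def _gauss(x, a, mu, sigma):
    return a * np.exp(-((x - mu) ** 2) / (2.0 * sigma**2))


def fit_gaussian(hist: RatioHistogram, n_refine: int = 2) -> GaussianFit:
    """Least-squares Gaussian fit to (bin center, count) pairs.

    The fit is windowed to bins within +-3 sigma-estimates of the modal
    bin so that the enriched tail (true interactors) does not drag the
    null fit; the window is re-derived from the fitted sigma ``n_refine``
    times. Initialization: modal bin height/center and the count-weighted
    standard deviation inside the window.
    """
    if np.count_nonzero(hist.counts) < 4:
        raise ModelError("need >= 4 non-empty bins to fit the background mode")
    x = hist.centers
    y = hist.counts.astype(float)

    mode_center = float(x[np.argmax(y)])
    # first-pass scale: count-weighted SD of the whole histogram
    w = y / y.sum()
    sigma_est = float(np.sqrt(np.sum(w * (x - np.average(x, weights=w)) ** 2)))
    sigma_est = max(sigma_est, hist.bin_width)

    fit: GaussianFit | None = None
    for _ in range(max(1, n_refine)):
        lo, hi = mode_center - 3.0 * sigma_est, mode_center + 3.0 * sigma_est
        sel = (x >= lo) & (x <= hi)
        if np.count_nonzero(y[sel] > 0) < 4:
            sel = np.ones_like(x, dtype=bool)
            lo, hi = float(x[0]), float(x[-1])
        xw, yw = x[sel], y[sel]
        ww = yw / yw.sum()
        mu0 = float(np.average(xw, weights=ww))
        s0 = float(np.sqrt(np.sum(ww * (xw - mu0) ** 2)))
        s0 = max(s0, hist.bin_width / 2.0)
        p0 = (float(yw.max()), mu0, s0)
        try:
            popt, _ = curve_fit(
                _gauss,
                xw,
                yw,
                p0=p0,
                bounds=([0.0, -np.inf, 1e-12], [np.inf, np.inf, np.inf]),
                maxfev=20000,
            )
        except RuntimeError as exc:
            raise ModelError(f"Gaussian fit did not converge (init {p0})") from exc
        a, mu, sigma = (float(v) for v in popt)
        rss = float(np.sum((yw - _gauss(xw, a, mu, sigma)) ** 2))
        fit = GaussianFit(amplitude=a, mu=mu, sigma=sigma, rss=rss, window=(lo, hi))
        mode_center, sigma_est = mu, sigma
    assert fit is not None
    return fit


def derive_threshold(
    fit: GaussianFit, fraction: float = DEFAULT_FRACTION_OF_PEAK,
    borderline_band: float = DEFAULT_BIN_WIDTH,
) -> ThresholdResult:
    """Place the threshold where the fitted curve drops to ``fraction`` of
    its peak height, on the upper flank only."""
    if not 0.0 < fraction <= 1.0:
        raise ParameterError(f"fraction must be in (0, 1], got {fraction}")
    offset = fit.sigma * math.sqrt(-2.0 * math.log(fraction))
    threshold = fit.mu + offset
    return ThresholdResult(
        fraction_of_peak=fraction,
        threshold_log2=threshold,
        borderline_lower=threshold - borderline_band,
        mu=fit.mu,
        sigma=fit.sigma,
    )


def classify(
    records: list[EnrichmentRecord], threshold: ThresholdResult
) -> dict[str, str]:
    """Tri-classify records against the threshold (plus the exclusive class).

    specific: log2_ratio >= threshold (closed lower bound);
    borderline: within the band just below the threshold;
    unspecific: everything else with a defined or undefined ratio;
    exclusive: bait-only detection, regardless of threshold.
    """
    out: dict[str, str] = {}
    for r in records:
        if r.exclusive:
            out[r.accession] = "exclusive"
        elif r.log2_ratio is None:
            out[r.accession] = "unspecific"
        elif r.log2_ratio >= threshold.threshold_log2:
            out[r.accession] = "specific"
        elif r.log2_ratio >= threshold.borderline_lower:
            out[r.accession] = "borderline"
        else:
            out[r.accession] = "unspecific"
    return out


@dataclass
class NullModelReport:
    """Serializable summary of the fitted background model."""

    histogram: RatioHistogram
    fit: GaussianFit
    threshold: ThresholdResult
    class_counts: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "bin_width": self.histogram.bin_width,
            "n_ratios": int(self.histogram.n_total),
            "bin_edges": [float(e) for e in self.histogram.bin_edges],
            "counts": [int(c) for c in self.histogram.counts],
            "amplitude": self.fit.amplitude,
            "mu": self.fit.mu,
            "sigma": self.fit.sigma,
            "rss": self.fit.rss,
            "fit_window": [float(w) for w in self.fit.window],
            "fraction_of_peak": self.threshold.fraction_of_peak,
            "threshold_log2": self.threshold.threshold_log2,
            "borderline_lower": self.threshold.borderline_lower,
            "class_counts": self.class_counts,
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def plot_histogram(report: NullModelReport, path) -> None:
    """Three-zone histogram plot (unspecific / borderline / specific)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    hist, fit, thr = report.histogram, report.fit, report.threshold
    centers = hist.centers
    colors = [
        "tab:green" if c >= thr.threshold_log2
        else ("gold" if c >= thr.borderline_lower else "tab:red")
        for c in centers
    ]
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.bar(centers, hist.counts, width=hist.bin_width * 0.95, color=colors)
    xs = np.linspace(hist.bin_edges[0], hist.bin_edges[-1], 400)
    ax.plot(xs, _gauss(xs, fit.amplitude, fit.mu, fit.sigma), "k-", lw=1.5)
    ax.axvline(thr.threshold_log2, color="k", ls="--", lw=1)
    ax.set_xlabel("log2 (bait / control)")
    ax.set_ylabel("proteins per bin")
    ax.set_title(
        f"background mode mu={fit.mu:.3f}, sigma={fit.sigma:.3f}; "
        f"threshold={thr.threshold_log2:.4f}"
    )
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
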