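"""Voxel-intensity histogram normalization chain and two-Gaussian model.

The chain mirrors how light-sheet VAR intensity distributions are made
comparable across hearts of varying clarity: (1) build an equal-width
histogram of the masked voxels, (2) delete low-intensity background, (3)
trim the low-frequency feet of the distribution at a fixed relative
threshold (0.002 % per bin), (4) rescale the retained intensity range onto
[0, 1] and convert counts to frequencies summing to one. Group-mean
frequency histograms are then fitted with a mixture of two Gaussians
truncated to [0, 1]; the right (high-intensity) component models the
oxidized (MetMb-like) signal and its mean is reported as the component's
median. The whole chain is invariant to positive affine transforms of the
raw voxel intensities.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import norm

from .errors import ConvergenceError, DegenerateDataError, EmptyMaskError
from .types import IntensityVolume


# ---------------------------------------------------------------------------
# Histogram containers
# ---------------------------------------------------------------------------

@dataclass
class IntensityHistogram:
    """Binned raw-intensity distribution of masked voxels.

    ``discarded_background`` and ``discarded_foot`` account for every voxel
    removed by the two trimming stages, so counts are conserved through the
    chain.
    """

    bin_edges: np.ndarray  # length B+1, raw intensity units
    counts: np.ndarray  # length B
    total_voxels: int
    background_removed: bool = False
    foot_trimmed: bool = False
    discarded_background: int = 0
    discarded_foot: int = 0

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=np.float64)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.bin_edges.size != self.counts.size + 1:
            raise ValueError("need len(bin_edges) == len(counts) + 1")
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if int(self.counts.sum()) > self.total_voxels:
            raise ValueError("counts exceed total_voxels")
        if self.foot_trimmed and not self.background_removed:
            raise ValueError("foot_trimmed implies background_removed (stage order)")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def retained(self) -> int:
        return int(self.counts.sum())


def default_grid(bin_count: int = 256) -> np.ndarray:
    """Default [0, 1] bin-centre grid shared by group averaging."""
    return (np.arange(bin_count) + 0.5) / bin_count


@dataclass
class FrequencyHistogram:
    """Trimmed, [0, 1]-rescaled, unit-sum frequency histogram."""

    bin_centers: np.ndarray
    frequencies: np.ndarray
    n_hearts: int = 1

    def __post_init__(self) -> None:
        self.bin_centers = np.asarray(self.bin_centers, dtype=np.float64)
        self.frequencies = np.asarray(self.frequencies, dtype=np.float64)
        if self.bin_centers.size != self.frequencies.size:
            raise ValueError("bin_centers and frequencies must have equal length")
        if self.bin_centers.size and (
            self.bin_centers.min() < -1e-12 or self.bin_centers.max() > 1 + 1e-12
        ):
            raise ValueError("bin centers must lie in [0, 1]")
        if self.bin_centers.size > 1 and np.any(np.diff(self.bin_centers) <= 0):
            raise ValueError("bin centers must be strictly increasing")
        if np.any(self.frequencies < 0):
            raise ValueError("frequencies must be non-negative")
        if abs(float(self.frequencies.sum()) - 1.0) > 1e-9:
            raise ValueError("frequencies must sum to 1 (±1e-9)")


# ---------------------------------------------------------------------------
# The normalization chain
# ---------------------------------------------------------------------------

def build_histogram(volume: IntensityVolume, mask: np.ndarray, bin_count: int = 256) -> IntensityHistogram:
    """Equal-width histogram of the masked voxels spanning their range."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != volume.shape:
        raise ValueError(f"mask shape {mask.shape} != volume shape {volume.shape}")
    if not mask.any():
        raise EmptyMaskError("cannot histogram an empty mask")
    vals = volume.as_float()[mask]
    if float(vals.min()) == float(vals.max()):
        raise DegenerateDataError("constant masked intensities give a single degenerate bin")
    counts, edges = np.histogram(vals, bins=bin_count)
    return IntensityHistogram(edges, counts, total_voxels=int(vals.size))


def remove_background(
    histogram: IntensityHistogram, cutoff: float, mode: str = "absolute"
) -> IntensityHistogram:
    """Delete low-intensity (background) bins below the cutoff.

    ``mode='absolute'`` interprets the cutoff in raw intensity units;
    ``mode='quantile'`` as a quantile of the binned distribution. Bins
    lying entirely below the cutoff are discarded and excluded from the
    retained intensity range.
    """
    if mode == "quantile":
        if not 0 <= cutoff < 1:
            raise ValueError("quantile cutoff must lie in [0, 1)")
        cum = np.cumsum(histogram.counts) / max(histogram.retained, 1)
        idx = int(np.searchsorted(cum, cutoff, side="left"))
        cutoff_value = histogram.bin_edges[idx]
    elif mode == "absolute":
        cutoff_value = float(cutoff)
    else:
        raise ValueError(f"unknown background cutoff mode {mode!r}")
    keep = histogram.bin_edges[1:] > cutoff_value  # bin survives unless wholly below
    if not keep.any():
        raise DegenerateDataError("background cutoff removes every bin")
    first = int(np.argmax(keep))
    discarded = int(histogram.counts[:first].sum())
    return replace(
        histogram,
        bin_edges=histogram.bin_edges[first:],
        counts=histogram.counts[first:],
        background_removed=True,
        discarded_background=histogram.discarded_background + discarded,
    )


def trim_foot(
    histogram: IntensityHistogram, foot_threshold_fraction: float = 2e-5
) -> IntensityHistogram:
    """Trim the low-frequency feet of the distribution.

    Each bin's relative frequency (count / retained total) is compared to
    the fixed threshold (default 2e-5, i.e. 0.002 %); the first and last
    bins reaching it bound the retained contiguous range and everything
    outside is discarded. Requires the background-removal stage first.
    """
    if not histogram.background_removed:
        raise ValueError("remove_background must run before trim_foot (stage order)")
    total = histogram.retained
    if total == 0:
        raise DegenerateDataError("empty histogram")
    rel = histogram.counts / total
    above = rel >= foot_threshold_fraction
    if not above.any():
        raise DegenerateDataError("no bin reaches the foot threshold")
    first = int(np.argmax(above))
    last = len(above) - 1 - int(np.argmax(above[::-1]))
    discarded = int(histogram.counts[:first].sum() + histogram.counts[last + 1:].sum())
    return replace(
        histogram,
        bin_edges=histogram.bin_edges[first:last + 2],
        counts=histogram.counts[first:last + 1],
        foot_trimmed=True,
        discarded_foot=histogram.discarded_foot + discarded,
    )


def normalize_range(histogram: IntensityHistogram) -> FrequencyHistogram:
    """Map the retained range onto [0, 1] and convert counts to frequencies.

    The first retained edge maps to 0 and the last to 1 (lowest and highest
    retained intensities); counts are divided by the retained total so the
    frequencies sum to one.
    """
    if not histogram.foot_trimmed:
        raise ValueError("trim_foot must run before normalize_range (stage order)")
    if histogram.counts.size < 2:
        raise DegenerateDataError("need at least two retained bins to normalize the range")
    lo, hi = histogram.bin_edges[0], histogram.bin_edges[-1]
    centers = (histogram.bin_centers - lo) / (hi - lo)
    freqs = histogram.counts / histogram.retained
    return FrequencyHistogram(centers, freqs, n_hearts=1)


def run_chain(
    volume: IntensityVolume,
    mask: np.ndarray,
    bin_count: int = 256,
    background_cutoff: float = 0.0,
    background_cutoff_mode: str = "absolute",
    foot_threshold_fraction: float = 2e-5,
) -> tuple[FrequencyHistogram, IntensityHistogram]:
    """Full S-chain: build → remove background → trim feet → normalize.

    Returns the final frequency histogram together with the trimmed
    intensity histogram (whose edges carry the retained raw range used to
    normalize voxel intensities for oxidized-volume segmentation).
    """
    hist = build_histogram(volume, mask, bin_count)
    hist = remove_background(hist, background_cutoff, background_cutoff_mode)
    hist = trim_foot(hist, foot_threshold_fraction)
    return normalize_range(hist), hist


def average_group(freq_histograms: Sequence[FrequencyHistogram], grid: np.ndarray | None = None) -> FrequencyHistogram:
    """Average frequency histograms of one experimental group.

    Histograms already sharing one bin grid are averaged directly;
    otherwise each is resampled onto the default [0, 1] grid by linear
    interpolation (zero outside its support) and renormalized before
    averaging. The result is renormalized to unit sum and records the
    number of contributing hearts.
    """
    hists = list(freq_histograms)
    if not hists:
        raise ValueError("average_group needs at least one histogram")
    n_hearts = sum(h.n_hearts for h in hists)
    same_grid = all(
        h.bin_centers.size == hists[0].bin_centers.size
        and np.allclose(h.bin_centers, hists[0].bin_centers)
        for h in hists
    )
    if same_grid and grid is None:
        centers = hists[0].bin_centers
        mean = np.mean([h.frequencies for h in hists], axis=0)
    else:
        centers = np.asarray(grid) if grid is not None else default_grid()
        resampled = []
        for h in hists:
            f = np.interp(centers, h.bin_centers, h.frequencies, left=0.0, right=0.0)
            s = f.sum()
            resampled.append(f / s if s > 0 else f)
        mean = np.mean(resampled, axis=0)
    total = mean.sum()
    if total <= 0:
        raise DegenerateDataError("averaged histogram has zero mass on the grid")
    return FrequencyHistogram(centers, mean / total, n_hearts=n_hearts)


# ---------------------------------------------------------------------------
# Two-Gaussian mixture model
# ---------------------------------------------------------------------------

def _truncated_gauss_pdf(x: np.ndarray, mu: float, sd: float) -> np.ndarray:
    """Gaussian density renormalized over [0, 1] (truncated support)."""
    z = norm.cdf(1.0, mu, sd) - norm.cdf(0.0, mu, sd)
    return norm.pdf(x, mu, sd) / max(z, 1e-300)


def mixture_curve(x: np.ndarray, weights, mus, sds, bin_width: float) -> np.ndarray:
    """Discretized mixture of [0, 1]-truncated Gaussians at bin centres."""
    out = np.zeros_like(np.asarray(x, dtype=float))
    for w, mu, sd in zip(weights, mus, sds):
        out += w * _truncated_gauss_pdf(x, mu, sd)
    return out * bin_width


@dataclass
class TwoGaussianFit:
    """Fitted two-Gaussian mixture and its derived surface metrics.

    Component weights are the exact areas of the weighted, [0, 1]-truncated
    components, so ``surface_1 + surface_2 = 1``; components are ordered by
    mean (``mu1 < mu2``) and the right component's median equals its mean.
    """

    w1: float
    mu1: float
    sigma1: float
    w2: float
    mu2: float
    sigma2: float
    surface_1: float = field(init=False)
    surface_2: float = field(init=False)
    overlap_area: float = 0.0
    median_right: float = field(init=False)
    mean_residual: float = 0.0
    converged: bool = True
    cost: float = 0.0
    n_bins: int = 0
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not self.mu1 <= self.mu2:
            raise ValueError("components must be ordered with mu1 <= mu2")
        if abs(self.w1 + self.w2 - 1.0) > 1e-6:
            raise ValueError("component weights must sum to 1 (±1e-6)")
        if self.sigma1 <= 0 or self.sigma2 <= 0:
            raise ValueError("component sigmas must be positive")
        self.surface_1 = self.w1
        self.surface_2 = self.w2
        self.median_right = self.mu2

    def curve(self, x: np.ndarray, bin_width: float) -> np.ndarray:
        return mixture_curve(x, (self.w1, self.w2), (self.mu1, self.mu2),
                             (self.sigma1, self.sigma2), bin_width)


def overlap_area(fit_or_params, step: float = 1e-3) -> float:
    """∫₀¹ min(w1·φ1, w2·φ2) dx by trapezoidal quadrature."""
    if isinstance(fit_or_params, TwoGaussianFit):
        p = fit_or_params
        w1, mu1, s1, w2, mu2, s2 = p.w1, p.mu1, p.sigma1, p.w2, p.mu2, p.sigma2
    else:
        w1, mu1, s1, w2, mu2, s2 = fit_or_params
    xs = np.arange(0.0, 1.0 + step / 2, step)
    lo = np.minimum(w1 * _truncated_gauss_pdf(xs, mu1, s1), w2 * _truncated_gauss_pdf(xs, mu2, s2))
    return float(np.trapezoid(lo, xs))


def fit_metrics(fit: TwoGaussianFit, freq_histogram: FrequencyHistogram) -> TwoGaussianFit:
    """Populate the Table-style metrics of a converged fit.

    Surfaces are the component weights (exact areas of the truncated
    weighted components); the overlap is the integral of the pointwise
    minimum of the two weighted components; the right component's median is
    its mean; the residual is the mean absolute difference between the
    fitted curve and the frequencies at the bin centres.
    """
    x = freq_histogram.bin_centers
    bw = float(np.mean(np.diff(x))) if x.size > 1 else 1.0
    model = fit.curve(x, bw)
    fit.overlap_area = overlap_area(fit)
    fit.mean_residual = float(np.mean(np.abs(model - freq_histogram.frequencies)))
    # near-coincident components: the overlap saturates at min(w1, w2)
    fit.degenerate = fit.overlap_area >= 0.95 * min(fit.w1, fit.w2)
    return fit


def _fit_starts(x: np.ndarray, y: np.ndarray, seed: int, n_random: int) -> list[np.ndarray]:
    """Deterministic multi-start initial parameter vectors (w, mu1, s1, mu2, s2)."""
    cum = np.cumsum(y)
    q25 = float(x[np.searchsorted(cum, 0.25)])
    q75 = float(x[np.searchsorted(cum, min(0.75, cum[-1]))])
    mean = float(np.sum(x * y))
    sd = float(np.sqrt(max(np.sum(y * (x - mean) ** 2), 1e-8)))
    starts = [np.array([0.5, q25, sd / 2, q75, sd / 2])]
    rng = np.random.default_rng(seed)
    for _ in range(n_random):
        mus = np.sort(rng.uniform(0.1, 0.9, 2))
        starts.append(np.array([
            rng.uniform(0.2, 0.8), mus[0], rng.uniform(0.03, 0.2),
            mus[1], rng.uniform(0.03, 0.2),
        ]))
    return starts


def fit_two_gaussians(
    freq_histogram: FrequencyHistogram, seed: int = 0, n_random_starts: int = 4
) -> TwoGaussianFit:
    """Least-squares two-Gaussian fit of a frequency histogram.

    The model is ``f(x) = [w·φ(x; mu1, s1) + (1−w)·φ(x; mu2, s2)] · Δx``
    with φ a Gaussian density renormalized over [0, 1], fitted to the
    frequencies at the bin centres under 0 ≤ mu ≤ 1 and a sigma floor of
    half a bin width (preventing delta-spike degeneracy). Initialization is
    the weighted 25th/75th percentiles plus seeded random restarts; the
    best residual wins, ties broken by the smaller parameter norm.
    Components are reported sorted by mean.
    """
    x = freq_histogram.bin_centers
    y = freq_histogram.frequencies
    if x.size < 8:
        raise DegenerateDataError("need at least 8 bins to fit a two-Gaussian mixture")
    bw = float(np.mean(np.diff(x)))
    sigma_floor = bw / 2.0

    def residual(p: np.ndarray) -> np.ndarray:
        w, mu1, s1, mu2, s2 = p
        return mixture_curve(x, (w, 1 - w), (mu1, mu2), (s1, s2), bw) - y

    lbound = np.array([1e-6, 0.0, sigma_floor, 0.0, sigma_floor])
    ubound = np.array([1 - 1e-6, 1.0, 2.0, 1.0, 2.0])
    best = None
    any_success = False
    for p0 in _fit_starts(x, y, seed, n_random_starts):
        p0 = np.clip(p0, lbound, ubound)
        res = least_squares(residual, p0, bounds=(lbound, ubound), method="trf")
        any_success = any_success or res.success
        if res.success:
            key = (res.cost, float(np.linalg.norm(res.x)))
            if best is None or key < best[0]:
                best = (key, res)
    if best is None:
        raise ConvergenceError(
            "two-Gaussian fit did not converge from any start", best_residual=None
        )
    res = best[1]
    w, mu1, s1, mu2, s2 = res.x
    if mu1 > mu2:
        w, mu1, s1, mu2, s2 = 1 - w, mu2, s2, mu1, s1
    fit = TwoGaussianFit(
        w1=float(w), mu1=float(mu1), sigma1=float(s1),
        w2=float(1 - w), mu2=float(mu2), sigma2=float(s2),
        converged=True, cost=float(res.cost), n_bins=int(x.size),
    )
    return fit_metrics(fit, freq_histogram)


def compare_gaussian_models(
    freq_histogram: FrequencyHistogram,
    k_candidates: Sequence[int] = (1, 2, 3),
    seed: int = 0,
) -> dict:
    """Fit k-component mixtures and pick k by a small-sample-corrected AIC.

    Each candidate mixture (free non-negative amplitudes, means in [0, 1],
    sigma-floored widths) is fitted by least squares with seeded restarts;
    the penalized score is AICc on Gaussian residuals with 3k parameters.
    Returns the chosen k plus per-k residuals and scores (non-convergent
    candidates score infinity).
    """
    x = freq_histogram.bin_centers
    y = freq_histogram.frequencies
    n = x.size
    bw = float(np.mean(np.diff(x))) if n > 1 else 1.0
    sigma_floor = bw / 2.0
    rng = np.random.default_rng(seed)
    results: dict[int, dict] = {}
    for k in k_candidates:
        def residual(p: np.ndarray, k=k) -> np.ndarray:
            amps, mus, sds = p[:k], p[k:2 * k], p[2 * k:]
            return mixture_curve(x, amps, mus, sds, bw) - y

        lb = np.concatenate([np.zeros(k), np.zeros(k), np.full(k, sigma_floor)])
        ub = np.concatenate([np.full(k, 2.0), np.ones(k), np.full(k, 2.0)])
        best_cost, best_p = np.inf, None
        starts = []
        base_mus = np.linspace(0.2, 0.8, k)
        starts.append(np.concatenate([np.full(k, 1.0 / k), base_mus, np.full(k, 0.1)]))
        for _ in range(3):
            starts.append(np.concatenate([
                rng.uniform(0.2, 1.0, k), np.sort(rng.uniform(0.05, 0.95, k)),
                rng.uniform(0.03, 0.2, k),
            ]))
        for p0 in starts:
            res = least_squares(residual, np.clip(p0, lb, ub), bounds=(lb, ub), method="trf")
            if res.success and res.cost < best_cost:
                best_cost, best_p = res.cost, res.x
        if best_p is None:
            results[k] = {"rss": np.inf, "score": np.inf, "params": None}
            continue
        rss = float(2 * best_cost)
        p_free = 3 * k
        score = n * np.log(max(rss / n, 1e-300)) + 2 * p_free
        if n - p_free - 1 > 0:
            score += 2 * p_free * (p_free + 1) / (n - p_free - 1)
        results[k] = {"rss": rss, "score": float(score), "params": best_p}
    chosen = min(results, key=lambda k: results[k]["score"])
    return {"chosen_k": int(chosen), "per_k": results}
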