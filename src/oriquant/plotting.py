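"""Figure helpers: frequency histograms with their two-Gaussian fits."""
from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .histogram import FrequencyHistogram, TwoGaussianFit, _truncated_gauss_pdf


def plot_histogram_fit(
    freq_histogram: FrequencyHistogram,
    fit: TwoGaussianFit | None = None,
    path=None,
    title: str | None = None,
):
    """Plot a frequency histogram, its two Gaussian components and the
    right-component median marker; optionally save to ``path``."""
    x = freq_histogram.bin_centers
    bw = float(np.mean(np.diff(x))) if x.size > 1 else 1.0
    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.bar(x, freq_histogram.frequencies, width=bw, color="0.8", label="frequency")
    if fit is not None:
        xs = np.linspace(0, 1, 400)
        c1 = fit.w1 * _truncated_gauss_pdf(xs, fit.mu1, fit.sigma1) * bw
        c2 = fit.w2 * _truncated_gauss_pdf(xs, fit.mu2, fit.sigma2) * bw
        ax.plot(xs, c1, "b-", label="left Gaussian")
        ax.plot(xs, c2, "r-", label="right Gaussian")
        ax.plot(xs, c1 + c2, "k--", lw=1, label="mixture")
        ax.axvline(fit.median_right, color="g", ls=":", label="median of right fit")
    ax.set_xlabel("normalized fluorescence intensity")
    ax.set_ylabel("frequency")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=7)
    fig.tight_layout()
    if path is not None:
        fig.savefig(Path(path), dpi=120)
        plt.close(fig)
    return fig
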