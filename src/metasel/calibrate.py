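"""Threshold calibration from labeled feature samples.

A decision threshold between two classes is taken as the intercept of the
two class-conditional Gaussian densities fitted to labeled samples; kernel
density estimates are computed alongside for diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "GaussianFit",
    "LabeledSample",
    "CalibrationResult",
    "kde",
    "fit_gaussian",
    "gaussian_intercept",
    "calibrate_threshold",
    "quantile_threshold",
]


@dataclass(frozen=True)
class GaussianFit:
    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("sd must be > 0")
        if self.n < 2:
            raise ValueError("need n >= 2")

    def pdf(self, x):
        return sps.norm.pdf(x, loc=self.mean, scale=self.sd)


@dataclass(frozen=True)
class LabeledSample:
    """Feature values sharing one class tag."""

    values: np.ndarray
    label: str

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size == 0:
            raise ValueError("values must be a nonempty 1-D array")
        if not np.all(np.isfinite(values)):
            raise ValueError("values must be finite")
        object.__setattr__(self, "values", values)


@dataclass(frozen=True)
class CalibrationResult:
    """Threshold plus plot-ready density curves for the two classes."""

    threshold: float
    fit_a: GaussianFit
    fit_b: GaussianFit
    grid: np.ndarray
    kde_a: np.ndarray
    kde_b: np.ndarray
    pdf_a: np.ndarray
    pdf_b: np.ndarray
    label_a: str
    label_b: str


def kde(sample: LabeledSample, grid: np.ndarray) -> np.ndarray:
    """Gaussian-kernel density estimate (Silverman bandwidth) on a grid."""
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty evaluation grid")
    if np.var(sample.values) == 0:
        raise ValueError("zero-variance sample")
    estimator = sps.gaussian_kde(sample.values, bw_method="silverman")
    return estimator(grid)


def fit_gaussian(sample: LabeledSample) -> GaussianFit:
    """Sample mean and (n-1)-denominator standard deviation."""
    values = sample.values
    if values.size < 2:
        raise ValueError("need at least 2 values")
    sd = float(np.std(values, ddof=1))
    if sd == 0:
        raise ValueError("degenerate (constant) sample")
    return GaussianFit(mean=float(np.mean(values)), sd=sd, n=int(values.size))


def gaussian_intercept(a: GaussianFit, b: GaussianFit) -> float:
    """The crossing point of two Gaussian pdfs that lies between the means.

    Solves pdf_a(x) = pdf_b(x) via the quadratic obtained by equating log
    densities.  With equal sds the unique crossing is the midpoint of the
    means; otherwise the root strictly between the means is returned.

    Raises
    ------
    ValueError
        If the means coincide, or if no crossing lies strictly between the
        means (a narrow density nested well inside a wide one — no usable
        decision boundary separates such a pair).
    """
    if a.mean == b.mean:
        raise ValueError("means must differ")
    lo, hi = sorted((a.mean, b.mean))
    if a.sd == b.sd:
        return 0.5 * (a.mean + b.mean)
    # (1/sb^2 - 1/sa^2) x^2 - 2(mb/sb^2 - ma/sa^2) x
    #   + (mb^2/sb^2 - ma^2/sa^2) + 2 ln(sb/sa) = 0
    va, vb = a.sd**2, b.sd**2
    c2 = 1.0 / vb - 1.0 / va
    c1 = -2.0 * (b.mean / vb - a.mean / va)
    c0 = b.mean**2 / vb - a.mean**2 / va + 2.0 * np.log(b.sd / a.sd)
    roots = np.roots([c2, c1, c0])
    roots = roots[np.isreal(roots)].real
    between = roots[(roots > lo) & (roots < hi)]
    if between.size != 1:
        raise ValueError("no density crossing strictly between the means")
    return float(between[0])


def quantile_threshold(fit: GaussianFit, z: float, side: str = "upper") -> float:
    """One-sample alternative: threshold at mean +/- z standard deviations."""
    if side not in ("upper", "lower"):
        raise ValueError("side must be 'upper' or 'lower'")
    return fit.mean + z * fit.sd if side == "upper" else fit.mean - z * fit.sd


def calibrate_threshold(
    class_a: LabeledSample,
    class_b: LabeledSample,
    grid_points: int = 512,
) -> CalibrationResult:
    """Fit a Gaussian to each labeled sample and return their intercept.

    The result carries both fits together with kernel-density and Gaussian
    pdf curves evaluated on a shared grid spanning both samples, ready for
    a diagnostic density plot.
    """
    fit_a = fit_gaussian(class_a)
    fit_b = fit_gaussian(class_b)
    threshold = gaussian_intercept(fit_a, fit_b)
    lo = min(class_a.values.min(), class_b.values.min())
    hi = max(class_a.values.max(), class_b.values.max())
    margin = 0.1 * (hi - lo) if hi > lo else 1.0
    grid = np.linspace(lo - margin, hi + margin, grid_points)
    return CalibrationResult(
        threshold=threshold,
        fit_a=fit_a,
        fit_b=fit_b,
        grid=grid,
        kde_a=kde(class_a, grid),
        kde_b=kde(class_b, grid),
        pdf_a=fit_a.pdf(grid),
        pdf_b=fit_b.pdf(grid),
        label_a=class_a.label,
        label_b=class_b.label,
    )


def plot_calibration(result: CalibrationResult, path) -> None:
    """Write a density plot (KDE + Gaussian fits + threshold) to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    for label, kde_curve, pdf_curve, color in (
        (result.label_a, result.kde_a, result.pdf_a, "tab:blue"),
        (result.label_b, result.kde_b, result.pdf_b, "tab:red"),
    ):
        ax.plot(result.grid, kde_curve, color=color, ls="--", lw=1,
                label=f"{label} (empirical)")
        ax.plot(result.grid, pdf_curve, color=color, lw=1.5,
                label=f"{label} (Gaussian)")
    ax.axvline(result.threshold, color="k", lw=1, ls=":",
               label=f"threshold = {result.threshold:.4f}")
    ax.set_xlabel("feature value")
    ax.set_ylabel("density")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
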