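"""Age regressions and correlations for hearing-loss progression.

Plain least-squares fits of threshold shift, hair-cell loss, or normalized
fluorescence against absolute age in days, summarized by slope (also scaled
to dB per 50 days), R², Pearson r and its two-sided p; comparison of two
group fits by intercept difference Δ and slope-difference growth
ε = Δslope × age span; and the coupling of threshold shift to outer-hair-cell
loss expressed in dB per 10% loss.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class RegressionSummary:
    """Simple OLS fit y = intercept + slope * x with correlation diagnostics.

    For a simple regression R² equals the squared Pearson r; p is the
    two-sided p for r from the t distribution with n-2 degrees of freedom.
    ``slope_per_50d`` re-expresses the slope per 50 days when x is age in
    days.  ``r_undefined`` flags a constant-y fit where r does not exist.
    """

    slope: float
    intercept: float
    r_squared: float
    pearson_r: float
    p_value: float
    n: int
    slope_se: float
    slope_ci95: tuple[float, float]
    r_undefined: bool = False

    @property
    def slope_per_50d(self) -> float:
        return self.slope * 50.0

    def predict(self, x) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(x, dtype=float)

    def summary(self) -> str:
        lines = [
            "Ordinary least squares (y ~ x)",
            f"  n                 {self.n}",
            f"  slope             {self.slope:.6g}  (SE {self.slope_se:.3g})",
            f"  slope per 50 d    {self.slope_per_50d:.6g}",
            f"  95% CI (slope)    [{self.slope_ci95[0]:.6g}, {self.slope_ci95[1]:.6g}]",
            f"  intercept         {self.intercept:.6g}",
        ]
        if self.r_undefined:
            lines.append("  R² / r            undefined (constant response)")
        else:
            lines.append(f"  R²                {self.r_squared:.4f}")
            lines.append(f"  Pearson r         {self.pearson_r:.4f}  (p = {self.p_value:.3g})")
        return "\n".join(lines)


def ols_fit(x, y) -> RegressionSummary:
    """Least-squares line of y on x (e.g. shift in dB on age in days).

    Requires n >= 3 and non-constant x.  A constant y returns slope 0 with r
    flagged undefined rather than an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be matching 1D arrays")
    if len(x) < 3:
        raise ValueError("need n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; slope undefined")
    n = len(x)
    if np.ptp(y) == 0:
        return RegressionSummary(0.0, float(y[0]), math.nan, math.nan, math.nan,
                                 n, 0.0, (0.0, 0.0), r_undefined=True)
    res = stats.linregress(x, y)
    tcrit = stats.t.ppf(0.975, n - 2)
    ci = (res.slope - tcrit * res.stderr, res.slope + tcrit * res.stderr)
    return RegressionSummary(float(res.slope), float(res.intercept),
                             float(res.rvalue ** 2), float(res.rvalue),
                             float(res.pvalue), n, float(res.stderr), ci)


@dataclass
class FitComparison:
    """Difference between two group fits over a common age span.

    Δ (``delta_intercept``) is the intercept difference B − A; ε is the growth
    of the between-group difference over the observed age span,
    ε = (slope_B − slope_A) × age_span.
    """

    delta_intercept: float
    delta_slope: float
    epsilon: float


def compare_fits(fit_a: RegressionSummary, fit_b: RegressionSummary,
                 age_span_days: float) -> FitComparison:
    d_int = fit_b.intercept - fit_a.intercept
    d_slope = fit_b.slope - fit_a.slope
    return FitComparison(d_int, d_slope, d_slope * age_span_days)


@dataclass
class OhcCouplingResult:
    """Threshold-shift growth per 10% outer-hair-cell loss."""

    db_per_10pct_loss: float
    ci95: tuple[float, float]
    fit: RegressionSummary


def shift_per_ohc_loss(shifts_db, losses_pct) -> OhcCouplingResult:
    """OLS slope of high-frequency threshold shift on OHC loss, scaled to
    dB per 10% loss."""
    losses = np.asarray(losses_pct, dtype=float)
    if len(losses) >= 1 and np.ptp(losses) == 0:
        raise ValueError("losses are constant; coupling undefined")
    fit = ols_fit(losses, shifts_db)
    return OhcCouplingResult(fit.slope * 10.0,
                             (fit.slope_ci95[0] * 10.0, fit.slope_ci95[1] * 10.0),
                             fit)
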