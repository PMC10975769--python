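"""Agreement statistics between measured and reference phenotype values.

MAE, RMSE, mean relative error (percent, reference in the denominator) and
the coefficient of determination of the ordinary least-squares fit of
measured on reference (with intercept), plus per-period growth-increment
summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class AgreementStats:
    r_squared: float
    mae: float
    mre_percent: float
    rmse: float
    n: int

    def as_dict(self) -> dict:
        return {
            "r_squared": self.r_squared,
            "mae": self.mae,
            "mre_percent": self.mre_percent,
            "rmse": self.rmse,
            "n": self.n,
        }


def agreement(measured, reference) -> AgreementStats:
    """Agreement of measured values with reference values.

    MAE = mean |m - r|; MRE = mean(|m - r| / r) * 100; RMSE = sqrt(mean
    (m - r)^2); R^2 from the OLS regression of measured on reference.
    """
    m = np.asarray(measured, float)
    r = np.asarray(reference, float)
    if m.shape != r.shape or m.ndim != 1:
        raise ValueError("measured and reference must be equal-length 1-D sequences")
    if len(m) < 2:
        raise ValueError("agreement needs at least 2 pairs")
    if np.any(r <= 0):
        raise ValueError("reference values must be positive (MRE denominator)")
    err = m - r
    mae = float(np.abs(err).mean())
    mre = float((np.abs(err) / r).mean() * 100.0)
    rmse = float(np.sqrt((err**2).mean()))
    if np.allclose(r, r[0]):
        # degenerate regressor: R^2 of the constant fit
        r2 = 1.0 if np.allclose(m, m[0]) else 0.0
    else:
        fit = stats.linregress(r, m)
        r2 = float(fit.rvalue**2)
    return AgreementStats(r_squared=r2, mae=mae, mre_percent=mre, rmse=rmse, n=len(m))


def increment_summary(per_period: list[list[float]]) -> tuple[list[float], list[float]]:
    """Per-period means and the differences between consecutive period
    means (the growth increments)."""
    if not per_period:
        raise ValueError("increment_summary needs at least one period")
    means = [float(np.mean(vals)) for vals in per_period]
    increments = [b - a for a, b in zip(means, means[1:])]
    return means, increments
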