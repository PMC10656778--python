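"""Standard-curve fitting and amplification-efficiency computation.

A qPCR standard curve regresses Ct on the log10 relative template amount of a
10-fold dilution series. For an assay with per-cycle amplification factor
1 + E/100, the theoretical slope is -1/log10(1 + E/100), so the efficiency is
recovered from the fitted slope magnitude as

    E% = (10^(1/|slope|) - 1) * 100,

with |slope| = 3.3219 corresponding to perfect doubling (E = 100%).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DimensionError, TableValueError
from .tabular_io import DilutionSeries


@dataclass
class CurveFit:
    """OLS fit of one dilution series (slope reported as a positive magnitude)."""

    gene_id: str
    slope: float
    intercept: float
    r_squared: float
    efficiency_pct: float


def efficiency_from_slope(slope_magnitude: float) -> float:
    """Amplification efficiency in percent from a standard-curve slope magnitude."""
    if not np.isfinite(slope_magnitude) or slope_magnitude <= 0:
        raise TableValueError("slope magnitude must be a positive finite number")
    return (10.0 ** (1.0 / slope_magnitude) - 1.0) * 100.0


def fit_standard_curve(series: DilutionSeries) -> CurveFit:
    """Ordinary least squares of Ct on log10 amount; R^2 is the squared Pearson r."""
    x = series.log10_amounts
    y = series.cts
    if np.allclose(x, x[0]):
        raise DimensionError("all dilution amounts identical: regression is rank-deficient")
    fit = stats.linregress(x, y)
    slope_mag = abs(float(fit.slope))
    if slope_mag == 0.0:
        raise TableValueError(f"flat standard curve for gene {series.gene_id!r}")
    return CurveFit(
        gene_id=series.gene_id,
        slope=slope_mag,
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
        efficiency_pct=efficiency_from_slope(slope_mag),
    )
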