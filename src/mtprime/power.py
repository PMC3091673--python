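"""Two-channel array preprocessing and detection-power analytics.

Preprocessing follows the classic spotted-array workflow: a spot is "well
measured" when its foreground exceeds the local background pixel
distribution by three standard deviations in both channels, and ratios
are formed after background subtraction and mean-by-mean normalization.

The power analytics quantify an experiment's sensitivity:

* GEL50 — the gene expression fold change at which there is a 50%
  empirical probability of a significant call, obtained by logistic
  regression of the per-gene significance indicator on |log2 fold
  change| and inverting the fitted curve at probability one half.
* A nested-model logistic likelihood-ratio test asking whether a
  covariate (e.g. the number of primer binding sites in a gene) predicts
  significant calls better than an intercept-only model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import chi2

__all__ = [
    "SpotMeasurement",
    "PowerEstimate",
    "SeparationError",
    "well_measured",
    "mean_by_mean_normalize",
    "fit_logistic",
    "gel50",
    "sites_power_regression",
    "plain_ratio",
]


class SeparationError(ValueError):
    """Perfect separation: the logistic MLE does not exist."""


@dataclass(frozen=True)
class SpotMeasurement:
    """One two-channel spot: foregrounds and background pixel statistics."""

    gene_id: str
    fg1: float
    bg1_mean: float
    bg1_sd: float
    fg2: float
    bg2_mean: float
    bg2_sd: float

    def __post_init__(self) -> None:
        if min(self.fg1, self.fg2) < 0 or min(self.bg1_sd, self.bg2_sd) < 0:
            raise ValueError("intensities and background SDs must be nonnegative")


def well_measured(spot: SpotMeasurement, n_sd: float = 3.0) -> bool:
    """Foreground strictly above background mean + ``n_sd``·SD in both channels."""
    return (
        spot.fg1 > spot.bg1_mean + n_sd * spot.bg1_sd
        and spot.fg2 > spot.bg2_mean + n_sd * spot.bg2_sd
    )


def mean_by_mean_normalize(
    spots: list[SpotMeasurement], n_sd: float = 3.0
) -> pd.DataFrame:
    """Background-subtracted, mean-by-mean-normalized ratios of well-measured spots.

    Net intensities are ``fg - bg_mean`` per channel; channel 2 is scaled so
    the two channels have equal mean net intensity over well-measured spots,
    and the per-gene ratio is ``net1 / (k * net2)``.  Returns a frame with
    columns gene_id, net1, net2, ratio for the well-measured spots only.
    """
    kept = [s for s in spots if well_measured(s, n_sd)]
    if not kept:
        raise ValueError("no well-measured spots")
    net1 = np.array([s.fg1 - s.bg1_mean for s in kept])
    net2 = np.array([s.fg2 - s.bg2_mean for s in kept])
    if net2.mean() <= 0:
        raise ValueError("channel-2 mean net intensity is not positive")
    k = net1.mean() / net2.mean()
    return pd.DataFrame(
        {
            "gene_id": [s.gene_id for s in kept],
            "net1": net1,
            "net2": net2,
            "ratio": net1 / (k * net2),
        }
    )


@dataclass(frozen=True)
class LogisticFit:
    intercept: float
    slope: float
    llf: float


@dataclass(frozen=True)
class PowerEstimate:
    """Logistic power fit: coefficients, GEL50 (when applicable) and the
    nested-model (slope = 0) likelihood-ratio p-value."""

    intercept: float
    slope: float
    gel50: Optional[float]
    lrt_p: float


def fit_logistic(y, x) -> LogisticFit:
    """Maximum-likelihood Bernoulli-logit fit of y on (1, x).

    Newton-Raphson via statsmodels, converged to score norm < 1e-8.
    Raises on a one-class outcome, a constant covariate, or perfect
    separation (where the MLE diverges).
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.size != x.size or y.size < 2:
        raise ValueError("y and x must be equal-length with n >= 2")
    if len(np.unique(y)) < 2:
        raise ValueError("outcome has a single class; logistic fit undefined")
    if len(np.unique(x)) < 2:
        raise ValueError("covariate is constant; slope not identifiable")
    if np.max(x[y == 1]) < np.min(x[y == 0]) or np.max(x[y == 0]) < np.min(x[y == 1]):
        raise SeparationError("outcome perfectly separated by the covariate")
    X = sm.add_constant(x)
    model = sm.Logit(y, X)
    try:
        res = model.fit(disp=0, method="newton", maxiter=200, tol=1e-12)
    except Exception as exc:  # statsmodels raises on separation mid-iteration
        raise SeparationError(f"logistic fit failed: {exc}") from exc
    grad_norm = float(np.linalg.norm(model.score(res.params)))
    if not np.all(np.isfinite(res.params)) or grad_norm >= 1e-8:
        raise SeparationError(
            f"logistic fit did not converge (score norm {grad_norm:.2e})"
        )
    return LogisticFit(float(res.params[0]), float(res.params[1]), float(res.llf))


def _null_llf(y: np.ndarray) -> float:
    """Log-likelihood of the intercept-only Bernoulli model (closed form)."""
    p = y.mean()
    n1 = y.sum()
    n0 = y.size - n1
    ll = 0.0
    if n1:
        ll += n1 * math.log(p)
    if n0:
        ll += n0 * math.log(1 - p)
    return ll


def plain_ratio(ratio) -> np.ndarray:
    """Convert signed fold ratios (-2 meaning 2-fold down) to plain ratios."""
    r = np.asarray(ratio, dtype=float)
    if np.any(r == 0):
        raise ValueError("fold ratios must be nonzero")
    return np.where(r > 0, r, -1.0 / r)


def _significance(table: pd.DataFrame, alpha: float) -> np.ndarray:
    if "significant" in table.columns:
        return table["significant"].to_numpy(dtype=float)
    if "p_value" in table.columns:
        return (table["p_value"].to_numpy(dtype=float) <= alpha).astype(float)
    raise ValueError("table needs a 'significant' or 'p_value' column")


def gel50(table: pd.DataFrame, alpha: float = 0.05) -> PowerEstimate:
    """Fold change at 50% empirical probability of a significant call.

    ``table`` needs a ``ratio`` column (plain or signed convention) and
    either a boolean ``significant`` column or a ``p_value`` column that is
    thresholded at ``alpha``.  The significance indicator is regressed on
    x = |log2 ratio|; GEL50 = 2**(-intercept/slope).  A non-positive slope
    (power not increasing in fold change) is an error.
    """
    y = _significance(table, alpha)
    x = np.abs(np.log2(plain_ratio(table["ratio"])))
    fit = fit_logistic(y, x)
    if fit.slope <= 0:
        raise ValueError(
            f"fitted slope {fit.slope:.4f} <= 0: significance does not increase "
            "with fold change; GEL50 undefined"
        )
    x50 = -fit.intercept / fit.slope
    lrt = max(0.0, 2.0 * (fit.llf - _null_llf(y)))
    return PowerEstimate(
        intercept=fit.intercept,
        slope=fit.slope,
        gel50=float(2.0 ** x50),
        lrt_p=float(chi2.sf(lrt, df=1)),
    )


def sites_power_regression(table: pd.DataFrame, alpha: float = 0.05) -> PowerEstimate:
    """Does the number of primer binding sites predict significant calls?

    Fits intercept-only and intercept + n_sites logistic models and
    compares them with a chi-square(1) likelihood-ratio test.
    """
    if "n_sites" not in table.columns:
        raise ValueError("table needs an 'n_sites' covariate column")
    y = _significance(table, alpha)
    x = table["n_sites"].to_numpy(dtype=float)
    fit = fit_logistic(y, x)
    lrt = max(0.0, 2.0 * (fit.llf - _null_llf(y)))
    return PowerEstimate(
        intercept=fit.intercept,
        slope=fit.slope,
        gel50=None,
        lrt_p=float(chi2.sf(lrt, df=1)),
    )
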