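"""Residual regression for paired-condition (OCT4-ON / OCT4-OFF) signal.

For each IZ the signal is the mean BPM over a +/-5 kb window around the
refined center, in both conditions. The residual

    residual = log2(ON + eps) - log2(OFF + eps) = log2((ON + eps)/(OFF + eps))

measures the log fold loss upon depletion, and per RT class an ordinary
least-squares fit of

    residual ~ log2(ON + eps)

tests (t test on the slope, n - 2 df) whether the loss depends systematically
on the strength of the zone in the control state.

Statistical caveat, reported rather than corrected: regressing a difference
on one of its terms yields a positive slope under independent measurement
noise alone. The package fits the model as defined and ships a
null-calibration simulation (see :func:`null_slope_calibration`) so users can
judge observed slopes against that baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .core import RT_CLASSES, BinnedTrack
from .iz_calling import IZSet
from .track_io import _interval_mean

DEFAULT_PSEUDOCOUNT = 0.01  # BPM


@dataclass
class ResidualRegressionResult:
    rt_class: str
    n: int
    slope: float
    intercept: float
    slope_stderr: float
    t_statistic: float
    p_value: float

    def to_row(self) -> dict:
        return self.__dict__.copy()


def window_signal(track: BinnedTrack, izs: IZSet, half_width: int = 5000) -> pd.Series:
    """Mean BPM over [center - half_width, center + half_width) per IZ.

    IZs whose window falls off the chromosome get NaN (callers drop them from
    both conditions)."""
    out = np.full(len(izs), np.nan)
    for i, row in enumerate(izs.df.itertuples(index=False)):
        length = track.genome.chrom_lengths[row.chrom]
        s, e = int(row.center) - half_width, int(row.center) + half_width
        if s < 0 or e > length:
            warnings.warn(f"window around {row.chrom}:{row.center} off chromosome; dropped")
            continue
        out[i] = _interval_mean(track, row.chrom, s, e)
    return pd.Series(out, index=izs.df.index)


def paired_window_signal(track_on: BinnedTrack, track_off: BinnedTrack, izs: IZSet,
                         half_width: int = 5000,
                         pseudocount: float = DEFAULT_PSEUDOCOUNT) -> pd.DataFrame:
    """Per-IZ paired signal table; IZs with an off-chromosome window are
    dropped from both conditions."""
    on = window_signal(track_on, izs, half_width)
    off = window_signal(track_off, izs, half_width)
    df = pd.DataFrame({"rt_class": izs.df["rt_class"], "signal_on": on,
                       "signal_off": off})
    df = df.dropna().reset_index(drop=True)
    df["pseudocount"] = pseudocount
    return df


def compute_residuals(paired: pd.DataFrame,
                      pseudocount: float = DEFAULT_PSEUDOCOUNT) -> np.ndarray:
    """residual = log2(on + eps) - log2(off + eps), one value per IZ."""
    on = paired["signal_on"].to_numpy(float)
    off = paired["signal_off"].to_numpy(float)
    if pseudocount <= 0 and ((on == 0) | (off == 0)).any():
        raise ValueError("pseudocount must be > 0 when any signal is 0")
    return np.log2(on + pseudocount) - np.log2(off + pseudocount)


def fit_residual_regression(residuals, log2_on, by_class=None
                            ) -> dict[str, ResidualRegressionResult]:
    """OLS of residual on log2(ON) per class (or pooled under key "all").

    Returns slope, intercept, slope standard error, t = slope/stderr, and the
    two-sided p-value from the t distribution with n - 2 df.
    """
    residuals = np.asarray(residuals, dtype=float)
    x = np.asarray(log2_on, dtype=float)
    if not np.all(np.isfinite(x)) or not np.all(np.isfinite(residuals)):
        raise ValueError("predictors and residuals must be finite")
    if by_class is None:
        groups = {"all": np.ones(len(x), dtype=bool)}
    else:
        by_class = np.asarray(by_class)
        groups = {c: by_class == c for c in dict.fromkeys(by_class)}
    results = {}
    for name, mask in groups.items():
        xv, yv = x[mask], residuals[mask]
        if xv.size < 3:
            raise ValueError(f"class {name} has fewer than 3 IZs")
        if np.ptp(xv) == 0:
            raise ValueError(f"zero predictor variance in class {name}")
        model = sm.OLS(yv, sm.add_constant(xv)).fit()
        results[name] = ResidualRegressionResult(
            rt_class=str(name), n=int(xv.size),
            slope=float(model.params[1]), intercept=float(model.params[0]),
            slope_stderr=float(model.bse[1]), t_statistic=float(model.tvalues[1]),
            p_value=float(model.pvalues[1]))
    return results


def regress_paired(paired: pd.DataFrame,
                   pseudocount: float = DEFAULT_PSEUDOCOUNT
                   ) -> dict[str, ResidualRegressionResult]:
    """Convenience: residuals + per-class regression from a paired table."""
    res = compute_residuals(paired, pseudocount)
    x = np.log2(paired["signal_on"].to_numpy(float) + pseudocount)
    return fit_residual_regression(res, x, paired["rt_class"].to_numpy())


def paired_scatter_table(paired: pd.DataFrame,
                         pseudocount: float = DEFAULT_PSEUDOCOUNT) -> pd.DataFrame:
    """Per-IZ (log2 ON, log2 OFF, class, identity-line deviation) for plotting."""
    out = pd.DataFrame({
        "rt_class": paired["rt_class"],
        "log2_on": np.log2(paired["signal_on"].to_numpy(float) + pseudocount),
        "log2_off": np.log2(paired["signal_off"].to_numpy(float) + pseudocount),
    })
    out["identity_deviation"] = out["log2_on"] - out["log2_off"]
    present = set(out["rt_class"])
    for cls in RT_CLASSES:
        if cls not in present:
            warnings.warn(f"no IZs of class {cls} in paired table; omitted")
    return out


def null_slope_calibration(n_izs: int = 100, n_replicates: int = 1000,
                           sigma: float = 0.3, alpha: float = 0.05,
                           seed: int = 17) -> float:
    """Rejection rate of the slope test under the null.

    OFF = ON x multiplicative noise with no class structure; the predictor is
    the noise-free log2 ON signal, so residuals are independent of it and the
    test should reject at close to ``alpha``. Returns the observed rate.
    """
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_replicates):
        x = rng.normal(2.0, 1.0, n_izs)          # log2 ON
        residual = rng.normal(0.0, sigma, n_izs)  # -log2(noise), independent of x
        result = fit_residual_regression(residual, x)["all"]
        rejections += result.p_value < alpha
    return rejections / n_replicates


def _ols_slope(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Slope, intercept, slope stderr by the normal equations (fast path)."""
    n = x.size
    xm, ym = x.mean(), y.mean()
    sxx = np.sum((x - xm) ** 2)
    slope = np.sum((x - xm) * (y - ym)) / sxx
    intercept = ym - slope * xm
    resid = y - intercept - slope * x
    s2 = np.sum(resid ** 2) / (n - 2)
    return float(slope), float(intercept), float(np.sqrt(s2 / sxx))
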