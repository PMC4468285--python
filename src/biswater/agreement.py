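"""Method-agreement statistics for body-water predictors.

Implements the comparison battery used to score impedance-based TBW
predictors against dilution reference volumes:

* Pearson product-moment correlation r_p,
* Lin concordance correlation r_c = 2 s_xy / (s_x^2 + s_y^2 + (x_bar - y_bar)^2)
  with n-divisor moments, which penalises location and scale shift on top
  of scatter,
* SEE, the standard error of estimate sqrt(RSS/(n-2)) from the ordinary
  least-squares regression of reference on predicted,
* Bland-Altman limits of agreement: differences d_i = reference - predicted
  (positive bias = under-prediction), bias = mean(d), LoA = bias +/- 2 SD
  (literal 2, not 1.96), in litres and as percentages of the reference
  volume, with a trend correlation of d against the reference volume (the
  conventional d-vs-pair-mean trend is emitted alongside),
* MAPE, the mean absolute percentage error with SD and a seeded percentile
  bootstrap CI of the mean,
* sex-stratified report tables, and
* the correlation-vs-frequency sweep of the impedance quotient H^2/R(f)
  against reference TBW and ECW, including extrapolated zero/infinite
  frequency points from the fitted Cole parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .cole import ColeParams, ImpedanceSpectrum, resistance_at

__all__ = [
    "MethodAgreement",
    "FrequencySweep",
    "pearson_r",
    "lin_ccc",
    "see",
    "bland_altman",
    "mape",
    "method_agreement",
    "stratified_report",
    "frequency_sweep",
]


def _as_pair(a, b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D arrays")
    return a, b


def pearson_r(a, b) -> float:
    """Product-moment correlation; rejects n < 3 or zero-variance input."""
    a, b = _as_pair(a, b)
    if a.size < 3:
        raise ValueError(f"need n >= 3, got n={a.size}")
    if np.var(a) == 0 or np.var(b) == 0:
        raise ValueError("zero variance: correlation undefined")
    return float(stats.pearsonr(a, b).statistic)


def lin_ccc(reference, predicted) -> float:
    """Lin concordance correlation with n-divisor (biased) moments."""
    x, y = _as_pair(reference, predicted)
    if x.size < 3:
        raise ValueError(f"need n >= 3, got n={x.size}")
    sx2 = np.var(x)
    sy2 = np.var(y)
    if sx2 == 0 or sy2 == 0:
        raise ValueError("zero variance: concordance undefined")
    sxy = np.mean((x - x.mean()) * (y - y.mean()))
    return float(2.0 * sxy / (sx2 + sy2 + (x.mean() - y.mean()) ** 2))


def see(reference, predicted) -> float:
    """Standard error of estimate from OLS of reference on predicted."""
    x, y = _as_pair(predicted, reference)  # regress reference (y) on predicted (x)
    if x.size < 3:
        raise ValueError(f"need n >= 3, got n={x.size}")
    if np.var(x) == 0:
        raise ValueError("zero variance in predictor")
    slope, intercept = np.polyfit(x, y, 1)
    rss = float(np.sum((y - (slope * x + intercept)) ** 2))
    return math.sqrt(rss / (x.size - 2))


@dataclass(frozen=True)
class BlandAltman:
    bias_l: float
    sd_l: float
    loa_l: tuple[float, float]
    bias_pct: float
    sd_pct: float
    loa_pct: tuple[float, float]
    trend_r: float
    trend_p: float
    trend_r_mean: float  # classical variant: d vs pair mean
    trend_p_mean: float


def bland_altman(reference, predicted) -> BlandAltman:
    """Limits of agreement bias +/- 2 SD, absolute (L) and % of reference."""
    ref, pred = _as_pair(reference, predicted)
    if ref.size < 3:
        raise ValueError(f"need n >= 3, got n={ref.size}")
    d = ref - pred
    dpct = 100.0 * d / ref
    bias, sd = float(d.mean()), float(d.std())
    bias_pct, sd_pct = float(dpct.mean()), float(dpct.std())
    if np.var(d) > 0 and np.var(ref) > 0:
        tr = stats.pearsonr(d, ref)
        trm = stats.pearsonr(d, (ref + pred) / 2.0)
        trend = (float(tr.statistic), float(tr.pvalue))
        trend_mean = (float(trm.statistic), float(trm.pvalue))
    else:
        trend = (0.0, 1.0)
        trend_mean = (0.0, 1.0)
    return BlandAltman(
        bias_l=bias,
        sd_l=sd,
        loa_l=(bias - 2 * sd, bias + 2 * sd),
        bias_pct=bias_pct,
        sd_pct=sd_pct,
        loa_pct=(bias_pct - 2 * sd_pct, bias_pct + 2 * sd_pct),
        trend_r=trend[0],
        trend_p=trend[1],
        trend_r_mean=trend_mean[0],
        trend_p_mean=trend_mean[1],
    )


def mape(
    reference, predicted, n_boot: int = 2000, seed: int = 0
) -> tuple[float, float, tuple[float, float]]:
    """(MAPE %, SD of APE, 95% percentile-bootstrap CI of the mean)."""
    ref, pred = _as_pair(reference, predicted)
    if ref.size < 1 or np.any(ref <= 0):
        raise ValueError("reference values must be positive and non-empty")
    ape = 100.0 * np.abs(pred - ref) / ref
    m, sd = float(ape.mean()), float(ape.std())
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, ape.size, size=(n_boot, ape.size))
    boot_means = ape[idx].mean(axis=1)
    lo, hi = np.percentile(boot_means, [2.5, 97.5])
    return m, sd, (float(lo), float(hi))


@dataclass(frozen=True)
class MethodAgreement:
    """Full agreement summary of one predictor against the reference."""

    method: str
    stratum: str  # "pooled" | "male" | "female"
    n: int
    mean_predicted_l: float
    sd_predicted_l: float
    bias_l: float
    sd_l: float
    loa_l: tuple[float, float]
    bias_pct: float
    sd_pct: float
    loa_pct: tuple[float, float]
    pearson_r: float
    lin_ccc: float
    see_l: float
    mape_pct: float
    mape_sd_pct: float
    mape_ci: tuple[float, float]
    mad_l: float  # mean absolute deviation, litres
    mad_sd_l: float
    trend_r: float
    trend_p: float


def method_agreement(
    method: str,
    reference,
    predicted,
    stratum: str = "pooled",
    n_boot: int = 2000,
    seed: int = 0,
) -> MethodAgreement:
    ref, pred = _as_pair(reference, predicted)
    ba = bland_altman(ref, pred)
    m, sd, ci = mape(ref, pred, n_boot=n_boot, seed=seed)
    abs_dev = np.abs(pred - ref)
    return MethodAgreement(
        method=method,
        stratum=stratum,
        n=ref.size,
        mean_predicted_l=float(pred.mean()),
        sd_predicted_l=float(pred.std(ddof=1)),
        bias_l=ba.bias_l,
        sd_l=ba.sd_l,
        loa_l=ba.loa_l,
        bias_pct=ba.bias_pct,
        sd_pct=ba.sd_pct,
        loa_pct=ba.loa_pct,
        pearson_r=pearson_r(ref, pred),
        lin_ccc=lin_ccc(ref, pred),
        see_l=see(ref, pred),
        mape_pct=m,
        mape_sd_pct=sd,
        mape_ci=ci,
        mad_l=float(abs_dev.mean()),
        mad_sd_l=float(abs_dev.std()),
        trend_r=ba.trend_r,
        trend_p=ba.trend_p,
    )


def stratified_report(
    predictions: pd.DataFrame,
    n_boot: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """Agreement statistics per method, pooled and stratified by sex.

    ``predictions`` needs columns: id, sex, method, tbw_pred_l,
    tbw_reference_l.  Rows with missing predictions are dropped per method
    (their count is reflected in the per-row n).
    """
    required = {"id", "sex", "method", "tbw_pred_l", "tbw_reference_l"}
    missing = required - set(predictions.columns)
    if missing:
        raise ValueError(f"predictions table missing columns: {sorted(missing)}")
    rows = []
    for method, grp in predictions.groupby("method", sort=False):
        grp = grp.dropna(subset=["tbw_pred_l"])
        strata: list[tuple[str, pd.DataFrame]] = [("pooled", grp)]
        strata += [(sex, sub) for sex, sub in grp.groupby("sex", sort=False)]
        for stratum, sub in strata:
            if len(sub) < 3:
                continue
            ma = method_agreement(
                method,
                sub["tbw_reference_l"].to_numpy(),
                sub["tbw_pred_l"].to_numpy(),
                stratum=stratum,
                n_boot=n_boot,
                seed=seed,
            )
            row = asdict(ma)
            for key in ("loa_l", "loa_pct", "mape_ci"):
                lo, hi = row.pop(key)
                row[f"{key}_lower"], row[f"{key}_upper"] = lo, hi
            rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class FrequencySweep:
    """Pearson r of H^2/R(f) with reference TBW and ECW per frequency.

    ``frequencies`` holds the measured grid; the extrapolated points are
    carried separately (``r_tbw_zero`` etc. computed from fitted R0/Rinf).
    """

    frequencies: np.ndarray
    r_tbw: np.ndarray
    r_ecw: np.ndarray
    r_tbw_zero: float
    r_tbw_inf: float
    r_ecw_zero: float
    r_ecw_inf: float

    @property
    def argmax_tbw_hz(self) -> float:
        return float(self.frequencies[int(np.argmax(self.r_tbw))])

    @property
    def argmax_ecw_hz(self) -> float:
        return float(self.frequencies[int(np.argmax(self.r_ecw))])

    def to_frame(self) -> pd.DataFrame:
        """Sweep as a table with sentinel rows for 0 and infinite frequency."""
        df = pd.DataFrame(
            {"frequency_hz": self.frequencies, "r_tbw": self.r_tbw, "r_ecw": self.r_ecw}
        )
        ends = pd.DataFrame(
            {
                "frequency_hz": [0.0, math.inf],
                "r_tbw": [self.r_tbw_zero, self.r_tbw_inf],
                "r_ecw": [self.r_ecw_zero, self.r_ecw_inf],
            }
        )
        return pd.concat([ends.iloc[:1], df, ends.iloc[1:]], ignore_index=True)


def frequency_sweep(
    heights_cm,
    spectra: list[ImpedanceSpectrum],
    cole_fits: list[ColeParams],
    reference_tbw_l,
    reference_ecw_l,
) -> FrequencySweep:
    """Correlation of the impedance quotient with reference volumes vs frequency.

    All spectra must share one frequency grid.  The zero- and
    infinite-frequency points use the fitted R0 and Rinf.
    """
    h = np.asarray(heights_cm, dtype=float)
    tbw = np.asarray(reference_tbw_l, dtype=float)
    ecw = np.asarray(reference_ecw_l, dtype=float)
    n = h.size
    if not (len(spectra) == len(cole_fits) == tbw.size == ecw.size == n):
        raise ValueError("all per-subject inputs must have equal length")
    if n < 3:
        raise ValueError(f"need >= 3 subjects for a correlation sweep, got {n}")
    grid = spectra[0].frequencies
    for sp in spectra[1:]:
        if not np.array_equal(sp.frequencies, grid):
            raise ValueError("all spectra must share one frequency grid")

    r_mat = np.stack([sp.r_ohm for sp in spectra])  # (n, n_freq)
    quot = h[:, None] ** 2 / r_mat
    r_tbw = np.array([pearson_r(quot[:, j], tbw) for j in range(grid.size)])
    r_ecw = np.array([pearson_r(quot[:, j], ecw) for j in range(grid.size)])

    q0 = h**2 / np.array([c.r0_ohm for c in cole_fits])
    qinf = h**2 / np.array([c.rinf_ohm for c in cole_fits])
    return FrequencySweep(
        frequencies=grid,
        r_tbw=r_tbw,
        r_ecw=r_ecw,
        r_tbw_zero=pearson_r(q0, tbw),
        r_tbw_inf=pearson_r(qinf, tbw),
        r_ecw_zero=pearson_r(q0, ecw),
        r_ecw_inf=pearson_r(qinf, ecw),
    )
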