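"""Calibration of dung density against cumulative grazing intensity.

The proxy premise: dung density observed in month m reflects the grazing
intensity accumulated over the preceding months.  This module builds the
(dung month, accumulation window) pairing scheme, fits ordinary
least-squares relationships per pair, regresses the resulting R^2 values
on window length k (the suitability-vs-accumulation trend), compares
identification accuracy between flight heights, and inverts a fitted
calibration to predict intensity from density.

Intensities are in yak-hours per m^2 and densities in pats per m^2, so a
calibration slope has units pats per yak-hour.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .geometry import Footprint
from .kde import GrazingIntensityRaster, month_label, sample_intensity_at


@dataclass(frozen=True)
class PairingScheme:
    """All accumulation windows of length k that fit in the season.

    Each pair maps a dung-census month to the window of months whose
    grazing intensity it is regressed against; the window always ends at
    the dung month.
    """

    accumulation_k: int
    pairs: tuple[tuple[int, tuple[int, int]], ...]  # (dung_month, (first, last))


@dataclass
class CalibrationResult:
    """OLS fit of dung density on cumulative grazing intensity."""

    k: int
    dung_month: int
    n_points: int
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    residual_sd: float
    degenerate: bool = False
    note: str = ""

    @property
    def window(self) -> tuple[int, int]:
        return (self.dung_month - self.k + 1, self.dung_month)


@dataclass(frozen=True)
class AccuracyRecord:
    """One ground-validation sample: counted vs detected dung pats."""

    validation_area_id: int
    flight_height_m: float
    ground_truth_count: int
    detected_count: int

    @property
    def accuracy_fraction(self) -> float:
        if self.ground_truth_count == 0:
            return 1.0 if self.detected_count == 0 else np.nan
        return self.detected_count / self.ground_truth_count


def dung_density(count: float, area_m2: float) -> float:
    """Pats per square metre within a validation area or footprint."""
    if area_m2 <= 0:
        raise ValueError("area must be > 0")
    if count < 0:
        raise ValueError("count must be >= 0")
    return count / area_m2


def enumerate_pairs(k: int, available_months: list[int],
                    exclude: set[tuple[int, int]] | None = None) -> PairingScheme:
    """Windows of length k ending at each feasible dung month.

    ``available_months`` is the ordered season (e.g. May..October as
    5..10).  ``exclude`` drops specific (dung_month, k) pairings, e.g. the
    June same-month pairing, without changing the enumeration rule.
    """
    months = sorted(available_months)
    if not 1 <= k <= len(months):
        raise ValueError(f"k={k} outside 1..{len(months)}")
    exclude = exclude or set()
    pairs = []
    for m in months:
        first = m - k + 1
        if first >= months[0] and all(mm in months for mm in range(first, m + 1)):
            if (m, k) not in exclude:
                pairs.append((m, (first, m)))
    return PairingScheme(accumulation_k=k, pairs=tuple(pairs))


def fit_relationship(densities, intensities, k: int = 0,
                     dung_month: int = 0) -> CalibrationResult:
    """OLS of dung density on cumulative grazing intensity.

    Returns slope, intercept, R^2 and the F-test p-value.  Zero variance
    in the intensities is an error; zero variance in the densities (e.g.
    all-zero late-season sites) yields a flagged degenerate result with
    R^2 = 0 and an undefined p-value.
    """
    y = np.asarray(densities, dtype=float)
    x = np.asarray(intensities, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise ValueError("densities and intensities must be equal-length vectors")
    n = len(y)
    if n < 3:
        raise ValueError("at least 3 points are required for a fit")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in intensities; nothing to regress on")
    if np.ptp(y) == 0:
        return CalibrationResult(k=k, dung_month=dung_month, n_points=n,
                                 slope=0.0, intercept=float(y[0]),
                                 r_squared=0.0, p_value=np.nan,
                                 residual_sd=0.0, degenerate=True,
                                 note="zero variance in densities")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return CalibrationResult(
        k=k, dung_month=dung_month, n_points=n,
        slope=float(model.params[1]), intercept=float(model.params[0]),
        r_squared=float(model.rsquared), p_value=float(model.f_pvalue),
        residual_sd=float(np.sqrt(model.mse_resid)))


@dataclass
class TrendResult:
    """OLS of per-pair R^2 on accumulation length k."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n_points: int
    excluded_degenerate: int = 0


def r2_trend(results: list[CalibrationResult]) -> TrendResult:
    """Does proxy quality improve with dung accumulation time?

    Regresses the R^2 of each (dung month, window) fit on its window
    length k; degenerate fits are excluded rather than entered as zero.
    """
    usable = [r for r in results if not r.degenerate]
    n_deg = len(results) - len(usable)
    if len(usable) < 3:
        raise ValueError("need at least 3 non-degenerate fits for a trend")
    ks = np.array([r.k for r in usable], dtype=float)
    r2 = np.array([r.r_squared for r in usable], dtype=float)
    if np.ptp(ks) == 0:
        raise ValueError("all fits share one accumulation length; no trend")
    model = sm.OLS(r2, sm.add_constant(ks)).fit()
    return TrendResult(slope=float(model.params[1]),
                       intercept=float(model.params[0]),
                       r_squared=float(model.rsquared),
                       p_value=float(model.f_pvalue),
                       n_points=len(usable), excluded_degenerate=n_deg)


@dataclass
class AccuracyComparison:
    """Outcome of the flight-height accuracy comparison."""

    test_name: str            # "anova" or "rank-sum"
    statistic: float
    p_value: float
    shapiro_p: tuple[float, float]
    levene_p: float
    group_means: tuple[float, float]
    note: str = ""


def compare_accuracy(records_2m, records_20m, alpha: float = 0.05,
                     arcsine: bool = False) -> AccuracyComparison:
    """Test whether identification accuracy differs between flight heights.

    Accuracy fractions per validation sample are first checked for
    normality (Shapiro-Wilk per group) and homogeneity of variances
    (Levene); if both hold at ``alpha``, a one-way ANOVA is run, otherwise
    a rank-sum (Mann-Whitney) fallback, and the path taken is reported.
    Fractions are analysed untransformed by default; ``arcsine`` applies
    the arcsine-square-root variance-stabilising transform.
    """
    def _fractions(records):
        out = np.array([r.accuracy_fraction if isinstance(r, AccuracyRecord)
                        else float(r) for r in records])
        return np.arcsin(np.sqrt(np.clip(out, 0, 1))) if arcsine else out

    a, b = _fractions(records_2m), _fractions(records_20m)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need at least 3 records per flight height")
    note = ""

    def _shapiro(x):
        if np.ptp(x) == 0:
            return 0.0   # constant group: normality untestable, fail it
        return float(stats.shapiro(x).pvalue)

    sp = (_shapiro(a), _shapiro(b))
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        # Degenerate all-equal groups: rank-sum with tie handling.
        if float(a[0]) == float(b[0]):
            return AccuracyComparison("rank-sum", 0.0, 1.0, sp, 1.0,
                                      (a.mean(), b.mean()),
                                      note="both groups constant and equal")
        note = "both groups constant"
    lv = float(stats.levene(a, b).pvalue) if np.ptp(np.concatenate([a, b])) else 1.0
    if min(sp) > alpha and lv > alpha:
        res = stats.f_oneway(a, b)
        return AccuracyComparison("anova", float(res.statistic),
                                  float(res.pvalue), sp, lv,
                                  (a.mean(), b.mean()), note)
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    note = (note + "; " if note else "") + "assumptions failed, rank-sum fallback"
    return AccuracyComparison("rank-sum", float(res.statistic),
                              float(res.pvalue), sp, lv,
                              (a.mean(), b.mean()), note)


@dataclass
class IntensityPrediction:
    """Inverse-regression estimate of grazing intensity from dung density."""

    estimate: float
    lower: float
    upper: float
    clamped: bool = False


def predict_intensity(calibration: CalibrationResult, density: float,
                      z: float = 1.96) -> IntensityPrediction:
    """Invert a calibration: intensity = (density - intercept) / slope.

    The interval is first-order: +/- z * residual_sd / slope.  A
    non-positive slope violates the proxy premise and is refused; negative
    point estimates are clamped to zero and flagged.
    """
    if calibration.degenerate:
        raise ValueError("cannot predict from a degenerate calibration")
    if calibration.slope <= 0:
        raise ValueError("non-positive calibration slope: proxy premise violated")
    est = (density - calibration.intercept) / calibration.slope
    half = z * calibration.residual_sd / calibration.slope
    lower, upper = est - half, est + half
    clamped = False
    if est < 0:
        est, clamped = 0.0, True
    return IntensityPrediction(estimate=est, lower=max(lower, 0.0),
                               upper=max(upper, 0.0), clamped=clamped)


def calibrate_study(counts: pd.DataFrame,
                    monthly_rasters: dict[int, GrazingIntensityRaster],
                    footprints: dict[int, Footprint],
                    ks: list[int] | None = None,
                    mode: str = "footprint_mean",
                    exclude: set[tuple[int, int]] | None = None,
                    min_points: int = 3) -> pd.DataFrame:
    """Fit every (dung month, accumulation window) pair of a study.

    ``counts`` must carry waypoint_id, month, observed_count and
    footprint_area_m2; ``monthly_rasters`` the per-month intensity
    surfaces; ``footprints`` the extraction footprint per waypoint.
    Returns one row per fitted pair (plus flagged degenerate pairs).
    """
    months = sorted(monthly_rasters)
    ks = ks or list(range(1, len(months) + 1))
    from .kde import cumulative_intensity
    rows = []
    for k in ks:
        scheme = enumerate_pairs(k, months, exclude=exclude)
        for dung_month, (first, last) in scheme.pairs:
            cum = cumulative_intensity([monthly_rasters[m]
                                        for m in months if first <= m <= last])
            sub = counts[counts.month == dung_month]
            dens, intens = [], []
            for rec in sub.itertuples():
                fp = footprints[rec.waypoint_id]
                dens.append(dung_density(rec.observed_count, rec.footprint_area_m2))
                intens.append(sample_intensity_at(cum, fp, mode=mode))
            if len(dens) < min_points:
                continue
            try:
                res = fit_relationship(dens, intens, k=k, dung_month=dung_month)
            except ValueError:
                continue
            rows.append({
                "k": k, "dung_month": dung_month,
                "months": f"{month_label(first)}-{month_label(last)}"
                          if first != last else month_label(last),
                "n": res.n_points, "slope": res.slope,
                "intercept": res.intercept, "R2": res.r_squared,
                "p": res.p_value, "residual_sd": res.residual_sd,
                "degenerate": res.degenerate})
    return pd.DataFrame(rows)


def results_from_table(table: pd.DataFrame) -> list[CalibrationResult]:
    """Rebuild CalibrationResult objects from a calibrate_study table."""
    return [CalibrationResult(k=int(r.k), dung_month=int(r.dung_month),
                              n_points=int(r.n), slope=r.slope,
                              intercept=r.intercept, r_squared=r.R2,
                              p_value=r.p, residual_sd=r.residual_sd,
                              degenerate=bool(r.degenerate))
            for r in table.itertuples()]
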