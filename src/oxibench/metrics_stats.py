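"""Performance metrics and statistical comparison.

Implements the bench protocol's scoring chain:

* signal-derived percent transmission and percent modulation,
* the weighted mean SpO₂ error over a sensor bank (the headline metric,
  reported as an absolute value),
* the 3% performance-concern flag,
* per-sensor aggregation of error over a (%T, %MOD) point of the signal
  space, and
* the unequal-variance (Welch) two-sample comparison between two device
  profiles at such a point, with Satterthwaite degrees of freedom and a 95%
  confidence interval on the difference of means.

The headline metric's wording — mean SpO₂ error "expressed as absolute
value" — admits two readings: the absolute value of the weighted mean of
signed errors (default here; absolute value applied last), or the weighted
mean of per-sensor absolute errors (available via ``absolute_first=True``).
Aggregation outputs report both.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.weightstats import CompareMeans, DescrStatsW

from .errors import UndefinedResultError, ValidationError
from .bench_protocol import SweepRecord
from .virtual_oximeter import estimate_heart_rate, extract_ac_spectral

__all__ = [
    "RegionComparison",
    "percent_transmission",
    "percent_modulation",
    "mean_spo2_error",
    "flag_threshold",
    "sensor_region_mean",
    "welch_compare",
    "aggregate_metrics",
    "compare_regions",
    "comparisons_to_frame",
    "ERROR_THRESHOLD_PCT",
]

logger = logging.getLogger(__name__)

ERROR_THRESHOLD_PCT = 3.0  # mean SpO2 error above this flags a performance concern


@dataclass(frozen=True)
class RegionComparison:
    """Welch comparison of two profiles at one (%T, %MOD) point.

    ``per_sensor_errors_a/b`` are the per-sensor mean absolute SpO₂ errors
    over the point's (SpO₂ × HR) settings; the confidence interval is on
    ``mean_b − mean_a``.
    """

    t_pct: float
    mod_pct: float
    per_sensor_errors_a: tuple[float, ...]
    per_sensor_errors_b: tuple[float, ...]
    mean_a: float
    mean_b: float
    t_stat: float
    df: float
    p_value: float
    ci_low: float
    ci_high: float
    significant: bool


def percent_transmission(signal_channel: np.ndarray, reference_intensity: float = 100.0) -> float:
    """Percent transmission of a channel: 100 × mean / reference intensity.

    With the synthesis convention (intensities already in %T units and
    reference 100) this returns the DC level in %T.
    """
    x = np.asarray(signal_channel, dtype=float)
    if x.size == 0:
        raise ValidationError("signal_channel must be non-empty")
    if reference_intensity <= 0:
        raise ValidationError("reference_intensity must be > 0")
    return float(100.0 * x.mean() / reference_intensity)


def percent_modulation(signal_channel: np.ndarray, sample_rate: float) -> float:
    """Percent modulation of a channel: 100 × cardiac-band peak-to-peak / DC.

    The AC amplitude comes from the noise-robust spectral extractor at the
    detected cardiac fundamental.  Raises :class:`UndefinedResultError` when
    no cardiac component is detectable (e.g. a constant channel).
    """
    x = np.asarray(signal_channel, dtype=float)
    try:
        f0 = estimate_heart_rate(x, sample_rate)
        ac = extract_ac_spectral(x, f0, sample_rate)
    except Exception as exc:
        raise UndefinedResultError(f"no cardiac component detectable: {exc}") from exc
    dc = x.mean()
    if dc <= 0:
        raise UndefinedResultError("non-positive DC level")
    return float(100.0 * ac / dc)


def mean_spo2_error(records: list[SweepRecord], absolute_first: bool = False) -> float:
    """Weighted mean SpO₂ error for one setting over a sensor bank, in %.

    Weights are per-sensor valid-reading counts.  Default: absolute value of
    the weighted mean of signed per-sensor errors.  With
    ``absolute_first=True``: weighted mean of per-sensor absolute errors.
    Records with no valid readings carry zero weight; if none have valid
    readings the metric is undefined.
    """
    usable = [r for r in records if r.n_valid > 0]
    if not usable:
        raise UndefinedResultError("no records with valid readings")
    w = np.array([r.n_valid for r in usable], dtype=float)
    if absolute_first:
        e = np.array([r.mean_abs_error for r in usable])
        return float(np.sum(w * e) / np.sum(w))
    e = np.array([r.mean_signed_error for r in usable])
    return float(abs(np.sum(w * e) / np.sum(w)))


def flag_threshold(mean_error: float, threshold: float = ERROR_THRESHOLD_PCT) -> bool:
    """Performance-concern flag: strictly greater than the threshold.

    An error of exactly ``threshold`` is *not* flagged.
    """
    if mean_error < 0:
        raise ValidationError("mean_error must be >= 0")
    return bool(mean_error > threshold)


def sensor_region_mean(records: list[SweepRecord]) -> float:
    """One sensor's mean absolute SpO₂ error over a (%T, %MOD) point, in %.

    ``records`` must all share (t_pct, mod_pct, sensor_id, profile) and span
    the point's (SpO₂ × HR) settings.  The aggregate is the valid-count-
    weighted mean over settings of the absolute per-setting mean error.
    """
    if not records:
        raise UndefinedResultError("no records for this region")
    keys = {
        (r.setting.t_pct, r.setting.mod_pct, r.sensor_id, r.profile_name) for r in records
    }
    if len(keys) != 1:
        raise ValidationError(
            "records must share (t_pct, mod_pct, sensor_id, profile); got "
            f"{sorted(keys)}"
        )
    usable = [r for r in records if r.n_valid > 0]
    if not usable:
        raise UndefinedResultError("no records with valid readings")
    w = np.array([r.n_valid for r in usable], dtype=float)
    e = np.array([abs(r.mean_signed_error) for r in usable])
    return float(np.sum(w * e) / np.sum(w))


def welch_compare(
    errors_a,
    errors_b,
    alpha: float = 0.05,
    t_pct: float = float("nan"),
    mod_pct: float = float("nan"),
) -> RegionComparison:
    """Welch two-sample comparison of per-sensor mean errors (b vs a).

    Unequal-variance t statistic with Satterthwaite degrees of freedom,
    two-sided p value, and the (1 − alpha) confidence interval of
    ``mean_b − mean_a``, computed through statsmodels.  The degenerate case
    of two constant, equal groups returns t = 0, p = 1 and a zero-width
    interval rather than erroring.
    """
    a = np.asarray(errors_a, dtype=float)
    b = np.asarray(errors_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each group needs at least 2 values")
    mean_a, mean_b = float(a.mean()), float(b.mean())
    if a.var() == 0 and b.var() == 0 and mean_a == mean_b:
        logger.warning("degenerate Welch comparison: both groups constant and equal")
        return RegionComparison(
            t_pct=t_pct, mod_pct=mod_pct,
            per_sensor_errors_a=tuple(a), per_sensor_errors_b=tuple(b),
            mean_a=mean_a, mean_b=mean_b,
            t_stat=0.0, df=float(a.size + b.size - 2), p_value=1.0,
            ci_low=0.0, ci_high=0.0, significant=False,
        )
    cm = CompareMeans(DescrStatsW(b), DescrStatsW(a))
    t_stat, p_value, df = cm.ttest_ind(usevar="unequal")
    ci_low, ci_high = cm.tconfint_diff(alpha=alpha, usevar="unequal")
    return RegionComparison(
        t_pct=t_pct, mod_pct=mod_pct,
        per_sensor_errors_a=tuple(a), per_sensor_errors_b=tuple(b),
        mean_a=mean_a, mean_b=mean_b,
        t_stat=float(t_stat), df=float(df), p_value=float(p_value),
        ci_low=float(ci_low), ci_high=float(ci_high),
        significant=bool(p_value < alpha),
    )


def aggregate_metrics(records: list[SweepRecord]) -> pd.DataFrame:
    """Per-(setting × profile) metric table (the error-map input).

    Columns: the four grid parameters, profile, ``mean_error`` (absolute
    value of the weighted mean signed error), ``mean_error_abs_first`` (the
    alternative convention), and ``flagged`` (strict 3% threshold on the
    default convention).
    """
    from .bench_protocol import records_to_frame

    frame = records_to_frame(records)
    keys = ["t_pct", "mod_pct", "spo2_pct", "hr_bpm", "profile"]
    rows = []
    for key_vals, group in frame.groupby(keys, sort=True):
        usable = group[group["n_valid"] > 0]
        if len(usable) == 0:
            mean_err = math.nan
            mean_abs = math.nan
        else:
            w = usable["n_valid"].to_numpy(dtype=float)
            mean_err = abs(np.sum(w * usable["mean_signed_error"].to_numpy()) / w.sum())
            mean_abs = float(np.sum(w * usable["mean_abs_error"].to_numpy()) / w.sum())
        rows.append(
            dict(
                zip(keys, key_vals),
                mean_error=mean_err,
                mean_error_abs_first=mean_abs,
                flagged=(not math.isnan(mean_err)) and flag_threshold(mean_err),
            )
        )
    return pd.DataFrame(rows)


def _region_sensor_means(
    records: list[SweepRecord], t_pct: float, mod_pct: float, profile: str
) -> dict[int, float]:
    by_sensor: dict[int, list[SweepRecord]] = {}
    for r in records:
        if (
            r.profile_name == profile
            and np.isclose(r.setting.t_pct, t_pct)
            and np.isclose(r.setting.mod_pct, mod_pct)
        ):
            by_sensor.setdefault(r.sensor_id, []).append(r)
    return {sid: sensor_region_mean(rs) for sid, rs in sorted(by_sensor.items())}


DEFAULT_REGIONS = ((0.39, 0.2), (0.39, 1.1), (0.87, 1.1), (1.98, 1.1))


def compare_regions(
    records: list[SweepRecord],
    profile_a: str,
    profile_b: str,
    regions=DEFAULT_REGIONS,
    alpha: float = 0.05,
) -> list[RegionComparison]:
    """Welch-compare two profiles at each (%T, %MOD) region of interest.

    For every region, each sensor's mean absolute error over the region's
    (SpO₂ × HR) settings is computed per profile, and the two per-sensor
    samples are compared.  Regions absent from the records raise a
    :class:`ValidationError` listing the available points.
    """
    available = sorted({(r.setting.t_pct, r.setting.mod_pct) for r in records})
    out = []
    for t_pct, mod_pct in regions:
        if not any(
            np.isclose(t_pct, t) and np.isclose(mod_pct, m) for t, m in available
        ):
            raise ValidationError(
                f"region ({t_pct}, {mod_pct}) not in sweep; available: {available}"
            )
        means_a = _region_sensor_means(records, t_pct, mod_pct, profile_a)
        means_b = _region_sensor_means(records, t_pct, mod_pct, profile_b)
        out.append(
            welch_compare(
                list(means_a.values()),
                list(means_b.values()),
                alpha=alpha,
                t_pct=t_pct,
                mod_pct=mod_pct,
            )
        )
    return out


def comparisons_to_frame(comparisons: list[RegionComparison]) -> pd.DataFrame:
    """Tabular per-region comparison (the two-profile comparison table)."""
    return pd.DataFrame(
        {
            "t_pct": [c.t_pct for c in comparisons],
            "mod_pct": [c.mod_pct for c in comparisons],
            "mean_error_a": [c.mean_a for c in comparisons],
            "mean_error_b": [c.mean_b for c in comparisons],
            "t_stat": [c.t_stat for c in comparisons],
            "df": [c.df for c in comparisons],
            "p_value": [c.p_value for c in comparisons],
            "ci_low": [c.ci_low for c in comparisons],
            "ci_high": [c.ci_high for c in comparisons],
            "significant": [c.significant for c in comparisons],
        }
    )
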