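"""Technical validation of RT-qPCR assays.

Standard-curve fitting on serial cDNA dilutions, amplification-efficiency
estimation from the slope (E% = (10^(-1/slope) - 1) * 100; a slope of
-3.3219 cycles per log10 dilution is perfect doubling, 100%), assessment of
the linear dynamic range, intra-/inter-assay replicate variation, and the
acceptance gate requiring a 5-log dynamic range with efficiency inside
[90%, 110%].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "DilutionSeries",
    "StandardCurveFit",
    "ReplicateSet",
    "fit_standard_curve",
    "assess_dynamic_range",
    "replicate_cv",
    "qc_gate",
    "efficiency_from_slope",
]

PERFECT_DOUBLING_SLOPE = -1.0 / np.log10(2.0)  # -3.3219 cycles / log10 dilution


@dataclass
class DilutionSeries:
    """Serial-dilution Cq measurements for one assay.

    ``points`` maps log10 dilution (e.g. -1 .. -5 for a 5-log series) to the
    replicate Cq values measured at that level; NaN marks a replicate that
    failed to amplify.
    """

    gene: str
    points: dict[float, list[float]]

    def __post_init__(self) -> None:
        for level, cqs in self.points.items():
            if any(np.isfinite(c) and c <= 0 for c in cqs):
                raise ValueError(f"{self.gene}: non-positive Cq at level {level}")

    def levels(self) -> list[float]:
        """Dilution levels from least to most dilute (descending log10)."""
        return sorted(self.points, reverse=True)

    def level_mean(self, level: float) -> float:
        cqs = np.asarray(self.points[level], dtype=float)
        cqs = cqs[np.isfinite(cqs)]
        return float(cqs.mean()) if cqs.size else np.nan

    def fully_amplified(self, level: float) -> bool:
        cqs = np.asarray(self.points[level], dtype=float)
        return bool(cqs.size and np.isfinite(cqs).all())


@dataclass
class StandardCurveFit:
    gene: str
    slope: float                   # cycles per log10 dilution unit
    intercept: float               # cycles at 10^0
    r_squared: float
    efficiency_percent: float      # NaN when slope >= 0
    efficiency_valid: bool
    n_levels: int
    n_logs_linear: int | None = None
    dynamic_range_ok: bool | None = None


@dataclass
class ReplicateSet:
    gene: str
    run_id: str
    cq_values: list[float] = field(default_factory=list)

    @property
    def cv_percent(self) -> float:
        return replicate_cv(self.cq_values)


def efficiency_from_slope(slope: float) -> float:
    """Amplification efficiency in percent from the standard-curve slope."""
    if not np.isfinite(slope) or slope >= 0:
        return np.nan
    return float((10.0 ** (-1.0 / slope) - 1.0) * 100.0)


def fit_standard_curve(
    series: DilutionSeries,
    use_level_means: bool = True,
) -> StandardCurveFit:
    """Ordinary least squares of Cq against log10 dilution.

    By default fits the level means (classic standard-curve practice);
    ``use_level_means=False`` fits all replicate points.  A non-negative
    slope is reported but the efficiency flagged invalid.
    """
    if use_level_means:
        x = np.array([lv for lv in series.levels()])
        y = np.array([series.level_mean(lv) for lv in series.levels()])
    else:
        pairs = [
            (lv, c)
            for lv in series.levels()
            for c in series.points[lv]
            if np.isfinite(c)
        ]
        x = np.array([p[0] for p in pairs])
        y = np.array([p[1] for p in pairs])
    keep = np.isfinite(y)
    x, y = x[keep], y[keep]
    if np.unique(x).size < 3:
        raise ValueError(f"{series.gene}: need >=3 dilution levels with data")
    res = stats.linregress(x, y)
    eff = efficiency_from_slope(res.slope)
    return StandardCurveFit(
        gene=series.gene,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        efficiency_percent=eff,
        efficiency_valid=bool(np.isfinite(eff)),
        n_levels=int(np.unique(x).size),
    )


def assess_dynamic_range(
    series: DilutionSeries,
    r2_min: float = 0.98,
    max_abs_residual: float = 0.5,
) -> tuple[int, bool]:
    """Largest span of dilution levels over which the assay stays linear.

    Starting from the full series, the span passes when every level has all
    replicates amplified, the fit R^2 is at least ``r2_min``, and no
    level-mean residual exceeds ``max_abs_residual`` cycles; otherwise the
    most dilute level is dropped and the check repeated.  Returns
    (number of levels in the passing span, True) or, once fewer than 3 levels
    remain, the observed span with a failure flag.
    """
    levels = series.levels()
    while len(levels) >= 3:
        sub = DilutionSeries(series.gene, {lv: series.points[lv] for lv in levels})
        if all(sub.fully_amplified(lv) for lv in levels):
            fit = fit_standard_curve(sub)
            means = np.array([sub.level_mean(lv) for lv in levels])
            resid = means - (fit.intercept + fit.slope * np.array(levels))
            if fit.r_squared >= r2_min and np.abs(resid).max() <= max_abs_residual:
                return len(levels), True
        levels = levels[:-1]  # drop the most dilute level
    return len(levels), False


def replicate_cv(cq_values) -> float:
    """CV% of replicate Cq values: 100 * sample SD / mean.

    For inter-assay variation the default is to pool every replicate across
    runs before computing the CV.
    """
    x = np.asarray(list(cq_values), dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 2:
        raise ValueError("replicate CV needs at least 2 values")
    return float(100.0 * x.std(ddof=1) / x.mean())


def pooled_replicate_cv(sets: list[ReplicateSet]) -> float:
    """Inter-assay CV: all replicate values pooled across runs."""
    pooled = [c for s in sets for c in s.cq_values]
    return replicate_cv(pooled)


def qc_gate(
    fits: dict[str, StandardCurveFit],
    efficiency_min: float = 90.0,
    efficiency_max: float = 110.0,
    min_logs: int = 5,
) -> dict[str, dict]:
    """Accept assays with >= ``min_logs`` linear range and efficiency in range.

    The efficiency interval is inclusive at both ends.  Each gene gets
    ``{"pass": bool, "reasons": [...]}`` where reasons name every violated
    condition ("efficiency", "dynamic_range").
    """
    out = {}
    for gene, fit in fits.items():
        reasons = []
        eff = fit.efficiency_percent
        if not (np.isfinite(eff) and efficiency_min <= eff <= efficiency_max):
            reasons.append("efficiency")
        n_logs = fit.n_logs_linear if fit.n_logs_linear is not None else fit.n_levels
        if n_logs < min_logs or fit.dynamic_range_ok is False:
            reasons.append("dynamic_range")
        out[gene] = {"pass": not reasons, "reasons": reasons}
    return out
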