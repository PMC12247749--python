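"""Experiment-level statistics: event rates, treatment-window analysis via
hyper-tangent fits, distribution summaries, and variance tests."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy import optimize, stats

from .control import ACTIVE, CEASED
from .simulate import SonicationRecord

__all__ = [
    "TanhFit",
    "FitError",
    "EmptyWindowError",
    "ArmSummary",
    "ExperimentSummary",
    "event_rate",
    "prediction_rate",
    "percent_reduction",
    "fit_tanh",
    "treatment_window",
    "distribution_stats",
    "variance_tests",
    "VarianceTests",
    "window_analysis",
    "WindowResult",
    "summarize_experiment",
]


class FitError(RuntimeError):
    pass


class EmptyWindowError(ValueError):
    pass


RecordsOrFlags = Union[Sequence[SonicationRecord], Sequence[bool], np.ndarray]


def _event_flags(records: RecordsOrFlags) -> np.ndarray:
    if len(records) == 0:
        raise ValueError("empty input")
    if isinstance(records[0], SonicationRecord):
        return np.concatenate([r.events for r in records])  # type: ignore[union-attr]
    return np.asarray(records, dtype=bool)


def event_rate(records: RecordsOrFlags) -> tuple[int, int, float]:
    """Exact event count, total pulse count, and percent (2 decimals)."""
    flags = _event_flags(records)
    count = int(flags.sum())
    total = int(flags.size)
    return count, total, round(100.0 * count / total, 2)


def prediction_rate(records: Sequence[SonicationRecord]) -> tuple[int, int, float]:
    """Positive-prediction count over pulses where the model ran."""
    preds = np.concatenate(
        [np.array([p.prediction for p in r.pulses]) for r in records]
    )
    ran = np.isfinite(preds)
    if not ran.any():
        raise ValueError("no pulses with model predictions")
    count = int((preds[ran] >= 0.5).sum())
    total = int(ran.sum())
    return count, total, round(100.0 * count / total, 2)


def percent_reduction(rate_ref: float, rate_new: float) -> float:
    """``100 * (rate_ref - rate_new) / rate_ref`` (round for reporting)."""
    if rate_ref <= 0:
        raise ValueError("reference rate must be > 0")
    return 100.0 * (rate_ref - rate_new) / rate_ref


@dataclass
class TanhFit:
    """Parameters of ``y = a + b * tanh((x - c) / d)``; c is the inflection."""

    a: float
    b: float
    c: float
    d: float
    residual: float
    degenerate: bool = False

    @property
    def inflection(self) -> float:
        return self.c

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.a + self.b * np.tanh((np.asarray(x) - self.c) / self.d)


def _tanh_model(x: np.ndarray, a: float, b: float, c: float, d: float) -> np.ndarray:
    return a + b * np.tanh((x - c) / d)


def fit_tanh(
    x: Sequence[float],
    y: Sequence[float],
    n_starts: int = 8,
    seed: int = 0,
) -> TanhFit:
    """Least-squares hyper-tangent fit with multi-start initialization.

    Starts span the x quantiles for the inflection and a range of widths;
    the best (lowest SSE) converged start wins.  A fit whose amplitude is
    negligible against the data spread is flagged degenerate (the
    inflection is then unidentifiable).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 5:
        raise ValueError("need at least 5 points")
    span = float(x.max() - x.min())
    if span <= 0:
        raise ValueError("x values must have positive spread")
    y_spread = float(y.max() - y.min())

    rng = np.random.default_rng(seed)
    best: Optional[tuple[float, np.ndarray]] = None
    failures = []
    quantiles = np.linspace(0.15, 0.85, n_starts)
    for i, q in enumerate(quantiles):
        c0 = float(np.quantile(x, q))
        d0 = span * float(rng.uniform(0.1, 0.5)) if i else span / 4.0
        p0 = [float(y.mean()), max(y_spread / 2.0, 1e-6), c0, d0]
        try:
            popt, _ = optimize.curve_fit(
                _tanh_model,
                x,
                y,
                p0=p0,
                bounds=([-np.inf, -np.inf, -np.inf, 1e-12], np.inf),
                maxfev=20000,
            )
        except (RuntimeError, ValueError) as exc:
            failures.append(str(exc))
            continue
        sse = float(np.sum((y - _tanh_model(x, *popt)) ** 2))
        if best is None or sse < best[0]:
            best = (sse, popt)
    if best is None:
        raise FitError(
            f"tanh fit failed for all {n_starts} starts: {failures[-1] if failures else 'no starts'}"
        )
    sse, (a, b, c, d) = best
    scale = y_spread if y_spread > 0 else 1.0
    degenerate = abs(b) < 1e-3 * scale or y_spread == 0.0
    return TanhFit(
        a=float(a), b=float(b), c=float(c), d=float(d),
        residual=sse, degenerate=degenerate,
    )


def treatment_window(
    lower_bound_mpa: float, fit: TanhFit
) -> tuple[float, float, float]:
    """Window (width, lower, upper): upper bound is the fit's inflection."""
    upper = fit.inflection
    if lower_bound_mpa >= upper:
        raise EmptyWindowError(
            f"lower bound {lower_bound_mpa} >= inflection {upper}"
        )
    return upper - lower_bound_mpa, lower_bound_mpa, upper


def distribution_stats(levels: Sequence[float]) -> tuple[float, float, float]:
    """Sample mean, sample SD (n-1), adjusted Fisher-Pearson skewness."""
    x = np.asarray(levels, dtype=float)
    if x.size < 3:
        raise ValueError("need n >= 3 for skewness")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    if sd == 0:
        raise ValueError("skewness undefined for a constant sample")
    n = x.size
    g1 = float(np.mean(((x - mean) / x.std(ddof=0)) ** 3))
    skew = math.sqrt(n * (n - 1)) / (n - 2) * g1
    return mean, sd, skew


@dataclass(frozen=True)
class VarianceTests:
    f_stat: float
    f_p: float
    levene_stat: float
    levene_p: float


def variance_tests(
    group_a: Sequence[float], group_b: Sequence[float]
) -> VarianceTests:
    """Two-sided variance F-test plus the median-centred (Brown-Forsythe)
    Levene test, implemented as one-way ANOVA on absolute deviations."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        raise ValueError("zero variance in both groups")
    f = va / vb if vb > 0 else math.inf
    dfa, dfb = a.size - 1, b.size - 1
    if math.isinf(f):
        f_p = 0.0
    else:
        cdf = stats.f.cdf(f, dfa, dfb)
        f_p = 2.0 * min(cdf, 1.0 - cdf)

    # Brown-Forsythe: ANOVA on |x - median| with median centring
    za = np.abs(a - np.median(a))
    zb = np.abs(b - np.median(b))
    n1, n2 = za.size, zb.size
    zbar = (za.sum() + zb.sum()) / (n1 + n2)
    ssb = n1 * (za.mean() - zbar) ** 2 + n2 * (zb.mean() - zbar) ** 2
    ssw = ((za - za.mean()) ** 2).sum() + ((zb - zb.mean()) ** 2).sum()
    df1, df2 = 1, n1 + n2 - 2
    if ssw == 0:
        lev_stat, lev_p = math.inf, 0.0
    else:
        lev_stat = (ssb / df1) / (ssw / df2)
        lev_p = float(stats.f.sf(lev_stat, df1, df2))
    return VarianceTests(
        f_stat=float(f), f_p=float(f_p),
        levene_stat=float(lev_stat), levene_p=lev_p,
    )


@dataclass
class ArmSummary:
    label: str
    n_records: int
    total_pulses: int
    event_count: int
    event_rate_percent: float
    prediction_count: Optional[int]
    prediction_rate_percent: Optional[float]
    h7_mean_db: float
    h7_sd_db: float
    h7_skewness: float
    mean_pressure_mpa: float
    max_pressure_mpa: float
    mean_ktrans: float


@dataclass
class ExperimentSummary:
    arms: list[ArmSummary] = field(default_factory=list)
    window_lower_mpa: Optional[float] = None
    window_upper_mpa: Optional[float] = None
    window_width_mpa: Optional[float] = None

    def arm(self, label: str) -> ArmSummary:
        for a in self.arms:
            if a.label == label:
                return a
        raise KeyError(label)


def _therapeutic_mask(record: SonicationRecord) -> np.ndarray:
    return np.array([p.phase in (ACTIVE, CEASED) for p in record.pulses])


def _arm_summary(label: str, records: Sequence[SonicationRecord]) -> ArmSummary:
    count, total, pct = event_rate(records)
    h7, pressures, ktr = [], [], []
    for r in records:
        mask = _therapeutic_mask(r)
        frames = r.frames
        h7.extend(frames[i].harmonic_db[5] for i in np.flatnonzero(mask))
        if mask.any():
            pressures.append(r.pressures[mask])
        ktr.append(r.ktrans)
    h7 = np.asarray(h7)
    if h7.size >= 3 and h7.std(ddof=1) > 0:
        h7_mean, h7_sd, h7_skew = distribution_stats(h7)
    elif h7.size:
        h7_mean, h7_sd, h7_skew = float(h7.mean()), 0.0, float("nan")
    else:
        h7_mean = h7_sd = h7_skew = float("nan")
    allp = np.concatenate(pressures) if pressures else np.array([np.nan])
    try:
        pc, pt, pr = prediction_rate(records)
        pred_count, pred_rate = pc, pr
    except ValueError:
        pred_count, pred_rate = None, None
    return ArmSummary(
        label=label,
        n_records=len(records),
        total_pulses=total,
        event_count=count,
        event_rate_percent=pct,
        prediction_count=pred_count,
        prediction_rate_percent=pred_rate,
        h7_mean_db=float(h7_mean),
        h7_sd_db=float(h7_sd),
        h7_skewness=float(h7_skew),
        mean_pressure_mpa=float(np.nanmean(allp)),
        max_pressure_mpa=float(np.nanmax(allp)),
        mean_ktrans=(
            float(np.nanmean(ktr)) if not np.all(np.isnan(ktr)) else float("nan")
        ),
    )


def summarize_experiment(
    arms: dict[str, Sequence[SonicationRecord]]
) -> ExperimentSummary:
    """Per-arm counts, rates, harmonic statistics, and pressure summary."""
    if len(arms) == 0:
        raise ValueError("need at least one arm")
    return ExperimentSummary(
        arms=[_arm_summary(label, recs) for label, recs in arms.items()]
    )


@dataclass
class WindowResult:
    lower_mpa: float
    upper_mpa: float
    width_mpa: float
    fit: TanhFit


def window_analysis(
    pressures_mpa: Sequence[float],
    broadband_levels_db: Sequence[float],
    ktrans: Optional[Sequence[float]] = None,
    background_ktrans: Optional[Sequence[float]] = None,
    lower_bound_mpa: Optional[float] = None,
    seed: int = 0,
) -> WindowResult:
    """Treatment window from per-run exposure summaries.

    The upper bound is the inflection of a tanh fit of broadband level vs
    pressure.  The lower bound is either given directly or computed as the
    smallest pressure whose permeability surrogate exceeds the background
    mean + 2 SD.
    """
    x = np.asarray(pressures_mpa, dtype=float)
    fit = fit_tanh(x, np.asarray(broadband_levels_db, dtype=float), seed=seed)
    if lower_bound_mpa is None:
        if ktrans is None or background_ktrans is None:
            raise ValueError(
                "provide lower_bound_mpa, or ktrans plus background_ktrans"
            )
        bg = np.asarray(background_ktrans, dtype=float)
        thresh = bg.mean() + 2.0 * bg.std(ddof=1)
        k = np.asarray(ktrans, dtype=float)
        above = x[k > thresh]
        if above.size == 0:
            raise EmptyWindowError("no exposure raised the surrogate above background")
        lower_bound_mpa = float(above.min())
    width, lower, upper = treatment_window(lower_bound_mpa, fit)
    return WindowResult(lower_mpa=lower, upper_mpa=upper, width_mpa=width, fit=fit)
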