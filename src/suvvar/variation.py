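"""Coefficient-of-variation estimation and extrapolation.

The core statistic: for a subset of n independent frames of reconstruction
length RL1, the coefficient of variation of an SUV metric is

    CoV% = 100 * SD / mean          (sample SD, n-1 denominator)

and, because count noise scales as the inverse square root of the
acquisition time, the CoV expected at another reconstruction length RL2 is

    SD2 = SD1 * sqrt(RL1 / RL2).

Each of the 14 default subsets therefore yields one estimate of the CoV at
the full 150 s length; their mean and spread quantify the estimator and
its uncertainty.  Extrapolation is applied to the scale-free CoV%, not the
raw SD.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .framing import FrameSchedule

__all__ = [
    "CoVEstimate",
    "StatTestResult",
    "coefficient_of_variation",
    "extrapolate_cov",
    "cov_table",
    "estimate_at_full_length",
    "cross_estimate_matrix",
    "ks_normality",
    "welch_t_test",
    "compare_table",
]


@dataclass(frozen=True)
class CoVEstimate:
    """CoV of one (metric, sphere, RL1) cell and its extrapolation to RL2."""

    metric: str
    sphere_id: int
    rl1_s: float
    n_frames: int
    mean_value: float
    sd_value: float
    cov_percent: float
    rl2_s: float
    sd2_percent: float


@dataclass(frozen=True)
class StatTestResult:
    test_name: str
    statistic: float
    p_value: float
    alpha: float = 0.05
    transform: str = "raw"
    df: float | None = None

    @property
    def reject(self) -> bool:
        return bool(self.p_value < self.alpha)


def coefficient_of_variation(values: Sequence[float]) -> tuple[float, float, float]:
    """Return (mean, sample SD, CoV%) of a set of metric values.

    Requires at least two values and a non-zero mean.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError(f"need >= 2 values for a standard deviation, got {arr.size}")
    mean = float(arr.mean())
    if mean == 0.0:
        raise ValueError("mean is zero; CoV undefined")
    sd = float(arr.std(ddof=1))
    return mean, sd, 100.0 * sd / mean


def extrapolate_cov(sd1: float, rl1_s: float, rl2_s: float) -> float:
    """Inverse-square-root-law extrapolation: SD2 = SD1 * sqrt(RL1/RL2).

    Works identically for a raw SD or a CoV% (the law is a ratio).
    """
    if sd1 < 0:
        raise ValueError("SD must be >= 0")
    if rl1_s <= 0 or rl2_s <= 0:
        raise ValueError("reconstruction lengths must be > 0")
    return sd1 * float(np.sqrt(rl1_s / rl2_s))


def _check_complete(records: pd.DataFrame, schedules: Sequence[FrameSchedule]) -> None:
    expected_rls = {s.rl_s for s in schedules}
    have = set(records["rl_s"].unique())
    missing = expected_rls - have
    if missing:
        raise ValueError(f"no SUV records for reconstruction lengths {sorted(missing)}")
    for s in schedules:
        if s.n_frames < 2:
            raise ValueError(f"schedule RL={s.rl_s} s has {s.n_frames} frame(s); need >= 2")


def cov_table(
    records: pd.DataFrame,
    schedules: Sequence[FrameSchedule],
    rl2_s: float = 150.0,
) -> pd.DataFrame:
    """Per-(metric, sphere, RL) CoV and its extrapolation to ``rl2_s``.

    ``records`` is the tidy SUV table (columns ``sphere_id, metric, rl_s,
    frame_index, value_kbq_ml``).  Raises if any (metric, sphere, RL) cell
    is missing or underpopulated.
    """
    _check_complete(records, schedules)
    n_expected = {s.rl_s: s.n_frames for s in schedules}
    rows = []
    for (metric, sphere, rl), grp in records.groupby(["metric", "sphere_id", "rl_s"], sort=True):
        if rl not in n_expected:
            continue
        if len(grp) != n_expected[rl]:
            raise ValueError(
                f"metric {metric}, sphere {sphere} mm, RL={rl} s: "
                f"{len(grp)} records, expected {n_expected[rl]}"
            )
        mean, sd, cov = coefficient_of_variation(grp["value_kbq_ml"].to_numpy())
        rows.append(
            {
                "metric": metric,
                "sphere_id": sphere,
                "rl1_s": rl,
                "n_frames": len(grp),
                "mean_value": mean,
                "sd_value": sd,
                "cov_percent": cov,
                "rl2_s": rl2_s,
                "sd2_percent": extrapolate_cov(cov, rl, rl2_s),
            }
        )
    return pd.DataFrame(rows)


def estimate_at_full_length(
    records: pd.DataFrame,
    schedules: Sequence[FrameSchedule],
    rl2_s: float = 150.0,
) -> pd.DataFrame:
    """Aggregate the per-subset extrapolations to the target length.

    Returns one row per (metric, sphere) with the number of source
    subsets, the mean extrapolated CoV% and the SD of the estimates.
    """
    table = cov_table(records, schedules, rl2_s=rl2_s)
    out = (
        table.groupby(["metric", "sphere_id"], sort=True)["sd2_percent"]
        .agg(n_estimates="size", mean_estimate="mean", sd_estimate=lambda x: x.std(ddof=1))
        .reset_index()
    )
    out["rl2_s"] = rl2_s
    return out


def cross_estimate_matrix(
    records: pd.DataFrame,
    schedules: Sequence[FrameSchedule],
) -> pd.DataFrame:
    """Leave-one-out cross-estimation between the subsets.

    For each target RL among the schedules, every *other* subset's CoV is
    extrapolated to the target, giving ``len(schedules) - 1`` estimates per
    (metric, sphere, target RL), plus their mean and SD and the directly
    measured CoV at the target.
    """
    rls = [s.rl_s for s in schedules]
    base = cov_table(records, schedules, rl2_s=rls[0])  # rl2 column unused here
    rows = []
    for (metric, sphere), grp in base.groupby(["metric", "sphere_id"], sort=True):
        cov_by_rl = dict(zip(grp["rl1_s"], grp["cov_percent"]))
        for target in rls:
            others = [rl for rl in rls if rl != target]
            est = [extrapolate_cov(cov_by_rl[rl], rl, target) for rl in others]
            rows.append(
                {
                    "metric": metric,
                    "sphere_id": sphere,
                    "target_rl_s": target,
                    "n_estimates": len(est),
                    "mean_estimate": float(np.mean(est)),
                    "sd_estimate": float(np.std(est, ddof=1)) if len(est) > 1 else 0.0,
                    "measured_cov_percent": cov_by_rl[target],
                }
            )
    return pd.DataFrame(rows)


def ks_normality(
    values: Sequence[float],
    transform: str = "raw",
    alpha: float = 0.05,
    lilliefors: bool = False,
    mean: float | None = None,
    sd: float | None = None,
) -> StatTestResult:
    """One-sample Kolmogorov–Smirnov test against a normal distribution.

    By default the reference normal uses the sample's own mean and SD
    (at least 5 values required); passing ``mean`` and ``sd`` tests
    against a fully specified normal instead.  With ``lilliefors=True``
    the p-value is Monte-Carlo calibrated for the estimated parameters
    (more powerful but not the default).
    """
    arr = np.asarray(values, dtype=float)
    fitted = mean is None or sd is None
    if fitted and arr.size < 5:
        raise ValueError(f"need >= 5 values to fit normal parameters, got {arr.size}")
    if transform == "log":
        if np.any(arr <= 0):
            raise ValueError("log transform requires strictly positive values")
        arr = np.log(arr)
    elif transform != "raw":
        raise ValueError(f"unknown transform {transform!r}")

    if fitted:
        mean, sd = arr.mean(), arr.std(ddof=1)
    if lilliefors:
        if not fitted:
            raise ValueError("lilliefors applies only to fitted parameters")
        from statsmodels.stats.diagnostic import lilliefors as _lf

        stat, p = _lf(arr, dist="norm")
    else:
        stat, p = stats.kstest(arr, "norm", args=(mean, sd))
    return StatTestResult(
        test_name="ks_normality", statistic=float(stat), p_value=float(p),
        alpha=alpha, transform=transform,
    )


def welch_t_test(a: Sequence[float], b: Sequence[float], alpha: float = 0.05) -> StatTestResult:
    """Two-sample t-test without the equal-variance assumption.

    Uses the Welch statistic with Welch–Satterthwaite degrees of freedom
    and a two-sided p-value.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs >= 2 values")
    res = stats.ttest_ind(a, b, equal_var=False)
    va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
    if va + vb == 0:
        df = float(a.size + b.size - 2)
        stat_val, p = 0.0, 1.0
    else:
        df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
        stat_val, p = float(res.statistic), float(res.pvalue)
    return StatTestResult(
        test_name="welch_t", statistic=stat_val, p_value=p, alpha=alpha, df=float(df)
    )


def _holm(pvals: np.ndarray) -> np.ndarray:
    """Holm step-down adjusted p-values."""
    m = len(pvals)
    order = np.argsort(pvals)
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * pvals[i])
        adj[i] = min(1.0, running)
    return adj


def compare_table(
    estimates_long: pd.DataFrame,
    alpha: float = 0.05,
    sphere_order: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Pairwise Welch tests on the per-subset estimate populations.

    Two families of comparisons on the ``sd2_percent`` populations from
    :func:`cov_table`: (i) adjacent sphere sizes within each metric and
    (ii) every metric pair within each sphere.  Unadjusted significance is
    flagged at ``alpha`` (no multiplicity correction); a Holm-adjusted
    column is emitted alongside for transparency, per family.
    """
    required = {"metric", "sphere_id", "sd2_percent"}
    if not required.issubset(estimates_long.columns):
        raise ValueError(f"estimates table must have columns {sorted(required)}")
    metrics = sorted(estimates_long["metric"].unique())
    spheres = list(sphere_order) if sphere_order is not None else sorted(
        estimates_long["sphere_id"].unique()
    )

    def population(metric, sphere):
        sel = estimates_long[
            (estimates_long["metric"] == metric) & (estimates_long["sphere_id"] == sphere)
        ]["sd2_percent"].to_numpy()
        if sel.size < 2:
            raise ValueError(f"incomplete estimates for metric {metric}, sphere {sphere} mm")
        return sel

    rows = []
    for metric in metrics:
        for s1, s2 in zip(spheres[:-1], spheres[1:]):
            res = welch_t_test(population(metric, s1), population(metric, s2), alpha=alpha)
            rows.append(
                {
                    "family": "adjacent_spheres",
                    "metric_a": metric,
                    "metric_b": metric,
                    "sphere_a": s1,
                    "sphere_b": s2,
                    "t": res.statistic,
                    "df": res.df,
                    "p_value": res.p_value,
                    "significant": res.reject,
                }
            )
    for sphere in spheres:
        for i, m1 in enumerate(metrics):
            for m2 in metrics[i + 1 :]:
                res = welch_t_test(population(m1, sphere), population(m2, sphere), alpha=alpha)
                rows.append(
                    {
                        "family": "metric_pairs",
                        "metric_a": m1,
                        "metric_b": m2,
                        "sphere_a": sphere,
                        "sphere_b": sphere,
                        "t": res.statistic,
                        "df": res.df,
                        "p_value": res.p_value,
                        "significant": res.reject,
                    }
                )
    out = pd.DataFrame(rows)
    out["p_holm"] = np.nan
    for family in out["family"].unique():
        sel = out["family"] == family
        out.loc[sel, "p_holm"] = _holm(out.loc[sel, "p_value"].to_numpy())
    out["significant_holm"] = out["p_holm"] < alpha
    return out
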