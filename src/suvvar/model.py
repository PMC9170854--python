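"""Model/Results interface over the variation estimator.

``SUVVariationModel`` is constructed from the long-format SUV measurement
table (or straight from frames, or from a simulation config); ``fit()``
returns a ``SUVVariationResults`` carrying the per-(metric, sphere)
estimates, their spread, the leave-one-out cross-estimation, the pairwise
significance tests and a printable summary table.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .framing import FrameSchedule, default_schedules
from .geometry import ImageVolume
from .metrics import METRIC_NAMES, compute_all_metrics
from .roi import SphereROI
from .variation import (
    compare_table,
    cov_table,
    cross_estimate_matrix,
    estimate_at_full_length,
    ks_normality,
)

__all__ = ["SUVVariationModel", "SUVVariationResults"]


class SUVVariationModel:
    """Estimator of the statistical technical variation of SUV metrics.

    Parameters
    ----------
    records : pandas.DataFrame
        Tidy SUV table with columns ``sphere_id, metric, rl_s,
        frame_index, value_kbq_ml`` — one row per sphere, metric and frame.
    schedules : sequence of FrameSchedule, optional
        The subsets the records came from; defaults to the fourteen
        standard subsets of a 150 s acquisition.
    target_rl_s : float
        Reconstruction length to which the CoV is extrapolated.
    alpha : float
        Significance level for the pairwise Welch tests.
    """

    def __init__(
        self,
        records: pd.DataFrame,
        schedules: Sequence[FrameSchedule] | None = None,
        target_rl_s: float = 150.0,
        alpha: float = 0.05,
    ):
        self.records = records
        self.schedules = list(schedules) if schedules is not None else default_schedules()
        self.target_rl_s = float(target_rl_s)
        self.alpha = float(alpha)

    @classmethod
    def from_frames(
        cls,
        frames: Mapping[float, Sequence[ImageVolume]],
        rois: Sequence[SphereROI],
        schedules: Sequence[FrameSchedule] | None = None,
        **kwargs,
    ) -> "SUVVariationModel":
        """Measure all frames with fixed ROIs, then build the model."""
        return cls(compute_all_metrics(frames, rois), schedules=schedules, **kwargs)

    @classmethod
    def from_simulation(cls, config=None, seed: int = 0, **kwargs) -> "SUVVariationModel":
        """Run the phantom simulator with a :class:`~suvvar.config.RunConfig`."""
        from .pipeline import simulate_records

        records, schedules, _ = simulate_records(config, seed=seed)
        return cls(records, schedules=schedules, **kwargs)

    def fit(self) -> "SUVVariationResults":
        cov = cov_table(self.records, self.schedules, rl2_s=self.target_rl_s)
        agg = estimate_at_full_length(self.records, self.schedules, rl2_s=self.target_rl_s)
        return SUVVariationResults(self, cov, agg)


class SUVVariationResults:
    """Fitted variation estimates.

    Attributes
    ----------
    cov_table : pandas.DataFrame
        Per (metric, sphere, source RL): n, mean, SD, CoV% and the
        extrapolated CoV% at the target RL.
    estimates : pandas.DataFrame
        Per (metric, sphere): number of source subsets, mean extrapolated
        CoV% and SD of the estimates.
    """

    def __init__(self, model: SUVVariationModel, cov: pd.DataFrame, agg: pd.DataFrame):
        self.model = model
        self.cov_table = cov
        self.estimates = agg

    def cross_estimates(self) -> pd.DataFrame:
        """Leave-one-out estimation of each subset's CoV from the others."""
        return cross_estimate_matrix(self.model.records, self.model.schedules)

    def comparisons(self) -> pd.DataFrame:
        """Welch tests between adjacent spheres and between metric pairs."""
        return compare_table(self.cov_table, alpha=self.model.alpha)

    def normality_report(self, transforms: Sequence[str] = ("raw", "log")) -> pd.DataFrame:
        """KS normality tests of every (metric, sphere, RL) value population."""
        rows = []
        for (metric, sphere, rl), grp in self.model.records.groupby(
            ["metric", "sphere_id", "rl_s"], sort=True
        ):
            vals = grp["value_kbq_ml"].to_numpy()
            if vals.size < 5:
                continue
            for tr in transforms:
                res = ks_normality(vals, transform=tr, alpha=self.model.alpha)
                rows.append(
                    {
                        "metric": metric,
                        "sphere_id": sphere,
                        "rl_s": rl,
                        "transform": tr,
                        "ks_statistic": res.statistic,
                        "p_value": res.p_value,
                        "reject_normality": res.reject,
                    }
                )
        columns = [
            "metric", "sphere_id", "rl_s", "transform", "ks_statistic", "p_value",
            "reject_normality",
        ]
        return pd.DataFrame(rows, columns=columns)

    def estimate_pivot(self) -> pd.DataFrame:
        """Metrics x spheres table of 'mean ± SD %' strings."""
        est = self.estimates.copy()
        est["cell"] = [
            f"{m:.1f} ± {s:.1f}%" for m, s in zip(est["mean_estimate"], est["sd_estimate"])
        ]
        pivot = est.pivot(index="metric", columns="sphere_id", values="cell")
        return pivot.reindex(index=[m for m in METRIC_NAMES if m in pivot.index])

    def summary(self) -> str:
        rl2 = self.model.target_rl_s
        lines = [
            "Estimated coefficient of variation of SUV metrics",
            f"target reconstruction length: {rl2:g} s; "
            f"{len(self.model.schedules)} source subsets; alpha={self.model.alpha:g}",
            "",
        ]
        pivot = self.estimate_pivot()
        header = "metric".ljust(8) + "".join(f"{c} mm".rjust(14) for c in pivot.columns)
        lines.append(header)
        for metric, row in pivot.iterrows():
            lines.append(metric.ljust(8) + "".join(str(v).rjust(14) for v in row))
        sig = self.comparisons()
        n_sig = int(sig["significant"].sum())
        lines.append("")
        lines.append(
            f"pairwise Welch tests: {n_sig}/{len(sig)} significant at alpha={self.model.alpha:g}"
        )
        return "\n".join(lines)

    def plot_cov_vs_rl(self, metric: str, ax=None):
        """CoV% against reconstruction length, one line per sphere."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        sub = self.cov_table[self.cov_table["metric"] == metric]
        for sphere, grp in sub.groupby("sphere_id"):
            grp = grp.sort_values("rl1_s")
            ax.plot(grp["rl1_s"], grp["cov_percent"], "o-", label=f"{sphere} mm")
        ax.set_xlabel("reconstruction length (s)")
        ax.set_ylabel("CoV (%)")
        ax.set_title(f"SUV{metric}")
        ax.legend()
        return ax

    def plot_estimates(self, metric: str, sphere_id: int, ax=None):
        """Per-subset extrapolated estimates with mean ± SD reference lines."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        sub = self.cov_table[
            (self.cov_table["metric"] == metric) & (self.cov_table["sphere_id"] == sphere_id)
        ].sort_values("rl1_s")
        ax.plot(sub["rl1_s"], sub["sd2_percent"], "o", label="estimate")
        row = self.estimates[
            (self.estimates["metric"] == metric) & (self.estimates["sphere_id"] == sphere_id)
        ].iloc[0]
        m, s = row["mean_estimate"], row["sd_estimate"]
        ax.axhline(m, color="red", label="mean")
        for y in (m - s, m + s):
            ax.axhline(y, color="blue", linestyle="--")
        ax.set_xlabel("source reconstruction length (s)")
        ax.set_ylabel(f"estimated CoV at {self.model.target_rl_s:g} s (%)")
        ax.set_title(f"SUV{metric}, {sphere_id} mm sphere")
        ax.legend()
        return ax
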