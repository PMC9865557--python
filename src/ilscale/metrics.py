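"""Experiment-calculation agreement statistics for solvation/partition data.

Absolute accuracy is measured by MAE, mean signed error and RMSE; ranking
power by Kendall's tau (tau-b, tie-corrected) and Pearlman's predictive
index, which weights each pair of compounds by the experimental difference

    PI = sum_{j>i} w_ij c_ij / sum_{j>i} w_ij,
    w_ij = |expt_j - expt_i|,
    c_ij = sign of (expt_j - expt_i)/(calc_j - calc_i), 0 if calc_j = calc_i;

linear association by Pearson's r.  Outlier counts report how many entries
fall outside +-threshold bands (1 and 2 kcal/mol by default for free
energies).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import UndefinedMetricError

__all__ = [
    "PairedData",
    "MetricsReport",
    "error_metrics",
    "kendall_tau",
    "pearlman_pi",
    "pearson_r",
    "outlier_counts",
    "compute_report",
    "read_paired_csv",
    "scatter_calc_expt",
]


@dataclass
class PairedData:
    """Labelled (calculated, experimental) value pairs in common units."""

    labels: list
    calc: np.ndarray
    expt: np.ndarray
    units: str = "kcal/mol"

    def __post_init__(self):
        self.calc = np.asarray(self.calc, dtype=float).ravel()
        self.expt = np.asarray(self.expt, dtype=float).ravel()
        self.labels = list(self.labels)
        if not (len(self.labels) == self.calc.size == self.expt.size):
            raise ValueError("labels, calc and expt must have equal lengths")
        if self.calc.size < 1:
            raise ValueError("empty dataset")
        if not (np.all(np.isfinite(self.calc)) and np.all(np.isfinite(self.expt))):
            raise ValueError("non-finite values in dataset")

    @property
    def n(self) -> int:
        return int(self.calc.size)

    @property
    def errors(self) -> np.ndarray:
        return self.calc - self.expt


def error_metrics(data: PairedData) -> tuple[float, float, float]:
    """(MAE, mean signed error, RMSE) of calc - expt."""
    e = data.errors
    return (
        float(np.mean(np.abs(e))),
        float(np.mean(e)),
        float(np.sqrt(np.mean(e**2))),
    )


def kendall_tau(data: PairedData) -> float:
    """Kendall's tau-b (tie-corrected) between calculation and experiment."""
    if data.n < 2:
        raise ValueError("Kendall's tau needs n >= 2")
    if np.ptp(data.calc) == 0 or np.ptp(data.expt) == 0:
        raise UndefinedMetricError("tau undefined: all values tied in one variable")
    tau = stats.kendalltau(data.calc, data.expt, variant="b").statistic
    return float(tau)


def pearlman_pi(data: PairedData) -> float:
    """Pearlman's predictive index in [-1, 1].

    Pairs with larger experimental separation weigh more; +1 means every
    experimentally-ordered pair is predicted in the right direction.
    """
    if data.n < 2:
        raise ValueError("predictive index needs n >= 2")
    if np.ptp(data.expt) == 0:
        raise UndefinedMetricError(
            "PI undefined: all experimental values equal (zero weights)"
        )
    i, j = np.triu_indices(data.n, k=1)
    de = data.expt[j] - data.expt[i]
    dc = data.calc[j] - data.calc[i]
    w = np.abs(de)
    c = np.where(dc == 0, 0.0, np.sign(de * dc))
    return float(np.sum(w * c) / np.sum(w))


def pearson_r(data: PairedData) -> float:
    """Product-moment correlation between calculation and experiment."""
    if data.n < 2:
        raise ValueError("Pearson r needs n >= 2")
    if np.std(data.calc) == 0 or np.std(data.expt) == 0:
        raise UndefinedMetricError("r undefined: zero variance in one variable")
    return float(stats.pearsonr(data.calc, data.expt).statistic)


def outlier_counts(data: PairedData, thresholds=(1.0, 2.0)) -> dict[float, int]:
    """Entries with |calc - expt| beyond each threshold (same units as data)."""
    thresholds = tuple(thresholds)
    if any(t <= 0 for t in thresholds) or list(thresholds) != sorted(thresholds):
        raise ValueError("thresholds must be positive and sorted ascending")
    abs_err = np.abs(data.errors)
    return {float(t): int(np.sum(abs_err > t)) for t in thresholds}


@dataclass
class MetricsReport:
    """All agreement statistics for one dataset."""

    mae: float
    mse: float
    rmse: float
    tau: float
    pi: float
    pearson: float
    outliers: dict = field(default_factory=dict)
    n: int = 0
    units: str = "kcal/mol"

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "units": self.units,
            "MAE": self.mae,
            "MSE": self.mse,
            "RMSE": self.rmse,
            "tau": self.tau,
            "PI": self.pi,
            "pearson_r": self.pearson,
            "outliers": {f"|err|>{t:g}": c for t, c in self.outliers.items()},
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), indent=2, **kw)

    def to_frame(self) -> pd.DataFrame:
        d = self.to_dict()
        d.update(d.pop("outliers"))
        return pd.DataFrame([d])


def compute_report(data: PairedData, thresholds=(1.0, 2.0)) -> MetricsReport:
    """Compute the full metric panel in one pass."""
    mae, mse, rmse = error_metrics(data)
    return MetricsReport(
        mae=mae,
        mse=mse,
        rmse=rmse,
        tau=kendall_tau(data),
        pi=pearlman_pi(data),
        pearson=pearson_r(data),
        outliers=outlier_counts(data, thresholds),
        n=data.n,
        units=data.units,
    )


def read_paired_csv(path_or_buf, units: str = "kcal/mol") -> PairedData:
    """Read a ``label,calc,expt`` CSV (header required)."""
    df = pd.read_csv(path_or_buf, comment="#")
    cols = {c.lower().strip(): c for c in df.columns}
    try:
        return PairedData(
            labels=df[cols["label"]].tolist(),
            calc=df[cols["calc"]].to_numpy(),
            expt=df[cols["expt"]].to_numpy(),
            units=units,
        )
    except KeyError as exc:
        raise ValueError("CSV must have columns label, calc, expt") from exc


def scatter_calc_expt(data: PairedData, path, thresholds=(1.0, 2.0)) -> None:
    """Simple calculation-vs-experiment scatter with +-threshold bands."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    lo = min(data.calc.min(), data.expt.min()) - 1
    hi = max(data.calc.max(), data.expt.max()) + 1
    line = np.array([lo, hi])
    ax.plot(line, line, "k-", lw=1)
    for t, style in zip(thresholds, ("--", ":")):
        ax.plot(line, line + t, f"k{style}", lw=0.8)
        ax.plot(line, line - t, f"k{style}", lw=0.8)
    ax.scatter(data.expt, data.calc, s=18, zorder=3)
    ax.set_xlabel(f"experiment ({data.units})")
    ax.set_ylabel(f"calculation ({data.units})")
    ax.set_xlim(lo, hi)
    ax.set_ylim(lo, hi)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
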