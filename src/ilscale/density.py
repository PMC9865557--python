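"""Density response to force-field scaling: fits and factor recommendations.

The bulk mass density of an ionic liquid responds almost linearly to a
uniform scaling of the ions' LJ sigma (and, where effective, of their
charges).  A scan of simulated densities over scaling factors is therefore
summarized by an ordinary least-squares line

    rho_sim(s) = a + b s,

whose slope b (g/mL per unit scaling factor) characterizes the system
response; b / rho_exp is the dimensionless relative response.  Solving
rho_sim(s*) = rho_exp gives the density-matched factor.  Because density
matching overfits solvent-solvent interactions at the expense of
solute-solvent ones, the recommended production factor lies between the
density-derived factor and the solvation/partition-derived one, one step
toward the latter (slightly denser-than-experiment packing is preferred).
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DensityScan",
    "DensityResponseFit",
    "BalancedRecommendation",
    "linear_fit",
    "relative_slope",
    "report_two_decimals",
    "density_matched_factor",
    "balanced_factor",
    "deviation_profile",
    "read_density_scan",
    "write_density_scan",
]


@dataclass
class DensityScan:
    """(scaling factor, simulated density, SD) points with the experimental
    reference density."""

    s: np.ndarray
    density: np.ndarray
    sd: np.ndarray
    kind: str = "sigma"           # "sigma" | "charge"
    rho_exp: float = float("nan")
    temperature: float = 298.0

    def __post_init__(self):
        self.s = np.asarray(self.s, dtype=float).ravel()
        self.density = np.asarray(self.density, dtype=float).ravel()
        if self.sd is None:
            self.sd = np.zeros_like(self.density)
        self.sd = np.asarray(self.sd, dtype=float).ravel()
        if not (self.s.size == self.density.size == self.sd.size):
            raise ValueError("s, density and sd must have equal lengths")
        if np.any(self.density <= 0):
            raise ValueError("densities must be > 0")
        if self.kind not in ("sigma", "charge"):
            raise ValueError("kind must be 'sigma' or 'charge'")

    @property
    def n(self) -> int:
        return int(self.s.size)


@dataclass
class DensityResponseFit:
    """OLS line through a density scan."""

    slope: float          # g/mL per unit scaling factor
    intercept: float      # g/mL
    r_squared: float
    rho_exp: float = float("nan")
    s_range: tuple = (float("nan"), float("nan"))

    @property
    def relative_slope(self) -> float:
        return relative_slope(self.slope, self.rho_exp)

    def predict(self, s) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(s, dtype=float)


def linear_fit(scan: DensityScan) -> DensityResponseFit:
    """Unweighted OLS of simulated density on the scaling factor.

    R^2 is the squared correlation coefficient.  Scan SDs are carried for
    display only, not used as weights.
    """
    if np.unique(scan.s).size < 2:
        raise ValueError("degenerate design: need >= 2 distinct scaling factors")
    res = stats.linregress(scan.s, scan.density)
    return DensityResponseFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2) if np.isfinite(res.rvalue) else 1.0,
        rho_exp=scan.rho_exp,
        s_range=(float(scan.s.min()), float(scan.s.max())),
    )


def relative_slope(b: float, rho_exp: float) -> float:
    """Dimensionless density response b / rho_exp at full precision."""
    if not rho_exp > 0:
        raise ValueError("experimental density must be > 0")
    return b / rho_exp


def report_two_decimals(x: float) -> float:
    """Two-decimal reporting by truncation toward zero (e.g. -1.3402 -> -1.34)."""
    return math.trunc(x * 100) / 100


def density_matched_factor(fit: DensityResponseFit, rho_exp: float | None = None) -> float:
    """Scaling factor at which the fitted line crosses the experimental density.

    Warns when the solution lies outside the scanned range (extrapolation),
    at or below zero, or when the scan slope has an anomalous positive sign.
    """
    rho = fit.rho_exp if rho_exp is None else rho_exp
    if not rho > 0:
        raise ValueError("experimental density must be > 0")
    if fit.slope == 0:
        raise ZeroDivisionError("zero slope: no density-matched factor exists")
    s_star = (rho - fit.intercept) / fit.slope
    if fit.slope > 0:
        warnings.warn(
            "positive density-vs-scaling slope is anomalous for sigma scaling",
            stacklevel=2,
        )
    if s_star <= 0:
        warnings.warn(f"density-matched factor {s_star:.4f} <= 0", stacklevel=2)
    lo, hi = fit.s_range
    if np.isfinite(lo) and not (lo <= s_star <= hi):
        warnings.warn(
            f"density-matched factor {s_star:.4f} extrapolates outside the "
            f"scanned range [{lo:.4f}, {hi:.4f}]",
            stacklevel=2,
        )
    return float(s_star)


@dataclass
class BalancedRecommendation:
    """Interval between the density- and solvation-derived factors, with a
    suggested compromise point."""

    interval: tuple
    suggestion: float
    s_density: float
    s_solvation: float


def balanced_factor(
    s_density: float, s_solvation: float, step: float = 0.01
) -> BalancedRecommendation:
    """Recommend a scaling factor balancing bulk density and solvation accuracy.

    The recommendation is the closed interval between the two derived factors
    together with a suggested point: the density-derived factor moved one
    ``step`` toward the solvation-derived one, since factors giving slightly
    denser-than-experiment packing are preferred.  If the step would overshoot,
    the suggestion is clamped to the midpoint (with a warning).
    """
    if step <= 0:
        raise ValueError("step must be > 0")
    if s_density == s_solvation:
        raise ValueError("density- and solvation-derived factors are equal; "
                         "nothing to balance")
    lo, hi = sorted((s_density, s_solvation))
    if step >= hi - lo:
        warnings.warn(
            "step spans the whole interval; clamping suggestion to the midpoint",
            stacklevel=2,
        )
        suggestion = 0.5 * (lo + hi)
    else:
        direction = 1.0 if s_solvation > s_density else -1.0
        suggestion = s_density + direction * step
    return BalancedRecommendation(
        interval=(lo, hi),
        suggestion=float(suggestion),
        s_density=float(s_density),
        s_solvation=float(s_solvation),
    )


def deviation_profile(scan: DensityScan) -> list[tuple[float, float]]:
    """Signed deviations (s, rho_sim - rho_exp) in scan order."""
    return [(float(s), float(d - scan.rho_exp))
            for s, d in zip(scan.s, scan.density)]


def read_density_scan(path_or_buf) -> DensityScan:
    """Read an ``s,density,sd`` CSV with ``# key = value`` header comments
    for rho_exp, temperature and kind."""
    if isinstance(path_or_buf, (str, bytes)):
        with open(path_or_buf) as fh:
            text = fh.read()
    else:
        text = path_or_buf.read()
    meta = {}
    for line in text.splitlines():
        if line.lstrip().startswith("#") and "=" in line:
            key, _, val = line.lstrip("# \t").partition("=")
            meta[key.strip().lower()] = val.strip()
    df = pd.read_csv(io.StringIO(text), comment="#")
    cols = {c.lower().strip(): c for c in df.columns}
    if "s" not in cols or "density" not in cols:
        raise ValueError("scan CSV must have columns s, density [, sd]")
    sd = df[cols["sd"]].to_numpy() if "sd" in cols else None
    return DensityScan(
        s=df[cols["s"]].to_numpy(),
        density=df[cols["density"]].to_numpy(),
        sd=sd,
        kind=meta.get("kind", "sigma"),
        rho_exp=float(meta.get("rho_exp", "nan")),
        temperature=float(meta.get("temperature", 298.0)),
    )


def write_density_scan(scan: DensityScan, path_or_buf) -> None:
    """Write the scan CSV format read by :func:`read_density_scan`."""
    buf = io.StringIO()
    buf.write(f"# rho_exp = {scan.rho_exp}\n")
    buf.write(f"# temperature = {scan.temperature}\n")
    buf.write(f"# kind = {scan.kind}\n")
    buf.write("s,density,sd\n")
    for s, d, e in zip(scan.s, scan.density, scan.sd):
        buf.write(f"{s:.6g},{d:.8g},{e:.8g}\n")
    if isinstance(path_or_buf, (str, bytes)):
        with open(path_or_buf, "w") as fh:
            fh.write(buf.getvalue())
    else:
        path_or_buf.write(buf.getvalue())
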