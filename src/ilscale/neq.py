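"""Nonequilibrium (fast-growth) free-energy estimation.

Solvation free energies are estimated from ensembles of irreversible-work
measurements taken while the solute is alchemically created in the solvent,
using exponential averaging (Jarzynski's identity)

    dA = -ln < exp(-W) > ,

with W the dimensionless microscopic work (units of kT) accumulated along the
switching path.  The estimator is asymptotically unbiased; at finite sample
size it is biased high, so uncertainties are obtained by bootstrap resampling
rather than from the analytical formula.  The solute-creation protocol is
two-staged (vdW coupling, then charging); the two stages of one realization
run sequentially, so their works sum per realization by default.

Works are stored dimensionless; conversion to kcal/mol uses k_B T at the
work set's temperature.  Sign convention: works are for solute creation
(decoupled -> coupled), so dA is the solvation free energy directly.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .constants import KB_KCAL
from .errors import PairingError, ScheduleError, UnitError

__all__ = [
    "WorkSet",
    "FreeEnergyEstimate",
    "LambdaSeries",
    "integrate_dhdl",
    "exp_estimator",
    "bootstrap_sd",
    "estimate_with_uncertainty",
    "combine_stages",
    "transfer_free_energy",
    "read_workset",
    "write_workset",
    "read_lambda_series",
]

STAGES = ("vdw-coupling", "charging", "total")


@dataclass
class WorkSet:
    """Per-realization dimensionless works W (kT) for one alchemical stage."""

    works: np.ndarray
    stage: str = "total"
    temperature: float = 298.0
    ids: list = None

    def __post_init__(self):
        self.works = np.asarray(self.works, dtype=float).ravel()
        if self.works.size < 1:
            raise ValueError("work set needs at least one realization")
        if self.stage not in STAGES:
            raise ValueError(f"stage must be one of {STAGES}")
        if not self.temperature > 0:
            raise ValueError("temperature must be > 0 K")
        if self.ids is None:
            self.ids = list(range(self.works.size))
        self.ids = list(self.ids)
        if len(self.ids) != self.works.size:
            raise ValueError("one realization id per work required")
        if not np.all(np.isfinite(self.works)):
            bad = [self.ids[i] for i in np.flatnonzero(~np.isfinite(self.works))]
            raise ValueError(f"non-finite work(s) for realization id(s) {bad}")

    @property
    def n(self) -> int:
        return int(self.works.size)


@dataclass
class FreeEnergyEstimate:
    """A free-energy difference in kT with a bootstrap SD, plus conversions."""

    value_kt: float
    sd_kt: float = 0.0
    temperature: float = 298.0
    n_realizations: int = 0
    estimator: str = "EXP"

    def __post_init__(self):
        if self.sd_kt < 0:
            raise ValueError("sd must be >= 0")

    @property
    def kt_in_kcal(self) -> float:
        return KB_KCAL * self.temperature

    @property
    def value_kcal(self) -> float:
        return self.value_kt * self.kt_in_kcal

    @property
    def sd_kcal(self) -> float:
        return self.sd_kt * self.kt_in_kcal

    @classmethod
    def from_kcal(cls, value_kcal, sd_kcal=0.0, temperature=298.0, **kw):
        kt = KB_KCAL * temperature
        return cls(value_kcal / kt, sd_kcal / kt, temperature, **kw)

    def __str__(self):
        return (
            f"dA = {self.value_kt:.4f} +- {self.sd_kt:.4f} kT "
            f"({self.value_kcal:.3f} +- {self.sd_kcal:.3f} kcal/mol, "
            f"{self.estimator}, n={self.n_realizations}, T={self.temperature} K)"
        )


@dataclass
class LambdaSeries:
    """One realization's (lambda, dH/dlambda) switching record.

    lambda runs 0 -> 1; dH/dlambda is in kT ("kT") or kJ/mol ("kJ/mol",
    converted using the temperature).
    """

    lam: np.ndarray
    dhdl: np.ndarray
    units: str = "kT"
    temperature: float = 298.0

    def __post_init__(self):
        self.lam = np.asarray(self.lam, dtype=float).ravel()
        self.dhdl = np.asarray(self.dhdl, dtype=float).ravel()
        if self.lam.shape != self.dhdl.shape or self.lam.size < 2:
            raise ValueError("need matching lambda/dhdl arrays with >= 2 samples")
        if self.units not in ("kT", "kJ/mol"):
            raise UnitError(f"unsupported dH/dl units {self.units!r}")
        if np.any(np.diff(self.lam) < 0):
            raise ScheduleError("lambda schedule must be non-decreasing")
        if abs(self.lam[0]) > 1e-9 or abs(self.lam[-1] - 1.0) > 1e-9:
            raise ScheduleError("lambda must start at 0 and end at 1")


def integrate_dhdl(series: LambdaSeries) -> float:
    """Work along the switching path by trapezoidal quadrature, in kT."""
    w = float(np.trapezoid(series.dhdl, series.lam))
    if series.units == "kJ/mol":
        from .constants import KB_KJ

        w /= KB_KJ * series.temperature
    return w


def exp_estimator(workset: WorkSet) -> FreeEnergyEstimate:
    """Jarzynski exponential average dA = -ln<exp(-W)>, in kT.

    Uses log-sum-exp stabilization, so works of magnitude up to ~1e3 kT are
    handled without overflow.  Exact for n = 1 (dA = W_1).
    """
    w = workset.works
    value = -(float(logsumexp(-w)) - np.log(w.size))
    return FreeEnergyEstimate(
        value_kt=value,
        sd_kt=0.0,
        temperature=workset.temperature,
        n_realizations=workset.n,
    )


def bootstrap_sd(workset: WorkSet, n_resamples: int = 1000, seed: int = 0) -> float:
    """Bootstrap SD (kT) of the EXP estimate over resamples with replacement.

    Deterministic for a fixed seed.  The SD is the sample standard deviation
    (ddof=1) of the resampled estimates.
    """
    if workset.n < 2:
        raise ValueError("bootstrap uncertainty undefined for a single realization")
    if n_resamples < 100:
        raise ValueError("use at least 100 bootstrap resamples")
    rng = np.random.default_rng(seed)
    w = workset.works
    idx = rng.integers(0, w.size, size=(n_resamples, w.size))
    est = -(logsumexp(-w[idx], axis=1) - np.log(w.size))
    return float(np.std(est, ddof=1))


def estimate_with_uncertainty(
    workset: WorkSet, n_resamples: int = 1000, seed: int = 0
) -> FreeEnergyEstimate:
    """EXP estimate with its bootstrap SD in one call."""
    est = exp_estimator(workset)
    est.sd_kt = bootstrap_sd(workset, n_resamples=n_resamples, seed=seed)
    return est


def combine_stages(
    vdw: WorkSet,
    charging: WorkSet,
    mode: str = "per-realization",
    n_resamples: int = 1000,
    seed: int = 0,
):
    """Combine the vdW-coupling and charging stages of a two-stage protocol.

    ``per-realization`` (default): the two sub-steps of each realization run
    sequentially, so their works are summed pairwise (matched by realization
    id) and a total :class:`WorkSet` is returned for downstream estimation.

    ``per-stage``: EXP is applied to each stage separately; the returned
    :class:`FreeEnergyEstimate` sums the stage dA values and combines the
    bootstrap SDs in quadrature.
    """
    if vdw.temperature != charging.temperature:
        raise UnitError("stage temperatures differ")
    if mode == "per-realization":
        order_v = {rid: i for i, rid in enumerate(vdw.ids)}
        if len(order_v) != len(vdw.ids):
            raise PairingError("duplicate realization ids in vdW stage")
        if sorted(vdw.ids) != sorted(charging.ids):
            raise PairingError("realization ids of the two stages do not match")
        idx = [order_v[rid] for rid in charging.ids]
        total = vdw.works[idx] + charging.works
        return WorkSet(
            works=total,
            stage="total",
            temperature=vdw.temperature,
            ids=list(charging.ids),
        )
    if mode == "per-stage":
        est_v = estimate_with_uncertainty(vdw, n_resamples, seed)
        est_c = estimate_with_uncertainty(charging, n_resamples, seed + 1)
        return FreeEnergyEstimate(
            value_kt=est_v.value_kt + est_c.value_kt,
            sd_kt=float(np.hypot(est_v.sd_kt, est_c.sd_kt)),
            temperature=vdw.temperature,
            n_realizations=min(vdw.n, charging.n),
            estimator="EXP(per-stage)",
        )
    raise ValueError("mode must be 'per-realization' or 'per-stage'")


def transfer_free_energy(
    dg_solv_il: FreeEnergyEstimate, dg_solv_water: FreeEnergyEstimate
) -> FreeEnergyEstimate:
    """Water -> IL transfer free energy ddG = dG_solv,IL - dG_solv,water.

    The SD combines in quadrature.  Both inputs must share a temperature so
    the kT scales are commensurate.
    """
    if abs(dg_solv_il.temperature - dg_solv_water.temperature) > 1e-9:
        raise UnitError("transfer requires both solvation estimates at the same T")
    return FreeEnergyEstimate(
        value_kt=dg_solv_il.value_kt - dg_solv_water.value_kt,
        sd_kt=float(np.hypot(dg_solv_il.sd_kt, dg_solv_water.sd_kt)),
        temperature=dg_solv_il.temperature,
        n_realizations=min(dg_solv_il.n_realizations, dg_solv_water.n_realizations),
        estimator="transfer",
    )


def read_workset(path_or_buf, temperature: float = 298.0, stage: str = "total") -> WorkSet:
    """Read a two-column ``realization_id work`` text file.

    A header comment may declare the units, e.g. ``# units: kT`` (default) or
    ``# units: kJ/mol`` (converted with k_B T).
    """
    if isinstance(path_or_buf, (str, bytes)):
        with open(path_or_buf) as fh:
            lines = fh.readlines()
    else:
        lines = path_or_buf.readlines()
    units = "kT"
    ids, works = [], []
    for line in lines:
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith(("#", "@", ";")):
            lowered = stripped.lstrip("#@; \t").lower()
            if lowered.startswith("units"):
                units = lowered.split(":", 1)[-1].split("=", 1)[-1].strip()
            continue
        tokens = stripped.split()
        if len(tokens) < 2:
            raise ValueError(f"expected 'id work' columns, got {stripped!r}")
        ids.append(tokens[0])
        works.append(float(tokens[1]))
    works = np.asarray(works)
    if units.lower() in ("kj/mol", "kj"):
        from .constants import KB_KJ

        works = works / (KB_KJ * temperature)
    elif units != "kT" and units.lower() != "kt":
        raise UnitError(f"unsupported work units {units!r}")
    return WorkSet(works=works, stage=stage, temperature=temperature, ids=ids)


def write_workset(workset: WorkSet, path_or_buf) -> None:
    """Write the ``realization_id work`` text format (works in kT)."""
    buf = io.StringIO()
    buf.write(f"# units: kT\n# stage: {workset.stage}\n"
              f"# temperature: {workset.temperature}\n")
    for rid, w in zip(workset.ids, workset.works):
        buf.write(f"{rid} {w:.12g}\n")
    if isinstance(path_or_buf, (str, bytes)):
        with open(path_or_buf, "w") as fh:
            fh.write(buf.getvalue())
    else:
        path_or_buf.write(buf.getvalue())


def read_lambda_series(
    path_or_buf, units: str = "kT", temperature: float = 298.0
) -> LambdaSeries:
    """Read an XVG-style two-column (lambda, dH/dlambda) series.

    Lines starting with ``@`` or ``#`` are tolerated and skipped.
    """
    if isinstance(path_or_buf, (str, bytes)):
        with open(path_or_buf) as fh:
            lines = fh.readlines()
    else:
        lines = path_or_buf.readlines()
    lam, dhdl = [], []
    for line in lines:
        stripped = line.strip()
        if not stripped or stripped.startswith(("@", "#", ";")):
            continue
        tokens = stripped.split()
        lam.append(float(tokens[0]))
        dhdl.append(float(tokens[1]))
    return LambdaSeries(lam=lam, dhdl=dhdl, units=units, temperature=temperature)
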