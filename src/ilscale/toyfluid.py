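"""Desk-scale fixture generators: a toy NPT Monte-Carlo ionic fluid and
synthetic data with known truth for the estimation and metrics stacks.

The fluid is a periodic soft-sphere 1:1 electrolyte: Lennard-Jones spheres
(Lorentz-Berthelot combination) carrying charges +-q, sampled at constant
temperature and pressure by Metropolis Monte Carlo with single-particle
displacement moves and ln-V volume moves.  Electrostatics use damped
shifted-force (Wolf-type) truncation, which is adequate for the qualitative
packing behaviour probed here; it is not a substitute for Ewald summation
and the model makes no claim of reproducing real ionic-liquid densities.
Its role is to exhibit the density responses that the analysis modules
consume: density rises monotonically as the ions' sigma shrinks, and falls
as sigma is scaled up.

The charge- and sigma-scaling factors enter exactly as they do in the
topology module: charges as +-q*s_q, collision diameters as sigma*s_sigma.

The Gaussian work generator draws dissipative works consistent with the
Crooks fluctuation theorem (mean = dG + sigma_w^2/2, variance sigma_w^2),
so the exponential-averaging estimator has the exact truth dG in the
large-sample limit.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.special import erfc

from .constants import (
    AMU_PER_NM3_TO_G_PER_ML,
    BAR_NM3_TO_KJ,
    COULOMB_KJ,
    KB_KJ,
)
from .density import DensityScan
from .errors import SimulationError
from .metrics import PairedData
from .neq import WorkSet

__all__ = [
    "ToyModelParams",
    "DensityObservation",
    "run_npt_mc",
    "density_scan_toy",
    "generate_gaussian_works",
    "generate_paired_dataset",
]


@dataclass
class ToyModelParams:
    """Parameters of the toy NPT ionic fluid.

    Defaults describe a coarse room-temperature ionic liquid at 298 K and
    1 bar: 24 ion pairs of NTF-like masses, half-nanometre soft spheres with
    liquid-grade LJ cohesion (eps ~ kT) and delocalized effective charges
    (+-0.6 e before scaling; single-site ions for large molecular ions carry
    less than a full point charge at contact), with the near-optimal 0.8
    charge-scaling factor applied by default.
    """

    n_pairs: int = 24
    sigma_cation: float = 0.45     # nm
    sigma_anion: float = 0.55      # nm
    eps_cation: float = 2.5        # kJ/mol
    eps_anion: float = 3.0         # kJ/mol
    q: float = 0.6                 # e (magnitude before scaling)
    mass_cation: float = 150.0     # amu
    mass_anion: float = 280.0      # amu
    s_q: float = 0.8               # charge-scaling factor
    s_sigma: float = 1.0           # vdW sigma-scaling factor
    temperature: float = 298.0     # K
    pressure: float = 1.0          # bar
    max_disp: float = 0.08         # nm, displacement move half-width
    max_lnv: float = 0.03          # ln-volume move half-width
    cutoff: float = 0.75           # nm, LJ and real-space Coulomb cutoff
    alpha: float = 1.5             # 1/nm, Wolf damping
    seed: int = 0
    init_box_edge: float | None = None  # nm; None -> heuristic from sigma

    def __post_init__(self):
        if self.n_pairs < 8:
            raise ValueError("need at least 8 ion pairs")
        if self.sigma_cation <= 0 or self.sigma_anion <= 0:
            raise ValueError("sigmas must be > 0")
        if self.eps_cation < 0 or self.eps_anion < 0:
            raise ValueError("epsilons must be >= 0")
        if self.temperature <= 0 or self.pressure <= 0:
            raise ValueError("temperature and pressure must be > 0")
        if self.cutoff <= 0:
            raise ValueError("cutoff must be > 0")


@dataclass
class DensityObservation:
    """Density estimate from a production run, with block-averaged SD."""

    density: float          # g/mL
    sd: float               # g/mL, SE of the mean from 10 blocks
    n_sweeps: int
    acc_displacement: float
    acc_volume: float
    mean_volume: float      # nm^3
    volume_sd: float        # nm^3, SE of the mean from 10 blocks
    n_particles: int
    u_final: float          # kJ/mol, incrementally tracked
    u_recomputed: float     # kJ/mol, from-scratch at the end


class _ToyFluid:
    """Internal simulation state and energy kernels."""

    def __init__(self, p: ToyModelParams):
        self.p = p
        n = 2 * p.n_pairs
        self.n = n
        sig = np.empty(n)
        eps = np.empty(n)
        q = np.empty(n)
        mass = np.empty(n)
        # alternate cation/anion so the initial lattice is charge-mixed
        sig[0::2] = p.sigma_cation * p.s_sigma
        sig[1::2] = p.sigma_anion * p.s_sigma
        eps[0::2] = p.eps_cation
        eps[1::2] = p.eps_anion
        q[0::2] = +p.q * p.s_q
        q[1::2] = -p.q * p.s_q
        mass[0::2] = p.mass_cation
        mass[1::2] = p.mass_anion
        self.mass_total = float(mass.sum())
        # pair tables (N x N)
        self.SIG = 0.5 * (sig[:, None] + sig[None, :])
        self.EPS = np.sqrt(eps[:, None] * eps[None, :])
        self.QQ = COULOMB_KJ * q[:, None] * q[None, :]
        # damped shifted-force constants
        rc, a = p.cutoff, p.alpha
        self.rc = rc
        self.rc2 = rc * rc
        self.e_shift = erfc(a * rc) / rc
        self.f_shift = erfc(a * rc) / rc**2 + (
            2 * a / np.sqrt(np.pi)
        ) * np.exp(-(a * rc) ** 2) / rc
        self.beta = 1.0 / (KB_KJ * p.temperature)
        self.p_kj = p.pressure * BAR_NM3_TO_KJ
        self.rng = np.random.default_rng(p.seed)
        self._init_positions()
        self.u = self.total_energy()

    def _init_positions(self):
        p = self.p
        if p.init_box_edge is not None:
            edge = float(p.init_box_edge)
        else:
            # start condensed (number density rho*sigma^3 ~ 0.7): the ionic
            # liquid phase is only locally stable, and MC without aggregation
            # moves cannot nucleate it from a dilute start
            sig3 = (self.n // 2) * (
                (p.sigma_cation * p.s_sigma) ** 3 + (p.sigma_anion * p.s_sigma) ** 3
            )
            edge = (sig3 / 0.7) ** (1.0 / 3.0)
        if edge < 2 * self.rc:
            raise SimulationError(
                f"initial box edge {edge:.3f} nm below 2 x cutoff "
                f"({2 * self.rc:.3f} nm)"
            )
        n_side = int(np.ceil(self.n ** (1 / 3)))
        grid = (np.arange(n_side) + 0.5) / n_side
        sites = np.array(np.meshgrid(grid, grid, grid)).T.reshape(-1, 3)[: self.n]
        self.pos = sites * edge
        self.box = edge

    # -- energy kernels ----------------------------------------------------
    def _pair_energy(self, r2, sig, eps, qq):
        r2 = np.asarray(r2)
        mask = r2 < self.rc2
        if not np.any(mask):
            return 0.0
        r2 = r2[mask]
        r = np.sqrt(r2)
        s2 = (sig[mask] ** 2) / r2
        s6 = s2 * s2 * s2
        e_lj = 4.0 * eps[mask] * (s6 * s6 - s6)
        e_c = qq[mask] * (
            erfc(self.p.alpha * r) / r - self.e_shift + self.f_shift * (r - self.rc)
        )
        return float(np.sum(e_lj + e_c))

    def particle_energy(self, k: int, xk: np.ndarray) -> float:
        d = self.pos - xk
        d -= self.box * np.rint(d / self.box)
        r2 = np.einsum("ij,ij->i", d, d)
        r2[k] = np.inf
        return self._pair_energy(r2, self.SIG[k], self.EPS[k], self.QQ[k])

    def total_energy(self, pos: np.ndarray | None = None, box: float | None = None):
        pos = self.pos if pos is None else pos
        box = self.box if box is None else box
        d = pos[:, None, :] - pos[None, :, :]
        d -= box * np.rint(d / box)
        r2 = np.einsum("ijk,ijk->ij", d, d)
        iu = np.triu_indices(self.n, k=1)
        return self._pair_energy(r2[iu], self.SIG[iu], self.EPS[iu], self.QQ[iu])

    # -- moves -------------------------------------------------------------
    def displacement_move(self) -> bool:
        k = int(self.rng.integers(self.n))
        old_e = self.particle_energy(k, self.pos[k])
        new_x = (self.pos[k] + self.rng.uniform(
            -self.p.max_disp, self.p.max_disp, 3)) % self.box
        new_e = self.particle_energy(k, new_x)
        du = new_e - old_e
        if du <= 0 or self.rng.random() < np.exp(-self.beta * du):
            self.pos[k] = new_x
            self.u += du
            return True
        return False

    def volume_move(self) -> bool:
        v_old = self.box**3
        lnv_new = np.log(v_old) + self.rng.uniform(-self.p.max_lnv, self.p.max_lnv)
        v_new = np.exp(lnv_new)
        box_new = v_new ** (1.0 / 3.0)
        scale = box_new / self.box
        pos_new = self.pos * scale
        u_new = self.total_energy(pos_new, box_new)
        arg = (
            -self.beta * (u_new - self.u + self.p_kj * (v_new - v_old))
            + (self.n + 1) * np.log(v_new / v_old)
        )
        if arg >= 0 or self.rng.random() < np.exp(arg):
            if box_new < 2 * self.rc:
                raise SimulationError(
                    f"box edge {box_new:.3f} nm shrank below 2 x cutoff "
                    f"({2 * self.rc:.3f} nm); reduce the cutoff or enlarge the system"
                )
            self.pos = pos_new
            self.box = box_new
            self.u = u_new
            return True
        return False

    @property
    def density(self) -> float:
        return self.mass_total * AMU_PER_NM3_TO_G_PER_ML / self.box**3


def _block_stats(samples: np.ndarray, n_blocks: int = 10):
    usable = (samples.size // n_blocks) * n_blocks
    blocks = samples[samples.size - usable:].reshape(n_blocks, -1).mean(axis=1)
    return float(samples.mean()), float(np.std(blocks, ddof=1) / np.sqrt(n_blocks))


def run_npt_mc(
    params: ToyModelParams,
    n_equil_sweeps: int = 800,
    n_prod_sweeps: int = 1600,
    vol_attempts_per_sweep: int = 2,
) -> DensityObservation:
    """Run the toy NPT fluid and estimate the mass density.

    One sweep is N displacement attempts plus ``vol_attempts_per_sweep``
    ln-V volume attempts.  The density is sampled once per production sweep
    and block-averaged over 10 blocks; the reported SD is the standard error
    of the mean of the block means.  The trajectory is deterministic for a
    fixed seed.
    """
    if n_prod_sweeps < 10:
        raise ValueError("need at least 10 production sweeps (one per block)")
    sim = _ToyFluid(params)
    acc_d = att_d = acc_v = att_v = 0

    def sweep():
        nonlocal acc_d, att_d, acc_v, att_v
        for _ in range(sim.n):
            att_d += 1
            acc_d += sim.displacement_move()
        for _ in range(vol_attempts_per_sweep):
            att_v += 1
            acc_v += sim.volume_move()

    for _ in range(n_equil_sweeps):
        sweep()
    dens = np.empty(n_prod_sweeps)
    vols = np.empty(n_prod_sweeps)
    for i in range(n_prod_sweeps):
        sweep()
        dens[i] = sim.density
        vols[i] = sim.box**3
    rho, rho_sd = _block_stats(dens)
    vol, vol_sd = _block_stats(vols)
    return DensityObservation(
        density=rho,
        sd=rho_sd,
        n_sweeps=n_equil_sweeps + n_prod_sweeps,
        acc_displacement=acc_d / max(att_d, 1),
        acc_volume=acc_v / max(att_v, 1),
        mean_volume=vol,
        volume_sd=vol_sd,
        n_particles=sim.n,
        u_final=sim.u,
        u_recomputed=sim.total_energy(),
    )


def density_scan_toy(
    params: ToyModelParams,
    s_values,
    n_equil_sweeps: int = 800,
    n_prod_sweeps: int = 1600,
    kind: str = "sigma",
    rho_exp: float | None = None,
    n_replicas: int = 3,
) -> DensityScan:
    """Scan the toy fluid's density over scaling factors.

    ``kind`` selects whether the factors apply to sigma or to the charges.
    Each scan point averages ``n_replicas`` independent runs (seeds offset
    from ``params.seed``): the strongly coupled ionic fluid relaxes slowly,
    so between-replica scatter dominates the single-run block SD.  The
    reported SD is the SE over replicas (block SD when ``n_replicas = 1``).
    ``rho_exp`` is the experimental-reference stand-in; when omitted, the
    mean of the scanned densities is used so that downstream density-matching
    lands inside the scanned range.
    """
    s_values = [float(s) for s in s_values]
    if len(s_values) < 2:
        raise ValueError("need at least 2 scaling factors for a scan")
    if kind not in ("sigma", "charge"):
        raise ValueError("kind must be 'sigma' or 'charge'")
    if n_replicas < 1:
        raise ValueError("n_replicas must be >= 1")
    rows = []
    for s in s_values:
        p = replace(params, s_sigma=s) if kind == "sigma" else replace(params, s_q=s)
        reps = [
            run_npt_mc(replace(p, seed=params.seed + 1000 * k),
                       n_equil_sweeps, n_prod_sweeps)
            for k in range(n_replicas)
        ]
        dens = np.array([r.density for r in reps])
        if n_replicas > 1:
            sd = float(np.std(dens, ddof=1) / np.sqrt(n_replicas))
        else:
            sd = reps[0].sd
        rows.append((s, float(dens.mean()), sd))
    s, d, sd = map(np.array, zip(*rows))
    return DensityScan(
        s=s,
        density=d,
        sd=sd,
        kind=kind,
        rho_exp=float(np.mean(d)) if rho_exp is None else float(rho_exp),
        temperature=params.temperature,
    )


def generate_gaussian_works(
    delta_g: float,
    sigma_w: float,
    n: int,
    seed: int = 0,
    temperature: float = 298.0,
    stage: str = "total",
) -> WorkSet:
    """Draw Crooks-consistent Gaussian works with known free-energy truth.

    Works ~ Normal(delta_g + sigma_w^2/2, sigma_w^2) in kT; for this family
    the exponential average converges exactly to ``delta_g``.
    """
    if sigma_w < 0:
        raise ValueError("sigma_w must be >= 0")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    works = delta_g + sigma_w**2 / 2.0 + sigma_w * rng.standard_normal(n)
    return WorkSet(works=works, stage=stage, temperature=temperature)


def generate_paired_dataset(
    n: int, noise_sd: float, seed: int = 0, units: str = "kcal/mol"
) -> PairedData:
    """Synthetic calculation/experiment pairs with known ideal metrics.

    Experimental values sit on a fixed grid spanning a solvation-like range
    (-12 to 0 kcal/mol); calculated values add iid Gaussian noise.  At
    ``noise_sd = 0`` every agreement metric is exactly perfect.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = np.random.default_rng(seed)
    expt = np.linspace(-12.0, 0.0, n)
    calc = expt + noise_sd * rng.standard_normal(n)
    labels = [f"solute-{i + 1:02d}" for i in range(n)]
    return PairedData(labels=labels, calc=calc, expt=expt, units=units)
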