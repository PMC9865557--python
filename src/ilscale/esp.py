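"""Point-charge quality scoring against a reference electrostatic potential.

A set of fitted atomic point charges is good if the Coulomb potential it
generates reproduces the ab initio electrostatic potential (ESP) on a grid of
points around the molecule.  The score is the relative root-mean-squared
error

    RRMSE = sqrt( sum_k (V_model,k - V_ref,k)^2 / sum_k V_ref,k^2 ),

the conventional figure of merit of the RESP charge-fitting literature (the
ratio of summed squared deviations to the summed squared reference values,
rooted).  Everything is in atomic units internally (bohr, Hartree/e);
Angstrom input is converted on read.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .constants import ANGSTROM_TO_BOHR
from .errors import SingularityError, UnitError

__all__ = [
    "EspGrid",
    "ChargeModel",
    "esp_from_charges",
    "rrmse",
    "mk_shell_grid",
    "read_esp_grid",
    "read_charge_model",
    "write_esp_grid",
]

_MIN_SEPARATION = 1e-6  # bohr


@dataclass
class EspGrid:
    """Grid points (bohr) with the reference potential (a.u.) at each point."""

    points: np.ndarray
    reference_potential: np.ndarray

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        self.reference_potential = np.asarray(self.reference_potential, dtype=float)
        if self.points.shape[0] < 1 or self.points.shape[1] != 3:
            raise ValueError("grid needs >= 1 point with 3 coordinates each")
        if self.reference_potential.shape != (self.points.shape[0],):
            raise ValueError("one reference potential per grid point required")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("grid coordinates must be finite")


@dataclass
class ChargeModel:
    """Atom coordinates (bohr) and atomic point charges (e)."""

    coordinates: np.ndarray
    charges: np.ndarray

    def __post_init__(self):
        self.coordinates = np.atleast_2d(np.asarray(self.coordinates, dtype=float))
        self.charges = np.asarray(self.charges, dtype=float)
        if self.coordinates.shape[0] != self.charges.shape[0]:
            raise ValueError("one charge per atom required")


def esp_from_charges(model: ChargeModel, grid: EspGrid) -> np.ndarray:
    """Coulomb potential of the point charges at every grid point (a.u.).

    V(r_k) = sum_i q_i / |r_k - r_i| with everything in atomic units.
    """
    dist = cdist(grid.points, model.coordinates)
    bad = np.argwhere(dist < _MIN_SEPARATION)
    if bad.size:
        raise SingularityError([(int(p), int(a)) for p, a in bad])
    return (model.charges / dist).sum(axis=1)


def rrmse(model_potential, reference_potential) -> float:
    """Relative RMSE of a model potential against the reference (fraction).

    Multiply by 100 for the percent form.  Invariant under simultaneous
    rescaling of both vectors and under permutation of the points.
    """
    v_mod = np.asarray(model_potential, dtype=float)
    v_ref = np.asarray(reference_potential, dtype=float)
    if v_mod.shape != v_ref.shape or v_ref.ndim != 1 or v_ref.size < 1:
        raise ValueError("potentials must be equal-length 1-D arrays")
    norm = float(np.sum(v_ref**2))
    if norm == 0.0:
        raise ZeroDivisionError(
            "reference potential is identically zero; RRMSE normalization undefined"
        )
    return float(np.sqrt(np.sum((v_mod - v_ref) ** 2) / norm))


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n quasi-uniform points on the unit sphere (golden-spiral lattice)."""
    i = np.arange(n, dtype=float)
    phi = (1 + np.sqrt(5.0)) / 2
    z = 1 - (2 * i + 1) / n
    theta = 2 * np.pi * i / phi
    r = np.sqrt(np.maximum(0.0, 1 - z * z))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    # QR of a Gaussian matrix gives a Haar-uniform rotation (up to signs)
    m, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(m) < 0:
        m[:, 0] = -m[:, 0]
    return m


def mk_shell_grid(
    coordinates,
    radii,
    shell_scales=(1.4, 1.6, 1.8, 2.0),
    target_density: float = 1.0,
    seed: int | None = 0,
) -> np.ndarray:
    """Build Merz-Kollman-style ESP grid points around a molecule.

    Quasi-uniform points are laid on spheres of radius ``scale * r_atom``
    around every atom for each shell scale, then points falling inside any
    other atom's scaled sphere are pruned.  ``target_density`` is points per
    bohr^2 of shell surface.  Deterministic for a fixed ``seed`` (the seed
    only randomizes the sphere orientations).
    """
    coords = np.atleast_2d(np.asarray(coordinates, dtype=float))
    radii = np.asarray(radii, dtype=float)
    if np.any(radii <= 0):
        raise ValueError("atomic radii must be > 0")
    scales = tuple(shell_scales)
    if any(s <= 1 for s in scales) or list(scales) != sorted(set(scales)):
        raise ValueError("shell_scales must be strictly increasing and all > 1")
    rng = np.random.default_rng(seed)
    kept: list[np.ndarray] = []
    for scale in scales:
        shell_r = scale * radii
        for i, center in enumerate(coords):
            radius = shell_r[i]
            n = max(1, int(round(target_density * 4 * np.pi * radius**2)))
            pts = center + radius * _fibonacci_sphere(n) @ _random_rotation(rng).T
            if len(coords) > 1:
                others = np.arange(len(coords)) != i
                d = cdist(pts, coords[others])
                inside = (d < shell_r[others] - 1e-9).any(axis=1)
                pts = pts[~inside]
            if pts.size:
                kept.append(pts)
    if not kept:
        raise ValueError("no grid points survive pruning; check radii/shell scales")
    return np.vstack(kept)


def _read_table(path_or_buf, n_cols: int, units: str | None):
    if isinstance(path_or_buf, (str, bytes)):
        with open(path_or_buf) as fh:
            lines = fh.readlines()
    else:
        lines = path_or_buf.readlines()
    file_units = None
    rows = []
    for line in lines:
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith(("#", "@", ";")):
            lowered = stripped.lstrip("#@; \t").lower()
            if lowered.startswith("units"):
                file_units = lowered.split(":", 1)[-1].split("=", 1)[-1].strip()
            continue
        rows.append(stripped.split())
    unit = (units or file_units or "bohr").lower()
    if unit not in ("bohr", "angstrom"):
        raise UnitError(f"unsupported length unit {unit!r}")
    data = np.array(rows, dtype=float)
    if data.ndim != 2 or data.shape[1] < n_cols:
        raise ValueError(f"expected {n_cols} whitespace-separated columns")
    factor = ANGSTROM_TO_BOHR if unit == "angstrom" else 1.0
    return data, factor


def read_esp_grid(path_or_buf, units: str | None = None) -> EspGrid:
    """Read an ``x y z V`` table (one header line may give the units)."""
    data, factor = _read_table(path_or_buf, 4, units)
    return EspGrid(points=data[:, :3] * factor, reference_potential=data[:, 3])


def read_charge_model(path_or_buf, units: str | None = None) -> ChargeModel:
    """Read an ``x y z q`` table (one header line may give the units)."""
    data, factor = _read_table(path_or_buf, 4, units)
    return ChargeModel(coordinates=data[:, :3] * factor, charges=data[:, 3])


def write_esp_grid(grid: EspGrid, path_or_buf) -> None:
    """Write an ``x y z V`` table in bohr / atomic units."""
    buf = io.StringIO()
    buf.write("# units: bohr\n")
    for p, v in zip(grid.points, grid.reference_potential):
        buf.write(f"{p[0]:18.10f} {p[1]:18.10f} {p[2]:18.10f} {v:18.10e}\n")
    if isinstance(path_or_buf, (str, bytes)):
        with open(path_or_buf, "w") as fh:
            fh.write(buf.getvalue())
    else:
        path_or_buf.write(buf.getvalue())
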