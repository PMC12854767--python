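"""Toy-scale electrostatic coupling between a charge cloud and its environment.

A rigid point-charge cloud stands in for a quantum region's charge density.
Its interaction with environment point charges is evaluated three ways:

* exactly (all pairwise Coulomb terms, analytic forces on the environment),
* via a single-center traceless Cartesian multipole expansion about the
  cloud centroid, truncated at order ``p`` (0..8), used for environment
  sites beyond a cutoff ``R_exact``,
* via ESPF: atom-centered charges least-squares fitted to the cloud's
  electrostatic potential on shells around the atoms, with the total charge
  constrained exactly.

The hybrid evaluator applies the exact sum inside ``R_exact`` (distance of
the environment atom from the cloud centroid) and the chosen approximation
outside, and a scan tabulates |dE| and |df_max| against the exact reference
over (R_exact, p) grids.  All quantities are in Hartree atomic units
(positions in bohr, charges in e, energies in hartree, forces in hartree/bohr).

Implementation note: derivatives of 1/r are generated once as the exact
rational tensors ``D_{ijk} = d^n/dx^i dy^j dz^k (1/r) = Q_{ijk}(x,y,z)/r^{2n+1}``
by a polynomial recursion, and the traceless moments of a point charge at
``a`` follow from the same harmonic polynomials,
``theta^(n) = (-1)^n/(2n-1)!! * Q(a)``, which makes tracelessness exact by
construction (the trace of a derivative tensor of 1/r is a Laplacian, hence
zero).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ChargeCloud",
    "MultipoleExpansion",
    "CouplingConfig",
    "exact_interaction",
    "expand_multipoles",
    "multipole_potential",
    "multipole_field",
    "espf_grid",
    "espf_fit",
    "hybrid_interaction",
    "convergence_scan",
]

#: Highest supported multipole order (9th-order derivatives are kept for forces).
MAX_ORDER = 8
_MAX_DERIV = MAX_ORDER + 1

Poly = dict[tuple[int, int, int], float]  # monomial (a,b,c) -> coefficient


def _poly_dx(poly: Poly, axis: int) -> Poly:
    out: Poly = {}
    for mono, coef in poly.items():
        if mono[axis] == 0:
            continue
        new = list(mono)
        new[axis] -= 1
        key = tuple(new)
        out[key] = out.get(key, 0.0) + coef * mono[axis]
    return out


def _poly_mul_r2(poly: Poly) -> Poly:
    out: Poly = {}
    for mono, coef in poly.items():
        for axis in range(3):
            new = list(mono)
            new[axis] += 2
            key = tuple(new)
            out[key] = out.get(key, 0.0) + coef
    return out


def _poly_mul_axis(poly: Poly, axis: int) -> Poly:
    out: Poly = {}
    for mono, coef in poly.items():
        new = list(mono)
        new[axis] += 1
        out[tuple(new)] = coef
    return out


@lru_cache(maxsize=None)
def _harmonic_polys(max_order: int = _MAX_DERIV) -> dict[tuple[int, int, int], Poly]:
    """Numerator polynomials Q_{ijk} with D_{ijk} = Q_{ijk}/r^(2n+1), n=i+j+k.

    Recursion: raising one derivative index maps Q -> r^2 dQ - (2n+1) x_axis Q.
    """
    polys: dict[tuple[int, int, int], Poly] = {(0, 0, 0): {(0, 0, 0): 1.0}}
    for n in range(max_order):
        for idx in [m for m in polys if sum(m) == n]:
            q = polys[idx]
            for axis in range(3):
                new_idx = list(idx)
                new_idx[axis] += 1
                key = tuple(new_idx)
                if key in polys:
                    continue
                term = _poly_mul_r2(_poly_dx(q, axis))
                scaled = _poly_mul_axis(q, axis)
                out = dict(term)
                for mono, coef in scaled.items():
                    out[mono] = out.get(mono, 0.0) - (2 * n + 1) * coef
                polys[key] = {m: c for m, c in out.items() if c != 0.0}
    return polys


def _eval_poly(poly: Poly, xyz: np.ndarray) -> np.ndarray:
    """Evaluate a monomial dict at points of shape (..., 3)."""
    x, y, z = xyz[..., 0], xyz[..., 1], xyz[..., 2]
    out = np.zeros(xyz.shape[:-1])
    for (a, b, c), coef in poly.items():
        out += coef * x**a * y**b * z**c
    return out


def _deriv_1_over_r(idx: tuple[int, int, int], xyz: np.ndarray) -> np.ndarray:
    """D_{ijk}(r) for points of shape (..., 3)."""
    n = sum(idx)
    r = np.linalg.norm(xyz, axis=-1)
    return _eval_poly(_harmonic_polys()[idx], xyz) / r ** (2 * n + 1)


def _multi_indices(n: int) -> list[tuple[int, int, int]]:
    return [(i, j, n - i - j) for i in range(n, -1, -1) for j in range(n - i, -1, -1)]


def _multinomial(n: int, idx: tuple[int, int, int]) -> float:
    return math.factorial(n) / (
        math.factorial(idx[0]) * math.factorial(idx[1]) * math.factorial(idx[2])
    )


def _double_factorial(n: int) -> int:
    return math.prod(range(n, 0, -2)) if n > 0 else 1


@dataclass
class ChargeCloud:
    """Rigid surrogate charge distribution: positions (bohr) and charges (e)."""

    positions: np.ndarray
    charges: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.charges = np.atleast_1d(np.asarray(self.charges, dtype=float))
        if self.positions.shape != (self.charges.size, 3):
            raise ValueError("positions must be (n, 3) matching n charges")
        if self.charges.size < 1:
            raise ValueError("need at least one charge")
        if not (np.all(np.isfinite(self.positions)) and np.all(np.isfinite(self.charges))):
            raise ValueError("non-finite cloud data")

    @property
    def centroid(self) -> np.ndarray:
        """Unweighted geometric centroid, recomputed on access."""
        return self.positions.mean(axis=0)

    @property
    def total_charge(self) -> float:
        return float(self.charges.sum())

    @property
    def radius(self) -> float:
        """Largest distance of any charge from the centroid."""
        return float(np.max(np.linalg.norm(self.positions - self.centroid, axis=1)))


@dataclass
class MultipoleExpansion:
    """Traceless Cartesian moments about ``center``, orders 0..p.

    ``moments[n]`` maps the multi-index (i, j, k), i+j+k = n, to the tensor
    component; symmetry makes this representation complete.  Order 0 equals
    the total charge by construction.
    """

    center: np.ndarray
    moments: list[dict[tuple[int, int, int], float]]

    @property
    def order(self) -> int:
        return len(self.moments) - 1

    def trace_norm(self, n: int) -> float:
        """Max |trace| over contracted index pairs of the order-n tensor (0 if traceless)."""
        if n < 2:
            return 0.0
        worst = 0.0
        for idx in _multi_indices(n - 2):
            tr = sum(
                self.moments[n].get((idx[0] + 2 * (a == 0), idx[1] + 2 * (a == 1), idx[2] + 2 * (a == 2)), 0.0)
                for a in range(3)
            )
            worst = max(worst, abs(tr))
        return worst


def exact_interaction(
    cloud: ChargeCloud, env_positions: np.ndarray, env_charges: np.ndarray
) -> dict:
    """All-pairs Coulomb energy and analytic forces on the environment points.

    E = sum_jk q_j Q_k / |a_j - r_k|; F_k = Q_k * sum_j q_j (r_k - a_j)/|..|^3.
    The cloud is rigid, so only environment forces are reported.
    """
    env_positions = np.atleast_2d(np.asarray(env_positions, dtype=float))
    env_charges = np.atleast_1d(np.asarray(env_charges, dtype=float))
    diff = env_positions[:, None, :] - cloud.positions[None, :, :]  # (n_env, n_cloud, 3)
    dist = np.linalg.norm(diff, axis=-1)
    if np.any(dist < 1e-12):
        raise ValueError("coincident cloud and environment points")
    inv = 1.0 / dist
    energy = float(np.einsum("k,j,kj->", env_charges, cloud.charges, inv))
    forces = np.einsum("k,j,kjd->kd", env_charges, cloud.charges, diff * inv[..., None] ** 3)
    return {"energy": energy, "forces": forces}


def expand_multipoles(cloud: ChargeCloud, order: int) -> MultipoleExpansion:
    """Traceless Cartesian multipole moments of the cloud about its centroid.

    Orders above 8 are not implemented (the far-field machinery keeps the
    tensor algebra explicit and the benchmarks never need more).
    """
    if order < 0:
        raise ValueError("order must be >= 0")
    if order > MAX_ORDER:
        raise ValueError(f"multipole order {order} exceeds implemented maximum {MAX_ORDER}")
    rel = cloud.positions - cloud.centroid
    moments: list[dict[tuple[int, int, int], float]] = []
    for n in range(order + 1):
        sign = (-1.0) ** n / _double_factorial(2 * n - 1)
        comp = {}
        for idx in _multi_indices(n):
            vals = _eval_poly(_harmonic_polys()[idx], rel) if n > 0 else np.ones(cloud.charges.size)
            comp[idx] = float(sign * np.dot(cloud.charges, vals))
        moments.append(comp)
    return MultipoleExpansion(center=cloud.centroid.copy(), moments=moments)


def multipole_potential(exp: MultipoleExpansion, points: np.ndarray) -> np.ndarray:
    """Far-field potential of the truncated expansion at the given points.

    phi(R) = sum_n (-1)^n/n! * theta^(n) : grad^n (1/R); trace terms vanish
    against the harmonic derivative tensors, so contracting the traceless
    moments is exact.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    rel = points - exp.center
    out = np.zeros(points.shape[0])
    for n, comp in enumerate(exp.moments):
        pref = (-1.0) ** n / math.factorial(n)
        for idx, m in comp.items():
            if m == 0.0:
                continue
            out += pref * _multinomial(n, idx) * m * _deriv_1_over_r(idx, rel)
    return out


def multipole_field(exp: MultipoleExpansion, points: np.ndarray) -> np.ndarray:
    """Electric field (-grad phi) of the truncated expansion at the points."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    rel = points - exp.center
    out = np.zeros_like(points)
    for n, comp in enumerate(exp.moments):
        pref = (-1.0) ** n / math.factorial(n)
        for idx, m in comp.items():
            if m == 0.0:
                continue
            w = pref * _multinomial(n, idx) * m
            for axis in range(3):
                up = (idx[0] + (axis == 0), idx[1] + (axis == 1), idx[2] + (axis == 2))
                out[:, axis] -= w * _deriv_1_over_r(up, rel)
    return out


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    return np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)], axis=1
    )


def espf_grid(
    cloud: ChargeCloud,
    shell_radii: Sequence[float] = (2.0, 3.0, 4.0),
    points_per_shell: int = 32,
    prune_radius: float = 1.5,
) -> np.ndarray:
    """Atom-centered shell grid for ESP fitting (radii in bohr).

    Points within ``prune_radius`` of any atom are removed.
    """
    pts = []
    unit = _fibonacci_sphere(points_per_shell)
    for pos in cloud.positions:
        for r in shell_radii:
            pts.append(pos + r * unit)
    grid = np.concatenate(pts, axis=0)
    dmin = np.min(
        np.linalg.norm(grid[:, None, :] - cloud.positions[None, :, :], axis=-1), axis=1
    )
    return grid[dmin >= prune_radius - 1e-9]


def espf_fit(
    cloud: ChargeCloud,
    grid: np.ndarray | None = None,
    order: int = 0,
    shell_radii: Sequence[float] = (2.0, 3.0, 4.0),
    fit_positions: np.ndarray | None = None,
) -> np.ndarray:
    """Atom-centered charges fitted to the cloud's potential on the grid.

    Least squares with the total charge constrained exactly (Lagrange
    multiplier on sum(q) = Q_total).  ``fit_positions`` are the atom centers
    carrying the fitted charges; they default to the cloud positions (the
    fit is then exact by construction — the interesting case is a cloud
    standing in for a continuous density, fitted onto fewer centers).  Only
    fitting order 0 (charges) is implemented; higher orders raise.
    """
    if order != 0:
        raise NotImplementedError("ESPF fitting is implemented for order 0 (charges) only")
    if grid is None:
        grid = espf_grid(cloud, shell_radii=shell_radii)
    grid = np.atleast_2d(np.asarray(grid, dtype=float))
    centers = (
        cloud.positions
        if fit_positions is None
        else np.atleast_2d(np.asarray(fit_positions, dtype=float))
    )
    n_atoms = centers.shape[0]
    if grid.shape[0] <= n_atoms:
        raise ValueError("ESP grid must hold more points than unknown charges")
    dist = np.linalg.norm(grid[:, None, :] - centers[None, :, :], axis=-1)
    if np.any(dist < 1e-12):
        raise ValueError("grid point coincides with a fit center")
    design = 1.0 / dist
    src = np.linalg.norm(grid[:, None, :] - cloud.positions[None, :, :], axis=-1)
    target = (1.0 / src) @ cloud.charges  # exact potential of the cloud on the grid
    if np.linalg.matrix_rank(design, tol=1e-10) < n_atoms:
        raise ValueError("rank-deficient ESP design matrix (degenerate grid)")
    # KKT system for min ||A q - b||^2 s.t. sum(q) = Q
    ata = design.T @ design
    kkt = np.zeros((n_atoms + 1, n_atoms + 1))
    kkt[:n_atoms, :n_atoms] = 2.0 * ata
    kkt[:n_atoms, n_atoms] = 1.0
    kkt[n_atoms, :n_atoms] = 1.0
    rhs = np.concatenate([2.0 * design.T @ target, [cloud.total_charge]])
    sol = np.linalg.solve(kkt, rhs)
    return sol[:n_atoms]


@dataclass
class CouplingConfig:
    """Hybrid-evaluation settings: cutoff (bohr), scheme and expansion order."""

    r_exact: float
    scheme: str = "single_center"
    order: int = MAX_ORDER
    shell_radii: tuple[float, ...] = (2.0, 3.0, 4.0)

    def __post_init__(self) -> None:
        if self.r_exact < 0:
            raise ValueError("r_exact must be >= 0")
        if self.scheme not in ("single_center", "espf"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.order < 0:
            raise ValueError("order must be >= 0")


def hybrid_interaction(
    cloud: ChargeCloud,
    env_positions: np.ndarray,
    env_charges: np.ndarray,
    config: CouplingConfig,
) -> dict:
    """Exact Coulomb inside ``R_exact`` (centroid distance), approximation beyond.

    Returns the energy, the forces on every environment point, and the
    boolean mask of points handled exactly (its complement is handled by the
    approximate scheme — a disjoint cover).  The energy is discontinuous
    exactly at the cutoff shell when a point crosses it; no damping applied.
    """
    env_positions = np.atleast_2d(np.asarray(env_positions, dtype=float))
    env_charges = np.atleast_1d(np.asarray(env_charges, dtype=float))
    dist = np.linalg.norm(env_positions - cloud.centroid, axis=1)
    near = dist <= config.r_exact
    energy = 0.0
    forces = np.zeros_like(env_positions)
    if near.any():
        res = exact_interaction(cloud, env_positions[near], env_charges[near])
        energy += res["energy"]
        forces[near] = res["forces"]
    far = ~near
    if far.any():
        if config.scheme == "single_center":
            exp = expand_multipoles(cloud, config.order)
            phi = multipole_potential(exp, env_positions[far])
            efield = multipole_field(exp, env_positions[far])
            energy += float(np.dot(env_charges[far], phi))
            forces[far] = env_charges[far][:, None] * efield
        else:  # espf
            fitted = espf_fit(cloud, order=0, shell_radii=config.shell_radii)
            surrogate = ChargeCloud(positions=cloud.positions.copy(), charges=fitted)
            res = exact_interaction(surrogate, env_positions[far], env_charges[far])
            energy += res["energy"]
            forces[far] = res["forces"]
    return {"energy": energy, "forces": forces, "exact_mask": near}


def convergence_scan(
    cloud: ChargeCloud,
    env_positions: np.ndarray,
    env_charges: np.ndarray,
    r_values: Sequence[float],
    p_values: Sequence[int],
    scheme: str = "single_center",
) -> pd.DataFrame:
    """|dE| and |df_max| of the hybrid evaluation vs the exact reference.

    One row per (R_exact, order) pair; |df_max| is the largest absolute
    Cartesian force-component error over all environment points.
    """
    if len(r_values) == 0 or len(p_values) == 0:
        raise ValueError("empty scan lists")
    ref = exact_interaction(cloud, env_positions, env_charges)
    rows = []
    for r in r_values:
        for p in p_values:
            cfg = CouplingConfig(r_exact=r, scheme=scheme, order=p)
            res = hybrid_interaction(cloud, env_positions, env_charges, cfg)
            rows.append(
                {
                    "r_exact": r,
                    "order": p,
                    "abs_dE": abs(res["energy"] - ref["energy"]),
                    "abs_dFmax": float(np.max(np.abs(res["forces"] - ref["forces"]))),
                }
            )
    return pd.DataFrame(rows)
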