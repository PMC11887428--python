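"""Collision cross sections in N2: projection approximation and trajectory
method, plus the Mason-Schamp mobility <-> CCS conversion.

Projection approximation (PA)
    Orientation-averaged area of the projected union of atom-centered hard
    disks of radius (element vdW radius + probe radius).  A fast
    lower-fidelity screen.

Trajectory method (TM)
    Momentum-transfer collision integral Omega(1,1) at temperature T:
    Maxwell-Boltzmann average over relative speed (Gauss-Legendre
    quadrature), uniform average over collision orientations, and
    impact-parameter Monte-Carlo integration of 2 pi b (1 - cos chi) db,
    with the deflection angle chi from classical trajectories in the
    solute-gas potential

        V(r) = sum_i 4 eps_i [(sigma_i/r_i)^12 - (sigma_i/r_i)^6]
               - (alpha/2) |E(r)|^2

    where E is the electric field of the solute partial charges at the gas
    position.  The buffer gas is a single-site isotropic pseudo-atom; the
    N2 quadrupole and gas anisotropy are omitted (stated limitation).

All internal mechanics use kcal/mol, Angstrom and Dalton; the implied time
unit cancels throughout.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit
from scipy import constants
from scipy.spatial.transform import Rotation
from shapely.geometry import Point
from shapely.ops import unary_union

from .molecule import Molecule, element_mass, vdw_radius

logger = logging.getLogger(__name__)

__all__ = [
    "GasModel",
    "TMSettings",
    "CCSResult",
    "pa_ccs",
    "tm_ccs",
    "mason_schamp",
    "inverse_mason_schamp",
    "N2",
]

KB_KCAL = 1.987204e-3  # kcal/mol/K
COULOMB_KCAL = 332.0637  # kcal*Angstrom/(mol*e^2)

# Solute-gas 12-6 parameters for an N2 buffer treated as a single isotropic
# site: eps in kcal/mol, sigma in Angstrom.  A physically standard
# ion-mobility set for H/C/N/O (see docs/methods.md for provenance notes).
_N2_LJ: dict[str, tuple[float, float]] = {
    "H": (0.0189, 2.38),
    "C": (0.1072, 3.55),
    "N": (0.1072, 3.55),
    "O": (0.1072, 3.50),
}


@dataclass(frozen=True)
class GasModel:
    name: str = "N2"
    mass: float = 28.0134  # Da, single-site effective mass
    polarizability: float = 1.710  # Angstrom^3
    lj_params: dict = field(default_factory=lambda: dict(_N2_LJ))
    probe_radius: float = 1.5  # Angstrom, hard-sphere probe for PA

    def lj_for(self, elements: list[str]) -> tuple[np.ndarray, np.ndarray]:
        eps, sigma = [], []
        for el in elements:
            if el not in self.lj_params:
                raise KeyError(f"no {self.name} 12-6 parameters for element {el!r}")
            e, s = self.lj_params[el]
            eps.append(e)
            sigma.append(s)
        return np.array(eps), np.array(sigma)


N2 = GasModel()


@dataclass(frozen=True)
class TMSettings:
    cycles: int = 10
    velocity_points: int = 20
    mc_points: int = 500  # impact-parameter Monte Carlo points
    orientations: int = 1000  # random collision orientations per cycle
    temperature: float = 298.0  # K
    seed: int = 0

    def __post_init__(self):
        if min(self.cycles, self.velocity_points, self.mc_points, self.orientations) < 1:
            raise ValueError("all TM counts must be >= 1")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


@dataclass
class CCSResult:
    omega: float  # Angstrom^2
    stderr: float  # Angstrom^2, over cycles/orientations
    method: str  # "PA" or "TM"
    settings: dict = field(default_factory=dict)
    structure: str = ""
    n_failed_trajectories: int = 0


# -- projection approximation --------------------------------------------


def pa_ccs(
    m: Molecule,
    gas: GasModel = N2,
    n_orientations: int = 1000,
    seed: int = 0,
) -> CCSResult:
    """Monte-Carlo orientation average of the projected hard-disk union area.

    Each atom contributes a disk of radius (vdW radius + probe radius) in
    the projection plane; the union area is computed exactly per
    orientation (polygonal circles at 256 segments), so the only stochastic
    error is the orientation average.
    """
    if m.n_atoms == 0:
        raise ValueError("empty molecule")
    radii = np.array([vdw_radius(a.element) + gas.probe_radius for a in m.atoms])
    coords = m.coords - m.coords.mean(axis=0)
    rng = np.random.default_rng(seed)
    rots = Rotation.random(n_orientations, random_state=rng)
    areas = np.empty(n_orientations)
    for k, rot in enumerate(rots):
        xy = (rot.apply(coords))[:, :2]
        disks = [Point(p).buffer(r, quad_segs=64) for p, r in zip(xy, radii)]
        areas[k] = unary_union(disks).area
    omega = float(areas.mean())
    stderr = float(areas.std(ddof=1) / math.sqrt(n_orientations)) if n_orientations > 1 else 0.0
    return CCSResult(
        omega,
        stderr,
        "PA",
        {"n_orientations": n_orientations, "probe_radius": gas.probe_radius, "seed": seed},
        m.label,
    )


# -- trajectory method ----------------------------------------------------


class _TMPotential:
    """Batched solute-gas potential: 12-6 per atom plus charge-induced dipole."""

    def __init__(self, coords: np.ndarray, eps: np.ndarray, sigma: np.ndarray,
                 charges: np.ndarray, alpha: float):
        self.coords = coords
        self.eps4 = 4.0 * eps
        self.sig6 = sigma**6
        self.sig12 = self.sig6**2
        self.charges = charges
        self.alpha = alpha
        self.charged = bool(np.any(charges != 0.0))

    def energy(self, p: np.ndarray) -> np.ndarray:
        d = p[:, None, :] - self.coords[None, :, :]
        r2 = np.einsum("ijk,ijk->ij", d, d)
        inv6 = self.sig6 / r2**3
        v = (self.eps4 * (inv6**2 - inv6)).sum(axis=1)
        if self.charged:
            r = np.sqrt(r2)
            e_fld = np.einsum("j,ijk->ik", self.charges, d / (r**3)[:, :, None])
            v = v - 0.5 * COULOMB_KCAL * self.alpha * np.einsum("ik,ik->i", e_fld, e_fld)
        return v

    def force(self, p: np.ndarray) -> np.ndarray:
        d = p[:, None, :] - self.coords[None, :, :]
        r2 = np.einsum("ijk,ijk->ij", d, d)
        inv2 = 1.0 / r2
        inv6 = self.sig6 * inv2**3
        inv12 = self.sig12 * inv2**6
        coef = self.eps4 * (12.0 * inv12 - 6.0 * inv6) * inv2
        f = np.einsum("ij,ijk->ik", coef, d)
        if self.charged:
            r = np.sqrt(r2)
            inv3 = 1.0 / r**3
            dn = d * inv3[:, :, None]
            e_fld = np.einsum("j,ijk->ik", self.charges, dn)
            de = np.einsum("ij,ik->ijk", self.charges * inv3, e_fld)
            proj = np.einsum("ijk,ik->ij", d, e_fld) * self.charges * inv3 * inv2 * 3.0
            term = de - d * proj[:, :, None]
            f = f + COULOMB_KCAL * self.alpha * term.sum(axis=1)
        return f

    def min_dist(self, p: np.ndarray) -> np.ndarray:
        d = p[:, None, :] - self.coords[None, :, :]
        return np.sqrt(np.einsum("ijk,ijk->ij", d, d).min(axis=1))


@njit(cache=False)
def _force_energy(coords, eps4, sig6, sig12, q, alpha_kc, charged, px, py, pz):
    """Scalar solute-gas force/energy at one gas position (numba kernel)."""
    n = coords.shape[0]
    fx = fy = fz = 0.0
    v = 0.0
    rmin2 = 1e30
    ex = ey = ez = 0.0
    for i in range(n):
        dx = px - coords[i, 0]
        dy = py - coords[i, 1]
        dz = pz - coords[i, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 < rmin2:
            rmin2 = r2
        inv2 = 1.0 / r2
        inv6 = sig6[i] * inv2 * inv2 * inv2
        inv12 = sig12[i] * inv2 * inv2 * inv2 * inv2 * inv2 * inv2
        v += eps4[i] * (inv12 - inv6)
        coef = eps4[i] * (12.0 * inv12 - 6.0 * inv6) * inv2
        fx += coef * dx
        fy += coef * dy
        fz += coef * dz
        if charged:
            inv3 = 1.0 / (r2 * np.sqrt(r2))
            ex += q[i] * dx * inv3
            ey += q[i] * dy * inv3
            ez += q[i] * dz * inv3
    if charged:
        v -= 0.5 * alpha_kc * (ex * ex + ey * ey + ez * ez)
        for i in range(n):
            dx = px - coords[i, 0]
            dy = py - coords[i, 1]
            dz = pz - coords[i, 2]
            r2 = dx * dx + dy * dy + dz * dz
            inv3 = 1.0 / (r2 * np.sqrt(r2))
            dot = dx * ex + dy * ey + dz * ez
            c = q[i] * inv3
            fx += alpha_kc * c * (ex - 3.0 * dot * dx / r2)
            fy += alpha_kc * c * (ey - 3.0 * dot * dy / r2)
            fz += alpha_kc * c * (ez - 3.0 * dot * dz / r2)
    return fx, fy, fz, v, np.sqrt(rmin2)


@njit(cache=False)
def _traj_kernel(coords, eps4, sig6, sig12, q, alpha_kc, charged,
                 p0, v0, mu, r_stop, eta, max_steps):
    nb = p0.shape[0]
    v_out = np.empty((nb, 3))
    unfinished = np.zeros(nb, dtype=np.bool_)
    err = np.zeros(nb)
    for t in range(nb):
        px, py, pz = p0[t, 0], p0[t, 1], p0[t, 2]
        vx, vy, vz = v0[t, 0], v0[t, 1], v0[t, 2]
        fx, fy, fz, pot0, rn = _force_energy(
            coords, eps4, sig6, sig12, q, alpha_kc, charged, px, py, pz)
        e0 = 0.5 * mu * (vx * vx + vy * vy + vz * vz) + pot0
        done = False
        for _ in range(max_steps):
            speed = np.sqrt(vx * vx + vy * vy + vz * vz)
            fmag = np.sqrt(fx * fx + fy * fy + fz * fz)
            # transit bound far out, local harmonic timescale near the wall
            # (a speed-based bound would collapse at turning points)
            dt1 = rn / max(speed, 1e-12)
            dt2 = np.sqrt(rn * mu / max(fmag, 1e-12))
            dt = eta * min(dt1, dt2)
            dt = min(max(dt, 1e-5), 50.0)
            hvx = vx + 0.5 * dt * fx / mu
            hvy = vy + 0.5 * dt * fy / mu
            hvz = vz + 0.5 * dt * fz / mu
            px += hvx * dt
            py += hvy * dt
            pz += hvz * dt
            fx, fy, fz, pot, rn = _force_energy(
                coords, eps4, sig6, sig12, q, alpha_kc, charged, px, py, pz)
            vx = hvx + 0.5 * dt * fx / mu
            vy = hvy + 0.5 * dt * fy / mu
            vz = hvz + 0.5 * dt * fz / mu
            if (px * px + py * py + pz * pz > r_stop * r_stop
                    and px * vx + py * vy + pz * vz > 0.0):
                e1 = 0.5 * mu * (vx * vx + vy * vy + vz * vz) + pot
                err[t] = abs(e1 - e0) / abs(e0)
                done = True
                break
        if not done:
            unfinished[t] = True
        v_out[t, 0] = vx
        v_out[t, 1] = vy
        v_out[t, 2] = vz
    return v_out, unfinished, err


def _propagate(pot: _TMPotential, p0: np.ndarray, v0: np.ndarray, mu: float,
               r_stop: float, eta: float, max_steps: int = 200_000):
    """Velocity-Verlet with a per-trajectory adaptive step (numba core).

    Returns (final velocities, unfinished mask, relative energy error).
    """
    v, unfinished, err = _traj_kernel(
        pot.coords, pot.eps4, pot.sig6, pot.sig12, pot.charges,
        COULOMB_KCAL * pot.alpha, pot.charged,
        np.ascontiguousarray(p0), np.ascontiguousarray(v0),
        mu, r_stop, eta, max_steps,
    )
    return v, unfinished, err


def _start_radius(pot: _TMPotential, r_mol: float, tol: float = 1e-6) -> float:
    """Smallest radius (probed on a coarse direction grid) where |V| < tol."""
    dirs = []
    for x in (-1.0, 0.0, 1.0):
        for y in (-1.0, 0.0, 1.0):
            for z in (-1.0, 0.0, 1.0):
                if (x, y, z) != (0.0, 0.0, 0.0):
                    v = np.array([x, y, z])
                    dirs.append(v / np.linalg.norm(v))
    dirs = np.array(dirs)
    r = max(r_mol + 5.0, 8.0)
    while r < 400.0:
        if np.abs(pot.energy(dirs * r)).max() < tol:
            return r
        r *= 1.3
    return r


def _deflection(pot: _TMPotential, b: np.ndarray, dirs: np.ndarray, azim: np.ndarray,
                g: float, mu: float, r_start: float, eta: float):
    """Integrate one batch of trajectories; returns (chi, failed mask)."""
    u = dirs
    # perpendicular basis per trajectory
    ref = np.where(np.abs(u[:, 2:3]) < 0.9, [[0.0, 0.0, 1.0]], [[1.0, 0.0, 0.0]])
    w1 = np.cross(u, ref)
    w1 /= np.linalg.norm(w1, axis=1, keepdims=True)
    w2 = np.cross(u, w1)
    w = np.cos(azim)[:, None] * w1 + np.sin(azim)[:, None] * w2
    p0 = -r_start * u + b[:, None] * w
    v0 = g * u
    v_f, active, err = _propagate(pot, p0, v0, mu, r_start * 1.01, eta)
    failed = active | (err > 1e-4)
    if failed.any():  # retry the hard ones with smaller steps
        idx = np.where(failed)[0]
        v_r, act_r, err_r = _propagate(pot, p0[idx], v0[idx], mu, r_start * 1.01, eta / 4.0)
        v_f[idx] = v_r
        still = act_r | (err_r > 1e-4)
        failed = np.zeros(len(b), dtype=bool)
        failed[idx[still]] = True
    speed = np.linalg.norm(v_f, axis=1)
    cos_chi = np.einsum("ik,ik->i", v_f, u) / np.maximum(speed, 1e-12)
    chi = np.arccos(np.clip(cos_chi, -1.0, 1.0))
    return chi, failed


def _find_bmax(pot: _TMPotential, r_mol: float, g: float, mu: float,
               r_start: float, eta: float, rng: np.random.Generator) -> float:
    """Adaptive impact-parameter bound: increase until the deflection on a
    handful of probe orientations falls below 1e-3 rad (Omega is sensitive
    to b_max, so the bound is searched per relative speed)."""
    b = r_mol + 2.0
    dirs = _random_dirs(rng, 8)
    azim = rng.uniform(0, 2 * np.pi, 8)
    while b < 120.0:
        chi, failed = _deflection(pot, np.full(8, b), dirs, azim, g, mu, max(r_start, b * 1.05), eta)
        if not failed.any() and np.abs(np.minimum(chi, 2 * np.pi - chi)).max() < 1e-3:
            return b
        b += 2.0
    return b


def _random_dirs(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def tm_ccs(m: Molecule, gas: GasModel = N2, settings: TMSettings | None = None,
           eta: float = 0.02) -> CCSResult:
    """Trajectory-method momentum-transfer cross section Omega(1,1)(T).

    Per cycle, each Gauss-Legendre relative-speed node is averaged over
    random collision orientations with stratified impact-parameter
    sampling; the cycle estimates give the mean and standard error.
    Trajectories that fail energy conservation beyond 1e-4 relative (after
    one step-size halving pass) are excluded and counted.
    """
    settings = settings or TMSettings()
    if m.n_atoms == 0:
        raise ValueError("empty molecule")
    eps, sigma = gas.lj_for(m.elements)
    charges = m.partial_charges
    coords = m.coords
    masses = np.array([element_mass(el) for el in m.elements])
    com = (coords * masses[:, None]).sum(axis=0) / masses.sum()
    coords = coords - com
    pot = _TMPotential(coords, eps, sigma, charges, gas.polarizability)

    ion_mass = masses.sum()
    mu = ion_mass * gas.mass / (ion_mass + gas.mass)
    kt = KB_KCAL * settings.temperature
    r_mol = float(np.linalg.norm(coords, axis=1).max() + sigma.max())
    r_start = _start_radius(pot, r_mol)

    # Gauss-Legendre nodes on the reduced-speed variable gamma in [0, 6];
    # the Maxwell-Boltzmann weight gamma^5 exp(-gamma^2) is applied
    # explicitly and self-normalized so a hard sphere is reproduced exactly.
    nodes, wts = np.polynomial.legendre.leggauss(settings.velocity_points)
    gamma = 3.0 * (nodes + 1.0)
    wts = 3.0 * wts
    boltz = wts * gamma**5 * np.exp(-(gamma**2))
    boltz /= boltz.sum()
    speeds = gamma * math.sqrt(2.0 * kt / mu)

    master = np.random.default_rng(settings.seed)
    bmax = np.array([
        _find_bmax(pot, r_mol, g, mu, r_start, eta, master) for g in speeds
    ])

    n_failed = 0
    cycle_omegas = []
    for _ in range(settings.cycles):
        pool_dirs = _random_dirs(master, settings.orientations)
        pool_azim = master.uniform(0, 2 * np.pi, settings.orientations)
        cursor = 0
        q_vals = np.empty(settings.velocity_points)
        for k, g in enumerate(speeds):
            nmc = settings.mc_points
            take = (cursor + np.arange(nmc)) % settings.orientations
            cursor += nmc
            # stratified sampling of b^2 over [0, bmax^2]
            strata = (np.arange(nmc) + master.uniform(0, 1, nmc)) / nmc
            b = bmax[k] * np.sqrt(strata)
            chi, failed = _deflection(
                pot, b, pool_dirs[take], pool_azim[take], g, mu,
                max(r_start, bmax[k] * 1.05), eta,
            )
            n_failed += int(failed.sum())
            ok = ~failed
            q_vals[k] = math.pi * bmax[k] ** 2 * float((1.0 - np.cos(chi[ok])).mean()) if ok.any() else 0.0
        cycle_omegas.append(float((boltz * q_vals).sum()))
    cycle_omegas = np.array(cycle_omegas)
    omega = float(cycle_omegas.mean())
    stderr = float(cycle_omegas.std(ddof=1) / math.sqrt(settings.cycles)) if settings.cycles > 1 else 0.0
    return CCSResult(
        omega,
        stderr,
        "TM",
        {
            "cycles": settings.cycles,
            "velocity_points": settings.velocity_points,
            "mc_points": settings.mc_points,
            "orientations": settings.orientations,
            "temperature": settings.temperature,
            "seed": settings.seed,
            "gas": gas.name,
        },
        m.label,
        n_failed,
    )


# -- Mason-Schamp ---------------------------------------------------------

_LOSCHMIDT = constants.physical_constants["Loschmidt constant (273.15 K, 101.325 kPa)"][0]
_DA = constants.atomic_mass


def mason_schamp(k0: float, ion_mass: float, gas: GasModel = N2,
                 temperature: float = 298.0, z: int = 1) -> float:
    """CCS (Angstrom^2) from reduced mobility K0 (cm^2 V^-1 s^-1).

    Standard low-field Mason-Schamp relation with the reduced mass of ion
    and buffer gas; z is the charge number.
    """
    if k0 <= 0 or ion_mass <= 0 or temperature <= 0 or z <= 0:
        raise ValueError("mason_schamp requires positive K0, mass, T and z")
    mu = ion_mass * gas.mass / (ion_mass + gas.mass) * _DA  # kg
    omega_m2 = (
        3.0 * z * constants.e / (16.0 * _LOSCHMIDT)
        * math.sqrt(2.0 * math.pi / (mu * constants.k * temperature))
        / (k0 * 1e-4)
    )
    return omega_m2 * 1e20


def inverse_mason_schamp(omega: float, ion_mass: float, gas: GasModel = N2,
                         temperature: float = 298.0, z: int = 1) -> float:
    """Reduced mobility K0 (cm^2 V^-1 s^-1) from CCS (Angstrom^2)."""
    if omega <= 0 or ion_mass <= 0 or temperature <= 0 or z <= 0:
        raise ValueError("inverse_mason_schamp requires positive inputs")
    mu = ion_mass * gas.mass / (ion_mass + gas.mass) * _DA
    k0_m = (
        3.0 * z * constants.e / (16.0 * _LOSCHMIDT)
        * math.sqrt(2.0 * math.pi / (mu * constants.k * temperature))
        / (omega * 1e-20)
    )
    return k0_m * 1e4
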