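"""Nonlinear Poisson-Boltzmann solver for the diffusive ion atmosphere.

The diffusively bound ions (Na+, Mg2+ and the neutralizing Cl-) are treated
at the mean-field level: their Boltzmann-weighted densities enter the
Poisson equation as a nonlinear source, while the RNA phosphates and any
tightly bound Mg2+ act as fixed charges embedded in a low-dielectric
molecular region.  The solver works in reduced units (potential in
k_B T / e, lengths in Angstrom) on a 7-point finite-difference stencil with
harmonic-mean face dielectrics, and uses two-level focusing: a coarse solve
over a box padded by several Debye lengths supplies Dirichlet boundary
values for a fine solve around the molecule.

Two potentials are produced per system: Psi, with the mobile ions present,
and Psi', the pure Poisson solution of the identical fixed-charge and
dielectric problem with every mobile-ion term switched off.  Both enter the
diffusive enthalpy functional; the entropy functional needs Psi only.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates

from . import _kernels
from .config import TbiConfig
from .constants import MOLAR_TO_PER_A3, bjerrum_vacuum_A, kbt_kcal_mol
from .structures import RnaStructure

logger = logging.getLogger("tbion")

_PSI_CLAMP = 40.0
_MAX_NODES = 4.0e7


class SolverError(RuntimeError):
    """PB relaxation failed to converge; carries the final residual."""

    def __init__(self, message: str, residual: float = math.nan):
        super().__init__(message)
        self.residual = residual


def dielectric_of_water(temperature_celsius: float) -> float:
    """Empirical dielectric constant of water vs. temperature (Celsius).

    Cubic fit 87.740 - 0.4008 T + 9.398e-4 T^2 - 1.41e-6 T^3, valid for
    liquid water between 0 and 100 C (78.3 at 25 C, 74.1 at 37 C).
    """
    t = float(temperature_celsius)
    if not 0.0 <= t <= 100.0:
        raise ValueError(f"temperature {t} C outside liquid-water range [0, 100]")
    return 87.740 - 0.4008 * t + 9.398e-4 * t * t - 1.41e-6 * t * t * t


@dataclass
class SolutionCondition:
    """Ionic condition: temperature plus bulk Na+/Mg2+ concentrations.

    Cl- is included implicitly at the neutralizing concentration
    c_na + 2 c_mg.  The water dielectric is computed from temperature
    unless overridden.
    """

    temperature_celsius: float = 25.0
    c_na: float = 0.1
    c_mg: float = 0.0
    eps_in: float = 12.0
    eps_w: float | None = None

    def __post_init__(self):
        if self.c_na < 0 or self.c_mg < 0:
            raise ValueError("ion concentrations must be non-negative")
        if self.eps_w is None:
            self.eps_w = dielectric_of_water(self.temperature_celsius)
        if self.eps_in <= 1.0:
            raise ValueError("eps_in must exceed 1")
        if self.eps_w <= self.eps_in:
            raise ValueError("eps_w must exceed eps_in")

    @property
    def c_cl(self) -> float:
        return self.c_na + 2.0 * self.c_mg

    @property
    def kbt(self) -> float:
        """k_B T in kcal/mol."""
        return kbt_kcal_mol(self.temperature_celsius)

    @property
    def bjerrum(self) -> float:
        """Vacuum Bjerrum length e^2/(k_B T) in Angstrom."""
        return bjerrum_vacuum_A(self.temperature_celsius)

    def densities(self) -> dict:
        """Bulk number densities (1/A^3) per species."""
        return {
            "NA": self.c_na * MOLAR_TO_PER_A3,
            "CL": self.c_cl * MOLAR_TO_PER_A3,
            "MG": self.c_mg * MOLAR_TO_PER_A3,
        }

    @property
    def species(self):
        """(name, valence, bulk number density) for all mobile species."""
        d = self.densities()
        return (("NA", 1.0, d["NA"]), ("CL", -1.0, d["CL"]), ("MG", 2.0, d["MG"]))

    @property
    def kappa(self) -> float:
        """Inverse Debye length (1/A)."""
        s = sum(z * z * n for _, z, n in self.species)
        return math.sqrt(4.0 * math.pi * self.bjerrum / self.eps_w * s)

    @property
    def debye_length(self) -> float:
        k = self.kappa
        return math.inf if k == 0 else 1.0 / k


@dataclass
class GridLevel:
    """One finite-difference level: geometry maps plus solved potentials."""

    origin: np.ndarray
    spacing: float
    shape: tuple
    psi: np.ndarray = None
    psi_prime: np.ndarray = None
    ex: np.ndarray = None
    ey: np.ndarray = None
    ez: np.ndarray = None
    q_node: np.ndarray = None
    acc1: np.ndarray = None        # Na+/Cl- accessibility (0/1)
    acc2: np.ndarray = None        # Mg2+ accessibility (0/1)
    dist: np.ndarray = None        # signed distance to vdW surface
    weight: np.ndarray = None      # nodes owned by this level for integrals
    iterations: int = 0
    residual: float = 0.0

    def axes(self):
        return tuple(
            self.origin[d] + self.spacing * np.arange(self.shape[d]) for d in range(3)
        )

    def node_positions_flat(self, mask=None):
        ax = self.axes()
        X, Y, Z = np.meshgrid(*ax, indexing="ij")
        pts = np.stack([X, Y, Z], axis=-1).reshape(-1, 3)
        if mask is not None:
            pts = pts[mask.ravel()]
        return pts


@dataclass
class PbField:
    """Solution of the (nonlinear) PB problem on one or two levels.

    ``levels`` is ordered coarse -> fine; integrals use each level's
    ``weight`` mask so fine-covered space is not double counted.
    """

    levels: list
    cond: SolutionCondition
    converged: bool = True
    meta: dict = field(default_factory=dict)

    @property
    def fine(self) -> GridLevel:
        return self.levels[-1]

    def concentrations(self, level: GridLevel) -> dict:
        """Local number densities n_alpha(r) (1/A^3) on a level's nodes."""
        psi = np.clip(level.psi, -_PSI_CLAMP, _PSI_CLAMP)
        out = {}
        for name, z, n0 in self.cond.species:
            acc = level.acc2 if name == "MG" else level.acc1
            out[name] = n0 * np.exp(-z * psi) * acc
        return out

    def ion_excess(self) -> dict:
        """Volume-integrated excess ion counts per species (dimensionless).

        integral of [c_alpha(r) - c0_alpha] d^3 r over the solved region,
        with c = 0 inside the exclusion layer (so the excluded volume
        contributes its deficit, as the defining integral demands).
        """
        out = {name: 0.0 for name, _, _ in self.cond.species}
        for lev in self.levels:
            h3 = lev.spacing ** 3
            conc = self.concentrations(lev)
            w = lev.weight
            for name, _z, n0 in self.cond.species:
                out[name] += h3 * float(np.sum((conc[name] - n0)[w]))
        return out


# ---------------------------------------------------------------------------
# grid construction
# ---------------------------------------------------------------------------

def _distance_field(origin, spacing, shape, centers, radii, reach):
    """min over atoms of (|r - center| - radius), clipped above at `reach`."""
    d = np.full(shape, reach, dtype=float)
    ax = [origin[k] + spacing * np.arange(shape[k]) for k in range(3)]
    for c, R in zip(centers, radii):
        lo = [max(0, int(math.floor((c[k] - R - reach - origin[k]) / spacing))) for k in range(3)]
        hi = [min(shape[k], int(math.ceil((c[k] + R + reach - origin[k]) / spacing)) + 1) for k in range(3)]
        if any(lo[k] >= hi[k] for k in range(3)):
            continue
        xs = ax[0][lo[0]:hi[0]] - c[0]
        ys = ax[1][lo[1]:hi[1]] - c[1]
        zs = ax[2][lo[2]:hi[2]] - c[2]
        r = np.sqrt(
            xs[:, None, None] ** 2 + ys[None, :, None] ** 2 + zs[None, None, :] ** 2
        )
        sub = d[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        np.minimum(sub, r - R, out=sub)
    return d


def _spread_charges(origin, spacing, shape, xyz, q):
    """Trilinear spreading of point charges onto grid nodes (units: e)."""
    qn = np.zeros(shape)
    if len(q) == 0:
        return qn
    g = (np.asarray(xyz) - origin) / spacing
    i0 = np.floor(g).astype(int)
    frac = g - i0
    for corner in range(8):
        off = np.array([(corner >> 2) & 1, (corner >> 1) & 1, corner & 1])
        w = np.prod(np.where(off, frac, 1.0 - frac), axis=1)
        idx = i0 + off
        if np.any(idx < 0) or np.any(idx >= np.array(shape)):
            raise ValueError("charge outside grid (grid too small)")
        np.add.at(qn, (idx[:, 0], idx[:, 1], idx[:, 2]), np.asarray(q) * w)
    return qn


def _build_level(origin, spacing, shape, atoms_xyz, atoms_r, chg_xyz, chg_q, cond,
                 hydrated_na, hydrated_mg):
    reach = max(hydrated_mg, hydrated_na) + 2.0 * spacing
    d = _distance_field(origin, spacing, shape, atoms_xyz, atoms_r, reach)
    # dielectric: harmonic mix over the fraction of the cell inside the vdW
    # surface, smoothed across one grid cell
    f_in = np.clip(0.5 - d / spacing, 0.0, 1.0)
    eps_node = 1.0 / ((1.0 - f_in) / cond.eps_w + f_in / cond.eps_in)
    ex = 2.0 / (1.0 / eps_node[:-1, :, :] + 1.0 / eps_node[1:, :, :])
    ey = 2.0 / (1.0 / eps_node[:, :-1, :] + 1.0 / eps_node[:, 1:, :])
    ez = 2.0 / (1.0 / eps_node[:, :, :-1] + 1.0 / eps_node[:, :, 1:])
    lev = GridLevel(origin=np.asarray(origin, float), spacing=spacing, shape=tuple(shape))
    lev.ex, lev.ey, lev.ez = ex, ey, ez
    lev.dist = d
    # sharp (staircase) accessibility: the mobile-ion integrands are
    # discontinuous at the Stern surface, so smearing the mask would bias
    # them first-order toward the interior value
    lev.acc1 = (d >= hydrated_na).astype(np.float64)
    lev.acc2 = (d >= hydrated_mg).astype(np.float64)
    lev.q_node = _spread_charges(origin, spacing, shape, chg_xyz, chg_q)
    lev.weight = np.ones(shape, dtype=bool)
    lev.psi = np.zeros(shape)
    lev.psi_prime = np.zeros(shape)
    return lev


def _boundary_values(level, chg_xyz, chg_q, cond, screened: bool):
    """Debye-Hueckel (or bare Coulomb) superposition on the box faces."""
    psi = np.zeros(level.shape)
    if len(chg_q) == 0:
        return psi
    kappa = cond.kappa if screened else 0.0
    pref = cond.bjerrum / cond.eps_w
    ax = level.axes()
    nx, ny, nz = level.shape
    faces = []
    X, Y = np.meshgrid(ax[0], ax[1], indexing="ij")
    for kk in (0, nz - 1):
        faces.append(((slice(None), slice(None), kk), X, Y, np.full_like(X, ax[2][kk])))
    X, Z = np.meshgrid(ax[0], ax[2], indexing="ij")
    for jj in (0, ny - 1):
        faces.append(((slice(None), jj, slice(None)), X, np.full_like(X, ax[1][jj]), Z))
    Y, Z = np.meshgrid(ax[1], ax[2], indexing="ij")
    for ii in (0, nx - 1):
        faces.append(((ii, slice(None), slice(None)), np.full_like(Y, ax[0][ii]), Y, Z))
    for sl, fx, fy, fz in faces:
        val = np.zeros_like(fx)
        for (x, y, z), q in zip(chg_xyz, chg_q):
            r = np.sqrt((fx - x) ** 2 + (fy - y) ** 2 + (fz - z) ** 2)
            r = np.maximum(r, 1e-6)
            val += pref * q * np.exp(-kappa * r) / r
        psi[sl] = val
    return psi


def _interp_onto(level_from: GridLevel, level_to: GridLevel, which: str):
    """Trilinear interpolation of a coarse field onto a finer level."""
    src = getattr(level_from, which)
    ax_to = level_to.axes()
    X, Y, Z = np.meshgrid(*ax_to, indexing="ij")
    coords = [
        (X - level_from.origin[0]) / level_from.spacing,
        (Y - level_from.origin[1]) / level_from.spacing,
        (Z - level_from.origin[2]) / level_from.spacing,
    ]
    return map_coordinates(src, coords, order=1, mode="nearest")


# ---------------------------------------------------------------------------
# relaxation driver
# ---------------------------------------------------------------------------

def _relax(level, cond, config, mobile: bool, which: str):
    psi = getattr(level, which)
    h = level.spacing
    s = 4.0 * math.pi * cond.bjerrum / h
    q_s = level.q_node * s
    fac = 4.0 * math.pi * cond.bjerrum * h * h
    if mobile:
        dn = cond.densities()
        n_na, n_cl, n_mg = dn["NA"], dn["CL"], dn["MG"]
    else:
        n_na = n_cl = n_mg = 0.0
    m = max(level.shape)
    omega_opt = 2.0 / (1.0 + math.sin(math.pi / m))
    omega_opt = min(omega_opt, 1.95)
    tol = config.pb_tol
    it = 0
    res = math.inf
    # a short damped phase tames the nonlinearity before over-relaxation
    warmup = 20 if mobile else 0
    while it < config.pb_max_iter:
        omega = 1.0 if it < warmup else omega_opt
        r0 = _kernels.sweep(psi, level.ex, level.ey, level.ez, q_s,
                            level.acc1, level.acc2, n_na, n_cl, n_mg, fac, omega, 0)
        r1 = _kernels.sweep(psi, level.ex, level.ey, level.ez, q_s,
                            level.acc1, level.acc2, n_na, n_cl, n_mg, fac, omega, 1)
        res = max(r0, r1)
        it += 1
        if it > warmup and res < tol:
            break
    level.iterations += it
    level.residual = res
    if res >= tol:
        raise SolverError(
            f"PB relaxation did not converge: residual {res:.3e} after {it} sweeps", res
        )
    return psi


# ---------------------------------------------------------------------------
# public entry points
# ---------------------------------------------------------------------------

def solve_fixed_charges(atoms_xyz, atoms_r, chg_xyz, chg_q, cond: SolutionCondition,
                        config: TbiConfig | None = None,
                        compute_psi_prime: bool = True) -> PbField:
    """Solve the full (nonlinear, mixed-valence) PB problem.

    ``atoms_xyz``/``atoms_r`` define the low-dielectric region and the ion
    exclusion layer; ``chg_xyz``/``chg_q`` are the fixed point charges
    (phosphates plus tightly bound ions).  Returns a :class:`PbField`
    carrying Psi and Psi' on one or two focusing levels.
    """
    config = config or TbiConfig()
    atoms_xyz = np.asarray(atoms_xyz, float).reshape(-1, 3)
    atoms_r = np.asarray(atoms_r, float)
    chg_xyz = np.asarray(chg_xyz, float).reshape(-1, 3)
    chg_q = np.asarray(chg_q, float)
    mobile = (cond.c_na > 0) or (cond.c_mg > 0)

    rmax = float(atoms_r.max()) if len(atoms_r) else 2.0
    lo = atoms_xyz.min(axis=0) - rmax
    hi = atoms_xyz.max(axis=0) + rmax
    ld = cond.debye_length
    pad = config.padding_min if not math.isfinite(ld) else max(
        config.padding_min, config.padding_debye * ld)
    outer_lo, outer_hi = lo - pad, hi + pad

    h_na = config.hydrated_radii.get("NA", 3.5)
    h_mg = config.hydrated_radii.get("MG", 4.5)

    focus_lo = lo - config.focus_margin
    focus_hi = hi + config.focus_margin
    single = bool(np.all(focus_lo <= outer_lo + config.coarse_spacing)
                  and np.all(focus_hi >= outer_hi - config.coarse_spacing))

    def _centered(lo, hi, h):
        # odd node counts keep a node exactly at the box center, so node
        # placement is identical across padding choices
        shape = tuple(2 * int(math.ceil((hi[k] - lo[k]) / h / 2.0)) + 1
                      for k in range(3))
        ctr = (lo + hi) / 2.0
        origin = np.array([ctr[k] - (shape[k] - 1) * h / 2.0 for k in range(3)])
        return origin, shape

    levels = []
    if single:
        h = config.grid_spacing
        origin, shape = _centered(outer_lo, outer_hi, h)
        _check_nodes(shape)
        lev = _build_level(origin, h, shape, atoms_xyz, atoms_r, chg_xyz, chg_q,
                           cond, h_na, h_mg)
        lev.psi[:] = _boundary_values(lev, chg_xyz, chg_q, cond, screened=mobile)
        _freeze_boundary_and_relax(lev, cond, config, mobile, "psi")
        if compute_psi_prime:
            lev.psi_prime[:] = _boundary_values(lev, chg_xyz, chg_q, cond, screened=False)
            _freeze_boundary_and_relax(lev, cond, config, False, "psi_prime")
        levels.append(lev)
    else:
        hc = config.coarse_spacing
        origin_c, shape_c = _centered(outer_lo, outer_hi, hc)
        _check_nodes(shape_c)
        coarse = _build_level(origin_c, hc, shape_c, atoms_xyz, atoms_r, chg_xyz, chg_q,
                              cond, h_na, h_mg)
        coarse.psi[:] = _boundary_values(coarse, chg_xyz, chg_q, cond, screened=mobile)
        _freeze_boundary_and_relax(coarse, cond, config, mobile, "psi")
        if compute_psi_prime:
            coarse.psi_prime[:] = _boundary_values(coarse, chg_xyz, chg_q, cond, screened=False)
            _freeze_boundary_and_relax(coarse, cond, config, False, "psi_prime")

        h = config.grid_spacing
        f_lo = np.maximum(focus_lo, outer_lo)
        f_hi = np.minimum(focus_hi, outer_hi)
        origin_f, shape_f = _centered(f_lo, f_hi, h)
        _check_nodes(shape_f)
        fine = _build_level(origin_f, h, shape_f, atoms_xyz, atoms_r, chg_xyz, chg_q,
                            cond, h_na, h_mg)
        fine.psi[:] = _interp_onto(coarse, fine, "psi")
        _freeze_boundary_and_relax(fine, cond, config, mobile, "psi")
        if compute_psi_prime:
            fine.psi_prime[:] = _interp_onto(coarse, fine, "psi_prime")
            _freeze_boundary_and_relax(fine, cond, config, False, "psi_prime")

        # integration ownership: coarse nodes strictly inside the fine box
        # belong to the fine level
        axc = coarse.axes()
        Xc, Yc, Zc = np.meshgrid(*axc, indexing="ij")
        inside_fine = (
            (Xc > origin_f[0]) & (Xc < origin_f[0] + h * (shape_f[0] - 1))
            & (Yc > origin_f[1]) & (Yc < origin_f[1] + h * (shape_f[1] - 1))
            & (Zc > origin_f[2]) & (Zc < origin_f[2] + h * (shape_f[2] - 1))
        )
        coarse.weight = ~inside_fine
        levels = [coarse, fine]
        return PbField(levels=levels, cond=cond,
                       meta={"padding": pad, "mobile": mobile})

    return PbField(levels=levels, cond=cond, meta={"padding": pad, "mobile": mobile})


def _check_nodes(shape):
    n = float(np.prod(shape))
    if n > _MAX_NODES:
        raise ValueError(f"grid of {n:.0f} nodes exceeds the {_MAX_NODES:.0f} cap; "
                         "coarsen the spacing or shrink the padding")


def _freeze_boundary_and_relax(level, cond, config, mobile, which):
    if not mobile and which == "psi":
        pass  # pure Poisson for psi as well (salt-free condition)
    _relax(level, cond, config, mobile, which)


def solve_nlpb(structure: RnaStructure, bound_ions, cond: SolutionCondition,
               config: TbiConfig | None = None,
               compute_psi_prime: bool = True) -> PbField:
    """PB solve for an RNA structure plus tightly bound ions.

    ``bound_ions`` is a sequence of (position, charge) pairs; each bound ion
    also contributes a hydrated-ion-sized cavity to the dielectric map.
    """
    config = config or TbiConfig()
    ion_r = config.hydrated_radii.get("MG", 4.5)
    atoms_xyz = structure.atom_xyz
    atoms_r = structure.atom_radius
    chg_xyz = [tuple(p) for p in structure.phos_xyz]
    chg_q = list(structure.phosphate_charges)
    for pos, q in bound_ions or []:
        atoms_xyz = np.vstack([atoms_xyz, np.asarray(pos, float)])
        atoms_r = np.append(atoms_r, ion_r)
        chg_xyz.append(tuple(pos))
        chg_q.append(q)
    return solve_fixed_charges(atoms_xyz, atoms_r, chg_xyz, chg_q, cond, config,
                               compute_psi_prime=compute_psi_prime)


def diffusive_free_energy(fld: PbField, cond: SolutionCondition | None = None):
    """Diffusive-ion enthalpy and entropy functionals.

    Returns ``(delta_u_d, delta_s_d)`` with the enthalpy in k_B T and the
    entropy in k_B, so the free-energy contribution is
    ``delta_u_d - delta_s_d`` (in k_B T):

      dU_d = 1/2 int sum_a c_a(r) z_a [Psi(r) + Psi'(r)] d^3 r
      dS_d = -k_B int sum_a [c_a ln(c_a/c0_a) - c_a + c0_a] d^3 r

    The bracketed entropy integrand is pointwise non-negative, so
    -T dS_d >= 0 always.
    """
    cond = cond or fld.cond
    du = 0.0
    neg_tds = 0.0
    for lev in fld.levels:
        h3 = lev.spacing ** 3
        w = lev.weight
        psi = np.clip(lev.psi, -_PSI_CLAMP, _PSI_CLAMP)
        psum = lev.psi + lev.psi_prime
        for name, z, n0 in cond.species:
            if n0 == 0.0:
                continue
            acc = lev.acc2 if name == "MG" else lev.acc1
            n = n0 * np.exp(-z * psi) * acc
            if np.any(n < 0):
                raise ValueError("negative local concentration (invariant violation)")
            du += 0.5 * h3 * float(np.sum((n * z * psum)[w]))
            # c ln(c/c0) - c + c0, with the c -> 0 limit giving +c0
            with np.errstate(divide="ignore", invalid="ignore"):
                term = np.where(n > 0, n * np.log(np.maximum(n, 1e-300) / n0) - n + n0, n0)
            neg_tds += h3 * float(np.sum(term[w]))
    return du, -neg_tds
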