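"""Generalized-Born energies for the tightly bound region.

The charges inside and on the RNA (phosphates, plus any tightly bound
Mg2+) interact through three terms:

* a Coulomb sum at the interior dielectric, U_ele;
* a Still-kernel polarization correction, U_pol, which restores full water
  screening for well-separated, solvent-exposed pairs;
* a self (Born) term, U_self, for each charge's own reaction field.

The self term for every charge x is evaluated as

    1/2 (1/eps_w - 1/eps_in) q_x^2 (1/B_x - 1/B0_x)

where B_x is the effective Born radius in the assembled structure and B0_x
the Born radius of the same charge in isolation (its reference state).  A
bound ion's B0 is its hydrated radius; a phosphate's B0 is its intrinsic
atomic radius, so the term is the desolvation penalty of burial and
vanishes for an unburied charge, consistent with the pair terms vanishing
at infinite separation.  Setting B0 = inf recovers the bare q^2/B form.

Born radii come from the Coulomb-field approximation: the reciprocal radius
is the intrinsic one minus the (1/4 pi) integral of r^-4 over the
low-dielectric region outside the charge's own sphere, evaluated by grid
quadrature over the atom-sphere union.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .config import TbiConfig
from .constants import COULOMB_KCAL_A
from .structures import RnaStructure

#: default quadrature spacing (A) for the Born-radius volume integral
BORN_GRID_SPACING = 0.6


@dataclass
class ChargeConfig:
    """Charges of the tightly bound region with their Born radii.

    positions : (n, 3) Angstrom; q : (n,) elementary charges;
    born : (n,) effective Born radii B; born_ref : (n,) reference radii B0
    (np.inf reproduces the unreferenced q^2/B self term); kind : list of
    'phosphate' | 'bound_ion'.
    """

    positions: np.ndarray
    q: np.ndarray
    born: np.ndarray
    born_ref: np.ndarray
    kind: list

    def __post_init__(self):
        self.positions = np.asarray(self.positions, float).reshape(-1, 3)
        self.q = np.asarray(self.q, float)
        self.born = np.asarray(self.born, float)
        self.born_ref = np.asarray(self.born_ref, float)
        if np.any(self.born <= 0) or np.any(self.born_ref <= 0):
            raise ValueError("Born radii must be positive")

    def __len__(self):
        return len(self.q)


def _solute_nodes(atoms_xyz, atoms_r, spacing):
    """Centers (and cell volume) of quadrature nodes inside the vdW union."""
    atoms_xyz = np.asarray(atoms_xyz, float).reshape(-1, 3)
    atoms_r = np.asarray(atoms_r, float)
    lo = (atoms_xyz - atoms_r[:, None]).min(axis=0) - spacing
    hi = (atoms_xyz + atoms_r[:, None]).max(axis=0) + spacing
    ax = [np.arange(lo[k] + spacing / 2, hi[k], spacing) for k in range(3)]
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    pts = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)
    inside = np.zeros(len(pts), dtype=bool)
    for c, R in zip(atoms_xyz, atoms_r):
        d2 = np.einsum("ij,ij->i", pts - c, pts - c)
        inside |= d2 <= R * R
    return pts[inside], spacing ** 3


def born_radii_from_geometry(charge_xyz, charge_a, atoms_xyz, atoms_r,
                             spacing: float = BORN_GRID_SPACING) -> np.ndarray:
    """Coulomb-field-approximation Born radii.

    ``charge_a`` are the intrinsic radii; the low-dielectric region is the
    union of the ``atoms_xyz``/``atoms_r`` spheres.  An isolated charge
    whose sphere is the only solute returns B = a; a charge buried at the
    center of a large solute sphere of radius R returns B -> R.
    """
    charge_xyz = np.asarray(charge_xyz, float).reshape(-1, 3)
    charge_a = np.asarray(charge_a, float)
    if len(charge_xyz) > 1:
        if pdist(charge_xyz).min() < 1e-9:
            raise ValueError("degenerate geometry: coincident charges")
    atoms_xyz = np.asarray(atoms_xyz, float).reshape(-1, 3)
    atoms_r = np.asarray(atoms_r, float)
    nodes, vol = _solute_nodes(atoms_xyz, atoms_r, spacing)
    # sub-cell offsets for refining cells close to the 1/r^4 singularity
    s3 = (np.arange(3) - 1.0) / 3.0 * spacing
    OX, OY, OZ = np.meshgrid(s3, s3, s3, indexing="ij")
    sub = np.stack([OX.ravel(), OY.ravel(), OZ.ravel()], axis=1)
    out = np.empty(len(charge_xyz))
    for i, (x, a) in enumerate(zip(charge_xyz, charge_a)):
        d2 = np.einsum("ij,ij->i", nodes - x, nodes - x)
        near = d2 < (a + 2.5 * spacing) ** 2
        far = ~near & (d2 > 0)
        integral = vol * float(np.sum(1.0 / (d2[far] ** 2)))
        if np.any(near):
            # refine: subpoints must lie in the solute union and outside
            # the charge's own sphere
            pts = (nodes[near][:, None, :] + sub[None, :, :]).reshape(-1, 3)
            member = np.zeros(len(pts), dtype=bool)
            for c, R in zip(atoms_xyz, atoms_r):
                member |= ((pts - c) ** 2).sum(axis=1) <= R * R
            dd2 = np.einsum("ij,ij->i", pts[member] - x, pts[member] - x)
            dd2 = dd2[dd2 > a * a]
            integral += vol / 27.0 * float(np.sum(1.0 / (dd2 ** 2)))
        inv_b = 1.0 / a - integral / (4.0 * math.pi)
        out[i] = 1.0 / max(inv_b, 1e-6)
    return out


def born_radii(structure: RnaStructure, bound_ions=None,
               config: TbiConfig | None = None,
               spacing: float = BORN_GRID_SPACING):
    """Born radii for a structure's phosphates plus bound ions.

    Returns ``(b_phos, b_ions)``; the dielectric region is the union of the
    structure's atoms and a hydrated-radius sphere per bound ion.
    """
    config = config or TbiConfig()
    ion_r = config.hydrated_radii.get("MG", 4.5)
    bound_ions = list(bound_ions or [])
    atoms_xyz = structure.atom_xyz
    atoms_r = structure.atom_radius
    # intrinsic radius of a phosphate charge = vdW radius of its P atom
    a_phos = np.empty(structure.n_phosphates)
    for k in range(structure.n_phosphates):
        hit = np.flatnonzero(
            (np.abs(structure.atom_xyz - structure.phos_xyz[k]).sum(axis=1) < 1e-9)
        )
        a_phos[k] = structure.atom_radius[hit[0]] if len(hit) else 2.0
    chg = [tuple(p) for p in structure.phos_xyz]
    a = list(a_phos)
    if bound_ions:
        atoms_xyz = np.vstack([atoms_xyz] + [np.asarray(p, float).reshape(1, 3)
                                             for p, _q in bound_ions])
        atoms_r = np.append(atoms_r, [ion_r] * len(bound_ions))
        chg += [tuple(p) for p, _q in bound_ions]
        a += [ion_r] * len(bound_ions)
    b = born_radii_from_geometry(chg, np.array(a), atoms_xyz, atoms_r, spacing)
    return b[: structure.n_phosphates], b[structure.n_phosphates:]


def make_charge_config(structure: RnaStructure, bound_ions=None,
                       config: TbiConfig | None = None,
                       spacing: float = BORN_GRID_SPACING,
                       phosphate_reference: str = "self") -> ChargeConfig:
    """Assemble the :class:`ChargeConfig` for a structure + bound ions.

    ``phosphate_reference`` fixes the reference state of the phosphate
    self term: ``'self'`` (default) takes B0_p = B_p, i.e. the phosphates'
    solvation state is part of the fixed reference and their self term
    vanishes — phosphates are covalently fixed in the structure, so only
    ions change solvation upon binding; ``'intrinsic'`` sets B0_p to the
    intrinsic atomic radius (self energy = desolvation penalty of burial);
    ``'none'`` sets B0 = inf (bare q^2/B self term).
    """
    config = config or TbiConfig()
    ion_r = config.hydrated_radii.get("MG", 4.5)
    bound_ions = list(bound_ions or [])
    b_phos, b_ion = born_radii(structure, bound_ions, config, spacing)
    a_phos = np.empty(structure.n_phosphates)
    for k in range(structure.n_phosphates):
        hit = np.flatnonzero(
            (np.abs(structure.atom_xyz - structure.phos_xyz[k]).sum(axis=1) < 1e-9)
        )
        a_phos[k] = structure.atom_radius[hit[0]] if len(hit) else 2.0
    positions = list(structure.phos_xyz) + [np.asarray(p, float) for p, _q in bound_ions]
    q = list(structure.phosphate_charges) + [q for _p, q in bound_ions]
    if phosphate_reference == "self":
        ref_p = list(b_phos)
    elif phosphate_reference == "intrinsic":
        ref_p = list(a_phos)
    elif phosphate_reference == "none":
        ref_p = [np.inf] * structure.n_phosphates
    else:
        raise ValueError(f"unknown phosphate_reference {phosphate_reference!r}")
    born = np.concatenate([b_phos, b_ion]) if len(b_ion) else b_phos
    born_ref = np.array(ref_p + [ion_r] * len(bound_ions))
    kind = ["phosphate"] * structure.n_phosphates + ["bound_ion"] * len(bound_ions)
    return ChargeConfig(positions=np.array(positions), q=np.array(q),
                        born=born, born_ref=born_ref, kind=kind)


# ---------------------------------------------------------------------------
# energy terms (returned in k_B T)
# ---------------------------------------------------------------------------

def _prefactor(cond) -> float:
    """(1/eps_w - 1/eps_in) * e^2 in kcal*A/mol, then per k_B T."""
    return (1.0 / cond.eps_w - 1.0 / cond.eps_in) * COULOMB_KCAL_A / cond.kbt


def u_self(cfg: ChargeConfig, cond) -> float:
    """Born self energy, k_B T; vanishes when eps_in = eps_w."""
    inv = 1.0 / cfg.born - np.where(np.isfinite(cfg.born_ref), 1.0 / cfg.born_ref, 0.0)
    return 0.5 * _prefactor(cond) * float(np.sum(cfg.q ** 2 * inv))


def still_kernel(r: np.ndarray, bm: np.ndarray, bn: np.ndarray) -> np.ndarray:
    """sqrt(r^2 + Bm Bn exp(-r^2 / (4 Bm Bn))): between r and sqrt(r^2+BmBn)."""
    bb = bm * bn
    return np.sqrt(r * r + bb * np.exp(-(r * r) / (4.0 * bb)))


def u_pol(cfg: ChargeConfig, cond) -> float:
    """Pairwise polarization (cross reaction-field) energy, k_B T."""
    n = len(cfg)
    if n < 2:
        return 0.0
    r = pdist(cfg.positions)
    iu = np.triu_indices(n, 1)
    qq = (cfg.q[:, None] * cfg.q[None, :])[iu]
    bb_m = cfg.born[iu[0]]
    bb_n = cfg.born[iu[1]]
    return _prefactor(cond) * float(np.sum(qq / still_kernel(r, bb_m, bb_n)))


def u_ele(cfg: ChargeConfig, cond) -> float:
    """Coulomb energy at the interior dielectric, k_B T."""
    n = len(cfg)
    if n < 2:
        return 0.0
    r = pdist(cfg.positions)
    if r.min() < 1e-9:
        raise ValueError("coincident charges in Coulomb sum")
    iu = np.triu_indices(n, 1)
    qq = (cfg.q[:, None] * cfg.q[None, :])[iu]
    return COULOMB_KCAL_A / (cond.eps_in * cond.kbt) * float(np.sum(qq / r))


def gb_energies(cfg: ChargeConfig, cond) -> dict:
    """All three tightly-bound-region terms at once (k_B T)."""
    return {
        "u_self": u_self(cfg, cond),
        "u_pol": u_pol(cfg, cond),
        "u_ele": u_ele(cfg, cond),
    }
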