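"""Discrete binding-mode statistics of the tightly bound ions.

The strongly correlated Mg2+ ions live in a thin layer over the RNA
surface, partitioned into one cell per phosphate.  A binding mode assigns
0 or 1 tightly bound ions to each cell; the model's partition sum runs over
modes, and within a mode over the positions of the bound ions inside their
cells.  Relative to the uniform ion solution, a mode's statistical weight
is

    w_M = prod_{occupied cells} (n0_Mg * V_cell) * < exp(-dG(R)/kT) >_R

with n0_Mg the bulk Mg2+ number density, V_cell the cell volume, and the
average a uniform one over in-cell placements R; dG(R) collects the
generalized-Born terms of the tightly bound charges plus the
Poisson-Boltzmann free energy of the diffusive ions around them.  The
total electrostatic free energy is dG_tot = -kT ln sum_M w_M and mode
probabilities are P_M = w_M / sum w_M.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .born import gb_energies, make_charge_config
from .config import TbiConfig
from .constants import MOLAR_TO_PER_A3
from .pb_solver import PbField, SolutionCondition, SolverError, diffusive_free_energy, solve_nlpb
from .structures import RnaStructure

logger = logging.getLogger("tbion")

#: quadrature/sampling grid spacing (A) for tightly-bound-region cells
REGION_SPACING = 0.9


class TooManyModes(RuntimeError):
    """Enumeration would exceed the configured cap; sample instead."""


@dataclass
class TightlyBoundRegion:
    """Per-phosphate cells of the tightly bound layer.

    Each cell is represented by the quadrature nodes (cell centers of a
    uniform grid) lying in the shell between the Mg2+ contact surface and
    ``t_shell`` beyond it, assigned to their nearest phosphate.  Cells are
    disjoint by construction.
    """

    nodes: list                  # per cell: (m_i, 3) node centers
    volumes: np.ndarray          # per cell volume, A^3
    spacing: float
    phos_xyz: np.ndarray

    @property
    def n_cells(self) -> int:
        return len(self.nodes)

    def sample_position(self, cell: int, rng: np.random.Generator) -> np.ndarray:
        """Uniform random point of a cell (node + in-cube jitter)."""
        pts = self.nodes[cell]
        if len(pts) == 0:
            raise ValueError(f"cell {cell} is empty")
        k = rng.integers(len(pts))
        return pts[k] + rng.uniform(-0.5, 0.5, 3) * self.spacing


@dataclass(frozen=True)
class BindingMode:
    """Occupancy vector over the N phosphate cells (0/1 each)."""

    counts: tuple

    def __post_init__(self):
        if any(c not in (0, 1) for c in self.counts):
            raise ValueError("cell occupancies must be 0 or 1")

    @property
    def n_bound(self) -> int:
        return int(sum(self.counts))

    @property
    def occupied(self) -> tuple:
        return tuple(i for i, c in enumerate(self.counts) if c)

    @classmethod
    def empty(cls, n: int) -> "BindingMode":
        return cls(counts=(0,) * n)


@dataclass
class ModeEvaluation:
    """A mode's averaged energies, weight and (later) probability.

    ``dG_M`` is the position-averaged energy part, -kT ln <exp(-dG(R)/kT)>,
    equal to the sum of the five averaged components within averaging
    tolerance.  ``log_weight`` additionally carries the fugacity/volume
    factor ln(n0_Mg V_cell) per bound ion; probabilities are computed from
    it.
    """

    mode: BindingMode
    dG_M: float
    components: dict
    log_weight: float
    n_position_samples: int
    ion_excess: dict = field(default_factory=dict)
    probability: float = 0.0


@dataclass
class TbiResult:
    """Total free energy, its components (all k_B T), and the mode set."""

    dG_tot: float
    dE_ele: float
    dG_pol: float
    dG_self: float
    dG_s: float
    dU_d: float
    tds_d: float
    evaluations: list
    most_probable: BindingMode
    mean_bound: float


# ---------------------------------------------------------------------------
# tightly bound region
# ---------------------------------------------------------------------------

def build_tb_region(structure: RnaStructure, cond: SolutionCondition | None = None,
                    config: TbiConfig | None = None,
                    spacing: float = REGION_SPACING) -> TightlyBoundRegion:
    """Partition the tightly bound layer into per-phosphate cells.

    The layer is the set of points whose distance beyond the van der Waals
    surface lies in [r_Mg_hydrated, r_Mg_hydrated + t_shell] — i.e. a shell
    of thickness ``t_shell`` starting at the Mg2+ contact surface.  Points
    are assigned to the nearest phosphate.  Deterministic for fixed inputs.
    """
    config = config or TbiConfig()
    contact = config.hydrated_radii.get("MG", 4.5)
    outer = contact + config.t_shell
    lo = (structure.atom_xyz - structure.atom_radius[:, None]).min(axis=0) - outer - spacing
    hi = (structure.atom_xyz + structure.atom_radius[:, None]).max(axis=0) + outer + spacing
    ax = [np.arange(lo[k] + spacing / 2, hi[k], spacing) for k in range(3)]
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    pts = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)
    # distance beyond the vdW surface
    d = np.full(len(pts), np.inf)
    for c, R in zip(structure.atom_xyz, structure.atom_radius):
        dd = np.sqrt(np.einsum("ij,ij->i", pts - c, pts - c)) - R
        np.minimum(d, dd, out=d)
    shell = (d >= contact) & (d < outer)
    pts = pts[shell]
    # nearest-phosphate partition
    d2 = ((pts[:, None, :] - structure.phos_xyz[None, :, :]) ** 2).sum(axis=2) \
        if len(pts) * structure.n_phosphates < 2.0e7 else None
    if d2 is not None:
        owner = np.argmin(d2, axis=1)
    else:
        owner = np.empty(len(pts), dtype=int)
        for i in range(0, len(pts), 50000):
            blk = pts[i:i + 50000]
            dd = ((blk[:, None, :] - structure.phos_xyz[None, :, :]) ** 2).sum(axis=2)
            owner[i:i + 50000] = np.argmin(dd, axis=1)
    nodes = [pts[owner == i] for i in range(structure.n_phosphates)]
    vol = np.array([len(n) * spacing ** 3 for n in nodes])
    return TightlyBoundRegion(nodes=nodes, volumes=vol, spacing=spacing,
                              phos_xyz=structure.phos_xyz.copy())


# ---------------------------------------------------------------------------
# mode sets
# ---------------------------------------------------------------------------

def n_modes(n_cells: int, max_bound: int) -> int:
    return sum(math.comb(n_cells, k) for k in range(min(max_bound, n_cells) + 1))


def enumerate_modes(region: TightlyBoundRegion, max_bound: int,
                    cap: int | None = None):
    """All modes with at most ``max_bound`` ions, one per cell at most."""
    n = region.n_cells
    if max_bound > n:
        raise ValueError("max_bound exceeds the number of cells")
    total = n_modes(n, max_bound)
    if cap is not None and total > cap:
        raise TooManyModes(f"{total} modes exceed the cap of {cap}; use sample_modes")
    out = []
    for k in range(max_bound + 1):
        for occ in itertools.combinations(range(n), k):
            counts = [0] * n
            for i in occ:
                counts[i] = 1
            out.append(BindingMode(counts=tuple(counts)))
    return out


def sample_modes(region: TightlyBoundRegion, single_energies, budget: int,
                 seed: int = 0, max_bound: int | None = None):
    """Landscape-guided reproducible mode sample.

    ``single_energies`` are the per-cell single-ion mode free energies (any
    consistent scale, k_B T); cells of low energy are favored when building
    multi-ion modes.  The empty mode and every single-ion mode are always
    included; the remainder of the budget is filled with distinct
    multi-ion modes drawn by weighted sampling without replacement.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    n = region.n_cells
    max_bound = n if max_bound is None else min(max_bound, n)
    total = n_modes(n, max_bound)
    if budget >= total:
        return enumerate_modes(region, max_bound)
    rng = np.random.default_rng(seed)
    e = np.asarray(single_energies, float)
    if len(e) != n:
        raise ValueError("need one single-ion energy per cell")
    logw = -(e - e.min())
    logw = np.clip(logw, -50.0, 0.0)
    p = np.exp(logw)
    p /= p.sum()
    modes = [BindingMode.empty(n)]
    for i in range(n):
        counts = [0] * n
        counts[i] = 1
        modes.append(BindingMode(counts=tuple(counts)))
    seen = {m.counts for m in modes}
    attempts = 0
    while len(modes) < budget and attempts < 200 * budget:
        attempts += 1
        k = int(rng.integers(2, max_bound + 1)) if max_bound >= 2 else 1
        occ = rng.choice(n, size=k, replace=False, p=p)
        counts = [0] * n
        for i in occ:
            counts[i] = 1
        key = tuple(counts)
        if key not in seen:
            seen.add(key)
            modes.append(BindingMode(counts=key))
    return modes[:budget] if len(modes) > budget else modes


# ---------------------------------------------------------------------------
# mode free energy
# ---------------------------------------------------------------------------

def _placement_energy(structure, positions, cond, config, pb_cache=None):
    """dG(R) (k_B T) and diagnostics for one set of bound-ion positions."""
    bound = [(tuple(p), 2.0) for p in positions]
    cfg = make_charge_config(structure, bound, config)
    gb = gb_energies(cfg, cond)
    key = None
    if pb_cache is not None:
        key = tuple(np.round(np.asarray(positions, float).ravel(), 2)) if len(positions) else ()
        key = (key, cond.c_na, cond.c_mg, cond.temperature_celsius)
    if key is not None and key in pb_cache:
        fld = pb_cache[key]
    else:
        fld = solve_nlpb(structure, bound, cond, config)
        if key is not None:
            pb_cache[key] = fld
    du_d, ds_d = diffusive_free_energy(fld, cond)
    comps = {
        "u_self": gb["u_self"],
        "u_pol": gb["u_pol"],
        "u_ele": gb["u_ele"],
        "u_d": du_d,
        "tds_d": ds_d,            # T dS_d in k_B T (enters as -tds_d)
    }
    total = gb["u_self"] + gb["u_pol"] + gb["u_ele"] + du_d - ds_d
    excess = fld.ion_excess()
    return total, comps, excess


def mode_free_energy(structure: RnaStructure, region: TightlyBoundRegion,
                     mode: BindingMode, cond: SolutionCondition,
                     n_samples: int | None = None, seed: int = 0,
                     config: TbiConfig | None = None,
                     pb_cache: dict | None = None) -> ModeEvaluation:
    """Position-averaged free energy of one binding mode.

    Bound ions are placed uniformly within their cells (Monte Carlo,
    seeded); dG_M = -kT ln < exp(-dG(R)/kT) > over placements, and the
    components are the Boltzmann-weighted placement averages.  The mode
    weight adds ln(n0_Mg V_cell) per occupied cell.
    """
    config = config or TbiConfig()
    if len(mode.counts) != region.n_cells:
        raise ValueError("mode length does not match the region")
    n_samples = n_samples if n_samples is not None else config.n_samples
    occ = mode.occupied
    rng = np.random.default_rng(seed)

    if not occ:
        total, comps, excess = _placement_energy(structure, [], cond, config, pb_cache)
        return ModeEvaluation(mode=mode, dG_M=total, components=comps,
                              log_weight=-total, n_position_samples=1,
                              ion_excess=excess)

    energies, comp_list, excess_list = [], [], []
    for _s in range(max(1, n_samples)):
        positions = [region.sample_position(c, rng) for c in occ]
        try:
            total, comps, excess = _placement_energy(structure, positions, cond,
                                                     config, pb_cache)
        except SolverError as err:
            logger.warning("placement discarded (PB failure: %s)", err)
            continue
        energies.append(total)
        comp_list.append(comps)
        excess_list.append(excess)
    if not energies:
        raise SolverError(f"all placements failed for mode {mode.counts}")
    e = np.array(energies)
    # exponential (free-energy) average over uniform placements
    log_mean = logsumexp(-e) - math.log(len(e))
    dG_M = -log_mean
    w = np.exp(-(e - e.min()))
    w /= w.sum()
    comps = {k: float(np.sum(w * np.array([c[k] for c in comp_list])))
             for k in comp_list[0]}
    excess = {k: float(np.sum(w * np.array([x[k] for x in excess_list])))
              for k in excess_list[0]}
    n0_mg = cond.c_mg * MOLAR_TO_PER_A3
    if n0_mg <= 0:
        log_pref = -np.inf
    else:
        log_pref = float(sum(math.log(n0_mg * region.volumes[c]) for c in occ))
    return ModeEvaluation(mode=mode, dG_M=dG_M, components=comps,
                          log_weight=log_pref - dG_M,
                          n_position_samples=len(e), ion_excess=excess)


def total_free_energy(evaluations, cond: SolutionCondition) -> TbiResult:
    """Assemble dG_tot, mode probabilities and the reported components.

    dG_tot = -kT ln sum_M w_M (log-sum-exp guarded); P_M = w_M / sum w_M;
    dE_ele, dG_pol, dG_self are the P_M-weighted component sums and dG_s is
    the remainder (diffusive-ion entropy plus tightly-bound combinatorial
    entropy).
    """
    evaluations = list(evaluations)
    if not evaluations:
        raise ValueError("no mode evaluations")
    if not any(ev.mode.n_bound == 0 for ev in evaluations):
        raise ValueError("the empty mode must be among the evaluations")
    logw = np.array([ev.log_weight for ev in evaluations])
    finite = np.isfinite(logw)
    lse = logsumexp(logw[finite])
    dG_tot = -lse
    probs = np.where(finite, np.exp(logw - lse), 0.0)
    for ev, p in zip(evaluations, probs):
        ev.probability = float(p)
    dE_ele = float(sum(ev.components["u_ele"] * ev.probability for ev in evaluations))
    dG_pol = float(sum(ev.components["u_pol"] * ev.probability for ev in evaluations))
    dG_self = float(sum(ev.components["u_self"] * ev.probability for ev in evaluations))
    dU_d = float(sum(ev.components["u_d"] * ev.probability for ev in evaluations))
    tds_d = float(sum(ev.components["tds_d"] * ev.probability for ev in evaluations))
    dG_s = dG_tot - (dE_ele + dG_pol + dG_self)
    best = min(evaluations,
               key=lambda ev: (-ev.log_weight, ev.mode.n_bound, ev.mode.counts))
    mean_bound = float(sum(ev.mode.n_bound * ev.probability for ev in evaluations))
    return TbiResult(dG_tot=float(dG_tot), dE_ele=dE_ele, dG_pol=dG_pol,
                     dG_self=dG_self, dG_s=dG_s, dU_d=dU_d, tds_d=tds_d,
                     evaluations=evaluations, most_probable=best.mode,
                     mean_bound=mean_bound)
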