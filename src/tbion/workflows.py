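"""End-user pipelines: single-structure runs, folding stability, ion uptake.

A single run orchestrates region construction, mode enumeration (or
landscape-guided sampling), per-mode evaluation and the final assembly of
free energies and binding fractions, then writes the ``.dat`` text report
(energies in k_B T, one row per nucleotide) with a ``.csv`` twin.

Folding stability follows the thermodynamic cycle: the Mg2+-induced
stabilization is the double difference

    ddG_Mg = [dG(F, Mg) - dG(F, 0)] - [dG(I, Mg) - dG(I, 0)]

between the folded structure F and the intermediate I, the latter usually
represented by an A-form helix whose free energy is rescaled by the
nucleotide-count ratio N_I / N_helix.  Ion uptake upon folding is the
difference of mean Mg2+ binding fractions f_F - f_I per nucleotide.
"""

from __future__ import annotations

import logging
import re
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .binding import BindingProfile, binding_fractions
from .config import TbiConfig
from .pb_solver import SolutionCondition
from .structures import RnaStructure
from .tbi_core import (BindingMode, TbiResult, TooManyModes, build_tb_region,
                       enumerate_modes, mode_free_energy, n_modes, sample_modes,
                       total_free_energy)

logger = logging.getLogger("tbion")

#: Mg2+ concentration grid (mol/L) used by the worked stability example.
DEFAULT_MG_GRID = (0.0, 5e-5, 1e-4, 5e-4, 1e-3, 5e-3, 1e-2)


@dataclass
class TbiRun:
    """A complete single-structure result: energies + binding profile."""

    result: TbiResult
    profile: BindingProfile
    cond: SolutionCondition
    structure: RnaStructure

    @property
    def dG_tot_kbt(self) -> float:
        return self.result.dG_tot

    @property
    def dG_tot_kcal(self) -> float:
        return self.result.dG_tot * self.cond.kbt


@dataclass
class StabilityResult:
    """ddG_Mg per concentration point, with the underlying curves."""

    c_mg: np.ndarray
    ddG_mg: np.ndarray          # kcal/mol
    dG_F: np.ndarray
    dG_I: np.ndarray


@dataclass
class UptakeResult:
    """Mg2+ uptake per nucleotide per concentration point."""

    c_mg: np.ndarray
    uptake: np.ndarray
    f_F: np.ndarray
    f_I: np.ndarray


# ---------------------------------------------------------------------------
# single-structure pipeline
# ---------------------------------------------------------------------------

def run_tbi(structure: RnaStructure, cond: SolutionCondition,
            config: TbiConfig | None = None, out_prefix: str | None = None,
            write_figures: bool = False) -> TbiRun:
    """Full TBI calculation for one structure at one ionic condition."""
    config = config or TbiConfig()
    config.log()
    pb_cache: dict = {}
    region = build_tb_region(structure, cond, config)
    n = region.n_cells

    def mode_seed(mode: BindingMode) -> int:
        # fingerprint-derived: the same mode draws the same placements at
        # every ionic condition, which removes sampling noise from
        # concentration-sweep comparisons
        return (config.seed * 1000003 + zlib.crc32(bytes(mode.counts))) % (2 ** 31)

    empty = mode_free_energy(structure, region, BindingMode.empty(n), cond,
                             n_samples=1, seed=config.seed, config=config,
                             pb_cache=pb_cache)
    evaluations = [empty]

    if cond.c_mg > 0 and n > 0:
        try:
            modes = enumerate_modes(region, min(config.max_bound, n),
                                    cap=config.mode_budget)
            modes = [m for m in modes if m.n_bound > 0]
        except TooManyModes:
            singles = []
            for i in range(n):
                counts = [0] * n
                counts[i] = 1
                singles.append(BindingMode(counts=tuple(counts)))
            single_evals = [
                mode_free_energy(structure, region, m, cond,
                                 n_samples=config.n_samples, seed=mode_seed(m),
                                 config=config, pb_cache=pb_cache)
                for m in singles
            ]
            e_single = [ev.dG_M for ev in single_evals]
            modes = sample_modes(region, e_single, config.mode_budget,
                                 seed=config.seed, max_bound=config.max_bound)
            done = {m.counts for m in singles} | {empty.mode.counts}
            evaluations.extend(single_evals)
            modes = [m for m in modes if m.counts not in done]
        for m in modes:
            evaluations.append(
                mode_free_energy(structure, region, m, cond,
                                 n_samples=config.n_samples, seed=mode_seed(m),
                                 config=config, pb_cache=pb_cache))

    result = total_free_energy(evaluations, cond)
    profile = binding_fractions(result.evaluations, structure, cond)
    run = TbiRun(result=result, profile=profile, cond=cond, structure=structure)
    if out_prefix:
        write_dat(run, f"{out_prefix}.dat")
        write_csv(run, f"{out_prefix}.csv")
        if write_figures:
            _write_figures(run, out_prefix)
    return run


# ---------------------------------------------------------------------------
# stability / uptake arithmetic
# ---------------------------------------------------------------------------

def scale_intermediate(dG_helix: float, n_I: int, n_helix: int) -> float:
    """Rescale a helix free energy to the intermediate's nucleotide count."""
    if n_I < 1 or n_helix < 1:
        raise ValueError("nucleotide counts must be positive")
    return dG_helix * n_I / n_helix


def _as_curve(curve):
    c = np.asarray([p[0] for p in curve], float)
    g = np.asarray([p[1] for p in curve], float)
    order = np.argsort(c)
    return c[order], g[order]


def folding_stability(dG_F_curve, dG_I_curve) -> StabilityResult:
    """Double-difference Mg2+-induced stability from two dG(c_Mg) curves.

    Both curves are sequences of (c_mg, dG) sharing the same concentration
    grid, which must contain c_mg = 0 (the reference of the cycle).
    """
    cF, gF = _as_curve(dG_F_curve)
    cI, gI = _as_curve(dG_I_curve)
    if len(cF) != len(cI) or not np.allclose(cF, cI):
        raise ValueError("folded and intermediate curves use different grids")
    if not np.any(cF == 0.0):
        raise ValueError("curves must include the zero-Mg2+ reference point")
    i0 = int(np.flatnonzero(cF == 0.0)[0])
    ddg = (gF - gF[i0]) - (gI - gI[i0])
    return StabilityResult(c_mg=cF, ddG_mg=ddg, dG_F=gF, dG_I=gI)


def ion_uptake(f_F_curve, f_I_curve) -> UptakeResult:
    """Mg2+ uptake per nucleotide: f_F - f_I on a shared grid."""
    cF, fF = _as_curve(f_F_curve)
    cI, fI = _as_curve(f_I_curve)
    if len(cF) != len(cI) or not np.allclose(cF, cI):
        raise ValueError("binding-fraction curves use different grids")
    return UptakeResult(c_mg=cF, uptake=fF - fI, f_F=fF, f_I=fI)


def stability_pipeline(folded: RnaStructure, helix: RnaStructure, n_I: int,
                       cond0: SolutionCondition, mg_grid=DEFAULT_MG_GRID,
                       config: TbiConfig | None = None) -> StabilityResult:
    """Run both structures over a Mg2+ grid and apply the cycle.

    The intermediate curve is the helix curve rescaled by n_I / N_helix;
    energies are reported in kcal/mol.
    """
    config = config or TbiConfig()
    curve_F, curve_I = [], []
    for c in mg_grid:
        cond = SolutionCondition(temperature_celsius=cond0.temperature_celsius,
                                 c_na=cond0.c_na, c_mg=c, eps_in=cond0.eps_in)
        gF = run_tbi(folded, cond, config).dG_tot_kcal
        gH = run_tbi(helix, cond, config).dG_tot_kcal
        curve_F.append((c, gF))
        curve_I.append((c, scale_intermediate(gH, n_I, helix.n_nucleotides)))
    return folding_stability(curve_F, curve_I)


def uptake_pipeline(folded: RnaStructure, intermediate: RnaStructure,
                    cond0: SolutionCondition, mg_grid=DEFAULT_MG_GRID,
                    config: TbiConfig | None = None) -> UptakeResult:
    """Binding-fraction curves for two structures and their difference."""
    config = config or TbiConfig()
    curve_F, curve_I = [], []
    for c in mg_grid:
        cond = SolutionCondition(temperature_celsius=cond0.temperature_celsius,
                                 c_na=cond0.c_na, c_mg=c, eps_in=cond0.eps_in)
        curve_F.append((c, run_tbi(folded, cond, config).profile.f_mg_total))
        curve_I.append((c, run_tbi(intermediate, cond, config).profile.f_mg_total))
    return ion_uptake(curve_F, curve_I)


# ---------------------------------------------------------------------------
# .dat report
# ---------------------------------------------------------------------------

_DAT_HEADER = """\
# TBI electrostatics result
# temperature  = {temp:.2f} C
# [Na+]        = {na:.6g} M
# [Mg2+]       = {mg:.6g} M
# energies in kBT (1 kBT = {kbt:.5f} kcal/mol)
#
# idx  res   f_Mg      f_Na      mode
"""

_DAT_TOTALS = """\
#
# dG_tot  = {dG_tot:.4f}
# dG_self = {dG_self:.4f}
# dG_pol  = {dG_pol:.4f}
# dE_ele  = {dE_ele:.4f}
# dG_s    = {dG_s:.4f}
"""


def format_dat(run: TbiRun, kcal: bool = False) -> str:
    """Render the per-nucleotide table and the totals block.

    Column 1: nucleotide index (renumbered 1..N); column 2: residue name;
    column 3: mean Mg2+ binding fraction; column 4: the (global) Na+
    binding fraction share; column 5: occupancy (0/1) in the most probable
    mode.  Totals are in k_B T unless ``kcal``.
    """
    cond = run.cond
    scale = cond.kbt if kcal else 1.0
    s = run.structure
    occ_per_nt = np.zeros(s.n_nucleotides, dtype=int)
    for cell in run.profile.most_probable_mode.occupied:
        occ_per_nt[s.phos_nt[cell] - 1] = 1
    text = _DAT_HEADER.format(temp=cond.temperature_celsius, na=cond.c_na,
                              mg=cond.c_mg, kbt=cond.kbt)
    if kcal:
        text = text.replace("energies in kBT", "energies in kcal/mol")
    for i in range(s.n_nucleotides):
        res = s.residue_names[i] if i < len(s.residue_names) else "N"
        text += (f"{i + 1:5d}  {res:>3s}  {run.profile.f_mg_per_nt[i]:8.5f}  "
                 f"{run.profile.f_na:8.5f}  {occ_per_nt[i]:4d}\n")
    r = run.result
    text += _DAT_TOTALS.format(dG_tot=r.dG_tot * scale, dG_self=r.dG_self * scale,
                               dG_pol=r.dG_pol * scale, dE_ele=r.dE_ele * scale,
                               dG_s=r.dG_s * scale)
    return text


def write_dat(run: TbiRun, path: str, kcal: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(format_dat(run, kcal=kcal))


def parse_dat(text: str) -> dict:
    """Re-parse a ``.dat`` report into rows and totals (round-trip aid)."""
    rows = []
    totals = {}
    for line in text.splitlines():
        m = re.match(r"#\s*(dG_tot|dG_self|dG_pol|dE_ele|dG_s)\s*=\s*([-\d.eE+]+)", line)
        if m:
            totals[m.group(1)] = float(m.group(2))
            continue
        m = re.match(r"\s*(\d+)\s+(\S+)\s+([-\d.eE+]+)\s+([-\d.eE+]+)\s+(\d+)\s*$", line)
        if m:
            rows.append({
                "idx": int(m.group(1)), "res": m.group(2),
                "f_mg": float(m.group(3)), "f_na": float(m.group(4)),
                "mode": int(m.group(5)),
            })
    return {"rows": rows, "totals": totals}


def write_csv(run: TbiRun, path: str) -> None:
    s = run.structure
    occ = np.zeros(s.n_nucleotides, dtype=int)
    for cell in run.profile.most_probable_mode.occupied:
        occ[s.phos_nt[cell] - 1] = 1
    df = pd.DataFrame({
        "idx": np.arange(1, s.n_nucleotides + 1),
        "res": s.residue_names,
        "f_mg": run.profile.f_mg_per_nt,
        "f_na": run.profile.f_na,
        "mode": occ,
    })
    df.to_csv(path, index=False)


def _write_figures(run: TbiRun, prefix: str) -> None:  # pragma: no cover
    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except Exception:
        logger.warning("matplotlib unavailable; figures skipped")
        return
    s = run.structure
    idx = np.arange(1, s.n_nucleotides + 1)
    fig, ax = plt.subplots(figsize=(7, 3))
    ax.bar(idx, run.profile.f_mg_per_nt, color="#2060a0")
    ax.set_xlabel("nucleotide")
    ax.set_ylabel("mean Mg$^{2+}$ fraction")
    fig.tight_layout()
    fig.savefig(f"{prefix}.eps")
    plt.close(fig)
    occ = np.zeros(s.n_nucleotides)
    for cell in run.profile.most_probable_mode.occupied:
        occ[s.phos_nt[cell] - 1] = 1
    fig, ax = plt.subplots(figsize=(7, 1.8))
    ax.imshow(occ[None, :], aspect="auto", cmap="Oranges", vmin=0, vmax=1)
    ax.set_yticks([])
    ax.set_xlabel("nucleotide (most probable mode occupancy)")
    fig.tight_layout()
    fig.savefig(f"{prefix}.site.eps")
    plt.close(fig)
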