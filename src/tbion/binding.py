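"""Per-nucleotide ion binding fractions and the most probable mode.

Mg2+ binds in two ways: as tightly bound ions (mode-resolved, per cell)
and as a diffusive excess in the PB ion atmosphere.  Per nucleotide i,

    fbar_b(i)  = sum_M N_b(i) P_M                     (tightly bound part)
    f_Mg(i)    = fbar_b(i) + (1/N) int [c_Mg - c0_Mg] dV
    f_Na       = (1/N) int [c_Na - c0_Na] dV

The diffusive excess integrals are evaluated per mode from its PB field
and P_M-averaged; the excess is shared uniformly over nucleotides (the
1/N), and a negative excess (depletion) is reported as computed.  Na+ is
never tightly bound: monovalent ions are too weakly correlated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structures import RnaStructure
from .tbi_core import BindingMode


@dataclass
class BindingProfile:
    """Binding fractions per nucleotide plus the most probable mode."""

    f_mg_per_nt: np.ndarray
    fbar_b_per_nt: np.ndarray
    f_na: float
    most_probable_mode: BindingMode
    mean_bound: float

    @property
    def f_mg_total(self) -> float:
        """Mean Mg2+ binding fraction per nucleotide (the f of the uptake
        tables): average of f_Mg(i) over nucleotides."""
        return float(np.mean(self.f_mg_per_nt))


def most_probable_mode(evaluations) -> BindingMode:
    """The evaluated mode of highest probability (lowest effective free
    energy); ties broken by fewer bound ions, then lexicographic order."""
    evaluations = list(evaluations)
    if not evaluations:
        raise ValueError("no evaluations")
    best = min(evaluations,
               key=lambda ev: (-ev.log_weight, ev.mode.n_bound, ev.mode.counts))
    return best.mode


def binding_fractions(evaluations, structure: RnaStructure, cond) -> BindingProfile:
    """Mode-averaged binding fractions (Eqs. of the model's binding layer).

    ``evaluations`` must carry normalized probabilities and per-mode
    diffusive ion excess counts (as produced by the core's mode
    evaluation + total assembly).
    """
    evaluations = list(evaluations)
    if not evaluations:
        raise ValueError("no evaluations")
    psum = sum(ev.probability for ev in evaluations)
    if not np.isclose(psum, 1.0, atol=1e-6):
        raise ValueError(f"mode probabilities not normalized (sum={psum})")
    n = structure.n_nucleotides
    fbar = np.zeros(n)
    for ev in evaluations:
        if ev.probability == 0.0:
            continue
        for cell in ev.mode.occupied:
            nt = structure.phos_nt[cell] - 1
            fbar[nt] += ev.probability
    excess_mg = sum(ev.ion_excess.get("MG", 0.0) * ev.probability for ev in evaluations)
    excess_na = sum(ev.ion_excess.get("NA", 0.0) * ev.probability for ev in evaluations)
    f_mg = fbar + excess_mg / n
    f_na = excess_na / n
    mean_bound = float(sum(ev.mode.n_bound * ev.probability for ev in evaluations))
    return BindingProfile(
        f_mg_per_nt=f_mg,
        fbar_b_per_nt=fbar,
        f_na=float(f_na),
        most_probable_mode=most_probable_mode(evaluations),
        mean_bound=mean_bound,
    )
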