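"""Run-time configuration: radii tables, grid parameters, sampling budgets.

Everything a user might legitimately want to change about the numerics lives
here, with the shipped defaults documented.  A :class:`TbiConfig` can be
loaded from / dumped to a YAML-style flat mapping so runs are reproducible
from a logged config block.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field

logger = logging.getLogger("tbion")

#: Bondi-style van der Waals radii (Angstrom) used for the dielectric
#: boundary and for intrinsic Born radii.  Overridable per config.
DEFAULT_RADII = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "P": 1.80,
    "S": 1.80,
    "MG": 0.65,
    "NA": 0.95,
    # generic fallback for anything else
    "*": 1.70,
}

#: Hydrated radii (Angstrom) of the mobile ions; set the Stern-like
#: ion-exclusion layer and the reference Born radius B0 of a bound ion.
DEFAULT_HYDRATED_RADII = {"NA": 3.5, "MG": 4.5, "CL": 3.5}


@dataclass
class TbiConfig:
    """Numerical and sampling parameters for a TBI calculation.

    Attributes
    ----------
    grid_spacing:
        Fine-level PB grid spacing in Angstrom.
    coarse_spacing:
        Coarse-level spacing for the focusing (outer) solve.
    padding_debye:
        Outer-box padding in units of the Debye length.
    padding_min:
        Minimum outer-box padding in Angstrom (used when the solution is
        nearly salt-free and the Debye length diverges).
    focus_margin:
        Margin (Angstrom) added around the structure for the fine box.
    pb_tol:
        Convergence threshold: max |delta psi| per sweep, in k_B T / e.
    pb_max_iter:
        Relaxation sweep cap before the solver reports non-convergence.
    t_shell:
        Thickness (Angstrom) of the tightly bound layer beyond the Mg2+
        contact surface.
    max_bound:
        Maximum number of simultaneously bound Mg2+ ions enumerated.
    mode_budget:
        Cap on the number of binding modes evaluated; above the exhaustive
        count, landscape-guided sampling is used instead of enumeration.
    n_samples:
        Monte-Carlo placements per bound ion per mode.
    """

    grid_spacing: float = 0.8
    coarse_spacing: float = 2.4
    padding_debye: float = 6.0
    padding_min: float = 12.0
    focus_margin: float = 12.0
    pb_tol: float = 1.0e-6
    pb_max_iter: int = 30000
    eps_in: float = 12.0
    t_shell: float = 3.0
    max_bound: int = 6
    mode_budget: int = 200
    n_samples: int = 20
    seed: int = 0
    radii: dict = field(default_factory=lambda: dict(DEFAULT_RADII))
    hydrated_radii: dict = field(default_factory=lambda: dict(DEFAULT_HYDRATED_RADII))

    def replace(self, **kw) -> "TbiConfig":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def log(self) -> None:
        """Log every numerical setting (the reproducibility contract)."""
        logger.info("TbiConfig: %s", json.dumps(self.to_dict(), sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict) -> "TbiConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


#: Preset that trades grid resolution for speed; used for concentration
#: sweeps where dozens of PB solves are needed.  Documented in the methods
#: note; results with it carry larger discretization error.
def sweep_preset(**overrides) -> TbiConfig:
    base = dict(
        grid_spacing=1.7,
        coarse_spacing=3.4,
        padding_debye=4.0,
        focus_margin=9.0,
        pb_tol=1.0e-5,
        max_bound=4,
        mode_budget=40,
        n_samples=2,
    )
    base.update(overrides)
    return TbiConfig(**base)
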