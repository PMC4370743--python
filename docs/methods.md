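# Methods

This note documents the model as implemented, the parameters that matter,
the numerical choices, and what the synthetic fixtures do and do not test.

## Model and assumptions

The molecule is a rigid RNA 3D structure with a coarse-grained charge
model: one point charge of −1 e at each phosphorus position. Partial
charges, ion dehydration, chelated (inner-sphere) binding, and ions other
than Na⁺/Mg²⁺ are outside the model; consequently the predicted most
probable Mg²⁺ binding mode reflects diffuse electrostatics and need not
coincide with crystallographically observed site-bound ions.

Mobile ions are Na⁺, Mg²⁺ and a neutralizing Cl⁻ at bulk concentration
c_Cl = c_Na + 2 c_Mg. Na⁺ and Cl⁻ are always treated at the mean-field
(PB) level: monovalent ions are weakly correlated. Mg²⁺ close to the RNA
surface is treated as *tightly bound*: the layer between the Mg²⁺ contact
surface and `t_shell` beyond it is partitioned into one cell per phosphate
(nearest-phosphate assignment), and a binding mode assigns 0 or 1 ions per
cell. The 0/1 cap matches the per-nucleotide occupancy reporting of the
output format.

For a mode M with bound-ion positions R, the energy relative to the
dispersed reference state is

    ΔG(R) = ΔU_self + ΔU_pol + ΔU_ele + ΔU_d − TΔS_d

with the first three terms generalized-Born (GB) energetics of the fixed
charges (phosphates + bound ions) and the last two the PB functionals of
the diffusive ions around that configuration. The mode weight is

    w_M = Π_occupied (n⁰_Mg · V_cell) · ⟨e^{−ΔG(R)/k_BT}⟩_R ,

the uniform in-cell position average times one fugacity/volume factor per
bound ion (the dimensionless reduction of the partition-function ratio
Z_M/Z^(id); the 2-cell brute-force oracle test pins this bookkeeping
down). Then ΔG_tot = −k_BT ln Σ_M w_M, P_M = w_M/Σ w_M, and the reported
components are P_M-weighted sums with the entropic component ΔG_s defined
by subtraction (it contains the diffusive-ion entropy and the
combinatorial entropy of the bound ions). The "mode free energy" that
ranks modes (most probable mode = largest w_M) therefore includes the
concentration term; the energy-only average −k_BT ln⟨e^{−ΔG}⟩ is stored
separately and equals the component sum within position-averaging
tolerance.

### Self-energy reference

All three GB terms are *differences* against the reference state in which
the interactions are absent. For the pair terms this is automatic (they
vanish at infinite separation). For the self term the package takes the
view that a phosphate, being covalently fixed in the structure, never
changes its solvation state: its Born radius is the same in the system and
in the reference, so its self term vanishes and only bound ions carry the
desolvation penalty ½(1/ε_w − 1/ε_in) q² (1/B − 1/B⁰), with B⁰ the
hydrated-ion radius. This is the only reading we found consistent with
the magnitude and sign of published absolute helix free energies;
alternatives (`phosphate_reference='intrinsic'` for a burial-desolvation
penalty, `'none'` for the bare q²/B sum) are implemented and unit-tested.
Note the bare q²/B sum is negative for ε_w > ε_in.

## Parameters (units, defaults, rationale)

| parameter | default | why |
|---|---|---|
| ε_in | 12 | standard nucleic-acid interior dielectric |
| ε_w(T) | cubic fit in T(°C) | 78.3 at 25 °C, 74.1 at 37 °C |
| atomic radii | Bondi-style table (config) | dielectric boundary + intrinsic Born radii |
| hydrated radii | Na⁺ 3.5 Å, Mg²⁺ 4.5 Å (config) | Stern-like exclusion; B⁰ of bound Mg²⁺ |
| t_shell | 3.0 Å | "thin layer" beyond the Mg²⁺ contact surface; the correlation-based criterion of the original theory is not reproduced here, so results should be quoted with this value |
| fine grid spacing | 0.8 Å | PB discretization around the RNA |
| outer padding | 6 Debye lengths (min 12 Å) | the ΔU_d functional involves the unscreened Ψ′ and needs this much box for <1% change on padding doubling |
| PB tolerance | max Δψ < 10⁻⁶ k_BT/e | relaxation convergence |
| max_bound / mode_budget | 6 / 200 | enumeration cap before landscape-guided sampling |
| n_samples | 20 | in-cell placements per bound ion per mode |
| Coulomb constant | 332.0637 kcal·Å/(mol·e²) | all unit conversions centralized |

Internal energies are k_BT; reporting converts with k_BT(37 °C) =
0.61633 kcal/mol.

## Numerics

**PB solver.** 7-point finite differences, harmonic-mean face dielectrics,
molecular region = atom-sphere union smoothed over one grid cell; ion
accessibility is a sharp mask at atom radius + hydrated ion radius
(smearing the mask would bias the mobile-ion integrands first-order,
because they are discontinuous at the Stern surface). Nonlinearity is
relaxed by red-black SOR where each node takes a damped Newton step on its
local residual (short ω = 1 warm-up, then near-optimal ω); a numba kernel
is used when available, with an equivalent vectorized numpy fallback.
Two-level focusing: a coarse solve over the padded box with screened-
Coulomb (Debye–Hückel superposition) Dirichlet boundaries feeds boundary
values to the fine solve around the molecule. Boxes are centered with odd
node counts so node placement does not shift with padding. Ψ′ solves the
identical fixed-charge/dielectric problem with all mobile terms off and
bare-Coulomb boundaries. Volume integrals combine the fine level with the
coarse level outside it. Validation: surface potential of an ion-excluded
sphere vs. the Debye–Hückel closed form (≤5%); linearized free energy vs.
the closed form including the exclusion-entropy term (≤2%); padding
doubling (<1%); mirror symmetry; far-field neutrality.

**Born radii.** Coulomb-field approximation: 1/B = 1/a − (1/4π)∫ r⁻⁴ dV
over the solute union outside the charge's own sphere, by grid quadrature
(0.6 Å) with 3³ sub-cell refinement near the singularity; exact for an
isolated sphere, validated against an independent 1D quadrature for a
two-sphere solute (≤2%) and the buried-charge limit B → R.

**Mode statistics.** Bound-ion placements are drawn uniformly from cell
quadrature nodes with in-cube jitter; the exponential (free-energy)
average over placements is used, per the position integral in the
partition function; components are Boltzmann-weighted placement averages.
Each mode's random stream is seeded from a CRC of its occupancy vector, so
the same mode re-draws the same placements at every ionic condition —
concentration sweeps then differ only through physics, not sampling noise.
When the enumeration count exceeds the budget, the sampler keeps the empty
and all single-ion modes and fills the budget with multi-ion modes drawn
with probabilities biased by the single-ion mode energies (a simple,
seeded stand-in for the energy-landscape-guided sampling of the original
method). PB fields are cached by bound-ion fingerprint within a run.

**Degenerate inputs.** Coincident charges raise errors (Coulomb/Born);
empty PDB input raises a structured error; unknown residues are skipped
with a warning; c_Mg = 0 short-circuits to the single empty mode (pure PB
+ GB of the bare RNA); budget ≥ mode count falls back to exhaustive
enumeration; ties in mode ranking prefer fewer bound ions, then
lexicographic cell order.

## Synthetic fixtures

`generate_aform_helix` builds an idealized A-form duplex from fibre-style
parameters (rise 2.81 Å/bp, twist 32.7°/bp, phosphate radius 9.4 Å) with
three pseudo-atoms per nucleotide (phosphate/ribose/base spheres) chosen
to fill a duplex-girth rod; strand 2 is the exact dyad image of strand 1,
so local geometry is independent of length. It emulates the size, charge
spacing and molecular volume of a real helix but not sequence-specific
atomic detail, grooved surface texture, or terminal fraying — tests that
pass on it validate the electrostatic machinery, not atomic-level realism.
The tiny one- and two-phosphate structures used in unit tests are
geometric probes only.

The full-structure checks against a 36-nt pseudoknot require the
experimental PDB entry (2TPK), which is not redistributable inside the
package; the corresponding test states where to place the file.

## Problem sizes used in the shipped checks

The default configuration (0.8 Å fine grid, 6-Debye padding) is used for
the single-structure helix checks (~3 s per PB solve). Concentration
sweeps use a documented coarse preset (1.7 Å fine grid, 4-Debye padding,
mode budget 40, 2 placements/mode) — these sizes keep a 7-point Mg²⁺ sweep
of the 24-nt helix to a few minutes while preserving the monotone trends
being tested; absolute energies under the coarse preset carry ~1–2
kcal/mol discretization offsets relative to the default grid.

## Known limitations

* The tightly-bound/diffusive split uses a geometric shell (`t_shell`),
  not the correlation-strength criterion of the original theory.
* The Coulomb-field approximation underestimates Born radii in deep
  crevices; radii are swappable behind `born_radii_from_geometry`.
* One ion per cell: very high [Mg²⁺] regimes with multiple ions per
  phosphate cell are outside the sampled mode space.
* Mode sampling beyond singles is heuristic; for N ≳ 40 phosphates the
  budget should be raised for converged multi-ion statistics.
* The diffusive-excess contribution to per-nucleotide fractions is shared
  uniformly (1/N) over nucleotides, as the binding-fraction definition
  prescribes, not assigned by proximity.
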