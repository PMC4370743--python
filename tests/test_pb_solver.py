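"""PB solver: dielectric model, analytic limits, free-energy functionals."""

import numpy as np
import pytest
from scipy.ndimage import map_coordinates

from tbion import (SolutionCondition, TbiConfig, dielectric_of_water,
                   diffusive_free_energy, solve_fixed_charges, solve_nlpb)
from tbion.pb_solver import GridLevel, PbField


class TestDielectricOfWater:
    @pytest.mark.parametrize("t, expected", [
        (0.0, 87.740),
        (25.0, 78.285),       # "~78 at room temperature"
        (37.0, 74.126),
    ])
    def test_values(self, t, expected):
        assert dielectric_of_water(t) == pytest.approx(expected, abs=5e-4)

    @pytest.mark.parametrize("t", [-5.0, 101.0])
    def test_out_of_range(self, t):
        with pytest.raises(ValueError):
            dielectric_of_water(t)


class TestSolutionCondition:
    def test_neutralizing_chloride(self):
        c = SolutionCondition(c_na=0.1, c_mg=0.01)
        assert c.c_cl == pytest.approx(0.12)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            SolutionCondition(c_na=-0.1)

    def test_debye_length_scale(self):
        c = SolutionCondition(temperature_celsius=25, c_na=0.1, c_mg=0.0)
        # ~9.6 A in 0.1 M 1:1 salt at room temperature
        assert c.debye_length == pytest.approx(9.6, abs=0.3)


def _dh_config(h, **kw):
    base = dict(grid_spacing=h, coarse_spacing=3 * h, padding_debye=3.0,
                padding_min=12.0, focus_margin=8.0,
                hydrated_radii={"NA": 1e-6, "MG": 1e-6, "CL": 1e-6})
    base.update(kw)
    return TbiConfig(**base)


def _surface_potential(fld, a, kappa):
    """Extrapolate psi(r) e^{kappa(r-a)} r / a back to the surface from
    outside, avoiding interpolation across the dielectric jump."""
    lev = fld.fine
    vals = []
    for rr in (a + 1.0, a + 1.5, a + 2.0):
        dirs = np.array([[1, 0, 0], [0, 1, 0], [0, 0, 1],
                         [-1, 0, 0], [0.57735, 0.57735, 0.57735]])
        pts = rr * dirs
        coords = [(pts[:, k] - lev.origin[k]) / lev.spacing for k in range(3)]
        psi_r = map_coordinates(lev.psi, coords, order=1).mean()
        vals.append(psi_r * np.exp(kappa * (rr - a)) * rr / a)
    return float(np.mean(vals))


class TestDebyeHuckelSphere:
    def test_surface_potential(self):
        """-1e in an ion-excluded sphere at low charge density: surface
        potential matches q l_B / (eps_w a (1 + kappa a)) within 5%."""
        cond = SolutionCondition(temperature_celsius=25, c_na=0.05, c_mg=0.0)
        a, q = 2.0, -0.2
        fld = solve_fixed_charges([[0, 0, 0]], [a], [[0, 0, 0]], [q], cond,
                                  _dh_config(0.4))
        analytic = q * cond.bjerrum / (cond.eps_w * a * (1 + cond.kappa * a))
        psi_a = _surface_potential(fld, a, cond.kappa)
        assert psi_a == pytest.approx(analytic, rel=0.05)

    def test_linearized_free_energy(self):
        """Small-potential diffusive free energy matches the closed form:
        ion-atmosphere charging energy plus the exclusion-entropy term."""
        cond = SolutionCondition(temperature_celsius=25, c_na=0.05, c_mg=0.0)
        a, q = 2.0, -0.05
        fld = solve_fixed_charges([[0, 0, 0]], [a], [[0, 0, 0]], [q], cond,
                                  _dh_config(0.3))
        du, ds = diffusive_free_energy(fld, cond)
        g_atm = -q * q * cond.bjerrum / cond.eps_w * cond.kappa / (2 * (1 + cond.kappa * a))
        n_tot = sum(n for _, _, n in cond.species)
        g_excl = n_tot * 4.0 / 3.0 * np.pi * a ** 3
        assert du - ds == pytest.approx(g_atm + g_excl, rel=0.02)

    def test_padding_insensitivity(self):
        """Doubling the outer-box padding changes dU_d by < 1% at the
        default padding (6 Debye lengths)."""
        cond = SolutionCondition(temperature_celsius=25, c_na=0.2, c_mg=0.0)
        res = []
        for pd in (6.0, 12.0):
            fld = solve_fixed_charges([[0, 0, 0]], [2.0], [[0, 0, 0]], [-0.5],
                                      cond, _dh_config(0.6, padding_debye=pd))
            du, _ = diffusive_free_energy(fld, cond)
            res.append(du)
        assert res[1] == pytest.approx(res[0], rel=0.01)


class TestSolverBasics:
    def test_zero_charge_flat_field(self):
        cond = SolutionCondition(temperature_celsius=25, c_na=0.05, c_mg=0.0)
        fld = solve_fixed_charges([[0, 0, 0]], [2.0], [[0, 0, 0]], [0.0], cond,
                                  _dh_config(0.6))
        lev = fld.fine
        assert np.abs(lev.psi).max() < 1e-8
        conc = fld.concentrations(lev)
        n0 = cond.densities()["NA"]
        acc = lev.acc1.astype(bool)
        np.testing.assert_allclose(conc["NA"][acc], n0, rtol=1e-9)
        assert np.all(conc["NA"][~acc] == 0.0)

    def test_mirror_symmetry(self):
        """Charges mirrored through a plane give a mirrored potential."""
        cond = SolutionCondition(temperature_celsius=25, c_na=0.1, c_mg=0.0)
        cfg = _dh_config(0.6)
        xyz = [[0, 0, -4.0], [0, 0, 4.0]]
        fld = solve_fixed_charges(xyz, [2.0, 2.0], xyz, [-1.0, -1.0], cond, cfg)
        lev = fld.fine
        rng = np.random.default_rng(3)
        pts = rng.uniform(-8, 8, size=(40, 3))
        mirrored = pts * [1, 1, -1]
        def sample(p):
            coords = [(p[:, k] - lev.origin[k]) / lev.spacing for k in range(3)]
            return map_coordinates(lev.psi, coords, order=1)
        a, b = sample(pts), sample(mirrored)
        np.testing.assert_allclose(a, b, atol=1e-6 * max(1.0, np.abs(a).max()))

    def test_far_field_neutrality(self, helix2, coarse_config):
        """Net mobile charge density -> ~0 far from the solute."""
        cond = SolutionCondition(temperature_celsius=25, c_na=0.1, c_mg=0.001)
        fld = solve_nlpb(helix2, None, cond, coarse_config.replace(padding_debye=6.0))
        coarse = fld.levels[0]
        conc = fld.concentrations(coarse)
        net = conc["NA"] - conc["CL"] + 2 * conc["MG"]
        n0 = cond.densities()["NA"]
        # outer shell of the coarse box
        edge = np.zeros(coarse.shape, dtype=bool)
        edge[0, :, :] = edge[-1, :, :] = True
        edge[:, 0, :] = edge[:, -1, :] = True
        assert np.abs(net[edge]).max() < 2e-2 * n0


class TestDiffusiveFreeEnergy:
    def _flat_field(self, cond, nacc=True):
        shape = (6, 6, 6)
        lev = GridLevel(origin=np.zeros(3), spacing=2.0, shape=shape)
        lev.psi = np.zeros(shape)
        lev.psi_prime = np.zeros(shape)
        a = np.ones(shape) if nacc else np.zeros(shape)
        lev.acc1 = a
        lev.acc2 = a.copy()
        lev.weight = np.ones(shape, dtype=bool)
        return PbField(levels=[lev], cond=cond)

    def test_uniform_concentration_zero(self):
        """c == c0 and Psi == Psi' == 0 annihilate both functionals."""
        cond = SolutionCondition(temperature_celsius=25, c_na=0.1, c_mg=0.01)
        du, ds = diffusive_free_energy(self._flat_field(cond))
        assert du == 0.0
        assert ds == pytest.approx(0.0, abs=1e-15)

    def test_full_exclusion_entropy(self):
        """c == 0 everywhere gives -T dS = sum_a c0_a V (bracketed form)."""
        cond = SolutionCondition(temperature_celsius=25, c_na=0.1, c_mg=0.01)
        fld = self._flat_field(cond, nacc=False)
        du, ds = diffusive_free_energy(fld)
        vol = (2.0 ** 3) * 6 ** 3
        expected = vol * sum(n for _, _, n in cond.species)
        assert du == 0.0
        assert -ds == pytest.approx(expected, rel=1e-12)

    def test_entropy_term_nonnegative(self, helix2, coarse_config):
        cond = SolutionCondition(temperature_celsius=37, c_na=0.1, c_mg=0.005)
        fld = solve_nlpb(helix2, None, cond, coarse_config)
        du, ds = diffusive_free_energy(fld, cond)
        assert -ds >= 0.0
        assert du < 0.0  # counterion attraction dominates for bare RNA
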