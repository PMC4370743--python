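"""Tightly bound region, mode enumeration/sampling, and mode statistics."""

import math

import numpy as np
import pytest

from tbion import (BindingMode, ModeEvaluation, SolutionCondition, TbiConfig,
                   TooManyModes, build_tb_region, enumerate_modes,
                   mode_free_energy, sample_modes, total_free_energy)
from tbion.tbi_core import n_modes


class TestRegion:
    def test_single_phosphate_shell_volume(self, single_phosphate):
        """One isolated phosphate: cell volume matches the closed-form
        spherical shell between contact and contact + t_shell."""
        cfg = TbiConfig(t_shell=3.0)
        region = build_tb_region(single_phosphate, config=cfg)
        assert region.n_cells == 1
        r_in = 2.1 + 4.5
        r_out = r_in + 3.0
        expected = 4.0 / 3.0 * math.pi * (r_out ** 3 - r_in ** 3)
        assert region.volumes[0] == pytest.approx(expected, rel=0.04)

    def test_two_far_phosphates_equal_cells(self):
        from tbion import RnaStructure
        xyz = np.array([[0.0, 0, 0], [60.0, 0, 0]])
        s = RnaStructure(elements=["P", "P"], atom_nt=np.array([1, 2]),
                         atom_xyz=xyz, atom_radius=np.array([2.1, 2.1]),
                         phos_nt=np.array([1, 2]), phos_xyz=xyz.copy(),
                         n_nucleotides=2)
        region = build_tb_region(s)
        assert region.n_cells == 2
        assert region.volumes[0] == pytest.approx(region.volumes[1], rel=0.02)

    def test_helix_cells_positive_and_disjoint(self, helix12):
        region = build_tb_region(helix12)
        assert region.n_cells == 24
        assert np.all(region.volumes > 0)
        # disjoint partition: no node belongs to two cells
        total = sum(len(n) for n in region.nodes)
        allpts = np.vstack([n for n in region.nodes if len(n)])
        assert len(np.unique(np.round(allpts, 6), axis=0)) == total


class TestModeEnumeration:
    def test_two_cells_four_modes(self, two_phosphates):
        region = build_tb_region(two_phosphates)
        modes = enumerate_modes(region, 2)
        assert sorted(m.counts for m in modes) == [(0, 0), (0, 1), (1, 0), (1, 1)]

    def test_binomial_count(self):
        assert n_modes(4, 2) == 11      # 1 + 4 + 6
        assert n_modes(24, 0) == 1

    def test_max_bound_zero(self, two_phosphates):
        region = build_tb_region(two_phosphates)
        modes = enumerate_modes(region, 0)
        assert [m.counts for m in modes] == [(0, 0)]

    def test_cap_guard(self, helix12):
        region = build_tb_region(helix12)
        with pytest.raises(TooManyModes):
            enumerate_modes(region, 4, cap=50)


class TestModeSampling:
    def _region(self, n):
        class Stub:
            n_cells = n
            volumes = np.full(n, 100.0)
        return Stub()

    def test_fallback_to_enumeration(self, two_phosphates):
        region = build_tb_region(two_phosphates)
        modes = sample_modes(region, [0.0, 0.0], budget=100, seed=1)
        assert sorted(m.counts for m in modes) == [(0, 0), (0, 1), (1, 0), (1, 1)]

    def test_seed_determinism(self):
        region = self._region(8)
        e = np.arange(8, dtype=float)
        a = sample_modes(region, e, budget=15, seed=42)
        b = sample_modes(region, e, budget=15, seed=42)
        assert [m.counts for m in a] == [m.counts for m in b]

    def test_always_includes_empty_and_singles(self):
        region = self._region(6)
        modes = sample_modes(region, np.zeros(6), budget=10, seed=0)
        counts = {m.counts for m in modes}
        assert (0,) * 6 in counts
        for i in range(6):
            c = [0] * 6
            c[i] = 1
            assert tuple(c) in counts

    def test_favorable_cell_dominates_sample(self):
        """A deeply favorable cell appears in the sampled multi-ion modes."""
        region = self._region(6)
        e = np.array([0.0, 0.0, -25.0, 0.0, 0.0, 0.0])
        modes = sample_modes(region, e, budget=12, seed=3)
        multi = [m for m in modes if m.n_bound >= 2]
        assert multi
        assert all(m.counts[2] == 1 for m in multi)


def _ev(counts, dg, logw=None):
    return ModeEvaluation(mode=BindingMode(counts=tuple(counts)), dG_M=dg,
                          components={"u_ele": 0.0, "u_pol": 0.0, "u_self": 0.0,
                                      "u_d": 0.0, "tds_d": 0.0},
                          log_weight=(-dg if logw is None else logw),
                          n_position_samples=1)


class TestTotalFreeEnergy:
    def test_single_mode(self):
        cond = SolutionCondition()
        res = total_free_energy([_ev((0, 0), 5.0)], cond)
        assert res.dG_tot == pytest.approx(5.0)
        assert res.evaluations[0].probability == pytest.approx(1.0)

    def test_two_equal_modes_ln2(self):
        """Equal weights: dG_tot = dG - kT ln 2 and P = 1/2 each."""
        cond = SolutionCondition()
        res = total_free_energy([_ev((0, 0), 5.0), _ev((1, 0), 5.0)], cond)
        assert res.dG_tot == pytest.approx(5.0 - math.log(2.0))
        for ev in res.evaluations:
            assert ev.probability == pytest.approx(0.5)

    def test_probabilities_normalized(self):
        cond = SolutionCondition()
        evs = [_ev((0, 0, 0), 1.0), _ev((1, 0, 0), 3.0), _ev((0, 1, 0), -2.0)]
        res = total_free_energy(evs, cond)
        assert sum(e.probability for e in res.evaluations) == pytest.approx(1.0)

    def test_adding_mode_never_raises_dG(self):
        cond = SolutionCondition()
        evs = [_ev((0, 0), 2.0)]
        g1 = total_free_energy(list(evs), cond).dG_tot
        evs.append(_ev((0, 1), 30.0))
        g2 = total_free_energy(evs, cond).dG_tot
        assert g2 <= g1
        assert g2 <= min(2.0, 30.0)

    def test_component_sum_identity(self):
        """dG_s + dE_ele + dG_pol + dG_self = dG_tot by construction."""
        cond = SolutionCondition()
        evs = [_ev((0,), 1.0), _ev((1,), 0.5)]
        evs[0].components.update({"u_ele": 3.0, "u_pol": -1.0, "u_self": 0.3})
        evs[1].components.update({"u_ele": 2.0, "u_pol": -0.5, "u_self": 0.1})
        res = total_free_energy(evs, cond)
        assert res.dG_s + res.dE_ele + res.dG_pol + res.dG_self == pytest.approx(res.dG_tot)

    def test_requires_empty_mode(self):
        cond = SolutionCondition()
        with pytest.raises(ValueError):
            total_free_energy([_ev((1, 0), 1.0)], cond)


class TestModeFreeEnergy:
    def test_empty_mode_is_single_pb_evaluation(self, two_phosphates, coarse_config):
        cond = SolutionCondition(temperature_celsius=25, c_na=0.1, c_mg=0.005)
        region = build_tb_region(two_phosphates, cond, coarse_config)
        ev = mode_free_energy(two_phosphates, region, BindingMode.empty(2),
                              cond, config=coarse_config)
        assert ev.n_position_samples == 1
        assert ev.mode.n_bound == 0
        # empty mode: energy part equals component sum exactly
        c = ev.components
        assert ev.dG_M == pytest.approx(
            c["u_self"] + c["u_pol"] + c["u_ele"] + c["u_d"] - c["tds_d"])
        assert ev.log_weight == pytest.approx(-ev.dG_M)

    def test_single_placement_determinism(self, two_phosphates, coarse_config):
        cond = SolutionCondition(temperature_celsius=25, c_na=0.1, c_mg=0.005)
        region = build_tb_region(two_phosphates, cond, coarse_config)
        mode = BindingMode(counts=(1, 0))
        a = mode_free_energy(two_phosphates, region, mode, cond, n_samples=1,
                             seed=5, config=coarse_config)
        b = mode_free_energy(two_phosphates, region, mode, cond, n_samples=1,
                             seed=5, config=coarse_config)
        assert a.dG_M == b.dG_M
        # with one placement the exponential average is exact
        c = a.components
        assert a.dG_M == pytest.approx(
            c["u_self"] + c["u_pol"] + c["u_ele"] + c["u_d"] - c["tds_d"])

    def test_bound_ion_desolvation_and_attraction(self, two_phosphates, coarse_config):
        """A bound Mg2+ near a phosphate: strong Coulomb attraction at
        eps_in, positive desolvation self term."""
        cond = SolutionCondition(temperature_celsius=25, c_na=0.1, c_mg=0.005)
        region = build_tb_region(two_phosphates, cond, coarse_config)
        ev = mode_free_energy(two_phosphates, region, BindingMode(counts=(1, 0)),
                              cond, n_samples=2, seed=0, config=coarse_config)
        assert ev.components["u_ele"] < 0
        assert ev.components["u_self"] > 0
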